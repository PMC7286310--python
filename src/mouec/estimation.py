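"""Estimation of MOU effective connectivity from spatiotemporal covariances.

The fitting target is the pair of empirical covariance matrices of the ROI
signals: FC0 (zero lag) and FC1 (lag of one sampling period).  The Lyapunov
optimization ("natural" gradient descent) iteratively adjusts the EC weights
``C`` on the structural mask and the diagonal input covariance ``Sigma`` so
that the model's theoretical Q0/Q1 reproduce FC0/FC1, stopping at the
minimum model error.  A symmetric heuristic variant fits FC0 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as spl

from .model import (
    MouParameters,
    SignalSession,
    StructuralMask,
    UnstableModelError,
    build_jacobian,
    is_stable,
    theoretical_cov0,
    theoretical_cov_lagged,
)

logger = logging.getLogger("mouec")

#: Condition number of FC0 above which a quasi-singular warning is logged.
CONDITION_WARN = 1e8

#: Ridge jitter scale applied to a quasi-singular FC0 before inversion.
RIDGE_JITTER = 1e-6


@dataclass
class SpatioTemporalCovariance:
    """Zero-lag and lagged covariance matrices of a session (FC0, FC1).

    ``q1[i, j]`` is cov(x_i(t), x_j(t + lag)); rows index the earlier time.
    """

    q0: np.ndarray
    q1: np.ndarray
    lag: float  # seconds
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.q0 = np.asarray(self.q0, dtype=float)
        self.q1 = np.asarray(self.q1, dtype=float)
        if self.q0.shape != self.q1.shape or self.q0.ndim != 2:
            raise ValueError("q0 and q1 must be square matrices of equal shape")
        if not (np.all(np.isfinite(self.q0)) and np.all(np.isfinite(self.q1))):
            raise ValueError("covariances must be finite")
        if not np.allclose(self.q0, self.q0.T, atol=1e-12 * max(1.0, abs(self.q0).max())):
            raise ValueError("q0 must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.q0.shape[0]


@dataclass
class FitHyperparams:
    """Hyperparameters of the Lyapunov optimization.

    ``rate_c`` is the EC learning rate: for the gradient fit it is the
    Adam-style step size (dimensionless, per-weight normalized); for the
    heuristic fit it multiplies the raw covariance mismatch and defaults to
    ``1e-4 * N``.  ``rate_sigma`` is the relaxation weight of the Sigma
    moment-matching update in the gradient fit (1 = exact each iteration)
    and the Sigma learning rate of the heuristic fit.
    """

    rate_c: float | None = None
    rate_sigma: float | None = None
    max_iter: int = 10000
    patience: int = 300
    sigma_min: float = 1e-6
    c_max: float | None = None

    def resolved(
        self, n_rois: int, method: str = "gradient"
    ) -> "FitHyperparams":
        if method == "gradient":
            rate_c = self.rate_c if self.rate_c is not None else 2e-3
            rate_sigma = self.rate_sigma if self.rate_sigma is not None else 1.0
        else:
            rate_c = self.rate_c if self.rate_c is not None else 1e-4 * n_rois
            rate_sigma = (
                self.rate_sigma if self.rate_sigma is not None else 0.1 * rate_c
            )
        if rate_c <= 0 or rate_sigma <= 0 or self.max_iter <= 0 or self.patience <= 0:
            raise ValueError("all hyperparameters must be positive")
        if self.patience > self.max_iter:
            raise ValueError("patience must not exceed max_iter")
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be positive")
        return FitHyperparams(
            rate_c=rate_c,
            rate_sigma=rate_sigma,
            max_iter=self.max_iter,
            patience=self.patience,
            sigma_min=self.sigma_min,
            c_max=self.c_max,
        )


@dataclass
class FitResult:
    """Outcome of a MOU fit: best parameters and the error trajectory."""

    params: MouParameters
    error_history: np.ndarray
    best_error: float
    best_iteration: int
    converged: bool
    hyperparams: FitHyperparams = field(default_factory=FitHyperparams)
    method: str = "gradient"


def empirical_covariances(
    session: SignalSession, lag_tr: int = 1
) -> SpatioTemporalCovariance:
    """Empirical FC0/FC1 of a session.

    Each ROI row is demeaned over the session; both covariances are computed
    on the overlapping window of T - lag points with denominator
    T - lag - 1, so the pair is mutually consistent; FC0 is symmetrized.
    """
    t_len = session.n_timepoints
    if t_len < lag_tr + 2:
        raise ValueError(
            f"session too short: T={t_len} needs at least lag+2={lag_tr + 2} points"
        )
    x = session.data - session.data.mean(axis=1, keepdims=True)
    x0 = x[:, : t_len - lag_tr]
    x1 = x[:, lag_tr:]
    denom = t_len - lag_tr - 1
    q0 = x0 @ x0.T / denom
    q0 = (q0 + q0.T) / 2
    q1 = x0 @ x1.T / denom
    cond = np.linalg.cond(q0)
    if cond > CONDITION_WARN:
        logger.warning(
            "empirical FC0 is quasi-singular (condition number %.3g)", cond
        )
    return SpatioTemporalCovariance(
        q0=q0, q1=q1, lag=lag_tr * session.tr, n_samples=t_len
    )


def tau_from_autocovariances(autocov: np.ndarray, tr: float) -> float:
    """Pool per-ROI autocovariance decays into one leakage time constant.

    ``autocov`` has one row per ROI and one column per lag (0..L, in TR
    steps).  For each ROI with strictly positive autocovariances, the log
    autocovariance is regressed linearly against the lag in seconds;
    tau = -1 / mean(slopes).  ROIs with a non-positive value at any lag are
    excluded (logged).
    """
    autocov = np.atleast_2d(np.asarray(autocov, dtype=float))
    lags_s = np.arange(autocov.shape[1]) * tr
    slopes = []
    excluded = []
    for i, ac in enumerate(autocov):
        if np.any(ac <= 0):
            excluded.append(i)
            continue
        slopes.append(np.polyfit(lags_s, np.log(ac), 1)[0])
    if excluded:
        logger.info(
            "estimate_tau: excluded %d ROI(s) with non-positive autocovariance: %s",
            len(excluded),
            excluded,
        )
    if not slopes:
        raise ValueError("all ROIs excluded: no positive autocovariance decay to fit")
    mean_slope = float(np.mean(slopes))
    if mean_slope >= 0:
        raise ValueError(
            f"mean log-autocovariance slope {mean_slope:.3g} is nonnegative; "
            "no exponential decay to invert"
        )
    return -1.0 / mean_slope


def estimate_tau(session: SignalSession, max_lag_tr: int = 2) -> float:
    """Estimate the global leakage time constant from autocovariance decay.

    Computes each ROI's autocovariance at lags 0..max_lag_tr and pools the
    log-linear decay slopes via :func:`tau_from_autocovariances`.
    """
    t_len = session.n_timepoints
    if t_len < max_lag_tr + 2:
        raise ValueError("session too short for the requested maximum lag")
    x = session.data - session.data.mean(axis=1, keepdims=True)
    autocov = np.array(
        [
            [
                np.dot(x[i, : t_len - k], x[i, k:]) / (t_len - k)
                for k in range(max_lag_tr + 1)
            ]
            for i in range(session.n_rois)
        ]
    )
    return tau_from_autocovariances(autocov, session.tr)


def model_error(target: SpatioTemporalCovariance, params: MouParameters) -> float:
    """Normalized distance between model and empirical covariances.

    E = (||FC0 - Q0||_F / ||FC0||_F + ||FC1 - Q1||_F / ||FC1||_F) / 2;
    zero iff the model reproduces both matrices exactly.
    """
    q0 = theoretical_cov0(params)
    q1 = theoretical_cov_lagged(params, target.lag)
    return 0.5 * (
        np.linalg.norm(target.q0 - q0) / np.linalg.norm(target.q0)
        + np.linalg.norm(target.q1 - q1) / np.linalg.norm(target.q1)
    )


def _maybe_jitter(q0: np.ndarray) -> np.ndarray:
    if np.linalg.cond(q0) > CONDITION_WARN:
        jitter = RIDGE_JITTER * np.mean(np.diag(q0))
        logger.warning(
            "quasi-singular FC0: adding ridge jitter %.3g before inversion", jitter
        )
        return q0 + jitter * np.eye(q0.shape[0])
    return q0


def fit_mou_gradient(
    target: SpatioTemporalCovariance,
    mask: StructuralMask,
    tau: float,
    hp: FitHyperparams | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit EC and Sigma by gradient descent on the (FC0, FC1) mismatch.

    The loss is the squared normalized covariance mismatch
    ``||dQ0||^2/||q0||^2 + ||dQ1||^2/||q1||^2``.  Its exact gradient with
    respect to the EC weights is computed by the adjoint method: one
    Lyapunov solve gives the model Q0, a second (adjoint) Lyapunov solve
    propagates the mismatch back through the stationarity equation, and the
    Frechet derivative of the matrix exponential handles the lagged term.
    Steps use per-weight adaptive moments (Adam), are restricted to the
    masked off-diagonal entries and clipped to [0, c_max]; Sigma is updated
    by moment matching (the diagonal of ``-(J q0 + q0 J^T)``, floored at
    ``sigma_min``, relaxed by ``rate_sigma``).  The model error E (mean of
    the two normalized Frobenius mismatches) is tracked each iteration and
    the parameters at its minimum are returned; the loop stops at max_iter
    or after ``patience`` non-improving iterations.  If a step destabilizes
    the Jacobian the best state is restored and the rate halved (fails
    after 5 halvings).

    ``seed`` is reserved for optional jittered restarts; the default fit is
    deterministic (C starts at zero, Sigma at the decoupled closed form).
    """
    if mask.n_rois != target.n_rois:
        raise ValueError("mask and target dimensions differ")
    hp = (hp or FitHyperparams()).resolved(target.n_rois, "gradient")
    q0_emp = _maybe_jitter(target.q0)
    q1_emp = target.q1
    lag = target.lag
    n = target.n_rois
    norm0 = np.linalg.norm(q0_emp)
    norm1 = np.linalg.norm(q1_emp)
    if norm0 == 0 or norm1 == 0:
        raise ValueError("empirical covariances are identically zero")
    a_w, b_w = 1.0 / norm0**2, 1.0 / norm1**2

    c_cur = np.zeros((n, n))
    sigma_cur = np.clip(2.0 * np.diag(q0_emp) / tau, hp.sigma_min, None)
    off_mask = mask.mask & ~np.eye(n, dtype=bool)
    eye = np.eye(n)

    lr = hp.rate_c
    mom = np.zeros((n, n))
    vel = np.zeros((n, n))
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    errors: list[float] = []
    best_error = np.inf
    best_c = c_cur.copy()
    best_sigma = sigma_cur.copy()
    best_iter = 0
    halvings = 0
    since_best = 0

    for it in range(hp.max_iter):
        jac = -eye / tau + c_cur.T
        # Sigma by moment matching: stationarity of the empirical q0 under
        # the current Jacobian fixes the input variances
        sigma_target = np.clip(
            -np.diag(jac @ q0_emp + q0_emp @ jac.T), hp.sigma_min, None
        )
        sigma_cur = sigma_cur + hp.rate_sigma * (sigma_target - sigma_cur)
        q0_mod = spl.solve_continuous_lyapunov(jac, -np.diag(sigma_cur))
        q0_mod = (q0_mod + q0_mod.T) / 2
        expm_lag = spl.expm(jac.T * lag)
        q1_mod = q0_mod @ expm_lag
        dq0 = q0_emp - q0_mod
        dq1 = q1_emp - q1_mod
        err = 0.5 * (np.linalg.norm(dq0) / norm0 + np.linalg.norm(dq1) / norm1)
        errors.append(err)
        if err < best_error:
            best_error = err
            best_c = c_cur.copy()
            best_sigma = sigma_cur.copy()
            best_iter = it
            since_best = 0
        else:
            since_best += 1
            if since_best >= hp.patience:
                break

        # adjoint gradient of the squared weighted mismatch w.r.t. C
        mix = a_w * dq0 + b_w * (dq1 @ expm_lag.T)
        mix = (mix + mix.T) / 2
        adjoint = spl.solve_continuous_lyapunov(jac.T, -mix)
        _, frechet = spl.expm_frechet(jac * lag, q0_mod @ dq1)
        grad_c = -(4.0 * q0_mod @ adjoint + 2.0 * b_w * lag * frechet)

        step = it + 1  # Adam bias-correction step counter
        mom = beta1 * mom + (1 - beta1) * grad_c
        vel = beta2 * vel + (1 - beta2) * grad_c**2
        update = (
            lr * (mom / (1 - beta1**step)) / (np.sqrt(vel / (1 - beta2**step)) + eps)
        )
        c_new = c_cur - update
        c_new[~off_mask] = 0.0
        np.clip(c_new, 0.0, hp.c_max, out=c_new)

        jac_new = -eye / tau + c_new.T
        if np.max(np.linalg.eigvals(jac_new).real) >= -1e-9:
            halvings += 1
            if halvings > 5:
                raise UnstableModelError(
                    "fit diverged: Jacobian unstable after 5 rate halvings"
                )
            lr /= 2
            logger.warning(
                "unstable update at iteration %d: restoring best state, "
                "halving rate to %.3g",
                it,
                lr,
            )
            c_cur = best_c.copy()
            sigma_cur = best_sigma.copy()
            mom[:] = 0.0
            vel[:] = 0.0
        else:
            c_cur = c_new

    fitted = MouParameters(C=best_c, Sigma=np.diag(best_sigma), tau=tau)
    return FitResult(
        params=fitted,
        error_history=np.array(errors),
        best_error=float(best_error),
        best_iteration=best_iter,
        converged=since_best >= hp.patience,
        hyperparams=hp,
        method="gradient",
    )


def fit_mou_heuristic(
    target: SpatioTemporalCovariance,
    mask: StructuralMask,
    tau: float,
    hp: FitHyperparams | None = None,
) -> FitResult:
    """Symmetric heuristic fit of FC0 only.

    C is constrained symmetric on the symmetrized mask; the EC update is the
    masked zero-lag covariance mismatch itself, Sigma is updated as in the
    gradient fit, and the model error uses FC0 alone.
    """
    if mask.n_rois != target.n_rois:
        raise ValueError("mask and target dimensions differ")
    hp = (hp or FitHyperparams()).resolved(target.n_rois, "heuristic")
    n = target.n_rois
    q0_emp = _maybe_jitter(target.q0)
    norm0 = np.linalg.norm(q0_emp)
    if norm0 == 0:
        raise ValueError("empirical covariance is identically zero")
    sym_mask = (mask.mask | mask.mask.T) & ~np.eye(n, dtype=bool)

    sigma_cur = np.clip(2.0 * np.diag(q0_emp) / tau, 1e-12, None)
    c_cur = np.zeros((n, n))
    rate_c, rate_sigma = hp.rate_c, hp.rate_sigma

    errors: list[float] = []
    best_error = np.inf
    best_c = c_cur.copy()
    best_sigma = sigma_cur.copy()
    best_iter = 0
    since_best = 0
    halvings = 0

    it = 0
    while it < hp.max_iter:
        jac = -np.eye(n) / tau + c_cur.T
        q0_mod = spl.solve_continuous_lyapunov(jac, -np.diag(sigma_cur))
        q0_mod = (q0_mod + q0_mod.T) / 2
        dq0 = q0_emp - q0_mod
        err = np.linalg.norm(dq0) / norm0
        errors.append(err)
        if err < best_error:
            best_error = err
            best_c = c_cur.copy()
            best_sigma = sigma_cur.copy()
            best_iter = it
            since_best = 0
        else:
            since_best += 1
            if since_best >= hp.patience:
                break

        delta = (dq0 + dq0.T) / 2
        c_new = c_cur + rate_c * delta
        c_new[~sym_mask] = 0.0
        np.clip(c_new, 0.0, hp.c_max, out=c_new)
        c_new = (c_new + c_new.T) / 2
        sigma_new = sigma_cur - rate_sigma * np.diag(jac @ dq0 + dq0 @ jac.T)
        np.clip(sigma_new, hp.sigma_min, None, out=sigma_new)

        jac_new = -np.eye(n) / tau + c_new.T
        if np.max(np.linalg.eigvals(jac_new).real) >= -1e-9:
            halvings += 1
            if halvings > 5:
                raise UnstableModelError(
                    "heuristic fit diverged: Jacobian unstable after 5 rate halvings"
                )
            rate_c /= 2
            rate_sigma /= 2
            c_cur = best_c.copy()
            sigma_cur = best_sigma.copy()
        else:
            c_cur = c_new
            sigma_cur = sigma_new
        it += 1

    fitted = MouParameters(C=best_c, Sigma=np.diag(best_sigma), tau=tau)
    return FitResult(
        params=fitted,
        error_history=np.array(errors),
        best_error=float(best_error),
        best_iteration=best_iter,
        converged=since_best >= hp.patience,
        hyperparams=hp,
        method="heuristic",
    )
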