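"""Multivariate Ornstein-Uhlenbeck (MOU) network model.

The MOU process is a continuous-time linear stochastic network: each node
(region of interest, ROI) relaxes with a common leakage time constant ``tau``,
receives weighted input from other nodes through the directed effective
connectivity (EC) matrix ``C``, and is driven by Gaussian fluctuations with
covariance ``Sigma`` per unit time::

    dx = J x dt + dW,   J = -I/tau + C^T,   cov(dW) = Sigma dt

Orientation convention (used by every module and file writer in this
package): ``C[i, j]`` is the weight of the directed connection FROM ROI ``i``
(source) TO ROI ``j`` (target).  The Jacobian therefore uses the transpose of
``C`` so that the state update reads target-from-source.

The model is fully determined by (C, Sigma, tau).  For a stable Jacobian
(all eigenvalues with negative real part) the stationary zero-lag covariance
Q0 solves the continuous Lyapunov equation ``J Q0 + Q0 J^T + Sigma = 0`` and
the lagged covariance is ``Q(lag) = Q0 expm(J^T lag)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as spl

logger = logging.getLogger("mouec")

#: Jacobians whose largest eigenvalue real part is at or above this value are
#: treated as unstable (no stationary covariance).
STABILITY_MARGIN = -1e-9

#: Relative tolerance on the Lyapunov-equation residual of theoretical_cov0.
LYAPUNOV_RTOL = 1e-10


class UnstableModelError(ValueError):
    """Raised when an operation requires a stable Jacobian but gets none."""


@dataclass
class MouParameters:
    """Parameters of a MOU network model.

    Parameters
    ----------
    C : ndarray, shape (N, N)
        Directed EC weights (1/time); ``C[i, j]`` is the connection from
        source ``i`` to target ``j``.  Nonnegative, zero diagonal.
    Sigma : ndarray, shape (N, N)
        Input (noise) covariance per unit time; symmetric PSD with strictly
        positive diagonal.  Diagonal in the standard use of this package.
    tau : float
        Global leakage time constant in seconds (> 0).
    roi_names : list of str, optional
        Labels for the N ROIs; defaults to ``roi_000`` ...
    """

    C: np.ndarray
    Sigma: np.ndarray
    tau: float
    roi_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.tau = float(self.tau)
        n = self.C.shape[0]
        if self.C.ndim != 2 or self.C.shape != (n, n):
            raise ValueError(f"C must be square, got shape {self.C.shape}")
        if self.Sigma.shape != (n, n):
            raise ValueError(
                f"Sigma shape {self.Sigma.shape} does not match C shape {self.C.shape}"
            )
        if n < 1:
            raise ValueError("need at least one ROI")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not np.all(np.isfinite(self.C)) or not np.all(np.isfinite(self.Sigma)):
            raise ValueError("C and Sigma must be finite")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("diagonal of C must be zero (no self-connections)")
        if np.any(self.C < 0):
            raise ValueError("EC weights must be nonnegative")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-12):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.diag(self.Sigma) <= 0):
            raise ValueError("diagonal of Sigma must be strictly positive")
        eigs = np.linalg.eigvalsh((self.Sigma + self.Sigma.T) / 2)
        if eigs.min() < -1e-10 * max(eigs.max(), 1.0):
            raise ValueError("Sigma must be positive semidefinite")
        if self.roi_names is None:
            self.roi_names = [f"roi_{i:03d}" for i in range(n)]
        elif len(self.roi_names) != n:
            raise ValueError("roi_names length does not match number of ROIs")

    @property
    def n_rois(self) -> int:
        return self.C.shape[0]


@dataclass
class StructuralMask:
    """Binary structural-connectivity mask constraining which EC entries exist.

    ``mask[i, j] = 1`` allows a connection from source ``i`` to target ``j``.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        n = self.mask.shape[0]
        if self.mask.ndim != 2 or self.mask.shape != (n, n):
            raise ValueError("mask must be square")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        if np.any(np.diag(self.mask) != 0):
            raise ValueError("mask diagonal must be zero")
        self.mask = self.mask.astype(bool)

    @property
    def n_rois(self) -> int:
        return self.mask.shape[0]

    @property
    def density(self) -> float:
        """Fraction of nonzero off-diagonal entries."""
        n = self.n_rois
        return float(self.mask.sum()) / (n * (n - 1))


@dataclass
class SignalSession:
    """One recording session: an N x T matrix of ROI signals plus metadata."""

    data: np.ndarray  # rows = ROIs, columns = time points
    tr: float  # sampling period, seconds
    subject_id: str = "sub-00"
    condition: str = "rest"
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("session data must be 2-D (ROIs x time)")
        if self.data.shape[1] < 3:
            raise ValueError("session must have at least 3 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("session data must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.roi_names is None:
            self.roi_names = [f"roi_{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def build_jacobian(params: MouParameters) -> np.ndarray:
    """Jacobian J = -I/tau + C^T of the MOU drift.

    The transpose maps the source->target orientation of ``C`` onto the
    row-acts-on-column convention of the linear ODE ``dx/dt = J x``.
    """
    n = params.n_rois
    return -np.eye(n) / params.tau + params.C.T


def is_stable(params: MouParameters) -> tuple[bool, float]:
    """Check stability of the Jacobian.

    Returns ``(stable, margin)`` where ``margin`` is the largest real part
    among the eigenvalues of J; stability requires ``margin < -1e-9``.
    """
    margin = float(np.max(np.linalg.eigvals(build_jacobian(params)).real))
    return margin < STABILITY_MARGIN, margin


def _require_stable(params: MouParameters) -> np.ndarray:
    stable, margin = is_stable(params)
    if not stable:
        raise UnstableModelError(
            f"Jacobian is not stable (max Re eig = {margin:.3g}); "
            "no stationary covariance exists"
        )
    return build_jacobian(params)


def theoretical_cov0(params: MouParameters) -> np.ndarray:
    """Stationary zero-lag covariance Q0 of the MOU process.

    Solves the continuous Lyapunov equation ``J Q0 + Q0 J^T + Sigma = 0``.
    """
    jac = _require_stable(params)
    q0 = spl.solve_continuous_lyapunov(jac, -params.Sigma)
    q0 = (q0 + q0.T) / 2
    # residual bound on the backward-error scale: for near-defective
    # Jacobians ||Q0|| blows up and eps * ||J|| * ||Q0|| is the smallest
    # residual float64 can represent, so ||Sigma|| alone is not attainable
    scale = np.linalg.norm(params.Sigma) + np.linalg.norm(jac) * np.linalg.norm(q0)
    for _ in range(3):  # iterative refinement when the direct solve is short
        residual_mat = jac @ q0 + q0 @ jac.T + params.Sigma
        if np.linalg.norm(residual_mat) <= LYAPUNOV_RTOL * scale:
            return q0
        correction = spl.solve_continuous_lyapunov(jac, -residual_mat)
        q0 = q0 + (correction + correction.T) / 2
    resid = np.linalg.norm(jac @ q0 + q0 @ jac.T + params.Sigma)
    if resid > LYAPUNOV_RTOL * scale:
        raise ArithmeticError(
            f"Lyapunov solve residual {resid:.3g} exceeds tolerance"
        )
    return q0


def theoretical_cov_lagged(params: MouParameters, lag: float) -> np.ndarray:
    """Lagged stationary covariance Q(lag) = Q0 expm(J^T lag).

    Entry (i, j) is cov(x_i(t), x_j(t + lag)); rows index the earlier time.
    """
    if lag < 0:
        raise ValueError(f"lag must be nonnegative, got {lag}")
    jac = _require_stable(params)
    q0 = theoretical_cov0(params)
    if lag == 0:
        return q0
    return q0 @ spl.expm(jac.T * lag)


def simulate(
    params: MouParameters,
    duration_tr: int,
    tr: float,
    dt: float | None = None,
    seed: int = 0,
    burn_in_tr: int | None = None,
    subject_id: str = "sub-00",
    condition: str = "rest",
) -> SignalSession:
    """Simulate the MOU process by Euler-Maruyama integration.

    Integrates ``dx = J x dt + sqrt(dt) L xi`` with ``L L^T = Sigma`` and
    ``xi`` standard normal, then subsamples every ``tr`` seconds after
    discarding the burn-in.  Identical seeds produce identical sessions.

    Parameters
    ----------
    duration_tr : int
        Number of output time points (>= 3).
    tr : float
        Output sampling period, seconds.
    dt : float, optional
        Integration step; default ``tr / 20``, must satisfy ``dt <= tr / 10``.
    burn_in_tr : int, optional
        Discarded initial samples; default covers 100 * tau seconds.
    """
    if duration_tr < 3:
        raise ValueError("duration_tr must be >= 3")
    if dt is None:
        dt = tr / 20
    if dt > tr / 10 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; need dt <= tr/10 = {tr / 10}")
    if burn_in_tr is None:
        burn_in_tr = int(np.ceil(100 * params.tau / tr))
    jac = _require_stable(params)
    n = params.n_rois
    if np.count_nonzero(params.Sigma - np.diag(np.diag(params.Sigma))) == 0:
        noise_fac = np.diag(np.sqrt(np.diag(params.Sigma)))
    else:
        try:
            noise_fac = np.linalg.cholesky(params.Sigma)
        except np.linalg.LinAlgError:
            # PSD but singular Sigma: fall back to an eigendecomposition factor
            evals, evecs = np.linalg.eigh((params.Sigma + params.Sigma.T) / 2)
            if evals.min() < -1e-10 * max(abs(evals.max()), 1.0):
                raise ValueError(
                    "Sigma factorization failed: matrix is not positive semidefinite"
                ) from None
            noise_fac = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))

    rng = np.random.default_rng(seed)
    steps_per_tr = int(round(tr / dt))
    n_tr = burn_in_tr + duration_tr
    out = np.empty((n, duration_tr))
    x = np.zeros(n)
    propagate = np.eye(n) + jac * dt  # explicit Euler drift
    sqrt_dt = np.sqrt(dt)
    for k in range(n_tr):
        for _ in range(steps_per_tr):
            x = propagate @ x + sqrt_dt * (noise_fac @ rng.standard_normal(n))
        if k >= burn_in_tr:
            out[:, k - burn_in_tr] = x
    return SignalSession(
        data=out,
        tr=tr,
        subject_id=subject_id,
        condition=condition,
        roi_names=list(params.roi_names) if params.roi_names else None,
    )
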