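# Methods

## The generative model

`mouec` models the joint activity of N brain regions (ROIs) as a
multivariate Ornstein-Uhlenbeck (MOU) process,

    dx = J x dt + dW,        J = -I/tau + C^T,       cov(dW) = Sigma dt,

where `tau` is a single leakage time constant shared by all ROIs (an
abstraction of the hemodynamic decay), `C` is the directed effective
connectivity (EC) — `C[i, j]` is the weight of the connection from source
`i` to target `j`, nonnegative, zero on the diagonal, and zero outside the
structural mask — and `Sigma` is the covariance per unit time of the
fluctuating inputs, diagonal in standard use.  The process is the
continuous-time analogue of a first-order autoregressive model: linear
feedback propagating noise through the network.

For a stable Jacobian (all eigenvalue real parts negative) the stationary
zero-lag covariance solves the continuous Lyapunov equation
`J Q0 + Q0 J^T + Sigma = 0`, and the lagged covariance is
`Q(lag) = Q0 expm(J^T lag)`.  These two matrices are the model counterparts
of the empirical FC0/FC1 (covariance of the ROI signals without lag and at
a lag of one sampling period TR), and the pair is what estimation matches:
FC0 alone cannot identify asymmetric connectivity; the lagged structure
breaks the symmetry.

Assumptions worth keeping in mind: stationarity over a session (no
within-session switching), linear dynamics, a single global `tau`, and no
explicit hemodynamic response function — the model describes the measured
signals directly.

## Estimation

`empirical_covariances` demeans each ROI and computes FC0/FC1 on the
overlapping window of `T - lag` points with denominator `T - lag - 1`, so
the two matrices are mutually consistent; FC0 is symmetrized.  A condition
number above 1e8 logs a quasi-singularity warning and adds a ridge jitter
of `1e-6 * mean(diag(FC0))` before any inversion.

`estimate_tau` regresses the log autocovariance of each ROI against lag (in
seconds) over lags 0..2 TR and pools ROIs by averaging the slopes
(`tau = -1/mean(slopes)`); ROIs with non-positive autocovariance at any
used lag are excluded and logged.  `tau` is estimated once per session and
held fixed during the fit.

`fit_mou_gradient` minimizes the squared normalized mismatch

    L = ||FC0 - Q0||_F^2 / ||FC0||_F^2 + ||FC1 - Q1||_F^2 / ||FC1||_F^2

over the masked EC weights.  The gradient is exact and cheap: the mismatch
is propagated back through the stationarity equation by one adjoint
Lyapunov solve, and the lagged term contributes through the Frechet
derivative of the matrix exponential — two Lyapunov solves and one
`expm_frechet` per iteration, O(N^3) each.  Steps use per-weight adaptive
moments (Adam, step size `rate_c = 2e-3`), restricted to the masked
off-diagonal entries and clipped nonnegative.  This replaces a simpler
fixed-point update (mismatch preconditioned by `Q0^{-1}`) that we found to
stall and then diverge on strongly coupled networks — those whose dominant
eigenvalue sits near the stability boundary, which is exactly the regime of
interest for realistic functional-connectivity strength.

`Sigma` is not descended at all: given the current Jacobian, stationarity
of the *empirical* FC0 fixes the input variances in closed form,
`Sigma_ii = -diag(J FC0 + FC0 J^T)_ii`, floored at `sigma_min = 1e-6`.
`rate_sigma` relaxes this update (1 = exact, the default).

The scalar model error tracked per iteration is
`E = (||dQ0||_F/||FC0||_F + ||dQ1||_F/||FC1||_F) / 2`; the returned
parameters are those at the minimum of E.  The loop stops at `max_iter`
(default 10000) or after `patience` (default 300) non-improving iterations;
a step that destabilizes the Jacobian restores the best state, halves the
step size and resets the Adam moments (the fit fails after 5 such
halvings).  The fit is deterministic: C starts at zero and Sigma at the
decoupled closed form `2 diag(FC0)/tau`.

Noise-free targets need deep convergence to pin down individual weights
(the map from EC to covariances is poorly conditioned near the stability
boundary): recovery tests use `max_iter = 30000, patience = 1000` and reach
Pearson r > 0.95 against the generating weights at N = 10-20.  Noisy
(finite-sample) targets plateau at their noise floor within ~3000
iterations, which is the budget used in the pipeline; at the default
cohort's 300 time points per session the median recovery correlation is
about 0.8.

`fit_mou_heuristic` is the symmetric baseline: C constrained symmetric on
the symmetrized mask, updated by the raw zero-lag mismatch
(`dC = rate_c (FC0 - Q0)`, masked, clipped nonnegative), fitting FC0 only.
It converges in the weak-to-moderate coupling regime and serves as the
comparison method: on asymmetric ground truth its full (FC0, FC1) model
error is worse than the gradient fit's, as the corresponding comparison on
real data shows.

## Network-dynamics measures

Dynamic communicability is the network impulse response with the
leakage-only response removed and a global normalization:

    C(t) = (expm(J t) - expm(J0 t)) / ||J0||,    J0 = -I/tau,

with `||J0|| = N/tau` (entrywise L1 norm), making the measure dimensionless
and comparable across network sizes.  Integration times are expressed in TR
units and converted internally with an explicit `tr` argument (default
2 s).  Entry (i, j) is read as the interaction from source i to target j.

Dynamic flow additionally scales each source row by `sqrt(Sigma_ii)` (or by
the symmetric matrix square root on the source axis for a full Sigma), so
that propagation of the ongoing input fluctuations — not just unit
perturbations — is quantified.  With `Sigma = I` the flow equals the
communicability exactly; this identity is the binding constraint of the
definition and is asserted bitwise in the tests.

Aggregates: total flow sums all N^2 entries per integration time; input
(output) flow of ROI k sums column (row) k, and each resums to the total —
a conservation identity tested to 1e-12.  Flow diversity is the
coefficient of variation of the N^2 entries (undefined, reported as NaN,
where the mean is at most 1e-15).

Communities are detected on the flow matrix at one integration time:
symmetrized as `min(F, F^T)` (a pair counts as strongly connected only if
both directions carry flow; arithmetic mean available), diagonal zeroed,
negatives clipped, then Louvain modularity maximization with 20 seeded
restarts keeping the best modularity (ties to the lowest seed index,
resolution 1.0).  Coparticipation across runs/subjects is the fraction of
partitions in which two ROIs share a community.  Degenerate inputs
(all-zero or fully homogeneous matrices) raise instead of returning an
arbitrary partition.

The long-time limits (communicability and lagged covariance vanishing) are
tested at 50 *effective* time constants, `50/|max Re eig(J)|`: for weakly
coupled systems this is 50 tau, but near the stability boundary the slowest
network mode, not the nodal leak, sets the horizon.

## Machine-learning pipeline

Sessions are samples; vectorized connectivity links are features (EC over
the mask in row-major order, or the FC upper triangle); labels are the
cognitive condition or the subject identity.  Condition classification
uses subject-grouped splits throughout — all sessions of a subject fall on
one side of every split — because paired sessions of one subject are far
more similar than chance and pooling them across train/test inflates
accuracy.  Subject identification splits sessions within each subject.
Defaults: 40 shuffle splits at 80:20 by subject; leave-one-subject-out as
the alternative.  With 22 subjects and 4-subject test sets, 100 random
draws repeat a split with probability just under 50% — the birthday
arithmetic behind preferring leave-one-group-out at small cohort sizes.

Classifiers: multinomial logistic regression (L2, strength 1.0), LDA, and
kNN with distance `1 - Pearson correlation` (k = 1 default).  Features are
standardized with train-fold statistics only; a sentinel test injects an
extreme outlier into a test fold and asserts the other test predictions are
unchanged.  The chance level reported is the majority-class frequency.

RFE eliminates 5% of the remaining features per round (at least one),
scoring each feature by the class-maximum absolute MLR coefficient averaged
over the CV train folds, so no fold's test data enters its own selection
statistic.  The accuracy-versus-size curve uses the same folds; the support
network is the retained set at the accuracy maximum (smallest on ties), and
ranks reverse the elimination order.

Link-wise testing runs two-sided Mann-Whitney tests per link and condition
pair (Welch t as an option), keeps the smallest p over pairs when more than
two conditions are present, and reports the Bonferroni threshold
(`alpha/L`) alongside Benjamini-Hochberg rejections at FDR `alpha`.
Constant features raise (rank tests are degenerate there) rather than being
dropped silently.

## The synthetic cohort

The generator emulates a movie-viewing study design: one structural mask
shared by all subjects, a group-level ground-truth EC, per-subject
variability, condition effects, and sessions of 300 time points at
TR = 2 s.  The desk-scale default is 20 ROIs and 10 subjects with 2 rest
plus 3 movie sessions each; the paper-scale preset (66 ROIs, 22 subjects,
110 sessions, 28% mask density) exists for design-count and scale checks.

Ground truth: a random directed mask at the requested density (no
self-loops, exact link count), weights drawn lognormal(0, 1.5) — the
heavy-tailed spread seen in empirical structural connectomes — and scaled
in closed form so the Jacobian's spectral margin equals `-0.1/tau`.  This
places the network in the strongly coupled regime where FC carries
substantial off-diagonal structure (correlation rms about 0.35, a realistic
BOLD range); weakly coupled draws produce covariances whose off-diagonal
structure drowns in sampling noise at 300 time points, leaving nothing to
estimate.  `Sigma = I`; `tau` defaults to 2 TR = 4 s.

Subject variability multiplies existing links by lognormal(0, 0.1) jitter
(topology shared across subjects), then rescales to a spectral margin of
at most `-0.08/tau`, leaving headroom for the condition effects.
Condition effects multiply a fixed link subset by `effect_size` (1.5) or
its reciprocal.  The modulated links are the strongest links of the group
network, walking down the weight ranking so finer condition sets strictly
extend the coarse one (making nested-biomarker overlap testable); strong
links are the only ones whose multiplicative modulation survives
estimation noise at 300 time points.  Factors alternate starting with
suppression on the strongest link, emulating a selection of pathways
(dominant resting pathways suppressed, others enhanced) while keeping the
spectral radius at or below baseline, so a global stability rescale —
which would add a spurious between-condition signature — is rarely needed
(it logs a warning when it is).  Non-baseline conditions also raise the input variance of the
first fifth of ROIs ("sensory" ROIs) by 50%, mirroring stimulus load.

What the generator does not emulate: hemodynamic convolution, measurement
noise distinct from the process noise, within-session nonstationarity,
physiological confounds, or spatial structure in the parcellation.
Passing tests therefore demonstrate correctness of the estimation and
analysis machinery under the model's own assumptions, not robustness to
the ways real BOLD data violate them.

## Numerical choices

- Stability: a model is declared unstable when `max Re eig(J) >= -1e-9`.
- Lyapunov solves use the Bartels-Stewart solver; the residual of every
  stationary covariance is checked against `1e-10` on the backward-error
  scale `||Sigma|| + ||J|| ||Q0||`, with up to 3 steps of iterative
  refinement.  (Near-defective Jacobians — a repeated eigenvalue at the
  spectral margin — inflate `||Q0||` to the point where a bound relative to
  `||Sigma||` alone is below what float64 can represent.)
- Euler-Maruyama integration at `dt = tr/20` with a burn-in of `100 tau`
  seconds; identical seeds give bitwise-identical sessions.  A singular but
  PSD `Sigma` falls back to an eigendecomposition factor.
- Covariance denominator `T - lag - 1` on the overlapping window for both
  FC0 and FC1.
- All cohort randomness derives from one spec seed through spawned seed
  sequences, so cohorts regenerate bit-identically.

## Problem sizes used in the shipped checks

Noise-free recovery runs at N = 10, density 0.3; the covariance oracles at
N = 6 (quadrature, and a 10^6-step simulation); the end-to-end pipeline at
the desk-scale default (20 ROIs, 10 subjects, 50 sessions, 3000-iteration
fits).  These sizes keep a full run on one CPU within minutes while
preserving the regime the method targets.

## Known limitations

- Identifiability near the stability boundary is poor in the sense that
  very small covariance mismatches can correspond to sizeable weight
  differences; deep convergence (or longer sessions) is needed for
  weight-level accuracy, and the shipped defaults reflect that trade-off.
- The heuristic baseline inherits the divergence of plain mismatch updates
  on strongly coupled targets; it is intended for the weak-to-moderate
  regime and for method comparison.
- A single global `tau` is assumed everywhere; per-ROI time constants are
  representable in the data types but not estimated.
- Off-diagonal `Sigma` is accepted by the model and flow code but never
  produced by estimation.
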