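# mouec

Model-based effective connectivity for multi-region time series.

`mouec` fits a multivariate Ornstein-Uhlenbeck (MOU) network model to the
spatiotemporal covariance structure of ROI signals (BOLD-like fMRI time
series), producing a directed, whole-brain effective-connectivity (EC)
estimate per recording session.  On top of the fitted model it provides
dynamic communicability/flow network measures, flow-based community
detection, and a group-aware machine-learning pipeline that uses the EC
links as features for condition and subject classification, biomarker
extraction by recursive feature elimination, and link-wise statistical
testing.  A synthetic-cohort generator with known ground truth makes every
step testable end to end.

It is written for researchers analyzing parcellated neuroimaging (or other
multivariate, stationary, noise-driven) time series who want directed
connectivity estimates with an explicit generative model behind them.

## The model

Activity of N regions follows the linear stochastic dynamics

```
dx = J x dt + dW,     J = -I/tau + C^T,     cov(dW) = Sigma dt
```

with a global leakage time constant `tau`, nonnegative directed weights
`C[i, j]` (source i → target j) restricted to a structural mask, and input
(noise) covariance `Sigma`.  For stable `J` the stationary covariances are

```
J Q0 + Q0 J^T + Sigma = 0          (zero lag; continuous Lyapunov equation)
Q(lag) = Q0 expm(J^T lag)          (lagged)
```

Estimation adjusts `C` (masked, nonnegative) and diagonal `Sigma` so that
(Q0, Q1) reproduce the empirical covariances FC0/FC1 of a session
(computed without lag and at a lag of one sampling period TR), descending
the exact gradient of the squared normalized mismatch and returning the
parameters at the minimum model error

```
E = ( ||FC0 - Q0||_F / ||FC0||_F  +  ||FC1 - Q1||_F / ||FC1||_F ) / 2 .
```

Fitting the lagged covariance is what makes the estimate directed: FC0
alone is symmetric information.  See `docs/methods.md` for the full
account (gradient derivation, network measures, cohort design, numerical
choices).

## Worked example

```python
import numpy as np
from mouec import (CohortSpec, FitHyperparams, make_ground_truth, simulate,
                   empirical_covariances, estimate_tau, fit_mou_gradient,
                   dynamic_flow, total_flow)

# a 20-ROI ground-truth network and one 300-point session at TR = 2 s
spec = CohortSpec(n_rois=20, seed=0)
mask, truth = make_ground_truth(spec)
session = simulate(truth, duration_tr=300, tr=2.0, seed=1)

cov = empirical_covariances(session, lag_tr=1)   # FC0, FC1
fit = fit_mou_gradient(cov, mask, tau=spec.tau,
                       hp=FitHyperparams(max_iter=3000))
r = np.corrcoef(fit.params.C[mask.mask], truth.C[mask.mask])[0, 1]
print(f"model error {fit.best_error:.3f}, recovery r {r:.2f}")

flow = dynamic_flow(fit.params, tr=2.0)          # N x N x T tensor
print(f"total flow peaks at t = {flow.t_grid[np.argmax(total_flow(flow))]:.1f} TR")
```

Output:

```
model error 0.165, recovery r 0.84
total flow peaks at t = 3.5 TR
```

The model error is the normalized distance between the session's
covariances and the fitted model's; at 300 time points it is dominated by
sampling noise (it falls to ~0.005 on noise-free covariances).  The
recovery correlation compares the estimated weights with the generating
ones, and the total-flow curve summarizes how network interactions build
up and dissipate over integration time.

The same steps are available as a CLI for file-based workflows
(`mouec simulate | fit | flow | communities | classify | testlinks |
pipeline`); `mouec pipeline --config config.json` runs the whole chain and
writes a results directory with provenance and a summary.

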