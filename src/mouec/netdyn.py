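"""Network-dynamics analysis of a fitted MOU model.

Dynamic communicability measures the pairwise interaction between ROIs as a
function of the integration time t: it is the network impulse response
(Green function) of the model with the leakage-only response subtracted and
a global normalization::

    C(t) = (expm(J t) - expm(J0 t)) / ||J0||,   J0 = -I/tau

The dynamic flow additionally weights each source ROI by the amplitude
sqrt(Sigma_ii) of its input fluctuations, so that propagation of ongoing
activity (not just unit perturbations) is quantified; with Sigma = I the
flow equals the communicability exactly.

Aggregates over the flow tensor (total/input/output flow, flow diversity)
and flow-based community detection (weighted modularity on the symmetrized
flow matrix, with coparticipation across runs or subjects) summarize the
interaction structure at a chosen integration time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import networkx as nx
import scipy.linalg as spl

from .model import MouParameters, build_jacobian, is_stable, UnstableModelError

logger = logging.getLogger("mouec")


def default_t_grid(t_max: float = 20.0, dt: float = 0.5) -> np.ndarray:
    """Default integration-time grid, in TR units: 0 to t_max in steps of dt."""
    return np.arange(0.0, t_max + dt / 2, dt)


@dataclass
class FlowTensor:
    """Stack of communicability or flow matrices over an integration-time grid.

    ``values[i, j, k]`` is the interaction from source ROI ``i`` to target
    ROI ``j`` at integration time ``t_grid[k]``.
    """

    values: np.ndarray  # (N, N, T)
    t_grid: np.ndarray  # (T,), increasing, starts at 0
    kind: str  # "communicability" or "flow"
    norm_constant: float  # the ||J0|| used

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must have shape (N, N, T)")
        if self.values.shape[2] != self.t_grid.size:
            raise ValueError("t_grid length does not match tensor depth")
        if self.t_grid[0] != 0 or np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be increasing and start at 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("flow values must be finite")
        if self.kind not in ("communicability", "flow"):
            raise ValueError(f"unknown tensor kind {self.kind!r}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def at(self, t: float) -> np.ndarray:
        """The N x N matrix at integration time ``t`` (must be on the grid)."""
        idx = np.nonzero(np.isclose(self.t_grid, t))[0]
        if idx.size == 0:
            raise ValueError(f"t={t} is not on the integration-time grid")
        return self.values[:, :, idx[0]]


@dataclass
class CommunityResult:
    """Partitions from repeated community detection plus their coparticipation."""

    partitions: list[dict[int, int]]
    coparticipation: np.ndarray
    t_used: float
    n_runs: int


def _green_function_stack(
    params: MouParameters, t_grid: np.ndarray, tr: float
) -> np.ndarray:
    """(expm(J t) - expm(J0 t)) / ||J0|| in source x target orientation.

    ``t_grid`` is in TR units; ``tr`` converts to the seconds of the
    Jacobian.
    """
    stable, margin = is_stable(params)
    if not stable:
        raise UnstableModelError(
            f"communicability requires a stable model (max Re eig = {margin:.3g})"
        )
    t_grid = np.asarray(t_grid, dtype=float)
    n = params.n_rois
    jac = build_jacobian(params)
    norm_j0 = n / params.tau  # entrywise L1 norm of J0 = -I/tau
    out = np.empty((n, n, t_grid.size))
    for k, t in enumerate(t_grid):
        t_s = t * tr
        # expm(J t) is target-from-source; transpose into source x target
        green = spl.expm(jac * t_s) - np.exp(-t_s / params.tau) * np.eye(n)
        out[:, :, k] = green.T / norm_j0
    return out


def dynamic_communicability(
    params: MouParameters, t_grid: np.ndarray | None = None, tr: float = 2.0
) -> FlowTensor:
    """Dynamic communicability tensor of a stable MOU model.

    ``t_grid`` holds integration times in TR units; ``tr`` (seconds per TR)
    converts them to the time base of the model.
    """
    if t_grid is None:
        t_grid = default_t_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    values = _green_function_stack(params, t_grid, tr)
    return FlowTensor(
        values=values,
        t_grid=t_grid,
        kind="communicability",
        norm_constant=params.n_rois / params.tau,
    )


def dynamic_flow(
    params: MouParameters, t_grid: np.ndarray | None = None, tr: float = 2.0
) -> FlowTensor:
    """Dynamic flow: communicability scaled by input amplitude at the source.

    For diagonal Sigma each source row i is multiplied by sqrt(Sigma_ii);
    for a full Sigma the symmetric matrix square root is applied on the
    source axis.  With Sigma = I the flow equals the communicability.
    """
    if t_grid is None:
        t_grid = default_t_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    values = _green_function_stack(params, t_grid, tr)
    off_diag = params.Sigma - np.diag(np.diag(params.Sigma))
    if np.count_nonzero(off_diag) == 0:
        scale = np.sqrt(np.diag(params.Sigma))
        values = values * scale[:, None, None]
    else:
        root = spl.sqrtm(params.Sigma).real
        values = np.einsum("is,sjt->ijt", root, values)
    return FlowTensor(
        values=values,
        t_grid=t_grid,
        kind="flow",
        norm_constant=params.n_rois / params.tau,
    )


def total_flow(ft: FlowTensor) -> np.ndarray:
    """Sum of all N^2 interactions at each integration time."""
    return ft.values.sum(axis=(0, 1))


def input_output_flow(ft: FlowTensor) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI incoming and outgoing flow over integration time.

    Returns ``(input_flow, output_flow)``, each N x T: the input flow of ROI
    k sums the column k (k as target), the output flow sums the row k (k as
    source); each sums over ROIs to the total flow at every t.
    """
    input_flow = ft.values.sum(axis=0)
    output_flow = ft.values.sum(axis=1)
    return input_flow, output_flow


def flow_diversity(ft: FlowTensor) -> np.ndarray:
    """Coefficient of variation of the N^2 entries at each integration time.

    Measures the heterogeneity within each flow matrix; NaN where the mean
    is at or below 1e-15 (undefined).
    """
    flat = ft.values.reshape(-1, ft.t_grid.size)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    out = np.full(ft.t_grid.size, np.nan)
    ok = mean > 1e-15
    out[ok] = std[ok] / mean[ok]
    return out


def symmetrize_flow(mat: np.ndarray, mode: str = "min") -> np.ndarray:
    """Symmetrize a flow matrix for community detection.

    ``min`` (default) keeps min(F, F^T): a pair is strongly connected only
    if both directions carry flow ("bidirectional exchange"); ``mean`` takes
    the arithmetic average.  The diagonal is zeroed (self-flow is not an
    inter-ROI exchange) and negatives are clipped to zero.
    """
    if mode == "min":
        sym = np.minimum(mat, mat.T)
    elif mode == "mean":
        sym = (mat + mat.T) / 2
    else:
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    sym = np.clip(sym, 0.0, None)
    np.fill_diagonal(sym, 0.0)
    return sym


def detect_communities(
    ft: FlowTensor,
    t: float,
    n_runs: int = 20,
    seed: int = 0,
    resolution: float = 1.0,
    symmetrization: str = "min",
) -> dict[int, int]:
    """Weighted-modularity (Louvain) communities of the flow matrix at time t.

    The flow matrix at ``t`` is symmetrized, diagonal-zeroed and clipped,
    then Louvain modularity maximization is run ``n_runs`` times with seeds
    ``seed .. seed+n_runs-1``; the best-modularity partition is returned
    (ties broken by the lowest seed index).  Labels are renumbered by each
    community's smallest member.
    """
    mat = ft.at(t)
    sym = symmetrize_flow(mat, symmetrization)
    if not np.any(sym > 0):
        raise ValueError(
            f"symmetrized flow matrix at t={t} is all-zero; no communities to detect"
        )
    off = sym[~np.eye(sym.shape[0], dtype=bool)]
    if np.allclose(off, off[0]):
        raise ValueError(
            f"flow matrix at t={t} is fully homogeneous; community structure undefined"
        )
    graph = nx.from_numpy_array(sym)
    best_mod = -np.inf
    best_parts: list[set[int]] | None = None
    for k in range(n_runs):
        parts = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=seed + k
        )
        mod = nx.community.modularity(
            graph, parts, weight="weight", resolution=resolution
        )
        if mod > best_mod + 1e-12:  # strict improvement; ties keep lowest seed
            best_mod = mod
            best_parts = parts
    assert best_parts is not None
    ordered = sorted(best_parts, key=min)
    return {node: label for label, comm in enumerate(ordered) for node in comm}


def coparticipation(partitions: list[dict[int, int]]) -> CommunityResult:
    """Fraction of partitions in which each ROI pair shares a community."""
    if not partitions:
        raise ValueError("need at least one partition")
    nodes = sorted(partitions[0])
    for p in partitions[1:]:
        if sorted(p) != nodes:
            raise ValueError("all partitions must cover the same ROI set")
    n = len(nodes)
    copart = np.zeros((n, n))
    for p in partitions:
        labels = np.array([p[node] for node in nodes])
        copart += (labels[:, None] == labels[None, :]).astype(float)
    copart /= len(partitions)
    return CommunityResult(
        partitions=partitions,
        coparticipation=copart,
        t_used=np.nan,
        n_runs=len(partitions),
    )
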