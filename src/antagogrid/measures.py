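"""Post-simulation analytics: patches, trajectories, correlations.

A *patch* is a maximal connected component of same-strain cells.  The
default connectivity is the 8-cell Moore neighborhood, mirroring the
interaction neighborhood of the simulator; 4-cell von Neumann
connectivity is available.  Components wrap across edges on a toroidal
grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .engine import EMPTY, Grid

__all__ = [
    "PatchReport",
    "StationarityRule",
    "ReplicateSummary",
    "patch_sizes",
    "population_counts",
    "stationarity_step",
    "rank_correlation",
    "aggregate_replicates",
]

_STRUCTURES = {
    "moore8": np.ones((3, 3), dtype=bool),
    "vonneumann4": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass(frozen=True)
class PatchReport:
    """Per-strain connected-component sizes for one grid."""

    sizes: dict[int, list[int]]  # strain id -> component sizes (cells)
    connectivity: str
    replicate: int | None = None

    @property
    def total_cells(self) -> int:
        return sum(sum(v) for v in self.sizes.values())

    def mean_size(self, strain_id: int) -> float:
        s = self.sizes.get(strain_id, [])
        return float(np.mean(s)) if s else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"replicate": self.replicate, "strain_id": s, "patch_size": sz}
            for s, sizes in sorted(self.sizes.items())
            for sz in sizes
        ]
        return pd.DataFrame(rows, columns=["replicate", "strain_id", "patch_size"])


@dataclass(frozen=True)
class StationarityRule:
    """Plateau detector: populations stable over ``window`` steps.

    A step t is stationary when every strain's population stays within
    ``max(rel_tol * pop(t), abs_floor)`` of its value at t for the next
    ``window`` steps.
    """

    window: int = 50
    rel_tol: float = 0.01
    abs_floor: float = 5.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-strain distributional summaries across simulation replicates."""

    n_replicates: int
    n_strains: int
    mean_final_pop: np.ndarray
    median_final_pop: np.ndarray
    q1_final_pop: np.ndarray
    q3_final_pop: np.ndarray
    mean_patch: np.ndarray  # NaN for strains with no patches in any replicate
    median_patch: np.ndarray
    survival_count: np.ndarray  # replicates with final population > 0

    def to_frame(self, ai=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "strain_id": np.arange(1, self.n_strains + 1),
                "mean_final_pop": self.mean_final_pop,
                "median_final_pop": self.median_final_pop,
                "q1": self.q1_final_pop,
                "q3": self.q3_final_pop,
                "mean_patch": self.mean_patch,
                "survival_count": self.survival_count,
                "replicates": self.n_replicates,
            }
        )
        if ai is not None:
            df.insert(1, "ai", np.asarray(ai))
        return df


def _union_across_seams(labeled: np.ndarray, boundary: str, connectivity: str):
    """Component sizes of a labeled mask, merging labels that touch across
    the wrap-around seams of a torus."""
    sizes = np.bincount(labeled.ravel())
    nlab = sizes.size - 1
    if boundary != "torus" or nlab == 0:
        return [int(s) for s in sizes[1:] if s > 0]

    h, w = labeled.shape
    parent = list(range(nlab + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    shifts = (-1, 0, 1) if connectivity == "moore8" else (0,)
    for d in shifts:
        for r in range(h):
            a = labeled[r, w - 1]
            b = labeled[(r + d) % h, 0]
            if a and b and (w > 1 or d != 0):
                union(a, b)
        for c in range(w):
            a = labeled[h - 1, c]
            b = labeled[0, (c + d) % w]
            if a and b and (h > 1 or d != 0):
                union(a, b)

    merged: dict[int, int] = {}
    for lab in range(1, nlab + 1):
        root = find(lab)
        merged[root] = merged.get(root, 0) + int(sizes[lab])
    return sorted(merged.values(), reverse=True)


def patch_sizes(
    grid: Grid, connectivity: str = "moore8", replicate: int | None = None
) -> PatchReport:
    """Sizes of maximal same-strain connected components, per strain."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"unknown connectivity {connectivity!r}")
    structure = _STRUCTURES[connectivity]
    out: dict[int, list[int]] = {}
    for s in np.unique(grid.state):
        if s == EMPTY:
            continue
        labeled, _ = ndimage.label(grid.state == s, structure=structure)
        out[int(s)] = _union_across_seams(labeled, grid.boundary, connectivity)
    return PatchReport(sizes=out, connectivity=connectivity, replicate=replicate)


def population_counts(grid: Grid, n_strains: int | None = None):
    """Exact census: per-strain counts (1-based ids) plus the empty count."""
    if n_strains is None:
        n_strains = int(grid.state.max(initial=0))
    counts = grid.population_counts(n_strains)
    return counts[1:], int(counts[0])


def stationarity_step(trajectory, rule: StationarityRule = StationarityRule()):
    """First step from which all populations plateau, or None.

    Returns the smallest t such that for every strain and every t' in
    (t, t + window], |pop(t') - pop(t)| <= max(rel_tol * pop(t), abs_floor).
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    if traj.shape[0] == 0:
        raise ValueError("trajectory is empty")
    n_steps = traj.shape[0] - 1
    if rule.window > n_steps:
        raise ValueError(
            f"window {rule.window} exceeds trajectory length {n_steps}"
        )
    for t in range(0, n_steps - rule.window + 1):
        ref = traj[t]
        tol = np.maximum(rule.rel_tol * ref, rule.abs_floor)
        dev = np.abs(traj[t + 1 : t + rule.window + 1] - ref)
        if (dev <= tol).all():
            return t
    return None


def rank_correlation(x, y, method: str = "spearman"):
    """Spearman (default) or Pearson correlation; None on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined for a constant vector", stacklevel=2)
        return None
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def aggregate_replicates(
    results,
    n_strains: int | None = None,
    connectivity: str = "moore8",
):
    """Summarize final populations and patch sizes across replicates.

    ``results`` is a list of SimResult.  Patch sizes are measured on each
    replicate's final grid and pooled across replicates per strain.
    """
    if not results:
        raise ValueError("need at least one replicate")
    n_set = {r.trajectory.shape[1] for r in results}
    if len(n_set) != 1:
        raise ValueError("replicates have inconsistent strain sets")
    n = n_set.pop()
    if n_strains is not None and n_strains != n:
        raise ValueError("n_strains does not match the replicates")

    finals = np.stack([r.final_populations for r in results])  # (R, n)
    pooled: list[list[int]] = [[] for _ in range(n)]
    for i, r in enumerate(results):
        report = patch_sizes(r.final_grid, connectivity=connectivity, replicate=i)
        for s, sizes in report.sizes.items():
            pooled[s - 1].extend(sizes)

    mean_patch = np.array(
        [np.mean(p) if p else np.nan for p in pooled], dtype=float
    )
    median_patch = np.array(
        [np.median(p) if p else np.nan for p in pooled], dtype=float
    )
    return ReplicateSummary(
        n_replicates=len(results),
        n_strains=n,
        mean_final_pop=finals.mean(axis=0),
        median_final_pop=np.median(finals, axis=0),
        q1_final_pop=np.quantile(finals, 0.25, axis=0),
        q3_final_pop=np.quantile(finals, 0.75, axis=0),
        mean_patch=mean_patch,
        median_patch=median_patch,
        survival_count=(finals > 0).sum(axis=0),
    )
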