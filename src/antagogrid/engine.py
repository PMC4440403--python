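"""Stochastic cellular automaton of antagonistic bacterial growth.

A rectangular lattice represents the pond sediment; each cell is empty or
holds one strain.  Per update step every cell draws one uniform Moore
neighbor and then applies, in order:

* empty cell, empty neighbor   -> stays empty;
* empty cell, occupied neighbor-> colonized by the neighbor's strain with
  probability Pg(neighbor strain);
* occupied cell                -> dies with probability Pd(own strain);
  otherwise, if the drawn neighbor's strain antagonizes it, it is killed;
  otherwise it is unchanged.

A cell never switches directly from one strain to another.  The default
update is synchronous (all next states computed from the time-n grid); an
asynchronous random-sweep mode is available for sensitivity checks.
Periodic full-grid shuffling models a well-mixed, high-motility
environment.

Random-stream contract: one ``numpy.random.Generator`` drives a run.  Per
synchronous step it consumes, in order, one uniform per cell for the
neighbor draw (row-major) and one uniform per cell for the probability
trial; every cell consumes both draws regardless of its state, so the
consumption pattern is configuration-independent.  Seeding consumes one
permutation; shuffling consumes one permutation per shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EMPTY = 0

__all__ = [
    "EMPTY",
    "Grid",
    "SimParams",
    "SimResult",
    "seed_grid",
    "neighbors",
    "step",
    "shuffle_grid",
    "run_simulation",
    "scaled_initial_counts",
]

_MOORE_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass
class Grid:
    """Lattice state: 0 = empty, k = strain id k; ``boundary`` in {torus, bounded}."""

    state: np.ndarray
    boundary: str = "torus"

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int32)
        if self.state.ndim != 2:
            raise ValueError("grid state must be 2-D")
        if self.boundary not in ("torus", "bounded"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        if (self.state < 0).any():
            raise ValueError("negative cell values are not valid strain ids")

    @property
    def height(self) -> int:
        return self.state.shape[0]

    @property
    def width(self) -> int:
        return self.state.shape[1]

    def copy(self) -> "Grid":
        return Grid(state=self.state.copy(), boundary=self.boundary)

    def population_counts(self, n_strains: int) -> np.ndarray:
        """Counts indexed 0..n_strains (index 0 = empty cells)."""
        return np.bincount(self.state.ravel(), minlength=n_strains + 1)[: n_strains + 1]


@dataclass
class SimParams:
    """Run configuration.

    ``pg``/``pd`` are per-strain probability vectors (index = strain id - 1)
    or scalars broadcast to all strains.  ``shuffle_interval=None`` disables
    shuffling.  ``snapshot_steps`` lists step indexes whose grids are kept
    (0 = initial grid).
    """

    width: int = 200
    height: int = 200
    steps: int = 500
    pg: float | np.ndarray = 1.0
    pd: float | np.ndarray = 0.0
    shuffle_interval: int | None = None
    update_mode: str = "synchronous"
    boundary: str = "torus"
    seed: int = 0
    snapshot_steps: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.shuffle_interval is not None and self.shuffle_interval < 1:
            raise ValueError("shuffle_interval must be >= 1 when set")
        if self.update_mode not in ("synchronous", "asynchronous_sweep"):
            raise ValueError(f"unknown update mode {self.update_mode!r}")
        for name in ("pg", "pd"):
            v = np.asarray(getattr(self, name), dtype=float)
            if (v < 0).any() or (v > 1).any():
                raise ValueError(f"{name} values must be probabilities in [0, 1]")

    def prob_vectors(self, n_strains: int) -> tuple[np.ndarray, np.ndarray]:
        """Length n+1 lookup tables indexed by cell value (index 0 unused)."""
        out = []
        for name in ("pg", "pd"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim == 0:
                v = np.full(n_strains, float(v))
            elif v.shape != (n_strains,):
                raise ValueError(f"{name} must be scalar or length {n_strains}")
            out.append(np.concatenate(([0.0], v)))
        return out[0], out[1]


@dataclass
class SimResult:
    """Trajectory (``(steps+1, n_strains)`` populations), snapshots, final grid."""

    trajectory: np.ndarray
    empty_trajectory: np.ndarray
    snapshots: dict[int, np.ndarray]
    final_grid: Grid
    params: SimParams
    seed_used: int

    @property
    def n_steps(self) -> int:
        return self.trajectory.shape[0] - 1

    @property
    def final_populations(self) -> np.ndarray:
        return self.trajectory[-1]

    @property
    def survivors(self) -> np.ndarray:
        """1-based ids of strains with nonzero final population."""
        return np.flatnonzero(self.trajectory[-1] > 0) + 1


# ---------------------------------------------------------------------------
# neighbor bookkeeping

_NEIGHBOR_CACHE: dict[tuple[int, int, str], tuple[np.ndarray, np.ndarray]] = {}


def _neighbor_table(height: int, width: int, boundary: str):
    """Flat neighbor index table (8, H*W) and per-cell neighbor counts."""
    key = (height, width, boundary)
    cached = _NEIGHBOR_CACHE.get(key)
    if cached is not None:
        return cached
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    table = np.zeros((8, height * width), dtype=np.int64)
    if boundary == "torus":
        for k, (dy, dx) in enumerate(_MOORE_OFFSETS):
            table[k] = (((rr + dy) % height) * width + (cc + dx) % width).ravel()
        counts = np.full(height * width, 8, dtype=np.int64)
    else:
        counts = np.zeros(height * width, dtype=np.int64)
        for dy, dx in _MOORE_OFFSETS:
            nr, nc = rr + dy, cc + dx
            ok = ((nr >= 0) & (nr < height) & (nc >= 0) & (nc < width)).ravel()
            flat = (nr.clip(0, height - 1) * width + nc.clip(0, width - 1)).ravel()
            idx = np.flatnonzero(ok)
            table[counts[idx], idx] = flat[idx]
            counts[idx] += 1
    _NEIGHBOR_CACHE[key] = (table, counts)
    return table, counts


def neighbors(grid: Grid, cell: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore neighbors of ``cell`` honoring the grid's boundary mode."""
    r, c = cell
    if not (0 <= r < grid.height and 0 <= c < grid.width):
        raise ValueError(f"cell {cell} outside {grid.height}x{grid.width} grid")
    out = []
    for dy, dx in _MOORE_OFFSETS:
        nr, nc = r + dy, c + dx
        if grid.boundary == "torus":
            out.append((nr % grid.height, nc % grid.width))
        elif 0 <= nr < grid.height and 0 <= nc < grid.width:
            out.append((nr, nc))
    return out


# ---------------------------------------------------------------------------
# operations


def seed_grid(
    width: int,
    height: int,
    counts,
    rng: np.random.Generator,
    boundary: str = "torus",
) -> Grid:
    """Place ``counts[s]`` one-cell colonies of strain s+1 uniformly at random.

    Colonies never collide: positions are a uniform draw without
    replacement over all cells.
    """
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total > width * height:
        raise ValueError(
            f"cannot place {total} colonies on a {width}x{height} grid "
            f"({width * height} cells)"
        )
    state = np.zeros(height * width, dtype=np.int32)
    positions = rng.permutation(height * width)[:total]
    values = np.repeat(np.arange(1, counts.size + 1, dtype=np.int32), counts)
    state[positions] = values
    return Grid(state=state.reshape(height, width), boundary=boundary)


def step(
    grid: Grid,
    matrix,
    params: SimParams,
    rng: np.random.Generator,
) -> Grid:
    """One update of every cell (dispatches on ``params.update_mode``)."""
    if params.update_mode == "asynchronous_sweep":
        return _step_async(grid, matrix, params, rng)
    return _step_sync(grid, matrix, params, rng)


def _antagonizes_lut(matrix, n: int) -> np.ndarray:
    """(n+1, n+1) boolean lookup with a guard row/column for empty cells."""
    adj = np.asarray(getattr(matrix, "adj", matrix), dtype=bool)
    if adj.shape != (n, n):
        raise ValueError(f"matrix shape {adj.shape} does not match {n} strains")
    lut = np.zeros((n + 1, n + 1), dtype=bool)
    lut[1:, 1:] = adj
    return lut


def _step_sync(grid, matrix, params, rng):
    n = np.asarray(getattr(matrix, "adj", matrix)).shape[0]
    pg_lut, pd_lut = params.prob_vectors(n)
    antag = _antagonizes_lut(matrix, n)
    table, counts = _neighbor_table(grid.height, grid.width, grid.boundary)
    flat = grid.state.ravel()
    ncell = flat.size

    u_nbr = rng.random(ncell)
    idx = np.minimum((u_nbr * counts).astype(np.int64), counts - 1)
    j_state = flat[table[idx, np.arange(ncell)]]
    u_evt = rng.random(ncell)

    new = flat.copy()
    empty = flat == EMPTY
    grow = empty & (j_state != EMPTY) & (u_evt < pg_lut[j_state])
    new[grow] = j_state[grow]
    occupied = ~empty
    die = occupied & (u_evt < pd_lut[flat])
    killed = occupied & ~die & antag[j_state, flat]
    new[die | killed] = EMPTY
    return Grid(state=new.reshape(grid.state.shape), boundary=grid.boundary)


def _step_async(grid, matrix, params, rng):
    """In-place sweep over cells in a fresh random order each step."""
    n = np.asarray(getattr(matrix, "adj", matrix)).shape[0]
    pg_lut, pd_lut = params.prob_vectors(n)
    antag = _antagonizes_lut(matrix, n)
    table, counts = _neighbor_table(grid.height, grid.width, grid.boundary)
    flat = grid.state.ravel().copy()
    order = rng.permutation(flat.size)
    u_nbr = rng.random(flat.size)
    u_evt = rng.random(flat.size)
    for pos, i in enumerate(order):
        k = min(int(u_nbr[pos] * counts[i]), counts[i] - 1)
        j = table[k, i]
        si, sj = flat[i], flat[j]
        if si == EMPTY:
            if sj != EMPTY and u_evt[pos] < pg_lut[sj]:
                flat[i] = sj
        else:
            if u_evt[pos] < pd_lut[si] or antag[sj, si]:
                flat[i] = EMPTY
    return Grid(state=flat.reshape(grid.state.shape), boundary=grid.boundary)


def shuffle_grid(grid: Grid, rng: np.random.Generator) -> Grid:
    """Permute all cell states uniformly at random (multiset preserved)."""
    flat = grid.state.ravel()
    return Grid(
        state=flat[rng.permutation(flat.size)].reshape(grid.state.shape),
        boundary=grid.boundary,
    )


def run_simulation(matrix, params: SimParams, initial) -> SimResult:
    """Run ``params.steps`` updates from an initial grid or per-strain counts.

    When ``initial`` is a count vector the grid is seeded from the run's
    own random stream, so a single seed fully determines the run.
    Shuffling (when enabled) is applied after every
    ``shuffle_interval``-th update step.
    """
    adj = np.asarray(getattr(matrix, "adj", matrix), dtype=bool)
    n = adj.shape[0]
    rng = np.random.default_rng(params.seed)

    if isinstance(initial, Grid):
        grid = initial.copy()
        grid.boundary = params.boundary
    else:
        grid = seed_grid(params.width, params.height, initial, rng, params.boundary)
    if grid.state.max(initial=0) > n:
        raise ValueError("grid holds strain ids outside the matrix's strain set")

    trajectory = np.zeros((params.steps + 1, n), dtype=np.int64)
    empties = np.zeros(params.steps + 1, dtype=np.int64)
    snapshots: dict[int, np.ndarray] = {}
    wanted = set(params.snapshot_steps)

    def record(t: int) -> None:
        counts = grid.population_counts(n)
        trajectory[t] = counts[1:]
        empties[t] = counts[0]
        if t in wanted:
            snapshots[t] = grid.state.copy()

    record(0)
    for t in range(1, params.steps + 1):
        grid = step(grid, matrix, params, rng)
        if params.shuffle_interval is not None and t % params.shuffle_interval == 0:
            grid = shuffle_grid(grid, rng)
        record(t)

    return SimResult(
        trajectory=trajectory,
        empty_trajectory=empties,
        snapshots=snapshots,
        final_grid=grid,
        params=params,
        seed_used=params.seed,
    )


def scaled_initial_counts(
    reference_pops,
    width: int,
    height: int,
    cap_fraction: float = 0.01,
) -> np.ndarray:
    """Scale a reference population vector into initial colony counts.

    The most populous strain receives ``round(cap_fraction * width * height)``
    colonies; other strains scale proportionally, with every strain that
    had a positive reference population guaranteed at least one colony.
    """
    ref = np.asarray(reference_pops, dtype=float)
    if (ref < 0).any():
        raise ValueError("reference populations must be non-negative")
    mx = ref.max(initial=0.0)
    if mx <= 0:
        raise ValueError("reference populations are all zero")
    cap = int(round(cap_fraction * width * height))
    counts = np.rint(ref / mx * cap).astype(int)
    counts[(ref > 0) & (counts < 1)] = 1
    counts[ref == mx] = cap
    return counts
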