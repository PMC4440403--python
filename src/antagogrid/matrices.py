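"""Directed antagonism networks: containers, CSV/TSV I/O, and generators.

Two generators are provided.  ``gen_random_matrix`` draws N directed links
uniformly without replacement among all ordered strain pairs (no
self-antagonism).  ``gen_experimental_like_matrix`` runs a Metropolis
Markov chain in the fixed-link-count ensemble so that the result has the
same number of high/medium/low-level antagonistic strains as a target
catalog (hard constraint) and, optionally, an aggressiveness-index vector
close in L1 to a target vector.  This stands in for the original assayed
matrix, which is published only as an image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import strains as _strains

__all__ = [
    "AntagonismMatrix",
    "MatrixGenSpec",
    "MatrixSummary",
    "MCMCResult",
    "MCMCNonConvergence",
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "write_edge_list",
    "gen_random_matrix",
    "gen_experimental_like_matrix",
    "summarize_matrix",
    "spec_from_strain_table",
]


@dataclass(frozen=True)
class AntagonismMatrix:
    """Boolean relation ``adj[a, v]`` = "strain a antagonizes strain v".

    The diagonal is identically false (no self-antagonism).  The relation
    need not be symmetric or antisymmetric.  ``labels`` are optional strain
    labels (defaults ``S1..Sn``); row/column order is strain order.
    """

    adj: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        adj = np.asarray(self.adj, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if adj.diagonal().any():
            raise ValueError("self-antagonism is not allowed (nonzero diagonal)")
        object.__setattr__(self, "adj", adj)
        labels = self.labels or tuple(f"S{i + 1}" for i in range(adj.shape[0]))
        if len(labels) != adj.shape[0]:
            raise ValueError("label count must match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate strain labels")
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n(self) -> int:
        return self.adj.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adj.sum())

    @property
    def out_degree(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(int)

    @property
    def in_degree(self) -> np.ndarray:
        return self.adj.sum(axis=0).astype(int)

    @property
    def ai(self) -> np.ndarray:
        return _strains.compute_ai(self.adj)


@dataclass(frozen=True)
class MatrixGenSpec:
    """Configuration for matrix generation.

    ``n_links`` is the number of directed links N; the assayed matrix's N
    is not published, so it is always an explicit input.  For
    experimental-like mode, ``target_class_counts`` is the (high, medium,
    low) strain-count triple the result must match exactly, and
    ``target_ai`` an optional AI vector to approach in L1 distance.
    ``level_feature`` names the scalar classified ("out_degree" or "ai")
    and must match how the targets were derived.
    """

    n_strains: int
    n_links: int
    mode: str = "random"  # or "experimental_like"
    target_class_counts: tuple[int, int, int] | None = None
    target_ai: np.ndarray | None = None
    target_out_degree: np.ndarray | None = None
    target_in_degree: np.ndarray | None = None
    level_feature: str = "out_degree"
    class_weight: float = 1000.0
    ai_weight: float = 1.0
    degree_weight: float = 1.0
    temperature: float = 1.0
    anneal: float = 1.0  # geometric cooling factor per 1000 proposals
    patience: int = 50_000
    max_proposals: int = 500_000
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be positive")
        max_links = self.n_strains * (self.n_strains - 1)
        if not (0 <= self.n_links <= max_links):
            raise ValueError(
                f"n_links must be in [0, {max_links}] for {self.n_strains} strains"
            )
        if self.mode not in ("random", "experimental_like"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "experimental_like":
            if self.target_class_counts is None:
                raise ValueError("experimental_like mode requires target_class_counts")
            if sum(self.target_class_counts) != self.n_strains:
                raise ValueError("target class counts must sum to n_strains")
        for name in ("target_ai", "target_out_degree", "target_in_degree"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=int)
                if v.shape != (self.n_strains,):
                    raise ValueError(f"{name} must have length n_strains")
                object.__setattr__(self, name, v)


@dataclass(frozen=True)
class MatrixSummary:
    out_degree: np.ndarray
    in_degree: np.ndarray
    ai: np.ndarray
    class_counts: tuple[int, int, int] | None  # (high, medium, low)
    n_links: int
    level_feature: str = "out_degree"


@dataclass(frozen=True)
class MCMCResult:
    matrix: AntagonismMatrix
    energy: float
    class_energy: float
    ai_l1: float
    degree_l1: float
    n_proposals: int
    converged: bool


class MCMCNonConvergence(RuntimeError):
    """Class-count constraint not met within the proposal budget.

    Carries the best matrix found so far in ``result``.
    """

    def __init__(self, msg: str, result: MCMCResult):
        super().__init__(msg)
        self.result = result


# ---------------------------------------------------------------------------
# CSV / edge-list I/O


def _check_labels(labels) -> None:
    for lab in labels:
        if "," in lab or "\n" in lab or "\t" in lab:
            raise ValueError(f"label {lab!r} contains a forbidden character")


def write_matrix(matrix: AntagonismMatrix, sink) -> None:
    """Write the documented CSV dialect (aggressor rows, 0/1 cells)."""
    _check_labels(matrix.labels)
    own = isinstance(sink, str)
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        fh.write("," + ",".join(matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.adj):
            fh.write(lab + "," + ",".join("1" if v else "0" for v in row) + "\n")
    finally:
        if own:
            fh.close()


def read_matrix(source, orientation: str = "aggressor_rows") -> AntagonismMatrix:
    """Read a labeled 0/1 CSV into an antagonism matrix.

    ``orientation="aggressor_rows"`` (default) means entry [i][j]=1 ⇔
    strain i antagonizes strain j; ``"aggressor_columns"`` is the
    transpose convention (the one used by the published heat-map figure),
    and is transposed on read so internal storage is always
    (aggressor, victim).
    """
    if orientation not in ("aggressor_rows", "aggressor_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    own = isinstance(source, str)
    fh = open(source, "r", encoding="utf-8") if own else source
    try:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    finally:
        if own:
            fh.close()
    if not lines:
        raise ValueError("empty matrix file")
    header = lines[0].split(",")
    col_labels = header[1:]
    if len(set(col_labels)) != len(col_labels):
        raise ValueError("duplicate column labels")
    n = len(col_labels)
    if len(lines) - 1 != n:
        raise ValueError(f"matrix is not square: {n} columns, {len(lines) - 1} rows")
    row_labels = []
    data = np.zeros((n, n), dtype=bool)
    for i, ln in enumerate(lines[1:]):
        parts = ln.split(",")
        if len(parts) != n + 1:
            raise ValueError(f"row {i + 1} has {len(parts) - 1} cells, expected {n}")
        row_labels.append(parts[0])
        for j, cell in enumerate(parts[1:]):
            if cell not in ("0", "1"):
                raise ValueError(f"non-binary cell {cell!r} at row {i + 1}")
            data[i, j] = cell == "1"
    if row_labels != col_labels:
        raise ValueError("row labels do not match column labels")
    if data.diagonal().any():
        raise ValueError("nonzero diagonal: self-antagonism is not allowed")
    if orientation == "aggressor_columns":
        data = data.T
    return AntagonismMatrix(adj=data, labels=tuple(col_labels))


def write_edge_list(matrix: AntagonismMatrix, sink) -> None:
    """Write links as a TSV of ``aggressor\\tvictim`` label pairs."""
    own = isinstance(sink, str)
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        fh.write("aggressor\tvictim\n")
        for a, v in zip(*np.nonzero(matrix.adj)):
            fh.write(f"{matrix.labels[a]}\t{matrix.labels[v]}\n")
    finally:
        if own:
            fh.close()


def read_edge_list(source, labels) -> AntagonismMatrix:
    """Read an ``aggressor\\tvictim`` TSV; ``labels`` fixes strain order."""
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    own = isinstance(source, str)
    fh = open(source, "r", encoding="utf-8") if own else source
    try:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    finally:
        if own:
            fh.close()
    if not lines or lines[0].split("\t") != ["aggressor", "victim"]:
        raise ValueError("expected header 'aggressor\\tvictim'")
    adj = np.zeros((len(labels), len(labels)), dtype=bool)
    for ln in lines[1:]:
        a, v = ln.split("\t")
        adj[index[a], index[v]] = True
    return AntagonismMatrix(adj=adj, labels=labels)


# ---------------------------------------------------------------------------
# Generators


def gen_random_matrix(spec: MatrixGenSpec, rng: np.random.Generator) -> AntagonismMatrix:
    """Draw ``n_links`` directed links uniformly among ordered pairs.

    Sampling is without replacement over the n(n-1) off-diagonal ordered
    pairs, so every pair has inclusion probability n_links / (n(n-1)).
    """
    n = spec.n_strains
    n_pairs = n * (n - 1)
    chosen = rng.choice(n_pairs, size=spec.n_links, replace=False)
    adj = np.zeros((n, n), dtype=bool)
    # pair index p -> (a, v): enumerate off-diagonal cells row by row
    a = chosen // (n - 1)
    r = chosen % (n - 1)
    v = np.where(r >= a, r + 1, r)
    adj[a, v] = True
    return AntagonismMatrix(adj=adj, labels=spec.labels)


def _class_term(feature: np.ndarray, spec: MatrixGenSpec) -> float:
    """L1 mismatch between the feature's k-means class counts and the target."""
    target = np.asarray(spec.target_class_counts, dtype=int)
    try:
        levels = _strains.classify_levels(feature, k=3)
    except ValueError:
        return float(np.abs(target).sum())  # degenerate feature: worst case
    return float(np.abs(levels.counts_vector() - target).sum())


def gen_experimental_like_matrix(
    spec: MatrixGenSpec, rng: np.random.Generator
) -> MCMCResult:
    """Metropolis rewiring toward target class counts (and AI vector).

    Starts from a uniform random matrix with the requested link count and
    proposes single-link relocations (delete one existing link, add one
    absent off-diagonal link), which keeps N fixed.  Energy is::

        class_weight  * |class counts - target|_1
      + ai_weight     * |AI - target_ai|_1
      + degree_weight * (|out - target_out|_1 + |in - target_in|_1)

    with absent targets contributing nothing.  With the default weights
    the class-count term acts as a hard constraint; the optional degree
    targets let the generator also emulate the exerted- and
    received-antagonism link distributions.  Raises
    :class:`MCMCNonConvergence` if the class term never reaches zero
    within the proposal budget.

    The acceptance test is exact Metropolis; as a pure speed-up, a
    proposal is rejected without re-running the classification whenever
    the AI term alone already implies rejection (the class term is
    non-negative, so the AI term is a lower bound on the new energy).
    """
    if spec.mode != "experimental_like":
        raise ValueError("spec.mode must be 'experimental_like'")
    n = spec.n_strains
    matrix = gen_random_matrix(spec, rng)
    adj = matrix.adj.copy()
    out_deg = adj.sum(axis=1).astype(int)
    in_deg = adj.sum(axis=0).astype(int)
    ai = out_deg - in_deg
    target_ai = spec.target_ai
    t_out = spec.target_out_degree
    t_in = spec.target_in_degree
    use_ai_feature = spec.level_feature != "out_degree"

    def feature() -> np.ndarray:
        return ai if use_ai_feature else out_deg

    ai_l1 = float(np.abs(ai - target_ai).sum()) if target_ai is not None else 0.0
    deg_l1 = 0.0
    if t_out is not None:
        deg_l1 += float(np.abs(out_deg - t_out).sum())
    if t_in is not None:
        deg_l1 += float(np.abs(in_deg - t_in).sum())
    class_term = _class_term(feature(), spec)
    energy = (
        spec.class_weight * class_term
        + spec.ai_weight * ai_l1
        + spec.degree_weight * deg_l1
    )
    best = (adj.copy(), energy, class_term, ai_l1, deg_l1)
    floor = 0.0
    if target_ai is not None:
        floor = spec.ai_weight * abs(int(target_ai.sum()))

    temperature = spec.temperature
    since_improve = 0
    proposals = 0
    links = np.flatnonzero(adj)  # flat indices of present links
    while proposals < spec.max_proposals and since_improve < spec.patience:
        if best[1] <= floor and best[2] == 0.0:
            break
        if links.size == 0 or links.size == n * n - n:
            break  # no move possible in an empty or complete relation
        proposals += 1
        if proposals % 1000 == 0:
            temperature *= spec.anneal
        # delete a uniform existing link, add a uniform absent off-diag cell
        del_idx = int(rng.integers(links.size))
        da, dv = divmod(int(links[del_idx]), n)
        while True:
            aa = int(rng.integers(n))
            av = int(rng.integers(n))
            if aa != av and not adj[aa, av]:
                break
        if (aa, av) == (da, dv):
            continue
        # net AI changes of the move (entries may coincide)
        delta: dict[int, int] = {}
        for i, d in ((da, -1), (dv, +1), (aa, +1), (av, -1)):
            delta[i] = delta.get(i, 0) + d
        new_ai_l1 = ai_l1
        if target_ai is not None:
            for i, d in delta.items():
                if d:
                    new_ai_l1 += abs(ai[i] + d - target_ai[i]) - abs(
                        ai[i] - target_ai[i]
                    )
        new_deg_l1 = deg_l1
        if t_out is not None and da != aa:
            new_deg_l1 += (
                abs(out_deg[da] - 1 - t_out[da])
                - abs(out_deg[da] - t_out[da])
                + abs(out_deg[aa] + 1 - t_out[aa])
                - abs(out_deg[aa] - t_out[aa])
            )
        if t_in is not None and dv != av:
            new_deg_l1 += (
                abs(in_deg[dv] - 1 - t_in[dv])
                - abs(in_deg[dv] - t_in[dv])
                + abs(in_deg[av] + 1 - t_in[av])
                - abs(in_deg[av] - t_in[av])
            )
        u = rng.random()
        # new class term >= 0, so the AI + degree terms bound the energy
        lower = spec.ai_weight * new_ai_l1 + spec.degree_weight * new_deg_l1
        temp = max(temperature, 1e-12)
        if lower > energy and u >= math.exp(-(lower - energy) / temp):
            since_improve += 1
            continue
        # exact evaluation on the candidate configuration
        adj[da, dv] = False
        adj[aa, av] = True
        out_deg[da] -= 1
        out_deg[aa] += 1
        in_deg[dv] -= 1
        in_deg[av] += 1
        for i, d in delta.items():
            ai[i] += d
        new_class = _class_term(feature(), spec)
        new_energy = spec.class_weight * new_class + lower
        if new_energy <= energy or u < math.exp(-(new_energy - energy) / temp):
            energy, class_term, ai_l1, deg_l1 = (
                new_energy,
                new_class,
                new_ai_l1,
                new_deg_l1,
            )
            links[del_idx] = aa * n + av
            if energy < best[1]:
                best = (adj.copy(), energy, class_term, ai_l1, deg_l1)
                since_improve = 0
            else:
                since_improve += 1
        else:
            adj[da, dv] = True
            adj[aa, av] = False
            out_deg[da] += 1
            out_deg[aa] -= 1
            in_deg[dv] += 1
            in_deg[av] -= 1
            for i, d in delta.items():
                ai[i] -= d
            since_improve += 1

    best_adj, best_energy, best_class, best_ai, best_deg = best
    result = MCMCResult(
        matrix=AntagonismMatrix(adj=best_adj, labels=spec.labels),
        energy=best_energy,
        class_energy=best_class,
        ai_l1=best_ai,
        degree_l1=best_deg,
        n_proposals=proposals,
        converged=best_class == 0.0,
    )
    if not result.converged:
        raise MCMCNonConvergence(
            f"class-count energy {best_class} not reduced to 0 within "
            f"{proposals} proposals",
            result,
        )
    return result


def summarize_matrix(
    matrix: AntagonismMatrix, levels_feature: str = "out_degree"
) -> MatrixSummary:
    """Degrees, AI, and high/medium/low class counts of a matrix.

    ``class_counts`` is None when the feature has fewer than three
    distinct values (the three-level split is undefined, e.g. for an
    empty relation).
    """
    out_deg = matrix.out_degree
    in_deg = matrix.in_degree
    feature = out_deg if levels_feature == "out_degree" else out_deg - in_deg
    try:
        levels = _strains.classify_levels(feature, k=3, feature_name=levels_feature)
        counts = tuple(levels.counts_vector())
    except ValueError:
        counts = None
    return MatrixSummary(
        out_degree=out_deg,
        in_degree=in_deg,
        ai=out_deg - in_deg,
        class_counts=counts,
        n_links=matrix.n_links,
        level_feature=levels_feature,
    )


def spec_from_strain_table(
    table,
    n_links: int | None = None,
    match_ai: bool = True,
    match_degrees: bool = True,
    level_feature: str = "ai",
    **kwargs,
) -> MatrixGenSpec:
    """Build an experimental-like generation spec from a strain catalog.

    The catalog prints only AI values, so the class-count target is the
    exact 1-D k-means split of the printed AI column and, when
    ``match_ai`` is set, the printed AI vector is also the L1 target.
    ``level_feature`` defaults to "ai" accordingly.

    With ``match_degrees`` (default) the generator also targets the
    minimal degree realization of the AI column: out-degree max(AI, 0)
    and in-degree max(-AI, 0).  This encodes the aggressive / neutral /
    vulnerable architecture the original network exhibits — aggressive
    strains are resistant (near-zero received antagonism), neutral
    strains neither exert nor receive links, vulnerable strains only
    receive them — and it pins the link count to N = Σ max(AI, 0)
    (440 for the packaged catalog), the smallest N any digraph
    realizing the printed AI vector can have.  Pass ``n_links``
    explicitly to use a different ensemble.
    """
    ai = table.ai
    levels = _strains.classify_levels(ai, k=3, feature_name="ai")
    kwargs.setdefault("anneal", 0.90)  # cooling helps the distance terms converge
    t_out = np.maximum(ai, 0)
    t_in = np.maximum(-ai, 0)
    if n_links is None:
        if not match_degrees:
            raise ValueError("n_links is required when match_degrees=False")
        n_links = int(t_out.sum())
    return MatrixGenSpec(
        n_strains=table.n,
        n_links=n_links,
        mode="experimental_like",
        target_class_counts=tuple(levels.counts_vector()),
        target_ai=ai if match_ai else None,
        target_out_degree=t_out if match_degrees else None,
        target_in_degree=t_in if match_degrees else None,
        level_feature=level_feature,
        labels=tuple(table.labels),
        **kwargs,
    )
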