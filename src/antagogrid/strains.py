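"""Strain catalog, aggressiveness index, antagonism-level classification.

The packaged strain table lists 78 *Bacillus*-dominated isolates from the
Churince pond system (Cuatro Cienegas, Mexico) together with their printed
aggressiveness index (AI).  The AI of a strain is the number of other
strains it antagonizes minus the number of strains that antagonize it,
i.e. out-degree minus in-degree of the directed antagonism network.
Strains are ordered by decreasing AI, matching the published catalog.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StrainRecord",
    "StrainTable",
    "AntagonismLevels",
    "load_strain_table",
    "compute_ai",
    "exact_kmeans_1d",
    "classify_levels",
    "pg_from_ai",
]

_LEVEL_NAMES = ("high", "medium", "low")  # ordered by decreasing centroid


@dataclass(frozen=True)
class StrainRecord:
    """One catalog entry: integer id (1-based), collection label, printed AI."""

    id: int
    label: str
    ai: int


@dataclass(frozen=True)
class StrainTable:
    """Ordered strain catalog (decreasing AI, ties allowed)."""

    records: tuple[StrainRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("strain ids must be contiguous from 1")
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("strain labels must be unique")
        ai = [r.ai for r in self.records]
        if any(a < b for a, b in zip(ai, ai[1:])):
            raise ValueError("strain table must be ordered by decreasing AI")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx: int) -> StrainRecord:
        return self.records[idx]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> np.ndarray:
        return np.array([r.id for r in self.records], dtype=int)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def ai(self) -> np.ndarray:
        """Printed aggressiveness indexes, in catalog order."""
        return np.array([r.ai for r in self.records], dtype=int)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tlabel\tai\n")
            for r in self.records:
                fh.write(f"{r.id}\t{r.label}\t{r.ai}\n")


@dataclass(frozen=True)
class AntagonismLevels:
    """Three-level (high/medium/low) classification of a scalar strain feature."""

    level: tuple[str, ...]
    feature_used: str
    centroids: tuple[float, ...] = field(default=())  # descending

    @property
    def counts(self) -> dict[str, int]:
        return {name: sum(1 for s in self.level if s == name) for name in _LEVEL_NAMES}

    def counts_vector(self) -> np.ndarray:
        """(high, medium, low) counts as an integer vector."""
        c = self.counts
        return np.array([c[name] for name in _LEVEL_NAMES], dtype=int)


def load_strain_table(path=None) -> StrainTable:
    """Load the packaged 78-strain catalog (or a user TSV with the same layout).

    The file is tab-separated with header ``id\\tlabel\\tai``.
    """
    if path is None:
        ref = importlib.resources.files("antagogrid.data") / "table1.tsv"
        try:
            text = ref.read_text(encoding="utf-8")
        except FileNotFoundError as exc:  # pragma: no cover - packaging fault
            raise FileNotFoundError(
                "packaged strain table 'table1.tsv' is missing or unreadable"
            ) from exc
        source_name = "table1.tsv"
    else:
        try:
            with open(path, "r", encoding="utf-8") as fh:
                text = fh.read()
        except OSError as exc:
            raise FileNotFoundError(f"cannot read strain table {path!r}") from exc
        source_name = str(path)

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != ["id", "label", "ai"]:
        raise ValueError(f"{source_name}: expected header 'id\\tlabel\\tai'")
    records = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{source_name}: malformed row {ln!r}")
        records.append(StrainRecord(int(parts[0]), parts[1], int(parts[2])))
    return StrainTable(tuple(records))


def _as_adjacency(matrix) -> np.ndarray:
    adj = getattr(matrix, "adj", matrix)
    adj = np.asarray(adj, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("antagonism matrix must be square")
    if adj.diagonal().any():
        raise ValueError("antagonism matrix must have an all-false diagonal")
    return adj


def compute_ai(matrix) -> np.ndarray:
    """Aggressiveness index per strain: out-degree minus in-degree.

    Accepts an :class:`~antagogrid.matrices.AntagonismMatrix` or a boolean
    adjacency array whose ``[a, v]`` entry means "a antagonizes v".  The
    vector always sums to zero because every link contributes +1 to its
    source and -1 to its target.
    """
    adj = _as_adjacency(matrix)
    return adj.sum(axis=1).astype(int) - adj.sum(axis=0).astype(int)


_SPLIT_PAIR_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _split_pairs_k3(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid split-point pairs 0 < a < b < n, flattened (cached per n)."""
    cached = _SPLIT_PAIR_CACHE.get(n)
    if cached is None:
        a, b = np.triu_indices(n - 1, k=1)
        cached = (a + 1, b + 1)
        _SPLIT_PAIR_CACHE[n] = cached
    return cached


def exact_kmeans_1d(values: Sequence[float], k: int) -> np.ndarray:
    """Globally optimal 1-D k-means by contiguous partition of sorted values.

    For one-dimensional data the optimal k-means partition consists of
    contiguous blocks of the sorted values, so the global optimum can be
    found by scanning all split points (cheap for the n=78, k=3 case this
    package needs).  Returns per-element cluster indexes, 0 = smallest
    centroid.  Ties in the input are kept together by stable sort order.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError("need at least k values")
    if np.unique(x).size < k:
        raise ValueError(
            f"only {np.unique(x).size} distinct values; reduce k below that"
        )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.concatenate(([0.0], np.cumsum(xs)))
    s2 = np.concatenate(([0.0], np.cumsum(xs * xs)))

    def seg_cost(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        # within-segment sum of squared deviations for xs[i:j]
        cnt = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / cnt

    if k == 1:
        labels_sorted = np.zeros(n, dtype=int)
    elif k == 2:
        a = np.arange(1, n)
        cost = seg_cost(np.zeros_like(a), a) + seg_cost(a, np.full_like(a, n))
        best = a[int(np.argmin(cost))]
        labels_sorted = (np.arange(n) >= best).astype(int)
    elif k == 3:
        A, B = _split_pairs_k3(n)
        cost = (
            seg_cost(np.zeros_like(A), A)
            + seg_cost(A, B)
            + seg_cost(B, np.full_like(B, n))
        )
        i = int(np.argmin(cost))
        sa, sb = int(A[i]), int(B[i])
        labels_sorted = np.zeros(n, dtype=int)
        labels_sorted[sa:sb] = 1
        labels_sorted[sb:] = 2
    else:
        # dynamic program, O(k n^2); only reached for k > 3
        cost_all = np.full((n + 1, n + 1), np.inf)
        for i in range(n):
            j = np.arange(i + 1, n + 1)
            cost_all[i, i + 1 :] = seg_cost(np.full_like(j, i), j)
        dp = np.full((k + 1, n + 1), np.inf)
        back = np.zeros((k + 1, n + 1), dtype=int)
        dp[0, 0] = 0.0
        for c in range(1, k + 1):
            for j in range(c, n + 1):
                cand = dp[c - 1, :j] + cost_all[:j, j]
                i = int(np.argmin(cand))
                dp[c, j] = cand[i]
                back[c, j] = i
        labels_sorted = np.zeros(n, dtype=int)
        j = n
        for c in range(k, 0, -1):
            i = back[c, j]
            labels_sorted[i:j] = c - 1
            j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def classify_levels(
    feature: Sequence[float], k: int = 3, feature_name: str = "out_degree"
) -> AntagonismLevels:
    """Partition strains into high/medium/low antagonism levels.

    Uses exact 1-D k-means (contiguous partition of the sorted feature);
    the cluster with the largest centroid is labeled "high".  ``feature``
    is typically either the out-degree (strains antagonized) or the AI.
    """
    if k != 3:
        raise ValueError("level classification is defined for k = 3")
    x = np.asarray(feature, dtype=float)
    labels = exact_kmeans_1d(x, k)  # 0 = smallest centroid
    centroids = np.array([x[labels == c].mean() for c in range(k)])
    # map ascending-centroid cluster index -> level name (high = largest)
    name_by_cluster = {k - 1 - c: _LEVEL_NAMES[c] for c in range(k)}
    level = tuple(name_by_cluster[int(c)] for c in labels)
    return AntagonismLevels(
        level=level,
        feature_used=feature_name,
        centroids=tuple(sorted(centroids, reverse=True)),
    )


def pg_from_ai(
    ai: Sequence[float],
    pg_at_extreme_low_ai: float = 1.0,
    pg_at_extreme_high_ai: float = 0.5,
) -> np.ndarray:
    """Affine map from aggressiveness index to colonization probability.

    Models the metabolic cost of antagonism: by default the most aggressive
    strain (max AI) grows slowest (Pg = 0.5) and the least aggressive one
    fastest (Pg = 1).  Swap the two endpoint arguments to flip the
    direction.  Endpoints are attained exactly; values are linear in AI.
    """
    ai = np.asarray(ai, dtype=float)
    for p in (pg_at_extreme_low_ai, pg_at_extreme_high_ai):
        if not (0.0 < p <= 1.0):
            raise ValueError("endpoint probabilities must be in (0, 1]")
    lo, hi = ai.min(), ai.max()
    if lo == hi:
        raise ValueError("constant AI vector: affine mapping undefined")
    t = (ai - lo) / (hi - lo)
    return pg_at_extreme_low_ai + t * (pg_at_extreme_high_ai - pg_at_extreme_low_ai)
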