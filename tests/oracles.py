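"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (double loops, flood fill,
exhaustive search) and shares no code with the package internals.
"""

from itertools import combinations

import numpy as np


def ai_by_double_loop(adj):
    """out-degree minus in-degree, counted cell by cell."""
    n = len(adj)
    ai = [0] * n
    for a in range(n):
        for v in range(n):
            if adj[a][v]:
                ai[a] += 1
                ai[v] -= 1
    return ai


def best_contiguous_3split(values):
    """Exhaustive optimal 3-way contiguous partition of sorted values.

    Returns cluster labels (0 = smallest block) per original element.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    xs = values[order]

    def wcss(seg):
        return float(((seg - seg.mean()) ** 2).sum()) if len(seg) else 0.0

    best, best_cost = None, np.inf
    for a, b in combinations(range(1, n), 2):
        cost = wcss(xs[:a]) + wcss(xs[a:b]) + wcss(xs[b:])
        if cost < best_cost - 1e-12:
            best_cost, best = cost, (a, b)
    a, b = best
    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[a:b] = 1
    labels_sorted[b:] = 2
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, best_cost


def flood_fill_patches(state, boundary="torus", connectivity="moore8"):
    """Per-strain component sizes by breadth-first flood fill."""
    h, w = state.shape
    if connectivity == "moore8":
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                   (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(state, dtype=bool)
    sizes = {}
    for r0 in range(h):
        for c0 in range(w):
            s = state[r0, c0]
            if s == 0 or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            size = 0
            while stack:
                r, c = stack.pop()
                size += 1
                for dy, dx in offsets:
                    nr, nc = r + dy, c + dx
                    if boundary == "torus":
                        nr, nc = nr % h, nc % w
                    elif not (0 <= nr < h and 0 <= nc < w):
                        continue
                    if not seen[nr, nc] and state[nr, nc] == s:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            sizes.setdefault(int(s), []).append(size)
    return {s: sorted(v, reverse=True) for s, v in sizes.items()}


def spearman_by_hand(x, y):
    """Mid-rank Spearman: Pearson product-moment of the rank vectors."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
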