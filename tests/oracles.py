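"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from its definition, avoiding the code
paths of the implementation it checks: the KS score via an explicit
position walk, UPGMA via from-scratch cross-pair means, and the dendrogram
F-score via exhaustive node enumeration with explicit set algebra.
"""

from __future__ import annotations

import numpy as np

from gslhc.core_io import Dendrogram


def naive_ks(positions: list[int], n: int) -> float:
    """Two-sided KS score by walking every rank position.

    At each rank x the hit empirical CDF is compared against the uniform
    x/n; the upward deviation is taken just after a hit and the downward
    deviation just before one.
    """
    hits = set(positions)
    t = len(hits)
    best_up = -np.inf
    best_down = -np.inf
    seen = 0
    for x in range(1, n + 1):
        before = seen / t
        if x in hits:
            seen += 1
        after = seen / t
        best_down = max(best_down, x / n - before)
        best_up = max(best_up, after - x / n)
    return best_up if best_up >= best_down else -best_down


def brute_upgma(ids: list[str], dist: np.ndarray) -> Dendrogram:
    """UPGMA recomputing every cluster-pair distance from the original matrix.

    At each step the distance between two clusters is the mean of all
    cross-pair leaf distances, recomputed from scratch (no recurrence);
    ties break on the lexicographically smallest member id.
    """
    n = len(ids)
    clusters: list[tuple[int, list[int]]] = [(i, [i]) for i in range(n)]
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                _, ma = clusters[a]
                _, mb = clusters[b]
                d = float(dist[np.ix_(ma, mb)].mean())
                key = tuple(
                    sorted((min(ids[k] for k in ma), min(ids[k] for k in mb)))
                )
                if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and key < best[1]
                ):
                    best = (d, key, a, b)
        d, _, a, b = best
        node_a, ma = clusters[a]
        node_b, mb = clusters[b]
        if min(ids[k] for k in mb) < min(ids[k] for k in ma):
            node_a, node_b = node_b, node_a
        merges.append((node_a, node_b, d))
        merged = (next_node, ma + mb)
        next_node += 1
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return Dendrogram(leaves=tuple(ids), merges=tuple(merges))


def brute_fscore(
    dendrogram: Dendrogram, labels: dict[str, str]
) -> tuple[dict[str, float], float]:
    """Exhaustive F-score: every node tried as predictor of every class."""
    n = dendrogram.n_leaves
    node_sets = [dendrogram.leaf_names(v) for v in range(2 * n - 1)]
    classes = sorted(set(labels.values()))
    per_class: dict[str, float] = {}
    weighted = 0.0
    for cls in classes:
        truth = {leaf for leaf in dendrogram.leaves if labels[leaf] == cls}
        best = 0.0
        for node_leaves in node_sets:
            tp = len(node_leaves & truth)
            fp = len(node_leaves - truth)
            fn = len(truth - node_leaves)
            if tp == 0:
                continue
            p = tp / (tp + fp)
            r = tp / (tp + fn)
            best = max(best, 2 * p * r / (p + r))
        per_class[cls] = best
        weighted += len(truth) / n * best
    return per_class, weighted


def random_dendrogram(rng: np.random.Generator, n: int) -> Dendrogram:
    """A random binary ultrametric tree with strictly increasing heights."""
    leaves = tuple(f"leaf{i:03d}" for i in range(n))
    available = list(range(n))
    merges = []
    height = 0.0
    for k in range(n - 1):
        height += float(rng.uniform(0.01, 0.2))
        i, j = sorted(rng.choice(len(available), size=2, replace=False))
        b = available.pop(j)
        a = available.pop(i)
        merges.append((a, b, height))
        available.append(n + k)
    return Dendrogram(leaves=leaves, merges=tuple(merges))
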