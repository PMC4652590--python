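"""Quantitative evaluation of clusterings and profiles.

* :func:`dendrogram_fscore` treats every dendrogram node (leaves included)
  as a candidate predictor of a class: precision P = TP/(TP+FP), recall
  R = TP/(TP+FN) over the node's leaf set, F = 2PR/(P+R).  Per class the
  best node is kept and the classification score is the class-size-weighted
  mean of the per-class maxima (the Larsen-Aone cluster F-measure).
* :func:`label_permutation_p` attaches permutation significance to the
  per-class F-scores by shuffling labels across leaves.
* :func:`topk_overlap` measures reproducibility of two profiles as the
  fractional overlap of their top-k features (ranked by |value| by default).
* :func:`group_correlation_compare` contrasts how strongly designated drug
  pairs correlate in two feature spaces (e.g. gene-set enrichment scores
  versus gene log-ratios).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Dendrogram, ExpressionMatrix

__all__ = [
    "PerClassScore",
    "ClassifierScore",
    "dendrogram_fscore",
    "label_permutation_p",
    "topk_overlap",
    "GroupCorrelationResult",
    "group_correlation_compare",
]


@dataclass(frozen=True)
class PerClassScore:
    best_node_id: int
    precision: float
    recall: float
    f: float


@dataclass(frozen=True)
class ClassifierScore:
    """Dendrogram-as-classifier evaluation against leaf labels."""

    per_class: dict[str, PerClassScore]
    weighted_f: float
    class_sizes: dict[str, int]


def _class_count_matrix(
    dendrogram: Dendrogram, labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-node class membership counts over all 2n-1 nodes.

    Returns (counts[node, class], node_sizes[node], class_names).
    """
    unlabeled = [leaf for leaf in dendrogram.leaves if leaf not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled[:5]}")
    classes = sorted({labels[leaf] for leaf in dendrogram.leaves})
    class_index = {c: k for k, c in enumerate(classes)}
    n = dendrogram.n_leaves
    counts = np.zeros((2 * n - 1, len(classes)))
    for i, leaf in enumerate(dendrogram.leaves):
        counts[i, class_index[labels[leaf]]] = 1.0
    for k, (a, b, _) in enumerate(dendrogram.merges):
        counts[n + k] = counts[a] + counts[b]
    node_sizes = counts.sum(axis=1)
    return counts, node_sizes, classes


def dendrogram_fscore(
    dendrogram: Dendrogram, labels: Mapping[str, str]
) -> ClassifierScore:
    """Best-node F-score per class and the size-weighted classification F.

    Every node's leaf set is tried as the predicted positive set; ties on F
    resolve to the smallest node id.  F_i = 1 exactly when some node's leaf
    set equals class i's leaf set.
    """
    counts, node_sizes, classes = _class_count_matrix(dendrogram, labels)
    n = dendrogram.n_leaves
    class_totals = counts[: 2 * n - 1].max(axis=0) if n == 1 else counts[-1]
    per_class: dict[str, PerClassScore] = {}
    class_sizes: dict[str, int] = {}
    weighted = 0.0
    for k, cls in enumerate(classes):
        size = class_totals[k]
        # F = 2*TP / (node_size + class_size): harmonic mean of P and R
        f_all = 2.0 * counts[:, k] / (node_sizes + size)
        best = int(np.argmax(f_all))
        tp = counts[best, k]
        per_class[cls] = PerClassScore(
            best_node_id=best,
            precision=float(tp / node_sizes[best]),
            recall=float(tp / size),
            f=float(f_all[best]),
        )
        class_sizes[cls] = int(size)
        weighted += (size / n) * f_all[best]
    return ClassifierScore(
        per_class=per_class, weighted_f=float(weighted), class_sizes=class_sizes
    )


def label_permutation_p(
    dendrogram: Dendrogram,
    labels: Mapping[str, str],
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Per-class permutation p for the best-node F-scores.

    Labels are shuffled jointly across leaves ``n_perm`` times; for class i,
    p = (1 + #{permuted F_i >= observed F_i}) / (n_perm + 1).
    """
    observed = dendrogram_fscore(dendrogram, labels)
    counts, node_sizes, classes = _class_count_matrix(dendrogram, labels)
    n = dendrogram.n_leaves
    rng = np.random.default_rng(seed)
    label_vector = np.array(
        [labels[leaf] for leaf in dendrogram.leaves], dtype=object
    )
    exceed = {c: 0 for c in classes}
    for _ in range(n_perm):
        permuted = rng.permutation(label_vector)
        perm_labels = dict(zip(dendrogram.leaves, permuted))
        score = dendrogram_fscore(dendrogram, perm_labels)
        for cls in classes:
            if score.per_class[cls].f >= observed.per_class[cls].f - 1e-12:
                exceed[cls] += 1
    return {c: (1 + exceed[c]) / (n_perm + 1) for c in classes}


def topk_overlap(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
    k: int = 1000,
    ranking: str = "absolute",
) -> float:
    """Fractional overlap of the top-k features of two profiles.

    Features are ranked by descending |value| (``ranking='absolute'``, the
    default — differential expression regardless of direction) or by
    descending signed value (``ranking='signed'``); ties keep input order.
    Only the shared feature universe is ranked.
    """
    if ranking not in ("absolute", "signed"):
        raise ValueError("ranking must be 'absolute' or 'signed'")
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    y_ids = set(ys.index)
    shared = [i for i in xs.index if i in y_ids]
    if k <= 0 or k > len(shared):
        raise ValueError(f"k must be in [1, {len(shared)}], got {k}")

    def top(series: pd.Series) -> set:
        values = series.loc[shared].to_numpy()
        key = -np.abs(values) if ranking == "absolute" else -values
        order = np.argsort(key, kind="stable")[:k]
        return {shared[i] for i in order}

    return len(top(xs) & top(ys)) / k


@dataclass(frozen=True)
class GroupCorrelationResult:
    """Per-pair correlations in two feature spaces plus summary statistics."""

    pairs: tuple[tuple[str, str], ...]
    r_a: np.ndarray
    r_b: np.ndarray
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    t_pvalue: float


def group_correlation_compare(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
) -> GroupCorrelationResult:
    """Pearson correlation of designated drug pairs in two feature spaces.

    For each (drug, drug) pair the two drugs' columns are correlated within
    each matrix; the summary reports per-matrix mean and SD (ddof=1) plus a
    Welch two-sample t between the two correlation sets.
    """
    if not pairs:
        raise ValueError("need at least one drug pair")
    r_a = np.empty(len(pairs))
    r_b = np.empty(len(pairs))
    for i, (d1, d2) in enumerate(pairs):
        for matrix, out in ((matrix_a, r_a), (matrix_b, r_b)):
            try:
                v1 = matrix.col(d1).to_numpy()
                v2 = matrix.col(d2).to_numpy()
            except KeyError:
                raise KeyError(f"drug pair ({d1!r}, {d2!r}) missing from matrix")
            out[i] = np.corrcoef(v1, v2)[0, 1]
    welch = stats.ttest_ind(r_a, r_b, equal_var=False)
    ddof = 1 if len(pairs) > 1 else 0
    return GroupCorrelationResult(
        pairs=tuple((str(a), str(b)) for a, b in pairs),
        r_a=r_a,
        r_b=r_b,
        mean_a=float(r_a.mean()),
        sd_a=float(r_a.std(ddof=ddof)),
        mean_b=float(r_b.mean()),
        sd_b=float(r_b.std(ddof=ddof)),
        t_statistic=float(welch.statistic),
        t_pvalue=float(welch.pvalue),
    )
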