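"""Cohort summaries and UPGMA dendrograms.

Each cohort of scalar complexity values (lambda_max or SampEn) is
summarized by its mean, sample SD, a two-sided one-sample Student-t test
of the mean against zero, and t-based 95%/99% confidence intervals:

    CI_level = mean +/- t_{n-1,(1+level)/2} * sd / sqrt(n)

Cohorts are compared through the absolute difference of their means, and
the resulting distance matrix is clustered with UPGMA (average linkage);
merge heights are half the inter-cluster distance, giving an ultrametric
tree serializable as newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "CohortSummary",
    "Dendrogram",
    "summarize_cohort",
    "summary_from_moments",
    "cohort_distance_matrix",
    "upgma",
]


@dataclass(frozen=True)
class CohortSummary:
    label: str
    n: int
    mean: float
    sd: float
    p_value: float
    ci95: tuple
    ci99: tuple
    degenerate: bool = False  # sd == 0: zero-width CIs, p-value not meaningful


def _t_ci(mean: float, sd: float, n: int, level: float) -> tuple:
    half = stats.t.ppf((1.0 + level) / 2.0, n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


def summary_from_moments(mean: float, sd: float, n: int, label: str = "") -> CohortSummary:
    """Cohort summary computed directly from (mean, sd, n).

    Lets printed Mean +/- SD table rows be checked without the raw values.
    """
    if n < 2:
        raise ValueError(f"cohort '{label}': need n >= 2, got {n}")
    if sd < 0 or not np.isfinite(sd) or not np.isfinite(mean):
        raise ValueError(f"cohort '{label}': invalid moments mean={mean}, sd={sd}")
    degenerate = sd == 0.0
    if degenerate:
        p = 0.0 if mean != 0 else 1.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return CohortSummary(
        label=label,
        n=int(n),
        mean=float(mean),
        sd=float(sd),
        p_value=p,
        ci95=_t_ci(mean, sd, n, 0.95),
        ci99=_t_ci(mean, sd, n, 0.99),
        degenerate=degenerate,
    )


def summarize_cohort(values, label: str = "") -> CohortSummary:
    """Summarize a cohort of finite scalar values (n >= 2).

    Infinite values (e.g. the SampEn infinity sentinel) are refused: a
    cohort mean over infinities is meaningless, and the remedy is to
    recompute the statistic with parameters under which it is finite.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"cohort '{label}': need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError(
            f"cohort '{label}': contains non-finite values; infinite SampEn "
            "cannot be averaged (recompute with a larger template length m)"
        )
    return summary_from_moments(float(v.mean()), float(v.std(ddof=1)), v.size, label)


def cohort_distance_matrix(summaries) -> np.ndarray:
    """Pairwise |mean_i - mean_j| over cohort summaries."""
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 cohorts")
    labels = [s.label for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate cohort labels: {labels}")
    means = np.array([s.mean for s in summaries])
    return np.abs(means[:, None] - means[None, :])


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    merges is an ordered list of ((left, right), height) where left/right
    are frozensets of leaf labels and height is half the inter-cluster
    distance at the merge.
    """

    labels: list
    merges: list
    newick: str

    def first_merge(self) -> frozenset:
        """The leaf pair (or clusters) joined first."""
        left, right = self.merges[0][0]
        return left | right

    def outermost_leaf(self):
        """The single leaf joined last, if the final merge attaches one leaf."""
        left, right = self.merges[-1][0]
        for side in (left, right):
            if len(side) == 1:
                return next(iter(side))
        return None


def _newick(node, heights, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    h = heights[node.id]
    parts = []
    for child in (node.left, node.right):
        ch = 0.0 if child.is_leaf() else heights[child.id]
        parts.append(f"{_newick(child, heights, labels)}:{h - ch:.6g}")
    return "(" + ",".join(parts) + ")"


def upgma(D: np.ndarray, labels) -> Dendrogram:
    """UPGMA (average-linkage) tree from a symmetric distance matrix.

    Inter-cluster distance is the size-weighted arithmetic mean of member
    distances; node heights are half the merge distance, so root-to-leaf
    path lengths are all equal (ultrametric).
    """
    D = np.asarray(D, dtype=float)
    labels = list(labels)
    k = len(labels)
    if D.shape != (k, k):
        raise ValueError(f"distance matrix shape {D.shape} does not match {k} labels")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    condensed = D[np.triu_indices(k, 1)]
    Z = hierarchy.linkage(condensed, method="average")

    clusters = {i: frozenset([lab]) for i, lab in enumerate(labels)}
    heights = {}
    merges = []
    for step, (a, b, dist, _size) in enumerate(Z):
        a, b = int(a), int(b)
        node_id = k + step
        height = dist / 2.0
        merges.append(((clusters[a], clusters[b]), height))
        clusters[node_id] = clusters[a] | clusters[b]
        heights[node_id] = height

    root = hierarchy.to_tree(Z)
    newick = _newick(root, heights, labels) + ";"
    return Dendrogram(labels, merges, newick)
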