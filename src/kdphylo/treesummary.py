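"""Posterior tree summaries and the divergence-tempo alignment statistics.

Covers the maximum-clade-credibility point summary with per-clade support
and mean node ages, shortest 95% HPD intervals, the one-sample t test of
the posterior root age against an external hypothesis, internal-node
counting in sliding windows, degree-1 local-regression smoothing, and
interval-cover counting for externally dated site records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.nonparametric.smoothers_lowess import lowess

from .phylo import TimeTree

__all__ = [
    "AnnotatedTree", "TempoSeries", "mcc_tree", "hpd_interval",
    "root_age_t_test", "divergence_tempo", "loess_smooth",
    "count_interval_cover",
]


@dataclass
class AnnotatedTree:
    """An MCC tree with per-clade posterior support and age summaries.

    ``support``, ``age_mean``, ``hpd_lower`` / ``hpd_upper`` are per-node
    arrays aligned with ``tree``'s node indexing; tips carry NaN support.
    Supports below the configured floor are masked to NaN rather than
    collapsed topologically.
    """
    tree: TimeTree
    support: np.ndarray
    age_mean: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray

    def node_table(self) -> pd.DataFrame:
        ints = self.tree.internal_nodes()
        return pd.DataFrame({
            "node": ints,
            "clade": [",".join(sorted(self.tree.descendant_tips(i)))
                      for i in ints],
            "support": self.support[ints],
            "age_mean": self.age_mean[ints],
            "hpd95_lower": self.hpd_lower[ints],
            "hpd95_upper": self.hpd_upper[ints],
        })

    def to_newick(self) -> str:
        """Newick with support / age annotations in comment blocks."""
        t = self.tree

        def rec(node: int) -> str:
            if not t.children[node]:
                return f"{t.labels[node]}:{t.branch_length(node):.10g}"
            inner = ",".join(rec(c) for c in t.children[node])
            sup = self.support[node]
            note = (f"[&support={sup:.3g},age_mean={self.age_mean[node]:.6g},"
                    f"hpd95={{{self.hpd_lower[node]:.6g},"
                    f"{self.hpd_upper[node]:.6g}}}]"
                    if np.isfinite(sup) else "")
            return f"({inner}){note}:{t.branch_length(node):.10g}"
        return rec(t.root) + ";"


def _clade_key(mask: int) -> int:
    return mask


def mcc_tree(trees: list[TimeTree], burnin_fraction: float = 0.1,
             support_floor: float = 0.5) -> AnnotatedTree:
    """Maximum clade credibility summary of a posterior tree sample.

    After discarding the first ``burnin_fraction`` of the sample, clade
    posterior frequencies are counted exactly; the *sampled* tree whose
    clades have the largest product of posteriors is returned (no
    consensus rebuild), annotated with mean node ages and 95% HPDs over
    the trees containing each clade.  Supports below ``support_floor``
    are masked.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    tipsets = {frozenset(t.tip_labels) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("trees have inconsistent tip sets")
    start = int(np.floor(burnin_fraction * len(trees)))
    kept = trees[start:]
    if not kept:
        raise ValueError("burn-in removed every tree")

    clade_count: dict[int, int] = {}
    clade_ages: dict[int, list[float]] = {}
    masks_per_tree = []
    for t in kept:
        masks = t.clade_bitmasks()
        internal = t.internal_nodes()
        masks_per_tree.append((t, masks))
        for i in internal:
            key = masks[i]
            clade_count[key] = clade_count.get(key, 0) + 1
            clade_ages.setdefault(key, []).append(float(t.ages[i]))

    n = len(kept)
    best, best_score = None, -np.inf
    for t, masks in masks_per_tree:
        score = sum(np.log(clade_count[masks[i]] / n)
                    for i in t.internal_nodes())
        if score > best_score:
            best, best_masks, best_score = t, masks, score

    tree = best.copy()
    support = np.full(tree.n_nodes, np.nan)
    age_mean = np.full(tree.n_nodes, np.nan)
    lo = np.full(tree.n_nodes, np.nan)
    hi = np.full(tree.n_nodes, np.nan)
    for i in tree.internal_nodes():
        key = best_masks[i]
        sup = clade_count[key] / n
        ages = np.asarray(clade_ages[key])
        age_mean[i] = ages.mean()
        if ages.size >= 20:
            lo[i], hi[i] = hpd_interval(ages)
        support[i] = sup if sup >= support_floor else np.nan
        if sup >= support_floor:
            tree.ages[i] = ages.mean()
    # masked-support nodes keep their sampled age; enforce parent>child
    for i in reversed(tree.postorder):
        p = tree.parent[i]
        if p >= 0 and tree.ages[i] > tree.ages[p]:
            tree.ages[i] = tree.ages[p]
    return AnnotatedTree(tree, support, age_mean, lo, hi)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def root_age_t_test(root_ages, mu0: float):
    """Classical one-sample t of posterior root ages against ``mu0``.

    Returns ``(t, p)``; a zero-variance sample raises, since the statistic
    is undefined there.
    """
    x = np.asarray(root_ages, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero-variance sample: t statistic undefined")
    res = st.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TempoSeries:
    """Internal-node counts in sliding windows over years BP."""
    window_centers: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"center_bp": self.window_centers, "count": self.counts}
        if self.smoothed is not None:
            d["smoothed"] = self.smoothed
        return pd.DataFrame(d)


def divergence_tempo(tree, window: float = 500.0, step: float = 50.0,
                     t_min: float | None = None, t_max: float | None = None
                     ) -> TempoSeries:
    """Count internal nodes per sliding window of node age.

    Windows are closed intervals ``[c - w/2, c + w/2]`` centred on a grid
    advancing by ``step``; a node sitting exactly on a boundary counts.
    """
    t = tree.tree if isinstance(tree, AnnotatedTree) else tree
    if not isinstance(t, TimeTree):
        raise TypeError("need a dated TimeTree or AnnotatedTree")
    ages = t.ages[t.internal_nodes()]
    if not np.all(np.isfinite(ages)):
        raise ValueError("tree has undated internal nodes")
    lo = 0.0 if t_min is None else t_min
    hi = (float(ages.max()) + window) if t_max is None else t_max
    centers = np.arange(lo, hi + step / 2, step)
    half = window / 2.0
    counts = np.array([np.sum((ages >= c - half) & (ages <= c + half))
                       for c in centers], dtype=float)
    return TempoSeries(centers, counts)


def loess_smooth(series, span: float = 0.1, x=None) -> np.ndarray:
    """Tricube-weighted degree-1 local regression over the nearest
    ``ceil(span * n)`` points (delegates to statsmodels' lowess)."""
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 points")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    xs = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    frac = min(1.0, np.ceil(span * n) / n)
    out = lowess(y, xs, frac=frac, it=0, return_sorted=False)
    return np.asarray(out, dtype=float)


def count_interval_cover(records, times) -> np.ndarray:
    """Count, for each query time, the records whose BP range covers it.

    ``records`` is an iterable of ``(start, end)`` pairs in years BP with
    ``start >= end`` (start is the older bound); both ends are treated as
    closed, so a query equal to either bound is covered.
    """
    recs = np.asarray(list(records), dtype=float)
    if recs.ndim != 2 or recs.shape[1] != 2:
        raise ValueError("records must be (start, end) pairs")
    bad = np.where(recs[:, 0] < recs[:, 1])[0]
    if bad.size:
        raise ValueError(f"record {bad[0]} has start < end "
                         f"({recs[bad[0], 0]} < {recs[bad[0], 1]}); "
                         "start must be the older BP bound")
    ts = np.asarray(times, dtype=float)
    return np.array([np.sum((recs[:, 0] >= t) & (recs[:, 1] <= t))
                     for t in ts], dtype=int)
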