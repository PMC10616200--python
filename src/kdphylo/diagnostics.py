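"""Reticulation and borrowing diagnostics on cognate matrices.

Tree-like evolution leaves pairwise lexical distances additive: for every
quartet the two largest of the three pairwise-sum combinations are equal
(the four-point condition).  Horizontal borrowing breaks that, which the
quartet-based delta score and Q-residual quantify; the four-point
borrowing analysis asks, for one suspect language, what share of its
cognates aligns with a geographically attractive group rather than with
its own subgroup.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cognates import MISSING, CognateMatrix

__all__ = ["DistanceMatrix", "lexical_distance", "delta_scores",
           "q_residuals", "four_point_borrowing"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal; NaN marks a pair
    with no comparable data."""
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(self.d < 0):
                raise ValueError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


def lexical_distance(matrix: CognateMatrix) -> DistanceMatrix:
    """Pairwise 1 - (shared present classes / comparable classes).

    A column is comparable for a pair when it is observed in both
    languages and present in at least one (a Jaccard distance over
    cognate-class sets, so identical inventories give 0 and disjoint ones
    give 1).  Ascertainment columns and columns missing in either
    language are skipped; a pair with zero comparable columns gets NaN
    (flagged)."""
    if matrix.n_languages < 2:
        raise ValueError("need at least 2 languages")
    keep = ~matrix.ascertainment_mask()
    cells = matrix.cells[:, keep]
    n = matrix.n_languages
    d = np.zeros((n, n))
    flagged = []
    for i, j in itertools.combinations(range(n), 2):
        a, b = cells[i], cells[j]
        comparable = (a != MISSING) & (b != MISSING) & ((a == 1) | (b == 1))
        nc = int(comparable.sum())
        if nc == 0:
            d[i, j] = d[j, i] = np.nan
            flagged.append((matrix.languages[i], matrix.languages[j]))
            continue
        shared = int(np.sum((a == 1) & (b == 1) & comparable))
        d[i, j] = d[j, i] = 1.0 - shared / nc
    if flagged:
        warnings.warn(f"{len(flagged)} pair(s) with no comparable columns, "
                      f"e.g. {flagged[0]}", stacklevel=2)
    return DistanceMatrix(list(matrix.languages), d)


def _quartet_sums(d: np.ndarray, quartets: np.ndarray):
    """The three pairwise-sum combinations per quartet, sorted descending."""
    i, j, k, l = (quartets[:, c] for c in range(4))
    s1 = d[i, j] + d[k, l]
    s2 = d[i, k] + d[j, l]
    s3 = d[i, l] + d[j, k]
    m = np.sort(np.stack([s1, s2, s3]), axis=0)[::-1]
    return m[0], m[1], m[2]


def _per_taxon_mean(values: np.ndarray, quartets: np.ndarray, n: int
                    ) -> np.ndarray:
    sums = np.zeros(n)
    counts = np.zeros(n)
    for c in range(4):
        np.add.at(sums, quartets[:, c], values)
        np.add.at(counts, quartets[:, c], 1)
    return sums / counts


def delta_scores(dm: DistanceMatrix):
    """Quartet delta scores: (m1 - m2) / (m1 - m3) averaged per taxon.

    Zero on every quartet of an additive (tree-like) matrix; 1 in the
    worst box-like case m1 > m2 = m3.  Returns (per-taxon Series, mean).
    """
    d = dm.d
    n = len(dm.taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix has missing entries")
    quartets = np.array(list(itertools.combinations(range(n), 4)))
    m1, m2, m3 = _quartet_sums(d, quartets)
    span = m1 - m3
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(span > 0, (m1 - m2) / span, 0.0)
    per_taxon = _per_taxon_mean(delta, quartets, n)
    return pd.Series(per_taxon, index=dm.taxa), float(delta.mean())


def q_residuals(dm: DistanceMatrix):
    """Quartet Q-residuals ((m1 - m2) / mean-distance)^2 per taxon.

    Scale-invariant by construction (the normalizer is the global mean
    pairwise distance); zero exactly on additive distances.
    """
    d = dm.d
    n = len(dm.taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix has missing entries")
    iu = np.triu_indices(n, 1)
    scale = d[iu].mean()
    if scale == 0:
        raise ValueError("all-zero distance matrix")
    quartets = np.array(list(itertools.combinations(range(n), 4)))
    m1, m2, _ = _quartet_sums(d, quartets)
    q = ((m1 - m2) / scale) ** 2
    per_taxon = _per_taxon_mean(q, quartets, n)
    return pd.Series(per_taxon, index=dm.taxa), float(q.mean())


def four_point_borrowing(matrix: CognateMatrix, suspect: str,
                         home_group, attractor_group,
                         threshold: float = 0.20):
    """Share of a suspect language's cognates pulled from an attractor group.

    The proportion counts the suspect's present cognate classes shared
    with at least one attractor-group language but with *no* home-group
    language, over all its present classes.  A proportion above
    ``threshold`` (default 0.20, the level beyond which tree-based
    phylogenetic placement is considered unreliable) flags the language
    as exceeding the limit.

    Returns ``(proportion, exceeds_threshold)``.
    """
    home = set(home_group)
    attract = set(attractor_group)
    if home & attract:
        raise ValueError("home and attractor groups must be disjoint")
    if suspect in home or suspect in attract:
        raise ValueError("suspect must be outside both groups")
    for name in {suspect} | home | attract:
        if name not in matrix.languages:
            raise KeyError(f"language {name!r} not in matrix")
    present = matrix.present_columns(suspect)
    if not present:
        raise ValueError(f"suspect {suspect!r} has no present cognate "
                         "classes")
    h_idx = [matrix.languages.index(x) for x in home]
    a_idx = [matrix.languages.index(x) for x in attract]
    cells = matrix.cells
    exclusive = 0
    for j in present:
        in_attract = any(cells[i, j] == 1 for i in a_idx)
        in_home = any(cells[i, j] == 1 for i in h_idx)
        if in_attract and not in_home:
            exclusive += 1
    proportion = exclusive / len(present)
    return proportion, proportion > threshold
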