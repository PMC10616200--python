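"""Felsenstein pruning over time trees, with ascertainment correction.

The likelihood engine is shared by every stage: binary/covarion cognate
columns, 5-state geographic traits and HKY nucleotide sites all reduce to
the same column-vectorized post-order pass.  Per-node scaling keeps
100-tip x 700-column problems away from underflow, and branch transition
matrices for all branches (and Gamma rate categories) come from a single
eigendecomposition of the generator.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .cognates import CognateMatrix
from .phylo import TimeTree
from .substitution import RateMatrix, SiteRateModel, build_rate_matrix, \
    transition_matrices

__all__ = ["pruning_loglik", "ascertainment_correct", "corrected_loglik",
           "pruning_loglik_states"]

_SCALE_FLOOR = 1e-300

try:                                     # optional numba acceleration
    from numba import njit

    @njit(cache=True)
    def _prune_kernel(post, c0, c1, P, part, freqs):   # pragma: no cover
        n_nodes, ncol, k = part.shape
        logscale = np.zeros(ncol)
        seen = 0
        for idx in range(post.shape[0]):
            v = post[idx]
            a = c0[v]
            b = c1[v]
            if a < 0:
                continue
            for col in range(ncol):
                for i in range(k):
                    s1 = 0.0
                    s2 = 0.0
                    for j in range(k):
                        s1 += P[a, i, j] * part[a, col, j]
                        s2 += P[b, i, j] * part[b, col, j]
                    part[v, col, i] = s1 * s2
            seen += 1
            if seen % 4 == 0:
                for col in range(ncol):
                    mx = part[v, col, 0]
                    for i in range(1, k):
                        if part[v, col, i] > mx:
                            mx = part[v, col, i]
                    if mx < 1e-280:
                        mx = 1e-280
                    for i in range(k):
                        part[v, col, i] /= mx
                    logscale[col] += np.log(mx)
        root = post[-1]
        out = np.empty(ncol)
        for col in range(ncol):
            s = 0.0
            for i in range(k):
                s += freqs[i] * part[root, col, i]
            out[col] = np.log(s) + logscale[col]
        return out

    _HAVE_NUMBA = True
except Exception:                        # pragma: no cover
    _HAVE_NUMBA = False


def _children_arrays(tree: TimeTree):
    c0 = np.full(tree.n_nodes, -1, dtype=np.int64)
    c1 = np.full(tree.n_nodes, -1, dtype=np.int64)
    for v in range(tree.n_nodes):
        kids = tree.children[v]
        if kids:
            c0[v] = kids[0]
            c1[v] = kids[-1]
    return c0, c1


def _prune_fast(tree: TimeTree, tip_part: dict[int, np.ndarray],
                P: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Kernel-dispatched pruning for strictly binary trees; falls back to
    the generic pass for multifurcations or when numba is unavailable."""
    if not (_HAVE_NUMBA and tree.is_binary):
        return _prune(tree, tip_part, P, np.arange(tree.n_nodes), freqs)
    ncol = next(iter(tip_part.values())).shape[0]
    k = freqs.shape[0]
    part = np.empty((tree.n_nodes, ncol, k))
    for t, arr in tip_part.items():
        part[t] = arr
    c0, c1 = _children_arrays(tree)
    return _prune_kernel(tree.postorder, c0, c1,
                         np.ascontiguousarray(P), part,
                         np.ascontiguousarray(freqs, dtype=float))


def _tip_partial_array(rm: RateMatrix, observations: np.ndarray) -> np.ndarray:
    """(n_tips, n_col, k) conditional likelihoods at the tips."""
    k = rm.n_states
    out = np.empty(observations.shape + (k,))
    for symbol, vec in rm.tip_partials.items():
        out[observations == symbol] = vec
    return out


def _prune(tree: TimeTree, tip_part: dict[int, np.ndarray],
           P: np.ndarray, node_of_branch_row: np.ndarray,
           freqs: np.ndarray,
           constrained: dict[int, np.ndarray] | None = None,
           scale_every: int = 4) -> np.ndarray:
    """One pruning pass.  ``P`` has a row of transition matrices per node
    (indexed by ``node_of_branch_row``); returns per-column log-likelihood.

    Partial likelihoods are renormalized every ``scale_every`` internal
    nodes, enough to keep 100-tip problems clear of underflow without
    paying for a rescale at every node.
    """
    ncol = next(iter(tip_part.values())).shape[0]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(ncol)
    seen = 0
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            partial[node] = tip_part[node]
            continue
        part = partial.pop(kids[0]) @ P[node_of_branch_row[kids[0]]].T
        for c in kids[1:]:
            part *= partial.pop(c) @ P[node_of_branch_row[c]].T
        if constrained and node in constrained:
            part = part * constrained[node]
        seen += 1
        if seen % scale_every == 0:
            mx = part.max(axis=1)
            np.clip(mx, _SCALE_FLOOR, None, out=mx)
            part /= mx[:, None]
            logscale += np.log(mx)
        partial[node] = part
    lik = partial[tree.root] @ freqs
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def pruning_loglik(tree: TimeTree, matrix: CognateMatrix, subst_model,
                   branch_rates, site_rates: SiteRateModel | None = None
                   ) -> tuple[np.ndarray, float]:
    """Per-column log-likelihoods and their total.

    Parameters
    ----------
    subst_model
        ``BinaryCTMCParams``/``CovarionParams`` (or a prebuilt
        :class:`RateMatrix`).
    branch_rates
        Scalar clock rate or per-node array of rates (substitutions per
        column per year); branch length in substitution units is
        ``rate * (age(parent) - age(node))``.
    site_rates
        Optional Gamma rate heterogeneity; categories are averaged with
        equal weights.
    """
    order = {lab: i for i, lab in enumerate(matrix.languages)}
    missing = [tree.labels[t] for t in tree.tips
               if tree.labels[t] not in order]
    if missing:
        raise KeyError(f"tip(s) not in matrix: {missing}")
    if len(tree.tips) != matrix.n_languages:
        raise ValueError("tree tip set does not match matrix language set")
    rm = subst_model if isinstance(subst_model, RateMatrix) \
        else build_rate_matrix(subst_model)
    rates = np.broadcast_to(np.asarray(branch_rates, dtype=float),
                            (tree.n_nodes,))
    bl = tree.branch_lengths() * rates
    if np.any(bl < -1e-9):
        raise ValueError("negative branch durations")
    bl = np.clip(bl, 0.0, None)
    cat_rates = site_rates.rates() if site_rates is not None else np.ones(1)

    obs = np.empty((tree.n_tips, matrix.n_columns), dtype=np.int64)
    tip_nodes = list(tree.tips)
    for i, t in enumerate(tip_nodes):
        obs[i] = matrix.cells[order[tree.labels[t]]]
    tip_arrays = _tip_partial_array(rm, obs)
    tip_part = {t: tip_arrays[i] for i, t in enumerate(tip_nodes)}

    ncol = matrix.n_columns
    percol = np.full((len(cat_rates), ncol), -np.inf)
    for ci, cr in enumerate(cat_rates):
        P = transition_matrices(rm, bl * cr)
        percol[ci] = _prune(tree, {t: p.copy() for t, p in tip_part.items()},
                            P, np.arange(tree.n_nodes), rm.freqs)
    col_loglik = logsumexp(percol, axis=0) - np.log(len(cat_rates))
    return col_loglik, float(col_loglik.sum())


def ascertainment_correct(per_column_loglik: np.ndarray,
                          matrix: CognateMatrix) -> float:
    """Condition each item block on its character not being all-absent.

    The ascertainment column of an item evaluates to L0, the probability of
    the never-observed all-absent pattern; every observed column in the
    block is divided by (1 - L0).  Returns the corrected total
    log-likelihood (ascertainment columns contribute nothing else).
    """
    if not matrix.has_ascertainment:
        raise ValueError("matrix has no ascertainment columns")
    per_column_loglik = np.asarray(per_column_loglik, dtype=float)
    if per_column_loglik.shape != (matrix.n_columns,):
        raise ValueError("per-column vector does not match matrix")
    total = 0.0
    for item, (s, e) in matrix.item_blocks.items():
        log_l0 = per_column_loglik[s]
        if log_l0 >= 0.0:
            raise ValueError(
                f"item {item!r}: all-absent probability >= 1 (degenerate "
                "model)")
        n_obs = e - s - 1
        total += per_column_loglik[s + 1:e].sum() \
            - n_obs * np.log1p(-np.exp(log_l0))
    return float(total)


def corrected_loglik(tree: TimeTree, matrix: CognateMatrix, subst_model,
                     branch_rates, site_rates: SiteRateModel | None = None
                     ) -> float:
    """Ascertainment-corrected total log-likelihood in one call."""
    percol, _ = pruning_loglik(tree, matrix, subst_model, branch_rates,
                               site_rates)
    return ascertainment_correct(percol, matrix)


class PruningEngine:
    """Cached pruning for repeated likelihood evaluations on one matrix.

    Site patterns are compressed once (unique columns with weights), tip
    partials are prebuilt per language, and the generator's
    eigendecomposition is reused across calls — the MCMC samplers call
    this thousands of times per second.
    """

    def __init__(self, matrix: CognateMatrix, subst_model,
                 site_rates: SiteRateModel | None = None):
        self.matrix = matrix
        self.site_rates = site_rates
        self._cat = site_rates.rates() if site_rates is not None \
            else np.ones(1)
        if matrix.has_ascertainment:
            starts = np.array([s for s, _ in matrix.item_blocks.values()])
            ends = np.array([e for _, e in matrix.item_blocks.values()])
            self._asc_idx = starts
            self._n_obs = (ends - starts - 1).astype(float)
            obs_mask = np.ones(matrix.n_columns, dtype=bool)
            obs_mask[starts] = False
            self._obs_idx = np.where(obs_mask)[0]
        self.set_model(subst_model)

    def set_model(self, subst_model) -> None:
        self.rm = subst_model if isinstance(subst_model, RateMatrix) \
            else build_rate_matrix(subst_model)
        cells = self.matrix.cells
        patterns, self._inv = np.unique(cells.T, axis=0, return_inverse=True)
        self._rows = None
        k = self.rm.n_states
        npat = patterns.shape[0]
        self._tip_part = {}
        for li, lang in enumerate(self.matrix.languages):
            arr = np.empty((npat, k))
            for symbol, vec in self.rm.tip_partials.items():
                arr[patterns[:, li] == symbol] = vec
            self._tip_part[lang] = arr

    def per_column_loglik(self, tree: TimeTree, branch_rates) -> np.ndarray:
        rates = np.broadcast_to(np.asarray(branch_rates, dtype=float),
                                (tree.n_nodes,))
        bl = np.clip(tree.branch_lengths() * rates, 0.0, None)
        if self._rows is None or self._rows.shape[0] != tree.n_nodes:
            self._rows = np.arange(tree.n_nodes)
        tip_part = {t: self._tip_part[tree.labels[t]] for t in tree.tips}
        per = np.empty((len(self._cat), next(iter(
            tip_part.values())).shape[0]))
        for ci, cr in enumerate(self._cat):
            P = transition_matrices(self.rm, bl * cr)
            per[ci] = _prune_fast(tree, tip_part, P, self.rm.freqs)
        pat = logsumexp(per, axis=0) - np.log(len(self._cat)) \
            if len(self._cat) > 1 else per[0]
        return pat[self._inv]

    def corrected_loglik(self, tree: TimeTree, branch_rates) -> float:
        """Ascertainment-corrected total (vectorized over item blocks)."""
        percol = self.per_column_loglik(tree, branch_rates)
        log_l0 = percol[self._asc_idx]
        if np.any(log_l0 >= 0.0):
            raise ValueError("all-absent probability >= 1 (degenerate model)")
        return float(percol[self._obs_idx].sum()
                     - self._n_obs @ np.log1p(-np.exp(log_l0)))


def pruning_loglik_states(tree: TimeTree, tip_states: dict[str, int],
                          rm, branch_lengths: np.ndarray,
                          root_freqs: np.ndarray | None = None,
                          constraints: dict[int, int] | None = None
                          ) -> float:
    """Single-character pruning over an arbitrary k-state alphabet.

    Used by the discrete phylogeography stage: ``rm`` is a
    :class:`RateMatrix` or plain generator, ``tip_states`` maps tip label
    -> integer state (-1 for missing), ``constraints`` maps internal node
    index -> state whose partials are zeroed elsewhere.
    """
    Q = rm.Q if hasattr(rm, "Q") else np.asarray(rm, dtype=float)
    k = Q.shape[0]
    part_map = {}
    for t in tree.tips:
        lab = tree.labels[t]
        if lab not in tip_states:
            raise KeyError(f"tip {lab!r} has no state assignment")
        s = tip_states[lab]
        v = np.ones((1, k)) if s < 0 else np.zeros((1, k))
        if s >= 0:
            if s >= k:
                raise ValueError(f"tip {lab!r}: state {s} out of range")
            v[0, s] = 1.0
        part_map[t] = v
    P = transition_matrices(rm, np.clip(branch_lengths, 0.0, None))
    cmask = None
    if constraints:
        cmask = {}
        for node, s in constraints.items():
            m = np.zeros((1, k))
            m[0, s] = 1.0
            cmask[node] = m
    if root_freqs is None:
        if not hasattr(rm, "freqs"):
            raise ValueError("root_freqs required for a plain generator")
        root_freqs = rm.freqs
    ll = _prune(tree, part_map, P, np.arange(tree.n_nodes),
                np.asarray(root_freqs), constrained=cmask)
    return float(ll[0])
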