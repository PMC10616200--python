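"""Coalescent Bayesian skyline reconstruction of effective population size.

Given a nucleotide alignment, a fixed strict clock rate and an HKY+Gamma
site model, :class:`SkylineModel` runs a joint MCMC over the genealogy,
the substitution parameters and a piecewise-constant population-size
function whose change points sit at grouped coalescent events.  The
result is an :class:`NeTrajectory`: per-time-point median Ne with credible
bounds, from which demographic fold changes can be read off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .chronology import MCMCConfig, _move_node_age, _move_root_scale, \
    _narrow_exchange, _random_coalescent_start, _subtree_slide
from .likelihood import _prune_fast
from .phylo import TimeTree
from .substitution import HKYParams, SiteRateModel, build_rate_matrix, \
    gamma_category_rates, transition_matrices

__all__ = ["SequenceAlignment", "NeTrajectory", "skyline_coalescent_loglik",
           "SkylineModel", "SkylineResults", "fold_change",
           "read_fasta", "write_fasta"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass
class SequenceAlignment:
    """Aligned nucleotide sequences as an integer matrix.

    ``codes`` is (n_taxa, n_sites) with A,C,G,T -> 0..3 and anything
    ambiguous or missing -> -1.
    """
    taxa: list[str]
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, named_seqs) -> "SequenceAlignment":
        taxa, rows = [], []
        for name, seq in named_seqs:
            taxa.append(name)
            rows.append([_CODE.get(c.upper(), -1) for c in seq])
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise ValueError("sequences have unequal lengths")
        return cls(taxa, np.asarray(rows, dtype=np.int8))

    def to_strings(self) -> dict[str, str]:
        alph = np.array(list("ACGT?"))
        return {t: "".join(alph[self.codes[i]])
                for i, t in enumerate(self.taxa)}

    def is_invariant(self) -> bool:
        for j in range(self.n_sites):
            col = self.codes[:, j]
            obs = col[col >= 0]
            if obs.size and np.unique(obs).size > 1:
                return False
        return True


def read_fasta(path) -> SequenceAlignment:
    from Bio import SeqIO
    recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceAlignment.from_sequences(recs)


def write_fasta(aln: SequenceAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.to_strings().items():
            fh.write(f">{name}\n{seq}\n")


# --------------------------------------------------------------------- #
# coalescent density
# --------------------------------------------------------------------- #
def skyline_coalescent_loglik(tree: TimeTree, group_sizes, sizes) -> float:
    """Piecewise-constant coalescent log-density of an ultrametric tree.

    ``group_sizes`` gives how many successive coalescent events (ordered
    from the present) share each population size; ``sizes`` are the
    effective sizes per group (units of the tree's time axis).  With one
    group this is the constant-size Kingman density.
    """
    if not tree.is_ultrametric():
        raise ValueError("skyline coalescent needs an ultrametric tree")
    sizes = np.asarray(sizes, dtype=float)
    group_sizes = np.asarray(group_sizes, dtype=int)
    if np.any(sizes <= 0):
        raise ValueError("population sizes must be positive")
    n = tree.n_tips
    events = np.sort(tree.ages[tree.internal_nodes()])
    if group_sizes.sum() != n - 1 or len(group_sizes) != len(sizes):
        raise ValueError("group sizes must partition the n-1 coalescences")
    ne_of_event = np.repeat(sizes, group_sizes)
    ll = 0.0
    t_prev = 0.0
    k = n
    for ev, ne in zip(events, ne_of_event):
        dt = ev - t_prev
        pairs = k * (k - 1) / 2.0
        ll += -pairs * dt / ne - math.log(ne)
        t_prev = ev
        k -= 1
    return float(ll)


# --------------------------------------------------------------------- #
# trajectory container
# --------------------------------------------------------------------- #
@dataclass
class NeTrajectory:
    """Effective population size through time with credible bands."""
    times_bp: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_BP": self.times_bp, "median": self.median,
                             "lower": self.lower, "upper": self.upper})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at(self, t: float, which: str = "median") -> float:
        tb = self.times_bp
        if not (tb.min() - 1e-9 <= t <= tb.max() + 1e-9):
            raise ValueError(f"time {t} outside the trajectory grid "
                             f"[{tb.min()}, {tb.max()}]")
        return float(np.interp(t, tb, getattr(self, which)))

    def plot(self, ax=None):  # pragma: no cover - thin plotting
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.times_bp, self.lower, self.upper, alpha=0.3)
        ax.plot(self.times_bp, self.median)
        ax.set_xlabel("years BP")
        ax.set_ylabel("Ne")
        ax.set_yscale("log")
        ax.invert_xaxis()
        return ax


def fold_change(traj: NeTrajectory, t_old: float, t_young: float) -> float:
    """Median-Ne ratio between a younger and an older time point."""
    return traj.at(t_young) / traj.at(t_old)


# --------------------------------------------------------------------- #
# the model object
# --------------------------------------------------------------------- #
class SkylineModel:
    """Bayesian skyline model for a nucleotide alignment.

    Parameters
    ----------
    alignment
        :class:`SequenceAlignment` of at least 5 sequences.
    clock_rate
        Fixed strict-clock substitution rate (subs/site/year); converts
        the year-scaled genealogy into substitution units.
    n_groups
        Number of population-size groups (default round(sqrt(n-1))).
    hky, site_rates
        Initial HKY parameters and Gamma heterogeneity (kappa and shape
        are sampled; empirical base frequencies are used by default).
    """

    def __init__(self, alignment: SequenceAlignment,
                 clock_rate: float = 1.691e-8,
                 n_groups: int | None = None,
                 hky: HKYParams | None = None,
                 site_rates: SiteRateModel | None = None):
        if alignment.n_taxa < 5:
            raise ValueError("need at least 5 sequences")
        if alignment.is_invariant():
            raise ValueError("alignment has no variable sites: no signal "
                             "for a demographic reconstruction")
        if clock_rate <= 0:
            raise ValueError("clock rate must be positive")
        self.alignment = alignment
        self.clock_rate = clock_rate
        n = alignment.n_taxa
        self.n_groups = n_groups or max(1, round(math.sqrt(n - 1)))
        if self.n_groups > n - 1:
            raise ValueError("more groups than coalescent events")
        if hky is None:
            counts = np.bincount(
                alignment.codes[alignment.codes >= 0].ravel(), minlength=4)
            freqs = (counts + 1) / (counts.sum() + 4)
            hky = HKYParams(kappa=2.0, freqs=tuple(freqs))
        self.hky = hky
        self.site_rates = site_rates or SiteRateModel(4, shape=0.5)
        # site-pattern compression
        cols = alignment.codes.T
        uniq, inv, counts = np.unique(cols, axis=0, return_inverse=True,
                                      return_counts=True)
        self._patterns = uniq.T          # (n_taxa, n_patterns)
        self._weights = counts.astype(float)
        # tip partials depend only on the observed codes, not on kappa
        npat = self._patterns.shape[1]
        eye = np.eye(4)
        self._tip_part_by_taxon = {}
        for i, tax in enumerate(self.alignment.taxa):
            codes = self._patterns[i]
            arr = np.ones((npat, 4))
            valid = codes >= 0
            arr[valid] = eye[codes[valid]]
            self._tip_part_by_taxon[tax] = arr
        self._rm_cache: tuple | None = None
        self._cat_cache: tuple | None = None

    def _group_sizes_vec(self) -> np.ndarray:
        n_ev = self.alignment.n_taxa - 1
        base = n_ev // self.n_groups
        rem = n_ev % self.n_groups
        return np.array([base + (1 if i < rem else 0)
                         for i in range(self.n_groups)])

    def _data_loglik(self, tree: TimeTree, kappa: float, shape: float
                     ) -> float:
        if self._rm_cache is None or self._rm_cache[0] != kappa:
            self._rm_cache = (kappa,
                              build_rate_matrix(replace(self.hky,
                                                        kappa=kappa)))
        rm = self._rm_cache[1]
        if self.site_rates.ncat == 1:
            cat = np.ones(1)
        else:
            if self._cat_cache is None or self._cat_cache[0] != shape:
                self._cat_cache = (shape, gamma_category_rates(
                    shape, self.site_rates.ncat))
            cat = self._cat_cache[1]
        bl = np.clip(tree.branch_lengths() * self.clock_rate, 0.0, None)
        tip_part = {t: self._tip_part_by_taxon[tree.labels[t]]
                    for t in tree.tips}
        npat = self._patterns.shape[1]
        percat = np.empty((len(cat), npat))
        for ci, cr in enumerate(cat):
            P = transition_matrices(rm, bl * cr)
            percat[ci] = _prune_fast(tree, tip_part, P, rm.freqs)
        percol = logsumexp(percat, axis=0) - math.log(len(cat))
        return float(percol @ self._weights)

    def _log_prior(self, tree, sizes, kappa, shape) -> float:
        from .chronology import _log_expon, _log_lognorm
        lp = skyline_coalescent_loglik(tree, self._group_sizes_vec(), sizes)
        # scale-free prior on the first size; exponential chain thereafter
        lp += -math.log(sizes[0])
        for a, b in zip(sizes[:-1], sizes[1:]):
            lp += -math.log(a) - b / a
        lp += _log_lognorm(kappa, 2.0, 1.25)
        lp += _log_expon(shape, 1.0)
        return lp

    def fit(self, config: MCMCConfig, grid_points: int = 50,
            init_tree: TimeTree | None = None) -> "SkylineResults":
        rng = np.random.default_rng(config.seed)
        # initial tree height guessed from pairwise diversity / clock rate
        div = self._mean_pairwise_diversity()
        height0 = max(div / (2 * self.clock_rate), 100.0)
        tree = init_tree.copy() if init_tree is not None else \
            _random_coalescent_start(self.alignment.taxa, rng,
                                     mean_height=height0)
        sizes = np.full(self.n_groups, height0 / 2 + 1.0)
        kappa, shape = self.hky.kappa, self.site_rates.shape
        cur_ll = self._data_loglik(tree, kappa, shape)
        cur_lp = self._log_prior(tree, sizes, kappa, shape)
        if not np.isfinite(cur_ll + cur_lp):
            raise ValueError("initial state has zero posterior probability")

        moves = ["ages", "root", "scale", "narrow", "spr", "ne", "nescale",
                 "updown", "kappa", "shape"]
        probs = np.array([4, 1, 1, 2, 1, 3, 1, 2, 1, 1], dtype=float)
        probs /= probs.sum()
        records, trees, size_samples = [], [], []
        for it in range(1, config.generations + 1):
            move = moves[rng.choice(len(moves), p=probs)]
            new_tree, new_sizes = tree, sizes
            new_kappa, new_shape = kappa, shape
            log_hastings, ok = 0.0, True
            if move == "ages":
                new_tree = tree.copy()
                ok = _move_node_age(new_tree, rng)
            elif move == "root":
                new_tree = tree.copy()
                log_hastings = _move_root_scale(new_tree, rng)
            elif move == "scale":
                new_tree = tree.copy()
                m = math.exp(0.3 * (rng.random() - 0.5))
                new_tree.ages *= m
                log_hastings = len(new_tree.internal_nodes()) * math.log(m)
            elif move == "narrow":
                new_tree = tree.copy()
                log_hastings = _narrow_exchange(new_tree, rng)
                ok = log_hastings is not None
            elif move == "spr":
                new_tree = tree.copy()
                ok = _subtree_slide(new_tree, rng)
            elif move == "ne":
                g = rng.integers(self.n_groups)
                m = math.exp(0.7 * (rng.random() - 0.5))
                new_sizes = sizes.copy()
                new_sizes[g] *= m
                log_hastings = math.log(m)
            elif move == "nescale":
                m = math.exp(0.5 * (rng.random() - 0.5))
                new_sizes = sizes * m
                log_hastings = self.n_groups * math.log(m)
            elif move == "updown":
                # scale the genealogy and the sizes together: the
                # coalescent density is nearly invariant along this ridge
                m = math.exp(0.4 * (rng.random() - 0.5))
                new_tree = tree.copy()
                new_tree.ages *= m
                new_sizes = sizes * m
                log_hastings = (len(new_tree.internal_nodes())
                                + self.n_groups) * math.log(m)
            elif move == "kappa":
                m = math.exp(0.3 * (rng.random() - 0.5))
                new_kappa = kappa * m
                log_hastings = math.log(m)
            elif move == "shape":
                m = math.exp(0.4 * (rng.random() - 0.5))
                new_shape = shape * m
                log_hastings = math.log(m)
            if ok:
                ll_changed = move in ("ages", "root", "scale", "narrow",
                                      "spr", "updown", "kappa", "shape")
                new_ll = self._data_loglik(new_tree, new_kappa, new_shape) \
                    if ll_changed else cur_ll
                new_lp = self._log_prior(new_tree, new_sizes, new_kappa,
                                         new_shape)
                if np.isfinite(new_lp) and \
                        math.log(rng.random()) < (new_ll - cur_ll
                                                  + new_lp - cur_lp
                                                  + log_hastings):
                    tree, sizes = new_tree, new_sizes
                    kappa, shape = new_kappa, new_shape
                    cur_ll, cur_lp = new_ll, new_lp
            if it % config.sample_every == 0:
                records.append({"state": it, "posterior": cur_ll + cur_lp,
                                "likelihood": cur_ll, "prior": cur_lp,
                                "root_age": tree.root_age, "kappa": kappa,
                                "gamma_shape": shape,
                                **{f"ne_{g}": sizes[g]
                                   for g in range(self.n_groups)}})
                trees.append(tree.copy())
                size_samples.append(sizes.copy())
        return SkylineResults(self, config, pd.DataFrame(records), trees,
                              np.asarray(size_samples), grid_points)

    def _mean_pairwise_diversity(self) -> float:
        c = self.alignment.codes
        n = c.shape[0]
        tot, cnt = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                m = (c[i] >= 0) & (c[j] >= 0)
                if m.sum():
                    tot += np.mean(c[i][m] != c[j][m])
                    cnt += 1
        return tot / max(cnt, 1)


class SkylineResults:
    """Posterior sample of genealogies and grouped population sizes."""

    def __init__(self, model: SkylineModel, config: MCMCConfig,
                 trace: pd.DataFrame, trees, size_samples: np.ndarray,
                 grid_points: int):
        self.model = model
        self.config = config
        self.trace = trace
        self.trees = trees
        self.size_samples = size_samples
        self.grid_points = grid_points
        self._trajectory = None

    @property
    def posterior_trace(self) -> pd.DataFrame:
        return self.trace.iloc[self.config.burnin_samples:]

    def trajectory(self, interpolation: str = "stepwise") -> NeTrajectory:
        """Ne(t) median and 95% central band on a uniform BP grid.

        Each posterior sample defines a stepwise Ne function whose change
        points are its grouped coalescent times; ``interpolation="linear"``
        instead interpolates between change points.
        """
        if interpolation not in ("stepwise", "linear"):
            raise ValueError("interpolation must be stepwise or linear")
        b = self.config.burnin_samples
        trees = self.trees[b:]
        sizes = self.size_samples[b:]
        gvec = self.model._group_sizes_vec()
        t_max = np.median([t.root_age for t in trees])
        grid = np.linspace(0.0, t_max, self.grid_points)
        vals = np.empty((len(trees), grid.size))
        for s, (t, sz) in enumerate(zip(trees, sizes)):
            events = np.sort(t.ages[t.internal_nodes()])
            bounds = np.concatenate([[0.0], events])
            change = bounds[np.concatenate([[0], np.cumsum(gvec)])[:-1]]
            if interpolation == "stepwise":
                idx = np.clip(np.searchsorted(change, grid, side="right") - 1,
                              0, len(sz) - 1)
                vals[s] = sz[idx]
            else:
                vals[s] = np.interp(grid, change, sz)
        return NeTrajectory(grid, np.median(vals, axis=0),
                            np.quantile(vals, 0.025, axis=0),
                            np.quantile(vals, 0.975, axis=0))

    def summary(self) -> pd.DataFrame:
        from .chronology import effective_sample_size
        from .treesummary import hpd_interval
        rows = []
        for col in self.posterior_trace.columns:
            if col == "state":
                continue
            x = self.posterior_trace[col].to_numpy()
            lo, hi = hpd_interval(x) if x.size >= 20 else (np.nan, np.nan)
            rows.append({"parameter": col, "mean": x.mean(),
                         "hpd95_lower": lo, "hpd95_upper": hi,
                         "ess": effective_sample_size(x)
                         if np.std(x) > 0 else np.nan})
        return pd.DataFrame(rows).set_index("parameter")
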