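"""Discrete 5-area phylogeography with reversible-jump restriction models.

The trait model is a k-state CTMC over geographic areas evaluated on a
posterior sample of time trees (branch lengths rescaled by 1e-4 before
exponentiation).  A reversible-jump sampler partitions the k(k-1) ordered
transition rates into shared rate classes, one of which pins its rates to
exactly zero; support for a named restriction pattern (e.g. "no moves
between non-adjacent areas") is a visit-count Bayes factor — how often the
chain occupies structures consistent with the pattern relative to the
uniform-prior expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats as st

from .chronology import MCMCConfig
from .likelihood import pruning_loglik_states
from .phylo import TimeTree
from .substitution import transition_matrices

__all__ = [
    "AreaStateSpace", "DispersalModel", "NodeConstraint",
    "DEFAULT_AREAS", "DEFAULT_ADJACENCY", "table_models",
    "multistate_loglik", "model_visit_bf", "prior_zero_fraction",
    "structure_logprior", "compare_root_areas", "DiscreteGeographyModel",
    "GeographyResults",
]

DEFAULT_AREAS = ("Guizhou", "Yunnan", "Coastal", "Hainan", "MSEA")

#: Geographic adjacency used to build the adjacent-transitions-only model:
#: the coastal Guangxi-Guangdong area touches everything, the two inland
#: provinces touch each other, Yunnan borders MSEA, and Hainan faces MSEA
#: across the sea lane.  Deliberately data, not code — override at will.
DEFAULT_ADJACENCY = (
    ("Coastal", "Guizhou"), ("Coastal", "Yunnan"), ("Coastal", "Hainan"),
    ("Coastal", "MSEA"), ("Guizhou", "Yunnan"), ("Yunnan", "MSEA"),
    ("Hainan", "MSEA"),
)


@dataclass(frozen=True)
class AreaStateSpace:
    """Ordered alphabet of discrete areas."""
    areas: tuple = DEFAULT_AREAS

    def __post_init__(self):
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area labels")

    @property
    def k(self) -> int:
        return len(self.areas)

    def index(self, area: str) -> int:
        return self.areas.index(area)

    def ordered_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.k) for j in range(self.k) if i != j]

    def pair_label(self, i: int, j: int) -> str:
        return f"{self.areas[i]}->{self.areas[j]}"


def _norm_pair(pair) -> frozenset:
    a, b = pair
    if a == b:
        raise ValueError(f"self-pair {pair!r} is not a transition")
    return frozenset((a, b))


@dataclass(frozen=True)
class DispersalModel:
    """A named restriction pattern: unordered area pairs whose transition
    rates (both directions) are fixed to zero."""
    name: str
    forbidden_pairs: frozenset = frozenset()

    @staticmethod
    def build(name: str, pairs) -> "DispersalModel":
        return DispersalModel(name, frozenset(_norm_pair(p) for p in pairs))

    def allows_reaching(self, space: AreaStateSpace,
                        observed: set[str]) -> bool:
        """True when every observed area is reachable from every candidate
        root area over the allowed-transition graph."""
        import itertools
        allowed = {frozenset(p) for p in
                   itertools.combinations(space.areas, 2)} - self.forbidden_pairs
        # union-find over areas
        comp = {a: a for a in space.areas}

        def find(a):
            while comp[a] != a:
                comp[a] = comp[comp[a]]
                a = comp[a]
            return a
        for p in allowed:
            a, b = tuple(p)
            comp[find(a)] = find(b)
        roots = {find(a) for a in observed}
        return len(roots) <= 1


def table_models(space: AreaStateSpace = AreaStateSpace(),
                 adjacency=DEFAULT_ADJACENCY) -> dict[str, DispersalModel]:
    """The standard candidate set: FULL (no restriction), adjacent-only
    (Model 1), and Model 1 plus one extra severed link each (Models 2-4)."""
    import itertools
    adj = {_norm_pair(p) for p in adjacency}
    all_pairs = {frozenset(p) for p in itertools.combinations(space.areas, 2)}
    non_adjacent = all_pairs - adj
    m1 = non_adjacent
    return {
        "FULL": DispersalModel("FULL", frozenset()),
        "Model1": DispersalModel("Model1", frozenset(m1)),
        "Model2": DispersalModel(
            "Model2", frozenset(m1 | {_norm_pair(("MSEA", "Hainan"))})),
        "Model3": DispersalModel(
            "Model3", frozenset(m1 | {_norm_pair(("MSEA", "Coastal"))})),
        "Model4": DispersalModel(
            "Model4", frozenset(m1 | {_norm_pair(("MSEA", "Yunnan"))})),
    }


@dataclass(frozen=True)
class NodeConstraint:
    """Fix the reconstructed area of the MRCA of a tip set."""
    taxa: frozenset
    fixed_state: str

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise ValueError("a node constraint needs at least 2 taxa")


# --------------------------------------------------------------------- #
# likelihood
# --------------------------------------------------------------------- #
def build_area_generator(space: AreaStateSpace, rates: dict | np.ndarray
                         ) -> np.ndarray:
    """Assemble the k-state generator from per-ordered-pair rates."""
    k = space.k
    Q = np.zeros((k, k))
    if isinstance(rates, dict):
        for (i, j), r in rates.items():
            Q[i, j] = r
    else:
        for idx, (i, j) in enumerate(space.ordered_pairs()):
            Q[i, j] = rates[idx]
    if np.any(Q < 0):
        raise ValueError("negative transition rate")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def multistate_loglik(tree: TimeTree, tip_areas: dict[str, str],
                      Q: np.ndarray, space: AreaStateSpace | None = None,
                      constraints=(), branch_scale: float = 1e-4) -> float:
    """Pruning log-likelihood of tip areas under generator ``Q``.

    Branch lengths in years are multiplied by ``branch_scale`` before
    exponentiation; constrained MRCA nodes have their partials zeroed
    outside the fixed state; the root prior is uniform over areas.
    """
    space = space or AreaStateSpace()
    k = Q.shape[0]
    states = {}
    for t in tree.tips:
        lab = tree.labels[t]
        if lab not in tip_areas:
            raise KeyError(f"no area for tip {lab!r}")
        area = tip_areas[lab]
        if area not in space.areas:
            raise ValueError(f"tip {lab!r} has unknown area {area!r}")
        states[lab] = space.index(area)
    cons = {tree.mrca(c.taxa): space.index(c.fixed_state)
            for c in constraints}
    bl = tree.branch_lengths() * branch_scale
    return pruning_loglik_states(tree, states, Q, bl,
                                 root_freqs=np.full(k, 1.0 / k),
                                 constraints=cons)


def limiting_distribution(Q: np.ndarray) -> np.ndarray:
    """Long-run state distribution of a (possibly reducible) generator,
    started from uniform — the root prior of the dispersal model."""
    k = Q.shape[0]
    rates = np.abs(np.diag(Q))
    top = rates.max()
    if top <= 0:
        return np.full(k, 1.0 / k)
    import scipy.linalg
    P_inf = scipy.linalg.expm(Q * (200.0 / top))
    pi = np.full(k, 1.0 / k) @ P_inf
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _marginal_node_probs(tree: TimeTree, tip_states: dict[str, int],
                         Q: np.ndarray, bl: np.ndarray,
                         constraints: dict[int, int],
                         root_freqs: np.ndarray | None = None) -> np.ndarray:
    """Marginal posterior state probabilities at every internal node
    (up-down algorithm; root prior defaults to the generator's limiting
    distribution)."""
    k = Q.shape[0]
    root_prior = limiting_distribution(Q) if root_freqs is None \
        else np.asarray(root_freqs)
    P = transition_matrices(Q, np.clip(bl, 0.0, None))
    up: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        if not tree.children[node]:
            s = tip_states[tree.labels[node]]
            v = np.ones(k) if s < 0 else np.eye(k)[s]
        else:
            v = np.ones(k)
            for c in tree.children[node]:
                v = v * (P[c] @ up[c])
            if node in constraints:
                v = v * np.eye(k)[constraints[node]]
        tot = v.sum()
        up[node] = v / tot if tot > 0 else v
    down: dict[int, np.ndarray] = {tree.root: root_prior}
    out = np.zeros((tree.n_nodes, k))
    for node in tree.postorder[::-1]:
        if tree.children[node]:
            base = down[node]
            if node in constraints:
                base = base * np.eye(k)[constraints[node]]
            for c in tree.children[node]:
                sibs = np.ones(k)
                for b in tree.children[node]:
                    if b != c:
                        sibs = sibs * (P[b] @ up[b])
                down[c] = (base * sibs) @ P[c]
            m = down[node] * up[node] if node not in constraints else \
                down[node] * up[node] * np.eye(k)[constraints[node]]
            out[node] = m / m.sum()
    return out


# --------------------------------------------------------------------- #
# visit-count Bayes factors
# --------------------------------------------------------------------- #
@lru_cache(maxsize=8)
def _bell_numbers(n: int) -> tuple[int, ...]:
    bell = [1]
    row = [1]
    for _ in range(n):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        row = new
        bell.append(row[0])
    return tuple(bell)


def prior_zero_fraction(n_rates: int, n_zeroed: int,
                        zero_prob: float = 0.5) -> float:
    """Prior probability that ``n_zeroed`` given ordered rates are all in
    the zero class.

    The structure prior places each rate in the zero class independently
    with probability ``zero_prob`` and partitions the remaining rates
    uniformly into shared rate classes, so the fraction is simply
    ``zero_prob ** n_zeroed``.
    """
    if n_zeroed > n_rates:
        raise ValueError("cannot zero more rates than exist")
    if not (0 < zero_prob < 1):
        raise ValueError("zero_prob must be in (0, 1)")
    return zero_prob ** n_zeroed


def structure_logprior(assign: np.ndarray, zero_prob: float = 0.5) -> float:
    """Log-prior of one rate-class structure under the zero-inclusion /
    uniform-partition prior."""
    n = len(assign)
    z = int(np.sum(assign == 0))
    bell = _bell_numbers(n)
    return (z * math.log(zero_prob) + (n - z) * math.log1p(-zero_prob)
            - math.log(bell[n - z]))


def model_visit_bf(zero_patterns, model: DispersalModel,
                   space: AreaStateSpace | None = None,
                   prior_expected_fraction: float | None = None,
                   zero_prob: float = 0.5) -> float:
    """Visit-count Bayes factor for one restriction pattern.

    A sampled structure is consistent with the model when every forbidden
    pair has both of its ordered rates in the zero class.  The BF is the
    observed fraction of consistent samples over the prior expected
    fraction of consistent structures (BF < 1 argues against the model;
    BF > 30 is very strong support).
    """
    space = space or AreaStateSpace()
    patterns = list(zero_patterns)
    if not patterns:
        raise ValueError("empty trace")
    required = set()
    for pair in model.forbidden_pairs:
        a, b = tuple(pair)
        required.add((space.index(a), space.index(b)))
        required.add((space.index(b), space.index(a)))
    hits = sum(1 for z in patterns if required <= z)
    observed = hits / len(patterns)
    if prior_expected_fraction is None:
        prior_expected_fraction = prior_zero_fraction(
            len(space.ordered_pairs()), len(required), zero_prob)
    if prior_expected_fraction <= 0:
        raise ValueError("zero prior fraction: Bayes factor unbounded")
    return observed / prior_expected_fraction


def compare_root_areas(probs_a, probs_b):
    """Paired one-sided Wilcoxon signed-rank test of P(root = A) > P(root = B).

    Zero differences are dropped; an all-tied comparison carries no signal
    and returns (0, 1) with a warning.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if np.all(a == b):
        warnings.warn("all paired differences are ties", stacklevel=2)
        return 0.0, 1.0
    res = st.wilcoxon(a, b, alternative="greater", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------- #
# the RJ-MCMC model object
# --------------------------------------------------------------------- #
class DiscreteGeographyModel:
    """Discrete-trait dispersal model over a posterior tree sample.

    Parameters
    ----------
    trees
        Posterior sample of :class:`TimeTree` (typically ~1000 trees
        resampled after burn-in); the sampler integrates over them by
        treating the tree index as a uniform MCMC variable.
    tip_areas
        Mapping tip label -> area label.
    space
        The area alphabet (5 areas by default; smaller spaces are fine
        for synthetic work).
    constraints
        :class:`NodeConstraint` list (e.g. pinning a clade's MRCA to the
        coastal area on historical evidence).
    branch_scale
        Year-to-likelihood rescaling of branch lengths (1e-4).
    hyper_max
        The rate-class values follow Exponential(mean m) with
        m ~ Uniform(0, hyper_max).
    """

    def __init__(self, trees, tip_areas: dict[str, str],
                 space: AreaStateSpace | None = None, constraints=(),
                 branch_scale: float = 1e-4, hyper_max: float = 10.0,
                 zero_prob: float = 0.5, symmetric: bool = False):
        self.trees = list(trees)
        if not self.trees:
            raise ValueError("need at least one tree")
        self.space = space or AreaStateSpace()
        self.tip_areas = dict(tip_areas)
        tipset = set(self.trees[0].tip_labels)
        for t in self.trees:
            if set(t.tip_labels) != tipset:
                raise ValueError("trees do not share a tip set")
        missing = tipset - set(self.tip_areas)
        if missing:
            raise KeyError(f"no area for tips {sorted(missing)[:3]}")
        self.constraints = list(constraints)
        self.branch_scale = branch_scale
        self.hyper_max = hyper_max
        self.zero_prob = zero_prob
        self.symmetric = symmetric
        if symmetric:
            # one tied rate per unordered pair (dispersal both ways)
            self.pairs = [(i, j) for i in range(self.space.k)
                          for j in range(i + 1, self.space.k)]
            self.n_rates = len(self.pairs)
            self._unordered_idx = []
        else:
            self.pairs = self.space.ordered_pairs()
            self.n_rates = len(self.pairs)
            index_of = {p: i for i, p in enumerate(self.pairs)}
            self._unordered_idx = [(index_of[(i, j)], index_of[(j, i)])
                                   for i in range(self.space.k)
                                   for j in range(i + 1, self.space.k)]
        self._tip_states = {lab: self.space.index(a)
                            for lab, a in self.tip_areas.items()
                            if lab in tipset}

    # -- likelihood ----------------------------------------------------- #
    def _generator(self, rates: np.ndarray) -> np.ndarray:
        if self.symmetric:
            d = {}
            for idx, (i, j) in enumerate(self.pairs):
                d[(i, j)] = d[(j, i)] = rates[idx]
            return build_area_generator(self.space, d)
        return build_area_generator(self.space, rates)

    def _loglik(self, tree_idx: int, rates: np.ndarray):
        tree = self.trees[tree_idx]
        Q = self._generator(rates)
        cons = {tree.mrca(c.taxa): self.space.index(c.fixed_state)
                for c in self.constraints}
        bl = tree.branch_lengths() * self.branch_scale
        ll = pruning_loglik_states(
            tree, self._tip_states, Q, bl,
            root_freqs=limiting_distribution(Q),
            constraints=cons)
        return ll, (tree, Q, bl, cons)

    def _rate_vector(self, assign, class_rates):
        return np.array([0.0 if assign[i] == 0 else class_rates[assign[i]]
                         for i in range(self.n_rates)])

    # -- fitting -------------------------------------------------------- #
    def fit(self, config: MCMCConfig, track_nodes: dict | None = None,
            n_runs: int = 1) -> "GeographyResults":
        """Run the reversible-jump sampler (optionally several independent
        runs whose retained samples are pooled, as replicate chains)."""
        runs = []
        for r in range(n_runs):
            runs.append(self._fit_single(replace(config,
                                                 seed=config.seed + r),
                                         track_nodes or {}))
        return GeographyResults(self, config, runs, track_nodes or {})

    def _fit_single(self, config: MCMCConfig, track_nodes: dict):
        rng = np.random.default_rng(config.seed)
        n = self.n_rates
        # start: one shared nonzero class for every rate
        assign = np.ones(n, dtype=np.int64)
        hyper_mean = rng.uniform(0, self.hyper_max)
        class_rates = {1: rng.exponential(max(hyper_mean, 1e-6))}
        tree_idx = int(rng.integers(len(self.trees)))
        rates = self._rate_vector(assign, class_rates)
        cur_ll, _ = self._loglik(tree_idx, rates)
        if not np.isfinite(cur_ll):
            raise ValueError("initial state has zero likelihood")

        def log_prior(a, class_rates, m):
            m = max(m, 1e-12)
            lp = sum(-math.log(m) - v / m for v in class_rates.values())
            return lp + structure_logprior(a, self.zero_prob)

        cur_lp = log_prior(assign, class_rates, hyper_mean)

        records = []
        zero_patterns = []
        root_probs = []
        node_probs = {name: [] for name in track_nodes}
        for it in range(1, config.generations + 1):
            move = rng.choice(["rate", "hyper", "jump", "tree"],
                              p=[0.35, 0.1, 0.4, 0.15])
            new_assign, new_rates_map = assign, class_rates
            new_hyper, new_idx = hyper_mean, tree_idx
            log_hastings = 0.0
            if move == "rate" and class_rates:
                cid = list(class_rates)[rng.integers(len(class_rates))]
                m = math.exp(0.7 * (rng.random() - 0.5))
                new_rates_map = dict(class_rates)
                new_rates_map[cid] = class_rates[cid] * m
                log_hastings = math.log(m)
            elif move == "hyper":
                new_hyper = hyper_mean + 0.5 * (rng.random() - 0.5) \
                    * self.hyper_max
                if not (0 < new_hyper < self.hyper_max):
                    continue
            elif move == "tree":
                new_idx = int(rng.integers(len(self.trees)))
            elif move == "jump":
                if not self._unordered_idx or rng.random() < 0.5:
                    out = _rj_element_move(assign, class_rates, hyper_mean,
                                           rng)
                else:
                    pr = self._unordered_idx[
                        rng.integers(len(self._unordered_idx))]
                    out = _rj_pair_move(assign, class_rates, hyper_mean,
                                        pr, rng)
                if out is None:
                    continue
                new_assign, new_rates_map, log_hastings = out
            new_rates = self._rate_vector(new_assign, new_rates_map)
            new_ll, _ = self._loglik(new_idx, new_rates)
            new_lp = log_prior(new_assign, new_rates_map, new_hyper)
            log_alpha = new_ll - cur_ll + new_lp - cur_lp + log_hastings
            if np.isfinite(new_ll) and math.log(rng.random()) < log_alpha:
                assign, class_rates = new_assign, new_rates_map
                hyper_mean, tree_idx = new_hyper, new_idx
                rates = new_rates
                cur_ll, cur_lp = new_ll, new_lp

            if it % config.sample_every == 0:
                if self.symmetric:
                    zero = frozenset(
                        d for i in range(n) if assign[i] == 0
                        for d in (self.pairs[i], self.pairs[i][::-1]))
                else:
                    zero = frozenset(self.pairs[i] for i in range(n)
                                     if assign[i] == 0)
                zero_patterns.append(zero)
                tree = self.trees[tree_idx]
                Q = self._generator(rates)
                cons = {tree.mrca(c.taxa): self.space.index(c.fixed_state)
                        for c in self.constraints}
                marg = _marginal_node_probs(
                    tree, self._tip_states, Q,
                    tree.branch_lengths() * self.branch_scale, cons)
                root_probs.append(marg[tree.root])
                for name, taxa in track_nodes.items():
                    try:
                        node = tree.mrca(taxa)
                        exists = tree.descendant_tips(node) == set(taxa)
                    except KeyError:
                        exists = False
                    node_probs[name].append(marg[node] if exists else None)
                records.append({
                    "state": it, "likelihood": cur_ll, "prior": cur_lp,
                    "n_zero": int(np.sum(assign == 0)),
                    "n_classes": len(class_rates),
                    "hyper_mean": hyper_mean, "tree_index": tree_idx,
                })
        return {"trace": pd.DataFrame(records),
                "zero_patterns": zero_patterns,
                "root_probs": np.array(root_probs),
                "node_probs": node_probs}


def _rj_element_move(assign, class_rates, hyper_mean, rng):
    """Move one ordered rate between classes (zero, existing, or a fresh
    class whose value is born from the Exponential(hyper_mean) prior).

    Returns ``(new_assign, new_class_rates, log_hastings)``; the uniform
    structure prior and the birth-from-prior rate proposal cancel, so the
    Hastings term only carries the candidate-count ratio.
    """
    n = len(assign)
    i = int(rng.integers(n))
    cur = assign[i]
    existing = sorted(class_rates)
    singleton = cur != 0 and int(np.sum(assign == cur)) == 1

    def n_candidates(a, cr):
        c = a[i]
        cand = (1 if c != 0 else 0)                 # the zero class
        cand += sum(1 for x in sorted(cr) if x != c)  # other classes
        # a fresh singleton class (pointless if already a singleton)
        single = c != 0 and int(np.sum(a == c)) == 1
        if not single:
            cand += 1
        return cand

    targets: list = []
    if cur != 0:
        targets.append(0)
    targets.extend(c for c in existing if c != cur)
    if not singleton:
        targets.append("new")
    if not targets:
        return None
    tgt = targets[int(rng.integers(len(targets)))]
    new_assign = assign.copy()
    new_rates = dict(class_rates)
    m = max(hyper_mean, 1e-6)
    log_h = 0.0
    if tgt == "new":
        cid = max(existing, default=0) + 1
        v = rng.exponential(m)
        new_rates[cid] = v
        new_assign[i] = cid
        # subtract the forward proposal density of the born rate; it
        # cancels the prior factor the new class adds
        log_h -= -math.log(m) - v / m
    else:
        new_assign[i] = tgt
    # drop the old class if it emptied; the reverse move would re-draw
    # its rate from the prior, so add that density back
    if cur != 0 and int(np.sum(new_assign == cur)) == 0:
        v_dead = new_rates.pop(cur)
        log_h += -math.log(m) - v_dead / m
    log_h += math.log(len(targets)) - math.log(
        n_candidates(new_assign, new_rates))
    return new_assign, new_rates, log_h


def _rj_pair_move(assign, class_rates, hyper_mean, idx_pair, rng):
    """Jump an unordered pair's two ordered rates between 'both zero' and
    'both sharing a fresh class' (the reversible pair of each other).

    Returns ``None`` when the pair is in neither canonical configuration.
    """
    i, j = idx_pair
    m = max(hyper_mean, 1e-6)
    new_assign = assign.copy()
    new_rates = dict(class_rates)
    if assign[i] == 0 and assign[j] == 0:
        cid = max(class_rates, default=0) + 1
        v = rng.exponential(m)
        new_rates[cid] = v
        new_assign[i] = new_assign[j] = cid
        log_h = -(-math.log(m) - v / m)
        return new_assign, new_rates, log_h
    if (assign[i] == assign[j] and assign[i] != 0
            and int(np.sum(assign == assign[i])) == 2):
        v = new_rates.pop(assign[i])
        new_assign[i] = new_assign[j] = 0
        log_h = -math.log(m) - v / m
        return new_assign, new_rates, log_h
    return None


class GeographyResults:
    """Pooled RJ-MCMC output (one or more replicate runs)."""

    def __init__(self, model: DiscreteGeographyModel, config: MCMCConfig,
                 runs: list[dict], track_nodes: dict):
        self.model = model
        self.config = config
        self.runs = runs
        self.track_nodes = track_nodes

    def _pool(self, key):
        b = self.config.burnin_samples
        out = []
        for r in self.runs:
            out.extend(list(r[key])[b:])
        return out

    @property
    def trace(self) -> pd.DataFrame:
        b = self.config.burnin_samples
        return pd.concat([r["trace"].iloc[b:] for r in self.runs],
                         ignore_index=True)

    @property
    def zero_patterns(self) -> list:
        return self._pool("zero_patterns")

    @property
    def root_area_probs(self) -> np.ndarray:
        """(n_samples, k) per-sample posterior root-area probabilities."""
        b = self.config.burnin_samples
        return np.concatenate([r["root_probs"][b:] for r in self.runs])

    def root_area_posterior(self) -> pd.Series:
        p = self.root_area_probs.mean(axis=0)
        return pd.Series(p, index=list(self.model.space.areas))

    def model_visit_bf(self, model: DispersalModel,
                       prior_expected_fraction: float | None = None) -> float:
        if prior_expected_fraction is None and self.model.symmetric:
            # one tied rate per forbidden pair under the symmetric model
            prior_expected_fraction = \
                self.model.zero_prob ** len(model.forbidden_pairs)
        return model_visit_bf(self.zero_patterns, model, self.model.space,
                              prior_expected_fraction,
                              zero_prob=self.model.zero_prob)

    def ancestral_area_posterior(self, node: str):
        """Mean posterior area vector for a tracked MRCA node, plus the
        fraction of samples in which the clade existed."""
        if node not in self.track_nodes:
            raise KeyError(f"node {node!r} was not tracked during fit")
        entries = self._pool_nodes(node)
        present = [e for e in entries if e is not None]
        if not present:
            raise ValueError(f"clade {node!r} never present in the sample")
        probs = np.mean(np.stack(present), axis=0)
        probs = probs / probs.sum()
        return pd.Series(probs, index=list(self.model.space.areas)), \
            len(present) / len(entries)

    def _pool_nodes(self, node):
        b = self.config.burnin_samples
        out = []
        for r in self.runs:
            out.extend(r["node_probs"][node][b:])
        return out

    def compare_root_areas(self, area_a: str, area_b: str):
        sp = self.model.space
        p = self.root_area_probs
        return compare_root_areas(p[:, sp.index(area_a)],
                                  p[:, sp.index(area_b)])

    def summary(self) -> pd.DataFrame:
        """Per-model visit-count Bayes factors plus the root-area vector."""
        rows = []
        if self.model.space.areas == DEFAULT_AREAS:
            for name, m in table_models(self.model.space).items():
                rows.append({"model": name, "bayes_factor":
                             self.model_visit_bf(m)})
        df = pd.DataFrame(rows)
        root = self.root_area_posterior()
        df2 = pd.DataFrame({"model": [f"P(root={a})" for a in root.index],
                            "bayes_factor": root.to_numpy()})
        return pd.concat([df, df2], ignore_index=True)
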