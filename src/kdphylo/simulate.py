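"""Synthetic data with the statistical structure each pipeline stage assumes.

Everything is generated, never shipped: dated birth-death trees with
incomplete extant sampling, item-blocked binary cognate matrices evolved
under the covarion/CTMC site models (all-absent columns dropped, exactly
the conditioning the ascertainment correction assumes), controlled
horizontal borrowing, discrete areas evolved by an exact jump process on a
restricted transition graph, and HKY+Gamma sequences on coalescent
genealogies with piecewise-constant population size (genealogies via
msprime).  One RNG stream per sub-simulation, derived from the master
seed, keeps every component independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cognates import MISSING, CognateMatrix, add_ascertainment_columns
from .geography import AreaStateSpace
from .phylo import TimeTree
from .skyline import SequenceAlignment
from .substitution import BinaryCTMCParams, CovarionParams, HKYParams, \
    build_rate_matrix, gamma_category_rates, transition_matrices

__all__ = [
    "SimulationSpec", "simulate_bd_tree", "simulate_cognate_matrix",
    "inject_borrowing", "simulate_discrete_geography", "simulate_sequences",
    "simulate_coalescent_tree", "streams",
]


@dataclass
class SimulationSpec:
    """Bundle of generative settings for one synthetic study.

    Defaults emulate the study conditions of the real analysis at reduced
    size: a 5-branch language family of contemporaneous doculects under a
    birth-death history (lambda=0.001/lineage-year, mu=0.0005, rho=0.84 —
    the prior-mean sampling regime), a covarion cognate process over
    Swadesh-style items, 5 discrete areas, and an mtDNA-like sequence
    block at 1.691e-8 subs/site/year.
    """
    seed: int = 1
    n_tips: int = 20
    root_age: float | None = None
    lam: float = 1e-3
    mu: float = 5e-4
    rho: float = 0.84
    # cognate block: ~7 cognate classes per concept (646 classes over 90
    # items in the real database) and stationary presence ~ 1/(classes
    # per item), since a language typically uses one class per concept
    n_items: int = 50
    mean_classes_per_item: float = 7.0
    cognate_model: CovarionParams = field(
        default_factory=lambda: CovarionParams(
            visible=BinaryCTMCParams(pi0=0.86, pi1=0.14)))
    cognate_clock_rate: float = 1.0e-4
    missing_prob: float = 0.1
    # geography block
    # ~0.5 expected dispersal events per average branch: enough movement
    # to populate all areas, little enough that tips still carry root
    # signal
    areas: AreaStateSpace = field(default_factory=AreaStateSpace)
    dispersal_rate: float = 1.0e-4
    root_area: str = "Coastal"
    # sequence block: mtDNA-coding-region scale, so that realistic Ne and
    # the slow mitochondrial clock still leave measurable diversity
    seq_length: int = 15000
    hky: HKYParams = field(default_factory=lambda: HKYParams(
        kappa=8.0, freqs=(0.31, 0.31, 0.13, 0.25)))
    gamma_shape: float = 0.5
    seq_clock_rate: float = 1.691e-8

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("lam", "mu", "rho", "cognate_clock_rate",
                     "dispersal_rate", "seq_clock_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def streams(seed: int, n: int = 8) -> list[np.random.Generator]:
    """Independent child RNG streams derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


# --------------------------------------------------------------------- #
# birth-death trees
# --------------------------------------------------------------------- #
def simulate_bd_tree(spec: SimulationSpec | None = None,
                     rng: np.random.Generator | None = None,
                     duration: float | None = None,
                     max_retries: int = 1000) -> TimeTree:
    """Forward birth-death simulation with binomial extant sampling.

    Two stopping modes: grow until ``spec.n_tips`` lineages are extant
    (then sample each with probability rho), or run for a fixed
    ``duration`` in years.  All-extinct (or <2 sampled tips) realizations
    are resampled up to ``max_retries``.  Tip ages are 0 BP; the root age
    is the sampled tips' MRCA age.
    """
    spec = spec or SimulationSpec()
    rng = rng or np.random.default_rng(spec.seed)
    if spec.mu >= spec.lam and duration is None:
        import warnings
        warnings.warn("mu >= lambda: expect many resamples", stacklevel=2)
    for _ in range(max_retries):
        tree = _forward_bd(spec, rng, duration)
        if tree is not None:
            return tree
    raise RuntimeError(f"all {max_retries} birth-death attempts went "
                       "extinct or left <2 sampled tips")


def _forward_bd(spec, rng, duration):
    # node bookkeeping: parent index, birth time (forward, 0 = root)
    parents = [-1]
    btimes = [0.0]
    alive = [0]
    t = 0.0
    target = None if duration is not None else spec.n_tips
    while True:
        k = len(alive)
        if k == 0:
            return None
        if target is not None and k >= target:
            # observe at a uniform point of the next holding interval so
            # the youngest split has a positive terminal branch
            t += rng.exponential(1.0 / (k * (spec.lam + spec.mu))) \
                * rng.random()
            break
        rate = k * (spec.lam + spec.mu)
        t += rng.exponential(1.0 / rate)
        if duration is not None and t >= duration:
            t = duration
            break
        idx = alive[rng.integers(k)]
        if rng.random() < spec.lam / (spec.lam + spec.mu):
            for _ in range(2):
                parents.append(idx)
                btimes.append(t)
                alive.append(len(parents) - 1)
            alive.remove(idx)
        else:
            alive.remove(idx)
    stop = t
    sampled = [v for v in alive if rng.random() < spec.rho]
    if len(sampled) < 2:
        return None
    return _reduce_to_sampled(parents, btimes, sampled, stop, spec)


def _reduce_to_sampled(parents, btimes, sampled, stop, spec):
    """Collapse the full realization to the dated genealogy of the sample."""
    n_all = len(parents)
    keep = np.zeros(n_all, dtype=bool)
    for v in sampled:
        while v >= 0 and not keep[v]:
            keep[v] = True
            v = parents[v]
    children: dict[int, list[int]] = {i: [] for i in range(n_all)}
    for i, p in enumerate(parents):
        if p >= 0 and keep[i] and keep[p]:
            children[p].append(i)
    # suppress unary chains from each sampled tip upward
    sampled_set = set(sampled)

    def collapse(v):
        kids = [collapse(c) for c in children[v]]
        if v in sampled_set:
            return ("tip", v)
        if len(kids) == 1:
            return kids[0]
        # a retained split: both direct children were born at the split time
        return ("node", btimes[children[v][0]], kids)

    root_struct = collapse(0)
    if root_struct is None or root_struct[0] == "tip":
        return None
    out_parent, out_age, out_label = [], [], []

    def emit(struct, parent_idx):
        my = len(out_parent)
        out_parent.append(parent_idx)
        if struct[0] == "tip":
            out_age.append(0.0)
            out_label.append(f"L{struct[1]:03d}")
        else:
            _, split_time, kids = struct
            out_age.append(stop - split_time)
            out_label.append(None)
            for kid in kids:
                emit(kid, my)
        return my

    emit(root_struct, -1)
    tree = TimeTree(out_parent, [a if a is not None else 0.0
                                 for a in out_age], out_label)
    if spec.root_age is not None and tree.root_age > 0:
        tree.ages *= spec.root_age / tree.root_age
    return tree


# --------------------------------------------------------------------- #
# generic CTMC realization along a tree
# --------------------------------------------------------------------- #
def _sample_states_down(tree: TimeTree, P: np.ndarray, root_probs: np.ndarray,
                        rng, n_traits: int) -> np.ndarray:
    """States at every node for ``n_traits`` independent characters;
    ``P`` is (n_nodes, k, k) per-branch transition matrices."""
    k = root_probs.shape[0]
    states = np.empty((tree.n_nodes, n_traits), dtype=np.int64)
    order = tree.postorder[::-1]         # root first
    states[tree.root] = rng.choice(k, size=n_traits, p=root_probs)
    for node in order:
        if node == tree.root:
            continue
        parent_states = states[tree.parent[node]]
        cum = np.cumsum(P[node], axis=1)
        cum = cum / cum[:, -1:]
        u = rng.random(n_traits)
        states[node] = (u[:, None] > cum[parent_states]).sum(axis=1)
    return states


# --------------------------------------------------------------------- #
# cognate matrices
# --------------------------------------------------------------------- #
def simulate_cognate_matrix(tree: TimeTree, spec: SimulationSpec,
                            rng: np.random.Generator | None = None,
                            ascertainment: bool = True):
    """Item-blocked binary matrix evolved under the covarion/CTMC model.

    Each cognate-class column is an independent realization of the binary
    site model along the dated tree (root state from the stationary
    distribution).  All-absent columns — classes that died everywhere —
    are dropped and logged, matching the conditioning the ascertainment
    correction assumes; whole item blocks go missing per language with
    ``spec.missing_prob``.

    Returns ``(matrix, truth)`` where ``truth`` records the generating
    parameters and the number of dropped columns.
    """
    rng = rng or np.random.default_rng(spec.seed)
    rm = build_rate_matrix(spec.cognate_model)
    bl = tree.branch_lengths() * spec.cognate_clock_rate
    P = transition_matrices(rm, bl)
    # visible state of covarion states (0/ON,1/ON,0/OFF,1/OFF) is s % 2
    visible = np.arange(rm.n_states) % 2 if rm.n_states == 4 else \
        np.arange(rm.n_states)
    n_classes = np.maximum(
        1, rng.poisson(spec.mean_classes_per_item - 1, spec.n_items) + 1)
    total = int(n_classes.sum())
    states = _sample_states_down(tree, P, rm.freqs, rng, total)
    tips = list(tree.tips)
    tipdata = visible[states[tips]]          # (n_tips, total)
    labels = [tree.labels[t] for t in tips]

    columns, cols, dropped = [], [], 0
    col = 0
    for item_i, nc in enumerate(n_classes):
        item = f"item{item_i:03d}"
        kept_in_item = 0
        for c in range(nc):
            v = tipdata[:, col]
            col += 1
            if v.sum() == 0:
                dropped += 1
                continue
            columns.append((item, f"c{kept_in_item}"))
            cols.append(v.astype(np.int8))
            kept_in_item += 1
        # an item whose classes all died is unobservable and simply absent
    if not cols:
        raise RuntimeError("every simulated column was all-absent; "
                           "increase the clock rate or tree depth")
    cells = np.stack(cols, axis=1)
    # block-wise missingness
    matrix = CognateMatrix(labels, columns, cells)
    if spec.missing_prob > 0:
        cells = matrix.cells.copy()
        for li in range(len(labels)):
            for item, (s, e) in matrix.item_blocks.items():
                if rng.random() < spec.missing_prob:
                    cells[li, s:e] = MISSING
        # ensure every column keeps at least one observed presence
        keep = [j for j in range(cells.shape[1])
                if np.any(cells[:, j] == 1)]
        matrix = CognateMatrix(labels, [matrix.columns[j] for j in keep],
                               cells[:, keep])
    if ascertainment:
        matrix = add_ascertainment_columns(matrix)
    truth = {"clock_rate": spec.cognate_clock_rate,
             "model": spec.cognate_model, "dropped_all_absent": dropped,
             "root_age": tree.root_age}
    return matrix, truth


def inject_borrowing(matrix: CognateMatrix, donor_group, recipient: str,
                     proportion: float,
                     rng: np.random.Generator | None = None,
                     avoid_group=()):
    """Replace a fraction of the recipient's cognates with donor classes.

    ``ceil(proportion * n_present)`` of the recipient's present classes
    are switched off; for each, a class carried by at least one donor
    language (in the same item block, not already carried by the
    recipient) is switched on.  ``avoid_group`` optionally restricts the
    borrowed classes to ones absent from those languages — real loans are
    donor-diagnostic words, which is what downstream borrowing detection
    keys on.  Returns ``(new_matrix, injected_columns)``.
    """
    if not (0 <= proportion <= 1):
        raise ValueError("proportion must be in [0, 1]")
    donors = list(donor_group)
    if not donors:
        raise ValueError("donor group is empty")
    for name in donors + [recipient]:
        if name not in matrix.languages:
            raise KeyError(f"language {name!r} not in matrix")
    rng = rng or np.random.default_rng()
    out = matrix.copy()
    ri = out.languages.index(recipient)
    d_idx = [out.languages.index(d) for d in donors]
    a_idx = [out.languages.index(a) for a in avoid_group]
    present = out.present_columns(recipient)
    n_replace = math.ceil(proportion * len(present))
    if n_replace == 0:
        return out, []

    def targets(j, require_avoid):
        item = out.columns[j][0]
        s, e = out.item_blocks[item]
        start = s + 1 if out.has_ascertainment else s
        return [c for c in range(start, e)
                if c != j and out.cells[ri, c] != 1
                and any(out.cells[d, c] == 1 for d in d_idx)
                and (not require_avoid
                     or all(out.cells[a, c] != 1 for a in a_idx))]

    # prefer replacements where a donor-diagnostic class is available
    diagnostic = [j for j in present if targets(j, True)] if a_idx else []
    other = [j for j in present if j not in set(diagnostic)
             and targets(j, False)]
    rng.shuffle(diagnostic)
    rng.shuffle(other)
    chosen = (diagnostic + other)[:n_replace]
    injected = []
    for j in chosen:
        candidates = targets(j, True) or targets(j, False)
        if not candidates:
            continue
        tgt = candidates[rng.integers(len(candidates))]
        out.cells[ri, j] = 0
        out.cells[ri, tgt] = 1
        injected.append(tgt)
    return out, injected


# --------------------------------------------------------------------- #
# discrete geography
# --------------------------------------------------------------------- #
def simulate_discrete_geography(tree: TimeTree, allowed_pairs, rates,
                                root_area: str,
                                space: AreaStateSpace | None = None,
                                rng: np.random.Generator | None = None):
    """Exact jump-process realization of areas along the tree.

    ``allowed_pairs`` are unordered area pairs with symmetric rate
    ``rates`` (scalar, or mapping pair -> rate); transitions outside the
    allowed graph never occur, by construction.  Returns
    ``(tip_areas, node_areas, events)`` where ``events`` counts realized
    ordered transitions.
    """
    space = space or AreaStateSpace()
    rng = rng or np.random.default_rng()
    k = space.k
    Q = np.zeros((k, k))
    for pair in allowed_pairs:
        a, b = tuple(pair)
        r = rates if np.isscalar(rates) else rates[frozenset((a, b))]
        Q[space.index(a), space.index(b)] = r
        Q[space.index(b), space.index(a)] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    node_state = np.empty(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = space.index(root_area)
    events = np.zeros((k, k), dtype=np.int64)
    for node in tree.postorder[::-1]:
        if node == tree.root:
            continue
        s = node_state[tree.parent[node]]
        t_remain = tree.branch_length(node)
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0:
                break
            dt = rng.exponential(1.0 / out_rate)
            if dt >= t_remain:
                break
            t_remain -= dt
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            nxt = rng.choice(k, p=probs)
            events[s, nxt] += 1
            s = nxt
        node_state[node] = s
    tip_areas = {tree.labels[t]: space.areas[node_state[t]]
                 for t in tree.tips}
    node_areas = {int(i): space.areas[node_state[i]]
                  for i in tree.internal_nodes()}
    return tip_areas, node_areas, events


# --------------------------------------------------------------------- #
# sequences
# --------------------------------------------------------------------- #
def simulate_coalescent_tree(n_samples: int, demography,
                             rng_seed: int) -> TimeTree:
    """Coalescent genealogy under piecewise-constant Ne via msprime.

    ``demography`` is either a constant size or a list of
    ``(time_start, size)`` steps (times in years = generations here,
    increasing into the past).
    """
    import msprime
    demo = msprime.Demography()
    if np.isscalar(demography):
        demo.add_population(initial_size=float(demography))
    else:
        steps = sorted(demography, key=lambda p: p[0])
        demo.add_population(initial_size=float(steps[0][1]))
        for t, size in steps[1:]:
            demo.add_population_parameters_change(time=float(t),
                                                  initial_size=float(size))
    ts = msprime.sim_ancestry(samples=n_samples, demography=demo,
                              ploidy=1, random_seed=max(1, rng_seed % (2**31)))
    tr = ts.first()
    newick = tr.as_newick()
    tree = TimeTree.from_newick(newick)
    # msprime labels samples n<node+1>; rename to s0..s{n-1}
    mapping = {f"n{i}": f"s{i}" for i in range(n_samples)}
    tree.labels = [mapping.get(l, l) if l is not None else None
                   for l in tree.labels]
    return tree


def simulate_sequences(tree: TimeTree | None, spec: SimulationSpec,
                       rng: np.random.Generator | None = None,
                       demography=None, n_samples: int | None = None
                       ) -> SequenceAlignment:
    """HKY+Gamma sequences along a genealogy at a fixed strict clock.

    If no tree is given, a coalescent genealogy is drawn under
    ``demography`` (constant Ne or piecewise steps) first.  Site rates use
    4 Gamma categories at category means.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if tree is None:
        if demography is None:
            raise ValueError("need a tree or a demographic function")
        tree = simulate_coalescent_tree(
            n_samples or spec.n_tips, demography,
            rng_seed=int(rng.integers(1, 2**31 - 1)))
    rm = build_rate_matrix(spec.hky)
    cat = gamma_category_rates(spec.gamma_shape, 4)
    L = spec.seq_length
    site_cat = rng.integers(0, 4, size=L)
    codes = np.empty((tree.n_tips, L), dtype=np.int8)
    bl = tree.branch_lengths() * spec.seq_clock_rate
    tips = list(tree.tips)
    for c in range(4):
        sites = np.where(site_cat == c)[0]
        if sites.size == 0:
            continue
        P = transition_matrices(rm, bl * cat[c])
        states = _sample_states_down(tree, P, rm.freqs, rng, sites.size)
        codes[:, sites] = states[tips]
    return SequenceAlignment([tree.labels[t] for t in tips], codes)
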