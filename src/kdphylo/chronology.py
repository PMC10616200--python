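"""Bayesian dating: birth-death tree prior, clocks, MCMC, marginal likelihoods.

The centre-piece is :class:`DatingModel` / :class:`DatingResults`, a
model-object pair in the statsmodels mould: the model bundles the cognate
matrix with a site model, a clock and the birth-death-with-extant-sampling
tree prior (hyperpriors lambda, mu ~ Exp(mean 0.01), rho ~ Beta(100, 19));
``fit`` runs a Metropolis-Hastings sampler over node ages, topology, clock
rate and the tree-prior parameters and returns a results object holding the
trace, the posterior tree sample and summary utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import betaln, logsumexp

from .cognates import CognateMatrix
from .phylo import TimeTree
from .substitution import BinaryCTMCParams, CovarionParams, SiteRateModel

__all__ = [
    "BDSKYParams", "ClockModel", "CalibrationPrior", "MCMCConfig",
    "bd_log_prior", "sample_hyperpriors", "initial_bdsky",
    "relaxed_branch_rates", "effective_sample_size",
    "harmonic_mean_log_ml", "path_sampling_log_ml", "estimate_log_ml",
    "power_schedule", "DatingModel", "DatingResults",
]


# --------------------------------------------------------------------- #
# parameter bundles
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class BDSKYParams:
    """Constant-rate birth-death with extant sampling probability rho."""
    lam: float
    mu: float
    rho: float

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("birth rate must be positive")
        if self.mu < 0:
            raise ValueError("death rate must be non-negative")
        if not (0 < self.rho <= 1):
            raise ValueError("sampling proportion must be in (0, 1]")


@dataclass(frozen=True)
class ClockModel:
    """Strict or relaxed-lognormal clock.

    ``rate`` is the mean substitution rate per column per year; ``stdev``
    is the lognormal standard deviation S of the branch-rate multipliers
    (multipliers have mean 1; S = 0 recovers the strict clock).
    """
    kind: str = "strict"
    rate: float = 1e-4
    stdev: float = 0.0

    def __post_init__(self):
        if self.kind not in ("strict", "relaxed-lognormal"):
            raise ValueError("kind must be 'strict' or 'relaxed-lognormal'")
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")
        if self.stdev < 0:
            raise ValueError("stdev must be non-negative")


@dataclass(frozen=True)
class CalibrationPrior:
    """Soft prior density on the age of the MRCA of a set of tips.

    ``dist`` is one of normal/lognormal/gamma/uniform/exponential with
    scipy-style ``params`` in years BP.  No topology constraint is imposed
    unless ``monophyly_enforced`` is set.
    """
    taxa: frozenset
    dist: str
    params: dict
    monophyly_enforced: bool = False

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise ValueError("a calibration needs at least 2 taxa")
        if self.dist not in ("normal", "lognormal", "gamma", "uniform",
                             "exponential"):
            raise ValueError(f"unknown calibration distribution {self.dist!r}")

    def _frozen(self):
        cached = getattr(self, "_frozen_dist", None)
        if cached is not None:
            return cached
        p = self.params
        if self.dist == "normal":
            d = st.norm(loc=p["mean"], scale=p["sd"])
        elif self.dist == "lognormal":
            d = st.lognorm(s=p["sdlog"], scale=math.exp(p["meanlog"]))
        elif self.dist == "gamma":
            d = st.gamma(a=p["shape"], scale=p["scale"])
        elif self.dist == "uniform":
            d = st.uniform(loc=p["lower"], scale=p["upper"] - p["lower"])
        else:
            d = st.expon(scale=p["mean"])
        object.__setattr__(self, "_frozen_dist", d)
        return d

    def logpdf(self, age: float) -> float:
        return float(self._frozen().logpdf(age))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length bookkeeping.

    The chain is sampled at every ``sample_every``-th generation, so the
    retained posterior sample size is
    ``generations / sample_every - burnin_samples`` (burn-in is counted in
    samples, not generations).
    """
    generations: int = 50_000
    sample_every: int = 50
    burnin_samples: int = 100
    seed: int = 1
    move_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.generations % self.sample_every:
            raise ValueError("generations must be divisible by sample_every")
        if self.burnin_samples >= self.generations // self.sample_every:
            raise ValueError("burn-in exceeds the number of samples")

    @property
    def n_samples(self) -> int:
        return self.generations // self.sample_every

    @property
    def n_retained(self) -> int:
        return self.n_samples - self.burnin_samples


# --------------------------------------------------------------------- #
# tree prior
# --------------------------------------------------------------------- #
def _p0_p1(t: np.ndarray, p: BDSKYParams):
    r = p.lam - p.mu
    if abs(r) < 1e-12:
        raise ValueError("birth and death rates must differ")
    c = p.lam * (1 - p.rho) - p.mu
    denom = p.rho * p.lam + c * np.exp(-r * t)
    p0 = 1 - p.rho * r / denom
    p1 = p.rho * r * r * np.exp(-r * t) / denom ** 2
    return p0, p1


def _cumulative_p1(t: float, p: BDSKYParams) -> float:
    """F(t) = integral_0^t lambda p1(x) dx, closed form."""
    r = p.lam - p.mu
    c = p.lam * (1 - p.rho) - p.mu
    if abs(c) < 1e-12:
        return r * (1 - math.exp(-r * t)) / (p.rho * p.lam)
    d1 = p.rho * p.lam + c * math.exp(-r * t)
    d0 = p.rho * p.lam + c
    return p.lam * p.rho * r / c * (1.0 / d1 - 1.0 / d0)


def bd_log_prior(tree: TimeTree, p: BDSKYParams,
                 condition: str = "root") -> float:
    """Log-density of a time tree under the constant-rate sampled birth-death.

    ``condition="root"`` gives the process density for a tree started from
    its root (each reconstructed lineage carries its lambda * p1 factor;
    no survival conditioning) — the form used inside the MCMC, where
    lambda, mu and rho all enter.  ``condition="ages"`` gives the density of the non-root node
    ages given the root age and the tip count, which is properly normalized
    (each subordinate age iid proportional to lambda * p1) and reduces to
    the classical Yule form when mu = 0, rho = 1.
    """
    root_age = tree.root_age
    if root_age <= 0:
        raise ValueError("zero-length tree")
    r = p.lam - p.mu
    if abs(r) < 1e-12:
        raise ValueError("birth and death rates must differ")
    c = p.lam * (1 - p.rho) - p.mu
    log_lam = math.log(p.lam)

    def log_p1(t):
        denom = p.rho * p.lam + c * math.exp(-r * t)
        if denom <= 0:
            return -math.inf
        return math.log(p.rho) + 2 * math.log(abs(r)) - r * t \
            - 2 * math.log(denom)

    total = 0.0
    for v in range(tree.n_nodes):
        if not tree.children[v] or v == tree.root:
            continue
        total += log_lam + log_p1(float(tree.ages[v]))
    if condition == "root":
        return total + 2 * log_p1(root_age)
    if condition == "ages":
        F = _cumulative_p1(root_age, p)
        n_others = len(tree.internal_nodes()) - 1
        return total - n_others * math.log(F)
    raise ValueError(f"unknown condition {condition!r}")


def sample_hyperpriors(rng: np.random.Generator) -> BDSKYParams:
    """One draw from the tree-prior hyperpriors:
    lambda, mu ~ Exponential(mean 0.01), rho ~ Beta(100, 19)."""
    return BDSKYParams(lam=float(rng.exponential(0.01)),
                       mu=float(rng.exponential(0.01)),
                       rho=float(rng.beta(100, 19)))


def initial_bdsky(rng: np.random.Generator) -> BDSKYParams:
    """The chain's starting state: lambda = 0.01, mu = 0.008, rho drawn
    from its Beta(100, 19) prior."""
    return BDSKYParams(lam=0.01, mu=0.008, rho=float(rng.beta(100, 19)))


_BETA_100_19_CONST = float(betaln(100, 19))


def _log_expon(x: float, mean: float) -> float:
    return -math.log(mean) - x / mean if x >= 0 else -math.inf


def _log_beta_100_19(x: float) -> float:
    if not (0 < x < 1):
        return -math.inf
    return 99 * math.log(x) + 18 * math.log1p(-x) - _BETA_100_19_CONST


def _log_lognorm(x: float, median: float, sd: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - math.log(median)) / sd
    return -math.log(x * sd * math.sqrt(2 * math.pi)) - 0.5 * z * z


def _hyper_logprior(p: BDSKYParams) -> float:
    return (_log_expon(p.lam, 0.01) + _log_expon(p.mu, 0.01)
            + _log_beta_100_19(p.rho))


# --------------------------------------------------------------------- #
# clocks
# --------------------------------------------------------------------- #
@lru_cache(maxsize=64)
def _discretized_lognormal_cached(stdev: float, ncat: int):
    q = (np.arange(ncat) + 0.5) / ncat
    out = st.lognorm.ppf(q, s=stdev, scale=math.exp(-stdev ** 2 / 2))
    out.setflags(write=False)
    return out


def discretized_lognormal_multipliers(stdev: float, ncat: int) -> np.ndarray:
    """Quantile-discretized LogNormal(-S^2/2, S) branch-rate multipliers."""
    if stdev == 0:
        return np.ones(ncat)
    return _discretized_lognormal_cached(float(stdev), int(ncat))


def relaxed_branch_rates(tree: TimeTree, clock: ClockModel,
                         categories: np.ndarray | None = None,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-node branch rates (substitutions per column per year).

    Under the relaxed lognormal clock each branch gets one of ``n_branches``
    equal-probability quantiles of a mean-1 lognormal; ``categories`` fixes
    the assignment, otherwise one is drawn uniformly at random.
    """
    n = tree.n_nodes
    if clock.kind == "strict" or clock.stdev == 0:
        return np.full(n, clock.rate)
    mult = discretized_lognormal_multipliers(clock.stdev, n)
    if categories is None:
        if rng is None:
            raise ValueError("need categories or an rng")
        categories = rng.integers(0, n, size=n)
    return clock.rate * mult[np.asarray(categories)]


# --------------------------------------------------------------------- #
# trace statistics & marginal likelihoods
# --------------------------------------------------------------------- #
def effective_sample_size(series) -> float:
    """Autocorrelation-time ESS with Geyer initial-positive truncation.

    Returns NaN (with a warning) for a constant series, where the
    autocorrelation time is undefined.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = np.mean(x * x)
    if var == 0:
        import warnings
        warnings.warn("constant series: ESS undefined", stacklevel=2)
        return float("nan")
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    # Geyer: sum of adjacent pairs, truncated at first negative pair
    tau = 1.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k]
        if pair < 0:
            break
        tau += 2 * pair
    return float(min(n, n / tau))


def harmonic_mean_log_ml(loglik_samples) -> float:
    """Harmonic-mean estimator of the log marginal likelihood (unstable but
    reported for comparability with common practice)."""
    ll = np.asarray(loglik_samples, dtype=float)
    if ll.size == 0:
        raise ValueError("empty trace")
    return float(-(logsumexp(-ll) - math.log(ll.size)))


def power_schedule(n_steps: int = 8, alpha: float = 0.3) -> np.ndarray:
    """Power-posterior temperatures beta as quantiles of Beta(alpha, 1),
    descending from 1 to 0."""
    if n_steps < 1:
        raise ValueError("need at least one step")
    if n_steps == 1:
        return np.array([1.0])
    q = np.linspace(1.0, 0.0, n_steps)
    return q ** (1.0 / alpha)


def path_sampling_log_ml(betas, mean_logliks) -> float:
    """Path-sampling (thermodynamic integration) estimate.

    ``mean_logliks[i]`` must be the posterior-expected data log-likelihood
    under the power posterior with temperature ``betas[i]``; the estimator
    is the trapezoid integral over beta in [0, 1].  A single step
    degenerates to the posterior-mean log-likelihood.
    """
    b = np.asarray(betas, dtype=float)
    m = np.asarray(mean_logliks, dtype=float)
    if b.size == 0:
        raise ValueError("empty schedule")
    if b.size == 1:
        return float(m[0])
    order = np.argsort(b)
    return float(np.trapezoid(m[order], b[order]))


def estimate_log_ml(loglik_samples=None, betas=None, mean_logliks=None) -> dict:
    """Both marginal-likelihood estimators; log Bayes factors are
    differences of the returned values between model configurations."""
    out = {}
    if loglik_samples is not None:
        out["hme"] = harmonic_mean_log_ml(loglik_samples)
    if betas is not None:
        out["path"] = path_sampling_log_ml(betas, mean_logliks)
    if not out:
        raise ValueError("provide a trace and/or a power-posterior schedule")
    return out


# --------------------------------------------------------------------- #
# the dating model
# --------------------------------------------------------------------- #
class DatingModel:
    """Joint model of a cognate matrix, a clock and the birth-death prior.

    Parameters
    ----------
    matrix
        Ascertainment-augmented :class:`CognateMatrix`.
    subst_model
        ``BinaryCTMCParams`` or ``CovarionParams``.
    site_rates
        Gamma heterogeneity (CTMC pairings use 1 or 4 categories; the
        covarion runs without Gamma by default).
    clock
        :class:`ClockModel`; the configured ``rate`` is the initial value
        and the prior median of the sampled clock rate.
    calibrations
        Iterable of :class:`CalibrationPrior`.
    """

    #: the six standard site-model x clock combinations
    MODEL_COMBINATIONS = [
        ("ctmc+g1", "strict"), ("ctmc+g1", "relaxed-lognormal"),
        ("ctmc+g4", "strict"), ("ctmc+g4", "relaxed-lognormal"),
        ("covarion", "strict"), ("covarion", "relaxed-lognormal"),
    ]

    def __init__(self, matrix: CognateMatrix, subst_model=None,
                 site_rates: SiteRateModel | None = None,
                 clock: ClockModel | None = None,
                 calibrations=(),
                 clock_rate_prior_sd: float = 1.0):
        if not matrix.has_ascertainment:
            raise ValueError("dating requires an ascertainment-augmented "
                             "matrix")
        self.matrix = matrix
        self.subst_model = subst_model or CovarionParams()
        self.site_rates = site_rates
        self.clock = clock or ClockModel()
        self.calibrations = list(calibrations)
        self.clock_rate_prior_sd = clock_rate_prior_sd
        from .likelihood import PruningEngine
        self._engine = PruningEngine(matrix, self.subst_model,
                                     self.site_rates)
        self._engine_s = getattr(self.subst_model, "s", None)

    # -- configuration helper ------------------------------------------ #
    @classmethod
    def from_combination(cls, matrix: CognateMatrix, site: str, clock: str,
                         rate: float, stdev: float = 0.3, **kw):
        """Build one of the six site-model x clock combinations by name."""
        if site == "ctmc+g1":
            sm, sr = BinaryCTMCParams(), SiteRateModel(1)
        elif site == "ctmc+g4":
            sm, sr = BinaryCTMCParams(), SiteRateModel(4, shape=0.5)
        elif site == "covarion":
            sm, sr = CovarionParams(), None
        else:
            raise ValueError(f"unknown site model {site!r}")
        ck = ClockModel(clock, rate, 0.0 if clock == "strict" else stdev)
        return cls(matrix, sm, sr, ck, **kw)

    # -- pieces of the posterior --------------------------------------- #
    def _data_loglik(self, tree, clock_rate, categories, cov_s) -> float:
        if (cov_s is not None and cov_s != self._engine_s
                and isinstance(self.subst_model, CovarionParams)):
            self._engine.set_model(replace(self.subst_model, s=cov_s))
            self._engine_s = cov_s
        rates = clock_rate if categories is None else \
            relaxed_branch_rates(tree, replace(self.clock, rate=clock_rate),
                                 categories)
        return self._engine.corrected_loglik(tree, rates)

    def _log_prior(self, tree, bd: BDSKYParams, clock_rate, cov_s) -> float:
        lp = bd_log_prior(tree, bd, condition="root")
        lp += _hyper_logprior(bd)
        for cal in self.calibrations:
            node = tree.mrca(cal.taxa)
            lp += cal.logpdf(tree.ages[node])
            if cal.monophyly_enforced and \
                    tree.descendant_tips(node) != set(cal.taxa):
                return -np.inf
        lp += _log_lognorm(clock_rate, self.clock.rate,
                           self.clock_rate_prior_sd)
        if cov_s is not None:
            lp += _log_expon(cov_s, 1.0)
        return lp

    # -- fitting -------------------------------------------------------- #
    def fit(self, config: MCMCConfig, init_tree: TimeTree | None = None,
            fix_clock_rate: bool = False, sample_covarion_switch: bool = True,
            prior_only: bool = False, power: float = 1.0,
            progress: bool = False) -> "DatingResults":
        """Run the Metropolis-Hastings sampler and return the results.

        ``prior_only`` strips the data term (for prior-predictive checks);
        ``power`` tempers the likelihood (power posteriors for path
        sampling).  Two runs with the same config are identical.
        """
        rng = np.random.default_rng(config.seed)
        tree = (init_tree.copy() if init_tree is not None
                else _random_coalescent_start(self.matrix.languages, rng))
        bd = initial_bdsky(rng)
        clock_rate = self.clock.rate
        relaxed = self.clock.kind == "relaxed-lognormal" and self.clock.stdev > 0
        categories = rng.integers(0, tree.n_nodes, tree.n_nodes) if relaxed \
            else None
        cov_s = (self.subst_model.s
                 if isinstance(self.subst_model, CovarionParams)
                 and sample_covarion_switch else None)

        def loglik(tr, cr, cat, s):
            if prior_only:
                return 0.0
            return self._data_loglik(tr, cr, cat, s)

        cur_ll = loglik(tree, clock_rate, categories, cov_s)
        cur_lp = self._log_prior(tree, bd, clock_rate, cov_s)
        if not np.isfinite(cur_ll + cur_lp):
            raise ValueError("initial state has zero posterior probability; "
                             "check calibrations and starting tree")

        weights = {"ages": 4.0, "root": 1.0, "scale": 1.0, "narrow": 2.0,
                   "spr": 1.0, "bd": 1.5, "clock": 0.0 if fix_clock_rate else 1.0,
                   "covarion_s": 1.0 if cov_s is not None else 0.0,
                   "categories": 2.0 if relaxed else 0.0}
        weights.update(config.move_weights)
        move_names = [k for k, w in weights.items() if w > 0]
        move_p = np.array([weights[k] for k in move_names])
        move_p = move_p / move_p.sum()

        records, trees = [], []
        accepted = {k: 0 for k in move_names}
        proposed = {k: 0 for k in move_names}
        for it in range(1, config.generations + 1):
            move = move_names[rng.choice(len(move_names), p=move_p)]
            proposed[move] += 1
            new_tree, new_bd = tree, bd
            new_rate, new_cat, new_s = clock_rate, categories, cov_s
            log_hastings = 0.0
            ok = True
            if move == "ages":
                new_tree = tree.copy()
                ok = _move_node_age(new_tree, rng)
            elif move == "root":
                new_tree = tree.copy()
                log_hastings = _move_root_scale(new_tree, rng)
                ok = log_hastings is not None
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
            elif move == "bd":
                which = rng.integers(3)
                if which == 0:
                    m = math.exp(0.5 * (rng.random() - 0.5))
                    new_bd = replace(bd, lam=bd.lam * m)
                    log_hastings = math.log(m)
                elif which == 1:
                    m = math.exp(0.5 * (rng.random() - 0.5))
                    new_bd = replace(bd, mu=max(bd.mu * m, 1e-12))
                    log_hastings = math.log(m)
                else:
                    # independence draw from the rho prior: prior ratio and
                    # proposal ratio cancel in the acceptance probability
                    new_bd = replace(bd, rho=float(rng.beta(100, 19)))
                    log_hastings = (_log_beta_100_19(bd.rho)
                                    - _log_beta_100_19(new_bd.rho))
            elif move == "clock":
                m = math.exp(0.4 * (rng.random() - 0.5))
                new_rate = clock_rate * m
                log_hastings = math.log(m)
            elif move == "covarion_s":
                m = math.exp(0.5 * (rng.random() - 0.5))
                new_s = cov_s * m
                log_hastings = math.log(m)
            elif move == "categories":
                new_cat = categories.copy()
                b = rng.integers(tree.n_nodes)
                new_cat[b] = rng.integers(tree.n_nodes)

            if ok:
                tree_changed = move in ("ages", "root", "scale", "narrow",
                                        "spr")
                ll_changed = tree_changed or move in ("clock", "covarion_s",
                                                      "categories")
                new_ll = loglik(new_tree, new_rate, new_cat, new_s) \
                    if ll_changed else cur_ll
                new_lp = self._log_prior(new_tree, new_bd, new_rate, new_s)
                log_alpha = power * (new_ll - cur_ll) + new_lp - cur_lp \
                    + log_hastings
                if np.isfinite(new_lp) and math.log(rng.random()) < log_alpha:
                    tree, bd = new_tree, new_bd
                    clock_rate, categories, cov_s = new_rate, new_cat, new_s
                    cur_ll, cur_lp = new_ll, new_lp
                    accepted[move] += 1

            if it % config.sample_every == 0:
                rec = {"state": it, "posterior": cur_ll + cur_lp,
                       "likelihood": cur_ll, "prior": cur_lp,
                       "root_age": tree.root_age, "clock_rate": clock_rate,
                       "lambda": bd.lam, "mu": bd.mu, "rho": bd.rho}
                if cov_s is not None:
                    rec["covarion_s"] = cov_s
                records.append(rec)
                trees.append(tree.copy())
        trace = pd.DataFrame(records)
        return DatingResults(self, config, trace, trees,
                             acceptance={k: accepted[k] / max(proposed[k], 1)
                                         for k in move_names})


class DatingResults:
    """Posterior sample from :meth:`DatingModel.fit`.

    ``trace`` keeps every sampled state; ``posterior_trace`` and
    ``posterior_trees`` drop the configured burn-in.
    """

    def __init__(self, model: DatingModel, config: MCMCConfig,
                 trace: pd.DataFrame, trees: list, acceptance: dict):
        self.model = model
        self.config = config
        self.trace = trace
        self.trees = trees
        self.acceptance = acceptance

    @property
    def posterior_trace(self) -> pd.DataFrame:
        return self.trace.iloc[self.config.burnin_samples:]

    @property
    def posterior_trees(self) -> list:
        return self.trees[self.config.burnin_samples:]

    @property
    def root_ages(self) -> np.ndarray:
        return self.posterior_trace["root_age"].to_numpy()

    def log_marginal_likelihood(self, method: str = "hme", n_steps: int = 8,
                                **fit_kw) -> float:
        """HME from the existing trace, or path sampling via fresh
        power-posterior runs at ``n_steps`` temperatures."""
        if method == "hme":
            return harmonic_mean_log_ml(
                self.posterior_trace["likelihood"].to_numpy())
        if method == "path":
            betas = power_schedule(n_steps)
            means = []
            for i, b in enumerate(betas):
                cfg = replace(self.config, seed=self.config.seed + 1000 + i)
                res = self.model.fit(cfg, power=float(b), **fit_kw)
                means.append(res.posterior_trace["likelihood"].mean())
            return path_sampling_log_ml(betas, means)
        raise ValueError(f"unknown method {method!r}")

    def ess(self, column: str = "root_age") -> float:
        return effective_sample_size(self.posterior_trace[column].to_numpy())

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, 95% HPD and ESS per scalar parameter."""
        from .treesummary import hpd_interval
        rows = []
        for col in self.posterior_trace.columns:
            if col == "state":
                continue
            x = self.posterior_trace[col].to_numpy()
            lo, hi = hpd_interval(x) if x.size >= 20 else (np.nan, np.nan)
            ess = effective_sample_size(x) if np.std(x) > 0 else np.nan
            rows.append({"parameter": col, "mean": x.mean(),
                         "sd": x.std(ddof=1), "hpd95_lower": lo,
                         "hpd95_upper": hi, "ess": ess})
        return pd.DataFrame(rows).set_index("parameter")

    def write_trace(self, path) -> None:
        self.trace.to_csv(path, sep="\t", index=False)

    def write_trees(self, path) -> None:
        from .phylo import write_newick_list
        write_newick_list(self.trees, path)

    def mcc_tree(self, burnin_fraction: float = 0.1,
                 support_floor: float = 0.5):
        from .treesummary import mcc_tree
        return mcc_tree(self.trees, burnin_fraction, support_floor)

    def plot_root_age(self, ax=None):  # pragma: no cover - thin plotting
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.root_ages, bins=40, density=True)
        ax.set_xlabel("root age (years BP)")
        ax.set_ylabel("posterior density")
        return ax


# --------------------------------------------------------------------- #
# tree moves (module-level so tests can hit them directly)
# --------------------------------------------------------------------- #
def _random_coalescent_start(labels, rng: np.random.Generator,
                             mean_height: float = 2000.0) -> TimeTree:
    """A random ultrametric starting tree (Kingman-style joins)."""
    n = len(labels)
    nodes = list(range(n))
    parent = [-1] * (2 * n - 1)
    ages = [0.0] * (2 * n - 1)
    labs: list = list(labels) + [None] * (n - 1)
    t = 0.0
    nxt = n
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(mean_height / (k * (k - 1) / 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent[a] = parent[b] = nxt
        ages[nxt] = t
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    return TimeTree(parent, ages, labs)


def _move_node_age(tree: TimeTree, rng) -> bool:
    """Uniform resample of one non-root internal node age (symmetric)."""
    internals = [i for i in tree.internal_nodes() if tree.parent[i] >= 0]
    if not internals:
        return False
    node = internals[rng.integers(len(internals))]
    lo = max(tree.ages[c] for c in tree.children[node])
    hi = tree.ages[tree.parent[node]]
    if hi <= lo:
        return False
    tree.ages[node] = lo + (hi - lo) * rng.random()
    return True


def _move_root_scale(tree: TimeTree, rng):
    """Scale the root height above its older child; returns log-Hastings."""
    root = tree.root
    lo = max(tree.ages[c] for c in tree.children[root])
    m = math.exp(0.5 * (rng.random() - 0.5))
    new = lo + (tree.ages[root] - lo) * m
    tree.ages[root] = new
    return math.log(m)


def _narrow_pairs(tree: TimeTree) -> list[tuple[int, int, int, int]]:
    """All valid (grandparent, parent, uncle, child) exchange tuples."""
    pairs = []
    for g in tree.internal_nodes():
        kids = tree.children[g]
        for p in kids:
            if not tree.children[p]:
                continue
            for u in kids:
                if u == p or tree.ages[p] <= tree.ages[u]:
                    continue
                for c in tree.children[p]:
                    pairs.append((g, p, u, c))
    return pairs


def _narrow_exchange(tree: TimeTree, rng):
    """Swap an 'uncle' with a grandchild; returns log-Hastings or None.

    The proposal picks uniformly among all age-valid (uncle, nephew)
    pairs, so the Hastings ratio is the ratio of valid-pair counts before
    and after the swap.
    """
    pairs = _narrow_pairs(tree)
    if not pairs:
        return None
    g, p, u, c = pairs[rng.integers(len(pairs))]
    tree.parent[u] = p
    tree.parent[c] = g
    tree._rebuild_topology_caches()
    n_new = len(_narrow_pairs(tree))
    return math.log(len(pairs) / n_new)


def _subtree_slide(tree: TimeTree, rng) -> bool:
    """Regraft a subtree's stem onto another branch crossing its age."""
    movable = [i for i in range(tree.n_nodes)
               if tree.parent[i] >= 0 and tree.parent[tree.parent[i]] >= 0]
    if not movable:
        return False
    c = movable[rng.integers(len(movable))]
    p = tree.parent[c]
    g = tree.parent[p]
    sib = [x for x in tree.children[p] if x != c][0]
    # forbidden: anything inside c's subtree, plus p itself
    sub = {c}
    stack = [c]
    while stack:
        v = stack.pop()
        for ch in tree.children[v]:
            sub.add(ch)
            stack.append(ch)
    t_p = tree.ages[p]
    targets = [i for i in range(tree.n_nodes)
               if i not in sub and i != p and tree.parent[i] >= 0
               and tree.parent[i] != p
               and tree.ages[i] < t_p < tree.ages[tree.parent[i]]]
    # the merged sib--g edge is also a valid (identity-ish) target
    if tree.ages[sib] < t_p < tree.ages[g]:
        targets.append(sib)
    if not targets:
        return False
    tgt = targets[rng.integers(len(targets))]
    tree.parent[sib] = g                      # detach p from its edge
    tree.parent[p] = g if tgt == sib else tree.parent[tgt]
    tree.parent[tgt] = p                      # insert p above the target
    tree.parent[c] = p
    tree._rebuild_topology_caches()
    return True
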