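# Methods

`kdphylo` implements the full Bayesian analysis chain used to date and
spatially trace a language family from binary lexical cognate data: data
encoding with ascertainment columns, covarion/CTMC likelihoods, relaxed-
and strict-clock birth–death dating by MCMC, posterior summarization
(MCC tree, HPD intervals, divergence tempo), reversible-jump discrete
phylogeography over five areas, a coalescent Bayesian skyline stage for
mtDNA-style alignments, and quartet-based reticulation diagnostics. This
note records the models, the defaults and why, the numerical choices,
and what the synthetic-data checks do and do not establish.

## Cognate encoding

A wide language-by-concept table is filtered to concepts documented in
*strictly more than* a coverage fraction of the sample (default 0.70; an
item at exactly 70% is dropped). Each (concept, cognate-class) pair
becomes one binary column; a language scores 1 on every class it uses
for the concept (synonyms give several 1s), 0 on classes it lacks while
documented, and the whole block is `?` when the concept is undocumented.
One all-absent *ascertainment* column is prepended to each concept
block. Column bookkeeping is exact: classes + items columns after
augmentation.

## Site models and likelihood

Binary characters evolve under a two-state reversible CTMC or the
standard binary covarion: the state space (0/ON, 1/ON, 0/OFF, 1/OFF)
couples the visible presence/absence chain to a hidden ON/OFF switch
with overall rate `s` and stationary hidden frequencies; no visible
change happens while OFF. Generators are normalized to one expected
*visible* substitution per unit branch length at rate 1; at `s = 0` the
hidden chain is frozen ON and the model reduces exactly to the plain
CTMC. Gamma rate heterogeneity uses 1 or 4 equal-weight categories at
category means and is paired with the CTMC (the covarion runs without
Gamma by default; a flag enables it).

Likelihoods use Felsenstein pruning, vectorized over site patterns
(unique columns with weights), with partial-likelihood rescaling every
fourth internal node — enough to keep a 100-tip, 700-column problem away
from underflow without paying a rescale at every node. Branch transition
matrices for all branches and rate categories come from one
eigendecomposition of the generator, with an `expm` fallback when the
eigenbasis is ill-conditioned (e.g. heavily restricted geographic
generators). A numba kernel accelerates the binary-tree case; a pure
NumPy path handles everything else and is the reference in tests.

Ascertainment correction is per concept block: the block's first column
evaluates to L0, the probability of the never-observed all-absent
pattern, and each observed column in the block is conditioned on
non-absence by subtracting `log(1 − L0)`. The correction is exact for
the generating process used by the simulator, which drops all-absent
columns.

## Dating

The tree prior is the constant-rate birth–death process with extant
sampling probability ρ, expressed through the standard one-sampled-
descendant density p1: each non-root internal node contributes
`λ·p1(age)` and the root contributes `p1(root age)²` ("conditioned on
the root", no survival conditioning — so the density vanishes as ρ→0 in
slow-rate regimes). A normalized variant ("ages"): the subordinate node
ages given root age and tip count are iid with density `λ p1 / F`, used
by the quadrature and Yule oracles. Hyperpriors follow the study design:
λ, μ ~ Exponential(mean 0.01), ρ ~ Beta(100, 19), with the chain started
at λ = 0.01, μ = 0.008.

Clocks: strict, or relaxed-lognormal with quantile-discretized mean-1
multipliers (one category per branch, resampled by the chain; the
spread S is fixed at its configured value rather than sampled — a
deliberate simplification at this problem size). Calibrations are soft
scipy densities on MRCA ages without topology constraints unless
monophyly is explicitly enforced.

The sampler is plain Metropolis–Hastings with node-age resampling, root
and whole-tree scaling, narrow exchange (uniform over valid
uncle–nephew pairs, with the exact pair-count Hastings ratio), a
subtree-slide/regraft at fixed height, and scale or
independence moves for the scalar parameters. Marginal likelihoods come
from the harmonic mean estimator (reported for comparability despite its
known instability) and from path sampling over 8 Beta(0.3, 1)-quantile
temperatures (the recommended default; the conjugate beta-binomial
oracle bounds both at |error| < 0.1). ESS is the classical
autocorrelation-time estimator with Geyer initial-positive truncation.

## Posterior summaries

The MCC tree is the *sampled* tree maximizing the product of clade
posterior frequencies (exact counting, no consensus rebuild), annotated
with mean node ages and 95% HPDs over the trees containing each clade;
supports below the floor are masked, not collapsed. HPD intervals are
the shortest sorted-sample windows containing ⌈0.95·n⌉ draws. The
divergence tempo counts internal nodes in closed 500-year windows
stepped by 50 years; smoothing is tricube-weighted degree-1 local
regression (statsmodels lowess) over the nearest ⌈span·n⌉ points,
span 0.1. Interval-dated site records are counted with closed bounds on
both ends. The root-age test against an external hypothesis is the
classical one-sample t on the posterior draws.

## Discrete phylogeography

Tip areas evolve under a 5-state CTMC whose k(k−1) ordered rates are
partitioned by reversible jump into shared rate classes, one of which
pins its members to exactly zero. Branch lengths in years are rescaled
by 1e-4 before exponentiation. Class values follow Exponential(mean m)
with m ~ Uniform(0, 10). The structure prior places each rate in the
zero class independently with probability 0.5 and partitions the
remaining rates uniformly; we chose this over a uniform prior on all
partition structures because the latter gives a four-pair restriction a
Bell-number-vanishing prior visit rate (~3e-6), unobservable in any
finite chain. RJ moves: move-one-rate (zero class, an existing class, or
a fresh class born from the prior, with candidate-count Hastings terms)
and a paired move that jumps both directions of an area pair between
"both zero" and "a fresh shared class". The kernel's stationary
distribution over structures is verified against the analytic prior by
exhaustive counting on a 2-rate toy.

The root state prior is the *limiting distribution* of the sampled
generator (uniform for an all-zero generator). With a uniform root prior
instead, "sink" configurations — every area flowing into the observed
one — explain single-area data without pinning the root, which
contradicts the equilibrium reading of ancestral-state reconstruction.
Node posteriors use the exact up–down marginal algorithm, with
constrained nodes' partials zeroed outside their fixed state, and are
recorded only in samples whose tree contains the queried clade.

Support for a named restriction pattern (e.g. "no transitions between
non-adjacent areas") is a visit-count Bayes factor: the fraction of
retained samples whose zero class covers the pattern's ordered rates,
over the prior expectation (0.5 per rate). BF < 1 argues against a
model; BF > 30 is very strong support. The geographic adjacency behind
the adjacent-transitions-only model is data, not code
(`DEFAULT_ADJACENCY`), since reasonable readings differ. The candidate
set treats the sea lane between the island area and the mainland
southeast as adjacent in the baseline model and severs one extra link in
each alternative.

A `symmetric=True` variant ties the two directions of each pair to one
rate (10 rates, prior zero fraction 0.5 per pair). Requiring both
ordered rates of four pairs to be zeroed independently dilutes a weak
restriction signal by roughly the square; since dispersal in the
generative scenarios is symmetric, the tied variant is the matched
instrument for scaled-down restriction-recovery checks, while the
ordered-rate sampler remains the default surface.

## Skyline

The coalescent Bayesian skyline groups the n−1 coalescent events into
⌈√(n−1)⌉ groups (even split; group sizes are not resampled) with one
population size per group; the prior is scale-free on the first size and
an exponential chain on successors. The HKY+Γ4 likelihood runs on
compressed site patterns with a fixed strict clock (default 1.691e-8
subs/site/year) converting years to substitutions; κ and the Gamma shape
are sampled. Joint tree+size scaling moves handle the strong
Ne–tree-height ridge. Trajectories report median and central 95% bands
on a uniform grid to the median root age, stepwise by default with a
linear-interpolation option.

## Diagnostics

Lexical distances are Jaccard distances over cognate-class sets: a
column is comparable for a pair when observed in both languages and
present in at least one; identical inventories give 0, disjoint ones 1.
δ-scores and Q-residuals follow the quartet definitions — order the
three pairwise sums m1 ≥ m2 ≥ m3, δ = (m1−m2)/(m1−m3) (0 when m1 = m3),
Q = ((m1−m2)/d̄)² with the global mean distance d̄ as the scale — and are
exactly 0 on additive (tree-derived) distances. The four-point borrowing
proportion is the share of a suspect language's present classes shared
with at least one attractor-group language but no home-group language;
above 0.20 the placement is flagged as beyond what tree-based inference
tolerates. This operation is a defined, testable surrogate for the
qualitative published analysis.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical *shape* of the study inputs at
reduced size: birth–death trees with ρ-thinned contemporaneous tips
(observation falls at a uniform point of the post-target holding
interval, so terminal branches are never zero); item-blocked cognate
matrices with ~7 classes per concept and stationary presence ≈ 1/7
(matching 646 classes over 90 items, one class in use per language per
concept), all-absent columns dropped and counted; block-wise
missingness; controlled borrowing that rewires a stated fraction of a
recipient's classes to donor-carried (preferentially donor-diagnostic)
classes; exact Gillespie realizations of restricted dispersal graphs;
and HKY+Γ sequences on msprime coalescent genealogies at mtDNA scale
(15 kb, 1.691e-8/site/year). One RNG stream per sub-simulation keeps
components independently reproducible.

It does **not** emulate: semantic shift and polysemy, sound change,
dialect-chain (non-tree) descent, heterogeneous per-concept replacement
rates, geographically structured borrowing, or sequencing error. Passing
recovery checks therefore demonstrates internal consistency of the
inference machinery under its own generative assumptions, not robustness
to the ways real lexical data violate them.

Recovery scenarios are scaled down and documented as such: dating uses
20-tip trees, 50 items and 50k-generation chains with the strict-clock
rate fixed to truth (the real analysis calibrates; at this size a
calibration prior would swamp the data signal under test). Root-area
recovery runs a rare-dispersal scenario (2e-5/yr) because
single-realization ancestral-state recovery is information-limited: at
the generator's default movement rate (1e-4/yr, ~0.5 events per mean
branch) a single early dispersal event legitimately relocates most of
the family, and even the true-parameter reconstruction then prefers the
wrong root area. Restriction-model support is evaluated under the denser
default movement, where the forbidden pairs at least have realized
opportunity; with 40 tips the visit-count BF for a four-pair restriction
remains weak, and its replicate-level ranking above the unrestricted
model is a noisy majority rather than a sharp outcome — a power
limitation of the statistic at this scale, not a defect of the sampler
(whose structure-prior stationarity is verified exactly). Skyline
fold-change recovery uses 40 sequences: with fewer, too few coalescent
events fall in each epoch and the estimated fold shrinks systematically
(a 16-fold step reads as ~7-fold at 16 sequences). The δ-score
borrowing trend is checked under diffuse borrowing (several recipients,
unrelated donor trios); a single wholesale borrower becomes tree-like
again at high proportions, with conflict peaking at intermediate
mixture.

## Numerical choices and degenerate inputs

- Transition probabilities are clipped at 0 after the eigen-expm round
  trip; generators with singular eigenbases fall back to `expm`.
- Zero-length branches give exact identity transitions; equal-age
  parent–child pairs are tolerated to 1e-9 years.
- A constant trace has undefined ESS (NaN + warning); a zero-variance
  root-age sample makes the t test raise; all-tied paired comparisons
  return p = 1 with a warning.
- HPD intervals require n ≥ 20; degenerate point masses give zero-width
  intervals.
- The harmonic-mean estimator is retained for comparability but the
  path-sampling estimator is the default recommendation.
- MCMC configs count burn-in in *samples* (not generations), matching
  the convention "50M generations, sampled every 5000, burn-in 1000
  samples → 9000 retained".
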