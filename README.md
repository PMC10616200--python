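# kdphylo

Bayesian phylogenetic dating, discrete phylogeography and demographic
reconstruction for lexical cognate data — the analysis chain used to ask
*when* a language family began to diversify, *where* it dispersed from,
and how its speaker population grew, built here for the Kra-Dai family
(five branches: Kra, Hlai, Ong-Be, Kam-Sui, Tai; five geographic areas:
Guizhou, Yunnan, the Guangxi–Guangdong coast, Hainan, and Mainland
Southeast Asia) but parameterized for any comparable dataset.

It is aimed at quantitative historical linguists and statistical
phylogeneticists who want the whole chain — encoding, likelihoods,
samplers, summaries, diagnostics — as a scriptable, tested Python
library rather than a collection of GUI tools.

## The models

**Data.** Cognate judgments arrive as a language × concept table of
cognate-class labels. After a 70% coverage filter, each (concept, class)
pair becomes a binary presence/absence column with `?` for undocumented
concepts, plus one all-absent *ascertainment* column per concept: the
likelihood of every observed column is conditioned on non-absence,
because all-absent cognate classes can never be coded,

    log L(block) = sum_j log L_j  -  n_obs * log(1 - L_0),

with `L_0` the probability of the all-absent pattern.

**Dating.** Characters evolve along a clock-scaled time tree under a
binary CTMC (optionally with Γ rate heterogeneity) or a binary covarion
with hidden ON/OFF switching at rate *s*. The tree prior is the
constant-rate birth–death process with extant-sampling probability ρ
(hyperpriors λ, μ ~ Exp(0.01), ρ ~ Beta(100, 19)); clocks are strict or
relaxed-lognormal; calibrations are soft densities on MRCA ages. A
Metropolis–Hastings sampler over node ages, topology, clock rate and the
tree-prior parameters yields the posterior; model combinations are
compared by harmonic-mean and path-sampling marginal likelihoods.

**Phylogeography.** Tip areas evolve under a 5-state CTMC whose 20
ordered transition rates are partitioned by reversible-jump MCMC into
shared rate classes including a zero class. Support for a restriction
pattern (e.g. "no transitions between non-adjacent areas") is a
visit-count Bayes factor: how often the chain's zero class covers the
pattern, relative to the prior expectation.

**Demography.** A coalescent Bayesian skyline under HKY+Γ with a fixed
strict clock (1.691e-8 subs/site/year by default) reconstructs
piecewise-constant Ne(t) with credible bands from a nucleotide
alignment.

**Diagnostics.** Quartet δ-scores and Q-residuals measure departure from
tree-likeness of the lexical distance matrix; a four-point borrowing
analysis quantifies how much of one language's lexicon aligns with a
geographically attractive group instead of its own subgroup.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Simulate a small family with a known history, encode it, and date it:

```python
import numpy as np
from kdphylo import (SimulationSpec, simulate_bd_tree,
                     simulate_cognate_matrix, DatingModel, ClockModel,
                     MCMCConfig, hpd_interval)
from kdphylo.simulate import streams

spec = SimulationSpec(seed=3, n_tips=20, n_items=50, root_age=4000.0)
rng_tree, rng_cog = streams(3, 2)
tree = simulate_bd_tree(spec, rng_tree)              # truth: root 4000 BP
matrix, truth = simulate_cognate_matrix(tree, spec, rng_cog)

model = DatingModel(matrix, spec.cognate_model,
                    clock=ClockModel("strict", spec.cognate_clock_rate))
res = model.fit(MCMCConfig(generations=50_000, sample_every=100,
                           burnin_samples=100, seed=3),
                init_tree=tree, fix_clock_rate=True,
                sample_covarion_switch=False)
lo, hi = hpd_interval(res.root_ages)
print(f"posterior mean root age {res.root_ages.mean():.0f} BP, "
      f"95% HPD [{lo:.0f}, {hi:.0f}]")
```

Output from this exact script:

```
posterior mean root age 4866 BP, 95% HPD [2826, 7153]
```

The generating root age (4000 BP) sits inside the 95% highest-posterior-
density interval; the interval is wide because 20 languages and 50
concepts carry limited signal. `res.summary()` tabulates every sampled
parameter with posterior mean, SD, HPD bounds and effective sample size,
and `res.mcc_tree()` returns the annotated maximum-clade-credibility
tree.

The same pattern runs the other stages: `DiscreteGeographyModel(trees,
tip_areas).fit(cfg)` for dispersal (`.root_area_posterior()`,
`.model_visit_bf(...)`), and `SkylineModel(alignment).fit(cfg)` for
Ne(t) (`.trajectory()`, `fold_change`). A thin CLI wraps each stage:
`kdp encode`, `kdp date`, `kdp summarize`, `kdp tempo`, `kdp geo`,
`kdp skyline`, `kdp reticulation`, `kdp simulate`.

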