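# nodecount

Bayesian phylogenetic Poisson modelling of how speciation events accumulate
through time across a time-scaled phylogeny — built for detecting
diversification slowdowns and downturns in fossil clades such as the major
dinosaur groups, where tip dates come from first/last appearance dates (FAD/
LAD) in the fossil record.

## The model

For each tip *i* of a time-scaled tree, the response is **N_Nodes**: the
number of internal nodes on the path from the root to the tip, root
included (so the minimum is 1).  Each node is a recorded speciation event,
and N_Nodes is regressed on the elapsed time from root to tip:

    N_Nodes_i ~ Poisson(exp(eta_i))
    eta_i = beta0 + f(Time_i) + gamma' z_i + u_i + e_i

with three candidate temporal forms

* **time-linear** (null): `f(Time) = beta1 * Time` — steady accumulation;
* **time-square-root**: `f(Time) = beta1 * sqrt(Time)` — rapid early
  accumulation slowing towards an asymptote;
* **time-quadratic**: `f(Time) = beta1 * Time + beta2 * Time^2` — a slowdown
  that may turn into an outright downturn (`beta2 < 0`).

`u ~ N(0, sigma2_phylo * A)` is a phylogenetic random effect (`A` = shared
root-to-node path lengths between tips, rescaled by the maximum tip depth),
`e_i ~ N(0, sigma2_resid)` is additive overdispersion, and `z_i` holds
covariates such as the log fossil-occurrence count (a sampling proxy).  In
the **group-wise** parameterization every clade group (e.g. Ceratopsidae,
Hadrosauriformes, other Ornithischia, Sauropodomorpha, Theropoda) gets its
own intercept and temporal coefficients inside one model; groups can be
restricted to the plain Time effect (the default for Ceratopsidae and
Hadrosauriformes).  The intercept is estimated by default — absorbing root-
age uncertainty — or can be fixed on the log-link scale (fixing it at 0
makes the expected count exp(0) = 1 at Time 0, the root).

Models are fitted by MCMC (Metropolis-within-Gibbs with conjugate updates
for coefficients, random effects and variances) and compared by **DIC**:
the lowest-DIC model is selected only when it beats the runner-up by at
least 4 units; anything closer is reported as ambiguous.  Non-significant
covariates (pMCMC >= 0.05) can be removed by backward elimination — temporal
terms are never eliminated; only DIC arbitrates between temporal forms.

A birth–death simulator with time-varying speciation rate (exact thinning,
no discretisation) generates clade-structured trees, jittered FAD/LAD
ranges and occurrence counts, so the entire pipeline is testable without
any external data.

## Worked example

```python
from nodecount import (ModelSpec, ChainSettings, fit, phylo_covariance,
                       build_response_table, simulate_tree, compare)
from nodecount.selection import comparison_report
from nodecount.synthetic_data import downturn_study_config

sim = simulate_tree(downturn_study_config(seed=8))   # 614 tips, 3 groups
table = build_response_table(sim.tree, sim.annotations)
cov = phylo_covariance(sim.tree)
chain = ChainSettings(iterations=6000, burn_in=1500, thin=5)
fits = {form: fit(table, ModelSpec(form, grouping="group_wise",
                                   group_restrictions={}),
                  cov, settings=chain, seed=1)
        for form in ("linear", "sqrt", "quadratic")}
print(comparison_report(compare(fits)))
```

prints

```
model comparison by DIC (threshold delta >= 4)
 * quadratic: DIC=3000.97 pD=67.46 deltaDIC=0.00
   sqrt: DIC=3028.78 pD=66.15 deltaDIC=27.81
   linear: DIC=3041.04 pD=69.68 deltaDIC=40.07
selected: quadratic
```

The tree was simulated with a strong quadratic downturn in the log
speciation rate, and the time-quadratic model wins by 27.8 DIC units over
the square-root model — far beyond the 4-unit selection threshold — while
the linear null is firmly rejected.  `summarize(fits["quadratic"])` shows
the fitted downturn, e.g. for group G1 a positive Time effect (posterior
mean 0.036, pMCMC 0.002) with a significantly negative Time² term.

The same analysis runs from the shell over many trees: `nodecount simulate`
writes a synthetic study bundle, and `nodecount run --config run.yaml`
time-scales every topology (shortest = tips at FAD, longest = tips at LAD),
extracts responses, fits the configured model set, and writes a fit
manifest, per-tree comparisons and an aggregate ΔDIC report
(`nodecount report`).

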