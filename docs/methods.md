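# Methods

## Model

The unit of observation is a tip of a rooted, time-scaled phylogeny.  The
response `N_Nodes` is the number of internal nodes on the root-to-tip path,
root included.  Counting the root makes the minimum response 1 and gives the
fixed-intercept-at-0 variant a coherent meaning: on the log link,
`E[N_Nodes | Time = 0] = exp(0) = 1`.  A polytomy contributes a single node
(one observed event) — branching order is irrelevant to the count, so
polytomies are accepted without random resolution; this undercounts events
relative to an unknown fully-resolved history, a documented limitation.

The regression is a Poisson generalized linear mixed model on the log link:

    N_Nodes_i ~ Poisson(exp(eta_i))
    eta_i = offset + x_i' beta + u_i + e_i
    u ~ Normal(0, sigma2_phylo * A),   e_i ~ Normal(0, sigma2_resid)

* `x_i` contains, per clade group or shared: an intercept (unless fixed, in
  which case its link-scale value enters the offset), the temporal terms of
  the candidate form (Time; sqrt(Time); Time + Time^2), and covariates such
  as `log N_Occ`.  Under the group-wise parameterization the intercept and
  temporal columns are block-structured: nonzero only for the tips of their
  own group.  Group restrictions cap a group's temporal form (downgrade
  only); the default restricts Ceratopsidae and Hadrosauriformes to the
  plain Time effect.
* `A` is the Brownian shared-path matrix: entry (i, j) is the root-to-MRCA
  path length of tips i and j, the diagonal the root-to-tip path length.  It
  is rescaled by its maximum diagonal entry so `sigma2_phylo` is comparable
  across alternative datings of the same topology (shortest vs longest
  trees); the raw matrix is kept for inspection.  On a non-ultrametric
  (fossil) tree the rescaled diagonal is <= 1, equal to 1 only for the
  deepest tips.
* `e` is additive per-observation overdispersion on the link scale
  (log-normal-Poisson): node counts are over-dispersed relative to a pure
  Poisson, and the variance component also carries the DIC's effective
  parameters for the latent layer.
* One `sigma2_phylo` is shared across groups; per-group phylogenetic
  variances are deliberately not implemented.

Time is measured forward from the root (Myr); ages are Ma before present
with `tip age = root_age − root-to-tip path length`, one convention asserted
everywhere.  Measuring time from the root rather than as absolute age is an
affine shift of the predictor; the fitted temporal shape is unaffected
whenever an intercept is estimated, and the fixed-intercept variant is only
meaningful with root-anchored time.

## Priors and sampler

Priors: coefficients `Normal(0, 1e8)` on the link scale; both variance
components inverse-gamma with shape = rate = 0.001 (configurable via
`ChainSettings`).  Either variance can instead be pinned to a constant, e.g.
`fix_phylo_variance=1e-8` switches the phylogenetic effect off for oracle
comparisons against an independent-observation GLM.

Sampling is Metropolis-within-Gibbs with the latent linear predictor `eta`
as the interface between the Poisson likelihood and the Gaussian hierarchy:

1. `eta_i` | rest: the full conditionals are independent across tips, so all
   n sites are updated at once by random-walk Metropolis with per-site step
   sizes adapted towards 44% acceptance during burn-in and frozen after.
2. `sigma2_resid` | residuals: conjugate inverse-gamma.
3. `u` | rest: conjugate Gaussian, sampled in the eigenbasis of `A`
   (decomposed once per fit; eigenvalues floored at 1e-10, and a matrix with
   an eigenvalue below −1e-8 is rejected as non-PSD).
4. `sigma2_phylo` | u: conjugate inverse-gamma.
5. `beta` | rest: conjugate Gaussian regression of `eta − u − offset` on X.
6. A joint translation move `(beta, eta) -> (beta + d, eta + X d)` with a
   Metropolis accept.  This move leaves the overdispersion residuals
   invariant and lets the coefficients feel the Poisson likelihood directly;
   without it the chain mixes very slowly whenever `sigma2_resid` is small
   (the usual variance funnel).  The proposal covariance is the inverse
   Poisson curvature at the initial state, with a scalar scale adapted
   towards 25% acceptance during burn-in.

Initialisation: `eta = log(y + 0.5)`, `beta` by least squares, `u = 0`,
variances at 0.1.  Chains are fully reproducible from a single integer seed
(`numpy.random.default_rng`); identical seeds give bitwise-identical traces.
Default chain settings (110,000 iterations, 10,000 burn-in, thinning 100)
are sized for production use; the tests and the acceptance script use
1,500–8,000 iterations, which give a few hundred effective samples per
coefficient on the synthetic benchmarks (split-chain R-hat and ESS are
computed for every fit via arviz and stored on the fit object).

A non-finite deviance at any retained sample aborts the fit with the
iteration number — a divergent chain is an error, never silently kept.

## DIC and model selection

`DIC = mean(D) + pD`, `pD = mean(D) − D(eta_bar)`, where `D` is the Poisson
deviance conditioned on the latent linear predictor and `eta_bar` its
posterior mean — the latent-focused convention of the GLMM family this
package follows; a marginal DIC is out of scope.  At least 10 retained
samples are required.

The selection rule: the lowest-DIC candidate is selected only when the
runner-up is at least 4 DIC units worse (the threshold is applied as >= 4;
the boundary case counts as selected).  Otherwise the comparison is reported
as "ambiguous", never silently resolved; the tie-break note names the
simplest candidate within 4 units (fewest estimated columns, then label
order).  Comparisons refuse to mix fits made on different response tables
(checked by a content hash).

Backward elimination applies to covariates only: per refit, the covariate
with the largest pMCMC >= 0.05 is dropped, until all survivors are
significant or none remain.  Temporal terms and intercepts are never
candidates — temporal forms compete only through DIC.  `pMCMC` is twice the
smaller posterior tail probability relative to zero, floored at
2/(number of samples); 95% intervals are highest-posterior-density
intervals.

## Time-scaling of topologies

Tip dates: mode `shortest` places every tip at its FAD, mode `longest` at
its LAD.  Internal nodes are dated the same way in both modes: a node's age
is `min_branch` (default 1 Myr) older than the oldest of its children's
ages and the FADs of all its descendant tips.  Anchoring nodes on descendant
FADs in both modes expresses that a clade is at least as old as its oldest
fossil; it also makes internal node ages identical across the two modes, so
the longest tree dominates the shortest in total length tip by tip — the
property that makes the shortest/longest pair a genuine bracket.  The
alternative convention (nodes floating down to the LADs in longest mode)
can make the "longest" tree shorter than the "shortest" one whenever range
widths vary across tips, which is why it was rejected.  Every branch of a
rescaled tree is at least `min_branch` long by construction.  Re-running the
procedure on its own output with the same ranges is a no-op.

Only the two range extremes (plus user-supplied fixed dates) are supported;
stochastic tip-date sampling is out of scope.

## Synthetic data generator

Each clade group runs an independent birth–death process whose per-lineage
speciation rate is `lambda(t) = exp(b0 + b1 t + b2 t^2)` (or the sqrt/linear
variants) with `t` in Myr since the root, and constant extinction rate
`mu`.  Waiting times are drawn by Ogata-style thinning against a per-window
(5 Myr) rate bound computed from the log-rate's monotone pieces and vertex —
exact for the time-varying rate, no discretisation.  Extinct lineages are
retained as fossil tips dated at their extinction time; lineages alive at
the horizon become tips at the horizon.  Groups hang off a pectinate
backbone at their stem origin times (backbone nodes count towards N_Nodes).
Tips get `FAD = age + U(0, jitter)` and `LAD = age − U(0, jitter)` clipped
to [0, root_age], and `n_occ = 1 + Poisson(occurrence_rate × terminal
branch duration)`, so occurrence counts correlate with lineage duration and
the response module's `n_occ >= 1` precondition always holds.

`min_group_tips` conditions each group's realisation on leaving at least
that many tips, by resampling the group's process.  This reflects
ascertainment — named clades are studied because they radiated — and is the
standard conditioning used by birth–death tree simulators.  Without it, any
rate curve that starts low (every strong-downturn curve does) loses most
group stems to early extinction and the tree degenerates to one dominant
group.

### Canonical scenarios

`downturn_study_config()`: three unrestricted groups with stem origins 0,
10, 20 Myr, `log lambda(t) = −5.3 + 0.18 t − 0.00225 t²` (vertex 40 Myr; the
rate collapses well before the 150 Myr horizon), extinction 0.06 per
lineage-Myr, each group conditioned on >= 25 tips.  These values were chosen
so that a lineage alive over the whole horizon expects ~7 speciation events
(node counts of the order seen in large fossil phylogenies) and a tree has
roughly 200–700 tips.  `constant_rate_config()` is the matching null:
`lambda = exp(−3.5)` constant, extinction 0.03, ~100–150 tips.

What the generator does *not* emulate: fossilized-birth–death sampling (all
extinct lineages are recovered, none are missed), heterogeneity of rates
across lineages within a group, correlated FAD/LAD errors, and real
covariates (sea level, competition) — covariate support in the regression is
generic.  Passing tests therefore show that the pipeline recovers the
generating regime under complete, honestly-dated sampling; they do not by
themselves establish robustness to the incomplete sampling of real fossil
data (the log-occurrence covariate is the model's handle on that).

## Orchestration

A study run is `trees × scalings × models`; per-fit seeds are
`sha256(master_seed, tree id, scaling, model) mod 2^31`, making runs
reproducible and order-independent.  A failed fit is recorded in the
manifest (`status=failed`) and the run continues; the CLI exits 1 on
partial failure and 2 on invalid configuration.  Reports (pairwise ΔDIC
min/median/max per scaling, selection counts) are pure functions of the
manifest and comparison files.

## Problem sizes used in the tests

The statistical acceptance tests run at sizes chosen to keep the whole
suite fast while leaving the checked properties sharp: oracle agreement at
n = 300 tips; parameter recovery at n = 250 with 8 replicates per temporal
form (pooled HPD coverage across 56 intervals); model selection on 10
downturn and 10 constant-rate trees (~200–700 tips each); covariate
elimination at n = 150 with 20 replicates per case; the node-count
combinatorial identity on 1,000 random topologies; and the 100-tree ×
2-scaling × 3-model manifest identity with a dry-run fit stub.  The
acceptance script fits 20 models on 10 simulated trees (6,000-iteration
chains) in under a minute.
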