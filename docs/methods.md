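# Methods

## The model

A quantitative phenotype `Y` (here: plant biomass) is assumed proportional
to the flux of a designated target reaction in a metabolic network of `K`
metabolites and `J` reactions.  For genotype `i` with stoichiometry matrix
`M_i` (signed coefficients, producers positive), steady state means
`M_i v_i = 0`.  The joint model treats the fluxes of **all** genotypes as
unknowns and encodes the steady-state requirement as a soft likelihood
term rather than a hard constraint:

    Y_i           = a + b * V_{i,J} + e_i,            e_i  ~ N(0, sigma2_e)
    0             = M_{i,k} v_i' + eps_{ik},          eps_{ik} ~ N(0, sigma2_eps)

    V_{,j} ~ N(U_{,j}, I sigma2_Vj)                   (reversible reactions)
    V_{,j} ~ TruncN_0(U_{,j}, I sigma2_Vj)            (irreversible reactions)
    U_{,j} ~ N(1 mu_j, G sigma2_Uj)

where `G` is the VanRaden genomic relationship matrix.  The kinship
structure of `U` is what lets the model predict fluxes — and hence the
phenotype — for genotypes whose `Y` is unobserved: those genotypes still
contribute constraint terms, and their `U` is coupled to phenotyped
relatives through `G`.  Hyperpriors: half-Cauchy HC(0, 0.1) on
`sigma2_e`; HC(0, S_eps) on `sigma2_eps` with `S_eps ~ Gamma(0.1, 1)`;
HC(0, 10) on `a`, `b` and each `sigma2_Vj'`; HC(0, 10000) on each
`sigma2_Uj'`.  `a` and `b` are positive (half-Cauchy support), which
matches the constructive relation between biomass flux and phenotype.

### Standardization across reactions

Flux locations and scales differ by orders of magnitude between
reactions.  Each reaction is standardized using rough estimates
`(mu~_j, sigma2~_Uj, sigma2~_Vj)` obtained from a per-reaction
single-kernel REML fit to training fluxes:

    delta_j = sqrt(sigma2~_Uj + sigma2~_Vj)
    V''_{,j} = V_{,j} / delta_j + alpha_j,   alpha_j = 10 - mu~_j / delta_j

so every reaction's prior location lands on 10.  `delta` on the
standard-deviation scale is the dimensionally coherent reading (fluxes are
divided by `delta`, variances by `delta^2`); a `literal` switch uses the
plain variance sum instead.  Inference runs entirely on `V''` and
`U' = U/delta`; the truncation bound 0 maps to `alpha_j`.

### The likelihood weight

The observation block has `N` terms and the constraint block `N*K`; added
naively the constraints swamp the phenotypes.  A weight `W in (0, 1]`
multiplies the constraint log-likelihood:

    L = -(N/2) log sigma2_e - (1/2 sigma2_e) sum_i (Y_i - a' - b' V''_{i,J})^2
        + W * [ -(NK/2) log sigma2_eps - (1/2 sigma2_eps) sum_{ik} r_{ik}^2 ]

with `r_{ik}` the standardized balance residual.  The observation sum runs
over training genotypes only; the constraint sum over all genotypes.  `W`
is compared over the grid {0.16, 0.32, 0.48, 0.64, 0.80, 0.96} by
cross-validation.  In simulation-fitting mode a fixed pre-drawn jitter
`psi_{ik} ~ N(0, 1e-4)` is added to the constraint left-hand side; it
keeps `sigma2_eps` from collapsing against exactly balanced data.

## Inference

Posteriors are sampled with an in-package No-U-Turn sampler (slice-variant
tree building, dual-averaging step size, diagonal mass matrix adapted in
doubling windows Stan-style) over an unconstrained parameterization:
logs of all positive scalars, `log(V'' - alpha)` for truncated
coordinates (truncation normalizer included in the density), and a
**non-centered** `U' = m + sqrt(sigma2_U') L xi` with `L L' = G`, which
removes both the kinship correlation and the genetic-variance funnel from
the sampling geometry.  Gradients are analytic and verified against
finite differences; the joint density is verified against an independent
loop-and-fsum implementation to 1e-10 relative.

Two further choices matter in practice, both aimed at the strong ridge
the constraint term creates once `sigma2_eps` is small:

* the chain starts with `sigma2_eps = 1` (soft constraints) and anneals
  onto the steady-state manifold as `sigma2_eps` contracts during warmup;
* fluxes initialize on each genotype's own balance manifold — training
  genotypes at their QP-estimated fluxes, held-out genotypes at the
  balanced projection of the rough locations (stoichiometry only, no
  phenotype information).

Defaults: 5000 iterations / 4000 warmup / thinning 1 / one chain, target
acceptance 0.9.  The posterior is multimodal and single short chains
frequently show split-R-hat above 1.1; `convergence_report` flags this
(threshold 1.1) but does not fail — method comparisons are robust to it,
point-prediction accuracy being much less sensitive than full posterior
summaries.  The benchmark harness caps tree depth at 6 to bound runtime
per leapfrog budget; the library default is 10.

## Rough estimates and GBLUP

`reml_single_kernel` fits `y = 1 mu + u + e`, `u ~ N(0, K sigma2_u)` by
restricted maximum likelihood via the spectral decomposition of `K`: the
profile criterion is scanned over the variance ratio on a 65-point log
grid spanning 1e-8..1e8 and refined by bounded 1-D optimization.  A
variance floor of 1e-8 times var(y) avoids boundary pathologies; BLUPs
are computed from the floored components so the returned pieces stay
mutually consistent.  Per-reaction fits that fail (constant fluxes) fall
back to the sample mean and an even split of the floored sample variance
— the standardization stage only needs rough magnitudes.

## The predict-then-project baseline

Three stages.  (i) For each training genotype, minimize
`sum_j (v_j / v_ref_j - 1)^2` subject to `M_i v = 0`, nonnegativity on
irreversible reactions and the hard ratio `v_J = v_ref_J * Y_i / Y_ref`
anchored at the reference genotype (the training objective is not
published; the same relative-deviation form as the projection stage is
used for symmetry).  (ii) Per-reaction GBLUP predicts test-genotype
fluxes.  (iii) Each predicted flux vector is projected back onto the
steady-state polytope, minimizing `sum_j (v_j/u_j - 1)^2`; the projected
target flux is the phenotype prediction.  Optional physiological box
constraints (`0.94 v_oxg <= v_car <= 3.81 v_oxg`,
`0.79 v_suc <= v_sta <= 3.37 v_suc`) default to off.

All programs eliminate the equality constraints through a nullspace
basis, so balance holds to machine precision; when the unconstrained
minimizer violates an inequality the reduced problem is solved with
`trust-constr` (analytic gradient and Hessian, feasibility tolerance
1e-8).  Anchor entries below 1e-6 in magnitude switch their term from
relative to absolute deviation scaled by the median anchor magnitude.
Training genotypes whose program is infeasible are skipped with a
warning; test-genotype failures yield missing predictions.

## The synthetic-data generator

The generator reproduces the statistical structure the methods rely on,
at configurable size:

* **SNPs / kinship** — markers with allele frequencies uniform on
  [maf_min, 0.5]; genotypes belong to clusters (default ~6 genotypes per
  cluster) sharing a founder haplotype pair, each marker redrawn from the
  population with probability `cluster_mix = 0.2`.  An unstructured panel
  would give a near-identity kinship matrix under which no genomic
  method has signal; the cluster design emulates the strong relatedness
  of a real diversity panel.
* **Network** — sparse signed stoichiometry with target medians of 4
  metabolites per reaction and 2 reactions per metabolite (a few hub
  metabolites absorb the imbalance, as cofactors do in real networks);
  every metabolite touches at least two reactions; the last reaction is
  the irreversible biomass drain and consumes every metabolite it
  touches.
* **Fluxes** — per reaction, genetic values `U_{,j} ~ N(1 mu_j, G s2_Uj)`
  (redrawn whole if an irreversible reaction draws a negative entry,
  preserving the kinship correlation) and fluxes
  `V_{ij} ~ N(U_{ij}, s2_Vj)` truncated at zero elementwise for
  irreversible reactions.  Exact balance is then imposed per genotype by
  overriding, for each metabolite, the coefficient of its **last**
  nonzero reaction: `M_{i,last,k} = -(sum of the other terms)/V_{i,last}`
  (genotypes with `|V_{i,last}| < 1e-6` are redrawn, 100 retries).
  Metabolites whose last reaction is the biomass column thereby acquire
  genotype-specific biomass coefficients, emulating the real panel's
  metabolite-derived biomass equations.
* **Parameters** — `mu_j` log-uniform on [1, 100], coefficient of
  variation log-uniform on [0.05, 0.5] (variances spanning two orders of
  magnitude — the heterogeneity the standardization step exists for),
  heritability uniform on [0.5, 0.9].
* **Phenotypes** — `Y = V_{,J} + e` with `var(e) = 0.25 var(V_{,J})`.

What the generator does **not** emulate: linkage disequilibrium and
realistic allele-frequency spectra; correlations among reactions beyond
those induced by balance; measurement structure of metabolite data; any
particular real network topology.  Passing tests therefore demonstrate
the machinery under the model's own assumptions, not performance on real
panels.

## Evaluation

3-fold cross-validation (fold sizes within 1), Pearson `R` between
observed and predicted phenotype within each fold; folds partition all
genotypes and are seeded.  The reference genotype's fluxes and phenotype
are treated as known side information in every fold (its biomass
stoichiometry and fluxes come from curation, not from the trait being
predicted); per-genotype stoichiometry overrides are likewise available
for test genotypes, the CV2-style information the original design
entails.  Methods are compared by two-sided Mann-Whitney-Wilcoxon tests
on pooled fold-level `R` (exact p-values up to group size 20, tie-corrected
normal approximation beyond), Bonferroni-corrected over all pairs, with
figure-style shared letters (two methods share a letter iff their
adjusted p >= 0.05).

## Problem sizes in the shipped tests

The full-scale study (67 genotypes, 350 x 336 network, 5000-iteration
chains, 20 CV repeats) is far beyond a desk run, so the test suite and
the acceptance script exercise the same pipeline at reduced size, chosen
as the smallest panels at which the methods are clearly distinguishable:
benchmark datasets of N = 42 genotypes, K = 10 metabolites, J = 12
reactions, 3-fold CV with 1000/500 NUTS iterations and tree depth capped
at 6 (5 replicate datasets in the test suite, 2 in the acceptance
script).  Within a fold, the weight grid is fit with a common chain seed
(common random numbers), so the accuracy-versus-W profile reflects the
weight's effect rather than chain-to-chain noise.  Oracle tests
(likelihood, REML, QP) run at N <= 30 in seconds.

## Known limitations

* The posterior is multimodal (the flux polytope admits many balanced
  solutions); single chains can land in different modes, and split-R-hat
  frequently exceeds 1.1 at the shipped chain lengths.  Predictions are
  posterior means within the found mode.  Per-draw log-posterior values
  are stored with the samples so that, when several chains are run, a
  chain stranded in a far-lower-probability mode can be identified and
  discarded (the acceptance script does this for its constraint-adherence
  summary).
* The accuracy-versus-W profile on exactly balanced synthetic data is
  shallow at the upper end of the grid; with short chains the observed
  peak can sit at the grid edge rather than strictly inside.
* The weight `W` is selected by grid search, not inferred.
* Reaction-reaction genetic covariances are not modeled (each reaction
  has its own independent `U_{,j}`).
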