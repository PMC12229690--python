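# Methods

## The prediction problem

Given continuous traits measured on the tips of a phylogeny, we want the
value of a dependent trait *Y* for taxa where only the predictor(s) *X* and
the taxon's position in the tree are known. Three estimators are compared
throughout the package:

1. **OLS predictive equation** — fit *Y = Xβ + ε* by ordinary least squares
   on the observed taxa and plug the target's predictors into the fitted
   coefficients. Shared ancestry is ignored both in fitting and prediction.
2. **PGLS predictive equation** — fit by generalized least squares with
   error covariance proportional to the phylogenetic variance–covariance
   matrix *V* (Pagel's λ estimated by maximum likelihood), then use only the
   coefficients. The fit respects phylogeny; the prediction still treats the
   target as phylogenetically average (implicitly attached at the root).
3. **Phylogenetically informed prediction** — the PGLS plug-in point plus
   ε<sub>u</sub> = V<sub>h</sub>ᵀV⁻¹(Y − Xβ̂), the GLS conditional
   expectation (BLUP) of the target's residual given the observed residuals,
   where V<sub>h</sub> holds the covariances between the target and the
   observed taxa.

## Model and estimation details

* **V** is built by summing branch lengths from the root to each pair's most
  recent common ancestor; the diagonal holds root-to-tip paths. A root edge,
  if present in the input, is ignored: it adds a constant to every entry and
  is not identifiable alongside an intercept.
* **Pagel's λ** multiplies the off-diagonal of *V*; it is estimated by
  maximising the Gaussian profile log-likelihood (β and σ² concentrated out,
  log|V| included) on [0, 1] by bounded scalar search (tolerance 1e−8) with
  explicit endpoint checks at 0 and 1. Maximum likelihood, not REML, is used
  throughout. All GLS solves go through a Cholesky factor of *V*; the
  explicit inverse appears only in test oracles.
* **Reported σ̂²** uses the unbiased n − p denominator; the likelihood uses
  the ML denominator n. R² is computed against the intercept-only GLS model
  under the same λ-transformed *V*; adjusted R² applies the usual
  (n−1)/(n−p) correction.
* **ε<sub>u</sub>**: the BLUP form above is the standard GLS conditional
  expectation and the construction Garland & Ives describe. (A commonly
  reprinted variant with an extra outer inverse is dimensionally inconsistent
  for more than one observed taxon and reduces to the same expression in the
  scalar case.)
* **Prediction variance** (Garland & Ives):
  σ̂²(v<sub>hh</sub> − V<sub>h</sub>ᵀV⁻¹V<sub>h</sub>) +
  σ̂² dᵀ(XᵀV⁻¹X)⁻¹d with d = x<sub>h</sub> − XᵀV⁻¹V<sub>h</sub> —
  conditional tree variance plus coefficient uncertainty propagated to the
  target. Intervals are point ± t<sub>1−α/2, n−p</sub>·√variance with
  α = 0.05 by default; a z-interval is available (`dist="z"`), the choice is
  immaterial beyond ~30 taxa.
* **λ and the target**: covariances between target and observed taxa are
  multiplied by λ̂; the target's self-variance v<sub>hh</sub> is left
  untransformed, consistent with λ acting on off-diagonal elements only.
  With λ̂ = 0 the informed prediction therefore collapses to the plug-in
  point.
* **"Generic" PGLS interval**: the informed interval evaluated at
  V<sub>h</sub> = 0 and v<sub>hh</sub> = mean root-to-tip path of the
  observed taxa — the uncertainty for a taxon of unknown position.
* **Tiny negative conditional variances** (within −1e−10, floating point)
  are clipped to 0; anything more negative raises.
* **Leave-one-out self-validation** fits the model once on the full data
  (coefficients and λ̂ frozen) and, per taxon, re-subsets the residual
  vector and *V* before computing the informed prediction — the phylogenetic
  weighting is adjusted, the regression is not refit. A full-refit variant
  is available (`refit=True` / `--loo-refit on`).

## The simulation benchmark

The generator emulates a comparative study in which traits evolve by
Brownian motion on birth–death trees:

* **Trees** grow by per-lineage exponential waiting times to speciation and
  extinction (a Bellman–Harris style branching process). In `taxa` mode the
  process runs until the target number of extant lineages exists and the
  tree is cut immediately before the next speciation; extinct lineages are
  kept as shallower tips. Under *symmetric* speciation both daughters draw
  fresh clocks; under *asymmetric* (budding) speciation the continuing
  daughter keeps the mother's extinction clock. With exponential waits the
  two modes coincide in distribution (memorylessness), so the distinction
  only matters for non-exponential families, which are left as a
  configuration hook. Numeric rates are exponential *rate* parameters
  (mean waiting time 1/rate).
* **Standardization.** Before trait simulation every tree is rescaled so its
  *total branch length* is 1. The phrase "tree length" is ambiguous
  (height vs. summed branch length); we resolved it by matching the
  benchmark's absolute error variances: with total-length standardization
  the pooled error variances under the reference conditions agree with the
  reference values to within a few percent, whereas height standardization
  inflates them ~24-fold (the *relative* results — fold improvements,
  orderings, proportions — are identical under either choice, since GLS is
  scale-invariant in *V*). Height standardization remains available
  (`standardize: height`).
* **Traits**: bivariate Brownian motion; each branch of length *b*
  contributes a mean-zero bivariate normal increment with covariance *R·b*,
  *R* = [[1, r], [r, 1]]. Defaults: unit rates, root state 0, correlations
  r ∈ {0.25, 0.5, 0.75}.
* **Missing-data schemes**: 10% of tips uniformly at random (ultrametric
  scenarios); all extinct tips (extinction scenarios); 20% of all tips
  (retain-20% scenario); 10 tips from the lower quartile of *Y* (biased
  scenarios; quartile by linear interpolation). The biased scheme's count
  (10 for n = 100) mirrors the unbiased scenario.
* **Per replicate**: simulate tree → down-sample to the target total tip
  count where extinction produced more (uniformly over extant and extinct
  tips) → standardize → simulate traits (one dataset per r on the same
  tree) → withhold *Y* → fit OLS and ML-λ PGLS on observed taxa → predict
  each withheld taxon by all three methods. Replicate-level failures (whole
  tree extinct, too few observed taxa) are resampled under fresh child
  seeds and counted in the run metadata.
* **Summaries**: pooled sample variance (n − 1) and median of errors per
  method; fold performance = equation σ² / informed σ²; per-tree median of
  |equation error| − |informed error| with an intercept-only one-sample
  t-test and the proportion of trees with positive median; OLS regressions
  of per-tree median absolute error on Colless, Sackin and stemminess.
* **Shape metrics**: Colless sums |n_left − n_right| over internal nodes
  (strict binary; a generalized pairwise sum exists for polytomies),
  Sackin sums tip depths in internal-node counts, and stemminess averages,
  over non-root internal nodes, the stem edge's share of its subtree's total
  branch length (stem included) — branch length concentrated toward the
  root gives values near 1.

### Problem sizes

Package defaults follow the reference design (1000 trees per scenario,
n ∈ {50, 100, 250, 500}). The shipped acceptance script and the acceptance
test suite run 500 replicates per scenario (300 for the extinct-taxa
scenario), which holds the Monte-Carlo error of pooled variances to a few
percent while keeping a full run in minutes on one CPU; replicate counts
are a `--reps` flag away from the full design.

### What the simulations do and do not show

The generator matches the benchmark's stated conditions — exponential
birth–death topologies, exactly bivariate Brownian traits, homogeneous
rates, no measurement error, missingness schemes applied to a perfectly
known tree. Real comparative datasets violate most of these: traits may
evolve under selection (OU-like dynamics), rates vary across clades, trees
carry topological and dating error, and missingness is rarely as clean as
the schemes modelled. Passing benchmarks therefore demonstrates correctness
of the estimators and the expected ranking of methods *under the Brownian
model*, not performance guarantees for any particular empirical dataset.

## Case-study pipelines

`case_studies.run_case_study` drives the same fit → predict → validate
machinery from a YAML configuration: a Newick tree, a trait CSV, a model
formula (patsy syntax; treatment-coded factors with an explicit reference
level support group-specific slopes, i.e. phylogenetic ANCOVA), optional
log10 transforms, fossil grafting instructions in age-before-present units
(sister insertion along a stem branch, or addition to a polytomy at a clade's
basal node), an optional κ = 0 transform for trees without meaningful branch
lengths (κ = 0 maps every branch, including zero-length polytomy branches,
to length 1), and derived columns with adjustable parameters (e.g. brain
mass as a fraction of endocranial volume, applied only where the column is
not directly measured). Tests exercise this pipeline on synthetic data
built to the same structure; the published case-study tables and trees are
third-party supplementary material and are not redistributed here — drop
them under `data/case_studies/` with matching YAML configs to reproduce
those analyses.

## Numerical and design choices

* λ domain is [0, 1]; values above the maximum the tree structure permits
  are not considered.
* Down-sampling is uniform over *all* tips, which can reduce the extant
  count below the nominal target on high-extinction trees; that is the
  literal protocol and drives the intended scarcity of observed taxa in
  those scenarios.
* Multiple unknown taxa are each predicted from the observed taxa only;
  unknowns do not inform each other.
* Prediction from phylogeny alone is available as an intercept-only design
  (`y ~ 1`): the informed prediction then reduces to the BLUP of *Y* given
  the observed values and the tree.
* The deterministic balanced/pectinate constructors provide exact
  end-member topologies; the corresponding stochastic presets keep the
  published waiting-time settings but cannot guarantee the exact shapes.
* One root seed drives everything through spawned child seeds; replicate i
  is reproducible in isolation, and identical configs + seeds give
  bitwise-identical outputs.

## Known limitations

* Statistics of the extreme-extinction benchmark (speciation 1, extinction
  0.9) that depend on tree-level medians are sensitive to exactly how the
  simulator conditions on reaching the target number of extant taxa: most
  tips are extinct targets, a sizable fraction attach at the root relative
  to the few survivors (zero covariance, so the informed prediction ties
  the generic one exactly), and λ̂ estimated from ~10–20 survivors
  occasionally collapses to 0. Pooled error variances and fold ratios are
  robust to these details; per-tree median-difference proportions are not.

* Only exponential waiting-time families are implemented (the config schema
  records the family explicitly so others can be added).
* No OU or rate-heterogeneous trait simulation; no REML or Bayesian
  estimation; no joint prediction of several unknowns with
  cross-covariances.
* Colless in strict mode requires a binary topology.
* NEXUS/phyloXML input is not supported; Newick only.
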