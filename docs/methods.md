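# Methods

This note documents the models and numerical choices behind `csfnet`: what
each stage computes, the parameters that matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## The synthetic cohorts

`csfnet.simulate.generate_cohorts` produces a discovery cohort spanning
CU/MCI/AD, a cognitively unimpaired replication cohort, and a set of buffer
(no-sample) wells. Protein abundances follow a rank-1 latent factor model
on the log10 RFU scale: for protein *i* in module *m* and sample *s*,

    log10 RFU_is = baseline_i + sqrt(v_tot) * a_i * f_m(s) + nuisance_i(s) + eps_is

with one standard-normal factor `f_m` per module. The per-protein loadings
`a_i = clip(sqrt(r_m) (1 + 0.15 sqrt(1 − r_m) z_i))` create hub/periphery
structure while keeping the mean pairwise within-module correlation at the
configured target `r_m` (verified to ±0.1 at n ≥ 100); the loading spread
shrinks as `r_m → 1` so near-deterministic modules stay near-deterministic.
The noise split is calibrated against the *total* per-protein variance
`v_tot = noise_sd² + Σ β_c²`, which includes the expected nuisance variance,
so the correlation target holds on the generated (pre-adjustment) scale.

Key defaults and why:

- `noise_sd = 0.25` (log10 scale): protein SDs of ~0.2–0.3 dex, the typical
  spread of aptamer readouts after vendor normalization.
- `nuisance_effects = 0.0625` per covariate (age, sex, storage time, study
  origin), entering additively with per-protein standard-normal
  multipliers: nuisance variance ≈ 20% of total, enough that covariate
  adjustment is consequential but not dominant.
- Buffer wells read `N(2.0, 0.2)` per-protein baselines with 0.1 well
  noise on the log10 scale, ~1.5 dex below clinical baselines
  (`N(3.5, 0.3)`); "junk" proteins reuse the buffer distribution in
  clinical samples and are therefore exchangeable with buffer wells.
- Module correlation targets default to 0.6 — chosen for testability (the
  source data's within-module correlations are not public knowledge), in
  the middle of the 0.4–0.8 band that keeps module detection nontrivial but
  solvable at n = 54.
- `amyloid_status` is Bernoulli with logit `−0.85 + 1.84 f_m`: the
  intercept gives ~30% positivity among unimpaired participants and the
  slope makes the Bayes-optimal AUC of the true factor ≈ 0.85, the
  performance regime the classifier stage is designed to probe (computed by
  numerical integration of the logistic-Gaussian mixture).
- p-tau181 is stored as `60 · 10^(0.15 y)` pg/mL with `y = effect·f + N(0,1)`
  (positive, right-skewed, log-linear in the factor); cognitive composites
  are standardized linear phenotypes; APOE ε4/ε2 counts are multinomial
  with probabilities conditioned on amyloid status, mixing to roughly
  77/21/2% ε4 carriage overall.
- Non-preserved modules are regenerated in the replication cohort with
  independent per-protein noise of the same marginal variance, destroying
  co-expression while leaving single-protein distributions intact.

What the generator does **not** emulate: plate layout and batch structure,
hybridization spike-ins, vendor normalization factors, missingness,
non-Gaussian heavy-tailed measurement error, and correlated background
(non-module) proteins. Passing tests therefore demonstrate correctness of
the algorithms under a clean factor model, not robustness to every artifact
of real SomaScan data.

## QC

The buffer filter models each protein's buffer distribution as Gaussian
(mean/SD over wells) and computes two-sided tail p-values for each clinical
sample; BH correction runs across samples within the protein, and a sample
"falls within" buffer when its adjusted p ≥ α = 0.05. A protein is removed
when more than 25% of samples fall within. The Gaussian two-sided test is
the simplest defensible choice where no test is canonical; the orientation
of the FDR (across samples within protein) follows the per-protein reading
of the rule. Zero buffer variance falls back to an exact-equality test with
a warning.

Sample outliers: connectivity `k_s` = sum of inter-sample Pearson
correlations of protein profiles; samples with `|Z(k)| > 3` are removed in
a single pass (no iteration).

Adjustment residualizes each protein on the known covariates (categoricals
one-hot encoded, aliased columns dropped with a warning), then removes the
first five left singular vectors of the column-centered residual matrix.
Computing the SVD on the residuals rather than the raw matrix prevents the
hidden factors from re-absorbing modeled covariates. One property of the
simulation is worth stating plainly: with *k* rank-1 planted modules and no
unmodeled technical structure, the top *k* singular vectors of the
residuals *are* the module factors, so five-component removal would erase a
five-module network. The pipeline demo therefore runs the network path with
`n_svd = 0` — in the simulation all hidden nuisance is spanned by the known
covariates — while the `adjust` operation keeps `n_svd = 5` as its default
for data with real technical structure.

## Network construction

Biweight midcorrelation uses Tukey weights `w = (1 − u²)² 1(|u| < 1)` on
`u = (x − median)/(9 MAD)`; columns with zero MAD fall back to Pearson
weighting for their pairs, constant columns get correlation 0. Signed
adjacency `((1 + cor)/2)^β` at β = 12; the scale-free fit regresses log10
binned connectivity density (10 equal-count bins, density = relative count
/ bin width) on log10 mean connectivity and sign-corrects so only
decreasing laws score high. TOM is the standard shared-neighbour overlap
with unit diagonal.

Module detection is a dynamic hybrid cut of the average-linkage tree of
1 − TOM, implemented in `_treecut.py` in three stages: branch exploration
(gap criteria evaluated only at genuine split points, i.e. nodes whose two
children both reach the minimum size of 15 — accretion merges that glue
stragglers onto a growing branch are passed through), trimming (leaves that
joined a branch above its core scatter plus 70% of the core-to-cut span are
returned to grey; these are background objects attached just below the cut
height), and a PAM-like stage that assigns grey objects to the nearest
module only within the module's own admission radius and, by default, only
on the object's own dendrogram branch. `deep_split` (0–4) maps linearly to
the core-scatter ceiling (0.64–0.96 of the base-to-cut height range) and
inversely to the minimum gap. The implementation is validated by behaviour
— planted blocks recovered at ARI ≈ 1, size-10 blocks dissolved at minimum
size 15, i.i.d. noise left all-grey, nested sub-blocks resolved at
deepSplit 4 but absorbed at 0 — rather than by numerical equivalence to any
particular reference implementation.

Eigenproteins are unit-norm first principal component scores of the
standardized module block, sign-aligned to correlate non-negatively with
the module mean profile (so kME ranks are reproducible); kME is the Pearson
correlation of each protein with each eigenprotein.

The merge rule examines, for each module in ascending size order, the top
50% of members ranked by kME to their own module; if strictly more than 25%
of them have greater membership in another module, the module merges into
the plurality target (ties toward the larger module), with eigenproteins
and kME recomputed after every merge until a full pass is quiet. One
numerical choice matters here: the member's own-module kME is computed
against a *leave-one-out* eigenprotein. With the member included, its own
noise inflates own-module membership enough that even a single factor
artificially split in two fails to merge; excluding the member removes that
bias while leaving the exported kME matrix in its standard (all-member)
form.

## Preservation

Seven statistics per module — four density statistics computed in the test
cohort (mean intramodule correlation, mean adjacency, eigenprotein
proportion of variance, mean |kME|) and three connectivity statistics
comparing cohorts (correlations of intramodular connectivity, of kME, and
of the intramodule correlation entries). The null permutes module labels
across all shared proteins (including unassigned ones — restricting the
pool to module-labelled proteins is available as an option, but then
permuted modules consist entirely of other modules' proteins and inherit
their cross-cohort structure, which makes the null far stricter).
Z_density and Z_connectivity are within-category medians of the
per-statistic Zs, Z_summary their mean; medianRank is the median across
statistics of the module's observed-value rank. 200 permutations at seed 1
are the defaults and runs are bit-reproducible.

## Trait models, enrichment, classifier

Trait regressions z-score the outcome and the eigenprotein, keep covariates
on their native scale, and log10-transform p-tau181 and white matter
hypointensities wherever they appear. Education enters only cognitive
models and intracranial volume only volumetric ones. The BH family is the
set of modules within one (outcome, approach) pair, matching the
per-outcome reading of the heatmap. APOE allele counts are modeled as
numeric 0/1/2 outcomes by the same linear machinery.

Enrichment draws module-sized samples **with replacement** from the full
annotated universe (module not excluded), reports the z-score against the
bootstrap null and a two-sided add-one-smoothed empirical p, and flags
|z| > 1.645. A constant annotation returns z = 0 by convention.

The L1 logistic path uses a 100-point descending geometric λ grid from the
smallest all-zero λ, with λ_min/λ_max = 1e-4 when observations outnumber
features and 1e-2 otherwise (the glmnet convention); fits use liblinear
with features standardized internally and `intercept_scaling = 50` so the
intercept is effectively unpenalized; coefficients are returned on the
original scale. Cross-validation assigns observations to 10 folds by a
seeded permutation and minimizes mean binomial deviance. Under a global
null the deviance curve is nearly flat near λ_max, so the CV minimizer
selects a small nonempty support in roughly half of random datasets — the
same behaviour as the reference cross-validated path — which is why the
tests assert near-null rather than exactly-null selection.

Stability selection draws 50 seeded half-subsamples without replacement,
stratified by outcome. Per subsample, the first *q* features to enter the
descending λ path count as selected, with
`q = ceil(sqrt(0.5 (2θ − 1) p))` (θ = 0.65 the selection threshold) from
the per-family error bound at half an expected false selection — at
p = 100 features, q = 4. This is the convention of subsampling-based
stability selection; the alternative "ever nonzero on a fixed λ sub-grid"
rule is not used because spurious full-data correlations persist across
half-subsamples and stably select a dozen pure-noise features. The stable
set keeps features with selection probability strictly above 65% (≥ 33 of
50 subsamples).

Refits are unpenalized logistic models — stable proteins plus the APOE ε4
allele count, against an age/sex/ε4 baseline — trained on the training
split and evaluated on a disjoint test cohort by trapezoid AUC with a
DeLong 95% CI (variance from the structural components of the
Mann–Whitney statistic; the interval collapses to the point estimate under
perfect separation). If no feature passes the stability threshold the
pipeline falls back to the single highest-probability feature for the
refit, reported as such.

## Problem sizes

The test suite and the acceptance script run on simulated cohorts sized to
the study design they emulate: 54-sample network construction over 1,200
proteins (five modules of 30–100), 100-sample two-cohort preservation over
400 proteins with 200 permutations, 150-sample stability selection over
100 features with 50 subsamples, and 1,000-repetition enrichment
calibration with 2,000-draw bootstrap nulls. These sizes exercise every
code path at full statistical fidelity while keeping a complete run in the
low minutes on a single CPU.

## Known limitations

- The tree cut is behaviourally, not numerically, matched to the reference
  dynamic tree cut family; exact module boundaries on borderline branches
  can differ.
- The buffer filter's Gaussian tail model is a simplification; heavy-tailed
  buffer noise would need the pluggable test statistic replaced.
- Preservation Z magnitudes depend on the module-to-background ratio of the
  protein universe; in module-dense universes the permutation null absorbs
  real structure and Z_summary compresses toward zero.
- Stability selection with strongly correlated module proteins splits
  selection probability across interchangeable members; the stable set is
  then small or empty even when the module signal is strong, and the
  fallback single best feature carries the refit.
- DeLong intervals are asymptotic and degenerate under perfect separation.
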