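# csfnet

Signed weighted co-expression network analysis for aptamer-based (SomaScan)
cerebrospinal-fluid proteomics, built for studies that ask how CSF protein
modules relate to Alzheimer's disease biology: amyloid status, p-tau181,
cognition, and *APOE* genotype, across a discovery cohort spanning
CU/MCI/AD and an independent cognitively unimpaired replication cohort.

The package covers the full analysis chain as reusable, tested components:

1. **QC** — a buffer-well filter that drops proteins indistinguishable from
   the assay's no-sample background (per protein: two-sided Gaussian tail
   p-values of each clinical sample against the buffer distribution, BH FDR
   at 5%, protein removed when >25% of samples fall inside), standardized
   inter-sample-connectivity outlier removal (|Z| > 3), log10 transform, and
   residualization on age, sex, CSF storage time, study origin and the first
   five SVD components of the residual matrix.
2. **Differential abundance** — per-protein one-way ANOVA across diagnostic
   groups plus an AD-vs-CU Welch t-test with BH FDR; modules holding at
   least one significant protein are flagged disease-relevant.
3. **Network** — biweight midcorrelation, signed adjacency
   `a_ij = ((1 + cor_ij)/2)^β` with β = 12, topological overlap
   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, average-linkage
   clustering of 1 − TOM, a dynamic hybrid tree cut (minimum module size 15,
   deepSplit 0–4, dendrogram-respecting PAM stage), module eigenproteins
   (first principal component of the standardized module block), kME
   membership, and a kME-based merge rule (top 50% of members; merge when
   more than 25% have greater membership elsewhere).
4. **Preservation** — permutation Z statistics (Z_density, Z_connectivity,
   Z_summary = their mean, medianRank) over 200 label permutations with a
   fixed seed; modules with Z_summary > 10 are called preserved.
5. **Module–trait models** — Kruskal–Wallis for categorical outcomes and
   OLS with standardized betas for continuous ones, under three nested
   covariate regimes (demographics; + amyloid status; + p-tau181), BH FDR
   per outcome/approach family.
6. **Enrichment** — bootstrap z-scores of a module's mean −log10(p) (or
   mean annotation count) against 10,000 module-sized random draws from the
   assayed universe, flagged at |z| > 1.645.
7. **Classifier** — 10-fold cross-validated L1 logistic regression over a
   glmnet-style λ path, stability selection on 50 half-subsamples with a
   65% threshold, and unpenalized refits (stable proteins + APOE ε4 count
   vs an age/sex/ε4 baseline) evaluated by ROC/AUC with DeLong 95% CIs on a
   held-out cohort.

Because the CSF datasets such analyses run on are institutional, `csfnet`
ships a first-class synthetic-data generator (`csfnet.simulate`) that
emulates the study design — log-normal RFUs, planted correlated modules
with hub/periphery loading structure, buffer wells, junk proteins,
nuisance covariates, a replication cohort in which chosen modules are
scrambled, and phenotypes causally driven by module factors — so every
stage is testable end to end without any restricted data.

## Worked example

```python
import json
from csfnet import SimConfig, generate_cohorts, build_network, module_preservation
from csfnet.qc import adjust

cfg = SimConfig(n_proteins=400, n_samples_discovery=100, n_samples_replication=100,
                module_sizes=(50, 50), module_cors=(0.7, 0.7),
                preserved_flags=(True, False), n_junk_proteins=0,
                n_buffer_wells=6, seed=0)
disc, rep, buffer, samples, proteins, truth = generate_cohorts(cfg)

covars = ["age", "sex", "storage_time", "study_origin"]
d = adjust(disc, samples.loc[disc.sample_ids, covars], n_svd=0)
r = adjust(rep, samples.loc[rep.sample_ids, covars], n_svd=0)

partition = build_network(d)
print(partition.sizes().to_dict())
report = module_preservation(d, r, partition.labels, n_perm=200, seed=1)
print(report.summary.round(2))
```

prints

```
{1: 50, 2: 50}
   Z_density  Z_connectivity  Z_summary  medianRank  preserved
1      61.06            1.17      31.11           1       True
2      -1.37           -1.85      -1.61           2      False
```

Both planted 50-protein modules are recovered exactly in the discovery
cohort. In the replication cohort the first module (generated with the same
factor loadings) scores Z_summary ≈ 31 — far above the preservation
threshold of 10 — while the second module, whose co-expression was
deliberately destroyed, sits near zero and is correctly called
non-preserved.

The same flow is available from the shell via the `csfnet` console script
(`csfnet simulate`, `qc`, `diffabund`, `network`, `preserve`, `traits`,
`enrich`, `classify`, and `pipeline run` for the whole chain with a
manifest of seeds and content digests).

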