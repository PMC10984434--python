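"""Two-cohort SomaScan-like synthetic data with planted module structure.

The generator emulates the study design every downstream stage expects: a
discovery cohort spanning CU/MCI/AD, an independent cognitively-unimpaired
replication cohort, buffer (no-sample) wells defining each protein's
no-signal distribution, and a handful of "junk" proteins whose clinical
measurements are exchangeable with buffer noise.

Protein abundances follow a rank-1 latent factor model on the log10 RFU
scale: for protein *i* in module *m*,

    log10 RFU = baseline_i + loading_i * factor_m(sample) + nuisance(sample) + eps

with the loading/noise split chosen so the within-module Pearson correlation
equals the configured target.  Phenotypes (amyloid status, p-tau181,
cognitive composites, APOE allele counts) are causally driven by the module
factors named in ``phenotype_links``, so planted effects are recoverable by
the trait models and the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["SimConfig", "GroundTruth", "ConfigurationError", "generate_cohorts",
           "write_dataset", "PTAU_BASE", "PTAU_LOG_SCALE"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# p-tau181 is stored in pg/mL-like units: ptau = PTAU_BASE * 10**(PTAU_LOG_SCALE * y)
# where y = effect * factor + N(0,1) is the latent linear phenotype.
PTAU_BASE = 60.0
PTAU_LOG_SCALE = 0.15

# Clinical baseline and buffer-well location/scale on the log10 RFU scale.
_CLINICAL_BASE_MEAN, _CLINICAL_BASE_SD = 3.5, 0.3
_BUFFER_BASE_MEAN, _BUFFER_BASE_SD = 2.0, 0.2
_BUFFER_NOISE_SD = 0.1

# APOE e4 allele-count probabilities conditional on amyloid status; the
# mixture at ~30% positivity lands near the 77/21/2% overall split.
_E4_PROBS_NEG = (0.85, 0.14, 0.01)
_E4_PROBS_POS = (0.55, 0.38, 0.07)
_E2_PROBS_NEG = (0.88, 0.11, 0.01)
_E2_PROBS_POS = (0.93, 0.066, 0.004)


@dataclass
class SimConfig:
    """Configuration of the two-cohort simulation.

    ``phenotype_links`` maps a phenotype name to ``(module_index, effect)``
    where ``module_index`` refers to position in ``module_sizes`` and
    ``effect`` is the coefficient of the module factor in the phenotype's
    generating model (log-odds scale for ``amyloid_status``, standardized
    linear scale otherwise).  ``nuisance_effects`` gives the per-covariate
    coefficient scale on the log10 RFU scale; defaults put nuisance variance
    at roughly 20% of total protein variance.
    """

    n_proteins: int = 1200
    n_samples_discovery: int = 111
    n_samples_replication: int = 147
    n_buffer_wells: int = 12
    module_sizes: Sequence[int] = (100, 80, 60, 40, 30)
    module_cors: Sequence[float] = (0.6, 0.6, 0.6, 0.6, 0.6)
    n_junk_proteins: int = 60
    preserved_flags: Sequence[bool] = (True, True, True, True, False)
    phenotype_links: Mapping[str, tuple[int, float]] = field(default_factory=lambda: {
        "amyloid_status": (0, 1.84),  # log-odds slope giving Bayes AUC ~0.85
        "ptau181": (0, 0.8),
        "abeta_ratio": (0, -0.5),
        "memory": (1, -0.5),
        "exec_function": (1, -0.4),
    })
    nuisance_effects: Mapping[str, float] = field(default_factory=lambda: {
        "age": 0.0625, "sex": 0.0625, "storage_time": 0.0625, "study_origin": 0.0625,
    })
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if len(self.module_cors) != len(self.module_sizes):
            raise ConfigurationError("module_cors and module_sizes lengths differ")
        if len(self.preserved_flags) != len(self.module_sizes):
            raise ConfigurationError("preserved_flags and module_sizes lengths differ")
        if any(s < 2 for s in self.module_sizes):
            raise ConfigurationError("every module size must be >= 2")
        if any(not (0.0 < c < 1.0) for c in self.module_cors):
            raise ConfigurationError("module_cors must lie strictly inside (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if sum(self.module_sizes) + self.n_junk_proteins > self.n_proteins:
            raise ConfigurationError("module and junk proteins exceed n_proteins")
        for name, (idx, _) in self.phenotype_links.items():
            if not (0 <= idx < len(self.module_sizes)):
                raise ConfigurationError(f"phenotype {name!r} links to missing module {idx}")

    @property
    def n_background(self) -> int:
        return self.n_proteins - sum(self.module_sizes) - self.n_junk_proteins

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["module_cors"] = list(self.module_cors)
        d["preserved_flags"] = list(self.preserved_flags)
        d["phenotype_links"] = {k: list(v) for k, v in self.phenotype_links.items()}
        d["nuisance_effects"] = dict(self.nuisance_effects)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        for key in ("module_sizes", "module_cors", "preserved_flags"):
            if key in d:
                d[key] = tuple(d[key])
        if "phenotype_links" in d:
            d["phenotype_links"] = {k: (int(v[0]), float(v[1]))
                                    for k, v in d["phenotype_links"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted: labels, factors, coefficients, junk set."""

    labels: pd.Series                      # protein -> true module (0 = background)
    factors_discovery: pd.DataFrame        # samples x modules latent factors
    factors_replication: pd.DataFrame
    phenotype_coefficients: dict[str, tuple[int, float]]
    junk_proteins: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "labels": self.labels.to_dict(),
            "factors_discovery": self.factors_discovery.to_dict(orient="list"),
            "factors_replication": self.factors_replication.to_dict(orient="list"),
            "phenotype_coefficients": {k: list(v) for k, v in
                                       self.phenotype_coefficients.items()},
            "junk_proteins": self.junk_proteins,
        }, indent=2))


def _nuisance_covariates(rng: np.random.Generator, n: int, cohort: str) -> pd.DataFrame:
    age = rng.normal(70.0, 6.0, n)
    sex = rng.integers(0, 2, n)
    storage = rng.uniform(0.5, 10.0, n)
    if cohort == "discovery":
        origin = rng.choice(["memory_center", "affiliated_clinic"], n)
    else:
        origin = np.repeat("aging_study", n)
    return pd.DataFrame({"age": age, "sex": sex, "storage_time": storage,
                         "study_origin": origin})


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _nuisance_signal(cov: pd.DataFrame, coef_scale: Mapping[str, float],
                     protein_mult: np.ndarray) -> np.ndarray:
    """n_samples x n_proteins additive nuisance term on the log10 scale."""
    n = len(cov)
    z = np.zeros((n, 4))
    z[:, 0] = _standardize(cov["age"].to_numpy(float))
    z[:, 1] = _standardize(cov["sex"].to_numpy(float))
    z[:, 2] = _standardize(cov["storage_time"].to_numpy(float))
    z[:, 3] = _standardize(pd.factorize(cov["study_origin"])[0].astype(float))
    betas = np.array([coef_scale.get(k, 0.0) for k in
                      ("age", "sex", "storage_time", "study_origin")])
    # per-protein random multipliers keep expected cross-protein nuisance
    # correlation near zero while the variance share stays at target
    return (z * betas) @ protein_mult


def _expression(rng: np.random.Generator, config: SimConfig, cov: pd.DataFrame,
                factors: np.ndarray, baselines: np.ndarray,
                buffer_baselines: np.ndarray, labels: np.ndarray,
                junk_mask: np.ndarray, scrambled: np.ndarray,
                nuisance_mult: np.ndarray, loadings: list[np.ndarray],
                sample_ids: list[str], protein_ids: list[str]) -> ExpressionMatrix:
    n = len(cov)
    log10 = np.tile(baselines, (n, 1)).astype(float)
    sd = config.noise_sd
    # expected additive nuisance variance per protein; folded into the
    # loading/noise split so within-module correlations hit their targets
    # on the generated (pre-adjustment) scale
    e_nuis = float(sum(b ** 2 for b in config.nuisance_effects.values()))
    total = sd ** 2 + e_nuis
    for m, size in enumerate(config.module_sizes):
        cols = np.where(labels == m + 1)[0]
        if scrambled[m]:
            # co-expression destroyed: every protein gets its own factor
            log10[:, cols] += sd * rng.standard_normal((n, size))
        else:
            a = loadings[m]
            resid = np.sqrt(np.maximum(total * (1.0 - a ** 2) - e_nuis,
                                       0.02 * total))
            log10[:, cols] += (np.sqrt(total) * a * factors[:, [m]]
                               + resid * rng.standard_normal((n, size)))
    bg = np.where((labels == 0) & ~junk_mask)[0]
    log10[:, bg] += sd * rng.standard_normal((n, bg.size))
    junk = np.where(junk_mask)[0]
    # junk proteins read buffer-level noise in clinical samples
    log10[:, junk] = (buffer_baselines[junk]
                      + _BUFFER_NOISE_SD * rng.standard_normal((n, junk.size)))
    nuis = _nuisance_signal(cov, config.nuisance_effects, nuisance_mult)
    log10[:, ~junk_mask] += nuis[:, ~junk_mask]
    df = pd.DataFrame(np.power(10.0, log10), index=sample_ids, columns=protein_ids)
    return ExpressionMatrix(df, "raw_rfu")


def _phenotypes(rng: np.random.Generator, config: SimConfig, cov: pd.DataFrame,
                factors: np.ndarray, cohort: str) -> pd.DataFrame:
    n = len(cov)
    pheno = cov.copy()
    links = dict(config.phenotype_links)

    if "amyloid_status" in links:
        m, eff = links["amyloid_status"]
        logits = -0.85 + eff * factors[:, m]
    else:
        logits = np.full(n, -0.85)
    amyloid = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    pheno["amyloid_status"] = amyloid

    def linear(name: str) -> np.ndarray:
        noise = rng.standard_normal(n)
        if name in links:
            m, eff = links[name]
            return eff * factors[:, m] + noise
        return noise

    pheno["ptau181"] = PTAU_BASE * np.power(10.0, PTAU_LOG_SCALE * linear("ptau181"))
    pheno["abeta_ratio"] = np.clip(0.08 + 0.015 * linear("abeta_ratio"), 1e-3, None)
    pheno["memory"] = linear("memory")
    pheno["exec_function"] = linear("exec_function")
    pheno["education"] = np.round(rng.normal(16.0, 2.0, n)).clip(8, 22)
    pheno["eicv"] = rng.normal(1.5e6, 1.5e5, n)
    pheno["hippocampus"] = rng.normal(7500.0, 700.0, n) + 0.002 * (pheno["eicv"] - 1.5e6)
    pheno["gray_matter"] = rng.normal(6.0e5, 5.0e4, n) + 0.2 * (pheno["eicv"] - 1.5e6)
    pheno["wmh"] = np.exp(rng.normal(7.0, 0.8, n))

    e4p = np.where(amyloid[:, None], _E4_PROBS_POS, _E4_PROBS_NEG)
    e2p = np.where(amyloid[:, None], _E2_PROBS_POS, _E2_PROBS_NEG)
    u4, u2 = rng.uniform(size=n), rng.uniform(size=n)
    pheno["apoe4_count"] = (u4[:, None] > np.cumsum(e4p, axis=1)[:, :2]).sum(axis=1)
    pheno["apoe2_count"] = (u2[:, None] > np.cumsum(e2p, axis=1)[:, :2]).sum(axis=1)

    if cohort == "discovery":
        # diagnosis tracks the amyloid-driving module: worst severity -> AD
        m = links.get("amyloid_status", (0, 0.0))[0]
        severity = factors[:, m] + 0.5 * rng.standard_normal(n)
        order = np.argsort(-severity)
        diag = np.array(["CU"] * n, dtype=object)
        n_ad = max(2, int(round(n * 20 / 111)))
        n_mci = max(2, int(round(n * 22 / 111)))
        diag[order[:n_ad]] = "AD"
        diag[order[n_ad:n_ad + n_mci]] = "MCI"
        pheno["diagnosis"] = diag
        pheno.loc[pheno["diagnosis"] != "CU", "amyloid_status"] = 1
    else:
        pheno["diagnosis"] = "CU"
    pheno["cohort"] = cohort
    return pheno


def generate_cohorts(config: SimConfig) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                                 ExpressionMatrix, pd.DataFrame,
                                                 pd.DataFrame, GroundTruth]:
    """Generate (discovery, replication, buffer, sample table, protein table, truth).

    All randomness flows from ``config.seed``; identical configurations give
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_proteins
    protein_ids = [f"P{i + 1:05d}" for i in range(p)]

    labels = np.zeros(p, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        labels[pos:pos + size] = m + 1
        pos += size
    junk_mask = np.zeros(p, dtype=bool)
    junk_mask[p - config.n_junk_proteins:] = True

    baselines = rng.normal(_CLINICAL_BASE_MEAN, _CLINICAL_BASE_SD, p)
    buffer_baselines = rng.normal(_BUFFER_BASE_MEAN, _BUFFER_BASE_SD, p)
    nuisance_mult = rng.standard_normal((4, p))
    # heterogeneous factor-correlation loadings (hub/periphery structure):
    # pairwise correlation of members i,j is ~a_i*a_j with mean near the
    # configured target; the spread shrinks as the target approaches 1 so
    # near-deterministic modules stay near-deterministic.  Preserved modules
    # reuse these loadings in the replication cohort.
    loadings = [np.clip(np.sqrt(r) * (1.0 + 0.15 * np.sqrt(1.0 - r)
                                      * rng.standard_normal(size)), 0.1, 0.995)
                for size, r in zip(config.module_sizes, config.module_cors)]

    k = len(config.module_sizes)
    nd, nr = config.n_samples_discovery, config.n_samples_replication
    disc_ids = [f"D{i + 1:04d}" for i in range(nd)]
    rep_ids = [f"R{i + 1:04d}" for i in range(nr)]
    fd = rng.standard_normal((nd, k))
    fr = rng.standard_normal((nr, k))

    cov_d = _nuisance_covariates(rng, nd, "discovery")
    cov_r = _nuisance_covariates(rng, nr, "replication")
    cov_d.index = disc_ids
    cov_r.index = rep_ids

    no_scramble = np.zeros(k, dtype=bool)
    scrambled = ~np.asarray(config.preserved_flags, dtype=bool)
    discovery = _expression(rng, config, cov_d, fd, baselines, buffer_baselines,
                            labels, junk_mask, no_scramble, nuisance_mult,
                            loadings, disc_ids, protein_ids)
    replication = _expression(rng, config, cov_r, fr, baselines, buffer_baselines,
                              labels, junk_mask, scrambled, nuisance_mult,
                              loadings, rep_ids, protein_ids)

    buf_ids = [f"B{i + 1:03d}" for i in range(config.n_buffer_wells)]
    buf_log10 = (buffer_baselines
                 + _BUFFER_NOISE_SD * rng.standard_normal((config.n_buffer_wells, p)))
    buffer = ExpressionMatrix(pd.DataFrame(np.power(10.0, buf_log10), index=buf_ids,
                                           columns=protein_ids), "raw_rfu")

    pheno_d = _phenotypes(rng, config, cov_d, fd, "discovery")
    pheno_r = _phenotypes(rng, config, cov_r, fr, "replication")
    samples = pd.concat([pheno_d, pheno_r])
    samples.index.name = "sample_id"

    gene_symbols = [f"GENE{i + 1}" for i in range(p)]
    proteins = pd.DataFrame({
        "gene_symbol": gene_symbols,
        "gwas_p": np.clip(rng.uniform(size=p), 1e-300, 1.0),
        "ubiquitination_sites": rng.poisson(2.0, p),
        "phosphopeptides": rng.poisson(3.0, p),
    }, index=pd.Index(protein_ids, name="protein_id"))

    mod_names = [f"M{m + 1}" for m in range(k)]
    truth = GroundTruth(
        labels=pd.Series(labels, index=protein_ids, name="module"),
        factors_discovery=pd.DataFrame(fd, index=disc_ids, columns=mod_names),
        factors_replication=pd.DataFrame(fr, index=rep_ids, columns=mod_names),
        phenotype_coefficients=dict(config.phenotype_links),
        junk_proteins=[protein_ids[i] for i in np.where(junk_mask)[0]],
    )
    return discovery, replication, buffer, samples, proteins, truth


def write_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full dataset as TSV/JSON files; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    disc, rep, buf, samples, proteins, truth = generate_cohorts(config)
    paths = {
        "discovery": outdir / "discovery_rfu.tsv",
        "replication": outdir / "replication_rfu.tsv",
        "buffer": outdir / "buffer_rfu.tsv",
        "samples": outdir / "samples.tsv",
        "proteins": outdir / "proteins.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "sim_config.json",
    }
    disc.write_tsv(paths["discovery"])
    rep.write_tsv(paths["replication"])
    buf.write_tsv(paths["buffer"])
    samples.to_csv(paths["samples"], sep="\t")
    proteins.to_csv(paths["proteins"], sep="\t")
    truth.to_json(paths["ground_truth"])
    config.to_json(paths["config"])
    return paths
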