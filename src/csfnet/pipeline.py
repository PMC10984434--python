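"""End-to-end orchestration: simulate -> qc -> differential abundance ->
network -> preservation -> traits -> enrichment -> classifier.

A single JSON config drives every stage; each stage writes its outputs under
the run directory and records them (with content digests and the seeds used)
in a manifest, so a finished run can be audited or resumed.  Stage seeds are
derived deterministically from one master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .classify import refit_and_evaluate, stability_selection
from .containers import ExpressionMatrix, ModulePartition
from .diffabund import diff_abundance, flag_ad_relevant_modules
from .enrichment import AnnotationVector, bootstrap_enrichment
from .network import NetworkConfig, build_network, eigenproteins
from .preservation import module_preservation
from .qc import adjust, buffer_filter, connectivity_outliers
from .simulate import SimConfig, generate_cohorts
from .traits import kruskal_wallis, trait_regressions

__all__ = ["run_pipeline", "load_manifest"]

_STAGE_SEED_OFFSETS = {"simulate": 11, "network": 23, "preservation": 31,
                       "enrichment": 47, "classifier": 59}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    return (master * 1009 + _STAGE_SEED_OFFSETS.get(stage, 0)) % (2 ** 31 - 1)


def _record(manifest: dict, stage: str, outputs: dict[str, Path],
            seed: int | None = None, **extra: Any) -> None:
    manifest["stages"][stage] = {
        "outputs": {k: str(p) for k, p in outputs.items()},
        "digests": {k: _digest(p) for k, p in outputs.items()},
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }


def _balanced_subset(samples: pd.DataFrame, per_group: int = 18,
                     seed: int = 0) -> pd.Index:
    """Diagnostically balanced discovery subset for network construction."""
    rng = np.random.default_rng(seed)
    picked = []
    disc = samples[samples["cohort"] == "discovery"]
    for g in ("CU", "MCI", "AD"):
        ids = disc.index[disc["diagnosis"] == g].to_numpy()
        take = min(per_group, len(ids))
        picked.extend(rng.choice(ids, take, replace=False))
    return pd.Index(picked)


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def run_pipeline(config: dict | str | Path, outdir: str | Path,
                 resume: bool = False) -> dict:
    """Execute the configured stages in dependency order; returns the manifest.

    ``config`` keys: ``seed`` (master seed), ``simulate`` (SimConfig fields),
    ``network`` (NetworkConfig fields), ``stages`` (per-stage ``enabled``
    flags), ``network_samples_per_group``, ``n_perm``, ``n_boot``.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    enabled = {k: v.get("enabled", True) if isinstance(v, dict) else bool(v)
               for k, v in config.get("stages", {}).items()}

    def on(stage: str) -> bool:
        return enabled.get(stage, True)

    manifest: dict = {"version": __version__, "config": config,
                      "master_seed": master_seed, "stages": {}}

    # --- simulate -----------------------------------------------------------
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs.setdefault("seed", _stage_seed(master_seed, "simulate"))
    sim = SimConfig(**sim_kwargs)
    discovery, replication, buffer, samples, proteins, truth = generate_cohorts(sim)
    data_dir = outdir / "data"
    data_dir.mkdir(exist_ok=True)
    discovery.write_tsv(data_dir / "discovery_rfu.tsv")
    replication.write_tsv(data_dir / "replication_rfu.tsv")
    buffer.write_tsv(data_dir / "buffer_rfu.tsv")
    samples.to_csv(data_dir / "samples.tsv", sep="\t")
    proteins.to_csv(data_dir / "proteins.tsv", sep="\t")
    truth.to_json(data_dir / "ground_truth.json")
    _record(manifest, "simulate",
            {k: data_dir / f"{k}.tsv" for k in
             ("discovery_rfu", "replication_rfu", "buffer_rfu", "samples", "proteins")},
            seed=sim.seed)

    # --- qc ----------------------------------------------------------------
    covar_cols = ["age", "sex", "storage_time", "study_origin"]
    adjusted = {}
    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    for name, mat in (("discovery", discovery), ("replication", replication)):
        kept, prot_report = buffer_filter(mat, buffer)
        kept = kept.log10()
        kept, samp_report = connectivity_outliers(kept)
        cov = samples.loc[kept.sample_ids, covar_cols]
        res = adjust(kept, cov, n_svd=int(config.get("n_svd", 5)))
        res.write_tsv(qc_dir / f"{name}_residual.tsv")
        prot_report.svd_components_used = int(config.get("n_svd", 5))
        prot_report.removed_samples = samp_report.removed_samples
        prot_report.to_json(qc_dir / f"{name}_qc_report.json")
        adjusted[name] = res
    _record(manifest, "qc", {f"{n}_residual": qc_dir / f"{n}_residual.tsv"
                             for n in adjusted})

    # --- differential abundance --------------------------------------------
    da_table = None
    if on("diffabund"):
        disc_adj = adjusted["discovery"]
        groups = samples.loc[disc_adj.sample_ids, "diagnosis"]
        da_table = diff_abundance(disc_adj, groups)
        da_table.to_csv(outdir / "diff_abundance.tsv", sep="\t")
        _record(manifest, "diffabund", {"table": outdir / "diff_abundance.tsv"})

    # --- network ------------------------------------------------------------
    net_seed = _stage_seed(master_seed, "network")
    subset = _balanced_subset(samples.loc[adjusted["discovery"].sample_ids],
                              config.get("network_samples_per_group", 18), net_seed)
    net_data = adjusted["discovery"].subset_samples(subset)
    net_cfg = NetworkConfig(**config.get("network", {}))
    partition = build_network(net_data, net_cfg)
    net_dir = outdir / "network"
    partition.write(net_dir)
    _record(manifest, "network",
            {"labels": net_dir / "modules_labels.tsv"}, seed=net_seed,
            n_modules=len(partition.module_ids))

    if da_table is not None and partition.module_ids:
        relevant = flag_ad_relevant_modules(partition, da_table)
        (outdir / "ad_relevant_modules.json").write_text(
            json.dumps(sorted(relevant)))

    # --- preservation -------------------------------------------------------
    if on("preservation") and partition.module_ids:
        report = module_preservation(adjusted["discovery"], adjusted["replication"],
                                     partition.labels,
                                     n_perm=int(config.get("n_perm", 200)),
                                     seed=int(config.get("preservation_seed", 1)))
        report.summary.to_csv(outdir / "preservation_summary.tsv", sep="\t")
        report.to_json(outdir / "preservation.json")
        _record(manifest, "preservation",
                {"summary": outdir / "preservation_summary.tsv"},
                seed=report.seed, n_permutations=report.n_permutations)

    # --- traits -------------------------------------------------------------
    if on("traits") and partition.module_ids:
        rep = adjusted["replication"]
        labels_kept = partition.labels.reindex(rep.protein_ids).fillna(0).astype(int)
        mes, _ = eigenproteins(rep, labels_kept)
        pheno = samples.loc[rep.sample_ids]
        table = trait_regressions(mes, pheno)
        kw = [{"module": m,
               "H": kruskal_wallis(mes[m], pheno["amyloid_status"])[0],
               "p": kruskal_wallis(mes[m], pheno["amyloid_status"])[1]}
              for m in mes.columns]
        table.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        pd.DataFrame(kw).to_csv(outdir / "module_amyloid_kw.tsv", sep="\t",
                                index=False)
        _record(manifest, "traits", {"table": outdir / "module_trait.tsv"})

    # --- enrichment ---------------------------------------------------------
    if on("enrichment") and partition.module_ids:
        seed = _stage_seed(master_seed, "enrichment")
        annot = AnnotationVector(proteins["gwas_p"], "p_value", "gwas_p")
        universe = partition.labels.index
        results = []
        for m in partition.module_ids:
            res = bootstrap_enrichment(partition.members(m), annot, universe,
                                       n_boot=int(config.get("n_boot", 10_000)),
                                       seed=seed + m, module_name=f"M{m}")
            results.append(res.to_dict())
        pd.DataFrame(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        _record(manifest, "enrichment", {"table": outdir / "enrichment.tsv"},
                seed=seed)

    # --- classifier ---------------------------------------------------------
    if on("classifier") and partition.module_ids:
        seed = _stage_seed(master_seed, "classifier")
        rng = np.random.default_rng(seed)
        rep = adjusted["replication"]
        target = config.get("classifier_module")
        if target is None:
            mes, _ = eigenproteins(rep, partition.labels.reindex(
                rep.protein_ids).fillna(0).astype(int))
            pvals = {m: kruskal_wallis(mes[f"M{m}"],
                                       samples.loc[rep.sample_ids, "amyloid_status"])[1]
                     for m in partition.module_ids if f"M{m}" in mes.columns}
            target = min(pvals, key=pvals.get)
        module_prots = [p for p in partition.members(int(target))
                        if p in rep.protein_ids]
        feats = rep.values.loc[:, module_prots].copy()
        for c in ("age", "sex", "apoe4_count"):
            feats[c] = samples.loc[rep.sample_ids, c].to_numpy(dtype=float)
        outcome = samples.loc[rep.sample_ids, "amyloid_status"]
        stab = stability_selection(feats[module_prots], outcome, seed=seed)
        stab.to_json(outdir / "stability.json")

        # train/validation within the replication cohort, external test from
        # discovery CU samples not used for network construction
        rep_ids = rep.sample_ids.to_numpy()
        perm = rng.permutation(len(rep_ids))
        n_train = int(round(0.8 * len(rep_ids)))
        split = pd.Series("validation", index=rep.sample_ids)
        split.iloc[perm[:n_train]] = "train"
        disc = adjusted["discovery"]
        test_ids = [s for s in disc.sample_ids
                    if samples.loc[s, "diagnosis"] == "CU" and s not in set(subset)]
        test_feats = disc.values.loc[test_ids, module_prots].copy()
        for c in ("age", "sex", "apoe4_count"):
            test_feats[c] = samples.loc[test_ids, c].to_numpy(dtype=float)
        all_feats = pd.concat([feats, test_feats])
        all_split = pd.concat([split, pd.Series("test", index=pd.Index(test_ids))])
        all_outcome = samples.loc[all_feats.index, "amyloid_status"]
        stable = stab.stable_features or list(
            stab.selection_probability.sort_values(ascending=False).index[:1])
        evals = refit_and_evaluate(all_feats, all_outcome, all_split, stable)
        (outdir / "classifier_eval.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in evals.items()}, indent=2))
        _record(manifest, "classifier", {"stability": outdir / "stability.json",
                                         "evaluation": outdir / "classifier_eval.json"},
                seed=seed, module=int(target))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
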