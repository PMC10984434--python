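"""Permutation-based module preservation across cohorts.

Quantifies whether modules defined in a reference (discovery) cohort keep
their density and connectivity structure in an independent test cohort.
Observed statistics per module:

density (test cohort):  mean intramodule correlation, mean intramodule
    adjacency, eigenprotein proportion of variance explained, mean |kME|;
connectivity (ref vs test):  correlation of intramodular connectivity
    (cor.kIM), of module membership (cor.kME), and of the intramodule
    correlation entries themselves (cor.cor).

The null permutes module labels across network (non-grey) proteins.  Each
statistic is standardized against its permutation null; Z_density and
Z_connectivity are the within-category medians, Z_summary their mean, and
medianRank the median across statistics of the module's observed-value rank.
Modules with Z_summary > 10 are called preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .network import bicor_matrix, signed_adjacency

__all__ = ["PreservationReport", "module_preservation", "Z_PRESERVED_THRESHOLD"]

Z_PRESERVED_THRESHOLD = 10.0
_DENSITY_STATS = ("mean_cor", "mean_adj", "prop_var_explained", "mean_abs_kme")
_CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")
_ALL_STATS = _DENSITY_STATS + _CONNECTIVITY_STATS


@dataclass
class PreservationReport:
    observed: pd.DataFrame          # modules x statistics
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    z: pd.DataFrame
    summary: pd.DataFrame           # Z_density, Z_connectivity, Z_summary, medianRank, preserved
    n_permutations: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "observed": self.observed.to_dict(),
            "null_mean": self.null_mean.to_dict(),
            "null_sd": self.null_sd.to_dict(),
            "z": self.z.to_dict(),
            "summary": self.summary.to_dict(),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }, indent=2, default=float))


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    z = x - x.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return z / sd


def _eigen(z: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-norm first PC scores and proportion of variance of a standardized
    module block (sign-aligned with the module mean profile)."""
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    ep = u[:, 0]
    if np.dot(ep, z.mean(axis=1)) < 0:
        ep = -ep
    return ep, float(s[0] ** 2 / np.sum(s ** 2))


def _member_kme(z: np.ndarray, ep: np.ndarray) -> np.ndarray:
    epc = ep - ep.mean()
    num = z.T @ epc
    denom = np.sqrt(np.sum(z ** 2, axis=0)) * np.sqrt(np.sum(epc ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, 0.0)


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _module_stats(idx: np.ndarray, cor_ref: np.ndarray, cor_test: np.ndarray,
                  adj_ref: np.ndarray, adj_test: np.ndarray,
                  z_ref: np.ndarray, z_test: np.ndarray) -> dict[str, float]:
    sub_cor_t = cor_test[np.ix_(idx, idx)]
    sub_cor_r = cor_ref[np.ix_(idx, idx)]
    sub_adj_t = adj_test[np.ix_(idx, idx)]
    sub_adj_r = adj_ref[np.ix_(idx, idx)]
    m = len(idx)
    tri = np.triu_indices(m, k=1)

    ep_t, pve_t = _eigen(z_test[:, idx])
    ep_r, _ = _eigen(z_ref[:, idx])
    kme_t = _member_kme(z_test[:, idx], ep_t)
    kme_r = _member_kme(z_ref[:, idx], ep_r)
    kim_t = sub_adj_t.sum(axis=1) - 1.0
    kim_r = sub_adj_r.sum(axis=1) - 1.0

    return {
        "mean_cor": float(sub_cor_t[tri].mean()),
        "mean_adj": float(sub_adj_t[tri].mean()),
        "prop_var_explained": pve_t,
        "mean_abs_kme": float(np.mean(np.abs(kme_t))),
        "cor_kim": _safe_cor(kim_r, kim_t),
        "cor_kme": _safe_cor(kme_r, kme_t),
        "cor_cor": _safe_cor(sub_cor_r[tri], sub_cor_t[tri]),
    }


def module_preservation(ref: ExpressionMatrix, test: ExpressionMatrix,
                        labels: pd.Series, n_perm: int = 200, seed: int = 1,
                        beta: int = 12,
                        exclude_grey: bool = False) -> PreservationReport:
    """Permutation Z preservation statistics of ``labels`` modules in ``test``.

    ``labels`` come from the reference-cohort network (0 = grey).  The null
    permutes module labels across all shared proteins; with
    ``exclude_grey=True`` the permutation pool is restricted to proteins
    carrying a module label (a stricter null: permuted modules then consist
    entirely of other modules' proteins).  Runs are bit-reproducible for a
    fixed seed.
    """
    missing = labels.index[labels != 0].difference(test.protein_ids)
    if len(missing):
        import warnings
        warnings.warn(f"{len(missing)} module protein(s) absent from test cohort; skipped")
    common = ref.protein_ids.intersection(test.protein_ids)
    labels = labels.reindex(common).fillna(0).astype(int)

    ref = ref.subset_proteins(common)
    test = test.subset_proteins(common)
    cor_ref = bicor_matrix(ref).to_numpy()
    cor_test = bicor_matrix(test).to_numpy()
    adj_ref = signed_adjacency(cor_ref, beta)
    adj_test = signed_adjacency(cor_test, beta)
    z_ref = _standardize_columns(ref.to_numpy())
    z_test = _standardize_columns(test.to_numpy())

    lab = labels.to_numpy()
    modules = sorted(int(m) for m in np.unique(lab) if m != 0)
    if not modules:
        raise ValueError("no non-grey modules to assess")
    pool = np.where(lab != 0)[0] if exclude_grey else np.arange(len(lab))

    def stats_for(assign: np.ndarray) -> pd.DataFrame:
        rows = {}
        for m in modules:
            idx = np.where(assign == m)[0]
            rows[m] = _module_stats(idx, cor_ref, cor_test, adj_ref, adj_test,
                                    z_ref, z_test)
        return pd.DataFrame(rows).T[list(_ALL_STATS)]

    observed = stats_for(lab)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(modules), len(_ALL_STATS)))
    for p in range(n_perm):
        perm = lab.copy()
        perm[pool] = lab[pool][rng.permutation(len(pool))]
        null[p] = stats_for(perm).to_numpy()

    null_mean = pd.DataFrame(np.nanmean(null, axis=0), index=modules,
                             columns=_ALL_STATS)
    null_sd = pd.DataFrame(np.nanstd(null, axis=0, ddof=1), index=modules,
                           columns=_ALL_STATS)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    z = z.mask(null_sd == 0)

    z_density = z[list(_DENSITY_STATS)].median(axis=1, skipna=True)
    z_connectivity = z[list(_CONNECTIVITY_STATS)].median(axis=1, skipna=True)
    z_summary = (z_density + z_connectivity) / 2.0
    ranks = observed.rank(axis=0, ascending=False, method="min")
    median_rank = ranks.median(axis=1).round().astype(int)

    summary = pd.DataFrame({
        "Z_density": z_density,
        "Z_connectivity": z_connectivity,
        "Z_summary": z_summary,
        "medianRank": median_rank,
        "preserved": z_summary > Z_PRESERVED_THRESHOLD,
    })
    return PreservationReport(observed, null_mean, null_sd, z, summary,
                              n_perm, seed)
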