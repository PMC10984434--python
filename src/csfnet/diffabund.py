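"""Differential abundance across diagnostic groups.

Per protein: one-way ANOVA across CU/MCI/AD, a two-sample t-test of AD
versus CU (Welch by default), BH FDR correction of the t-test p-values
across proteins, and a log2 fold change (AD minus CU mean).  Modules holding
at least one FDR-significant protein are flagged as disease-relevant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ModulePartition

__all__ = ["diff_abundance", "flag_ad_relevant_modules"]

_GROUPS = ("CU", "MCI", "AD")


def diff_abundance(data: ExpressionMatrix, groups: pd.Series, alpha: float = 0.05,
                   equal_var: bool = False) -> pd.DataFrame:
    """Per-protein ANOVA + AD-vs-CU t-test with BH FDR.

    ``log2_fold_change`` is the AD minus CU mean difference on the log2
    scale: raw matrices are log2 transformed, log10 matrices rescaled by
    log2(10), residual-scale differences reported as-is.
    """
    groups = groups.loc[data.sample_ids]
    present = set(groups.unique())
    missing = [g for g in _GROUPS if g not in present]
    if missing:
        raise ValueError(f"missing diagnostic group(s): {missing}")

    if data.scale_tag == "raw_rfu":
        x = np.log2(data.to_numpy())
    elif data.scale_tag == "log10":
        x = data.to_numpy() * np.log2(10.0)
    else:
        x = data.to_numpy()

    masks = {g: (groups == g).to_numpy() for g in _GROUPS}
    if any(m.sum() < 2 for m in masks.values()):
        raise ValueError("every diagnostic group needs at least 2 samples")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        anova_p = stats.f_oneway(*(x[masks[g]] for g in _GROUPS)).pvalue
        t_res = stats.ttest_ind(x[masks["AD"]], x[masks["CU"]], equal_var=equal_var)
        t_p = np.asarray(t_res.pvalue, dtype=float)

    # zero within-group variance makes the t statistic undefined
    degenerate = np.isnan(t_p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} protein(s) with zero within-group "
                      "variance; exact-equality p assigned")
        means_equal = np.isclose(x[masks["AD"]].mean(axis=0),
                                 x[masks["CU"]].mean(axis=0))
        t_p[degenerate] = np.where(means_equal[degenerate], 1.0, 0.0)
    anova_p = np.nan_to_num(anova_p, nan=1.0)

    fdr_q = multipletests(t_p, method="fdr_bh")[1]
    log2fc = x[masks["AD"]].mean(axis=0) - x[masks["CU"]].mean(axis=0)
    return pd.DataFrame({
        "anova_p": anova_p,
        "t_p": t_p,
        "fdr_q": fdr_q,
        "log2_fold_change": log2fc,
        "significant": fdr_q < alpha,
    }, index=data.protein_ids)


def flag_ad_relevant_modules(partition: ModulePartition,
                             table: pd.DataFrame) -> set[int]:
    """Modules containing at least one FDR-significant protein."""
    sig = table.index[table["significant"]]
    labels = partition.labels.reindex(sig).dropna()
    return {int(m) for m in labels.unique() if m != 0}
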