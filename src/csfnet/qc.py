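"""Preprocessing: buffer-distribution protein filter, connectivity-based
sample outlier removal, log10 transform and covariate/SVD adjustment.

The buffer filter drops proteins whose clinical measurements are largely
indistinguishable from the assay's no-sample buffer wells: per protein, each
clinical sample gets a two-sided Gaussian tail p-value against the buffer
location/scale, Benjamini-Hochberg is applied across that protein's samples,
and the protein is removed when more than ``max_inside_frac`` of samples fail
to separate from buffer at FDR ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = ["QcReport", "buffer_filter", "connectivity_outliers", "adjust"]


@dataclass
class QcReport:
    """Record of what QC removed and why."""

    removed_proteins: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    removed_samples: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    svd_components_used: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "removed_proteins": self.removed_proteins.to_dict(),
            "removed_samples": self.removed_samples.to_dict(),
            "svd_components_used": self.svd_components_used,
        }, indent=2))


def buffer_filter(clinical: ExpressionMatrix, buffer: ExpressionMatrix,
                  alpha: float = 0.05,
                  max_inside_frac: float = 0.25) -> tuple[ExpressionMatrix, QcReport]:
    """Remove proteins whose clinical values sit inside the buffer distribution.

    A clinical sample "falls within" the buffer distribution when its
    BH-adjusted two-sided tail p-value (Gaussian, buffer mean/SD) is >= alpha.
    Proteins with an inside fraction above ``max_inside_frac`` are removed.
    Works on the log10 scale internally; raw matrices are transformed first.
    """
    if buffer.n_samples < 3:
        raise ValueError("buffer_filter requires at least 3 buffer wells")
    if not clinical.protein_ids.equals(buffer.protein_ids):
        raise ValueError("clinical and buffer protein registries differ")

    clin = clinical.log10() if clinical.scale_tag == "raw_rfu" else clinical
    buf = buffer.log10() if buffer.scale_tag == "raw_rfu" else buffer
    x = clin.to_numpy()
    b = buf.to_numpy()
    mu = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)

    inside_frac = np.empty(clin.n_proteins)
    for j in range(clin.n_proteins):
        if sd[j] == 0:
            warnings.warn(f"zero buffer variance for {clin.protein_ids[j]}; "
                          "using exact-equality test")
            inside = x[:, j] == mu[j]
        else:
            p = 2.0 * stats.norm.sf(np.abs(x[:, j] - mu[j]) / sd[j])
            padj = multipletests(p, method="fdr_bh")[1]
            inside = padj >= alpha
        inside_frac[j] = inside.mean()

    removed = inside_frac > max_inside_frac
    report = QcReport(removed_proteins=pd.Series(inside_frac[removed],
                                                 index=clin.protein_ids[removed]))
    kept = ExpressionMatrix(clinical.values.loc[:, ~removed], clinical.scale_tag)
    return kept, report


def connectivity_outliers(data: ExpressionMatrix,
                          z_thresh: float = 3.0) -> tuple[ExpressionMatrix, QcReport]:
    """Remove samples whose standardized connectivity is > ``z_thresh`` SD from
    the mean.

    Connectivity of sample *s* is the sum, over the other samples, of the
    inter-sample Pearson correlations of protein profiles.  Applied once, no
    iteration.
    """
    if data.n_samples < 4:
        raise ValueError("connectivity_outliers requires at least 4 samples")
    x = data.to_numpy()
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x)
    np.fill_diagonal(c, 0.0)
    k = np.nansum(c, axis=1)
    sd = k.std(ddof=1)
    if sd == 0:
        return data, QcReport()
    z = (k - k.mean()) / sd
    out = np.abs(z) > z_thresh
    report = QcReport(removed_samples=pd.Series(z[out], index=data.sample_ids[out]))
    kept = ExpressionMatrix(data.values.loc[~out, :], data.scale_tag)
    return kept, report


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """One-hot encode categoricals, drop aliased columns, prepend intercept."""
    cols = [np.ones((len(covariates), 1))]
    for name in sorted(covariates.columns):
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            if not dummies.empty:
                cols.append(dummies.to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    design = np.hstack(cols)
    # drop linearly dependent columns (QR with column pivoting via rank checks)
    q, r, piv = _qr_pivot(design)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0])))
    if rank < design.shape[1]:
        warnings.warn("rank-deficient covariate design; dropping aliased columns")
        design = design[:, sorted(piv[:rank])]
    return design


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr
    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def adjust(data: ExpressionMatrix, covariates: pd.DataFrame,
           n_svd: int = 5) -> ExpressionMatrix:
    """Residualize each protein on known covariates, then on the first
    ``n_svd`` left singular vectors of the column-centered residual matrix.

    Raw matrices are log10 transformed first.  Output ``scale_tag`` is
    ``residual``; every output column is orthogonal (to numerical precision)
    to the known covariates and to the removed singular vectors.
    """
    x = data.log10() if data.scale_tag == "raw_rfu" else data
    if not covariates.index.equals(x.sample_ids):
        covariates = covariates.loc[x.sample_ids]
    mat = x.to_numpy()

    design = _design_matrix(covariates)
    beta, *_ = np.linalg.lstsq(design, mat, rcond=None)
    resid = mat - design @ beta

    if n_svd > 0:
        centered = resid - resid.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        uk = u[:, :n_svd]
        resid = resid - uk @ (uk.T @ resid)

    out = pd.DataFrame(resid, index=x.sample_ids, columns=x.protein_ids)
    return ExpressionMatrix(out, "residual")
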