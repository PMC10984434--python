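"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a thin wrapper around a
samples x proteins :class:`pandas.DataFrame` that tracks which scale the
values live on (raw relative fluorescence units, log10, or covariate-adjusted
residuals).  Downstream stages check the ``scale_tag`` so that, e.g., the
network is never accidentally built on raw RFUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SCALE_TAGS = ("raw_rfu", "log10", "residual")


@dataclass
class ExpressionMatrix:
    """Samples x proteins abundance matrix with aligned registries.

    Parameters
    ----------
    values
        DataFrame with sample identifiers as the index and protein
        identifiers as columns.  Must be free of missing values.
    scale_tag
        One of ``raw_rfu`` (strictly positive), ``log10`` or ``residual``.
    """

    values: pd.DataFrame
    scale_tag: str = "raw_rfu"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.scale_tag == "raw_rfu" and (self.values.to_numpy() <= 0).any():
            raise ValueError("raw_rfu values must be strictly positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_proteins(self, proteins: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(proteins)], self.scale_tag)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(samples), :], self.scale_tag)

    def log10(self) -> "ExpressionMatrix":
        """Return the matrix on the log10 scale (identity if already there)."""
        if self.scale_tag == "log10":
            return self
        if self.scale_tag != "raw_rfu":
            raise ValueError("log10 transform only applies to raw_rfu matrices")
        return ExpressionMatrix(np.log10(self.values), "log10")

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path: str | Path, scale_tag: str = "raw_rfu") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale_tag)


@dataclass
class ModulePartition:
    """Protein -> module assignment plus module summary profiles.

    ``labels`` maps each protein to an integer module id with 0 reserved for
    unassigned ("grey") proteins.  ``eigenproteins`` holds per-module first
    principal component scores across samples (unit norm, sign-aligned with
    the module mean profile); ``kme`` the protein x module membership
    correlations; ``prop_var_explained`` the per-module fraction of variance
    captured by the eigenprotein.
    """

    labels: pd.Series
    eigenproteins: pd.DataFrame = field(default_factory=pd.DataFrame)
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)
    prop_var_explained: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in set(self.labels) if m != 0)

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def write(self, outdir: str | Path, prefix: str = "modules") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.labels.rename("module").to_csv(outdir / f"{prefix}_labels.tsv", sep="\t",
                                            index_label="protein_id")
        if not self.eigenproteins.empty:
            self.eigenproteins.to_csv(outdir / f"{prefix}_eigenproteins.tsv", sep="\t",
                                      index_label="sample_id")
        if not self.kme.empty:
            self.kme.to_csv(outdir / f"{prefix}_kme.tsv", sep="\t", index_label="protein_id")
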