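"""Bootstrap module-enrichment z-scores.

For a per-protein annotation (gene-level GWAS p-values, ubiquitination-site
or phosphopeptide counts), the module's observed statistic — mean -log10(p)
for p-value annotations, plain mean for counts — is compared against a null
of module-sized random samples drawn with replacement from the assayed
universe.  The z-score is flagged significant outside +/-1.645 (the 90%
confidence critical value); a two-sided empirical p accompanies it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import json
import numpy as np
import pandas as pd

__all__ = ["AnnotationVector", "EnrichmentResult", "bootstrap_enrichment",
           "Z_CRITICAL"]

Z_CRITICAL = 1.645


@dataclass
class AnnotationVector:
    """Per-protein annotation values; ``value_kind`` is 'p_value' or 'count'."""

    values: pd.Series
    value_kind: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.value_kind not in ("p_value", "count"):
            raise ValueError("value_kind must be 'p_value' or 'count'")
        v = self.values.dropna()
        if self.value_kind == "p_value" and ((v <= 0) | (v > 1)).any():
            raise ValueError("p_value annotations must lie in (0, 1]")
        if self.value_kind == "count" and (v < 0).any():
            raise ValueError("count annotations must be non-negative")

    def statistic_values(self) -> pd.Series:
        """Per-protein contribution: -log10(p) or the raw count."""
        v = self.values.dropna()
        return -np.log10(v) if self.value_kind == "p_value" else v.astype(float)

    @classmethod
    def read_tsv(cls, path: str | Path, value_kind: str, name: str = "") -> "AnnotationVector":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.iloc[:, 0], value_kind, name or df.columns[0])


@dataclass
class EnrichmentResult:
    module: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_boot: int
    seed: int
    n_excluded: int = 0

    @property
    def significant(self) -> bool:
        return abs(self.z) > Z_CRITICAL

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("module", "observed", "null_mean",
                                           "null_sd", "z", "empirical_p",
                                           "n_boot", "seed", "n_excluded")}
        d["significant"] = self.significant
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def bootstrap_enrichment(module_proteins: Iterable[str], annotation: AnnotationVector,
                         universe: Iterable[str], n_boot: int = 10_000,
                         seed: int = 0, module_name: str = "") -> EnrichmentResult:
    """Bootstrap z-score of a module's mean annotation statistic.

    The null resamples ``len(module)``-sized protein sets with replacement
    from the annotated universe.  Proteins without annotation are excluded
    from the universe (count reported); an unannotated module protein is an
    error.  A constant annotation yields z = 0 by convention.
    """
    stat_values = annotation.statistic_values()
    universe = pd.Index(universe)
    annotated = universe.intersection(stat_values.index)
    n_excluded = len(universe) - len(annotated)
    module = pd.Index(module_proteins)
    if not module.isin(annotated).all():
        missing = module.difference(annotated)
        raise ValueError(f"module proteins outside annotated universe: {list(missing[:5])}")
    if len(module) == 0:
        raise ValueError("empty module")

    pool = stat_values.loc[annotated].to_numpy(dtype=float)
    observed = float(stat_values.loc[module].mean())

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(pool), size=(n_boot, len(module)))
    null = pool[draws].mean(axis=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))

    if null_sd == 0:
        if np.isclose(observed, null_mean):
            z = 0.0  # constant annotation: every draw equals the observed mean
        else:
            raise ValueError("degenerate null (SD = 0) with observed != null mean")
    else:
        z = (observed - null_mean) / null_sd

    # two-sided empirical p with add-one smoothing, mirroring around the null mean
    dev = abs(observed - null_mean)
    extreme = np.sum(np.abs(null - null_mean) >= dev - 1e-15)
    empirical_p = float((1 + extreme) / (n_boot + 1))
    return EnrichmentResult(module_name or "module", observed, null_mean, null_sd,
                            float(z), empirical_p, n_boot, seed, n_excluded)
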