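"""Module eigenprotein versus phenotype associations.

Categorical outcomes (clinical diagnosis, amyloid status) use Kruskal-Wallis
tests on the eigenprotein; continuous outcomes use ordinary least squares of
the outcome on the eigenprotein under three nested covariate regimes:

approach 1  age + sex (+ education for cognitive composites; + estimated
            intracranial volume for volumetric outcomes)
approach 2  approach 1 + amyloid status (amyloid ratio dropped as outcome)
approach 3  approach 2 + log p-tau181 (p-tau181 also dropped as outcome)

Betas are standardized (outcome and eigenprotein z-scored); BH FDR is
applied across modules within each (outcome, approach) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TraitModelSpec", "kruskal_wallis", "trait_regressions",
           "build_specs", "DEFAULT_OUTCOMES"]

COGNITIVE_OUTCOMES = {"memory", "exec_function"}
VOLUMETRIC_OUTCOMES = {"hippocampus", "gray_matter", "wmh"}
LOG_OUTCOMES = {"ptau181", "wmh"}
DEFAULT_OUTCOMES = ("abeta_ratio", "ptau181", "hippocampus", "gray_matter", "wmh",
                    "apoe2_count", "apoe4_count", "memory", "exec_function")


@dataclass(frozen=True)
class TraitModelSpec:
    """One outcome/approach pair with its resolved covariate set."""

    outcome: str
    approach: int
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.outcome in self.covariates:
            raise ValueError(f"outcome {self.outcome!r} cannot be its own covariate")


def build_specs(outcomes=DEFAULT_OUTCOMES, approaches=(1, 2, 3)) -> list[TraitModelSpec]:
    """Resolve the covariate set per outcome under each approach, dropping
    outcomes that become covariates (amyloid ratio at 2+, p-tau181 at 3)."""
    specs = []
    for approach in approaches:
        if approach not in (1, 2, 3):
            raise ValueError("approach must be 1, 2 or 3")
        for outcome in outcomes:
            if approach >= 2 and outcome == "abeta_ratio":
                continue
            if approach >= 3 and outcome == "ptau181":
                continue
            cov = ["age", "sex"]
            if outcome in COGNITIVE_OUTCOMES:
                cov.append("education")
            if outcome in VOLUMETRIC_OUTCOMES:
                cov.append("eicv")
            if approach >= 2:
                cov.append("amyloid_status")
            if approach >= 3:
                cov.append("ptau181")
            specs.append(TraitModelSpec(outcome, approach, tuple(cov)))
    return specs


def kruskal_wallis(me: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) of an eigenprotein across groups."""
    groups = groups.loc[me.index]
    samples = [me[groups == g].to_numpy() for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("kruskal_wallis needs >= 2 groups with >= 2 members each")
    values = np.concatenate(samples)
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def trait_regressions(mes: pd.DataFrame, phenotypes: pd.DataFrame,
                      specs: list[TraitModelSpec] | None = None) -> pd.DataFrame:
    """Standardized eigenprotein betas for every (module, outcome, approach).

    Samples with a missing outcome or covariate are dropped per spec
    (complete-case, count reported in ``n_used``).  p-tau181 and white matter
    hypointensities are log10-transformed, as outcome and as covariate.
    """
    specs = specs if specs is not None else build_specs()
    phenotypes = phenotypes.loc[mes.index]
    rows = []
    for spec in specs:
        cols = [spec.outcome, *spec.covariates]
        frame = phenotypes[cols].copy()
        for c in set(cols) & LOG_OUTCOMES:
            frame[c] = np.log10(frame[c])
        if "sex" in frame.columns and frame["sex"].dtype == object:
            frame["sex"] = pd.factorize(frame["sex"])[0]
        keep = frame.notna().all(axis=1)
        frame = frame.loc[keep]
        n_used = int(keep.sum())
        y = _zscore(frame[spec.outcome].to_numpy(dtype=float))
        cov = frame[list(spec.covariates)].to_numpy(dtype=float)
        for module in mes.columns:
            me = _zscore(mes.loc[frame.index, module].to_numpy(dtype=float))
            design = sm.add_constant(np.column_stack([me, cov]), has_constant="add")
            fit = sm.OLS(y, design).fit()
            rows.append({"module": module, "outcome": spec.outcome,
                         "approach": spec.approach,
                         "std_beta": float(fit.params[1]),
                         "p": float(fit.pvalues[1]),
                         "n_used": n_used})
    table = pd.DataFrame(rows)
    table["fdr_p"] = np.nan
    for (_, _), idx in table.groupby(["outcome", "approach"]).groups.items():
        table.loc[idx, "fdr_p"] = multipletests(table.loc[idx, "p"],
                                                method="fdr_bh")[1]
    return table
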