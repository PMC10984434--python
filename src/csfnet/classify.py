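"""Amyloid-status classification: cross-validated LASSO, stability selection,
and unpenalized refits evaluated by ROC/AUC with DeLong confidence intervals.

The L1 path follows the glmnet convention: binomial deviance minimized over
a 100-point descending geometric lambda grid from the smallest lambda that
zeroes every penalized coefficient.  Stability selection refits the path on
seeded half-subsamples (stratified by outcome), counts the first q features
to enter each subsample's path, and keeps features selected in more than
65% of subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = ["StabilityResult", "ClassifierEvaluation", "lasso_cv",
           "stability_selection", "refit_and_evaluate", "auc_score", "delong_ci"]

_N_LAMBDA = 100


def _lambda_grid(xs: np.ndarray, y: np.ndarray, n_lambda: int = _N_LAMBDA,
                 ratio: float | None = None) -> np.ndarray:
    """Descending geometric grid from the all-zero lambda (standardized X).

    The lambda_min/lambda_max ratio follows the glmnet convention: 1e-4 when
    there are more observations than features, 1e-2 otherwise.
    """
    n = len(y)
    if ratio is None:
        ratio = 1e-4 if n > xs.shape[1] else 1e-2
    lam_max = np.max(np.abs(xs.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd, mu, sd


def _fit_l1_path(xs: np.ndarray, y: np.ndarray,
                 lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path (n_lambda x p) and intercepts on the standardized scale."""
    n = len(y)
    coefs = np.zeros((len(lambdas), xs.shape[1]))
    icepts = np.zeros(len(lambdas))
    for i, lam in enumerate(lambdas):
        c = 1.0 / (n * lam)
        model = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                   intercept_scaling=50.0, max_iter=500, tol=1e-6)
        model.fit(xs, y)
        coefs[i] = model.coef_[0]
        icepts[i] = model.intercept_[0]
    return coefs, icepts


def _binomial_deviance(xs: np.ndarray, y: np.ndarray, coef: np.ndarray,
                       icept: float) -> float:
    eta = np.clip(xs @ coef + icept, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    return float(-2.0 * np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def lasso_cv(features: pd.DataFrame, outcome: pd.Series, n_folds: int = 10,
             fold_seed: int = 0) -> tuple[float, pd.Series]:
    """10-fold cross-validated L1 logistic regression.

    Observations are assigned to folds by a seeded random permutation;
    assignments violating the both-classes-per-training-fold requirement are
    re-randomized up to 10 times.  Returns the deviance-minimizing lambda and
    the full-data coefficients at that lambda on the original feature scale
    (index: 'intercept' followed by feature names).
    """
    x = features.to_numpy(dtype=float)
    y = outcome.loc[features.index].to_numpy(dtype=int)
    n = len(y)
    xs, mu, sd = _standardize(x)
    lambdas = _lambda_grid(xs, y)

    rng = np.random.default_rng(fold_seed)
    folds = None
    for _ in range(10):
        cand = rng.permutation(np.arange(n) % n_folds)
        ok = all(len(np.unique(y[cand != f])) == 2 for f in range(n_folds))
        if ok:
            folds = cand
            break
    if folds is None:
        raise ValueError("could not build folds with both classes in every training set")

    dev = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        tr, va = folds != f, folds == f
        xs_tr, mu_tr, sd_tr = _standardize(x[tr])
        xs_va = (x[va] - mu_tr) / sd_tr
        coefs, icepts = _fit_l1_path(xs_tr, y[tr], lambdas)
        for i in range(len(lambdas)):
            dev[f, i] = _binomial_deviance(xs_va, y[va], coefs[i], icepts[i])

    best = int(np.argmin(dev.mean(axis=0)))
    lambda_min = float(lambdas[best])
    coefs, icepts = _fit_l1_path(xs, y, lambdas[[best]])
    beta_std, b0_std = coefs[0], icepts[0]
    beta = beta_std / sd
    intercept = b0_std - float(np.sum(beta_std * mu / sd))
    out = pd.Series(np.concatenate([[intercept], beta]),
                    index=["intercept", *features.columns])
    return lambda_min, out


@dataclass
class StabilityResult:
    """Per-feature selection probabilities over subsample LASSO fits."""

    selection_probability: pd.Series
    threshold: float
    n_subsamples: int
    subsample_frac: float
    seed: int
    n_redraws: int = 0
    lambda_grid: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def stable_features(self) -> list[str]:
        probs = self.selection_probability
        return list(probs.index[probs > self.threshold])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selection_probability": self.selection_probability.to_dict(),
            "stable_features": self.stable_features,
            "threshold": self.threshold,
            "n_subsamples": self.n_subsamples,
            "subsample_frac": self.subsample_frac,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
        }, indent=2, default=float))


def _first_q_entries(xs, y, q, n_lambda=25):
    """Boolean mask of the first ``q`` features entering the L1 path."""
    grid = _lambda_grid(xs, y, n_lambda=n_lambda, ratio=1e-2)
    coefs, _ = _fit_l1_path(xs, y, grid)
    sel = np.zeros(xs.shape[1], dtype=bool)
    for i in range(n_lambda):
        active = np.abs(coefs[i]) > 1e-10
        if (sel | active).sum() >= q:
            new = np.where(active & ~sel)[0]
            new = new[np.argsort(-np.abs(coefs[i][new]))][: q - sel.sum()]
            sel[new] = True
            break
        sel |= active
    return sel


def stability_selection(features: pd.DataFrame, outcome: pd.Series,
                        n_subsamples: int = 50, subsample_frac: float = 0.5,
                        threshold: float = 0.65, seed: int = 0,
                        q: int | None = None) -> StabilityResult:
    """Selection probability of each feature across half-subsample L1 paths.

    Each seeded subsample is drawn without replacement, stratified by
    outcome.  Per subsample the first ``q`` features to enter the descending
    lambda path count as selected, the convention of subsampling-based
    stability selection; by default
    ``q = ceil(sqrt(0.5 * (2*threshold - 1) * p))`` — the per-family error
    bound at half an expected false selection — so a pure noise feature set
    yields an empty stable set.  The stable set keeps features with
    selection probability strictly above ``threshold``.
    """
    x = features.to_numpy(dtype=float)
    y = outcome.loc[features.index].to_numpy(dtype=int)
    n, p = x.shape
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    size = int(round(subsample_frac * n))
    if size < 2 * min(n0, n1, 2):
        raise ValueError("subsample too small for stratified selection")
    if q is None:
        q = max(2, int(np.ceil(np.sqrt(0.5 * (2 * threshold - 1) * p))))
    q = min(q, p)

    rng = np.random.default_rng(seed)
    idx0, idx1 = np.where(y == 0)[0], np.where(y == 1)[0]
    k1 = int(round(subsample_frac * n1))
    k0 = size - k1
    counts = np.zeros(p)
    n_redraws = 0
    for _ in range(n_subsamples):
        for _attempt in range(10):
            sub = np.concatenate([rng.choice(idx0, k0, replace=False),
                                  rng.choice(idx1, k1, replace=False)])
            if len(np.unique(y[sub])) == 2:
                break
            n_redraws += 1
        xs_sub, _, _ = _standardize(x[sub])
        counts += _first_q_entries(xs_sub, y[sub], q)

    probs = pd.Series(counts / n_subsamples, index=features.columns)
    xs_full, _, _ = _standardize(x)
    grid = _lambda_grid(xs_full, y, ratio=1e-2)
    return StabilityResult(probs, threshold, n_subsamples, subsample_frac,
                           seed, n_redraws, grid)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the trapezoid rule over all thresholds."""
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_ci(scores: np.ndarray, labels: np.ndarray,
              alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with its DeLong (1988) asymptotic confidence interval.

    Returns (auc, lower, upper); the interval is clipped to [0, 1] and
    collapses to the point estimate when the variance is zero (e.g. perfect
    separation).
    """
    labels = np.asarray(labels, dtype=int)
    pos = np.asarray(scores, dtype=float)[labels == 1]
    neg = np.asarray(scores, dtype=float)[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required for AUC")
    all_scores = np.concatenate([pos, neg])
    rk_all = _midrank(all_scores)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rk_all[:m] - rk_pos) / n            # structural components, positives
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m      # negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


@dataclass
class ClassifierEvaluation:
    label: str
    auc: float
    ci_lower: float
    ci_upper: float
    roc: pd.DataFrame
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {"label": self.label, "auc": self.auc, "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper, "n_train": self.n_train,
                "n_test": self.n_test}


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticRegression:
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model


def refit_and_evaluate(features: pd.DataFrame, outcome: pd.Series,
                       splits: pd.Series, stable_features: list[str],
                       covariates: tuple[str, ...] = ("age", "sex", "apoe4_count"),
                       e4_col: str = "apoe4_count") -> dict[str, ClassifierEvaluation]:
    """Unpenalized logistic refits evaluated on a held-out test set.

    Two models: 'stable' (stably selected features plus the APOE e4 allele
    count) and the demographics-only 'baseline' (age + sex + e4).  Both are
    fit on the training split and scored on the disjoint test split with a
    DeLong 95% CI around the trapezoid AUC.
    """
    splits = splits.loc[features.index]
    train_idx = features.index[splits.isin(["train"])]
    test_idx = features.index[splits == "test"]
    if len(train_idx.intersection(test_idx)):
        raise ValueError("train and test splits overlap")
    y_test = outcome.loc[test_idx].to_numpy(dtype=int)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set contains a single class")
    y_train = outcome.loc[train_idx].to_numpy(dtype=int)

    stable_cols = list(dict.fromkeys([*stable_features, e4_col]))
    models = {"stable": stable_cols, "baseline": list(covariates)}
    out = {}
    for label, cols in models.items():
        xs_tr, mu, sd = _standardize(features.loc[train_idx, cols].to_numpy(float))
        model = _fit_logistic(xs_tr, y_train)
        x_te = (features.loc[test_idx, cols].to_numpy(float) - mu) / sd
        scores = model.predict_proba(x_te)[:, 1]
        auc, lo, hi = delong_ci(scores, y_test)
        from sklearn.metrics import roc_curve
        fpr, tpr, thr = roc_curve(y_test, scores)
        roc = pd.DataFrame({"sensitivity": tpr, "specificity": 1 - fpr,
                            "threshold": thr})
        out[label] = ClassifierEvaluation(label, auc, lo, hi, roc,
                                          len(train_idx), len(test_idx))
    return out
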