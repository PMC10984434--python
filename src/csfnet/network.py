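"""Signed weighted co-expression network construction and module detection.

Pipeline: biweight midcorrelation -> signed adjacency ((1+cor)/2)^beta ->
topological overlap matrix -> average-linkage clustering of 1-TOM -> dynamic
hybrid tree cut -> module eigenproteins and kME -> kME-based module merging
(top 50% of members by kME; merge when more than 25% have greater membership
elsewhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._treecut import cutree_hybrid
from .containers import ExpressionMatrix, ModulePartition

__all__ = ["NetworkConfig", "bicor_matrix", "signed_adjacency", "scale_free_fit",
           "tom", "detect_modules", "eigenproteins", "kme", "merge_modules",
           "pick_soft_threshold", "build_network"]


@dataclass
class NetworkConfig:
    beta: int = 12
    min_module_size: int = 15
    deep_split: int = 4
    pam_respects_dendro: bool = True
    merge_top_frac: float = 0.5
    merge_switch_frac: float = 0.25
    scale_free_target_r2: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.merge_top_frac < 1.0 and 0.0 < self.merge_switch_frac < 1.0):
            raise ValueError("merge fractions must lie in (0, 1)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")


def bicor_matrix(data: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Biweight midcorrelation between all protein pairs.

    Tukey biweights ``w = (1 - u^2)^2`` on ``u = (x - median) / (9 MAD)``
    downweight observations far from the column median, making the
    correlation robust to single gross outliers.  Columns with zero MAD fall
    back to Pearson weighting for the pairs that involve them; constant
    columns get correlation 0.
    """
    values = data.values if isinstance(data, ExpressionMatrix) else data
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    if n < 4:
        raise ValueError("bicor requires at least 4 samples")

    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    zero_mad = mad == 0
    if zero_mad.any():
        warnings.warn(f"{int(zero_mad.sum())} column(s) with zero MAD; "
                      "falling back to Pearson for pairs involving them")

    dev = x - med
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
        w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    w = np.nan_to_num(w)
    # Pearson weighting (mean-centered, unit weights) for zero-MAD columns
    dev[:, zero_mad] = x[:, zero_mad] - x[:, zero_mad].mean(axis=0)
    w[:, zero_mad] = 1.0

    g = dev * w
    norm = np.sqrt(np.sum(g * g, axis=0))
    constant = norm == 0
    norm[constant] = 1.0
    g = g / norm
    c = g.T @ g
    c[constant, :] = 0.0
    c[:, constant] = 0.0
    np.clip(c, -1.0, 1.0, out=c)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    cols = values.columns
    return pd.DataFrame(c, index=cols, columns=cols)


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: int = 12) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta with unit diagonal."""
    c = np.asarray(cor, dtype=float)
    a = np.power((1.0 + c) / 2.0, beta)
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray) -> float:
    """Signed R^2 of the log-log connectivity-distribution fit.

    Connectivity k_i is binned into 10 equal-count bins; the log10 frequency
    density per bin (bin count / total / bin width) is regressed on the log10
    mean connectivity per bin.  R^2 is sign-corrected so only decreasing
    (scale-free-like) laws score high; increasing laws return 0.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] < 20:
        raise ValueError("scale_free_fit requires at least 20 nodes")
    k = a.sum(axis=1) - np.diag(a)
    if np.ptp(k) < 1e-12:
        return 0.0
    edges = np.unique(np.quantile(k, np.linspace(0, 1, 11)))
    if len(edges) - 1 < 3:
        raise ValueError("fewer than 3 usable connectivity bins")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    log_k, log_d = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        width = edges[b + 1] - edges[b]
        if width <= 0:
            continue
        density = mask.mean() / width
        mk = k[mask].mean()
        if mk > 0 and density > 0:
            log_k.append(np.log10(mk))
            log_d.append(np.log10(density))
    if len(log_k) < 3:
        raise ValueError("fewer than 3 usable connectivity bins")
    slope, intercept = np.polyfit(log_k, log_d, 1)
    fitted = slope * np.asarray(log_k) + intercept
    ss_res = np.sum((np.asarray(log_d) - fitted) ** 2)
    ss_tot = np.sum((np.asarray(log_d) - np.mean(log_d)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(max(0.0, -np.sign(slope) * r2))


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij the shared-neighbour adjacency product sum; TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    np.clip(t, 0.0, 1.0, out=t)
    return (t + t.T) / 2.0


def detect_modules(tom_matrix: np.ndarray, config: NetworkConfig,
                   protein_ids: pd.Index) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM followed by the dynamic hybrid cut."""
    dissim = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    if dissim.shape[0] < config.min_module_size:
        return ModulePartition(pd.Series(0, index=protein_ids, name="module"))
    link = linkage(squareform(dissim, checks=False), method="average")
    labels = cutree_hybrid(link, dissim, min_size=config.min_module_size,
                           deep_split=config.deep_split,
                           pam_respects_dendro=config.pam_respects_dendro)
    return ModulePartition(pd.Series(labels, index=protein_ids, name="module"))


def eigenproteins(data: ExpressionMatrix,
                  labels: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component summary profile per module.

    Member columns are standardized (mean 0, SD 1); the eigenprotein is the
    unit-norm first left singular vector of the standardized module matrix,
    sign-aligned to correlate non-negatively with the module mean profile.
    Returns (samples x modules scores, proportion of variance explained).
    """
    modules = sorted(int(m) for m in labels.unique() if m != 0)
    scores = {}
    pve = {}
    for m in modules:
        member_ids = labels.index[labels == m]
        x = data.values.loc[:, member_ids].to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
        if np.all(sd == 0):
            raise ValueError(f"module {m} is degenerate (all-constant members)")
        sd[sd == 0] = 1.0
        z = (x - x.mean(axis=0)) / sd
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        ep = u[:, 0]
        mean_profile = z.mean(axis=1)
        if np.dot(ep, mean_profile) < 0:
            ep = -ep
        scores[f"M{m}"] = ep
        pve[f"M{m}"] = float(s[0] ** 2 / np.sum(s ** 2))
    eig = pd.DataFrame(scores, index=data.sample_ids)
    return eig, pd.Series(pve, dtype=float)


def kme(data: ExpressionMatrix, eigen: pd.DataFrame) -> pd.DataFrame:
    """Module membership: Pearson correlation of each protein with each
    eigenprotein. Constant proteins get kME 0."""
    x = data.to_numpy()
    e = eigen.to_numpy(dtype=float)
    xs = x - x.mean(axis=0)
    es = e - e.mean(axis=0)
    xn = np.sqrt(np.sum(xs ** 2, axis=0))
    en = np.sqrt(np.sum(es ** 2, axis=0))
    constant = xn == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant protein(s); kME set to 0")
    xn[constant] = 1.0
    c = (xs / xn).T @ (es / en)
    c[constant, :] = 0.0
    np.clip(c, -1.0, 1.0, out=c)
    return pd.DataFrame(c, index=data.protein_ids, columns=eigen.columns)


def _partition_with_summaries(data: ExpressionMatrix, labels: pd.Series) -> ModulePartition:
    eig, pve = eigenproteins(data, labels)
    return ModulePartition(labels, eig, kme(data, eig), pve)


def _loo_own_kme(data: ExpressionMatrix, labels: pd.Series, module: int) -> pd.Series:
    """kME of each member to its own module's leave-one-out eigenprotein.

    Excluding the protein from the eigenprotein removes the self-correlation
    term that otherwise inflates own-module membership relative to other
    modules, which would suppress legitimate merges.
    """
    members = labels.index[labels == module]
    x = data.values.loc[:, members].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    out = np.empty(len(members))
    for i in range(len(members)):
        rest = np.delete(z, i, axis=1)
        u, _, _ = np.linalg.svd(rest, full_matrices=False)
        ep = u[:, 0]
        if np.dot(ep, rest.mean(axis=1)) < 0:
            ep = -ep
        epc = ep - ep.mean()
        xi = z[:, i]
        out[i] = float(xi @ epc / (np.linalg.norm(xi) * np.linalg.norm(epc)))
    return pd.Series(out, index=members)


def _merge_decision(own_kme: pd.Series, other_kme: pd.DataFrame,
                    module_sizes: dict[int, int], top_frac: float,
                    switch_frac: float) -> int | None:
    """Merge target for one module, or None.

    ``own_kme`` holds each member's membership to its own module,
    ``other_kme`` the members x other-modules kME (columns named ``M<k>``).
    The top ``ceil(top_frac * n)`` members by own kME (ties broken by
    protein id) are examined; the module merges only when strictly more
    than ``switch_frac`` of them have greater membership elsewhere.  The
    target is the plurality best-membership module, ties broken toward the
    larger module, then the smaller label.
    """
    ranked = own_kme.sort_values(ascending=False, kind="stable")
    n_top = int(np.ceil(top_frac * len(own_kme)))
    top = ranked.index[:n_top]
    other = other_kme.loc[top]
    better = other.max(axis=1) > own_kme.loc[top]
    if better.sum() <= switch_frac * n_top:
        return None
    targets = other.loc[better].idxmax(axis=1).str.lstrip("M").astype(int)
    counts = targets.value_counts()
    candidates = counts.index[counts == counts.max()]
    return max(candidates, key=lambda x: (module_sizes.get(int(x), 0), -int(x)))


def merge_modules(partition: ModulePartition, data: ExpressionMatrix,
                  config: NetworkConfig) -> ModulePartition:
    """Merge highly similar modules by the kME membership rule.

    For each module, take the top ``merge_top_frac`` of members ranked by kME
    to the module's own eigenprotein (leave-one-out, so a member's own noise
    does not inflate its membership).  If strictly more than
    ``merge_switch_frac`` of them have greater kME to some other module, the
    module merges into the plurality better-membership target (ties broken
    toward the larger module).  Eigenproteins and kME are recomputed after
    every merge; passes repeat until stable.
    """
    labels = partition.labels.copy()
    while True:
        modules = sorted(int(m) for m in labels.unique() if m != 0)
        if len(modules) < 2:
            break
        sizes = {m: int((labels == m).sum()) for m in modules}
        merged_this_pass = False
        for m in sorted(modules, key=lambda mm: (sizes[mm], mm)):
            current = sorted(int(x) for x in labels.unique() if x != 0)
            if m not in current or len(current) < 2:
                continue
            eig, _ = eigenproteins(data, labels)
            km = kme(data, eig)
            own = _loo_own_kme(data, labels, m)
            other_cols = [f"M{x}" for x in current if x != m]
            module_sizes = {int(c[1:]): int((labels == int(c[1:])).sum())
                            for c in other_cols}
            target = _merge_decision(own, km[other_cols], module_sizes,
                                     config.merge_top_frac, config.merge_switch_frac)
            if target is None:
                continue
            labels.loc[labels == m] = target
            merged_this_pass = True
        if not merged_this_pass:
            break
    # relabel 1..K by decreasing size
    final = sorted((int(m) for m in labels.unique() if m != 0),
                   key=lambda mm: (-(labels == mm).sum(), mm))
    remap = {m: i + 1 for i, m in enumerate(final)}
    labels = labels.map(lambda v: remap.get(int(v), 0))
    return _partition_with_summaries(data, labels)


def pick_soft_threshold(data: ExpressionMatrix,
                        candidate_betas: list[int],
                        target_r2: float = 0.8) -> tuple[pd.DataFrame, int | None]:
    """Scale-free fit and mean connectivity per candidate power; recommends
    the smallest beta whose fit reaches ``target_r2`` (None if none does)."""
    if not candidate_betas:
        raise ValueError("candidate_betas must be non-empty")
    cor = bicor_matrix(data)
    rows = []
    for beta in candidate_betas:
        a = signed_adjacency(cor, beta)
        k = a.sum(axis=1) - 1.0
        rows.append({"beta": beta, "r_squared": scale_free_fit(a),
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r_squared"] >= target_r2]
    recommended = int(ok["beta"].min()) if not ok.empty else None
    return table, recommended


def build_network(data: ExpressionMatrix,
                  config: NetworkConfig | None = None) -> ModulePartition:
    """Full network pass: bicor -> adjacency -> TOM -> modules -> merge."""
    config = config or NetworkConfig()
    cor = bicor_matrix(data)
    adj = signed_adjacency(cor, config.beta)
    t = tom(adj)
    pre = detect_modules(t, config, data.protein_ids)
    if not pre.module_ids:
        return pre
    pre = _partition_with_summaries(data, pre.labels)
    if len(pre.module_ids) < 2:
        return pre
    return merge_modules(pre, data, config)
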