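"""Weighted co-expression network analysis for metabolite profiles.

The WGCNA recipe adapted to metabolomics: variance filtering, soft
threshold selection by scale-free topology fit, signed/unsigned
adjacency, topological overlap (TOM), module detection by average
linkage on TOM dissimilarity with a static tree cut plus eigengene
merging, module eigengenes, and the MM/GS hub-metabolite screen.

``X`` is sample × feature throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "NetworkConfig",
    "ModuleResult",
    "variance_filter",
    "adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "mm_gs_screen",
    "correlation_p",
]

# WGCNA-style module colour names, assigned to modules by decreasing size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
GREY = "grey"


@dataclass
class NetworkConfig:
    keep_top_variance_frac: float = 0.5
    beta_candidates: tuple = tuple(range(1, 21))
    scale_free_target_r2: float = 0.60
    min_module_size: int = 10
    merge_height: float = 0.25
    network_sign: str = "unsigned"
    cut_quantile: float = 0.99

    def __post_init__(self):
        if not (0 < self.keep_top_variance_frac <= 1):
            raise ValueError("keep_top_variance_frac must be in (0, 1]")
        if min(self.beta_candidates) < 1:
            raise ValueError("soft-threshold candidates must be >= 1")
        if not (0 < self.scale_free_target_r2 < 1):
            raise ValueError("scale_free_target_r2 must be in (0, 1)")


@dataclass
class ModuleResult:
    labels: pd.Series               # feature -> module colour ("grey" = unassigned)
    eigengenes: pd.DataFrame        # sample × module
    mm: pd.DataFrame                # feature × module correlations
    mm_p: pd.DataFrame
    gs: pd.Series                   # |cor(feature, trait)|
    gs_p: pd.Series
    module_trait: pd.DataFrame      # module, cor, p
    hubs: pd.Series                 # boolean per feature


def variance_filter(X: pd.DataFrame, frac: float = 0.5) -> pd.DataFrame:
    """Keep the top ``frac`` fraction of features by variance."""
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    k = max(1, int(round(frac * X.shape[1])))
    keep = X.var(axis=0, ddof=1).sort_values(ascending=False).index[:k]
    return X[keep]


def adjacency(X: pd.DataFrame, beta: float, sign: str = "unsigned") -> pd.DataFrame:
    """Soft-threshold adjacency from Pearson correlations, zero diagonal."""
    cor = np.corrcoef(X.to_numpy(float), rowvar=False)
    cor = np.nan_to_num(cor, nan=0.0)
    if sign == "unsigned":
        a = np.abs(cor) ** beta
    elif sign == "signed":
        a = ((1 + cor) / 2) ** beta
    else:
        raise ValueError("sign must be 'unsigned' or 'signed'")
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=X.columns, columns=X.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R² of the log-log connectivity-distribution regression.

    Connectivities are binned; log10 frequency is regressed on log10
    mean connectivity per bin. Returns (signed_r2, slope): positive when
    the slope is negative (scale-free-like decay), negated otherwise.
    """
    k = k[k > 0]
    if len(k) < 3 or np.ptp(k) < 1e-12:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        kb = k[idx == b]
        if len(kb) == 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(len(kb) / len(k)))
    if len(xs) < 3:
        return float("nan"), float("nan")
    res = stats.linregress(xs, ys)
    signed = res.rvalue**2 if res.slope < 0 else -res.rvalue**2
    return float(signed), float(res.slope)


def pick_soft_threshold(
    X: pd.DataFrame,
    candidates=tuple(range(1, 21)),
    target_r2: float = 0.60,
    sign: str = "unsigned",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest soft-threshold exponent reaching the scale-free fit target.

    Returns (beta, fit table). If no candidate reaches ``target_r2``
    the candidate with the highest fit is returned with a warning.
    """
    rows = []
    for beta in candidates:
        a = adjacency(X, beta, sign=sign).to_numpy()
        k = a.sum(axis=0)
        fit, slope = _scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {"beta": beta, "fit_r2": fit, "slope": slope, "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    ok = table[table["fit_r2"] >= target_r2]
    if len(ok):
        beta = int(ok.iloc[0]["beta"])
    else:
        if table["fit_r2"].isna().all():
            warnings.warn("scale-free fit degenerate for every candidate")
            beta = int(table.iloc[0]["beta"])
        else:
            beta = int(table.loc[table["fit_r2"].idxmax(), "beta"])
            warnings.warn(
                f"no candidate reached fit {target_r2}; using beta={beta} "
                f"(best fit {table['fit_r2'].max():.2f})"
            )
    return beta, table


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    TOM_ii = 1. Requires a symmetric adjacency with zero diagonal and
    entries in [0, 1].
    """
    a = adj.to_numpy(float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def module_eigengene(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First-principal-component eigengene per module.

    Each module's standardized feature block is summarized by its first
    PC score, sign-aligned so it correlates positively with the module
    mean profile, and scaled to unit variance. Grey (unassigned)
    features are skipped; a single-feature module yields that feature
    standardized.
    """
    me = {}
    for mod in sorted(set(labels) - {GREY}):
        cols = labels.index[labels == mod]
        block = X[cols].to_numpy(float)
        block = (block - block.mean(axis=0)) / np.where(
            block.std(axis=0, ddof=1) == 0, 1, block.std(axis=0, ddof=1)
        )
        if block.shape[1] == 1:
            score = block[:, 0]
        else:
            u, s, vt = np.linalg.svd(block, full_matrices=False)
            score = u[:, 0] * s[0]
        mean_profile = block.mean(axis=1)
        if np.corrcoef(score, mean_profile)[0, 1] < 0:
            score = -score
        sd = score.std(ddof=1)
        me[mod] = score / (sd if sd > 0 else 1.0)
    return pd.DataFrame(me, index=X.index)


def detect_modules(
    X: pd.DataFrame,
    tom: pd.DataFrame,
    min_size: int = 10,
    merge_height: float = 0.25,
    cut_quantile: float = 0.99,
) -> pd.Series:
    """Module labels from average-linkage clustering of TOM dissimilarity.

    A static cut at ``cut_quantile`` times the dendrogram height
    approximates the dynamic tree cut; clusters below ``min_size``
    become grey. Modules whose eigengene dissimilarity 1 - cor(ME_a,
    ME_b) falls below ``merge_height`` are then merged iteratively.
    Module colours are assigned by decreasing size.
    """
    features = list(tom.index)
    n = len(features)
    if n < min_size:
        warnings.warn("fewer features than min_size; everything is grey")
        return pd.Series(GREY, index=features)
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    h = cut_quantile * float(Z[:, 2].max())
    raw = fcluster(Z, t=h, criterion="distance")
    labels = pd.Series(raw, index=features)
    sizes = labels.value_counts()
    small = sizes[sizes < min_size].index
    labels = labels.where(~labels.isin(small), other=-1)

    def _colourize(lab: pd.Series) -> pd.Series:
        out = pd.Series(GREY, index=lab.index, dtype=object)
        ranked = lab[lab != -1].value_counts().index
        for i, cluster in enumerate(ranked):
            name = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
            out[lab == cluster] = name
        return out

    labels = _colourize(labels)
    if merge_height <= 0:
        return labels
    # iterative eigengene merging
    while True:
        mods = sorted(set(labels) - {GREY})
        if len(mods) < 2:
            break
        me = module_eigengene(X, labels)
        cor = me.corr().to_numpy()
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1 - cor[i, j] >= merge_height:
            break
        a, b = me.columns[i], me.columns[j]
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels = labels.replace(drop, keep)
    return labels


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via t = r sqrt((n-2)/(1-r²))."""
    if n <= 3:
        raise ValueError("need n > 3 for the correlation t-test")
    r = np.clip(np.asarray(r, float), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with the trait."""
    trait = np.asarray(trait, float)
    n = len(trait)
    rows = []
    for mod in eigengenes.columns:
        r = float(np.corrcoef(eigengenes[mod], trait)[0, 1])
        rows.append({"module": mod, "cor": r, "p": float(correlation_p(r, n))})
    return pd.DataFrame(rows).set_index("module")


def mm_gs_screen(
    X: pd.DataFrame,
    labels: pd.Series,
    eigengenes: pd.DataFrame,
    trait,
    mm_min: float = 0.7,
    gs_min: float = 0.2,
    p_max: float = 0.05,
) -> ModuleResult:
    """Hub-metabolite screen on module membership and trait significance.

    MM = cor(feature, own-module eigengene); GS = |cor(feature, trait)|.
    A feature is a hub iff MM > mm_min, GS > gs_min, both correlation
    p-values < p_max, and its module's eigengene-trait correlation is
    itself significant (p < 0.05). The trait is the group indicator
    (case = 1, control = 0) or any numeric phenotype.
    """
    trait = pd.Series(list(trait))
    if trait.dtype == object:
        trait = trait.map(lambda v: {"DD": 1.0, "ND": 0.0}.get(v, v))
    trait = trait.astype(float).to_numpy()
    n = X.shape[0]
    if n <= 3:
        raise ValueError("need more than 3 samples")
    Xv = X.to_numpy(float)
    mm = pd.DataFrame(index=X.columns, columns=eigengenes.columns, dtype=float)
    for mod in eigengenes.columns:
        me = eigengenes[mod].to_numpy()
        mm[mod] = [float(np.corrcoef(Xv[:, j], me)[0, 1]) for j in range(Xv.shape[1])]
    mm_p = pd.DataFrame(
        correlation_p(mm.to_numpy(float), n), index=mm.index, columns=mm.columns
    )
    gs_signed = np.array(
        [float(np.corrcoef(Xv[:, j], trait)[0, 1]) for j in range(Xv.shape[1])]
    )
    gs = pd.Series(np.abs(gs_signed), index=X.columns, name="gs")
    gs_p = pd.Series(correlation_p(gs_signed, n), index=X.columns, name="gs_p")
    mt = module_trait_correlation(eigengenes, trait)
    hubs = pd.Series(False, index=X.columns)
    for f in X.columns:
        mod = labels.get(f, GREY)
        if mod == GREY or mod not in eigengenes.columns:
            continue
        if mt.loc[mod, "p"] >= 0.05:
            continue
        if (
            mm.loc[f, mod] > mm_min
            and gs[f] > gs_min
            and mm_p.loc[f, mod] < p_max
            and gs_p[f] < p_max
        ):
            hubs[f] = True
    return ModuleResult(
        labels=labels, eigengenes=eigengenes, mm=mm, mm_p=mm_p,
        gs=gs, gs_p=gs_p, module_trait=mt, hubs=hubs,
    )
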