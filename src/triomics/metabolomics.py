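"""Untargeted metabolomics statistics.

Internal-standard normalization with RSD filtering, OPLS-DA (orthogonal
projections to latent structures discriminant analysis) fitted by a
NIPALS-style algorithm, cross-validated Q², label-permutation model
validation, VIP (variable importance in projection) scoring, and the
VIP/p two-criterion differential-metabolite screen.

Orientation conventions: abundance tables are feature × sample (as read
from disk); model-fitting functions take ``X`` as sample × feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "OplsModel",
    "normalize_intensities",
    "fit_oplsda",
    "permutation_test",
    "vip_scores",
    "screen_differentials",
]


def normalize_intensities(
    matrix: pd.DataFrame,
    internal_standard_ids: list[str],
    qc_sample_ids: list[str] | None = None,
    rsd_cutoff: float = 0.3,
    qc_rsd_cutoff: float | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Internal-standard (IS) normalization of a feature × sample matrix.

    IS features whose cross-sample relative standard deviation exceeds
    ``rsd_cutoff`` are excluded from the normalizer when at least one
    IS passes; if every IS fails the cutoff, all are used with a
    warning (``strict=True`` raises instead). Each sample's intensities
    are divided by the mean intensity of the retained IS features in
    that sample. With ``qc_sample_ids`` and ``qc_rsd_cutoff`` set,
    features whose QC-sample RSD exceeds the cutoff are dropped
    afterwards.

    Returns the normalized matrix (IS rows removed) and a report of
    dropped features with reasons.
    """
    missing = [i for i in internal_standard_ids if i not in matrix.index]
    if missing:
        raise ValueError(f"internal standards absent from matrix: {missing}")
    is_block = matrix.loc[internal_standard_ids]
    rsd = is_block.std(axis=1, ddof=1) / is_block.mean(axis=1)
    kept_is = rsd[rsd <= rsd_cutoff].index.tolist()
    if not kept_is:
        if strict:
            raise ValueError("all internal standards exceed the RSD cutoff")
        warnings.warn(
            "every internal standard exceeds the RSD cutoff; using all of them"
        )
        kept_is = list(internal_standard_ids)
    dropped = [
        {"feature": f, "reason": f"IS cross-sample RSD {rsd[f]:.3f} > {rsd_cutoff}"}
        for f in internal_standard_ids
        if f not in kept_is
    ]
    normalizer = matrix.loc[kept_is].mean(axis=0)
    out = matrix.drop(index=internal_standard_ids).div(normalizer, axis=1)
    if qc_sample_ids and qc_rsd_cutoff is not None:
        qc = out[qc_sample_ids]
        qc_rsd = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
        bad = qc_rsd[qc_rsd > qc_rsd_cutoff].index
        dropped += [
            {"feature": f, "reason": f"QC RSD {qc_rsd[f]:.3f} > {qc_rsd_cutoff}"}
            for f in bad
        ]
        out = out.drop(index=bad)
    return out, pd.DataFrame(dropped, columns=["feature", "reason"])


@dataclass
class OplsModel:
    """Fitted one-predictive-component OPLS-DA state."""

    features: list[str]
    w: np.ndarray           # predictive weights, unit norm
    t: np.ndarray           # predictive scores (n_samples,)
    p: np.ndarray           # predictive loadings
    q: float                # regression of (centred) y on t
    w_ortho: np.ndarray     # (n_ortho, n_features)
    t_ortho: np.ndarray     # (n_ortho, n_samples)
    p_ortho: np.ndarray     # (n_ortho, n_features)
    r2y: float
    q2: float
    vip: pd.Series
    center: np.ndarray = field(repr=False, default=None)
    scale: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[0]


def _coerce_binary(y) -> np.ndarray:
    """Map group labels (DD/ND or numeric) to a float 0/1 vector."""
    s = pd.Series(list(y))
    if s.dtype == object:
        s = s.map(lambda v: {"DD": 1.0, "ND": 0.0}.get(v, v))
    return s.astype(float).to_numpy()


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    return (X - center) / scale, center, scale


def _opls_core(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """NIPALS OPLS for a single centred response.

    The predictive weight is w ∝ X'y; each orthogonal component removes
    from X the part of the X-loading orthogonal to w.
    """
    Xd = X.copy()
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response carries no signal (X'y = 0)")
    w = w / nw
    w_o_list, t_o_list, p_o_list = [], [], []
    for _ in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            raise ValueError("orthogonal component rank exhausted; lower n_ortho")
        w_o = w_o / n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_o_list.append(w_o)
        t_o_list.append(t_o)
        p_o_list.append(p_o)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    n_feat, n_samp = X.shape[1], X.shape[0]
    w_o = np.array(w_o_list) if w_o_list else np.zeros((0, n_feat))
    t_o = np.array(t_o_list) if t_o_list else np.zeros((0, n_samp))
    p_o = np.array(p_o_list) if p_o_list else np.zeros((0, n_feat))
    return w, t, p, q, w_o, t_o, p_o


def _predict_core(Xc, w, w_ortho, p_ortho, q):
    Xd = Xc.copy()
    for w_o, p_o in zip(w_ortho, p_ortho):
        t_o = Xd @ w_o
        Xd = Xd - np.outer(t_o, p_o)
    return q * (Xd @ w)


def fit_oplsda(
    X: pd.DataFrame,
    y,
    n_ortho: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
) -> OplsModel:
    """Fit OPLS-DA on a sample × feature table against a binary class.

    Features are centred and unit-variance scaled internally (constant
    features are dropped with a warning). R²Y is the fraction of class
    variance explained by the predictive score; Q² is its
    cross-validated counterpart from stratified k-fold PRESS with the
    fold assignment seeded.
    """
    y = _coerce_binary(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("y must be binary")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least two samples per class")
    const = X.columns[X.std(axis=0, ddof=1) == 0]
    if len(const):
        warnings.warn(f"dropping {len(const)} constant feature(s)")
        X = X.drop(columns=const)
    if n_ortho >= min(X.shape) - 1:
        raise ValueError("n_ortho must be below the matrix rank")
    Xv = X.to_numpy(float)
    Xc, center, scale = _autoscale(Xv)
    y_mean = y.mean()
    yc = y - y_mean
    w, t, p, q, w_o, t_o, p_o = _opls_core(Xc, yc, n_ortho)
    y_hat = q * t
    ssy = yc @ yc
    r2y = float(1 - ((yc - y_hat) @ (yc - y_hat)) / ssy)

    # Q2: stratified k-fold cross-validated PRESS
    n_folds = min(cv_folds, int(min(np.sum(y == c) for c in classes)))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    press = 0.0
    sstot = 0.0
    for tr, te in skf.split(Xv, y):
        Xtr, ctr, str_ = _autoscale(Xv[tr])
        ym = y[tr].mean()
        ytr = y[tr] - ym
        try:
            wk, _, _, qk, wok, _, pok = _opls_core(Xtr, ytr, n_ortho)
        except ValueError:
            continue
        Xte = (Xv[te] - ctr) / str_
        pred = _predict_core(Xte, wk, wok, pok, qk) + ym
        press += float(np.sum((y[te] - pred) ** 2))
        sstot += float(np.sum((y[te] - ym) ** 2))
    q2 = float(1 - press / sstot) if sstot > 0 else float("nan")

    vip = pd.Series(np.sqrt(len(X.columns)) * np.abs(w), index=X.columns, name="vip")
    return OplsModel(
        features=list(X.columns),
        w=w, t=t, p=p, q=q,
        w_ortho=w_o, t_ortho=t_o, p_ortho=p_o,
        r2y=r2y, q2=q2, vip=vip,
        center=center, scale=scale, y_mean=y_mean,
    )


def vip_scores(model: OplsModel) -> pd.Series:
    """Per-feature VIP over the predictive component.

    With one predictive component VIP_j = sqrt(n_features) * |w_j| for
    the unit-norm weight vector, so mean(VIP²) = 1 exactly.
    """
    return model.vip


def permutation_test(
    X: pd.DataFrame,
    y,
    n_ortho: int = 1,
    n_perm: int = 200,
    seed: int = 0,
    cv_folds: int = 7,
) -> dict:
    """Label-permutation validation of an OPLS-DA model.

    The class labels are permuted ``n_perm`` times and the model refit;
    p = (1 + #{permuted stat >= observed}) / (n_perm + 1) for both R²Y
    and Q², so p can never reach zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 10:
        warnings.warn("fewer than 10 permutations gives a very coarse p-value")
    rng = np.random.default_rng(seed)
    observed = fit_oplsda(X, y, n_ortho=n_ortho, cv_folds=cv_folds, seed=seed)
    y_arr = _coerce_binary(y)
    perm_rows = []
    for i in range(n_perm):
        yp = rng.permutation(y_arr)
        try:
            m = fit_oplsda(X, yp, n_ortho=n_ortho, cv_folds=cv_folds, seed=seed)
            perm_rows.append({"perm": i, "r2y": m.r2y, "q2": m.q2})
        except ValueError:
            perm_rows.append({"perm": i, "r2y": np.nan, "q2": np.nan})
    table = pd.DataFrame(perm_rows)
    p_r2 = float((1 + (table["r2y"] >= observed.r2y).sum()) / (n_perm + 1))
    p_q2 = float((1 + (table["q2"] >= observed.q2).sum()) / (n_perm + 1))
    return {"model": observed, "p_r2": p_r2, "p_q2": p_q2, "table": table}


def _impute_zeros(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace zero intensities by half the feature's minimum positive value."""
    out = matrix.copy()
    for f in out.index[(out <= 0).any(axis=1)]:
        row = out.loc[f]
        pos = row[row > 0]
        fill = pos.min() / 2 if len(pos) else 1.0
        out.loc[f] = row.where(row > 0, fill)
    return out


def screen_differentials(
    matrix: pd.DataFrame,
    y,
    vip: pd.Series,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    welch: bool = False,
    case_label="DD",
) -> pd.DataFrame:
    """Two-criterion differential-metabolite screen.

    Per feature of the feature × sample ``matrix``: a two-sided Student
    t-test on log2 intensities, fold change = case mean / control mean
    of the normalized intensities, and ``passes_screen`` iff
    VIP > vip_threshold and p < p_threshold. The community uses both a
    lenient (VIP > 1.0) and a strict (VIP > 1.5) cut; the threshold is
    a parameter.
    """
    if vip_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    y = pd.Series(list(y), index=matrix.columns)
    is_case = (y == case_label) if (y == case_label).any() else y.astype(float) == 1
    logm = np.log2(_impute_zeros(matrix))
    case, ctrl = matrix.loc[:, is_case], matrix.loc[:, ~is_case]
    lcase, lctrl = logm.loc[:, is_case.values], logm.loc[:, (~is_case).values]
    tstat, pvals = stats.ttest_ind(
        lcase, lctrl, axis=1, equal_var=not welch
    )
    fc = case.mean(axis=1) / ctrl.mean(axis=1)
    log2fc = np.log2(fc)
    vip_aligned = vip.reindex(matrix.index)
    out = pd.DataFrame(
        {
            "feature": matrix.index,
            "case_mean": case.mean(axis=1).values,
            "control_mean": ctrl.mean(axis=1).values,
            "fold_change": fc.values,
            "log2fc": log2fc.values,
            "t": tstat,
            "p": pvals,
            "vip": vip_aligned.values,
        }
    ).set_index("feature")
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["passes_screen"] = (out["vip"] > vip_threshold) & (out["p"] < p_threshold)
    return out
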