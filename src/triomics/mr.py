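"""Two-sample Mendelian randomization on GWAS summary statistics.

Instrument selection (association p-value and F-statistic), greedy LD
clumping, allele harmonization, Steiger directionality filtering, the
IVW / MR-Egger / weighted-median / simple-mode estimators, and the
sensitivity suite (Cochran's Q, leave-one-out, a seeded PRESSO-style
global outlier test).

Summary tables are pandas DataFrames with columns
``snp, effect_allele, other_allele, eaf, beta, se, pval, n``;
harmonized instruments carry ``beta_exp/se_exp/p_exp`` and
``beta_out/se_out/p_out`` plus the instrument F-statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MrEstimate",
    "select_instruments",
    "ld_clump",
    "harmonize",
    "steiger_filter",
    "ivw",
    "egger",
    "weighted_median",
    "simple_mode",
    "sensitivity_suite",
    "run_mr",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    ancillary: dict = field(default_factory=dict)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


def instrument_f(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Approximate per-SNP instrument strength F = (beta/se)²."""
    return (np.asarray(beta, float) / np.asarray(se, float)) ** 2


def select_instruments(
    exposure: pd.DataFrame, p_thresh: float = 1e-5, f_min: float = 10.0
) -> pd.DataFrame:
    """Keep SNPs associated with the exposure (p < p_thresh) and F > f_min."""
    f = instrument_f(exposure["beta"], exposure["se"])
    keep = (exposure["pval"] < p_thresh) & (f > f_min)
    out = exposure[keep].copy()
    out["F"] = f[keep]
    if out.empty:
        raise ValueError("no instruments pass the selection thresholds")
    return out


def ld_clump(
    candidates: pd.DataFrame,
    ld_matrix: pd.DataFrame | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    positions: pd.Series | None = None,
    ld_is_r: bool = True,
) -> pd.DataFrame:
    """Greedy LD clumping to near-independent instruments.

    SNPs are visited in order of ascending exposure p-value (ties broken
    by SNP ID); a SNP is kept iff its r² with every already-kept SNP
    within ``window_kb`` is below ``r2_max``. ``ld_matrix`` holds
    pairwise correlations r (``ld_is_r=False`` if it already holds r²);
    a missing entry is treated as r² = 0 with a warning. Without
    positions every pair is treated as within-window.
    """
    order = candidates.sort_values(["pval", "snp"]).reset_index(drop=True)
    kept: list[str] = []
    missing_warned = False

    def r2(a: str, b: str) -> float:
        nonlocal missing_warned
        if ld_matrix is None:
            return 0.0
        try:
            v = float(ld_matrix.loc[a, b])
        except KeyError:
            if not missing_warned:
                warnings.warn("missing LD entries treated as r² = 0")
                missing_warned = True
            return 0.0
        return v**2 if ld_is_r else v

    def within_window(a: str, b: str) -> bool:
        if positions is None:
            return True
        return abs(float(positions[a]) - float(positions[b])) <= window_kb * 1_000

    for _, row in order.iterrows():
        snp = row["snp"]
        if all(
            r2(snp, k) < r2_max or not within_window(snp, k) for k in kept
        ):
            kept.append(snp)
    return candidates[candidates["snp"].isin(kept)]


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_window: tuple[float, float] = (0.42, 0.58),
    outcome_p_exclude: float | None = 5e-8,
) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Swapped alleles flip the outcome beta; palindromic SNPs with
    outcome EAF inside ``palindrome_window`` are dropped as ambiguous,
    outside it they are aligned by allele frequency. SNPs already
    associated with the outcome at genome-wide significance
    (p_out < ``outcome_p_exclude``; None disables the step) are removed
    so instruments act through the exposure only. Idempotent.
    """
    exp = exposure.set_index("snp")
    out = outcome.set_index("snp")
    shared = exp.index.intersection(out.index)
    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        oea, ooa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        if (oea, ooa) == (ea, oa):
            pass
        elif (oea, ooa) == (oa, ea):
            beta_out, eaf_out = -beta_out, 1 - eaf_out
        elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(ooa)) == (ea, oa):
            pass  # strand flip, same orientation
        elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(ooa)) == (oa, ea):
            beta_out, eaf_out = -beta_out, 1 - eaf_out
        else:
            log.info("dropping %s: irreconcilable alleles", snp)
            continue
        if _is_palindromic(ea, oa):
            lo, hi = palindrome_window
            if lo < eaf_out < hi or lo < float(e["eaf"]) < hi:
                log.info("dropping palindromic %s with ambiguous EAF", snp)
                continue
            # align by frequency: both EAFs should sit on the same side of 0.5
            if (float(e["eaf"]) - 0.5) * (eaf_out - 0.5) < 0:
                beta_out, eaf_out = -beta_out, 1 - eaf_out
        if outcome_p_exclude is not None and float(o["pval"]) < outcome_p_exclude:
            log.info("dropping %s: associated with the outcome", snp)
            continue
        rows.append(
            {
                "snp": snp,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": float(e["eaf"]),
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "p_exp": float(e["pval"]),
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "p_out": float(o["pval"]),
                "n_exp": int(e["n"]) if "n" in e else np.nan,
                "n_out": int(o["n"]) if "n" in o else np.nan,
            }
        )
    res = pd.DataFrame(rows)
    if not res.empty:
        res["F"] = instrument_f(res["beta_exp"], res["se_exp"])
    return res


def steiger_filter(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep SNPs explaining more variance in exposure than in outcome.

    r² on each side is approximated from the F-statistic as
    F / (F + n - 2); SNPs with r²_exp <= r²_out (including ties) fail.
    Skipped with a warning when sample sizes are unavailable.
    """
    if rows.empty:
        return rows.assign(steiger_ok=pd.Series(dtype=bool))
    if rows["n_exp"].isna().any() or rows["n_out"].isna().any():
        warnings.warn("sample sizes missing; Steiger filtering skipped")
        return rows.assign(steiger_ok=True)
    f_exp = instrument_f(rows["beta_exp"], rows["se_exp"])
    f_out = instrument_f(rows["beta_out"], rows["se_out"])
    r2_exp = f_exp / (f_exp + rows["n_exp"] - 2)
    r2_out = f_out / (f_out + rows["n_out"] - 2)
    out = rows.assign(steiger_ok=(r2_exp > r2_out).values)
    return out[out["steiger_ok"]]


def _weights(rows: pd.DataFrame) -> np.ndarray:
    return (rows["beta_exp"] / rows["se_out"]) ** 2


def _ratios(rows: pd.DataFrame) -> np.ndarray:
    return (rows["beta_out"] / rows["beta_exp"]).to_numpy(float)


def cochran_q(rows: pd.DataFrame, beta: float) -> tuple[float, int, float]:
    w = _weights(rows).to_numpy(float)
    q = float(np.sum(w * (_ratios(rows) - beta) ** 2))
    df = len(rows) - 1
    return q, df, float(stats.chi2.sf(q, df)) if df > 0 else 1.0


def ivw(rows: pd.DataFrame, model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted estimate of the causal effect.

    beta = Σ(βx βy / se_y²) / Σ(βx² / se_y²) — identical to
    weighted least squares of βy on βx through the origin with weights
    1/se_y². The multiplicative random-effects standard error inflates
    the fixed-effect one by sqrt(max(1, Q/(k−1))).
    """
    if len(rows) < 2:
        raise ValueError("IVW needs >= 2 instruments; use a Wald ratio for one")
    bx = rows["beta_exp"].to_numpy(float)
    by = rows["beta_out"].to_numpy(float)
    se = rows["se_out"].to_numpy(float)
    w = bx**2 / se**2
    beta = float(np.sum(bx * by / se**2) / np.sum(w))
    se_fixed = float(np.sqrt(1 / np.sum(w)))
    q, df, q_p = cochran_q(rows, beta)
    if model == "multiplicative_random":
        se_beta = se_fixed * float(np.sqrt(max(1.0, q / df))) if df > 0 else se_fixed
    elif model == "fixed":
        se_beta = se_fixed
    else:
        raise ValueError("model must be 'fixed' or 'multiplicative_random'")
    p = float(2 * stats.norm.sf(abs(beta / se_beta)))
    return MrEstimate(
        method="IVW", beta=beta, se=se_beta, p=p, n_snps=len(rows),
        ancillary={"cochran_Q": q, "Q_df": df, "Q_p": q_p, "se_fixed": se_fixed},
    )


def egger(rows: pd.DataFrame) -> MrEstimate:
    """MR-Egger regression: weighted fit of βy on βx with an intercept.

    Exposure effects are oriented positive first; a nonzero intercept
    indicates directional pleiotropy. Standard errors use the residual
    scale floored at 1 (multiplicative random-effects convention), with
    t-distribution p-values on k − 2 df.
    """
    if len(rows) < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    sign = np.sign(rows["beta_exp"].to_numpy(float))
    sign[sign == 0] = 1
    bx = rows["beta_exp"].to_numpy(float) * sign
    by = rows["beta_out"].to_numpy(float) * sign
    w = 1.0 / rows["se_out"].to_numpy(float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ WX)
    coef = xtx_inv @ (WX.T @ by)
    resid = by - X @ coef
    k = len(rows)
    scale = max(1.0, float(np.sum(w * resid**2) / (k - 2)))
    cov = xtx_inv * scale
    se_int, se_slope = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se_slope
    t_int = coef[0] / se_int
    p_slope = float(2 * stats.t.sf(abs(t_slope), df=k - 2))
    p_int = float(2 * stats.t.sf(abs(t_int), df=k - 2))
    return MrEstimate(
        method="Egger", beta=float(coef[1]), se=float(se_slope), p=p_slope,
        n_snps=k,
        ancillary={
            "egger_intercept": float(coef[0]),
            "egger_intercept_se": float(se_int),
            "egger_intercept_p": p_int,
        },
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    rows: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median causal estimate (valid if >50% of weight is valid).

    Per-SNP Wald ratios are weighted by the inverse of their first-order
    variance se_y²/βx²; the standard error comes from a seeded
    parametric bootstrap.
    """
    if len(rows) < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    bx = rows["beta_exp"].to_numpy(float)
    by = rows["beta_out"].to_numpy(float)
    se_x = rows["se_exp"].to_numpy(float)
    se_y = rows["se_out"].to_numpy(float)
    ratios = by / bx
    weights = bx**2 / se_y**2
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * se_x
        bys = by + rng.standard_normal(len(by)) * se_y
        boots[i] = _weighted_median(bys / bxs, bxs**2 / se_y**2)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    return MrEstimate(method="weighted_median", beta=beta, se=se, p=p, n_snps=len(rows))


def simple_mode(
    rows: pd.DataFrame, n_boot: int = 1000, seed: int = 0, bandwidth_factor: float = 1.0
) -> MrEstimate:
    """Mode of the Wald-ratio density (Gaussian kernel, Silverman rule × φ)."""
    if len(rows) < 3:
        raise ValueError("simple mode needs >= 3 instruments")
    ratios = _ratios(rows)

    def _mode(vals: np.ndarray) -> float:
        if np.ptp(vals) < 1e-12:
            return float(vals[0])
        kde = stats.gaussian_kde(vals, bw_method="silverman")
        kde.set_bandwidth(kde.factor * bandwidth_factor)
        grid = np.linspace(vals.min(), vals.max(), 512)
        return float(grid[np.argmax(kde(grid))])

    beta = _mode(ratios)
    rng = np.random.default_rng(seed)
    bx = rows["beta_exp"].to_numpy(float)
    by = rows["beta_out"].to_numpy(float)
    se_x = rows["se_exp"].to_numpy(float)
    se_y = rows["se_out"].to_numpy(float)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * se_x
        bys = by + rng.standard_normal(len(by)) * se_y
        boots[i] = _mode(bys / bxs)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    return MrEstimate(method="simple_mode", beta=beta, se=se, p=p, n_snps=len(rows))


def presso_global(
    rows: pd.DataFrame, n_sim: int = 1000, seed: int = 0
) -> float:
    """Seeded global outlier test in the PRESSO spirit.

    The observed weighted residual sum of squares around the IVW fit is
    compared with its distribution under a no-outlier model in which
    outcome effects are resampled as N(beta_IVW · βx, se_y²); the
    empirical p uses the +1 correction. The distortion/outlier
    sub-tests of the original procedure are not included.
    """
    est = ivw(rows)
    bx = rows["beta_exp"].to_numpy(float)
    by = rows["beta_out"].to_numpy(float)
    se = rows["se_out"].to_numpy(float)
    w = bx**2 / se**2

    def rss(b_out: np.ndarray) -> float:
        beta = float(np.sum(bx * b_out / se**2) / np.sum(bx**2 / se**2))
        return float(np.sum(w * (b_out / bx - beta) ** 2))

    obs = rss(by)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_sim)
    for i in range(n_sim):
        sims[i] = rss(est.beta * bx + rng.standard_normal(len(bx)) * se)
    return float((1 + np.sum(sims >= obs)) / (n_sim + 1))


def sensitivity_suite(
    rows: pd.DataFrame, seed: int = 0, n_sim: int = 1000, n_boot: int = 500
) -> dict:
    """Heterogeneity, leave-one-out, global-outlier and mode analyses."""
    if len(rows) < 3:
        raise ValueError("sensitivity suite needs >= 3 instruments")
    est = ivw(rows)
    q, df, q_p = est.ancillary["cochran_Q"], est.ancillary["Q_df"], est.ancillary["Q_p"]
    loo_rows = []
    for snp in rows["snp"]:
        sub = rows[rows["snp"] != snp]
        e = ivw(sub)
        loo_rows.append(
            {"dropped_snp": snp, "beta": e.beta, "se": e.se, "p": e.p,
             "shift": abs(e.beta - est.beta)}
        )
    loo = pd.DataFrame(loo_rows)
    return {
        "ivw": est,
        "cochran_Q": q,
        "Q_df": df,
        "Q_p": q_p,
        "leave_one_out": loo,
        "presso_global_p": presso_global(rows, n_sim=n_sim, seed=seed),
        "simple_mode": simple_mode(rows, n_boot=n_boot, seed=seed),
    }


def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld_matrix: pd.DataFrame | None = None,
    positions: pd.Series | None = None,
    p_thresh: float = 1e-5,
    f_min: float = 10.0,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    outcome_p_exclude: float | None = 5e-8,
    seed: int = 0,
) -> dict:
    """Full per-exposure pipeline: select, clump, harmonize, Steiger, estimate.

    Returns the harmonized instrument table plus IVW, Egger and
    weighted-median estimates and the sensitivity suite (methods
    requiring >= 3 instruments are skipped with a log entry when too few
    survive filtering).
    """
    cand = select_instruments(exposure, p_thresh=p_thresh, f_min=f_min)
    cand = ld_clump(cand, ld_matrix, r2_max=r2_max, window_kb=window_kb,
                    positions=positions)
    rows = harmonize(cand, outcome, outcome_p_exclude=outcome_p_exclude)
    rows = steiger_filter(rows)
    if len(rows) < 2:
        raise ValueError("fewer than 2 instruments survive filtering")
    result = {"instruments": rows, "ivw": ivw(rows)}
    if len(rows) >= 3:
        result["egger"] = egger(rows)
        result["weighted_median"] = weighted_median(rows, seed=seed)
        result["sensitivity"] = sensitivity_suite(rows, seed=seed)
    else:
        log.info("fewer than 3 instruments; Egger/median/sensitivity skipped")
    return result
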