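"""Cohort construction for a two-group elderly depression study.

Implements the screening pipeline that turns a community roster into a
matched case/control sample: exclusion filtering, 30-item Geriatric
Depression Scale (GDS) scoring with the >10 clinical cutoff, 1:1
age/sex frequency matching, a normal-approximation sample-size formula,
and a baseline characteristics table (Student t-tests for numeric
variables, Pearson chi-square without continuity correction for
categorical ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POSITIVE_GDS_ITEMS",
    "NEGATIVE_GDS_ITEMS",
    "ParticipantRecord",
    "score_gds",
    "apply_exclusions",
    "match_controls",
    "required_n_per_group",
    "baseline_table",
    "counts_from_percent",
    "chi2_from_percents",
]

# GDS-30 keying: a "yes" on these items scores one point ...
POSITIVE_GDS_ITEMS = frozenset(
    {2, 3, 4, 6, 8, 10, 11, 12, 13, 14, 16, 17, 18, 20, 22, 23, 24, 25, 26, 28}
)
# ... and a "no" on these items scores one point.
NEGATIVE_GDS_ITEMS = frozenset({1, 5, 7, 9, 15, 19, 21, 27, 29, 30})

#: GDS total strictly greater than this marks clinically significant depression.
GDS_CUTOFF = 10


@dataclass
class ParticipantRecord:
    """One roster entry prior to screening.

    ``gds_responses`` holds the 30 yes/no item answers (True = "yes"),
    indexed 0..29 for items 1..30; ``gds_score`` may be supplied
    pre-computed instead.
    """

    id: str
    age: float
    sex: str  # "male" | "female"
    questionnaire_complete: bool = True
    on_antidepressant: bool = False
    has_blood_sample: bool = True
    gds_responses: Sequence[bool] | None = None
    gds_score: int | None = None
    covariates: dict = field(default_factory=dict)

    def score(self) -> int:
        if self.gds_score is not None:
            return int(self.gds_score)
        if self.gds_responses is None:
            raise ValueError(f"participant {self.id}: no GDS responses or score")
        s, _ = score_gds(self.gds_responses)
        return s

    @property
    def depressed(self) -> bool:
        return self.score() > GDS_CUTOFF


def _as_bool(answer) -> bool | None:
    if answer is None:
        return None
    if isinstance(answer, str):
        a = answer.strip().lower()
        if a in {"yes", "y", "1", "true"}:
            return True
        if a in {"no", "n", "0", "false"}:
            return False
        return None
    return bool(answer)


def score_gds(responses: Sequence) -> tuple[int, bool]:
    """Score the 30-item GDS and apply the >10 depression cutoff.

    Parameters
    ----------
    responses
        Exactly 30 yes/no answers (bools or "yes"/"no" strings) in item
        order 1..30.

    Returns
    -------
    (score, depressed)
        ``score`` counts "yes" answers on the 20 positively keyed items
        plus "no" answers on the 10 reverse-keyed items; ``depressed``
        is True iff score > 10.
    """
    responses = list(responses)
    if len(responses) != 30:
        raise ValueError(f"expected 30 GDS responses, got {len(responses)}")
    score = 0
    for item, raw in enumerate(responses, start=1):
        ans = _as_bool(raw)
        if ans is None:
            raise ValueError(f"GDS item {item} is missing or unparseable")
        if item in POSITIVE_GDS_ITEMS:
            score += int(ans)
        else:
            score += int(not ans)
    return score, score > GDS_CUTOFF


#: Exclusion criteria in precedence order: a participant failing several is
#: counted once, under the first criterion in this order.
EXCLUSION_ORDER = (
    ("incomplete_questionnaire", lambda p: not p.questionnaire_complete),
    ("antidepressant_use", lambda p: p.on_antidepressant),
    ("missing_blood_sample", lambda p: not p.has_blood_sample),
)


def apply_exclusions(
    roster: Iterable[ParticipantRecord],
) -> tuple[list[ParticipantRecord], dict[str, int]]:
    """Order-preserving exclusion filter with per-criterion counts."""
    counts = {name: 0 for name, _ in EXCLUSION_ORDER}
    eligible: list[ParticipantRecord] = []
    for p in roster:
        for name, fails in EXCLUSION_ORDER:
            if fails(p):
                counts[name] += 1
                break
        else:
            eligible.append(p)
    return eligible, counts


def match_controls(
    cases: Sequence[ParticipantRecord],
    control_pool: Sequence[ParticipantRecord],
    age_tol_years: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """1:1 frequency matching on sex (exact) and age (± ``age_tol_years``).

    Greedy: each case takes the unused same-sex control with the
    smallest absolute age difference; ties are broken by a seeded
    shuffle of the pool so repeated runs with the same seed are
    identical. Raises if any case has no admissible control left,
    listing every unmatchable case ID.
    """
    case_ids = {c.id for c in cases}
    if case_ids & {c.id for c in control_pool}:
        raise ValueError("control pool overlaps the case list")
    rng = np.random.default_rng(seed)
    pool = list(control_pool)
    rng.shuffle(pool)
    used: set[str] = set()
    pairs: list[dict] = []
    unmatchable: list[str] = []
    for case in cases:
        best = None
        best_gap = None
        for ctrl in pool:
            if ctrl.id in used or ctrl.sex != case.sex:
                continue
            gap = abs(ctrl.age - case.age)
            if gap > age_tol_years:
                continue
            if best is None or gap < best_gap:
                best, best_gap = ctrl, gap
        if best is None:
            unmatchable.append(case.id)
            continue
        used.add(best.id)
        pairs.append(
            {
                "case_id": case.id,
                "control_id": best.id,
                "sex": case.sex,
                "case_age": case.age,
                "control_age": best.age,
                "age_gap": best_gap,
            }
        )
    if unmatchable:
        raise ValueError(
            "no admissible control for case(s): " + ", ".join(unmatchable)
        )
    return pd.DataFrame(pairs)


def required_n_per_group(
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tail: str = "two",
) -> int:
    """Per-group sample size for a two-sample comparison of means.

    Normal approximation: ``n = ceil(2 (z_{1-a/tails} + z_{power})^2 / d^2)``
    with a floor of 2 per group. For d=0.5, alpha=0.05, power=0.80 this
    gives 50 (one-tailed) or 63 (two-tailed).
    """
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    tails = {"one": 1, "two": 2}.get(tail)
    if tails is None:
        raise ValueError("tail must be 'one' or 'two'")
    z_a = stats.norm.ppf(1 - alpha / tails)
    z_b = stats.norm.ppf(power)
    n = ceil(2 * (z_a + z_b) ** 2 / effect_size**2)
    return max(n, 2)


def counts_from_percent(percent: float, n: int) -> int:
    """Reconstruct a count from a printed percentage (nearest integer; lossy)."""
    return int(round(percent * n / 100.0))


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def baseline_table(
    metadata: pd.DataFrame,
    numeric_vars: Sequence[str] = (),
    categorical_vars: Sequence[str] = (),
    group_col: str = "group",
    welch: bool = False,
) -> pd.DataFrame:
    """Group comparison table: t-tests for numeric, chi-square for categorical.

    Numeric variables use a pooled-variance (Student) two-sided t-test by
    default (``welch=True`` switches to Welch); categorical variables use
    Pearson chi-square without continuity correction on the contingency
    table of counts.
    """
    groups = sorted(metadata[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    g1 = metadata[metadata[group_col] == groups[0]]
    g2 = metadata[metadata[group_col] == groups[1]]
    rows = []
    for var in numeric_vars:
        x, y = g1[var].dropna().to_numpy(float), g2[var].dropna().to_numpy(float)
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            warnings.warn(f"{var}: zero variance in both groups; p set to 1")
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=not welch)
            if np.isnan(p):  # identical constant groups edge case
                stat, p = 0.0, 1.0
        rows.append(
            {
                "variable": var,
                "kind": "numeric",
                f"{groups[0]}_summary": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
                f"{groups[1]}_summary": f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
                "test": "welch t" if welch else "student t",
                "statistic": float(stat),
                "p": float(p),
            }
        )
    for var in categorical_vars:
        tab = pd.crosstab(metadata[group_col], metadata[var])
        stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        pct1 = 100 * g1[var].value_counts(normalize=True)
        pct2 = 100 * g2[var].value_counts(normalize=True)
        rows.append(
            {
                "variable": var,
                "kind": "categorical",
                f"{groups[0]}_summary": "; ".join(
                    f"{k}: {v:.1f}%" for k, v in pct1.items()
                ),
                f"{groups[1]}_summary": "; ".join(
                    f"{k}: {v:.1f}%" for k, v in pct2.items()
                ),
                "test": "chi-square",
                "statistic": float(stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def chi2_from_percents(
    pct1: float, pct2: float, n1: int, n2: int
) -> tuple[float, float]:
    """Chi-square p for a binary variable given printed per-group percentages.

    Counts are reconstructed by rounding percentage*n; returns
    (statistic, p) from the 2x2 Pearson chi-square without continuity
    correction.
    """
    a = counts_from_percent(pct1, n1)
    c = counts_from_percent(pct2, n2)
    return _chi2_2x2(a, n1 - a, c, n2 - c)
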