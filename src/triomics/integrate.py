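"""Multi-evidence integration: pool merge, trend flags, pathway tiers.

Merges the three evidence streams (differential metabolites from
LC/GC-MS, co-expression hub metabolites, MR-causal metabolites) into a
high-confidence compound pool with provenance, derives per-pathway
trend flags per stream, and assigns each pathway one of four tiers:

* Class I   — impact >= 0.25, significant in at least two evidence
  streams, significantly enriched in the pooled analysis, and both
  streams showing an internally consistent (non-mixed, non-absent)
  direction;
* Class II  — 0.1 <= impact < 0.25 and significant in the LC/GC-MS or
  MR stream;
* Class III — otherwise significant (minimum p < 0.05);
* Class III* — any stream with internally contradictory hit
  directions, regardless of impact (checked first).

Consistency is judged within each stream: an LC/GC-MS "up" together
with an MR "down" does not disqualify Class I.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "EvidencePool",
    "TierInput",
    "TierResult",
    "build_pool",
    "direction_flags",
    "classify_tier",
    "tier_table",
    "load_tier_fixture",
]

TRENDS = {"up", "down", "mixed", "absent"}
ARROWS = {"up": "↑", "down": "↓", "mixed": "↑↓", "absent": "/"}


@dataclass
class EvidencePool:
    """Merged compound pool with per-member provenance flags."""

    members: dict[str, set[str]]  # compound ID -> subset of {"diff","hub","mr"}
    unmatched: dict[str, list[str]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def ids(self) -> set[str]:
        return set(self.members)


def build_pool(
    diff_ids,
    hub_ids,
    mr_ids,
    mapping=None,
) -> EvidencePool:
    """Union of the three evidence lists, de-duplicated by compound ID.

    Inputs may be metabolite names; with ``mapping`` provided they are
    KEGG-matched first and unmatched entries are reported (never
    silently dropped). The merge is unweighted: membership in several
    streams sets several provenance flags on the same pool entry.
    """
    from .pathways import match_kegg

    streams = {"diff": list(diff_ids), "hub": list(hub_ids), "mr": list(mr_ids)}
    if all(len(v) == 0 for v in streams.values()):
        raise ValueError("all evidence lists are empty")
    members: dict[str, set[str]] = {}
    unmatched: dict[str, list[str]] = {}
    for stream, items in streams.items():
        if mapping is not None:
            matched, missed = match_kegg(items, mapping)
            unmatched[stream] = missed
        else:
            matched = [str(i) for i in items]
        for cid in matched:
            members.setdefault(cid, set()).add(stream)
    return EvidencePool(members=members, unmatched=unmatched)


def _stream_trend(directions: list[str]) -> str:
    known = [d for d in directions if d in {"up", "down"}]
    if not known:
        return "absent"
    if all(d == "up" for d in known):
        return "up"
    if all(d == "down" for d in known):
        return "down"
    return "mixed"


def direction_flags(
    pathway_hits: dict[str, set[str]],
    lcgcms_direction: dict[str, str],
    mr_sign: dict[str, str],
) -> dict[str, dict[str, str]]:
    """Per-pathway, per-stream trend flags.

    ``lcgcms_direction`` maps compound -> "up"/"down" (expression in
    cases vs controls); ``mr_sign`` maps compound -> "up"/"down"
    (positive/negative causal association). A pathway's stream flag is
    "up"/"down" when every hit with a known direction agrees, "mixed"
    when both occur, "absent" when none is known.
    """
    out = {}
    for pid, hits in pathway_hits.items():
        out[pid] = {
            "lcgcms": _stream_trend([lcgcms_direction.get(h, "absent") for h in hits]),
            "mr": _stream_trend([mr_sign.get(h, "absent") for h in hits]),
        }
    return out


@dataclass
class TierInput:
    pathway: str
    impact: float
    pathway_p: float
    enrichment_p: float
    sig_methods: frozenset  # subset of {"LCGCMS", "WGCNA", "MR"}
    pool_enriched: bool
    lcgcms_trend: str = "absent"
    mr_trend: str = "absent"
    super_class: str = ""
    hit_count: int | None = None
    kegg_ids: tuple = ()

    def __post_init__(self):
        if self.impact < 0:
            raise ValueError("impact must be non-negative")
        for t in (self.lcgcms_trend, self.mr_trend):
            if t not in TRENDS:
                raise ValueError(f"unknown trend flag {t!r}")
        self.sig_methods = frozenset(self.sig_methods)


@dataclass
class TierResult:
    tier: str  # "I" | "II" | "III" | "III*" | "unclassified"
    rationale: str


def classify_tier(x: TierInput) -> TierResult:
    """Assign the pathway tier; rules are applied in order, first hit wins."""
    min_p = min(x.pathway_p, x.enrichment_p)
    if x.lcgcms_trend == "mixed" or x.mr_trend == "mixed":
        which = [s for s, t in [("LC/GC-MS", x.lcgcms_trend), ("MR", x.mr_trend)]
                 if t == "mixed"]
        return TierResult(
            "III*",
            f"contradictory hit directions in {' and '.join(which)} "
            f"(impact {x.impact:.2g} not considered)",
        )
    if (
        x.impact >= 0.25
        and len(x.sig_methods) >= 2
        and x.pool_enriched
        and x.lcgcms_trend in {"up", "down"}
        and x.mr_trend in {"up", "down"}
    ):
        return TierResult(
            "I",
            f"impact {x.impact:.2g} >= 0.25, significant in "
            f"{len(x.sig_methods)} methods, pool-enriched, consistent trends",
        )
    if 0.1 <= x.impact < 0.25 and ({"LCGCMS", "MR"} & x.sig_methods):
        return TierResult(
            "II",
            f"impact {x.impact:.2g} in [0.1, 0.25) with LC/GC-MS or MR significance",
        )
    if min_p < 0.05:
        return TierResult("III", f"significant (min p {min_p:.3g} < 0.05)")
    return TierResult("unclassified", "no rule applies; excluded from the tier table")


def tier_table(inputs: list[TierInput]) -> pd.DataFrame:
    """Tiered pathway report, sorted by tier then impact descending."""
    order = {"I": 0, "II": 1, "III": 2, "III*": 3}
    rows = []
    for x in inputs:
        res = classify_tier(x)
        if res.tier == "unclassified":
            continue
        rows.append(
            {
                "tier": res.tier,
                "super_class": x.super_class,
                "pathway": x.pathway,
                "hit_count": x.hit_count,
                "pathway_p": x.pathway_p,
                "enrichment_p": x.enrichment_p,
                "impact": x.impact,
                "kegg_ids": ",".join(x.kegg_ids),
                "lcgcms": ARROWS[x.lcgcms_trend],
                "mr": ARROWS[x.mr_trend],
                "rationale": res.rationale,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["tier", "super_class", "pathway", "hit_count", "pathway_p",
                     "enrichment_p", "impact", "kegg_ids", "lcgcms", "mr", "rationale"]
        )
    df["_o"] = df["tier"].map(order)
    df = df.sort_values(["_o", "impact"], ascending=[True, False]).drop(columns="_o")
    return df.reset_index(drop=True)


def load_tier_fixture() -> tuple[list[TierInput], list[str]]:
    """Bundled worked example: 12 published pathway rows with known tiers.

    Returns (inputs, expected tiers). The fixture encodes each row's
    printed impact, p-values, per-stream trend flags, reconstructed
    method-significance flags and pooled-enrichment flag; p-values
    printed only as "<0.01" are stored as 0.005 (their position
    relative to the 0.05/0.01 rules is all that matters).
    """
    ref = importlib.resources.files("triomics").joinpath("data/table2.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    inputs, expected = [], []
    for _, r in df.iterrows():
        sig = set()
        for m, col in [("LCGCMS", "sig_lcgcms"), ("WGCNA", "sig_wgcna"), ("MR", "sig_mr")]:
            if bool(r[col]):
                sig.add(m)
        inputs.append(
            TierInput(
                pathway=r["pathway"],
                super_class=r["super_class"],
                impact=float(r["impact"]),
                pathway_p=float(r["pathway_p"]),
                enrichment_p=float(r["enrichment_p"]),
                sig_methods=frozenset(sig),
                pool_enriched=bool(r["pool_enriched"]),
                lcgcms_trend=r["lcgcms_trend"],
                mr_trend=r["mr_trend"],
                hit_count=int(r["hit_count"]),
                kegg_ids=tuple(str(r["kegg_ids"]).split(",")),
            )
        )
        expected.append(str(r["level"]))
    return inputs, expected
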