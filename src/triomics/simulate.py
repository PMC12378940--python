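"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (i) two-group log-normal metabolite abundance tables with
planted differential features and planted correlated feature blocks,
(ii) exposure/outcome GWAS summary-statistic pairs with a planted
causal effect, tunable instrument strength, optional directional
pleiotropy and a block-diagonal AR(1) LD structure, (iii) a toy pathway
database (membership sets, graphs, name-to-ID mapping), and (iv) a
screening roster for the cohort stage.

All randomness flows from one integer seed per generator via
``numpy.random.SeedSequence`` spawning, so fixed seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import NEGATIVE_GDS_ITEMS, ParticipantRecord
from .pathways import PathwayDb

__all__ = [
    "MetabolomeTruth",
    "GwasTruth",
    "generate_metabolome",
    "generate_gwas_pair",
    "ar1_ld_matrix",
    "generate_pathway_db",
    "generate_roster",
    "gds_responses_for_score",
]


@dataclass
class MetabolomeTruth:
    """Planted structure of a synthetic metabolome.

    ``effect_size`` is the standardized mean difference (Cohen's d on
    the log scale) added to ``diff_features`` in the case group;
    ``module_blocks`` lists disjoint correlated feature blocks with
    target within-block correlation ``block_cor`` (one-factor model:
    r = λ² with λ = sqrt(block_cor)).
    """

    diff_features: frozenset = frozenset()
    effect_size: float = 1.0
    module_blocks: dict = field(default_factory=dict)
    block_cor: float = 0.8

    def __post_init__(self):
        if not (0 <= self.block_cor < 1):
            raise ValueError("block_cor must lie in [0, 1)")
        seen: set[str] = set()
        for label, members in self.module_blocks.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(
                    f"block {label!r} overlaps another block: {sorted(overlap)}"
                )
            seen |= set(members)
        self.diff_features = frozenset(self.diff_features)


def feature_ids(n_features: int) -> list[str]:
    return [f"met{i + 1:04d}" for i in range(n_features)]


def sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def gds_responses_for_score(score: int, rng: np.random.Generator) -> list[bool]:
    """A random 30-item yes/no vector scoring exactly ``score``."""
    if not (0 <= score <= 30):
        raise ValueError("GDS score must lie in 0..30")
    scoring_items = set(rng.choice(np.arange(1, 31), size=score, replace=False))
    responses = []
    for item in range(1, 31):
        scores_point = item in scoring_items
        if item in NEGATIVE_GDS_ITEMS:
            responses.append(not scores_point)  # "no" scores on reverse-keyed items
        else:
            responses.append(scores_point)
    return responses


def generate_metabolome(
    n_per_group: int,
    n_features: int,
    truth: MetabolomeTruth | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group log-normal abundance matrix plus sample metadata.

    Log intensities are standard Gaussian with a one-factor correlation
    structure inside each planted block (loading sqrt(block_cor)) and
    an ``effect_size``-SD upward shift of the planted differential
    features in the case (DD) group, then exponentiated around a
    per-feature baseline. Returns (feature × sample abundance table,
    metadata with group/age/sex/GDS score).
    """
    truth = truth or MetabolomeTruth(diff_features=frozenset(), module_blocks={})
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    feats = feature_ids(n_features)
    feat_set = set(feats)
    for label, members in truth.module_blocks.items():
        if not set(members) <= feat_set:
            raise ValueError(f"block {label!r} references unknown features")
    if not set(truth.diff_features) <= feat_set:
        raise ValueError("diff_features reference unknown features")

    ss = np.random.SeedSequence(seed)
    rng_z, rng_blocks, rng_base, rng_meta = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    n_samples = 2 * n_per_group
    z = rng_z.standard_normal((n_features, n_samples))
    index = {f: i for i, f in enumerate(feats)}
    lam = np.sqrt(truth.block_cor)
    for members in truth.module_blocks.values():
        factor = rng_blocks.standard_normal(n_samples)
        for f in members:
            noise = rng_blocks.standard_normal(n_samples)
            z[index[f]] = lam * factor + np.sqrt(1 - truth.block_cor) * noise
    case_cols = np.arange(n_per_group)  # first half are cases (DD)
    for f in truth.diff_features:
        z[index[f], case_cols] += truth.effect_size
    baseline = rng_base.uniform(8.0, 12.0, size=n_features)
    abundance = pd.DataFrame(
        np.exp(z + baseline[:, None]), index=feats, columns=sample_ids(n_samples)
    )
    abundance.index.name = "feature"

    groups = ["DD"] * n_per_group + ["ND"] * n_per_group
    ages = np.round(rng_meta.normal(73, 5, size=n_samples).clip(65, 95), 1)
    sexes = rng_meta.choice(["male", "female"], size=n_samples, p=[0.35, 0.65])
    scores = [
        int(rng_meta.integers(11, 26)) if g == "DD" else int(rng_meta.integers(0, 11))
        for g in groups
    ]
    metadata = pd.DataFrame(
        {
            "sample_id": abundance.columns,
            "group": groups,
            "age": ages,
            "sex": sexes,
            "gds_score": scores,
        }
    )
    return abundance, metadata


@dataclass
class GwasTruth:
    """Planted structure of a synthetic exposure→outcome GWAS pair."""

    causal_beta: float = 0.0
    n_instruments: int = 30
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.1    # directional shift on the outcome scale
    pleiotropy_sd: float = 0.01
    ld_matrix: pd.DataFrame | None = None
    f_range: tuple = (20.0, 150.0)  # instrument strength span; (2, 30) for weak

    def __post_init__(self):
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        if self.ld_matrix is not None:
            m = self.ld_matrix.to_numpy(float)
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
                raise ValueError("ld_matrix must be symmetric with unit diagonal")


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def generate_gwas_pair(
    n_snps: int,
    truth: GwasTruth | None = None,
    n_exposure: int = 8_299,
    n_outcome: int = 494_164,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure and outcome summary-statistic tables with known truth.

    Standard errors follow 1/sqrt(2 EAF (1-EAF) n); true exposure
    effects are drawn so the instrument F-statistic spans
    ``truth.f_range``; the outcome effect is causal_beta × true exposure
    effect plus (for a ``pleiotropy_frac`` fraction of SNPs) a
    N(pleiotropy_mean, pleiotropy_sd) direct effect oriented to the
    exposure-increasing allele (so nonzero pleiotropy_mean is
    directional in the MR-Egger sense), plus sampling noise at the
    stated se. Any LD matrix on ``truth`` applies to the clumping step
    only; effect draws are independent across SNPs.
    """
    truth = truth or GwasTruth()
    if n_snps < 3:
        raise ValueError("need at least 3 SNPs")
    if n_exposure <= 0 or n_outcome <= 0:
        raise ValueError("sample sizes must be positive")
    ss = np.random.SeedSequence(seed)
    rng_snp, rng_eff, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]
    snps = [f"rs{i + 1:06d}" for i in range(n_snps)]
    pairs = [_ALLELE_PAIRS[i] for i in rng_snp.integers(0, len(_ALLELE_PAIRS), n_snps)]
    eaf = rng_snp.uniform(0.05, 0.95, n_snps)
    pos = (1 + np.arange(n_snps)) * 500_000  # bp, one chromosome
    se_exp = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * n_exposure)
    f_true = rng_eff.uniform(*truth.f_range, n_snps)
    beta_x = np.sqrt(f_true) * se_exp * rng_eff.choice([-1.0, 1.0], n_snps)
    beta_exp = beta_x + rng_noise.standard_normal(n_snps) * se_exp
    p_exp = 2 * _norm_sf(np.abs(beta_exp / se_exp))

    se_out = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * n_outcome)
    alpha = np.zeros(n_snps)
    n_pleio = int(round(truth.pleiotropy_frac * n_snps))
    if n_pleio:
        idx = rng_eff.choice(n_snps, size=n_pleio, replace=False)
        alpha[idx] = rng_eff.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, n_pleio)
    alpha *= np.sign(beta_x)  # directional relative to the exposure-increasing allele
    beta_out = truth.causal_beta * beta_x + alpha + rng_noise.standard_normal(n_snps) * se_out
    p_out = 2 * _norm_sf(np.abs(beta_out / se_out))

    def table(beta, se, p, n):
        return pd.DataFrame(
            {
                "snp": snps,
                "effect_allele": [a for a, _ in pairs],
                "other_allele": [b for _, b in pairs],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": p,
                "n": n,
                "pos": pos,
            }
        )

    return (
        table(beta_exp, se_exp, p_exp, n_exposure),
        table(beta_out, se_out, p_out, n_outcome),
    )


def _norm_sf(z):
    from scipy.stats import norm

    return norm.sf(z)


def ar1_ld_matrix(block_sizes: list[int], rho: float = 0.8) -> pd.DataFrame:
    """Block-diagonal AR(1) LD correlation matrix (r, unit diagonal).

    SNP IDs follow the ``rs######`` numbering of ``generate_gwas_pair``
    so the matrix can be passed straight to the clumping step.
    """
    n = sum(block_sizes)
    m = np.zeros((n, n))
    start = 0
    for size in block_sizes:
        idx = np.arange(start, start + size)
        lag = np.abs(np.subtract.outer(idx, idx))
        m[start : start + size, start : start + size] = rho**lag
        start += size
    snps = [f"rs{i + 1:06d}" for i in range(n)]
    return pd.DataFrame(m, index=snps, columns=snps)


def generate_pathway_db(
    n_pathways: int,
    size_range: tuple[int, int] = (4, 12),
    graph_model: str = "random_tree",
    seed: int = 0,
    universe_factor: float = 2.0,
) -> tuple[PathwayDb, pd.DataFrame]:
    """Toy pathway database: GMT sets, per-pathway graphs, name mapping.

    Compound IDs follow the KEGG-style ``C#####`` pattern; every set
    member is a node of its pathway graph. ``graph_model`` is one of
    ``path``, ``star``, ``random_tree``. Returns (db, mapping table
    with columns name/kegg_id).
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("pathway sizes must be >= 2")
    if graph_model not in {"path", "star", "random_tree"}:
        raise ValueError(f"unknown graph_model {graph_model!r}")
    rng = np.random.default_rng(seed)
    n_compounds = max(hi, int(universe_factor * n_pathways * (lo + hi) / 2))
    compounds = [f"C{i + 1:05d}" for i in range(n_compounds)]
    sets: dict[str, set[str]] = {}
    graphs: dict[str, nx.Graph] = {}
    names: dict[str, str] = {}
    for p in range(n_pathways):
        pid = f"path{p + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(compounds, size=size, replace=False))
        g = nx.Graph()
        g.add_nodes_from(members)
        if graph_model == "path":
            g.add_edges_from(zip(members[:-1], members[1:]))
        elif graph_model == "star":
            g.add_edges_from((members[0], m) for m in members[1:])
        else:  # random tree: random attachment gives m - 1 edges
            for i in range(1, size):
                j = int(rng.integers(0, i))
                g.add_edge(members[i], members[j])
        sets[pid] = set(members)
        graphs[pid] = g
        names[pid] = f"Toy pathway {p + 1}"
    db = PathwayDb(sets=sets, graphs=graphs, names=names)
    mapping = pd.DataFrame(
        {"name": [f"compound {c[1:]}" for c in compounds], "kegg_id": compounds}
    )
    return db, mapping


def generate_roster(
    n_total: int = 379,
    n_incomplete: int = 8,
    n_antidepressant: int = 2,
    n_no_blood: int = 1,
    n_depressed: int = 49,
    seed: int = 0,
) -> list[ParticipantRecord]:
    """Screening roster with planted exclusion counts and matchable strata.

    The eligible remainder contains exactly ``n_depressed`` participants
    with GDS > 10; each depressed case is guaranteed at least one
    same-sex control within ±3 years among the non-depressed remainder
    so 1:1 matching can always succeed.
    """
    n_excluded = n_incomplete + n_antidepressant + n_no_blood
    n_eligible = n_total - n_excluded
    if n_depressed > n_eligible:
        raise ValueError("more depressed cases than eligible participants")
    rng = np.random.default_rng(seed)
    records: list[ParticipantRecord] = []

    def person(pid, depressed, age=None, sex=None, **flags):
        age = float(age if age is not None else np.round(rng.normal(73, 5), 1))
        age = float(np.clip(age, 65, 95))
        sex = sex or ("male" if rng.random() < 0.35 else "female")
        score = int(rng.integers(11, 26)) if depressed else int(rng.integers(0, 11))
        return ParticipantRecord(
            id=pid, age=age, sex=sex,
            gds_responses=gds_responses_for_score(score, rng), **flags
        )

    cases = [person(f"P{i + 1:03d}", True) for i in range(n_depressed)]
    records.extend(cases)
    k = n_depressed
    # one guaranteed match per case, then free controls
    for case in cases:
        k += 1
        records.append(
            person(f"P{k:03d}", False,
                   age=case.age + rng.uniform(-3, 3), sex=case.sex)
        )
    while k < n_eligible:
        k += 1
        records.append(person(f"P{k:03d}", False))
    for _ in range(n_incomplete):
        k += 1
        records.append(person(f"P{k:03d}", False, questionnaire_complete=False))
    for _ in range(n_antidepressant):
        k += 1
        records.append(person(f"P{k:03d}", False, on_antidepressant=True))
    for _ in range(n_no_blood):
        k += 1
        records.append(person(f"P{k:03d}", False, has_blood_sample=False))
    rng.shuffle(records)
    return records
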