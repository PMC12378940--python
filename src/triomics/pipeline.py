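"""End-to-end orchestration: simulate → cohort → diff → net → mr → pathways → integrate.

Each stage writes plain-text tables into the output directory and logs
its filter counts so the sample-flow (roster → eligible → matched;
features → screened → pool) is auditable. A manifest JSON records the
seed, thresholds, and SHA-256 hashes of every output, making
end-to-end determinism checkable by hash equality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as chort
from . import integrate as integ
from . import metabolomics as mstats
from . import mr as mrmod
from . import network as net
from . import pathways as pw
from . import simulate as sim

__all__ = ["PipelineConfig", "default_config_yaml", "run_all", "validate_inputs"]

log = logging.getLogger("triomics.pipeline")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "triomics_out"
    # simulation sizes
    n_per_group: int = 49
    n_features: int = 300
    n_diff_features: int = 20
    effect_size: float = 1.5
    n_blocks: int = 3
    block_size: int = 15
    block_cor: float = 0.8
    n_exposures: int = 6
    n_snps_per_exposure: int = 40
    n_exposure_gwas: int = 8_299
    n_outcome_gwas: int = 5_000   # desk-scale outcome GWAS; see docs/methods.md
    causal_beta: float = 0.3
    n_pathways: int = 12
    # thresholds (each appears once; see docs/methods.md for rationale)
    vip_threshold: float = 1.0       # VIP cut for the differential screen
    p_threshold: float = 0.05        # univariate t-test cut
    n_permutations: int = 200        # OPLS-DA label permutations
    mm_min: float = 0.7              # module-membership hub cut
    gs_min: float = 0.2              # trait-significance hub cut
    mr_p_instr: float = 1e-5         # instrument association cut
    f_min: float = 10.0              # instrument strength cut
    clump_r2: float = 0.001          # LD pruning r² cut
    window_kb: float = 10_000        # LD pruning window
    mr_p_sig: float = 0.05           # IVW significance cut for the pool
    impact_class1: float = 0.25      # tier rule: Class I impact floor
    impact_class2: float = 0.1       # tier rule: Class II impact floor
    min_module_size: int = 10
    merge_height: float = 0.25
    scale_free_target_r2: float = 0.6
    run_mr_stage: bool = True
    run_net_stage: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise KeyError(f"unknown config key(s): {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def default_config_yaml() -> str:
    return yaml.safe_dump(asdict(PipelineConfig()), sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _seeds(master: int, n: int) -> list[int]:
    """Derive per-stage 31-bit seeds from the master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def validate_inputs(
    abundance: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    gwas: pd.DataFrame | None = None,
) -> dict:
    """Schema checks; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    if abundance is not None:
        if abundance.index.duplicated().any():
            errors.append("duplicate feature IDs in abundance matrix")
        if abundance.columns.duplicated().any():
            errors.append("duplicate sample IDs in abundance matrix")
    if metadata is not None:
        required = {"sample_id", "group"}
        missing = required - set(metadata.columns)
        if missing:
            errors.append(f"metadata missing column(s): {sorted(missing)}")
        else:
            levels = set(metadata["group"].unique())
            if not levels <= {"DD", "ND"}:
                errors.append(f"unknown group label(s): {sorted(levels - {'DD', 'ND'})}")
        if "sex" in metadata.columns:
            bad = set(metadata["sex"].unique()) - {"male", "female"}
            if bad:
                errors.append(f"unknown sex code(s): {sorted(bad)}")
        extra = set(metadata.columns) - {
            "sample_id", "group", "age", "sex", "gds_score",
        } - {f"gds_item{i}" for i in range(1, 31)}
        if extra:
            warnings_.append(f"extra metadata column(s) ignored: {sorted(extra)}")
    if gwas is not None:
        required = {"snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"}
        missing = required - set(gwas.columns)
        if missing:
            errors.append(f"GWAS table missing column(s): {sorted(missing)}")
        elif not gwas["effect_allele"].astype(str).str.upper().isin(list("ACGT")).all():
            errors.append("invalid allele codes in GWAS table")
    return {"errors": errors, "warnings": warnings_}


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on simulated inputs; returns in-memory results.

    Writes per-stage TSVs plus ``manifest.json`` under
    ``config.out_dir``. Identical config and seed reproduce identical
    manifest hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_met, s_gwas, s_db, s_roster, s_fit, s_match = _seeds(config.seed, 6)
    results: dict = {}

    # --- simulate ------------------------------------------------------
    feats = sim.feature_ids(config.n_features)
    blocks = {}
    cursor = config.n_diff_features  # blocks planted after the diff features
    for b in range(config.n_blocks):
        blocks[f"block{b + 1}"] = feats[cursor : cursor + config.block_size]
        cursor += config.block_size
    truth = sim.MetabolomeTruth(
        diff_features=frozenset(feats[: config.n_diff_features]),
        effect_size=config.effect_size,
        module_blocks=blocks,
        block_cor=config.block_cor,
    )
    abundance, metadata = sim.generate_metabolome(
        config.n_per_group, config.n_features, truth, seed=s_met
    )
    db, mapping = sim.generate_pathway_db(config.n_pathways, seed=s_db)
    compounds = sorted(db.universe)
    rng_map = np.random.default_rng(s_db)
    mapped = rng_map.choice(
        compounds, size=min(len(feats), len(compounds)), replace=False
    )
    feat2cpd = dict(zip(feats, mapped))
    abundance.to_csv(out / "abundance.tsv", sep="\t")
    metadata.to_csv(out / "metadata.csv", index=False)
    pw.write_gmt(db.sets, out / "pathways.gmt", names=db.names)
    results["truth"] = truth

    v = validate_inputs(abundance=abundance, metadata=metadata)
    if v["errors"]:
        raise ValueError(f"simulated inputs failed validation: {v['errors']}")

    # --- cohort --------------------------------------------------------
    roster = sim.generate_roster(seed=s_roster)
    eligible, excl = chort.apply_exclusions(roster)
    log.info("roster %d -> eligible %d (excluded %s)", len(roster), len(eligible), excl)
    cases = [p for p in eligible if p.depressed]
    controls = [p for p in eligible if not p.depressed]
    pairs = chort.match_controls(cases, controls, seed=s_match)
    pairs.to_csv(out / "matched_pairs.tsv", sep="\t", index=False)
    baseline = chort.baseline_table(
        metadata, numeric_vars=["age", "gds_score"], categorical_vars=["sex"]
    )
    baseline.to_csv(out / "baseline_table.tsv", sep="\t", index=False)
    results["cohort"] = {
        "n_roster": len(roster), "n_eligible": len(eligible),
        "exclusions": excl, "n_matched": 2 * len(pairs), "baseline": baseline,
    }

    # --- differential screen ------------------------------------------
    X = np.log(abundance).T  # samples × features
    y = metadata.set_index("sample_id").loc[X.index, "group"]
    perm = mstats.permutation_test(
        X, y, n_perm=config.n_permutations, seed=s_fit
    )
    model = perm["model"]
    diff = mstats.screen_differentials(
        abundance, y, model.vip,
        vip_threshold=config.vip_threshold, p_threshold=config.p_threshold,
    )
    diff.to_csv(out / "differential.tsv", sep="\t")
    perm["table"].to_csv(out / "permutations.tsv", sep="\t", index=False)
    diff_hits = diff.index[diff["passes_screen"]].tolist()
    log.info("differential screen: %d / %d features pass", len(diff_hits), len(diff))
    results["diff"] = {
        "model": model, "p_r2": perm["p_r2"], "p_q2": perm["p_q2"],
        "table": diff, "hits": diff_hits,
    }

    # --- co-expression network ----------------------------------------
    hub_feats: list[str] = []
    if config.run_net_stage:
        Xf = net.variance_filter(X, frac=0.5)
        beta, fit_table = net.pick_soft_threshold(
            Xf, target_r2=config.scale_free_target_r2
        )
        adj = net.adjacency(Xf, beta)
        tom = net.tom_similarity(adj)
        labels = net.detect_modules(
            Xf, tom, min_size=config.min_module_size,
            merge_height=config.merge_height,
        )
        me = net.module_eigengene(Xf, labels)
        trait = (y == "DD").astype(float).to_numpy()
        if me.shape[1] > 0:
            mod_res = net.mm_gs_screen(
                Xf, labels, me, trait, mm_min=config.mm_min, gs_min=config.gs_min
            )
            hub_feats = mod_res.hubs.index[mod_res.hubs].tolist()
            assign = pd.DataFrame({"feature": labels.index, "module": labels.values})
            assign["hub"] = assign["feature"].isin(hub_feats)
            assign.to_csv(out / "modules.tsv", sep="\t", index=False)
            results["net"] = {
                "beta": beta, "fit_table": fit_table, "labels": labels,
                "result": mod_res, "hubs": hub_feats,
            }
        fit_table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
        log.info("network: beta=%d, %d hub feature(s)", beta, len(hub_feats))

    # --- Mendelian randomization --------------------------------------
    mr_hits: list[str] = []
    mr_sign: dict[str, str] = {}
    if config.run_mr_stage:
        rng_mr = np.random.default_rng(s_gwas)
        exposure_cpds = [
            str(c) for c in rng_mr.choice(compounds, size=config.n_exposures, replace=False)
        ]
        mr_rows = []
        for i, cpd in enumerate(exposure_cpds):
            causal = config.causal_beta if i % 2 == 0 else 0.0
            exp_t, out_t = sim.generate_gwas_pair(
                config.n_snps_per_exposure,
                sim.GwasTruth(causal_beta=causal),
                n_exposure=config.n_exposure_gwas,
                n_outcome=config.n_outcome_gwas,
                seed=int((s_gwas + 17 * i + 1) % 2**31),
            )
            try:
                res = mrmod.run_mr(
                    exp_t, out_t,
                    p_thresh=config.mr_p_instr, f_min=config.f_min,
                    r2_max=config.clump_r2, window_kb=config.window_kb,
                    seed=s_gwas,
                )
            except ValueError as e:
                log.info("exposure %s skipped: %s", cpd, e)
                continue
            est = res["ivw"]
            mr_rows.append(
                {"exposure": cpd, "method": "IVW", "beta": est.beta,
                 "se": est.se, "p": est.p, "n_snps": est.n_snps,
                 "true_beta": causal}
            )
            if est.p < config.mr_p_sig:
                mr_hits.append(cpd)
                mr_sign[cpd] = "up" if est.beta > 0 else "down"
        mr_table = pd.DataFrame(mr_rows)
        mr_table.to_csv(out / "mr_results.tsv", sep="\t", index=False)
        log.info("MR: %d / %d exposures significant", len(mr_hits), len(mr_rows))
        results["mr"] = {"table": mr_table, "hits": mr_hits}

    # --- evidence pool + pathways -------------------------------------
    diff_cpds = [feat2cpd[f] for f in diff_hits if f in feat2cpd]
    hub_cpds = [feat2cpd[f] for f in hub_feats if f in feat2cpd]
    pool = integ.build_pool(diff_cpds, hub_cpds, mr_hits)
    log.info("evidence pool: %d compounds", pool.size)
    report = pw.pathway_report(pool.ids(), db)
    report.to_csv(out / "pathway_report.tsv", sep="\t")
    results["pool"] = pool
    results["pathways"] = report

    # --- tier classification ------------------------------------------
    lc_dir = {
        feat2cpd[f]: ("up" if diff.loc[f, "log2fc"] > 0 else "down")
        for f in diff_hits if f in feat2cpd
    }
    hits_by_path = {
        pid: set(str(report.loc[pid, "hit_compounds"]).split(";"))
        for pid in report.index
    }
    trends = integ.direction_flags(hits_by_path, lc_dir, mr_sign)

    def _stream_sig(ids) -> set[str]:
        if not ids:
            return set()
        t = pw.enrich(set(ids), db)
        return set(t.index[t["p"] < 0.05])

    sig_lc = _stream_sig(diff_cpds)
    sig_hub = _stream_sig(hub_cpds)
    sig_mr = _stream_sig(mr_hits)
    tier_inputs = []
    for pid in report.index:
        sig = set()
        if pid in sig_lc:
            sig.add("LCGCMS")
        if pid in sig_hub:
            sig.add("WGCNA")
        if pid in sig_mr:
            sig.add("MR")
        tier_inputs.append(
            integ.TierInput(
                pathway=str(report.loc[pid, "name"]),
                impact=float(report.loc[pid, "impact"]),
                pathway_p=float(report.loc[pid, "p"]),
                enrichment_p=float(report.loc[pid, "p"]),
                sig_methods=frozenset(sig),
                pool_enriched=bool(report.loc[pid, "p"] < 0.05),
                lcgcms_trend=trends[pid]["lcgcms"],
                mr_trend=trends[pid]["mr"],
                hit_count=int(report.loc[pid, "hits"]),
            )
        )
    tiers = integ.tier_table(tier_inputs)
    tiers.to_csv(out / "tier_table.tsv", sep="\t", index=False)
    results["tiers"] = tiers

    # --- manifest ------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
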