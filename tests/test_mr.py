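"""Instrument selection, clumping, harmonization, estimators, sensitivity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from triomics import mr
from triomics.simulate import GwasTruth, ar1_ld_matrix, generate_gwas_pair


def _exposure(rows):
    return pd.DataFrame(rows, columns=["snp", "beta", "se", "pval"]).assign(
        effect_allele="A", other_allele="G", eaf=0.3, n=8000
    )


class TestSelection:
    def test_f_and_p_thresholds(self):
        exp = _exposure(
            [
                ("rs1", 0.0317, 0.01, 1e-6),   # F ≈ 10.05 → kept
                ("rs2", 0.0300, 0.01, 1e-6),   # F = 9 → dropped
                ("rs3", 0.0500, 0.01, 2e-5),   # p too large → dropped
            ]
        )
        kept = mr.select_instruments(exp)
        assert list(kept["snp"]) == ["rs1"]

    def test_empty_selection_is_an_error(self):
        exp = _exposure([("rs1", 0.001, 0.01, 0.5)])
        with pytest.raises(ValueError, match="no instruments"):
            mr.select_instruments(exp)


class TestClumping:
    def _cands(self):
        return _exposure(
            [("rs000001", 0.1, 0.01, 1e-8), ("rs000002", 0.1, 0.01, 1e-6)]
        )

    def test_correlated_pair_keeps_lower_p(self):
        ld = pd.DataFrame(
            [[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]],
            index=["rs000001", "rs000002"], columns=["rs000001", "rs000002"],
        )
        kept = mr.ld_clump(self._cands(), ld)
        assert list(kept["snp"]) == ["rs000001"]

    def test_sub_threshold_r2_keeps_both(self):
        r = np.sqrt(0.0005)
        ld = pd.DataFrame(
            [[1.0, r], [r, 1.0]],
            index=["rs000001", "rs000002"], columns=["rs000001", "rs000002"],
        )
        kept = mr.ld_clump(self._cands(), ld)
        assert len(kept) == 2

    def test_distant_pair_ignores_ld(self):
        ld = pd.DataFrame(
            [[1.0, 0.95], [0.95, 1.0]],
            index=["rs000001", "rs000002"], columns=["rs000001", "rs000002"],
        )
        positions = pd.Series(
            {"rs000001": 0.0, "rs000002": 20_000 * 1000.0}  # 20,000 kb apart
        )
        kept = mr.ld_clump(self._cands(), ld, positions=positions)
        assert len(kept) == 2

    def test_ar1_blocks_reduce_to_one_per_block(self):
        exp = _exposure(
            [(f"rs{i + 1:06d}", 0.1, 0.01, 1e-8 * (i + 1)) for i in range(6)]
        )
        ld = ar1_ld_matrix([3, 3], rho=0.9)
        kept = mr.ld_clump(exp, ld, r2_max=0.5)
        assert len(kept) == 2  # the top SNP of each block

    def test_missing_ld_entry_warns(self):
        ld = pd.DataFrame([[1.0]], index=["rs000001"], columns=["rs000001"])
        with pytest.warns(UserWarning, match="LD"):
            kept = mr.ld_clump(self._cands(), ld)
        assert len(kept) == 2


class TestHarmonization:
    def _pair(self, out_ea="A", out_oa="G", out_beta=0.05, out_eaf=0.3, out_p=0.5):
        exp = _exposure([("rs1", 0.1, 0.01, 1e-8)])
        out = pd.DataFrame(
            {
                "snp": ["rs1"], "effect_allele": [out_ea], "other_allele": [out_oa],
                "eaf": [out_eaf], "beta": [out_beta], "se": [0.01],
                "pval": [out_p], "n": [50000],
            }
        )
        return exp, out

    def test_consistent_rows_unchanged(self):
        exp, out = self._pair()
        rows = mr.harmonize(exp, out)
        assert rows.loc[0, "beta_out"] == pytest.approx(0.05)

    def test_swapped_alleles_flip_sign(self):
        exp, out = self._pair(out_ea="G", out_oa="A", out_eaf=0.7)
        rows = mr.harmonize(exp, out)
        assert rows.loc[0, "beta_out"] == pytest.approx(-0.05)

    def test_ambiguous_palindrome_dropped(self):
        exp = _exposure([("rs1", 0.1, 0.01, 1e-8)])
        exp.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        exp.loc[0, "eaf"] = 0.5
        out = pd.DataFrame(
            {
                "snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["T"],
                "eaf": [0.5], "beta": [0.05], "se": [0.01], "pval": [0.5],
                "n": [50000],
            }
        )
        assert mr.harmonize(exp, out).empty

    def test_outcome_associated_snp_excluded(self):
        exp, out = self._pair(out_p=1e-9)
        assert mr.harmonize(exp, out).empty
        assert len(mr.harmonize(exp, out, outcome_p_exclude=None)) == 1

    def test_idempotent_on_aligned_tables(self):
        exp, out = self._pair(out_ea="G", out_oa="A", out_eaf=0.7)
        once = mr.harmonize(exp, out)
        # feed the aligned outcome back through: nothing should change
        realigned_out = pd.DataFrame(
            {
                "snp": once["snp"], "effect_allele": once["effect_allele"],
                "other_allele": once["other_allele"], "eaf": once["eaf"],
                "beta": once["beta_out"], "se": once["se_out"],
                "pval": once["p_out"], "n": once["n_out"],
            }
        )
        twice = mr.harmonize(exp, realigned_out)
        assert np.allclose(once["beta_out"], twice["beta_out"])


class TestSteiger:
    def test_direction_rules(self):
        rows = pd.DataFrame(
            {
                "snp": ["strong", "reversed"],
                "beta_exp": [0.10, 0.003], "se_exp": [0.01, 0.01],
                "beta_out": [0.001, 0.02], "se_out": [0.003, 0.002],
                "n_exp": [8299, 8299], "n_out": [494164, 494164],
            }
        )
        kept = mr.steiger_filter(rows)
        assert list(kept["snp"]) == ["strong"]

    def test_tie_is_dropped(self):
        rows = pd.DataFrame(
            {
                "snp": ["tie"], "beta_exp": [0.1], "se_exp": [0.01],
                "beta_out": [0.1], "se_out": [0.01],
                "n_exp": [10000], "n_out": [10000],
            }
        )
        assert mr.steiger_filter(rows).empty

    def test_missing_n_skips_with_warning(self):
        rows = pd.DataFrame(
            {
                "snp": ["a"], "beta_exp": [0.1], "se_exp": [0.01],
                "beta_out": [0.1], "se_out": [0.01],
                "n_exp": [np.nan], "n_out": [10000],
            }
        )
        with pytest.warns(UserWarning, match="Steiger"):
            kept = mr.steiger_filter(rows)
        assert len(kept) == 1


class TestIvw:
    def test_identical_ratios(self, toy_instruments):
        est = mr.ivw(toy_instruments)
        assert est.beta == pytest.approx(0.2)
        assert est.ancillary["cochran_Q"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_through_origin(self, toy_instruments):
        rows = toy_instruments.copy()
        rows["beta_out"] = [0.03, 0.02, 0.12]  # heterogeneous ratios
        est = mr.ivw(rows)
        wls = sm.WLS(
            rows["beta_out"], rows[["beta_exp"]], weights=1 / rows["se_out"] ** 2
        ).fit()
        assert est.beta == pytest.approx(wls.params.iloc[0], rel=1e-12)

    def test_order_and_weight_scale_invariance(self, toy_instruments):
        est = mr.ivw(toy_instruments)
        shuffled = toy_instruments.sample(frac=1, random_state=1)
        assert mr.ivw(shuffled).beta == pytest.approx(est.beta)
        scaled = toy_instruments.copy()
        scaled["se_out"] *= 3.0  # rescales all weights by 1/9
        assert mr.ivw(scaled).beta == pytest.approx(est.beta)

    def test_random_effects_se_never_below_fixed(self):
        exp_t, out_t = generate_gwas_pair(
            30, GwasTruth(causal_beta=0.1, pleiotropy_frac=0.5),
            n_outcome=5000, seed=3,
        )
        rows = mr.harmonize(
            mr.select_instruments(exp_t), out_t, outcome_p_exclude=None
        )
        fixed = mr.ivw(rows, model="fixed")
        random = mr.ivw(rows, model="multiplicative_random")
        q, df = random.ancillary["cochran_Q"], random.ancillary["Q_df"]
        assert q > df  # heterogeneity planted
        assert random.se >= fixed.se

    def test_single_instrument_rejected(self, toy_instruments):
        with pytest.raises(ValueError, match="Wald"):
            mr.ivw(toy_instruments.iloc[:1])


class TestEgger:
    def test_identical_ratio_toy(self, toy_instruments):
        est = mr.egger(toy_instruments)
        assert est.beta == pytest.approx(0.2)
        assert est.ancillary["egger_intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_shift_moves_intercept_only(self, toy_instruments):
        base = mr.egger(toy_instruments)
        shifted = toy_instruments.copy()
        shifted["beta_out"] += 0.05
        est = mr.egger(shifted)
        assert est.ancillary["egger_intercept"] == pytest.approx(
            base.ancillary["egger_intercept"] + 0.05
        )
        assert est.beta == pytest.approx(base.beta)

    def test_slope_equals_ivw_when_intercept_constrained(self, toy_instruments):
        rows = toy_instruments.copy()
        rows["beta_out"] = [0.03, 0.02, 0.12]
        wls = sm.WLS(
            rows["beta_out"], rows[["beta_exp"]], weights=1 / rows["se_out"] ** 2
        ).fit()  # Egger with the intercept forced to zero
        assert mr.ivw(rows).beta == pytest.approx(wls.params.iloc[0], rel=1e-12)

    def test_too_few_instruments(self, toy_instruments):
        with pytest.raises(ValueError):
            mr.egger(toy_instruments.iloc[:2])


class TestWeightedMedian:
    def test_identical_ratios(self, toy_instruments):
        est = mr.weighted_median(toy_instruments, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_robust_to_minority_outliers(self):
        # 10 valid instruments (ratio 0.3) + 4 outliers (ratio 2.0), equal weights
        k = 14
        rows = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(k)],
                "beta_exp": [0.1] * k,
                "se_exp": [0.01] * k,
                "beta_out": [0.03] * 10 + [0.2] * 4,
                "se_out": [0.01] * k,
            }
        )
        est = mr.weighted_median(rows, n_boot=50, seed=0)
        mean_ratio = np.mean([0.3] * 10 + [2.0] * 4)
        assert abs(est.beta - 0.3) < 0.05
        assert abs(est.beta - mean_ratio) > 0.3

    def test_concentrated_weight_returns_that_ratio(self):
        rows = pd.DataFrame(
            {
                "snp": ["a", "b", "c"],
                "beta_exp": [1.0, 0.01, 0.01],
                "se_exp": [0.01] * 3,
                "beta_out": [0.5, 0.02, 0.03],
                "se_out": [0.001, 10.0, 10.0],  # weight ~ all on SNP a
            }
        )
        est = mr.weighted_median(rows, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-6)


class TestSensitivity:
    def test_homogeneous_rows(self, toy_instruments):
        sens = mr.sensitivity_suite(toy_instruments, seed=0, n_sim=200, n_boot=50)
        assert sens["cochran_Q"] == pytest.approx(0.0, abs=1e-12)
        assert sens["Q_p"] == pytest.approx(1.0)
        assert np.allclose(sens["leave_one_out"]["beta"], 0.2)

    def test_q_matches_direct_sum_oracle(self):
        exp_t, out_t = generate_gwas_pair(
            25, GwasTruth(causal_beta=0.2), n_outcome=5000, seed=4
        )
        rows = mr.harmonize(mr.select_instruments(exp_t), out_t)
        est = mr.ivw(rows)
        w = (rows["beta_exp"] / rows["se_out"]) ** 2
        ratios = rows["beta_out"] / rows["beta_exp"]
        q_oracle = float(np.sum(w * (ratios - est.beta) ** 2))
        assert est.ancillary["cochran_Q"] == pytest.approx(q_oracle, abs=1e-10)

    def test_gross_outlier_flagged_by_loo_and_presso(self):
        exp_t, out_t = generate_gwas_pair(
            20, GwasTruth(causal_beta=0.2), n_outcome=5000, seed=42
        )
        rows = mr.harmonize(
            mr.select_instruments(exp_t), out_t, outcome_p_exclude=None
        ).reset_index(drop=True)
        rows.loc[0, "beta_out"] = rows.loc[0, "beta_exp"] * 2.0
        sens = mr.sensitivity_suite(rows, seed=5, n_sim=500, n_boot=50)
        loo = sens["leave_one_out"]
        assert loo.loc[loo["shift"].idxmax(), "dropped_snp"] == rows.loc[0, "snp"]
        assert sens["presso_global_p"] < 0.05

    def test_simple_mode_tracks_majority_ratio(self):
        rows = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(12)],
                "beta_exp": [0.1] * 12,
                "se_exp": [0.001] * 12,
                "beta_out": [0.030, 0.031, 0.029, 0.030, 0.032, 0.028,
                             0.031, 0.029, 0.2, 0.15, 0.030, 0.031],
                "se_out": [0.01] * 12,
            }
        )
        est = mr.simple_mode(rows, n_boot=50, seed=0)
        assert abs(est.beta - 0.3) < 0.05


class TestFullRun:
    def test_run_mr_end_to_end(self):
        exp_t, out_t = generate_gwas_pair(
            40, GwasTruth(causal_beta=0.25), n_outcome=5000, seed=8
        )
        res = mr.run_mr(exp_t, out_t, seed=8)
        est = res["ivw"]
        assert abs(est.beta - 0.25) < 3 * est.se
        assert {"egger", "weighted_median", "sensitivity"} <= set(res)
        assert (res["instruments"]["F"] > 10).all()
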