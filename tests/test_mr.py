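import numpy as np
import pandas as pd
import pytest

from crossgwas import mr
from crossgwas.loci import LdMatrix
from crossgwas.synthetic import sim_instruments


def _inst(rows):
    return pd.DataFrame(rows, columns=[
        "snp", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp",
        "eaf_out", "f_stat"])


def _simple(ratios, se=0.1, bx=0.2):
    return _inst([(f"iv{i}", bx, 0.01, r * bx, se * bx, 0.3, 0.3,
                   (bx / 0.01) ** 2) for i, r in enumerate(ratios)])


class TestSelectInstruments:
    def _exposure(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p", "beta",
                                           "se", "ea", "oa", "eaf"])

    def test_strong_instrument_retained(self):
        exp = self._exposure([("rs1", "1", 100, 1e-7, 0.1, 0.02, "A", "G", 0.3)])
        out = mr.select_instruments(exp, LdMatrix(), "forward")
        assert list(out["snp"]) == ["rs1"]
        assert out["f_stat"].iloc[0] == pytest.approx(25.0)

    def test_weak_instrument_dropped_at_f_boundary(self):
        exp = self._exposure([("rs1", "1", 100, 1e-7, 0.03, 0.01, "A", "G", 0.3)])
        out = mr.select_instruments(exp, LdMatrix(), "forward")
        assert len(out) == 0  # F = 9, below the strict F > 10 floor

    def test_reverse_exclusion_set_applies(self):
        exp = self._exposure([("rs1", "1", 100, 1e-9, 0.1, 0.01, "A", "G", 0.3)])
        out = mr.select_instruments(exp, LdMatrix(), "reverse",
                                    exclude={"rs1"})
        assert len(out) == 0

    def test_direction_thresholds_differ(self):
        # p = 3e-6 passes forward (1e-5) and reverse (5e-6) thresholds;
        # p = 3e-5 passes neither
        exp = self._exposure([("rs1", "1", 100, 3e-6, 0.1, 0.01, "A", "G", 0.3),
                              ("rs2", "2", 100, 3e-5, 0.1, 0.01, "A", "G", 0.3)])
        fwd = mr.select_instruments(exp, LdMatrix(), "forward")
        rev = mr.select_instruments(exp, LdMatrix(), "reverse")
        assert list(fwd["snp"]) == ["rs1"] and list(rev["snp"]) == ["rs1"]


class TestHarmonize:
    def _exp(self, ea="A", oa="G", eaf=0.3):
        return pd.DataFrame([("rs1", 0.2, 0.02, 1e-8, ea, oa, eaf, 100.0)],
                            columns=["snp", "beta", "se", "p", "ea", "oa",
                                     "eaf", "f_stat"])

    def _out(self, ea="A", oa="G", beta=0.1, eaf=0.3):
        return pd.DataFrame([("rs1", beta, 0.05, ea, oa, eaf)],
                            columns=["snp", "beta", "se", "ea", "oa", "eaf"])

    def test_matched_alleles_unchanged(self):
        h = mr.harmonize(self._exp(), self._out())
        assert h["beta_out"].iloc[0] == pytest.approx(0.1)

    def test_swapped_alleles_negate_outcome(self):
        h = mr.harmonize(self._exp(), self._out(ea="G", oa="A", eaf=0.7))
        assert h["beta_out"].iloc[0] == pytest.approx(-0.1)
        assert h["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_palindromic_ambiguous_frequency_dropped(self):
        h = mr.harmonize(self._exp(ea="A", oa="T", eaf=0.5),
                         self._out(ea="A", oa="T", eaf=0.5))
        assert len(h) == 0

    def test_palindromic_clear_frequency_kept(self):
        h = mr.harmonize(self._exp(ea="A", oa="T", eaf=0.1),
                         self._out(ea="A", oa="T", eaf=0.1))
        assert len(h) == 1

    def test_missing_outcome_snp_dropped(self):
        out = self._out()
        out["snp"] = ["rsOTHER"]
        assert len(mr.harmonize(self._exp(), out)) == 0


class TestIvw:
    def test_single_instrument_ratio_identity(self):
        inst = _inst([("iv1", 0.2, 0.01, 0.1, 0.02, 0.3, 0.3, 400.0)])
        est = mr.ivw(inst)
        assert est.beta == pytest.approx(0.5)

    def test_identical_ratios_q_zero(self):
        inst = _simple([0.5, 0.5])
        est = mr.ivw(inst)
        q, _ = mr.cochran_q(inst, est.beta)
        assert est.beta == pytest.approx(0.5) and q == pytest.approx(0.0)

    def test_equal_weights_equal_unweighted_mean(self):
        inst = _simple([0.1, 0.4, 0.7])
        est = mr.ivw(inst)
        assert est.beta == pytest.approx(np.mean([0.1, 0.4, 0.7]))

    def test_or_and_ci_consistent_with_beta(self):
        inst = _simple([0.5, 0.52, 0.48])
        est = mr.ivw(inst)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low == pytest.approx(np.exp(est.beta - 1.959964 * est.se))
        assert est.ci_high == pytest.approx(np.exp(est.beta + 1.959964 * est.se))

    def test_recovers_planted_causal_effect(self):
        inst = sim_instruments(50, 0.3, seed=7)
        est = mr.ivw(inst)
        assert abs(est.beta - 0.3) <= 2 * est.se

    def test_zero_exposure_effect_instrument_excluded(self):
        inst = _inst([("iv1", 0.0, 0.01, 0.1, 0.02, 0.3, 0.3, 0.0),
                      ("iv2", 0.2, 0.01, 0.1, 0.02, 0.3, 0.3, 400.0)])
        assert mr.ivw(inst).n_snps == 1


class TestEgger:
    def test_exact_linear_fixture(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inst = _inst([(f"iv{i}", x, 0.01, 0.02 + 0.4 * x, 0.05, 0.3, 0.3, 1.0)
                      for i, x in enumerate(bx)])
        slope, icpt, _se, _p = mr.egger(inst)
        assert slope.beta == pytest.approx(0.4, abs=1e-12)
        assert icpt == pytest.approx(0.02, abs=1e-12)

    def test_zero_intercept_fixture(self):
        bx = np.array([0.1, 0.2, 0.3])
        inst = _inst([(f"iv{i}", x, 0.01, 0.4 * x, 0.05, 0.3, 0.3, 1.0)
                      for i, x in enumerate(bx)])
        _slope, icpt, _se, _p = mr.egger(inst)
        assert icpt == pytest.approx(0.0, abs=1e-14)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr.egger(_simple([0.5, 0.5]))

    def test_agrees_with_statsmodels_wls(self):
        import statsmodels.api as sm

        inst = sim_instruments(20, 0.25, seed=3, pleiotropy_sd=0.02)
        slope, icpt, icpt_se, icpt_p = mr.egger(inst)
        bx = np.abs(inst["beta_exp"].to_numpy())
        by = inst["beta_out"].to_numpy() * np.sign(inst["beta_exp"])
        w = 1.0 / inst["se_out"].to_numpy() ** 2
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert slope.beta == pytest.approx(fit.params.iloc[1], rel=1e-10)
        assert icpt == pytest.approx(fit.params.iloc[0], rel=1e-10)
        assert icpt_se == pytest.approx(fit.bse.iloc[0], rel=1e-8)
        assert icpt_p == pytest.approx(fit.pvalues.iloc[0], rel=1e-8)

    def test_intercept_type_i_error_nominal(self):
        """Under balanced pleiotropy, the intercept test rejects at ~5%."""
        rej = 0
        reps = 500
        for r in range(reps):
            inst = sim_instruments(30, 0.2, seed=20_000 + r, se_exp=0.001,
                                   se_out=0.01, pleiotropy_sd=0.01)
            _, _, _, p = mr.egger(inst)
            rej += p < 0.05
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= 2 * mc_se


class TestWeightedMedian:
    def test_identical_ratios(self):
        est = mr.weighted_median(_simple([0.4, 0.4, 0.4]))
        assert est.beta == pytest.approx(0.4)

    def test_plain_median_with_equal_weights(self):
        est = mr.weighted_median(_simple([0.1, 0.5, 0.9]))
        assert est.beta == pytest.approx(0.5)

    def test_robust_to_outlier_contamination(self):
        rng = np.random.default_rng(31)
        n = 30
        bx = rng.uniform(0.1, 0.3, n)
        ratios = np.full(n, 0.3) + rng.normal(0, 0.02, n)
        ratios[:9] = 5.0  # 30% contamination
        inst = _inst([(f"iv{i}", bx[i], 0.01, ratios[i] * bx[i], 0.02 * bx[i],
                       0.3, 0.3, 1.0) for i in range(n)])
        wm = mr.weighted_median(inst, seed=1)
        iv = mr.ivw(inst)
        assert abs(wm.beta - 0.3) <= 2 * wm.se
        assert iv.beta > 0.3 + 4 * wm.se  # IVW dragged upward

    def test_seeded_bootstrap_reproducible(self):
        inst = _simple([0.2, 0.5, 0.8, 0.3])
        a = mr.weighted_median(inst, seed=5)
        b = mr.weighted_median(inst, seed=5)
        assert a.se == b.se


class TestCochranQAndLoo:
    def test_two_ratio_hand_value(self):
        # ratios 0.1 and 0.3 with ratio-scale SEs 0.1 each -> Q = 2
        inst = _inst([("a", 1.0, 0.01, 0.1, 0.1, 0.3, 0.3, 1.0),
                      ("b", 1.0, 0.01, 0.3, 0.1, 0.3, 0.3, 1.0)])
        est = mr.ivw(inst)
        q, q_p = mr.cochran_q(inst, est.beta)
        assert q == pytest.approx(2.0)

    def test_q_over_df_near_one_under_homogeneity(self):
        rng = np.random.default_rng(41)
        qs = []
        for r in range(300):
            inst = sim_instruments(20, 0.2, seed=40_000 + r, se_exp=0.001,
                                   se_out=0.01)
            est = mr.ivw(inst)
            q, _ = mr.cochran_q(inst, est.beta)
            qs.append(q / 19)
        assert abs(np.mean(qs) - 1.0) < 0.05

    def test_loo_with_two_instruments_swaps_ratios(self):
        inst = _inst([("a", 0.2, 0.01, 0.08, 0.02, 0.3, 0.3, 1.0),
                      ("b", 0.2, 0.01, 0.12, 0.02, 0.3, 0.3, 1.0)])
        loo, _ = mr.leave_one_out(inst)
        assert loo.set_index("snp").loc["a", "beta"] == pytest.approx(0.6)
        assert loo.set_index("snp").loc["b", "beta"] == pytest.approx(0.4)

    def test_removing_planted_outlier_moves_estimate_toward_truth(self):
        inst = sim_instruments(10, 0.3, seed=9, se_exp=0.001, se_out=0.01)
        inst.loc[0, "beta_out"] += 0.2
        full = mr.ivw(inst).beta
        loo, _ = mr.leave_one_out(inst)
        without = loo.iloc[0]["beta"]
        assert abs(without - 0.3) < abs(full - 0.3)

    def test_identical_instruments_identical_loo(self):
        inst = _simple([0.5, 0.5, 0.5])
        loo, passed = mr.leave_one_out(inst)
        assert loo["beta"].nunique() == 1 and passed


class TestPressoGlobal:
    def test_deterministic_under_seed(self):
        inst = sim_instruments(8, 0.2, seed=2)
        assert (mr.presso_global(inst, seed=3)
                == mr.presso_global(inst, seed=3))

    def test_outlier_detected(self):
        inst = sim_instruments(10, 0.2, seed=42, se_exp=0.001, se_out=0.01)
        inst.loc[0, "beta_out"] += 10 * 0.01
        assert mr.presso_global(inst, n_sim=1000, seed=3) <= 0.01

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr.presso_global(sim_instruments(3, 0.2, seed=1))


class TestRunBidirectional:
    def test_empty_panel_empty_outputs(self):
        outcome = pd.DataFrame(columns=["snp", "chrom", "pos", "p", "beta",
                                        "se", "ea", "oa", "eaf"])
        reports, table = mr.run_bidirectional({}, outcome, LdMatrix())
        assert reports == [] and len(table) == 0

    def test_all_weak_trait_skipped_with_report(self):
        exp = pd.DataFrame([("rs1", "1", 100, 1e-7, 0.02, 0.01, "A", "G", 0.3)],
                           columns=["snp", "chrom", "pos", "p", "beta", "se",
                                    "ea", "oa", "eaf"])
        outcome = exp.copy()
        reports, table = mr.run_bidirectional({"t1": exp}, outcome, LdMatrix())
        assert reports[0].skipped is not None
        assert table["skipped"].iloc[0] != ""

    def test_causal_traits_attain_smallest_bh_p(self, small_sim,
                                                small_pipeline):
        tbl = small_pipeline.mr_table
        truth = small_sim.trait_truth
        fwd_causal = set(truth.loc[truth["forward_beta"] != 0, "trait"])
        fwd = tbl[tbl["direction"] == "forward"].dropna(subset=["mr_p_bh"])
        best = set(fwd.nsmallest(len(fwd_causal), "mr_p_bh")["trait"])
        assert best == fwd_causal
        rev_causal = set(truth.loc[truth["reverse_beta"] != 0, "trait"])
        rev = tbl[tbl["direction"] == "reverse"].dropna(subset=["mr_p_bh"])
        best_rev = set(rev.nsmallest(len(rev_causal), "mr_p_bh")["trait"])
        assert best_rev == rev_causal

    def test_forward_and_reverse_instruments_disjoint(self, small_pipeline):
        fwd, rev = set(), set()
        for rep in small_pipeline.mr_reports:
            if rep.loo is None:
                continue
            (fwd if rep.direction == "forward" else rev).update(rep.loo["snp"])
        assert fwd.isdisjoint(rev)
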