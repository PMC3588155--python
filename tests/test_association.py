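"""Contingency testing, FDR, stepwise logistic and meta-analysis."""

import math

import hypothesis.strategies as st
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings

import crcmolclass as cm
from crcmolclass.association import (
    ContingencyTable2x2,
    crosstab,
    fdr_adjust,
    meta_analysis,
    pairwise_screen,
    stepwise_logistic,
)
from crcmolclass.association import test_association as assoc_test
from crcmolclass.cohort import from_records
from conftest import molecular_cohort


class TestCrosstab:
    def test_hand_counted_fixture(self):
        coh = from_records([
            {"tumour_id": "a", "msi": 1, "cin": 1},
            {"tumour_id": "b", "msi": 1, "cin": 0},
            {"tumour_id": "c", "msi": 0, "cin": 0},
        ])
        t = crosstab(coh, "msi", "cin")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)

    def test_empty_complete_case_set_is_an_error(self):
        coh = from_records([{"tumour_id": "a", "msi": 1}])  # cin missing
        with pytest.raises(ValueError, match="complete"):
            crosstab(coh, "msi", "cin")

    def test_totals_match_per_marker_typed_counts(self, small_cohort):
        t = crosstab(small_cohort, "msi", "cin")
        both = (small_cohort.df["msi"].notna()
                & small_cohort.df["cin"].notna()).sum()
        assert t.total == both

    def test_non_binary_factor_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            crosstab(small_cohort, "msi", "age")


class TestFisher:
    def test_perfect_balance_gives_unit_odds_ratio_and_p_one(self):
        r = assoc_test(ContingencyTable2x2(10, 10, 10, 10))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_cross_product_odds_ratio(self):
        # (14*526)/(8*278) by direct arithmetic
        r = assoc_test(ContingencyTable2x2(14, 8, 278, 526))
        assert r.odds_ratio == pytest.approx(3.31, abs=0.005)

    def test_published_tables_reproduce_printed_p_roundings(self):
        p1 = assoc_test(ContingencyTable2x2(102, 78, 244, 313)).p
        p2 = assoc_test(ContingencyTable2x2(14, 8, 278, 526)).p
        assert round(p1, 3) == 0.003
        assert round(p2, 3) == 0.007

    def test_chi2_variant_is_available_but_less_exact_on_small_cells(self):
        t = ContingencyTable2x2(14, 8, 278, 526)
        assert assoc_test(t, method="chi2").p != assoc_test(t, method="fisher").p

    def test_zero_margin_flags_undefined_odds_ratio(self):
        r = assoc_test(ContingencyTable2x2(0, 0, 5, 5))
        assert r.p == 1.0
        assert r.odds_ratio is None

    def test_zero_cell_uses_haldane_correction(self):
        r = assoc_test(ContingencyTable2x2(0, 10, 10, 10))
        expected = (0.5 * 10.5) / (10.5 * 10.5)
        assert r.odds_ratio == pytest.approx(expected)
        assert r.ci_low is not None and r.ci_low > 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_p_symmetric_under_simultaneous_row_and_column_swap(self, cells):
        a, b, c, d = cells
        p1 = assoc_test(ContingencyTable2x2(a, b, c, d)).p
        p2 = assoc_test(ContingencyTable2x2(d, c, b, a)).p
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestFdr:
    def test_identical_pvalues_are_unchanged(self):
        qs = fdr_adjust([0.02, 0.02, 0.02])
        assert np.allclose(qs, 0.02)

    def test_textbook_sequence(self):
        # q_i = min over j>=i of p_(j)*m/rank(j): all collapse to 0.04
        qs = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(qs, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_its_own_q(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_order_invariant_and_dominates_p(self, ps):
        qs = fdr_adjust(ps)
        assert (qs >= np.asarray(ps) - 1e-12).all()
        assert (qs <= 1 + 1e-12).all()
        perm = np.random.RandomState(0).permutation(len(ps))
        qs_perm = fdr_adjust(np.asarray(ps)[perm])
        assert np.allclose(qs_perm, qs[perm])


class TestPairwiseScreen:
    def test_independent_factors_are_rarely_flagged(self):
        # nominal false-positive rate 0.05; 100 seeds, 4-sigma allowance
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({"msi": r.integers(0, 2, 2_000),
                               "cin": r.integers(0, 2, 2_000)})
            res = pairwise_screen(molecular_cohort(df), ["msi", "cin"])
            hits += res[0].sign != "none"
        assert hits <= 13

    def test_calibrated_generator_recovers_marginal_edge_signs(self, calibrated_model):
        df = cm.sample_molecular(calibrated_model, 5_000, 17)
        res = pairwise_screen(molecular_cohort(df), list(cm.CORE_MARKERS))
        signs = {frozenset(r.factors): r.sign for r in res}
        assert signs[frozenset(("msi", "braf"))] == "positive"
        assert signs[frozenset(("msi", "cin"))] == "negative"

    def test_single_pair_q_equals_p(self, small_cohort):
        res = pairwise_screen(small_cohort, ["msi", "cin"])
        assert res[0].q == pytest.approx(res[0].p)

    def test_fewer_than_two_factors_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            pairwise_screen(small_cohort, ["msi"])

    def test_six_non_nras_edge_signs_recovered_in_most_seeds(self, calibrated_model):
        # marginal versions of the primary-association signs; NRAS edges are
        # marginally weak at 4% prevalence and are excluded by design
        wanted = {
            frozenset(("cin", "tp53")): "positive",
            frozenset(("msi", "braf")): "positive",
            frozenset(("kras", "pik3ca")): "positive",
            frozenset(("msi", "cin")): "negative",
            frozenset(("kras", "braf")): "negative",
            frozenset(("kras", "tp53")): "negative",
        }
        hits = 0
        for seed in range(50):
            df = cm.sample_molecular(calibrated_model, 5_000, seed)
            res = pairwise_screen(molecular_cohort(df), list(cm.CORE_MARKERS))
            signs = {frozenset(r.factors): r.sign for r in res}
            hits += all(signs[e] == s for e, s in wanted.items())
        assert hits >= 40  # >= 80% of 50 seeds


class TestStepwise:
    @staticmethod
    def _cohort_with_signal(n=5_000, seed=0):
        r = np.random.default_rng(seed)
        x = r.integers(0, 2, n)
        noise = r.integers(0, 2, n)
        p = 1 / (1 + np.exp(-(-1 + 1.0 * x)))
        y = (r.random(n) < p).astype(int)
        return molecular_cohort(pd.DataFrame(
            {"msi": y, "kras": x, "braf": noise}))

    def test_signal_retained_noise_dropped(self):
        fit = stepwise_logistic(self._cohort_with_signal(), "msi", ["kras", "braf"])
        assert list(fit.retained.index) == ["kras"]
        assert ("braf", "p-threshold") in fit.dropped

    def test_every_predictor_appears_exactly_once(self):
        fit = stepwise_logistic(self._cohort_with_signal(), "msi", ["kras", "braf"])
        seen = set(fit.retained.index) | {d for d, _ in fit.dropped}
        assert seen == {"kras", "braf"}

    def test_exit_threshold_one_disables_elimination(self):
        fit = stepwise_logistic(self._cohort_with_signal(), "msi",
                                ["kras", "braf"], p_exit=1.0)
        assert set(fit.retained.index) == {"kras", "braf"}
        assert fit.dropped == []

    def test_perfectly_collinear_predictor_dropped_with_reason(self):
        r = np.random.default_rng(1)
        x = r.integers(0, 2, 2_000)
        p = 1 / (1 + np.exp(-(-1 + x)))
        y = (r.random(2_000) < p).astype(int)
        coh = molecular_cohort(pd.DataFrame({"msi": y, "kras": x, "nras": x}))
        fit = stepwise_logistic(coh, "msi", ["kras", "nras"])
        assert [reason for _p, reason in fit.dropped] == ["collinearity"]
        assert len(fit.retained) == 1

    def test_constant_outcome_rejected(self):
        coh = molecular_cohort(pd.DataFrame(
            {"msi": [1] * 20, "kras": [0, 1] * 10}))
        with pytest.raises(ValueError, match="constant"):
            stepwise_logistic(coh, "msi", ["kras"])


class TestMetaAnalysis:
    def test_single_study_pools_to_its_own_odds_ratio(self):
        t = ContingencyTable2x2(14, 8, 278, 526)
        r = meta_analysis([t])
        assert r.odds_ratio == pytest.approx((14 * 526) / (8 * 278), rel=1e-6)

    def test_identical_studies_share_the_common_odds_ratio_with_narrower_ci(self):
        t = ContingencyTable2x2(20, 30, 30, 20)
        one = meta_analysis([t])
        five = meta_analysis([t] * 5)
        assert five.odds_ratio == pytest.approx(one.odds_ratio, rel=1e-9)
        assert (five.ci_high - five.ci_low) < (one.ci_high - one.ci_low)

    def test_common_odds_ratio_recovered_from_simulated_studies(self):
        recovered = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            tabs = []
            for _ in range(3):
                x = r.integers(0, 2, 500)
                py = 1 / (1 + np.exp(-(math.log(0.4 / 0.6) + math.log(0.6) * x)))
                y = (r.random(500) < py).astype(int)
                tabs.append(ContingencyTable2x2(
                    int(((x == 1) & (y == 1)).sum()), int(((x == 1) & (y == 0)).sum()),
                    int(((x == 0) & (y == 1)).sum()), int(((x == 0) & (y == 0)).sum())))
            recovered.append(meta_analysis(tabs).odds_ratio)
        assert abs(np.mean(recovered) - 0.6) < 0.1

    def test_zero_margin_study_excluded_with_warning(self):
        good = ContingencyTable2x2(20, 30, 30, 20)
        degenerate = ContingencyTable2x2(0, 0, 30, 20)
        with pytest.warns(UserWarning, match="excluded"):
            r = meta_analysis([good, degenerate])
        assert r.odds_ratio == pytest.approx(meta_analysis([good]).odds_ratio)

    def test_no_studies_rejected(self):
        with pytest.raises(ValueError):
            meta_analysis([])
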