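"""Group statistics: percent change, t/F tests, block ANOVA, endpoint rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import betainc

from immunogate.groups import (
    ClinicalScore,
    CLINICAL_ITEMS,
    block_group_anova,
    compare_groups,
    endpoint_reached,
    paired_changes,
    percent_change,
    two_sample_test,
    variance_ratio_test,
    welch_test,
)
from immunogate.synthetic import PopulationSpec, SimulationConfig, generate_challenge_study


class TestPercentChange:
    @pytest.mark.parametrize(
        "base,follow,expect", [(100, 100, 0.0), (200, 50, -75.0), (50, 100, 100.0)]
    )
    def test_examples(self, base, follow, expect):
        assert percent_change(base, follow) == pytest.approx(expect)

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            percent_change(0, 10)

    def test_paired_changes_flags_zero_baseline(self):
        df = pd.DataFrame(
            {
                "animal_id": ["a1", "a1", "a2", "a2"],
                "timepoint": ["T1", "T2", "T1", "T2"],
                "node": ["X"] * 4,
                "cells_per_uL": [100.0, 150.0, 0.0, 10.0],
            }
        )
        changes = paired_changes(df, "T1", "T2")
        by_animal = {c.animal_id: c for c in changes}
        assert by_animal["a1"].defined and by_animal["a1"].pct_change == pytest.approx(50)
        assert not by_animal["a2"].defined and by_animal["a2"].pct_change is None


class TestTwoSampleTest:
    def test_identical_groups(self):
        t, p, diff = two_sample_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0) and diff == 0

    def test_textbook_oracle(self):
        # hand formula: pooled s^2 = 1, t = -3 / sqrt(2/3), df = 4
        a, b = [1, 2, 3], [4, 5, 6]
        t, p, diff = two_sample_test(a, b)
        t_hand = -3 / math.sqrt(1 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand)
        # p via the regularized incomplete beta (independent route)
        df = 4
        p_hand = betainc(df / 2, 0.5, df / (df + t_hand**2))
        assert p == pytest.approx(p_hand)
        assert diff == pytest.approx(-3)

    def test_degenerate_zero_variance(self):
        t, p, _ = two_sample_test([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)
        t, p, _ = two_sample_test([2, 2], [3, 3])
        assert p == 0.0 and np.isinf(t)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(5)
        rej = 0
        n_sim = 4000
        for _ in range(n_sim):
            _, p, _ = two_sample_test(rng.normal(0, 1, 6), rng.normal(0, 1, 6))
            rej += p <= 0.05
        assert 0.04 < rej / n_sim < 0.06

    def test_welch_variant_available(self):
        t, p, diff = welch_test([1.0, 2, 3, 4], [10.0, 20, 30, 40])
        assert p < 0.1 and diff < 0


class TestBlockGroupAnova:
    @staticmethod
    def _oracle(y, g, b):
        """Brute-force additive two-way sums of squares."""
        y = np.asarray(y, float)
        grand = y.mean()
        ss_g = sum(
            (g == gg).sum() * (y[g == gg].mean() - grand) ** 2 for gg in np.unique(g)
        )
        ss_b = sum(
            (b == bb).sum() * (y[b == bb].mean() - grand) ** 2 for bb in np.unique(b)
        )
        ss_t = ((y - grand) ** 2).sum()
        return ss_g, ss_b, ss_t - ss_g - ss_b

    def test_balanced_integer_fixture_vs_oracle_and_statsmodels(self):
        y = np.array([3, 5, 4, 6, 8, 7, 2, 4, 9, 11, 10, 12], dtype=float)
        g = np.array(["c", "c", "t", "t"] * 3)
        b = np.repeat(["b1", "b2", "b3"], 4)
        fg, pg, fb, pb = block_group_anova(y, g, b)

        ss_g, ss_b, ss_r = self._oracle(y, g, b)
        df_r = 12 - 1 - 1 - 2
        assert fg == pytest.approx((ss_g / 1) / (ss_r / df_r))
        assert fb == pytest.approx((ss_b / 2) / (ss_r / df_r))

        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols

        df = pd.DataFrame({"y": y, "g": g, "b": b})
        tab = sm.stats.anova_lm(ols("y ~ C(g) + C(b)", df).fit(), typ=2)
        assert fg == pytest.approx(tab.loc["C(g)", "F"])
        assert fb == pytest.approx(tab.loc["C(b)", "F"])
        assert pg == pytest.approx(tab.loc["C(g)", "PR(>F)"])
        assert pb == pytest.approx(tab.loc["C(b)", "PR(>F)"])

    def test_pure_block_shift_detected_as_block_effect(self):
        rng = np.random.default_rng(21)
        base = rng.normal(0, 0.1, 12)
        b = np.repeat(["b1", "b2", "b3"], 4)
        g = np.array(["c", "c", "t", "t"] * 3)
        shift = {"b1": 0.0, "b2": 5.0, "b3": 10.0}
        y = base + np.array([shift[x] for x in b])
        fg, pg, fb, pb = block_group_anova(y, g, b)
        assert pg > 0.1
        assert fb > 100

    def test_pure_group_effect_leaves_block_flat(self):
        # the same within-block pattern repeats in every block, so the
        # block sum of squares is exactly zero by construction
        b = np.repeat(["b1", "b2", "b3"], 4)
        g = np.array(["c", "c", "t", "t"] * 3)
        y = np.where(g == "t", 5.0, 0.0) + np.tile([0.0, 0.1, 0.0, 0.1], 3)
        fg, pg, fb, pb = block_group_anova(y, g, b)
        assert fg > 100
        assert fb == pytest.approx(0.0, abs=1e-20)
        assert pb == pytest.approx(1.0)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            block_group_anova([1, 2, 3, 4], ["c", "c", "t", "t"], ["b1", "b1", "b2", "b2"])

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="block"):
            block_group_anova([1, 2, 3, 4], ["c", "t", "c", "t"], ["b1"] * 4)


class TestVarianceRatioTest:
    def test_equal_samples(self):
        f, p = variance_ratio_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert f == 1.0 and p == pytest.approx(1.0)

    def test_exact_ratio_and_distribution_oracle(self):
        a = [0.0, 4.0]  # variance 8
        b = [0.0, 2.0]  # variance 2
        f, p = variance_ratio_test(a, b)
        assert f == pytest.approx(4.0)
        # independent route: F(1,1) survival via the incomplete beta
        sf = betainc(0.5, 0.5, 1 / (1 + 4.0))
        assert p == pytest.approx(2 * sf)

    def test_larger_variance_goes_to_numerator(self):
        f1, p1 = variance_ratio_test([0, 1], [0, 10])
        f2, p2 = variance_ratio_test([0, 10], [0, 1])
        assert f1 == f2 == pytest.approx(100.0)
        assert p1 == p2

    def test_zero_variance_denominator_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_test([1, 1], [1, 1])

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(6)
        rej = 0
        n_sim = 4000
        for _ in range(n_sim):
            _, p = variance_ratio_test(rng.normal(0, 1, 6), rng.normal(0, 1, 6))
            rej += p <= 0.05
        assert 0.04 < rej / n_sim < 0.06


class TestEndpointRule:
    def test_all_zero_is_fine(self):
        score = ClinicalScore({k: 0 for k in CLINICAL_ITEMS})
        assert endpoint_reached(score) == (False, None)

    def test_single_item_at_four_triggers(self):
        scores = {k: 0 for k in CLINICAL_ITEMS}
        scores["lesions"] = 4
        hit, reason = endpoint_reached(ClinicalScore(scores))
        assert hit and "lesions" in reason and "4" in reason

    def test_cumulative_over_sixteen_triggers(self):
        # items {3,3,3,3,3,1,1}: sum 17 > 16, no single 4
        vals = [3, 3, 3, 3, 3, 1, 1]
        score = ClinicalScore(dict(zip(CLINICAL_ITEMS, vals)))
        hit, reason = endpoint_reached(score)
        assert hit and "cumulative" in reason

    def test_sum_of_exactly_sixteen_does_not_trigger(self):
        vals = [3, 3, 3, 3, 2, 1, 1]  # sum 16: strict rule
        hit, _ = endpoint_reached(ClinicalScore(dict(zip(CLINICAL_ITEMS, vals))))
        assert not hit

    def test_out_of_range_item_rejected(self):
        scores = {k: 0 for k in CLINICAL_ITEMS}
        scores["passivity"] = 5
        with pytest.raises(ValueError):
            ClinicalScore(scores)

    @settings(deadline=None, max_examples=100)
    @given(
        base=st.lists(st.integers(0, 3), min_size=7, max_size=7),
        idx=st.integers(0, 6),
        bump=st.integers(1, 4),
    )
    def test_monotone_in_every_item(self, base, idx, bump):
        lo = ClinicalScore(dict(zip(CLINICAL_ITEMS, base)))
        hi_vals = list(base)
        hi_vals[idx] = min(4, hi_vals[idx] + bump)
        hi = ClinicalScore(dict(zip(CLINICAL_ITEMS, hi_vals)))
        if endpoint_reached(lo)[0]:
            assert endpoint_reached(hi)[0]


@pytest.fixture(scope="module")
def challenge_counts():
    pops = [
        PopulationSpec("hit", {"X": "high"}, 200.0),
        PopulationSpec("stable", {"Y": "high"}, 400.0),
    ]
    cfg = SimulationConfig(
        populations=pops, n_animals=12, n_timepoints=2,
        events_per_sample=None, sigma_inter=0.05, sigma_intra=0.05, seed=77,
    )
    study = generate_challenge_study(cfg, n_blocks=3, effect_log10={"hit": -0.5})
    rows = []
    for ev, truth in study:
        for _, r in truth.table.iterrows():
            rows.append(
                (ev.sample_id, ev.animal_id, ev.timepoint, ev.group, ev.block,
                 r["population"], r["concentration"])
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "animal_id", "timepoint", "group", "block",
                 "node", "cells_per_uL"],
    )


class TestCompareGroups:
    def test_detects_true_effect_and_spares_null(self, challenge_counts):
        res = compare_groups(challenge_counts, baseline="T1", followup="T2")
        tab = res.table.set_index("variable")
        assert tab.loc["hit", "p"] <= 0.05
        assert tab.loc["stable", "p"] > 0.05
        assert not res.block_significant
        assert any("block factor non-significant" in n for n in res.notes)

    def test_followup_mode_and_bh_adjustment(self, challenge_counts):
        res = compare_groups(
            challenge_counts, baseline="T1", followup="T2", mode="followup", adjust="bh"
        )
        assert "p_adjusted" in res.table.columns
        assert (res.table["p_adjusted"].dropna() >= res.table["p"].dropna() - 1e-12).all()

    def test_unknown_mode_rejected(self, challenge_counts):
        with pytest.raises(ValueError):
            compare_groups(challenge_counts, baseline="T1", followup="T2", mode="delta")
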