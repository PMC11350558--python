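"""Variance decomposition, detectable change, and sample size."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from immunogate.variance import (
    ConstantVariableError,
    LongitudinalMatrix,
    anova_components,
    decompose_study,
    detectable_change,
    eta_squared,
    load_reference_variability,
    panel_mean_eta,
    required_n,
    two_sample_power,
    variance_components,
    VarianceDecomposition,
)


def brute_force_components(x):
    """Independent oracle: direct mean-deviation summation, element-wise."""
    a, t = x.shape
    grand = sum(x[i][j] for i in range(a) for j in range(t)) / (a * t)
    row = [sum(x[i]) / t for i in range(a)]
    col = [sum(x[i][j] for i in range(a)) / a for j in range(t)]
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(a) for j in range(t))
    ss_animal = t * sum((r - grand) ** 2 for r in row)
    ss_time = a * sum((c - grand) ** 2 for c in col)
    return ss_animal, ss_time, ss_total - ss_animal - ss_time, ss_total


class TestAnovaComponents:
    def test_between_animal_only(self):
        c = anova_components(LongitudinalMatrix("v", [[1, 1], [3, 3]]))
        assert (c.ss_animal, c.ss_time, c.ss_residual) == (4, 0, 0)

    def test_within_animal_only(self):
        c = anova_components(LongitudinalMatrix("v", [[1, 3], [1, 3]]))
        assert (c.ss_animal, c.ss_time, c.ss_residual) == (0, 4, 0)

    def test_three_by_three_vs_bruteforce(self):
        x = np.array([[1, 5, 2], [4, 4, 9], [0, 7, 3]], dtype=float)
        c = anova_components(LongitudinalMatrix("v", x))
        ssa, sst, ssr, tot = brute_force_components(x)
        assert c.ss_animal == pytest.approx(ssa)
        assert c.ss_time == pytest.approx(sst)
        assert c.ss_residual == pytest.approx(ssr)
        assert c.ss_total == pytest.approx(tot)

    def test_exhaustive_random_integer_matrices(self):
        rng = np.random.default_rng(11)
        for a in range(2, 7):
            for t in range(2, 7):
                x = rng.integers(0, 10, size=(a, t)).astype(float)
                c = anova_components(LongitudinalMatrix("v", x))
                ssa, sst, ssr, tot = brute_force_components(x)
                assert c.ss_animal == pytest.approx(ssa)
                assert c.ss_time == pytest.approx(sst)
                assert c.ss_residual == pytest.approx(ssr)
                assert abs(c.ss_animal + c.ss_time + c.ss_residual - c.ss_total) < 1e-9

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            LongitudinalMatrix("v", [[1, 2]])

    def test_unbalanced_listwise_drop(self):
        x = np.array([[1.0, 2.0, np.nan], [3.0, 4.0, 5.0]])
        lm = LongitudinalMatrix("v", x, balanced=False)
        assert lm.values.shape == (2, 2)
        with pytest.raises(ValueError):
            LongitudinalMatrix("v", x, balanced=True)


class TestEtaSquared:
    def test_between_animal_fixture(self):
        d = eta_squared(anova_components(LongitudinalMatrix("v", [[1, 1], [3, 3]])))
        assert (d.eta_sq_inter, d.eta_sq_intra, d.eta_sq_residual) == (1, 0, 0)

    def test_within_animal_fixture(self):
        d = eta_squared(anova_components(LongitudinalMatrix("v", [[1, 3], [1, 3]])))
        assert (d.eta_sq_inter, d.eta_sq_intra, d.eta_sq_residual) == (0, 1, 0)

    def test_constant_variable_flagged_not_zero(self):
        with pytest.raises(ConstantVariableError):
            eta_squared(anova_components(LongitudinalMatrix("v", [[2, 2], [2, 2]])))

    def test_components_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=(4, 5))
            d = eta_squared(anova_components(LongitudinalMatrix("v", x)))
            assert abs(d.eta_sq_inter + d.eta_sq_intra + d.eta_sq_residual - 1) < 1e-9

    def test_residual_folding_option(self):
        x = np.random.default_rng(8).normal(size=(4, 5))
        c = anova_components(LongitudinalMatrix("v", x))
        d0 = eta_squared(c)
        d1 = eta_squared(c, intra_includes_residual=True)
        assert d1.eta_sq_residual == 0
        assert d1.eta_sq_intra == pytest.approx(d0.eta_sq_intra + d0.eta_sq_residual)
        assert d1.eta_sq_inter == pytest.approx(d0.eta_sq_inter)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            VarianceDecomposition("v", 0.7, 0.7, -0.4)


class TestPanelMeanEta:
    def test_single_decomposition(self):
        d = VarianceDecomposition("v", 0.2, 0.4, 0.4)
        assert panel_mean_eta([d]) == (0.4, 0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            panel_mean_eta([])

    def test_reference_table_means(self):
        # the bundled healthy-mouse reference: myeloid panel averages
        ref = load_reference_variability()
        my = ref[ref["panel"] == "myeloid"]
        intra, inter = panel_mean_eta(my)
        assert intra == pytest.approx(35.49, abs=0.01)
        assert inter == pytest.approx(22.90, abs=0.01)
        assert len(my) == 16 and len(ref) == 42

    def test_intra_double_inter_design(self):
        # sigma_intra^2 = 2 sigma_inter^2 with a longer follow-up: the
        # intra/inter ratio of panel means settles between 1.5 and 2.5
        from immunogate.synthetic import PopulationSpec, SimulationConfig, generate_abundances

        ratios = []
        for rep in range(200):
            cfg = SimulationConfig(
                populations=[PopulationSpec("p", {"X": "high"}, 100.0)],
                n_animals=5, n_timepoints=10,
                sigma_inter=0.1, sigma_intra=0.1 * np.sqrt(2), seed=40_000 + rep,
            )
            ab = generate_abundances(cfg)
            mat = ab.pivot_table(index="animal_id", columns="timepoint",
                                 values="log10_concentration").to_numpy()
            d = eta_squared(anova_components(LongitudinalMatrix("p", mat)),
                            intra_includes_residual=True)
            ratios.append((d.eta_sq_intra, d.eta_sq_inter))
        mean_intra = np.mean([r[0] for r in ratios])
        mean_inter = np.mean([r[1] for r in ratios])
        assert 1.5 < mean_intra / mean_inter < 2.5


class TestVarianceComponents:
    def test_pure_between_animal(self):
        c = anova_components(LongitudinalMatrix("v", [[1, 1], [3, 3]]))
        s2i, s2w = variance_components(c)
        assert s2w == 0
        assert s2i > 0

    def test_known_model_recovery_pooled(self):
        from immunogate.synthetic import PopulationSpec, SimulationConfig, generate_abundances

        comps = []
        for rep in range(200):
            cfg = SimulationConfig(
                populations=[PopulationSpec("p", {"X": "high"}, 100.0)],
                n_animals=5, n_timepoints=5,
                sigma_inter=0.2, sigma_intra=0.1, seed=30_000 + rep,
            )
            ab = generate_abundances(cfg)
            mat = ab.pivot_table(index="animal_id", columns="timepoint",
                                 values="log10_concentration").to_numpy()
            comps.append(variance_components(anova_components(LongitudinalMatrix("p", mat))))
        mi = np.mean([c[0] for c in comps])
        mw = np.mean([c[1] for c in comps])
        assert mi == pytest.approx(0.04, abs=0.008)
        assert mw == pytest.approx(0.01, abs=0.002)


class TestDetectableChange:
    def test_direct_formula(self):
        # SD 100, d = 0.5, own mean 1000 -> 50 cells, 5%
        rng = np.random.default_rng(12)
        vals = rng.normal(1000, 100, 200000)
        m = detectable_change(vals, cohens_d=0.5)
        assert m.mdc_cells == pytest.approx(50, rel=0.01)
        assert m.mdc_relative_pct == pytest.approx(5, rel=0.02)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            detectable_change([5.0, 5.0, 5.0])

    def test_mdc_over_sd_converges_to_d(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0, 3.0, 10_000)
        m = detectable_change(vals, cohens_d=0.5, denominator="leukocyte_mean",
                              leukocyte_mean=100.0)
        assert m.mdc_cells / 3.0 == pytest.approx(0.5, rel=0.02)

    def test_leukocyte_denominator(self):
        vals = [900.0, 1000.0, 1100.0]
        m = detectable_change(vals, denominator="leukocyte_mean", leukocyte_mean=2000.0)
        assert m.mdc_relative_pct == pytest.approx(100 * m.mdc_cells / 2000.0)


class TestRequiredN:
    def test_medium_effect_standard_design(self):
        # d=0.5, 80% power, two-sided alpha 0.05
        assert required_n(0.5, 0.80, 0.05) == (64, 63)

    def test_huge_effect_floors_at_two(self):
        assert required_n(10.0) == (2, 2)

    def test_monotone_in_effect_size(self):
        ns = [required_n(d)[0] for d in (0.2, 0.4, 0.6, 0.8, 1.2)]
        assert ns == sorted(ns, reverse=True)

    def test_power_monotone_in_n_and_d(self):
        powers_n = [two_sample_power(n, 0.5) for n in (5, 10, 20, 40, 80)]
        assert powers_n == sorted(powers_n)
        powers_d = [two_sample_power(20, d) for d in (0.2, 0.5, 0.8, 1.2)]
        assert powers_d == sorted(powers_d)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            required_n(0.0)
        with pytest.raises(ValueError):
            required_n(0.5, power=1.0)


class TestDecomposeStudy:
    def test_tidy_roundtrip_shapes(self):
        rng = np.random.default_rng(14)
        rows = []
        for a in range(4):
            for t in range(3):
                for var in ("X", "Y"):
                    rows.append((f"A{a}", f"T{t}", var, rng.normal()))
        import pandas as pd

        df = pd.DataFrame(rows, columns=["animal_id", "timepoint", "node", "log10_value"])
        out = decompose_study(df)
        assert list(out["variable"]) == ["X", "Y"]
        assert np.allclose(
            out[["eta_intra_pct", "eta_inter_pct", "eta_residual_pct"]].sum(axis=1), 100
        )

    def test_constant_variable_yields_nan_row(self):
        import pandas as pd

        rows = [(f"A{a}", f"T{t}", "C", 1.0) for a in range(3) for t in range(3)]
        df = pd.DataFrame(rows, columns=["animal_id", "timepoint", "node", "log10_value"])
        out = decompose_study(df)
        assert out["eta_intra_pct"].isna().all()
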