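"""S/N conversion, main effects, balanced ANOVA, optimum selection, prediction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import taguchigra as tg
from tests import printed_tables as pt

finite_vec18 = arrays(np.float64, 18, elements=st.floats(-50, 50, allow_nan=False, width=32))


class TestSnr:
    @pytest.mark.parametrize(
        "replicates, expected, tol",
        [
            ([98.60], 39.8776, 5e-4),
            ([97.63], 39.7918, 5e-4),
            ([1.0], 0.0, 1e-12),
            ([10.0, 10.0], 20.0, 1e-12),
        ],
    )
    def test_values(self, replicates, expected, tol):
        assert tg.snr_larger_better(replicates) == pytest.approx(expected, abs=tol)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            tg.snr_larger_better([10.0, 0.0])

    @given(y=st.floats(1e-3, 1e6))
    def test_single_replicate_is_20log10(self, y):
        assert tg.snr_larger_better([y]) == pytest.approx(20 * np.log10(y), abs=1e-12)

    @given(y=st.floats(1e-3, 1e5), gap=st.floats(1e-3, 1e3))
    def test_monotone_increasing(self, y, gap):
        assert tg.snr_larger_better([y + gap]) > tg.snr_larger_better([y])

    def test_table_matches_printed_snr_column(self, study):
        recomputed = tg.snr_table(study.ef_table["EF"], "EF")
        # agreement at the printed 4-dp precision (half a unit in the last place)
        assert (np.abs(np.round(recomputed, 4) - study.ef_table["snr"]) <= 5e-4 + 1e-9).all()

    def test_grg_snr_matches_printed(self, gra_result):
        snr = tg.snr_table(gra_result.grg, "GRG")
        assert np.abs(snr.values - pt.GRG_SNR).max() <= 2e-3

    def test_constant_ones_give_zero(self):
        assert (tg.snr_table(np.ones(18)) == 0).all()


class TestMainEffects:
    def test_level_mean_against_brute_force(self, design, study):
        snr = study.ef_table["snr"].values
        effects = tg.main_effects(design, snr)
        # oracle: explicit mean over runs 1,4,7,10,13,16 (factor B at level 1)
        runs_b1 = [i for i, row in enumerate(design.assignment) if row[1] == 1]
        assert runs_b1 == [0, 3, 6, 9, 12, 15]
        assert effects.level_means.loc["B", 1] == pytest.approx(snr[runs_b1].mean(), abs=1e-12)
        assert effects.level_means.loc["B", 1] == pytest.approx(39.5309, abs=1e-3)

    def test_balanced_design_identity(self, design, rng):
        values = rng.normal(size=18)
        effects = tg.main_effects(design, values)
        # mean of the three level means equals the overall mean, per factor
        assert np.allclose(effects.level_means.mean(axis=1), effects.overall_mean)
        assert (effects.delta >= 0).all()

    def test_constant_values_flat(self, design):
        effects = tg.main_effects(design, np.full(18, 3.7))
        assert (effects.delta == 0).all()

    def test_grg_snr_factor_b_peaks_at_level_1(self, design, gra_result):
        snr = tg.snr_table(gra_result.grg).values
        effects = tg.main_effects(design, snr)
        row = effects.level_means.loc["B"]
        assert row.idxmax() == 1

    def test_unbalanced_design_rejected(self, design):
        from taguchigra.design import DesignMatrix

        assignment = design.assignment.copy()
        assignment[0, 0] = 2
        with pytest.raises(ValueError, match="confounded"):
            tg.main_effects(DesignMatrix(design.factors, assignment), np.zeros(18))


class TestSelectOptimal:
    def test_ef_optimum(self, design, study):
        effects = tg.main_effects(design, tg.snr_table(study.ef_table["EF"]).values)
        assert tg.select_optimal(effects) == tuple((l,) for l in pt.EF_OPTIMUM)

    def test_grg_optimum(self, design, gra_result):
        effects = tg.main_effects(design, tg.snr_table(gra_result.grg).values)
        assert tg.select_optimal(effects) == tuple((l,) for l in pt.GRG_OPTIMUM)

    def test_constant_values_tie_everywhere(self, design):
        effects = tg.main_effects(design, np.zeros(18))
        assert tg.select_optimal(effects) == ((1, 2, 3),) * 5

    @given(
        shift=st.integers(-100, 100),
        values=arrays(np.float64, 18, elements=st.integers(-50, 50).map(float)),
    )
    def test_invariant_under_constant_shift(self, design, shift, values):
        # integer-valued inputs keep level-mean comparisons exact, so ties
        # are preserved rather than resolved by rounding noise
        base = tg.select_optimal(tg.main_effects(design, values))
        shifted = tg.select_optimal(tg.main_effects(design, values + float(shift)))
        assert base == shifted


class TestAnova:
    def test_table5_from_printed_snr(self, design, study):
        anova = tg.anova_balanced(design, study.ef_table["snr"].values)
        assert anova.ss("B") == pytest.approx(15.7743, abs=1e-3)
        assert anova.f_value("B") == pytest.approx(36.24, abs=0.05)
        assert anova.p_value("B") < 5e-4

    def test_table9_from_printed_grg_snr(self, design):
        anova = tg.anova_balanced(design, pt.GRG_SNR)
        assert anova.ss("A") == pytest.approx(10.2073, abs=1e-3)
        assert anova.f_value("A") == pytest.approx(3.01, abs=0.05)
        assert anova.p_value("A") == pytest.approx(0.114, abs=5e-3)

    def test_degrees_of_freedom(self, design, rng):
        table = tg.anova_balanced(design, rng.normal(size=18)).table
        assert (table.loc[list("ABCDE"), "df"] == 2).all()
        assert table.loc["Error", "df"] == 7 and table.loc["Total", "df"] == 17

    def test_constant_values_zero_ss(self, design):
        table = tg.anova_balanced(design, np.full(18, 1.23)).table
        assert table["sum_sq"].abs().max() == pytest.approx(0.0, abs=1e-18)

    @given(values=finite_vec18)
    def test_ss_decomposition(self, design, values):
        table = tg.anova_balanced(design, values).table
        factor_plus_error = table.loc[list("ABCDE"), "sum_sq"].sum() + table.loc["Error", "sum_sq"]
        total = table.loc["Total", "sum_sq"]
        assert factor_plus_error == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_against_two_pass_oracle(self, design, rng):
        # brute force: explicit group means and residual sum per factor
        for _ in range(5):
            y = rng.normal(size=18)
            anova = tg.anova_balanced(design, y)
            grand = y.mean()
            for k, notation in enumerate("ABCDE"):
                ss = 0.0
                for level in (1, 2, 3):
                    group = y[design.assignment[:, k] == level]
                    ss += len(group) * (group.mean() - grand) ** 2
                assert anova.ss(notation) == pytest.approx(ss, abs=1e-10)

    def test_exact_additive_fit_gives_infinite_f(self, design):
        # values that are a pure factor-A contrast: error SS collapses to 0
        y = design.assignment[:, 0].astype(float)
        anova = tg.anova_balanced(design, y)
        assert np.isinf(anova.f_value("A")) and anova.p_value("A") == 0.0


class TestPredictAdditive:
    def test_all_terms_value_scale_matches_brute_force(self, design):
        effects = tg.main_effects(design, pt.GRG)
        pred = tg.predict_additive(effects, (3, 1, 2, 3, 1))
        # oracle: explicit additive sum over the printed grades
        grand = pt.GRG.mean()
        expected = grand
        for k, level in enumerate((3, 1, 2, 3, 1)):
            expected += pt.GRG[design.assignment[:, k] == level].mean() - grand
        assert pred.predicted == pytest.approx(expected, abs=1e-12)
        assert pred.predicted == pytest.approx(0.8712, abs=1e-3)

    def test_empty_terms_is_overall_mean(self, design):
        effects = tg.main_effects(design, pt.GRG)
        pred = tg.predict_additive(effects, (1, 1, 1, 1, 1), terms=())
        assert pred.predicted == pytest.approx(0.6269, abs=1e-3)

    def test_additivity_identity_on_noise_free_data(self, design):
        config = tg.default_config(seed=0, sigma_scale=0.0)
        matrix, truth = tg.generate(config)
        effects = tg.main_effects(design, matrix.data["EF"].values)
        for run_id in (1, 7, 18):
            pred = tg.predict_additive(effects, design.run_combination(run_id))
            assert pred.predicted == pytest.approx(matrix.data.loc[run_id, "EF"], abs=1e-9)

    def test_snr_scale_back_transform(self, design, gra_result):
        snr = tg.snr_table(gra_result.grg).values
        effects = tg.main_effects(design, snr)
        pred = tg.predict_additive(effects, (3, 1, 2, 3, 1), scale="snr-db")
        assert pred.back_transformed == pytest.approx(10 ** (pred.predicted / 20), abs=1e-12)

    def test_unknown_term_rejected(self, design):
        effects = tg.main_effects(design, pt.GRG)
        with pytest.raises(ValueError, match="unknown factor"):
            tg.predict_additive(effects, (1, 1, 1, 1, 1), terms=("F",))
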