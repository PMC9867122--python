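"""Inhibition normalisation, 4PL GI50 fitting, synergy calls, grids."""

import numpy as np
import pandas as pd
import pytest

from drugsig import (
    DoseResponseModel,
    assess_synergy,
    combination_grid,
    fit_gi50,
    generate_dose_response,
    normalize_inhibition,
)
from drugsig.doseresponse import (
    ControlError,
    Gi50Results,
    combination_potency_shifts,
    inhibition_ttests,
    normalize_wells,
)
from drugsig.simulate import DR_COLUMNS, generate_combination_table


def plate(rows):
    return pd.DataFrame(rows, columns=DR_COLUMNS)


class TestNormalizeInhibition:
    def test_untreated_level_gives_zero_inhibition(self):
        t = plate([("d", 0.0, None, np.nan, 0, 1.0),
                   ("d", 1.0, None, np.nan, 0, 1.0)])
        out = normalize_inhibition(t)
        assert out.loc[out["conc_a"] == 1.0, "inhibition"].iloc[0] == 0.0

    def test_quarter_absorbance_is_75_percent(self):
        t = plate([("d", 0.0, None, np.nan, 0, 1.0),
                   ("d", 2.0, None, np.nan, 0, 0.25)])
        out = normalize_inhibition(t)
        assert out.loc[out["conc_a"] == 2.0, "inhibition"].iloc[0] == pytest.approx(75.0)

    def test_stimulation_clamped_to_zero_but_raw_kept(self):
        t = plate([("d", 0.0, None, np.nan, 0, 1.0),
                   ("d", 1.0, None, np.nan, 0, 1.2)])
        out = normalize_inhibition(t)
        row = out.loc[out["conc_a"] == 1.0]
        assert row["inhibition"].iloc[0] == 0.0
        assert row["inhibition_raw"].iloc[0] == pytest.approx(-20.0)

    def test_missing_controls_raise(self):
        t = plate([("d", 1.0, None, np.nan, 0, 0.5)])
        with pytest.raises(ControlError):
            normalize_inhibition(t)

    def test_monotone_absorbance_gives_monotone_inhibition(self):
        rows = [("d", 0.0, None, np.nan, 0, 1.0)]
        rows += [("d", c, None, np.nan, 0, ab)
                 for c, ab in zip([1, 2, 4, 8], [0.9, 0.7, 0.4, 0.1])]
        out = normalize_inhibition(plate(rows)).sort_values("conc_a")
        treated = out.loc[out["conc_a"] > 0, "inhibition"]
        assert treated.is_monotonic_increasing
        assert ((out["inhibition"] >= 0) & (out["inhibition"] <= 100)).all()


class TestGi50Fit:
    @pytest.mark.parametrize("planted", [0.1, 5.0, 12.54])
    @pytest.mark.parametrize("dilution", ["log", "linear"])
    def test_zero_noise_round_trip(self, planted, dilution):
        doses = np.geomspace(planted / 30, planted * 30, 8)
        t = generate_dose_response(gi50=planted, hill=1.2, top=100.0, bottom=0.0,
                                   doses=doses, noise_sd=0.0, seed=0)
        fit = fit_gi50(t, dilution=dilution)
        assert abs(fit.gi50 - planted) / planted <= 1e-4
        assert fit.hill == pytest.approx(1.2, rel=1e-4)
        assert fit.top == pytest.approx(100.0, rel=1e-4)
        assert abs(fit.bottom) <= 1e-3
        assert not fit.capped

    def test_zero_noise_tight_recovery_of_planted_5(self):
        doses = np.geomspace(0.1, 300.0, 8)
        t = generate_dose_response(gi50=5.0, doses=doses, noise_sd=0.0, seed=1)
        fit = fit_gi50(t)
        assert abs(fit.gi50 - 5.0) <= 1e-6

    def test_noisy_triplicates_median_error_under_10_percent(self):
        errs = []
        doses = np.geomspace(12.54 / 30, 12.54 * 30, 8)  # series bracketing the expected GI50
        for seed in range(100):
            t = generate_dose_response(gi50=12.54, doses=doses, n_reps=3,
                                       noise_sd=5.0, seed=seed)
            errs.append(abs(fit_gi50(t).gi50 - 12.54) / 12.54)
        assert np.median(errs) < 0.10

    def test_flat_response_capped_at_max_dose(self):
        t = generate_dose_response(gi50=1e7, doses=[1.0, 3.0, 10.0, 30.0],
                                   noise_sd=0.0, seed=0)
        fit = fit_gi50(t)
        assert fit.capped
        assert fit.gi50 == 30.0

    def test_results_object_reports_diagnostics(self):
        t = generate_dose_response(gi50=5.0, noise_sd=3.0, seed=2)
        fit = fit_gi50(t)
        assert isinstance(fit, Gi50Results)
        assert fit.nobs == 24
        assert np.isfinite(fit.rmse)
        assert "GI50" in fit.summary()

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct doses"):
            DoseResponseModel([1.0, 2.0, 3.0], [10.0, 50.0, 90.0])


class TestSynergy:
    def test_two_and_a_half_fold_shift_is_synergistic(self):
        call = assess_synergy(10.0, 4.0, drug_pair=("a", "b"))
        assert call.potency_shift == pytest.approx(2.5)
        assert call.synergistic

    def test_identical_potencies_not_synergistic(self):
        call = assess_synergy(7.0, 7.0)
        assert call.potency_shift == pytest.approx(1.0)
        assert not call.synergistic

    def test_capped_single_agent_flags_lower_bound(self):
        t = generate_dose_response(gi50=1e7, doses=[1.0, 3.0, 10.0, 30.0],
                                   noise_sd=0.0, seed=0)
        capped_single = fit_gi50(t)
        call = assess_synergy(capped_single, 3.0)
        assert call.synergistic
        assert call.shift_is_lower_bound
        assert "lower bound" in call.note

    def test_scale_invariance_of_shift(self):
        base = assess_synergy(10.0, 4.0)
        scaled = assess_synergy(10.0 * 37.0, 4.0 * 37.0)
        assert scaled.potency_shift == pytest.approx(base.potency_shift)

    def test_nonpositive_combination_rejected(self):
        with pytest.raises(ValueError, match="combination"):
            assess_synergy(10.0, 0.0)


class TestCombinationGrid:
    @pytest.fixture()
    def combo_table(self):
        return generate_combination_table(
            "A", "B",
            params_a={"gi50": 500.0, "hill": 1.0},
            params_b={"gi50": 10.0, "hill": 1.0},
            doses_a=[1.0, 3.0, 10.0, 30.0],
            doses_b=[3.0, 10.0],
            bliss_excess=20.0,
            noise_sd=0.0,
            seed=0,
        )

    def test_origin_cell_is_zero(self, combo_table):
        grid = combination_grid(combo_table, "A", "B")
        assert grid.loc[0.0, 0.0] == pytest.approx(0.0, abs=1e-9)

    def test_margins_match_single_agent_analysis(self, combo_table):
        grid = combination_grid(combo_table, "A", "B")
        singles = normalize_inhibition(
            combo_table[combo_table["conc_b"] == 0.0]
        ).set_index("conc_a")["inhibition"]
        for conc in [1.0, 3.0, 10.0, 30.0]:
            assert grid.loc[conc, 0.0] == pytest.approx(singles.loc[conc])

    def test_planted_bliss_excess_exceeds_own_margins(self, combo_table):
        """With a planted Bliss surplus, every interior cell exceeds the larger
        of its two corresponding single-agent margin cells."""
        grid = combination_grid(combo_table, "A", "B")
        for ca in grid.index[grid.index > 0]:
            for cb in grid.columns[grid.columns > 0]:
                margin = max(grid.loc[ca, 0.0], grid.loc[0.0, cb])
                assert grid.loc[ca, cb] > margin

    def test_missing_cells_are_nan_not_zero(self, combo_table):
        dropped = combo_table[~((combo_table["conc_a"] == 3.0)
                                & (combo_table["conc_b"] == 10.0))]
        grid = combination_grid(dropped, "A", "B")
        assert np.isnan(grid.loc[3.0, 10.0])

    def test_per_row_shifts_detect_planted_synergy(self, combo_table):
        shifts = combination_potency_shifts(combo_table, "A", "B")
        assert shifts["synergistic"].any()
        assert shifts["single_capped"].all()
        assert shifts["shift_is_lower_bound"].all()


class TestInhibitionTtests:
    def test_strong_effect_significant_null_not(self):
        t = generate_dose_response(gi50=1.0, doses=[0.01, 100.0, 200.0, 400.0],
                                   n_reps=4, noise_sd=2.0, seed=5)
        res = inhibition_ttests(t).set_index("conc_a")
        assert res.loc[100.0, "p_value"] < 0.05
        assert res.loc[0.01, "p_value"] > 0.05

    def test_wells_table_keeps_raw_and_clamped(self):
        t = generate_dose_response(gi50=5.0, noise_sd=10.0, seed=3)
        wells = normalize_wells(t)
        assert {"inhibition", "inhibition_raw"} <= set(wells.columns)
        assert (wells["inhibition"] >= 0).all() and (wells["inhibition"] <= 100).all()
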