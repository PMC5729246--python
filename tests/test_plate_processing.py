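"""Microplate reduction: blanking, autofluorescence, growth and synthesis
rates, normalisation, and round trips through the kinetics generator."""

import numpy as np
import pandas as pd
import pytest

from txcascade.plate import (
    AutofluorescenceModel,
    PlateWellSeries,
    blank_series,
    compute_growth_rate,
    compute_synthesis_rate,
    correlation_analysis,
    dose_response_from_summaries,
    fit_autofluorescence,
    normalize_to_reference,
    process_plate,
    read_plate_csv,
    write_plate_csv,
)
from txcascade.simulate import generate_plate_kinetics, plate_wells_from_dose_response

T = np.arange(0.0, 300.0, 5.0)


def _well(role="sample", absorbance=None, red=None, green=None, **kw):
    n = len(T)
    return PlateWellSeries(
        well=kw.pop("well", "w"),
        role=role,
        time=T.copy(),
        absorbance=np.full(n, 0.05) if absorbance is None else absorbance,
        red=np.zeros(n) if red is None else red,
        green=green,
        **kw,
    )


class TestBlanking:
    def test_sample_equal_to_blanks_gives_zero_series(self):
        blank_abs = _well("abs_blank", absorbance=np.full(len(T), 0.04), red=np.full(len(T), 100.0))
        blank_red = _well("red_blank", absorbance=np.full(len(T), 0.04), red=np.full(len(T), 100.0))
        sample = _well("sample", absorbance=np.full(len(T), 0.04), red=np.full(len(T), 100.0))
        out = blank_series(sample, [blank_abs], [blank_red])
        assert np.allclose(out.od, 0.0) and np.allclose(out.rfp, 0.0)
        assert out.flags == []

    def test_blanking_is_linear_in_the_sample_signal(self):
        rng = np.random.default_rng(0)
        bg_abs = 0.04 + 0.001 * np.sin(T / 40)
        bg_red = 100 + rng.normal(0, 1, len(T))
        signal_od = 0.02 * np.exp(0.01 * T)
        signal_red = 3.0 * T
        blanks_a = [_well("abs_blank", absorbance=bg_abs, red=bg_red)]
        blanks_r = [_well("red_blank", absorbance=bg_abs, red=bg_red)]
        sample = _well("sample", absorbance=signal_od + bg_abs, red=signal_red + bg_red)
        out = blank_series(sample, blanks_a, blanks_r)
        assert np.allclose(out.od, signal_od, atol=1e-12)
        assert np.allclose(out.rfp, signal_red, atol=1e-9)

    def test_green_blanked_exactly_with_known_autofluorescence(self):
        q, m = 1.0, 2.0
        od = 0.02 * np.exp(0.012 * T)
        signal = 50.0 * T
        green = signal + np.exp(q + m * od)
        sample = _well("sample", absorbance=od + 0.04, green=green)
        blanks_a = [_well("abs_blank", absorbance=np.full(len(T), 0.04))]
        blanks_r = [_well("red_blank")]
        out = blank_series(sample, blanks_a, blanks_r, AutofluorescenceModel(q, m))
        assert np.allclose(out.gfp, signal, rtol=1e-10)

    def test_green_without_autofluorescence_model_rejected(self):
        sample = _well("sample", green=np.ones(len(T)))
        with pytest.raises(ValueError, match="autofluorescence"):
            blank_series(sample, [_well("abs_blank")], [_well("red_blank")])

    def test_strongly_negative_od_flagged(self):
        sample = _well("sample", absorbance=np.full(len(T), 0.01))
        blanks_a = [_well("abs_blank", absorbance=np.full(len(T), 0.08))]
        out = blank_series(sample, blanks_a, [_well("red_blank")])
        assert "negative_od" in out.flags


class TestAutofluorescence:
    def _controls(self, q, m, n=2):
        od = np.linspace(0.02, 0.4, len(T))
        wells = []
        for i in range(n):
            wells.append(
                _well("autofluo_control", absorbance=od + 0.04, green=np.exp(q + m * od),
                      well=f"c{i}")
            )
        return wells, [_well("abs_blank", absorbance=np.full(len(T), 0.04))]

    def test_exact_recovery(self):
        controls, blanks = self._controls(1.0, 2.0)
        model = fit_autofluorescence(controls, blanks)
        assert model.q == pytest.approx(1.0, abs=1e-9)
        assert model.m == pytest.approx(2.0, abs=1e-9)

    def test_constant_green_flat_od_gives_zero_slope(self):
        wells = [
            _well("autofluo_control", absorbance=np.full(len(T), 0.14),
                  green=np.full(len(T), 7.0), well=f"c{i}")
            for i in range(2)
        ]
        blanks = [_well("abs_blank", absorbance=np.full(len(T), 0.04))]
        model = fit_autofluorescence(wells, blanks)
        assert model.m == 0.0
        assert model.q == pytest.approx(np.log(7.0), abs=1e-12)

    def test_duplicate_controls_match_single_control_fit(self):
        controls, blanks = self._controls(0.5, 3.0, n=2)
        both = fit_autofluorescence(controls, blanks)
        with pytest.warns(UserWarning):
            one = fit_autofluorescence(controls[:1], blanks)
        assert both.q == pytest.approx(one.q) and both.m == pytest.approx(one.m)

    def test_nonpositive_green_dropped_with_warning(self):
        controls, blanks = self._controls(1.0, 2.0)
        controls[0].green[:5] = -1.0
        with pytest.warns(UserWarning, match="non-positive"):
            model = fit_autofluorescence(controls, blanks)
        assert model.q == pytest.approx(1.0, abs=1e-6)

    def test_too_few_usable_points_rejected(self):
        wells = [_well("autofluo_control", green=np.full(len(T), -1.0), well=f"c{i}")
                 for i in range(2)]
        blanks = [_well("abs_blank", absorbance=np.full(len(T), 0.05))]
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            fit_autofluorescence(wells, blanks)


class TestGrowthAndSynthesisRates:
    @pytest.mark.parametrize("mu", [0.01, 0.02])
    def test_growth_rate_exact_on_exponential(self, mu):
        od = 0.05 * np.exp(mu * T)
        est = compute_growth_rate(T, od, window=(0.05, 0.18))
        assert est == pytest.approx(mu, rel=1e-9)

    def test_growth_window_never_entered_is_an_error(self):
        od = np.full(len(T), 0.5)
        with pytest.raises(ValueError, match="OD range"):
            compute_growth_rate(T, od)

    def test_linear_fluorescence_constant_od(self):
        od = np.full(len(T), 0.1)
        s = compute_synthesis_rate(T, 3.0 * T, od)
        assert s == pytest.approx(3.0 / 0.1, rel=1e-9)

    def test_constant_fluorescence_gives_zero(self):
        od = np.full(len(T), 0.1)
        assert compute_synthesis_rate(T, np.full(len(T), 42.0), od) == pytest.approx(0.0)

    def test_too_few_window_points_rejected(self):
        od = np.full(len(T), 0.5)
        with pytest.raises(ValueError):
            compute_synthesis_rate(T, T.copy(), od)


class TestNormalisation:
    def test_reference_mean_division(self):
        assert normalize_to_reference(6.0, [2.0, 4.0]) == pytest.approx(2.0)
        assert normalize_to_reference(3.0, [3.0]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = normalize_to_reference(6.0, [2.0, 4.0])
        b = normalize_to_reference(6.0 * 7.3, [2.0 * 7.3, 4.0 * 7.3])
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference(1.0, [0.0, 0.0])


class TestCorrelation:
    def test_exact_linear_relationships(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"x": x, "double": 2 * x, "neg": -x})
        r, p = correlation_analysis(table)
        assert r.loc["x", "double"] == pytest.approx(1.0)
        assert r.loc["x", "neg"] == pytest.approx(-1.0)
        assert p.loc["x", "double"] < 1e-6

    def test_independent_columns_weakly_correlated(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        r, _ = correlation_analysis(table)
        assert abs(r.loc["a", "b"]) < 0.1

    def test_constant_column_undefined(self):
        table = pd.DataFrame({"a": np.arange(5.0), "c": np.ones(5)})
        r, _ = correlation_analysis(table)
        assert np.isnan(r.loc["a", "c"])


class TestRoundTrips:
    def test_generator_rates_recovered_within_two_percent(self):
        mu, s_r, s_g = 0.015, 300.0, 200.0
        wells = generate_plate_kinetics(mu, s_r, s_g, seed=5)
        summaries = process_plate(wells)
        samples = summaries[summaries["role"] == "sample"]
        assert np.allclose(samples["mu"], mu, rtol=0.02)
        assert np.allclose(samples["s_cell_rfp"], s_r, rtol=0.02)
        assert np.allclose(samples["s_cell_gfp"], s_g, rtol=0.02)
        # normalised rates against the 500-unit reference cultures
        assert np.allclose(samples["s_norm_rfp"], s_r / 500.0, rtol=0.02)
        refs = summaries[summaries["role"] == "reference_RFP"]
        assert np.allclose(refs["s_norm_rfp"], 1.0, rtol=0.02)

    def test_growth_rate_estimate_insensitive_to_saturation_density(self):
        est = {}
        for od_max in (0.6, 1.2):
            wells = generate_plate_kinetics(0.014, 250.0, od_max=od_max, seed=9)
            summaries = process_plate(wells)
            est[od_max] = summaries[summaries["role"] == "sample"]["mu"].mean()
        assert est[0.6] == pytest.approx(est[1.2], rel=0.01)

    def test_plate_csv_round_trip(self, tmp_path):
        wells = generate_plate_kinetics(0.015, 100.0, 50.0, n_replicates=1, seed=2)
        write_plate_csv(wells, tmp_path / "data.csv", tmp_path / "map.csv")
        back = read_plate_csv(tmp_path / "data.csv", tmp_path / "map.csv")
        orig = {w.well: w for w in wells}
        assert set(orig) == {w.well for w in back}
        for w in back:
            assert np.allclose(w.absorbance, orig[w.well].absorbance)
            assert w.role == orig[w.well].role

    def test_dose_response_to_plate_closure(self, reg):
        """Dose-response table -> synthetic plates -> reduction reproduces the
        table within 3% (values) and 2% (growth rates)."""
        from txcascade.simulate import GenerationSpec, generate_dose_response

        spec = GenerationSpec(seed=4, model="BM", truth_column="BM_training",
                              circuits=["X_1_rg"], hsl_grid=[0.0, 10.0, 1000.0],
                              n_replicates=1, cv=0.0)
        table = generate_dose_response(spec)
        wells = plate_wells_from_dose_response(table, seed=8, n_replicates=1)
        recovered = dose_response_from_summaries(process_plate(wells))
        merged = table.df.merge(
            recovered, on=["circuit_id", "hsl_nM", "observable"], suffixes=("_true", "_est")
        )
        assert len(merged) == len(table.df)
        assert np.allclose(merged["value_est"], merged["value_true"], rtol=0.03)
        assert np.allclose(merged["mu_est"], merged["mu_true"], rtol=0.02)
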