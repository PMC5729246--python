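"""Monte Carlo prediction bands, sensitivity analyses and prediction
performance, including the bottom-up pipeline closure on synthetic data."""

import numpy as np
import pandas as pd
import pytest

from txcascade.circuits import test_ids as collection_test_ids
from txcascade.circuits import training_ids
from txcascade.fitting import (
    ParameterDistribution,
    bootstrap_training_nbm,
    fit_training_bm,
    monte_carlo_uncertainty,
)
from txcascade.params import default_parameters
from txcascade.predict import (
    SensitivitySpec,
    _positive_normal,
    predict_circuit,
    prediction_performance,
    sensitivity_multivariate,
    sensitivity_univariate,
)
from txcascade.simulate import GenerationSpec, generate_dose_response
from txcascade.steady_state import cascade_outputs


@pytest.fixture(scope="module")
def nbm_distribution(nbm_training_noisy):
    """Small two-stage bootstrap distribution on noisy training data."""
    _point, dist = bootstrap_training_nbm(nbm_training_noisy, n_datasets=40, seed=9,
                                          n_starts_point=2)
    return dist


class TestPredictCircuit:
    def test_degenerate_distribution_collapses_to_deterministic_curve(
        self, reg, nbm_params, growth_table, hsl_grid
    ):
        dist = ParameterDistribution.from_point(nbm_params.to_flat())
        topo = reg["X_1_Tr"]
        bands = predict_circuit(topo, dist, nbm_params, growth_table, hsl_grid, "NBM")
        rfp = bands.for_observable("RFP")
        mu = growth_table.set_index(["circuit_id", "hsl_nM"])["mu"]
        direct = cascade_outputs(
            topo, hsl_grid, [mu.loc[("X_1_Tr", h)] for h in hsl_grid], nbm_params, "NBM"
        )["RFP"]
        assert np.allclose(rfp["median"], direct, rtol=1e-12)
        assert np.allclose(rfp["lower"], rfp["upper"], rtol=1e-12)

    def test_inner_bands_nested_within_outer(
        self, reg, nbm_distribution, nbm_params, growth_table, hsl_grid
    ):
        topo = reg["X_rep_Tr"]
        outer = predict_circuit(topo, nbm_distribution, nbm_params, growth_table,
                                hsl_grid, "NBM", percentiles=(2.5, 97.5))
        inner = predict_circuit(topo, nbm_distribution, nbm_params, growth_table,
                                hsl_grid, "NBM", percentiles=(25.0, 75.0))
        o, i = outer.for_observable("RFP"), inner.for_observable("RFP")
        assert np.all(o["lower"] <= i["lower"] + 1e-12)
        assert np.all(i["upper"] <= o["upper"] + 1e-12)
        assert np.all(o["lower"] <= o["median"]) and np.all(o["median"] <= o["upper"])

    def test_median_curve_monotone_for_nbm_cascade(
        self, reg, nbm_distribution, nbm_params, hsl_grid
    ):
        """At fixed growth rate every no-burden draw curve is monotone, so the
        pointwise median inherits the direction (one inversion: falling)."""
        topo = reg["X_1_Tr"]
        mu = {("X_1_Tr", float(h)): 0.014 for h in hsl_grid}
        bands = predict_circuit(topo, nbm_distribution, nbm_params, mu, hsl_grid, "NBM")
        med = bands.for_observable("RFP")["median"].to_numpy()
        assert np.all(np.diff(med) <= 1e-12)

    def test_bands_widen_with_training_noise(self, reg, nbm_params, growth_table, hsl_grid):
        """Wider replicate noise in the training data propagates to wider
        prediction bands."""
        widths = []
        for cv in (0.0, 0.10, 0.25):
            spec = GenerationSpec(seed=31, circuits=training_ids(), cv=cv)
            data = generate_dose_response(spec)
            _, dist = bootstrap_training_nbm(data, n_datasets=25, seed=13,
                                             n_starts_point=2)
            bands = predict_circuit(reg["X_1_Tr"], dist, nbm_params, growth_table,
                                    hsl_grid, "NBM")
            b = bands.for_observable("RFP")
            widths.append(float(np.mean(b["upper"] - b["lower"])))
        assert widths[0] < widths[1] < widths[2]


class TestSensitivity:
    def test_positive_gaussian_quantiles_match_cv(self):
        rng = np.random.default_rng(0)
        draws = _positive_normal(rng, 10.0, 2.5, 40000)
        assert np.percentile(draws, 2.5) == pytest.approx(10 * 0.51, rel=0.02)
        assert np.percentile(draws, 97.5) == pytest.approx(10 * 1.49, rel=0.02)
        assert np.all(draws > 0)

    def test_small_cv_collapses_bands(self, reg, nbm_params, growth_table, hsl_grid):
        spec = SensitivitySpec(cv=1e-6, n_draws=50, seed=1)
        bands = sensitivity_univariate(reg["X_2_Tr"], nbm_params, "delta", spec,
                                       growth_table, hsl_grid)
        b = bands.for_observable("RFP")
        assert np.all((b["upper"] - b["lower"]) / b["median"] < 1e-4)

    def test_invalid_target_rejected(self, reg, nbm_params, growth_table, hsl_grid):
        with pytest.raises(ValueError, match="target"):
            sensitivity_univariate(reg["X_2_Tr"], nbm_params, "gamma",
                                   SensitivitySpec(), growth_table, hsl_grid)

    def test_basal_rate_perturbation_hits_tet_device_harder(
        self, reg, nbm_params, growth_table, hsl_grid
    ):
        """The tet NOT gate is a steep, sensitive switch: perturbing the basal
        rates produces wider relative bands through P_LtetO1 than through the
        lac device."""
        spec = SensitivitySpec(cv=0.25, n_draws=400, seed=3)
        widths = {}
        for cid in ("X_2_Tr", "X_3_Lr"):
            bands = sensitivity_univariate(reg[cid], nbm_params, "delta", spec,
                                           growth_table, hsl_grid)
            b = bands.for_observable("RFP")
            widths[cid] = ((b["upper"] - b["lower"]) / b["median"]).mean()
        assert widths["X_2_Tr"] > widths["X_3_Lr"]

    def test_multivariate_preserves_sample_correlation(
        self, reg, nbm_params, growth_table, hsl_grid
    ):
        rng = np.random.default_rng(5)
        flat = nbm_params.to_flat()
        names = [f"{d}.{p}" for d in ("X_1", "T") for p in ("delta", "alpha", "K", "eta")]
        z = rng.normal(size=300)
        cols = {}
        for n in names:
            # X_1.alpha and X_1.K perfectly correlated; others independent
            src = z if n in ("X_1.alpha", "X_1.K") else rng.normal(size=300)
            cols[n] = flat[n] * (1 + 0.05 * src)
        dist = ParameterDistribution(pd.DataFrame(cols))
        bands = sensitivity_multivariate(reg["X_1_Tr"], dist, nbm_params,
                                         SensitivitySpec(cv=0.25, n_draws=500, seed=2),
                                         growth_table, hsl_grid)
        corr = bands.parameter_samples[["X_1.alpha", "X_1.K"]].corr().iloc[0, 1]
        assert corr > 0.95

    def test_multivariate_bands_contain_univariate(
        self, reg, nbm_distribution, nbm_params, growth_table, hsl_grid
    ):
        spec = SensitivitySpec(cv=0.25, n_draws=800, seed=4)
        # centre both analyses on the same estimates (distribution medians),
        # on a dense grid at fixed growth rate for a stable point fraction
        centre = nbm_params.updated(dict(nbm_distribution.median()))
        grid = np.concatenate([[0.0], np.geomspace(0.05, 2e4, 24)])
        mu = {("X_1_Tr", float(h)): 0.014 for h in grid}
        mv = sensitivity_multivariate(reg["X_1_Tr"], nbm_distribution, centre, spec,
                                      mu, grid).for_observable("RFP")
        uv = sensitivity_univariate(reg["X_1_Tr"], centre, "K", spec,
                                    mu, grid).for_observable("RFP")
        contained = (mv["lower"].to_numpy() <= uv["lower"].to_numpy() + 1e-9) & (
            mv["upper"].to_numpy() >= uv["upper"].to_numpy() - 1e-9
        )
        assert contained.mean() >= 0.9


class TestPerformance:
    def _table(self, values):
        return pd.DataFrame(
            dict(circuit_id="c", hsl_nM=np.arange(len(values), dtype=float),
                 observable="RFP", value=values)
        )

    def test_perfect_and_inverse_agreement(self):
        obs = self._table([1.0, 2.0, 5.0, 9.0])
        perf, _ = prediction_performance(obs, obs.copy())
        assert perf["r"].iloc[0] == pytest.approx(1.0)
        anti = self._table([9.0, 5.0, 2.0, 1.0])
        anti["value"] = [-v for v in [1.0, 2.0, 5.0, 9.0]]
        perf, _ = prediction_performance(obs, anti)
        assert perf["r"].iloc[0] == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        obs = self._table([1.0, 2.0])
        with pytest.raises(ValueError):
            prediction_performance(obs, obs.copy())


class TestPipelineClosure:
    def test_bottom_up_burden_prediction_tracks_truth(self, reg, bm_collection_noisy,
                                                      bm_params, growth_table, hsl_grid):
        """Fit the burden model on the monitor training circuits and predict
        all eight unseen test circuits: observed-vs-predicted correlation
        > 0.95, and the generating truth inside the 95% bands of the
        multivariate (CV 25%) sensitivity analysis at >= 90% of grid points
        (the band flavour the source analysis uses to capture its data)."""
        from txcascade.fitting import bootstrap_training_bm

        train_slice = bm_collection_noisy.subset(
            circuits=training_ids(monitor=True) + ["Mon_rg"]
        )
        point = fit_training_bm(train_slice, seed=0, n_starts=2)
        _, dist = bootstrap_training_bm(train_slice, n_datasets=25, seed=1,
                                        n_starts_point=2)
        observed = bm_collection_noisy.condition_means()
        spec = SensitivitySpec(cv=0.25, n_draws=300, seed=2)
        mu = growth_table.set_index(["circuit_id", "hsl_nM"])["mu"]
        pred_rows, covered, total = [], 0, 0
        for cid in collection_test_ids(monitor=True):
            topo = reg[cid]
            bands = predict_circuit(topo, dist, point.params, growth_table, hsl_grid, "BM")
            b = bands.for_observable("RFP")
            pred_rows.append(
                b.rename(columns={"median": "value"}).assign(circuit_id=cid)[
                    ["circuit_id", "hsl_nM", "observable", "value"]
                ]
            )
            wide = sensitivity_multivariate(
                topo, dist, point.params, spec, growth_table, hsl_grid, "BM"
            ).for_observable("RFP")
            truth = cascade_outputs(
                topo, hsl_grid, [mu.loc[(cid, h)] for h in hsl_grid], bm_params, "BM"
            )["RFP"]
            inside = (wide["lower"].to_numpy() <= truth) & (truth <= wide["upper"].to_numpy())
            covered += int(inside.sum())
            total += len(truth)
        assert covered / total >= 0.9
        perf, _ = prediction_performance(
            observed[observed["observable"] == "RFP"], pd.concat(pred_rows)
        )
        assert perf.loc[perf["observable"] == "RFP", "r"].iloc[0] > 0.95
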