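import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from alpinecast.climate import BioclimGrid, compute_bioclim, apply_gcm_delta
from alpinecast.climate import GcmScenario
from alpinecast.config import (DailySynthesisConfig, LandscapeConfig,
                               SnowModelParams, TrueResponseParams)
from alpinecast.gam import DegenerateDataError
from alpinecast.geometry import GridGeometry
from alpinecast.metrics import roc_auc, spearman_rho
from alpinecast.synthetic import (VegetationMap, generate_climatology,
                                  generate_dem, generate_vegetation)
from alpinecast.terrain import derive_terrain
from alpinecast.vegmodels import (fit_fraction_models, fit_zone_model,
                                  fraction_training_table,
                                  increased_mse_importance, make_zone_labels,
                                  predict_fractions, predict_zone_probability,
                                  zone_training_table)


def _synthetic_zone_table(n, seed, beta_wi=1.2, noise=True):
    """Direct draws from a known zone response over realistic bioclim ranges."""
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame({
        "wi": rng.uniform(5, 100, n),
        "tmc": rng.uniform(-22, -4, n),
        "prs": rng.uniform(700, 1800, n),
        "msw": rng.uniform(20, 1200, n),
    })
    eta = beta_wi * (15.0 - tab["wi"]) + 0.002 * (tab["msw"] - 300)
    p = expit(eta)
    draws = rng.random(n) < p if noise else p > 0.5
    tab["zone_presence"] = draws.astype(int)
    return tab


class TestZoneLabels:
    def test_all_zero_cover_is_absent(self):
        geom = GridGeometry(2, 2, 300.0)
        veg = VegetationMap(np.zeros((6, 6)), np.zeros((6, 6)), np.zeros((6, 6)),
                            GridGeometry(6, 6, 100.0))
        np.testing.assert_array_equal(make_zone_labels(veg, geom), 0)

    def test_full_cover_is_present(self):
        geom = GridGeometry(2, 2, 300.0)
        ones = np.ones((6, 6)) / 3
        veg = VegetationMap(ones, ones, ones, GridGeometry(6, 6, 100.0))
        np.testing.assert_array_equal(make_zone_labels(veg, geom), 1)

    def test_hand_count_on_toy_grid(self):
        # vegetated west half only: labels follow the coarse-cell means
        fine = GridGeometry(4, 4, 100.0)
        pp = np.zeros((4, 4))
        pp[:, :2] = 0.5
        veg = VegetationMap(pp, np.zeros((4, 4)), np.zeros((4, 4)), fine)
        labels = make_zone_labels(veg, fine.coarsen(2))
        np.testing.assert_array_equal(labels, [[1, 0], [1, 0]])


class TestZoneModel:
    def test_separable_signal_recovers_high_auc_and_negative_wi_effect(self):
        tab = _synthetic_zone_table(2000, 0, beta_wi=4.0, noise=False)
        fit = fit_zone_model(tab, n_bootstrap=10)
        scores = fit.model.fitted_values_
        assert roc_auc(scores, tab["zone_presence"]) >= 0.99
        # partial surface decreases along WI at fixed TMC
        grid = pd.DataFrame({"wi": np.linspace(10, 90, 40), "tmc": -12.0,
                             "prs": 1200.0, "msw": 500.0})
        probs = fit.model.predict(grid)
        # cold (low-WI) side suitable, warm side not, with no spurious revival
        assert probs[0] > 0.9 and probs[-1] < 0.1
        assert probs[grid["wi"].to_numpy() > 30].max() < 0.1
        assert np.all(np.diff(probs) < 0.05)

    def test_permuted_labels_near_null_auc(self):
        tab = _synthetic_zone_table(2000, 1)
        tab["zone_presence"] = np.random.default_rng(2).permutation(
            tab["zone_presence"].to_numpy())
        fit = fit_zone_model(tab, n_bootstrap=10)
        assert 0.45 <= roc_auc(fit.model.fitted_values_, tab["zone_presence"]) <= 0.65

    def test_single_class_and_tiny_tables_rejected(self):
        tab = _synthetic_zone_table(100, 3)
        tab["zone_presence"] = 1
        with pytest.raises(DegenerateDataError):
            fit_zone_model(tab)
        with pytest.raises(DegenerateDataError):
            fit_zone_model(_synthetic_zone_table(20, 3))

    def test_prediction_consistency_and_resampling(self):
        tab = _synthetic_zone_table(600, 4)
        fit = fit_zone_model(tab, n_bootstrap=5)
        geom = GridGeometry(20, 30, 1000.0)
        bio = BioclimGrid(wi=tab["wi"].to_numpy().reshape(20, 30),
                          tmc=tab["tmc"].to_numpy().reshape(20, 30),
                          prs=tab["prs"].to_numpy().reshape(20, 30),
                          msw=tab["msw"].to_numpy().reshape(20, 30), geom=geom)
        coarse, fine = predict_zone_probability(fit, bio, geom.refine(10))
        np.testing.assert_allclose(coarse.ravel(), fit.model.fitted_values_,
                                   rtol=1e-9)
        # nearest-neighbor resampling preserves coarse values exactly
        np.testing.assert_array_equal(fine[::10, ::10], coarse)
        assert np.all((coarse > 0) & (coarse < 1))

    def test_constant_predictors_give_constant_grid(self):
        tab = _synthetic_zone_table(600, 5)
        fit = fit_zone_model(tab, n_bootstrap=5)
        geom = GridGeometry(3, 3, 1000.0)
        const = BioclimGrid(wi=np.full((3, 3), 40.0), tmc=np.full((3, 3), -10.0),
                            prs=np.full((3, 3), 1200.0), msw=np.full((3, 3), 400.0),
                            geom=geom)
        coarse, _ = predict_zone_probability(fit, const)
        assert np.ptp(coarse) == 0.0


def _fraction_data(n, seed, signal="ridge_distance"):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "slope": rng.uniform(0, 45, n),
        "aspect": rng.uniform(0, 360, n),
        "curvature": rng.normal(0, 1e-3, n),
        "twi": rng.uniform(2, 12, n),
        "ridge_distance": rng.uniform(0, 2000, n),
        "zone_probability": rng.random(n),
    })
    if signal == "ridge_distance":
        y = 0.7 * np.exp(-X["ridge_distance"] / 300.0)
    elif signal == "zone_probability":
        y = 0.6 * X["zone_probability"] ** 2
    elif signal == "constant":
        return X, np.full(n, 0.4)
    y = np.clip(y + rng.normal(0, 0.02, n), 0, 1)
    return X, np.asarray(y)


class TestFractionModels:
    def test_constant_response_has_flat_predictions_and_no_importance(self):
        X, y = _fraction_data(1500, 0, "constant")
        fit = fit_fraction_models(X, {"pp": y}, n_trees=100, seed=0)
        rf = fit.forests["pp"]
        assert rf.predict(X.to_numpy()).std() < 0.01
        imp = increased_mse_importance(rf, X, y, n_permutations=3, seed=0)
        assert np.abs(imp.to_numpy()).max() < 1e-3

    @pytest.mark.parametrize("signal", ["ridge_distance", "zone_probability"])
    def test_planted_signal_ranks_first(self, signal):
        X, y = _fraction_data(2000, 1, signal)
        fit = fit_fraction_models(X, {"pp": y}, n_trees=200, seed=1)
        imp = increased_mse_importance(fit.forests["pp"], X, y,
                                       n_permutations=5, seed=1)
        assert imp.index[0] == signal
        assert imp.iloc[0] > 5 * abs(imp.iloc[1])

    def test_null_variable_importance_near_zero(self):
        X, y = _fraction_data(2000, 2, "ridge_distance")
        fit = fit_fraction_models(X, {"pp": y}, n_trees=200, seed=2)
        imp = increased_mse_importance(fit.forests["pp"], X, y,
                                       n_permutations=5, seed=2)
        assert abs(imp["aspect"]) < 0.1 * imp["ridge_distance"]

    def test_response_column_cannot_be_permuted(self):
        X, y = _fraction_data(300, 3)
        fit = fit_fraction_models(X, {"pp": y}, n_trees=50, seed=3)
        with pytest.raises(ValueError):
            increased_mse_importance(fit.forests["pp"], X, y,
                                     variables=["area_fraction"])

    def test_forest_determinism(self):
        X, y = _fraction_data(500, 4)
        a = fit_fraction_models(X, {"pp": y}, n_trees=80, seed=7)
        b = fit_fraction_models(X, {"pp": y}, n_trees=80, seed=7)
        np.testing.assert_array_equal(a.forests["pp"].predict(X.to_numpy()),
                                      b.forests["pp"].predict(X.to_numpy()))


class TestPredictFractions:
    small = LandscapeConfig(domain_width_m=4000, domain_height_m=4000,
                            terrain_resolution_m=100, climate_resolution_m=1000,
                            territory_resolution_m=400, seed=11)

    def _world(self, noise_sd=0.0):
        dem, geom = generate_dem(self.small)
        terrain = derive_terrain(dem, geom, 0.97)
        clim = generate_climatology(dem, self.small, temp_noise_sd=0.0,
                                    precip_noise_cv=0.0)
        bio = compute_bioclim(clim, SnowModelParams(), DailySynthesisConfig(seed=1))
        # pitch the alpine heat ceiling inside this small world's WI range so
        # roughly the coolest third of the domain supports the zone
        truth = TrueResponseParams(noise_sd=noise_sd,
                                   wi_center=float(np.quantile(bio.wi, 0.3)))
        veg = generate_vegetation(bio, terrain, truth, seed=2)
        return terrain, bio, truth, veg

    def test_recovery_of_strong_signal_fractions(self):
        terrain, bio, truth, veg = self._world(noise_sd=0.02)
        from alpinecast.synthetic import true_zone_suitability
        from alpinecast.geometry import upsample_nearest
        zone_fine = upsample_nearest(true_zone_suitability(bio, truth),
                                     terrain.geom.factor_to(bio.geom))
        X, valid = fraction_training_table(terrain, zone_fine)
        y = veg.pp.ravel()[valid]
        fit = fit_fraction_models(X, {"pp": y}, n_trees=150, seed=1)
        rho, _ = spearman_rho(fit.forests["pp"].predict(X.to_numpy()), y)
        assert rho >= 0.85

    def test_outputs_clipped_and_zone_gating_respected(self):
        terrain, bio, truth, veg = self._world()
        from alpinecast.synthetic import true_zone_suitability
        from alpinecast.geometry import upsample_nearest
        zone_fine = upsample_nearest(true_zone_suitability(bio, truth),
                                     terrain.geom.factor_to(bio.geom))
        X, valid = fraction_training_table(terrain, zone_fine)
        resp = {n: veg.as_dict()[n].ravel()[valid] for n in ("pp", "sg", "ff")}
        fit = fit_fraction_models(X, resp, n_trees=100, seed=2)
        out = predict_fractions(fit, terrain, zone_fine)
        assert min(out.pp.min(), out.sg.min(), out.ff.min()) >= 0.0
        assert out.total().max() <= 1.0 + 1e-9
        # with the zone switched off everywhere, predictions collapse
        off = predict_fractions(fit, terrain, np.zeros(terrain.geom.shape))
        assert off.pp.mean() < 0.05
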