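"""Synthetic-data generator: structure, determinism, self-consistency."""

import numpy as np
import pytest

from soilrisk.compositional import clr_transform
from soilrisk.exceptions import ValidationError
from soilrisk.model import poisson_loglik
from soilrisk.simulate import (
    ScenarioConfig,
    generate_mortality,
    generate_scenario,
    generate_towns,
)

from conftest import small_scenario_config


class TestTowns:
    def test_queen_adjacency_degrees(self):
        cfg = ScenarioConfig(n_rows=3, n_cols=3, n_soil_samples=10)
        towns, graph = generate_towns(cfg, seed=0)
        assert towns.n_towns == 9
        degrees = graph.degrees()
        assert degrees[0] == 3          # corner
        assert degrees[4] == 8          # centre
        assert graph.n_components == 1

    def test_zone_dummies_present(self):
        cfg = small_scenario_config()
        towns, _ = generate_towns(cfg, seed=1)
        assert "zone_semiurban" in towns.covariate_names
        assert "zone_urban" in towns.covariate_names
        assert set(np.unique(towns.covariates[:, -2:])) <= {0.0, 1.0}

    def test_determinism(self):
        cfg = small_scenario_config()
        a, _ = generate_towns(cfg, seed=3)
        b, _ = generate_towns(cfg, seed=3)
        assert np.array_equal(a.expected, b.expected)
        assert np.array_equal(a.covariates, b.covariates)


class TestConfounding:
    def test_zero_confounding_leaves_covariate_independent(self, reference_scenario):
        _, _, towns, _, truth = reference_scenario
        r = np.corrcoef(towns.covariates[:, 0], truth.fields_centroids[:, 0])[0, 1]
        assert abs(r) < 0.1  # 400 towns

    def test_confounding_knob_induces_correlation(self):
        cfg = small_scenario_config(confounding=0.7, n_rows=15, n_cols=15)
        _, towns, _, truth = generate_scenario(cfg, seed=5)
        r = np.corrcoef(towns.covariates[:, 0], truth.fields_centroids[:, 0])[0, 1]
        assert r > 0.5


class TestSoil:
    def test_all_concentrations_positive(self, reference_scenario):
        _, soil, *_ = reference_scenario
        assert np.all(soil.concentrations > 0)

    def test_noiseless_single_loading_is_exact(self):
        loadings = np.array([[1.3], [0.0]])
        cfg = ScenarioConfig(
            n_rows=4, n_cols=4, n_soil_samples=50, elements=["Pb", "Zn"],
            loadings=loadings, base_log_conc=np.log([25.0, 60.0]),
            noise_sd=0.0, beta=(0.1,),
        )
        soil, _, _, truth = generate_scenario(cfg, seed=6)
        expected = np.log(25.0) + 1.3 * truth.fields_samples[:, 0]
        assert np.allclose(np.log(soil.concentrations[:, 0]), expected,
                           atol=1e-10)
        assert np.allclose(soil.concentrations[:, 1], 60.0)

    def test_closure_rows_sum_to_total_and_clr_opens(self):
        cfg = small_scenario_config(closure=True, closure_total=1e6)
        soil, *_ = generate_scenario(cfg, seed=7)
        assert np.allclose(soil.concentrations.sum(axis=1), 1e6, rtol=1e-9)
        y = clr_transform(soil).values
        assert np.max(np.abs(y.sum(axis=1))) < 1e-10


class TestMortality:
    def test_null_model_mean_ratio_is_one(self):
        cfg = ScenarioConfig(n_rows=20, n_cols=20, n_soil_samples=20,
                             beta=(0.0, 0.0), sd_u=0.0, sd_v=0.0,
                             mean_expected=50.0)
        _, towns, _, _ = generate_scenario(cfg, seed=8)
        ratio = towns.observed / towns.expected
        mc_sd = np.sqrt(np.mean(1.0 / towns.expected) / towns.n_towns)
        assert abs(ratio.mean() - 1.0) < 3 * mc_sd

    def test_effect_shows_in_exposure_deciles(self, reference_scenario):
        _, _, towns, _, truth = reference_scenario
        expos = truth.fields_centroids[:, 0]
        ratio = towns.observed / towns.expected
        hi = ratio[expos >= np.quantile(expos, 0.9)].mean()
        lo = ratio[expos <= np.quantile(expos, 0.1)].mean()
        assert hi > lo

    def test_determinism(self):
        cfg = small_scenario_config()
        _, t1, _, _ = generate_scenario(cfg, seed=9)
        _, t2, _, _ = generate_scenario(cfg, seed=9)
        assert np.array_equal(t1.observed, t2.observed)

    def test_eta_overflow_guard(self):
        cfg = small_scenario_config()
        towns, _ = generate_towns(cfg, seed=10)
        with pytest.raises(ValidationError, match="30"):
            generate_mortality(towns, np.full(towns.n_towns, 40.0), seed=0)


class TestTruthConsistency:
    def test_lambda_matches_recomputed_eta(self, reference_scenario):
        cfg, _, towns, _, truth = reference_scenario
        eta = (cfg.alpha
               + truth.fields_centroids @ np.asarray(cfg.beta)
               + towns.covariates[:, : cfg.delta.size] @ cfg.delta
               + truth.u + truth.v)
        assert np.allclose(truth.lam, np.exp(eta), atol=1e-12)

    def test_generator_respects_its_own_likelihood(self, reference_scenario):
        _, _, towns, _, truth = reference_scenario
        ll = poisson_loglik(towns.observed, towns.expected, truth.eta)
        assert np.isfinite(ll)
        # mean scaled deviance about 1 per observation
        mu = towns.expected * truth.lam
        o = towns.observed.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(o > 0, o * np.log(o / mu), 0.0) - (o - mu)
        deviance = 2 * dev_terms.sum() / towns.n_towns
        assert 0.7 < deviance < 1.3

    def test_bym_icar_component_sums_to_zero(self, reference_scenario):
        *_, truth = reference_scenario
        assert abs(truth.u.sum()) < 1e-8

    def test_exposure_scores_shape_and_determinism(self, reference_scenario):
        *_, truth = reference_scenario
        s1 = truth.exposure_scores(factor=0, seed=3)
        s2 = truth.exposure_scores(factor=0, seed=3)
        assert np.array_equal(s1.scores, s2.scores)
        assert s1.scores.shape == (truth.fields_samples.shape[0], 1)
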