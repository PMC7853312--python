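import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pikapop.datasets import pika_localities
from pikapop.landscape import (
    build_distance_set,
    climate_distance,
    climate_pca,
    elevation_matrix,
    haversine_matrix,
    model_scan,
    mrm,
    population_midpoints,
)
from pikapop.synthetic_data import ClimateGeographyParams, simulate_climate_geography


def sym_random(rng, m):
    a = rng.random((m, m))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    return a


class TestHaversine:
    def test_one_degree_longitude_at_equator(self):
        loc = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [0.0, 1.0], "elevation_m": [0, 0]})
        d = haversine_matrix(loc)
        assert d[0, 1] == pytest.approx(2 * np.pi * 6371 / 360, abs=1e-3)

    def test_identical_coordinates_zero(self):
        loc = pd.DataFrame({"latitude": [45.0, 45.0], "longitude": [-110.0, -110.0], "elevation_m": [0, 0]})
        assert haversine_matrix(loc)[0, 1] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        loc = pd.DataFrame(
            {"latitude": rng.uniform(-80, 80, 5), "longitude": rng.uniform(-179, 179, 5)}
        )
        d = haversine_matrix(loc)
        assert np.allclose(d, d.T) and (d >= 0).all()
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestElevation:
    def test_study_localities_example(self):
        loc = pika_localities()
        e = elevation_matrix(loc)
        pops = list(loc["population"])
        i, j = pops.index("Bodie"), pops.index("Pipet Tarn")
        assert e[i, j] == pytest.approx(670.0)
        assert np.allclose(np.diag(e), 0.0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        loc = pd.DataFrame({"elevation_m": rng.uniform(1000, 4000, 6)})
        e = elevation_matrix(loc)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert e[i, j] <= e[i, k] + e[k, j] + 1e-9


class TestClimatePca:
    def test_duplicated_rows_get_identical_scores(self):
        _, climate = simulate_climate_geography(ClimateGeographyParams(seed=1))
        dup = pd.concat([climate, climate.iloc[[0]]], ignore_index=True)
        scores, _ = climate_pca(dup)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-9)

    def test_variance_fractions_sum_to_one(self):
        _, climate = simulate_climate_geography(ClimateGeographyParams(seed=2))
        _, var = climate_pca(climate)
        assert var.sum() == pytest.approx(1.0)

    def test_constant_variable_with_scaling_named(self):
        _, climate = simulate_climate_geography(ClimateGeographyParams(seed=3))
        climate["bio7"] = 5.0
        with pytest.raises(ValueError, match="bio7"):
            climate_pca(climate, scale=True)
        climate_pca(climate, scale=False)  # unscaled path tolerates it

    def test_climate_distance_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        scores = rng.random((7, 3))
        d = climate_distance(scores, 1)
        for i in range(7):
            for j in range(7):
                assert d[i, j] == pytest.approx(abs(scores[i, 1] - scores[j, 1]))

    def test_climate_distance_scalar_examples(self):
        d = climate_distance(np.array([[1.0], [4.0]]), 0)
        assert d[0, 1] == 3.0


class TestMrm:
    def test_perfect_fit(self):
        rng = np.random.default_rng(5)
        g = sym_random(rng, 8)
        res = mrm(2 * g, {"Geography": g}, n_perm=199, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.coefficients["Geography"] == pytest.approx(2.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 200)

    def test_added_noise_predictor_never_lowers_r2(self):
        rng = np.random.default_rng(6)
        g, noise, resp = sym_random(rng, 9), sym_random(rng, 9), sym_random(rng, 9)
        r1 = mrm(resp, {"g": g}, n_perm=99, seed=1).r_squared
        r2 = mrm(resp, {"g": g, "noise": noise}, n_perm=99, seed=1).r_squared
        assert r2 >= r1 - 1e-12

    def test_rank_deficient_predictors_rejected(self):
        rng = np.random.default_rng(7)
        g = sym_random(rng, 6)
        with pytest.raises(ValueError, match="rank-deficient"):
            mrm(sym_random(rng, 6), {"a": g, "b": 2 * g}, n_perm=99, seed=0)

    def test_null_pvalues_approximately_uniform(self):
        from scipy.stats import kstest

        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            resp, pred = sym_random(rng, 10), sym_random(rng, 10)
            pvals.append(mrm(resp, {"x": pred}, n_perm=199, seed=rep).p_value)
        _, p = kstest(pvals, "uniform")
        assert p > 0.01

    def test_population_reordering_leaves_r2_unchanged(self):
        rng = np.random.default_rng(8)
        resp, pred = sym_random(rng, 9), sym_random(rng, 9)
        r = mrm(resp, {"x": pred}, n_perm=99, seed=0).r_squared
        perm = rng.permutation(9)
        r_perm = mrm(
            resp[np.ix_(perm, perm)], {"x": pred[np.ix_(perm, perm)]}, n_perm=99, seed=0
        ).r_squared
        assert r_perm == pytest.approx(r, abs=1e-12)


class TestModelScan:
    def test_fifteen_models_and_nested_monotonicity(self):
        samples, climate = simulate_climate_geography(ClimateGeographyParams(seed=9))
        ds = build_distance_set(samples, climate)
        rng = np.random.default_rng(9)
        resp = 0.002 * ds.geographic + sym_random(rng, len(ds.populations)) * 0.05
        table = model_scan(resp, ds.predictors(), n_perm=99, seed=2)
        assert len(table) == 15
        r2 = dict(zip(table["model"], table["r_squared"]))
        for model, r in r2.items():
            parts = set(model.split(" + "))
            for other, r_other in r2.items():
                if set(other.split(" + ")) < parts:
                    assert r >= r_other - 1e-12

    def test_geography_only_response_found_by_single_predictor_model(self):
        samples, climate = simulate_climate_geography(ClimateGeographyParams(seed=10))
        ds = build_distance_set(samples, climate)
        resp = 0.001 * ds.geographic
        table = model_scan(resp, ds.predictors(), n_perm=99, seed=3).set_index("model")
        full = table.loc["Elevation + Geography + Climate 1 + Climate 2", "r_squared"]
        assert table.loc["Geography", "r_squared"] >= full - 0.02


class TestMidpoints:
    def test_population_midpoint_is_mean_of_members(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "population": ["p1", "p1", "p2"],
                "latitude": [40.0, 42.0, 45.0],
                "longitude": [-115.0, -117.0, -110.0],
                "elevation_m": [2000.0, 3000.0, 1500.0],
            }
        )
        mids = population_midpoints(samples)
        row = mids.set_index("population").loc["p1"]
        assert row["latitude"] == 41.0 and row["longitude"] == -116.0 and row["elevation_m"] == 2500.0
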