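"""Synthetic-data generator: hierarchy ordering, calibration, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from pointcount.detection import DetectionParams, distance_cell_probs, removal_cell_probs
from pointcount.simulate import (
    ScenarioConfig,
    expected_counts,
    read_dataset,
    scenario_grid,
    simulate_dataset,
    simulate_trend_dataset,
    validate_records,
    write_dataset,
)


class TestExpectedCounts:
    def test_no_thinning_limit(self):
        cfg = ScenarioConfig(lam=5, p_presence=1 - 1e-12, availability=1 - 1e-12,
                             sigma=1e9)
        assert expected_counts(cfg) == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize("pp, pa, expected", [
        (0.8, 0.8, 1.058), (0.4, 0.4, 0.418),
    ])
    def test_analytic_products(self, pp, pa, expected):
        cfg = ScenarioConfig(lam=5, p_presence=pp, availability=pa)
        assert expected_counts(cfg) == pytest.approx(expected, abs=2e-3)


class TestSimulateDataset:
    def test_latent_ordering_invariant(self):
        """detections <= N_avail <= N_pres <= N_super for every record."""
        cfg = ScenarioConfig(p_presence=0.6, availability=0.6, n_points=500, n_visits=3)
        ds = simulate_dataset(cfg, seed=3)
        lat = ds.latents
        assert (lat.n_detected <= lat.n_available).all()
        assert (lat.n_available <= lat.n_present).all()
        assert (lat.n_present <= lat.n_super).all()
        assert (lat.n_detected >= 0).all()
        # detection records agree with the latent detected counts
        counted = (ds.detections.groupby(["point_id", "visit"]).size()
                   .reindex(pd.MultiIndex.from_frame(lat[["point_id", "visit"]]),
                            fill_value=0))
        np.testing.assert_array_equal(counted.to_numpy(), lat.n_detected.to_numpy())

    def test_superpopulation_mean_calibration(self):
        cfg = ScenarioConfig(lam=5, n_points=4000, n_visits=1)
        ds = simulate_dataset(cfg, seed=11)
        per_point = ds.latents.groupby("point_id").n_super.first()
        se = np.sqrt(5.0 / len(per_point))
        assert abs(per_point.mean() - 5.0) < 3 * se

    def test_detected_mean_matches_analytic(self):
        cfg = ScenarioConfig(lam=5, p_presence=0.8, availability=0.8,
                             n_points=4000, n_visits=1)
        ds = simulate_dataset(cfg, seed=5)
        mean = ds.latents.n_detected.mean()
        mu = expected_counts(cfg)
        se = ds.latents.n_detected.std(ddof=1) / np.sqrt(len(ds.latents))
        assert abs(mean - mu) < 3 * se

    def test_no_thinning_limit_equals_superpopulation(self):
        cfg = ScenarioConfig(lam=5, p_presence=1 - 1e-12, availability=1 - 1e-12,
                             sigma=1e9, n_points=50, n_visits=2)
        ds = simulate_dataset(cfg, seed=1)
        assert (ds.latents.n_detected == ds.latents.n_super).all()

    def test_cell_frequencies_match_conditional_multinomial(self):
        """Empirical (distance x interval) frequencies over ~1e5 detections
        match pi_d*pi_a/(p_d*phi) (chi-square GOF, alpha = 0.01)."""
        cfg = ScenarioConfig(lam=5, p_presence=0.8, availability=0.8,
                             n_points=35000, n_visits=3)
        ds = simulate_dataset(cfg, seed=17)
        assert ds.n_detections > 1e5
        pi_d, p_d = distance_cell_probs(cfg.binning, DetectionParams(cfg.sigma))
        pi_a, phi = removal_cell_probs(cfg.p_a, cfg.removal)
        expected = np.outer(pi_d / p_d, pi_a / phi).ravel()
        obs = (ds.detections.groupby(["distance_class", "time_interval"]).size()
               .reindex(pd.MultiIndex.from_product([range(1, 5), range(1, 4)]),
                        fill_value=0).to_numpy())
        stat, p = chisquare(obs, expected * obs.sum())
        assert p > 0.01

    def test_seed_determinism(self):
        cfg = ScenarioConfig(n_points=80, n_visits=2)
        a = simulate_dataset(cfg, seed=9)
        b = simulate_dataset(cfg, seed=9)
        c = simulate_dataset(cfg, seed=10)
        assert a == b
        assert not a.detections.equals(c.detections)

    def test_growing_points_preserves_early_streams(self):
        small = simulate_dataset(ScenarioConfig(n_points=40, n_visits=2), seed=4)
        big = simulate_dataset(ScenarioConfig(n_points=80, n_visits=2), seed=4)
        pd.testing.assert_frame_equal(
            small.latents, big.latents[big.latents.point_id <= 40].reset_index(drop=True))

    def test_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_dataset(ScenarioConfig())

    @pytest.mark.parametrize("kw", [
        {"lam": -1}, {"p_presence": 0.0}, {"availability": 1.0},
        {"n_points": 0}, {"sigma": 0.0},
        {"availability_interpretation": "sometimes"},
    ])
    def test_config_validation(self, kw):
        with pytest.raises(ValueError):
            ScenarioConfig(**kw)

    def test_overall_interpretation(self):
        cfg = ScenarioConfig(availability=0.875, availability_interpretation="overall")
        assert cfg.p_a == pytest.approx(0.5)


class TestScenarioGrid:
    def test_full_cross_is_72(self):
        grid = scenario_grid()
        assert len(grid) == 72
        assert len({c.scenario_id for c in grid}) == 72

    def test_single_visit_restriction(self):
        assert len(scenario_grid(n_visits=(1,))) == 36

    def test_factor_levels(self):
        grid = scenario_grid()
        assert {c.p_presence for c in grid} == {0.4, 0.6, 0.8}
        assert {c.n_points for c in grid} == {50, 150, 300, 500}


class TestDatasetIO:
    def test_round_trip(self, tmp_path):
        cfg = ScenarioConfig(n_points=60, n_visits=2)
        ds = simulate_dataset(cfg, seed=2)
        path = tmp_path / "survey.csv"
        write_dataset(path, ds)
        back = read_dataset(path, config=cfg)
        pd.testing.assert_frame_equal(ds.detections, back.detections)
        pd.testing.assert_frame_equal(ds.latents, back.latents)
        # a re-write is byte-identical
        write_dataset(tmp_path / "again.csv", back)
        assert (tmp_path / "again.csv").read_bytes() == path.read_bytes()

    def test_empty_dataset_header_only(self, tmp_path):
        cfg = ScenarioConfig(lam=0.001, p_presence=0.01, availability=0.01,
                             n_points=3, n_visits=1)
        ds = simulate_dataset(cfg, seed=1)
        assert ds.n_detections == 0
        path = tmp_path / "empty.csv"
        write_dataset(path, ds)
        header = path.read_text().splitlines()[0]
        assert header == "refuge,point_id,year,visit,species,distance_class,time_interval"

    def test_out_of_range_class_rejected(self, tmp_path):
        bad = pd.DataFrame({
            "refuge": ["r"], "point_id": [1], "year": [1], "visit": [1],
            "species": ["SIM"], "distance_class": [5], "time_interval": [1]})
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1.*distance_class 5"):
            read_dataset(path)

    def test_validate_records_reports_rows(self):
        df = pd.DataFrame({
            "refuge": ["r", "r"], "point_id": [1, 1], "year": [1, 1],
            "visit": [1, 1], "species": ["SIM", "SIM"],
            "distance_class": [2, 1], "time_interval": [1, 4]})
        problems = validate_records(df)
        assert len(problems) == 1 and "row 2" in problems[0]


class TestTrendSimulator:
    def test_latent_matches_detection_records(self):
        ds = simulate_trend_dataset(gamma=(0.5,), n_points=60, n_years=5, seed=8)
        y = np.zeros((60, 5), int)
        np.add.at(y, (ds.detections.point_id - 1, ds.detections.year - 1), 1)
        assert (y <= ds.latent_n).all()

    def test_stationary_spin_up_disperses_initial_year(self):
        """A stationary AR(1) with gamma=0.9 has between-point variance
        ~mu/(1-gamma^2) >> mu; mean-initialized series do not."""
        hot = simulate_trend_dataset(gamma=(0.9,), n_points=400, n_years=3, seed=1)
        cold = simulate_trend_dataset(gamma=(0.9,), n_points=400, n_years=3, seed=1,
                                      spin_up=0)
        assert hot.latent_n[:, 0].var() > 2.5 * cold.latent_n[:, 0].var()

    def test_invalid_ar_coefficients(self):
        with pytest.raises(ValueError):
            simulate_trend_dataset(gamma=(0.7, 0.4))
        with pytest.raises(ValueError):
            simulate_trend_dataset(gamma=(-0.1,))

    def test_refuge_assignment(self):
        ds = simulate_trend_dataset(gamma=(0.3,), n_points=30, n_years=4,
                                    refuge_effects=(0.0, 0.5, -0.5), seed=2)
        assert set(ds.point_refuge) == {0, 1, 2}
        assert set(ds.detections.refuge.unique()) <= {"refuge_1", "refuge_2", "refuge_3"}
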