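import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from coastsdm.grid import generate_grid
from coastsdm.gridding import build_cell_season_table
from coastsdm.habitat import (
    abundance_surface,
    build_mask,
    classify_habitat,
    mpa_comparison,
    prediction_summary,
)
from coastsdm.models import ModelSpec, fit_glm, predict_model
from coastsdm.screening import PredictorStandardizer
from coastsdm.synthetic import (
    EffortConfig,
    TruthScenario,
    generate_environment,
    simulate_effort,
    simulate_observations,
)


class TestSummary:
    def test_mean_and_sample_sd_closed_form(self):
        mean, sd = prediction_summary([np.array([0.2]), np.array([0.4])])
        assert mean[0] == pytest.approx(0.3)
        assert sd[0] == pytest.approx(np.sqrt(((0.2 - 0.3) ** 2 +
                                               (0.4 - 0.3) ** 2) / 1))
        assert sd[0] == pytest.approx(0.1414, abs=5e-4)

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            prediction_summary([np.array([0.5, 0.5])])

    def test_identical_layers_have_zero_sd(self):
        layer = np.array([0.1, 0.5, 0.9])
        _, sd = prediction_summary([layer, layer.copy(), layer.copy()])
        np.testing.assert_allclose(sd, 0.0, atol=1e-15)

    def test_missing_layer_value_marks_cell_nodata(self):
        a = np.array([0.2, np.nan])
        b = np.array([0.4, 0.5])
        mean, sd = prediction_summary([a, b])
        assert np.isnan(mean[1]) and np.isnan(sd[1])
        assert mean[0] == pytest.approx(0.3)


class TestClassification:
    def _maps(self):
        # engineered so the global thresholds are mean 0.3 and SD 0.1
        mean = np.array([0.5, 0.1, 0.1, 0.5])
        sd = np.array([0.05, 0.25, 0.05, 0.05])
        return mean, sd

    def test_three_definitions(self):
        habitat = classify_habitat(*self._maps())
        assert habitat.attrs["mean_threshold"] == pytest.approx(0.3)
        assert habitat.attrs["sd_threshold"] == pytest.approx(0.1)
        cat = habitat["category"].tolist()
        assert cat[0] == "recurrent"      # high mean, low SD
        assert cat[1] == "occasional"     # high SD wins regardless of mean
        assert cat[2] == "unfavourable"   # low mean, low SD

    def test_high_mean_high_sd_is_occasional(self):
        mean = np.array([0.9, 0.1, 0.1, 0.1])
        sd = np.array([0.4, 0.05, 0.05, 0.05])
        habitat = classify_habitat(mean, sd)
        assert habitat["category"].iloc[0] == "occasional"

    def test_threshold_ties_fall_low(self):
        # a cell exactly at both global thresholds is unfavourable
        mean = np.array([0.3, 0.3, 0.3, 0.3])
        sd = np.array([0.2, 0.2, 0.2, 0.2])
        habitat = classify_habitat(mean, sd)
        assert (habitat["category"] == "unfavourable").all()

    def test_nan_cells_uncategorized_and_excluded_from_thresholds(self):
        mean = np.array([0.5, 0.1, np.nan])
        sd = np.array([0.05, 0.05, np.nan])
        habitat = classify_habitat(mean, sd)
        assert habitat["category"].iloc[2] == "uncategorized"
        assert habitat.attrs["mean_threshold"] == pytest.approx(0.3)

    def test_partition_of_categorizable_cells(self):
        rng = np.random.default_rng(0)
        mean = rng.uniform(size=200)
        sd = rng.uniform(0, 0.3, size=200)
        mean[:10] = np.nan
        habitat = classify_habitat(mean, sd)
        counts = habitat["category"].value_counts()
        assert counts.get("uncategorized", 0) == 10
        assert counts.sum() == 200

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        mean = rng.uniform(size=50)
        sd = rng.uniform(0, 0.3, size=50)
        h1 = classify_habitat(mean, sd)
        h2 = classify_habitat(4.0 * mean + 2.0, 4.0 * sd + 2.0)
        assert (h1["category"] == h2["category"]).all()


class TestAbundance:
    def test_product_and_total(self):
        ab, total = abundance_surface(np.array([1.0, 2.0]),
                                      np.array([10.0, 5.0]))
        np.testing.assert_allclose(ab, [10.0, 10.0])
        assert total == 20.0

    def test_zero_sightings_absorb(self):
        ab, total = abundance_surface(np.zeros(5), np.full(5, 30.0))
        assert total == 0.0 and (ab == 0).all()

    def test_bruteforce_product_sum_oracle(self):
        rng = np.random.default_rng(2)
        s, g = rng.uniform(size=40), rng.uniform(1, 50, size=40)
        ab, total = abundance_surface(s, g)
        brute = sum(si * gi for si, gi in zip(s, g))
        assert total == pytest.approx(brute, rel=1e-12)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            abundance_surface(np.zeros(3), np.zeros(4))


def _ray_cast(point, ring):
    """Independent point-in-polygon oracle (even-odd ray casting)."""
    x, y = point
    inside = False
    for (x1, y1), (x2, y2) in zip(ring[:-1], ring[1:]):
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestMask:
    def test_whole_grid_polygon(self):
        g = generate_grid(4, 4, 1.0)
        ring = [(-1, -1), (5, -1), (5, 5), (-1, 5), (-1, -1)]
        assert build_mask(ring, g).all()

    def test_empty_polygon(self):
        g = generate_grid(4, 4, 1.0)
        ring = [(10, 10), (11, 10), (11, 11), (10, 11), (10, 10)]
        assert not build_mask(ring, g).any()

    def test_open_ring_rejected(self):
        g = generate_grid(2, 2, 1.0)
        with pytest.raises(ValueError):
            build_mask([(0, 0), (1, 0), (1, 1)], g)

    def test_matches_ray_casting_oracle(self):
        g = generate_grid(8, 8, 1.0)
        rng = np.random.default_rng(3)
        # random star-convex simple polygon around the grid center
        angles = np.sort(rng.uniform(0, 2 * np.pi, 7))
        radii = rng.uniform(1.0, 4.5, 7)
        ring = [(4 + r * np.cos(a), 4 + r * np.sin(a))
                for a, r in zip(angles, radii)]
        ring.append(ring[0])
        mask = build_mask(ring, g)
        oracle = np.array([_ray_cast(c, ring) for c in g.cell_centers()])
        # boundary-exact centers are convention-dependent; none here
        np.testing.assert_array_equal(mask, oracle)


class TestComparison:
    def _habitat(self, cats):
        n = len(cats)
        return pd.DataFrame({"cell_id": range(n), "mean": 0.5, "sd": 0.1,
                             "category": cats})

    def test_all_inside_gives_100_percent(self):
        habitat = self._habitat(["recurrent", "occasional", "unfavourable"])
        rep = mpa_comparison(habitat, np.ones(3, dtype=bool))
        for cat in ("recurrent", "occasional", "unfavourable"):
            assert rep["categories"][cat]["pct_inside"] == 100.0

    def test_three_quarters_inside(self):
        habitat = self._habitat(["recurrent"] * 4)
        mask = np.array([True, True, True, False])
        rep = mpa_comparison(habitat, mask)
        assert rep["categories"]["recurrent"]["pct_inside"] == 75.0
        assert rep["categories"]["recurrent"]["pct_outside"] == 25.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        cats = rng.choice(["recurrent", "occasional", "unfavourable"], 60)
        mask = rng.uniform(size=60) < 0.4
        rep = mpa_comparison(self._habitat(cats), mask)
        for cat in ("recurrent", "occasional", "unfavourable"):
            c = rep["categories"][cat]
            if c["n"]:
                assert c["pct_inside"] + c["pct_outside"] == pytest.approx(100.0)

    def test_welch_t_detects_inside_shift(self):
        rng = np.random.default_rng(5)
        habitat = self._habitat(["recurrent"] * 200)
        mask = np.zeros(200, dtype=bool)
        mask[:80] = True
        surf = rng.normal(size=200)
        surf[mask] += 2.0
        rep = mpa_comparison(habitat, mask, surfaces={"occ": surf})
        assert rep["t_tests"]["occ"]["t"] < 0  # outside minus inside
        assert rep["t_tests"]["occ"]["p_value"] < 1e-6

    def test_empty_inside_rejected(self):
        habitat = self._habitat(["recurrent"] * 4)
        with pytest.raises(ValueError):
            mpa_comparison(habitat, np.zeros(4, dtype=bool))


def test_end_to_end_power_when_truth_concentrates_inside_polygon():
    """With suitability concentrated east (near the isobath and front) and an
    eastern protected polygon, the fitted surface should be higher inside and
    the Welch test should detect it in nearly every replicate."""
    g = generate_grid(10, 10, 1.0)
    schedule = [(2006, "summer"), (2006, "autumn")]
    truth = TruthScenario(
        occurrence={"intercept": -0.5, "BATH100": -1.2, "FRONT": -0.8},
        sightings={"intercept": -3.0},
        group_size={"intercept": 2.0},
    )
    polygon = [(5.0, 0.0), (10.0, 0.0), (10.0, 10.0), (5.0, 10.0), (5.0, 0.0)]
    mask = build_mask(polygon, g)
    detected = 0
    n_rep = 50
    for rep in range(n_rep):
        env = generate_environment(g, schedule, seed=1000 + rep)
        eff = simulate_effort(g, schedule,
                              EffortConfig(coverage_mean=0.9, coverage_sd=0.05),
                              seed=2000 + rep)
        ds = simulate_observations(env, eff, truth, seed=3000 + rep)
        table = build_cell_season_table(ds)
        std = PredictorStandardizer(columns=["BATH100", "FRONT"]).fit(table)
        z = std.transform(table)
        m = fit_glm(ModelSpec("presence", "binomial", ("BATH100", "FRONT")), z)
        layers = [
            predict_model(m, std.transform(env.frame(y, s)))
            for (y, s) in schedule
        ]
        mean_map, sd_map = prediction_summary(layers)
        habitat = classify_habitat(mean_map, sd_map)
        rep_out = mpa_comparison(habitat, mask, surfaces={"occ": mean_map})
        t = rep_out["t_tests"]["occ"]
        if t["p_value"] < 0.05 and t["mean_inside"] > t["mean_outside"]:
            detected += 1
    assert detected >= 45  # power >= 0.9 at this effect size
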