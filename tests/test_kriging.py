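import numpy as np
import pandas as pd
import pytest

import stcoreg as sc
from stcoreg.kriging import solve_cokriging_system

from conftest import make_table, ps


@pytest.fixture()
def uni_model():
    return sc.STLCM(["z"], [ps(1.0, 0.3, 0.2, 60.0, 6.0)], [np.array([[2.0]])])


@pytest.fixture()
def uni_table():
    pts = [
        ("s0", 10.0, 10.0, 1, "z", 1.2),
        ("s1", 40.0, 20.0, 2, "z", -0.4),
        ("s2", 25.0, 50.0, 3, "z", 0.8),
        ("s3", 60.0, 35.0, 2, "z", 0.3),
        ("s4", 15.0, 70.0, 4, "z", -1.0),
    ]
    return make_table(pts, role="residual")


WIDE = sc.NeighborhoodConfig(max_per_variable=16, spatial_radius=1e6,
                             temporal_radius=1e6)


class TestKrige:
    def test_exact_at_data_points(self, uni_model, uni_table):
        pts = uni_table.data[["x", "y", "t"]].to_numpy(dtype=float)
        res = sc.krige(uni_model, uni_table, pts, config=WIDE)
        assert np.abs(res.values - uni_table.data["value"].to_numpy()).max() < 1e-6
        assert np.abs(res.variances).max() < 1e-8

    def test_constant_data_constant_prediction(self, uni_model):
        rows = [(f"s{i}", 10.0 * i, 5.0 * i, 1 + i % 3, "z", 4.2) for i in range(6)]
        table = make_table(rows, role="residual")
        targets = np.array([[12.0, 8.0, 2.0], [50.0, 1.0, 3.0]])
        res = sc.krige(uni_model, table, targets, config=WIDE)
        assert np.allclose(res.values, 4.2, atol=1e-8)

    def test_two_point_system_hand_solved(self, uni_model):
        # hand-assembled 3x3 ordinary kriging system solved independently
        rows = [("s0", 0.0, 0.0, 1, "z", 2.0), ("s1", 30.0, 0.0, 1, "z", -1.0)]
        table = make_table(rows, role="residual")
        engine = sc.CokrigingEngine(uni_model, table, WIDE)
        value, var, n, det = engine.predict_point(
            10.0, 0.0, 1.0, "z", return_weights=True
        )
        comp, b = uni_model.components[0], 2.0
        c01 = b * comp(30.0, 0.0)
        c00 = b * comp(0.0, 0.0)
        K = np.array([[c00, c01, 1.0], [c01, c00, 1.0], [1.0, 1.0, 0.0]])
        rhs = np.array([b * comp(10.0, 0.0), b * comp(20.0, 0.0), 1.0])
        sol = np.linalg.solve(K, rhs)
        w = np.zeros(2)
        w[det["indices"]] = det["weights"]
        assert np.abs(w - sol[:2]).max() < 1e-10
        assert abs(var - (c00 - sol[:2] @ rhs[:2] - sol[2])) < 1e-10

    def test_weights_sum_to_one(self, uni_model, uni_table):
        engine = sc.CokrigingEngine(uni_model, uni_table, WIDE)
        for tx, ty, tt in [(0.0, 0.0, 1.0), (33.0, 44.0, 2.5)]:
            _, _, _, det = engine.predict_point(tx, ty, tt, "z", return_weights=True)
            assert abs(det["weights"].sum() - 1.0) < 1e-9


class TestCokrige:
    def test_reduces_to_krige_for_single_variable(self, uni_model, uni_table):
        targets = np.array([[20.0, 20.0, 2.0], [45.0, 60.0, 3.0]])
        a = sc.cokrige(uni_model, uni_table, targets, "z", config=WIDE)
        b = sc.krige(uni_model, uni_table, targets, config=WIDE)
        assert np.allclose(a.values, b.values)
        assert np.allclose(a.variances, b.variances)

    def test_exactness_multivariate(self, two_scale_truth, small_world):
        res = small_world["residuals"]
        sub = res.data[res.data["variable"] == "rn_flux"].head(5)
        targets = sub[["x", "y", "t"]].to_numpy(dtype=float)
        cfg = sc.NeighborhoodConfig(
            max_per_variable=12, spatial_radius=150.0, temporal_radius=12.0
        )
        out = sc.cokrige(two_scale_truth, res, targets, "rn_flux", config=cfg)
        assert np.abs(out.values - sub["value"].to_numpy()).max() < 1e-6

    def test_auxiliary_weights_sum_to_zero(self, two_scale_truth, small_world):
        engine = sc.CokrigingEngine(
            two_scale_truth, small_world["residuals"],
            sc.NeighborhoodConfig(max_per_variable=8, spatial_radius=150.0,
                                  temporal_radius=12.0),
        )
        _, _, _, det = engine.predict_point(
            100.0, 100.0, 18.0, "rn_flux", return_weights=True
        )
        w, vi = det["weights"], det["var_index"]
        assert abs(w[vi == 0].sum() - 1.0) < 1e-9
        assert abs(w[vi == 1].sum()) < 1e-9

    def test_variance_smaller_near_data(self, uni_model, uni_table):
        engine = sc.CokrigingEngine(uni_model, uni_table, WIDE)
        _, var_near, _ = engine.predict_point(10.0, 10.0, 1.0, "z")
        _, var_far, _ = engine.predict_point(500.0, 500.0, 30.0, "z")
        assert var_near < var_far

    def test_empty_neighborhood_flagged(self, uni_model, uni_table):
        cfg = sc.NeighborhoodConfig(
            max_per_variable=4, spatial_radius=5.0, temporal_radius=1.0
        )
        res = sc.cokrige(
            uni_model, uni_table, np.array([[500.0, 500.0, 30.0]]), "z", config=cfg
        )
        assert res.frame.loc[0, "flag"] == "empty-neighborhood"
        assert np.isnan(res.frame.loc[0, "value"])

    def test_solve_system_requires_target_datum(self):
        with pytest.raises(ValueError):
            solve_cokriging_system(
                np.eye(2), np.zeros(2), np.array([1, 1]), 0, 1.0
            )


class TestIndicatorKriging:
    def test_all_data_above_threshold(self, uni_model, uni_table):
        targets = np.array([[20.0, 30.0, 2.0]])
        res = sc.indicator_krige(uni_table, -100.0, uni_model, targets, config=WIDE)
        assert res.values[0] == pytest.approx(1.0)
        assert res.frame.loc[0, "flag"] == "degenerate"

    def test_extreme_thresholds_give_zero_and_one(self, uni_model, uni_table):
        targets = np.array([[20.0, 30.0, 2.0]])
        low = sc.indicator_krige(uni_table, -100.0, uni_model, targets, config=WIDE)
        high = sc.indicator_krige(uni_table, 100.0, uni_model, targets, config=WIDE)
        assert low.values[0] == 1.0 and high.values[0] == 0.0

    def test_probabilities_clamped(self, uni_model, uni_table):
        targets = np.column_stack(
            [np.random.default_rng(0).uniform(0, 80, (12, 2)), np.full(12, 2.0)]
        )
        res = sc.indicator_krige(uni_table, 0.0, uni_model, targets, config=WIDE)
        ok = np.isfinite(res.values)
        assert np.all((res.values[ok] >= 0) & (res.values[ok] <= 1))

    def test_order_relation_correction_monotone(self):
        rng = np.random.default_rng(1)
        probs = rng.uniform(0, 1, size=(50, 3))
        fixed = sc.correct_order_relations(probs)
        assert np.all(np.diff(fixed, axis=1) <= 1e-12)
        assert fixed.min() >= 0 and fixed.max() <= 1
        # already-monotone rows unchanged
        mono = np.sort(probs, axis=1)[:, ::-1]
        assert np.allclose(sc.correct_order_relations(mono), mono)


class TestPredictMaps:
    def test_zero_residual_world_reproduces_seasonal_surface(self, small_world):
        raw = small_world["raw"]
        _, profile = sc.deseasonalize(raw)
        zero = raw.data.copy()
        zero["value"] = 0.0
        zero_res = sc.ObservationTable(zero, role="residual")
        model = small_world["truth"]
        coords = raw.station_coords().to_numpy(dtype=float)[:4]
        months = [3, 7]
        maps = sc.predict_maps(
            model, zero_res, profile, coords, months, "rn_flux",
            config=sc.NeighborhoodConfig(max_per_variable=8, spatial_radius=200.0,
                                         temporal_radius=12.0),
        )
        # at station locations the IDW seasonal surface is exact
        stations = raw.station_coords().index[:4]
        for month in months:
            for k, st in enumerate(stations):
                row = maps[
                    (maps["t"] == month)
                    & (maps["x"] == coords[k, 0])
                    & (maps["y"] == coords[k, 1])
                ].iloc[0]
                expected = profile.value(st, "rn_flux", ((month - 1) % 12) + 1)
                assert row["value"] == pytest.approx(expected, abs=1e-8)

    def test_output_shape_grid_times_months(self, small_world):
        res = small_world["residuals"]
        _, profile = sc.deseasonalize(small_world["raw"])
        grid = sc.make_grid((0, 200, 0, 200), 3, 3)
        maps = sc.predict_maps(
            small_world["truth"], res, profile, grid, [10, 11, 40], "rn_flux",
            config=sc.NeighborhoodConfig(max_per_variable=8, spatial_radius=200.0,
                                         temporal_radius=12.0),
        )
        assert len(maps) == 9 * 3
        # months beyond the record (forecasting) still produce predictions
        beyond = maps[maps["t"] == 40]
        assert np.isfinite(beyond["value"]).all()


class TestNeighborhoodConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            sc.NeighborhoodConfig(max_per_variable=1)
        with pytest.raises(ValueError):
            sc.NeighborhoodConfig(spatial_radius=-1.0)

    def test_for_model_uses_largest_scales(self, two_scale_truth):
        cfg = sc.NeighborhoodConfig.for_model(two_scale_truth)
        assert cfg.spatial_radius == 120.0
        assert cfg.temporal_radius == 12.0
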