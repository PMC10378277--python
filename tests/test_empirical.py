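import itertools

import numpy as np
import pytest

import stcoreg as sc

from conftest import make_table, ps


def toy_grid():
    return sc.LagGrid(spatial=(10.0,), temporal=(1.0, 2.0), spatial_tol=5.0)


def three_by_three_table():
    """3 stations x 3 months, one variable, hand-enumerable."""
    coords = {"a": (0.0, 0.0), "b": (10.0, 0.0), "c": (0.0, 10.0)}
    vals = {
        ("a", 1): 1.0, ("a", 2): -0.5, ("a", 3): 0.7,
        ("b", 1): 0.2, ("b", 2): 1.4, ("b", 3): -1.1,
        ("c", 1): -0.3, ("c", 2): 0.9, ("c", 3): 0.4,
    }
    rows = [
        (s, coords[s][0], coords[s][1], t, "z", v) for (s, t), v in vals.items()
    ]
    return make_table(rows, role="residual"), coords, vals


class TestLagGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            sc.LagGrid(spatial=(0.0, 10.0), temporal=(1.0,), spatial_tol=5.0)
        with pytest.raises(ValueError):
            sc.LagGrid(spatial=(10.0, 5.0), temporal=(1.0,), spatial_tol=2.0)
        with pytest.raises(ValueError):
            sc.LagGrid(spatial=(10.0,), temporal=(1.0,), spatial_tol=8.0)

    def test_regular_and_default(self, small_world):
        grid = sc.LagGrid.regular(120.0, 8, 15)
        assert len(grid.spatial) == 8 and len(grid.temporal) == 15
        assert grid.spatial_tol == pytest.approx(7.5)
        default = sc.LagGrid.default_for(small_world["residuals"])
        assert len(default.spatial) == 8


class TestEstimateCov:
    def test_brute_force_oracle_same_station_lag(self):
        table, coords, vals = three_by_three_table()
        covset = sc.estimate_cov(table, toy_grid(), symmetrize=False, min_pairs=1)
        m = np.mean(list(vals.values()))
        # all ordered same-station pairs with z leading by 1 month
        prods = [
            (vals[(s, t + 1)] - m) * (vals[(s, t)] - m)
            for s in "abc" for t in (1, 2)
        ]
        expected = np.mean(prods)
        assert covset.value(0, 0, 0.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_brute_force_oracle_spatial_bin(self):
        table, coords, vals = three_by_three_table()
        covset = sc.estimate_cov(table, toy_grid(), symmetrize=False, min_pairs=1)
        m = np.mean(list(vals.values()))
        # ordered station pairs with |dist - 10| < 5: a-b and a-c at 10 km,
        # b-c at sqrt(200) ~ 14.1 km
        pairs = list(itertools.permutations("abc", 2))
        prods = [
            (vals[(s1, t)] - m) * (vals[(s2, t)] - m)
            for s1, s2 in pairs for t in (1, 2, 3)
        ]
        assert covset.value(0, 0, 10.0, 0.0) == pytest.approx(
            np.mean(prods), rel=1e-12
        )

    def test_zero_lag_is_plugin_variance(self):
        table, _, vals = three_by_three_table()
        covset = sc.estimate_cov(table, toy_grid(), min_pairs=1)
        v = np.array(list(vals.values()))
        assert covset.value(0, 0, 0.0, 0.0) == pytest.approx(
            np.mean((v - v.mean()) ** 2), rel=1e-12
        )

    def test_duplicated_variable_gives_identical_cross(self):
        table, _, vals = three_by_three_table()
        dup = table.data.copy()
        dup2 = dup.copy()
        dup2["variable"] = "w"
        both = make_table(
            list(map(tuple, np.concatenate([dup.values, dup2.values]))),
            role="residual",
        )
        covset = sc.estimate_cov(both, toy_grid(), min_pairs=1)
        assert np.allclose(
            covset.values[0, 1], covset.values[0, 0], equal_nan=True
        )

    def test_white_noise_origin_matches_sample_cov(self):
        rng = np.random.default_rng(0)
        coords = sc.make_station_layout(20, (100.0, 100.0), "uniform", seed=1)
        rows = []
        Z = rng.standard_normal((2, 20, 40))
        for k, v in enumerate(("a", "b")):
            for s in range(20):
                for t in range(40):
                    rows.append(
                        (f"s{s}", coords[s, 0], coords[s, 1], t + 1, v, Z[k, s, t])
                    )
        table = make_table(rows, role="residual")
        grid = sc.LagGrid(spatial=(30.0,), temporal=(1.0,), spatial_tol=15.0)
        covset = sc.estimate_cov(table, grid, min_pairs=1)
        flat = Z.reshape(2, -1)
        sample = np.cov(flat, bias=True)
        assert covset.matrix_at(0, 0) == pytest.approx(sample, abs=5e-3)

    def test_record_order_invariance(self):
        table, _, _ = three_by_three_table()
        shuffled = make_table(
            list(map(tuple, table.data.sample(frac=1, random_state=3).values)),
            role="residual",
        )
        a = sc.estimate_cov(table, toy_grid(), min_pairs=1)
        b = sc.estimate_cov(shuffled, toy_grid(), min_pairs=1)
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_symmetrize_averages_orientations(self, small_world):
        covset = sc.estimate_cov(
            small_world["residuals"],
            sc.LagGrid.regular(90.0, 4, 4),
            symmetrize=False,
            min_pairs=5,
        )
        sym = covset.symmetrize()
        assert np.allclose(
            sym.values[0, 1],
            (covset.values[0, 1] + covset.values[1, 0]) / 2,
            equal_nan=True,
        )

    def test_estimator_converges_to_model(self, two_scale_truth):
        # mean over replicates at a mid-range lag approaches the model value
        coords = sc.make_station_layout(40, (200.0, 200.0), "uniform", seed=5)
        sim = sc.STLCMSimulator(
            sc.SimulationSpec(model=two_scale_truth, coords=coords, n_months=48, seed=0)
        )
        grid = sc.LagGrid(spatial=(30.0,), temporal=(2.0,), spatial_tol=15.0)
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(10):
            _, res = sim.simulate(rng)
            covset = sc.estimate_cov(res, grid, min_pairs=5)
            vals.append(covset.value(0, 0, 30.0, 2.0))
        # truth with unit-sill components; tolerance reflects the binning of
        # distances in (15, 45) km around the nominal 30 km lag
        truth_val = two_scale_truth.cov(0, 0, 30.0, 2.0)
        assert np.mean(vals) == pytest.approx(truth_val, abs=0.15)


class TestAssembleMatrices:
    def test_univariate_scalars(self):
        table, _, _ = three_by_three_table()
        covset = sc.estimate_cov(table, toy_grid(), min_pairs=1)
        lags, mats = sc.assemble_matrices(covset)
        assert mats.shape[1:] == (1, 1)
        assert lags[0] == (0.0, 0.0)

    def test_matrices_match_covset_entries(self, small_world):
        covset = sc.estimate_cov(
            small_world["residuals"], sc.LagGrid.regular(90.0, 3, 3), min_pairs=5
        )
        lags, mats = sc.assemble_matrices(covset)
        for (rs, rt), m in zip(lags, mats):
            a = int(np.argmin(np.abs(covset.spatial_lags - rs)))
            b = int(np.argmin(np.abs(covset.temporal_lags - rt)))
            assert np.allclose(m, covset.values[:, :, a, b])
            assert np.allclose(m, m.T)

    def test_case_study_grid_yields_120_plus_marginals(self, small_world):
        # 8 spatial x 15 temporal non-zero lags = 120, plus marginal rows
        grid = sc.LagGrid.regular(100.0, 8, 15)
        covset = sc.estimate_cov(small_world["residuals"], grid, min_pairs=1)
        assert (len(covset.spatial_lags) - 1) * (len(covset.temporal_lags) - 1) == 120

    def test_unsymmetrized_rejected(self):
        table, _, _ = three_by_three_table()
        covset = sc.estimate_cov(table, toy_grid(), symmetrize=False, min_pairs=1)
        with pytest.raises(ValueError, match="symmetrized"):
            sc.assemble_matrices(covset)

    def test_min_pairs_flags_sparse_lags(self):
        table, _, _ = three_by_three_table()
        covset = sc.estimate_cov(table, toy_grid(), min_pairs=30)
        assert not covset.retained.all()
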