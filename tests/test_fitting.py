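import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stcoreg as sc
from stcoreg.fitting import ComponentSurface, fit_product_sum

from conftest import ps


def haar(p, seed):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((p, p)))
    return q * np.sign(np.diag(r))


def signed_perm_dev(psi, psi0):
    M = psi @ psi0
    p = M.shape[0]
    cols = np.argmax(np.abs(M), axis=1)
    assert len(set(cols.tolist())) == p
    Q = np.zeros_like(M)
    Q[np.arange(p), cols] = np.sign(M[np.arange(p), cols])
    return np.abs(M - Q).max()


def surface_from(comp, spatial=None, temporal=None):
    hs = np.concatenate([[0.0], spatial if spatial is not None else 15.0 * np.arange(1, 9)])
    ht = np.concatenate([[0.0], temporal if temporal is not None else np.arange(1.0, 16.0)])
    return ComponentSurface(
        values=comp(hs[:, None], ht[None, :]),
        spatial_lags=hs, temporal_lags=ht, psi_row=np.array([1.0]),
    )


class TestJointDiagonalize:
    def test_already_diagonal(self):
        rng = np.random.default_rng(0)
        mats = np.array([np.diag(rng.uniform(0.5, 2, 3)) for _ in range(5)])
        res = sc.joint_diagonalize(mats)
        assert res.criterion[-1] < 1e-20
        assert signed_perm_dev(res.psi, np.eye(3)) < 1e-10

    def test_construct_then_recover(self):
        rng = np.random.default_rng(1)
        psi0 = haar(4, 2)
        mats = np.einsum(
            "ab,kb,cb->kac", psi0, rng.uniform(0.2, 3.0, size=(30, 4)), psi0
        )
        res = sc.joint_diagonalize(mats)
        assert signed_perm_dev(res.psi, psi0) < 1e-8
        assert np.abs(res.psi @ res.psi.T - np.eye(4)).max() < 1e-10

    def test_single_matrix_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((5, 5))
        A = A + A.T
        res = sc.joint_diagonalize(A[None])
        eig = np.linalg.eigvalsh(A)
        assert np.sort(res.diagonals[0]) == pytest.approx(eig, rel=1e-10)

    def test_objective_non_increasing(self, small_world):
        covset = sc.estimate_cov(
            small_world["residuals"], sc.LagGrid.regular(90.0, 4, 6), min_pairs=5
        )
        _, mats = sc.assemble_matrices(covset)
        res = sc.joint_diagonalize(mats)
        assert np.all(np.diff(res.criterion) <= 1e-12)
        assert np.abs(res.psi @ res.psi.T - np.eye(2)).max() < 1e-10

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            sc.joint_diagonalize(np.array([[[1.0, 2.0], [0.0, 1.0]]]))


class TestDetectScales:
    def test_exact_exponential_practical_range(self):
        comp = ps(1.0, 0.0, 0.0, 55.0, 7.0)
        surf = surface_from(
            comp, spatial=np.arange(5.0, 151.0, 5.0), temporal=np.arange(1.0, 25.0)
        )
        s_scale, t_scale = sc.detect_scales(surf)
        assert abs(s_scale - 55.0) <= 5.0
        assert abs(t_scale - 7.0) <= 1.0

    def test_constant_surface_censored(self):
        hs = np.concatenate([[0.0], 10.0 * np.arange(1, 6)])
        ht = np.concatenate([[0.0], np.arange(1.0, 6.0)])
        surf = ComponentSurface(
            values=np.full((6, 6), 2.0), spatial_lags=hs, temporal_lags=ht,
            psi_row=np.array([1.0]),
        )
        s_scale, t_scale = sc.detect_scales(surf)
        assert s_scale == 50.0 and surf.spatial_censored
        assert t_scale == 5.0 and surf.temporal_censored

    def test_scale_invariance(self):
        comp = ps(1.0, 0.3, 0.1, 40.0, 4.0)
        s1 = sc.detect_scales(surface_from(comp))
        scaled = surface_from(comp)
        scaled.values = scaled.values * 17.3
        s2 = sc.detect_scales(scaled)
        assert s1 == s2

    def test_nonpositive_sill_rejected(self):
        surf = surface_from(ps(1.0, 0.0, 0.0, 40.0, 4.0))
        surf.values = surf.values - 10.0
        with pytest.raises(ValueError):
            sc.detect_scales(surf)


class TestFitProductSum:
    @pytest.mark.parametrize(
        "truth", [ps(1.2, 0.4, 0.3, 55.0, 7.0), ps(0.8, 0.05, 1.5, 25.0, 11.0)]
    )
    def test_noiseless_recovery_within_one_percent(self, truth):
        rep = fit_product_sum(surface_from(truth))
        c = rep.component
        for got, want in [
            (c.k1, truth.k1), (c.k2, truth.k2), (c.k3, truth.k3),
            (c.spatial_range, truth.spatial_range),
            (c.temporal_range, truth.temporal_range),
        ]:
            assert abs(got - want) / want < 0.01

    def test_separable_truth_yields_negligible_sum_terms(self):
        truth = ps(1.0, 0.0, 0.0, 60.0, 6.0)
        rep = fit_product_sum(surface_from(truth))
        assert rep.component.k2 < 0.01 * rep.component.k1
        assert rep.component.k3 < 0.01 * rep.component.k1

    def test_fitted_parameters_admissible_on_noisy_surface(self):
        rng = np.random.default_rng(4)
        surf = surface_from(ps(1.0, 0.5, 0.2, 50.0, 5.0))
        surf.values = surf.values + 0.05 * rng.standard_normal(surf.values.shape)
        surf.values[0, 0] = abs(surf.values[0, 0])
        rep = fit_product_sum(surf)
        assert sc.check_admissibility(rep.component).positive_semi_definite

    def test_degenerate_surface_rejected(self):
        hs = np.concatenate([[0.0], 10.0 * np.arange(1, 6)])
        ht = np.concatenate([[0.0], np.arange(1.0, 6.0)])
        surf = ComponentSurface(
            values=np.full((6, 6), 3.0), spatial_lags=hs, temporal_lags=ht,
            psi_row=np.array([1.0]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_product_sum(surf)


class TestEstimateCoregionalization:
    def _toy_covset(self, values_by_lag, sill=2.0):
        """Univariate covset with prescribed values at (0,0) and two lags."""
        ns, nt = 3, 2
        values = np.full((1, 1, ns, nt), np.nan)
        counts = np.zeros((1, 1, ns, nt), dtype=int)
        for (a, b), v in values_by_lag.items():
            values[0, 0, a, b] = v
            counts[0, 0, a, b] = 100
        return sc.EmpiricalCovSet(
            variables=("z",),
            spatial_lags=np.array([0.0, 20.0, 120.0]),
            temporal_lags=np.array([0.0, 2.0]),
            values=values, counts=counts, means=np.zeros(1),
            min_pairs=1, symmetrized=True,
        )

    def test_sequential_arithmetic_example(self):
        # C(0,0)=10, C(lag1)=4, c1(0,0)=2 -> b1 = 3
        covset = self._toy_covset({(0, 0): 10.0, (1, 1): 4.0})
        comp = ps(2.0, 0.0, 0.0, 20.0, 2.0)
        B = sc.estimate_coregionalization(
            covset, [comp], method="sequential", scale_lags=[(20.0, 2.0)]
        )
        assert B[0][0, 0] == pytest.approx(3.0)

    def test_sequential_single_scale_limit(self):
        covset = self._toy_covset({(0, 0): 10.0, (2, 1): 0.0})
        comp = ps(2.0, 0.0, 0.0, 20.0, 2.0)
        B = sc.estimate_coregionalization(
            covset, [comp], method="sequential", scale_lags=[(120.0, 2.0)]
        )
        assert B[0][0, 0] == pytest.approx(10.0 / 2.0)

    def test_least_squares_recovers_exact_model(self, two_scale_truth):
        grid = sc.LagGrid.regular(120.0, 8, 15)
        hs = grid.spatial_with_zero
        ht = grid.temporal_with_zero
        p = two_scale_truth.p
        values = np.empty((p, p, len(hs), len(ht)))
        for i in range(p):
            for j in range(p):
                values[i, j] = two_scale_truth.cov(
                    i, j, hs[:, None], ht[None, :]
                )
        covset = sc.EmpiricalCovSet(
            variables=two_scale_truth.variables,
            spatial_lags=hs, temporal_lags=ht, values=values,
            counts=np.full((p, p, len(hs), len(ht)), 50),
            means=np.zeros(p), min_pairs=1, symmetrized=True,
        )
        B = sc.estimate_coregionalization(
            covset, two_scale_truth.components, method="least-squares"
        )
        for est, true in zip(B, two_scale_truth.coreg):
            assert np.abs(est - true).max() < 1e-8

    def test_nonpositive_component_sill_rejected(self):
        covset = self._toy_covset({(0, 0): 10.0})
        bad = ps(0.0, 0.0, 0.0, 20.0, 2.0)
        with pytest.raises(ValueError, match="sill"):
            sc.estimate_coregionalization(
                covset, [bad], method="sequential", scale_lags=[(20.0, 2.0)]
            )


class TestRepairPSD:
    def test_canonical_example_exact(self):
        out = sc.repair_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert out == pytest.approx(np.array([[1.5, 1.5], [1.5, 1.5]]), abs=1e-12)

    def test_identity_unchanged(self):
        assert np.array_equal(sc.repair_psd(np.eye(3)), np.eye(3))

    @given(st.integers(0, 1000))
    def test_idempotent_and_psd(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((4, 4))
        B = A + A.T
        once = sc.repair_psd(B)
        assert np.linalg.eigvalsh(once).min() >= -1e-10
        assert np.abs(sc.repair_psd(once) - once).max() < 1e-12

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            sc.repair_psd(np.array([[1.0, 1.0], [0.0, 1.0]]))


class TestAssembleSTLCM:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sc.assemble_stlcm([ps(1, 0, 0, 20, 2)], [], ["z"])

    def test_four_components_like_case_study(self):
        model = sc.veneto_fitted_model()
        rebuilt = sc.assemble_stlcm(model.components, model.coreg, model.variables)
        assert rebuilt.L == 4 and rebuilt.p == 4

    def test_intrinsic_single_component(self):
        model = sc.veneto_intrinsic_model()
        assert model.L == 1


class TestEndToEndFit:
    def test_two_scale_recovery_single_replicate(self, two_scale_truth):
        coords = sc.make_station_layout(50, (250.0, 250.0), "uniform", seed=42)
        grid = sc.LagGrid(
            spatial=tuple(15.0 * k for k in range(1, 9)),
            temporal=tuple(float(k) for k in range(1, 16)),
            spatial_tol=7.5,
        )
        sim = sc.STLCMSimulator(
            sc.SimulationSpec(model=two_scale_truth, coords=coords, n_months=60, seed=0)
        )
        _, res = sim.simulate(np.random.default_rng(12))
        fit = sc.fit_stlcm(res, grid=grid, min_pairs=10)
        assert fit.model.L == 2
        # ordering convention: ascending spatial scale
        assert (
            fit.model.components[0].spatial_range
            < fit.model.components[1].spatial_range
        )
        for b in fit.model.coreg:
            assert np.linalg.eigvalsh(b).min() >= -1e-10
        assert fit.off_diagonal_ratio < 0.5
        # component surfaces positive at the origin
        for s in fit.surfaces:
            assert s.sill > 0

    def test_univariate_fit(self, small_world):
        res = small_world["residuals"].filter(variables=["rn_flux"])
        fit = sc.fit_stlcm(res, grid=sc.LagGrid.regular(90.0, 4, 6), min_pairs=5)
        assert fit.model.p == 1 and fit.model.L == 1
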