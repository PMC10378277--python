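"""Reproducible simulation studies exercising the whole pipeline.

Each study fixes its conditions (truth model, station network, lag grid,
replicate counts) and takes a seed only for the random fields, so the same
function backs both the test suite and the acceptance script.  Problem sizes
are desk-scale by design: 50 stations x 60 months for the recovery studies,
20 stations x 100 months for the test-calibration studies; the station
network is part of the study conditions (a fixed monitoring network), drawn
once from a layout seed that is independent of the field seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariance import STLCM, ExponentialMarginal, ProductSumComponent
from .diagnostics import component_ratio_surface, symmetry_test
from .empirical import LagGrid
from .fitting import ComponentSurface, fit_product_sum, fit_stlcm, repair_psd
from .kriging import (
    CokrigingEngine,
    NeighborhoodConfig,
    correct_order_relations,
    indicator_krige,
    indicator_table,
    krige,
    make_grid,
)
from .observations import ObservationTable
from .simulate import SimulationSpec, STLCMSimulator, inject_asymmetry, make_station_layout
from .validation import covariance_fit_metrics, jackknife_holdout
from .veneto import veneto_fitted_model

__all__ = [
    "default_truth",
    "strong_cross_truth",
    "recovery_grid",
    "jd_recovery_study",
    "stlcm_recovery_study",
    "noiseless_product_sum_recovery",
    "symmetry_study",
    "kriging_correctness_study",
    "cokriging_vs_kriging_study",
    "multi_vs_intrinsic_study",
    "psd_repair_check",
    "nonsep_ratio_check",
    "risk_map_study",
    "reference_sill_check",
]


def _ps(k1, k2, k3, a, b) -> ProductSumComponent:
    return ProductSumComponent(k1, k2, k3, ExponentialMarginal(a), ExponentialMarginal(b))


def default_truth() -> STLCM:
    """Two-variable, two-scale truth for the recovery studies.

    Scales (20 km, 2 mo) and (120 km, 12 mo); rank-one coregionalization
    matrices with orthogonal principal directions (so the truth is exactly
    jointly diagonalizable) and a negative cross-dependence entry at the
    large scale.
    """
    u = np.array([np.cos(np.pi / 6), np.sin(np.pi / 6)])
    v = np.array([-np.sin(np.pi / 6), np.cos(np.pi / 6)])
    return STLCM(
        ["rn_flux", "tm"],
        [_ps(1, 0, 0, 20.0, 2.0), _ps(1, 0, 0, 120.0, 12.0)],
        [2.0 * np.outer(u, u), 1.0 * np.outer(v, v)],
    )


def strong_cross_truth() -> STLCM:
    """Truth with cross-correlation ~0.88 at the origin (|b_12| near the PSD
    bound), the regime where cokriging should clearly beat kriging."""
    u = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])
    v = np.array([-np.sin(np.pi / 4), np.cos(np.pi / 4)])
    return STLCM(
        ["rn_flux", "tm"],
        [_ps(1, 0, 0, 20.0, 2.0), _ps(1, 0, 0, 120.0, 12.0)],
        [0.25 * np.outer(v, v), 4.0 * np.outer(u, u)],
    )


def recovery_grid(n_temporal: int = 15) -> LagGrid:
    """Case-study-style grid: 8 spatial lags of 15 km, monthly lags."""
    return LagGrid(
        spatial=tuple(15.0 * k for k in range(1, 9)),
        temporal=tuple(float(k) for k in range(1, n_temporal + 1)),
        spatial_tol=7.5,
    )


_LAYOUT_SEED = 42  # the monitoring network is a fixed study condition


# ---------------------------------------------------------------------------
# joint diagonalization oracle
# ---------------------------------------------------------------------------

def _haar_orthogonal(p: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((p, p)))
    return q * np.sign(np.diag(r))


def _signed_permutation_deviation(psi: np.ndarray, psi0: np.ndarray) -> float:
    """How far psi @ psi0 is from the nearest signed permutation matrix."""
    M = psi @ psi0
    p = M.shape[0]
    cols = np.argmax(np.abs(M), axis=1)
    if len(set(cols.tolist())) != p:
        return float("inf")
    Q = np.zeros_like(M)
    Q[np.arange(p), cols] = np.sign(M[np.arange(p), cols])
    return float(np.abs(M - Q).max())


def jd_recovery_study(seed: int, n_instances: int = 20, p: int = 4,
                      K: int = 30) -> dict:
    """Construct-then-recover oracle for the joint diagonalizer.

    Random instances of K exactly co-diagonalizable symmetric matrices
    Psi0 D_k Psi0^T; the recovered rotation must match Psi0 up to row sign
    and permutation.
    """
    from .fitting import joint_diagonalize

    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_orth = 0.0
    for _ in range(n_instances):
        psi0 = _haar_orthogonal(p, rng)
        diags = rng.uniform(0.2, 3.0, size=(K, p))
        mats = np.einsum("ab,kb,cb->kac", psi0, diags, psi0)
        res = joint_diagonalize(mats)
        worst = max(worst, _signed_permutation_deviation(res.psi, psi0))
        worst_orth = max(
            worst_orth, float(np.abs(res.psi @ res.psi.T - np.eye(p)).max())
        )
    return {
        "max_abs_deviation": worst,
        "max_orthogonality_defect": worst_orth,
        "n_instances": n_instances,
    }


# ---------------------------------------------------------------------------
# full ST-LCM recovery
# ---------------------------------------------------------------------------

def stlcm_recovery_study(seed: int, n_replicates: int = 20) -> dict:
    """Simulate the default truth (50 stations x 60 months), run the full
    fit, and summarize scale detection and coregionalization recovery.

    Reports medians over replicates: the detected (threshold-crossing)
    scales per component and the relative Frobenius error of each recovered
    coregionalization contribution B_l c_l(0,0) against the truth.
    """
    truth = default_truth()
    coords = make_station_layout(50, (250.0, 250.0), "uniform", seed=_LAYOUT_SEED)
    grid = recovery_grid()
    sim = STLCMSimulator(
        SimulationSpec(model=truth, coords=coords, n_months=60, seed=0)
    )
    rng = np.random.default_rng(seed)
    detected, errors = [], []
    for _ in range(n_replicates):
        _, res = sim.simulate(rng)
        fit = fit_stlcm(res, grid=grid, min_pairs=10)
        if fit.model.L != truth.L:
            detected.append([(np.nan, np.nan)] * truth.L)
            errors.append([np.inf] * truth.L)
            continue
        detected.append(
            [(s.spatial_scale, s.temporal_scale) for s in fit.surfaces]
        )
        errs = []
        for l in range(truth.L):
            est = fit.model.coreg[l] * fit.model.components[l].sill
            ref = truth.coreg[l] * truth.components[l].sill
            errs.append(np.linalg.norm(est - ref) / np.linalg.norm(ref))
        errors.append(errs)
    detected = np.array(detected)  # (R, L, 2)
    errors = np.array(errors)
    return {
        "true_scales": [(c.spatial_range, c.temporal_range) for c in truth.components],
        "median_detected_scales": np.median(detected, axis=0).tolist(),
        "grid_step": (15.0, 1.0),
        "median_coreg_relerr": np.median(errors, axis=0).tolist(),
        "n_replicates": n_replicates,
    }


def noiseless_product_sum_recovery() -> dict:
    """Fit a product-sum model to its own noiseless evaluation on the
    recovery grid and report the worst parameter relative error."""
    truth = _ps(1.2, 0.4, 0.3, 55.0, 7.0)
    grid = recovery_grid()
    hs = grid.spatial_with_zero
    ht = grid.temporal_with_zero
    surf = ComponentSurface(
        values=truth(hs[:, None], ht[None, :]),
        spatial_lags=hs, temporal_lags=ht, psi_row=np.array([1.0]),
    )
    rep = fit_product_sum(surf)
    c = rep.component
    rel = [
        abs(c.k1 - truth.k1) / truth.k1,
        abs(c.k2 - truth.k2) / truth.k2,
        abs(c.k3 - truth.k3) / truth.k3,
        abs(c.spatial_range - truth.spatial_range) / truth.spatial_range,
        abs(c.temporal_range - truth.temporal_range) / truth.temporal_range,
    ]
    return {"max_param_relerr": float(max(rel)), "rss": rep.rss}


# ---------------------------------------------------------------------------
# symmetry test calibration and power
# ---------------------------------------------------------------------------

def symmetry_study(seed: int, n_replicates: int = 200, level: float = 0.05) -> dict:
    """Empirical size under a fully symmetric truth and power under a
    one-month injected lead-lag (20 stations x 100 months)."""
    truth = STLCM(
        ["a", "b"],
        [_ps(1, 0, 0, 40.0, 3.0)],
        [np.array([[1.0, 0.5], [0.5, 1.0]])],
    )
    coords = make_station_layout(20, (150.0, 150.0), "uniform", seed=3)
    sim = STLCMSimulator(
        SimulationSpec(model=truth, coords=coords, n_months=100, seed=0)
    )
    rng = np.random.default_rng(seed)
    rej_null = 0
    for _ in range(n_replicates):
        _, res = sim.simulate(rng)
        rej_null += symmetry_test(res).pvalue < level
    rej_alt = 0
    for _ in range(n_replicates):
        _, res = sim.simulate(rng)
        shifted = inject_asymmetry(res, ("a", "b"), shift=1, noise_sd=0.3, seed=rng)
        rej_alt += symmetry_test(shifted).pvalue < level
    return {
        "size": rej_null / n_replicates,
        "power": rej_alt / n_replicates,
        "level": level,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# kriging correctness
# ---------------------------------------------------------------------------

def _toy_univariate() -> tuple[STLCM, ObservationTable, np.ndarray, np.ndarray]:
    model = STLCM(["z"], [_ps(1.0, 0.3, 0.2, 60.0, 6.0)], [np.array([[2.0]])])
    pts = np.array(
        [[10.0, 10.0, 1.0], [40.0, 20.0, 2.0], [25.0, 50.0, 3.0],
         [60.0, 35.0, 2.0], [15.0, 70.0, 4.0]]
    )
    vals = np.array([1.2, -0.4, 0.8, 0.3, -1.0])
    df = pd.DataFrame(
        {"station": [f"s{i}" for i in range(5)], "x": pts[:, 0], "y": pts[:, 1],
         "t": pts[:, 2].astype(int), "variable": "z", "value": vals}
    )
    return model, ObservationTable(df, role="residual"), pts, vals


def kriging_correctness_study(seed: int) -> dict:
    """Exactness at data points, unbiasedness residuals, and agreement with
    a dense one-shot linear solve on small systems (uni- and bivariate)."""
    rng = np.random.default_rng(seed)
    cfg = NeighborhoodConfig(max_per_variable=16, spatial_radius=1e6,
                             temporal_radius=1e6)

    model, tab, pts, vals = _toy_univariate()
    res = krige(model, tab, pts, config=cfg)
    exactness = float(np.abs(res.values - vals).max())
    var_at_data = float(np.abs(res.variances).max())

    # dense oracle at random targets, univariate
    engine = CokrigingEngine(model, tab, cfg)
    comp, b = model.components[0], model.coreg[0][0, 0]
    oracle_dev = 0.0
    unbias = 0.0
    for _ in range(5):
        tx, ty, tt = rng.uniform(0, 80), rng.uniform(0, 80), rng.uniform(1, 4)
        value, var, n, det = engine.predict_point(tx, ty, tt, "z", return_weights=True)
        w = np.zeros(len(pts))
        w[det["indices"]] = det["weights"]
        ds = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
        dt = pts[:, 2, None] - pts[None, :, 2]
        C = b * comp(ds, dt)
        c0 = b * comp(np.hypot(pts[:, 0] - tx, pts[:, 1] - ty), pts[:, 2] - tt)
        K = np.zeros((6, 6))
        K[:5, :5] = C
        K[:5, 5] = 1.0
        K[5, :5] = 1.0
        sol = np.linalg.solve(K, np.concatenate([c0, [1.0]]))
        oracle_var = b * float(comp(0.0, 0.0)) - sol[:5] @ c0 - sol[5]
        oracle_dev = max(
            oracle_dev,
            float(np.abs(sol[:5] - w).max()),
            abs(float(oracle_var) - var),
        )
        unbias = max(unbias, abs(det["weights"].sum() - 1.0))

    # bivariate 2+2 data, one target: block-structured dense oracle
    truth = default_truth()
    pts2 = np.array([[5.0, 5.0, 1.0], [30.0, 10.0, 2.0]])
    rows = []
    z2 = rng.standard_normal(4)
    for k, v in enumerate(truth.variables):
        for i, (x, y, t) in enumerate(pts2):
            rows.append((f"s{i}", x, y, int(t), v, z2[2 * k + i]))
    tab2 = ObservationTable(
        pd.DataFrame(rows, columns=["station", "x", "y", "t", "variable", "value"]),
        role="residual",
    )
    eng2 = CokrigingEngine(truth, tab2, cfg)
    tx, ty, tt = 15.0, 8.0, 1.5
    value, var, n, det = eng2.predict_point(tx, ty, tt, "rn_flux", return_weights=True)
    idx, vi = det["indices"], det["var_index"]
    npts = len(idx)
    C = np.zeros((npts, npts))
    for a in range(npts):
        for c_ in range(npts):
            ds = np.hypot(eng2.x[idx[a]] - eng2.x[idx[c_]], eng2.y[idx[a]] - eng2.y[idx[c_]])
            dt = eng2.t[idx[a]] - eng2.t[idx[c_]]
            C[a, c_] = truth.cov(int(vi[a]), int(vi[c_]), ds, dt)
    c0 = np.array(
        [truth.cov(int(vi[a]), 0, np.hypot(eng2.x[idx[a]] - tx, eng2.y[idx[a]] - ty),
                   eng2.t[idx[a]] - tt) for a in range(npts)]
    )
    Q = np.column_stack([(vi == 0).astype(float), (vi == 1).astype(float)])
    K = np.zeros((npts + 2, npts + 2))
    K[:npts, :npts] = C
    K[:npts, npts:] = Q
    K[npts:, :npts] = Q.T
    sol = np.linalg.solve(K, np.concatenate([c0, [1.0, 0.0]]))
    oracle_dev = max(oracle_dev, float(np.abs(sol[:npts] - det["weights"]).max()))
    unbias = max(
        unbias,
        abs(det["weights"][vi == 0].sum() - 1.0),
        abs(det["weights"][vi == 1].sum()),
    )
    return {
        "exactness_max_abs_dev": exactness,
        "variance_at_data_max": var_at_data,
        "oracle_max_abs_dev": oracle_dev,
        "unbiasedness_max_resid": unbias,
    }


# ---------------------------------------------------------------------------
# method comparisons
# ---------------------------------------------------------------------------

def cokriging_vs_kriging_study(seed: int, n_replicates: int = 20) -> dict:
    """Hold-out forecast comparison under strong cross-dependence.

    40 stations x 48 months with seasonality, last 4 months of the primary
    variable withheld; cokriging with the fitted ST-LCM against univariate
    kriging with the primary's own product-sum structure, paired per
    replicate.
    """
    truth = strong_cross_truth()
    coords = make_station_layout(40, (250.0, 250.0), "uniform", seed=11)
    grid = recovery_grid(n_temporal=12)
    sim = STLCMSimulator(
        SimulationSpec(
            model=truth, coords=coords, n_months=48,
            mean={"rn_flux": 20.0, "tm": 12.0},
            seasonal_amplitude={"rn_flux": 5.0, "tm": 8.0},
            seed=5,
        )
    )
    rng = np.random.default_rng(seed)
    wins = 0
    co_corr, kr_corr = [], []
    for _ in range(n_replicates):
        raw, _ = sim.simulate(rng)
        report = jackknife_holdout(
            raw, "rn_flux", 4, methods=("cokriging-stlcm", "kriging"),
            grid=grid, min_pairs=10,
        ).set_index("method")["correlation"]
        wins += report["cokriging-stlcm"] >= report["kriging"]
        co_corr.append(report["cokriging-stlcm"])
        kr_corr.append(report["kriging"])
    return {
        "wins": int(wins),
        "n_replicates": n_replicates,
        "median_corr_cokriging": float(np.median(co_corr)),
        "median_corr_kriging": float(np.median(kr_corr)),
    }


def multi_vs_intrinsic_study(seed: int, n_replicates: int = 20) -> dict:
    """Covariance-fit quality of the multi-component ST-LCM against the
    forced one-component (intrinsic) fit on the two-scale truth; paired
    comparison of the median RAE across variable pairs."""
    truth = default_truth()
    coords = make_station_layout(50, (250.0, 250.0), "uniform", seed=_LAYOUT_SEED)
    grid = recovery_grid()
    sim = STLCMSimulator(
        SimulationSpec(model=truth, coords=coords, n_months=60, seed=0)
    )
    rng = np.random.default_rng(seed)
    wins = 0
    full_rae, intr_rae = [], []
    for _ in range(n_replicates):
        _, res = sim.simulate(rng)
        full = fit_stlcm(res, grid=grid, min_pairs=10)
        intrinsic = fit_stlcm(full.covset, n_components=1, min_pairs=10)
        m_full = float(covariance_fit_metrics(full.covset, full.model)["rae"].median())
        m_intr = float(
            covariance_fit_metrics(full.covset, intrinsic.model)["rae"].median()
        )
        wins += m_full < m_intr
        full_rae.append(m_full)
        intr_rae.append(m_intr)
    return {
        "wins": int(wins),
        "n_replicates": n_replicates,
        "median_rae_multicomponent": float(np.median(full_rae)),
        "median_rae_intrinsic": float(np.median(intr_rae)),
    }


# ---------------------------------------------------------------------------
# small deterministic checks
# ---------------------------------------------------------------------------

def psd_repair_check() -> dict:
    """Eigenvalue-clipping repair on the canonical indefinite example."""
    B = np.array([[1.0, 2.0], [2.0, 1.0]])
    repaired = repair_psd(B)
    expected = np.array([[1.5, 1.5], [1.5, 1.5]])
    twice = repair_psd(repaired)
    return {
        "example_max_abs_dev": float(np.abs(repaired - expected).max()),
        "idempotence_max_abs_dev": float(np.abs(twice - repaired).max()),
        "min_eigenvalue_after": float(np.linalg.eigvalsh(repaired).min()),
    }


def nonsep_ratio_check() -> dict:
    """Ratios on a dense lag grid: identically one for a separable model,
    strictly below one for product-sum models with k2 + k3 > 0."""
    hs = np.linspace(1.0, 200.0, 40)
    ht = np.linspace(0.5, 24.0, 40)
    separable = _ps(1.7, 0.0, 0.0, 60.0, 6.0)
    sep_dev = float(
        np.abs(component_ratio_surface(separable, hs, ht).ratios - 1.0).max()
    )
    worst = -np.inf
    for comp in (_ps(1, 1, 1, 60, 6), _ps(0.5, 2.0, 0.1, 30, 12), _ps(2, 0.0, 0.7, 100, 3)):
        worst = max(worst, float(np.nanmax(component_ratio_surface(comp, hs, ht).ratios)))
    example = _ps(1, 1, 1, 60.0, 6.0)
    hs_half = 60.0 * np.log(2.0) / 3.0  # marginal exactly 0.5
    ht_half = 6.0 * np.log(2.0) / 3.0
    r = component_ratio_surface(example, np.array([hs_half]), np.array([ht_half]))
    return {
        "separable_max_dev_from_1": sep_dev,
        "productsum_max_ratio": worst,
        "example_ratio_at_half_marginals": float(r.ratios[0, 0]),
    }


def risk_map_study(seed: int) -> dict:
    """Indicator-kriging exceedance maps for three data-driven thresholds.

    A univariate seasonal world (30 stations x 36 months); thresholds are the
    25th percentile, mean and median of the historical same-calendar-month
    values; probabilities on a 6 x 6 grid are order-corrected and checked for
    coherence.
    """
    truth = STLCM(["rn_flux"], [_ps(1.0, 0.2, 0.2, 60.0, 6.0)], [np.array([[4.0]])])
    coords = make_station_layout(30, (150.0, 150.0), "uniform", seed=9)
    sim = STLCMSimulator(
        SimulationSpec(model=truth, coords=coords, n_months=36,
                       mean={"rn_flux": 20.0}, seasonal_amplitude={"rn_flux": 4.0},
                       seed=8)
    )
    raw, _ = sim.simulate(np.random.default_rng(seed))
    month = 31  # a July, the high-exhalation season
    hist = raw.data[((raw.data["t"] - 1) % 12) + 1 == ((month - 1) % 12) + 1]["value"]
    thresholds = sorted(
        [float(np.percentile(hist, 25)), float(hist.mean()), float(hist.median())]
    )
    grid_lags = LagGrid(
        spatial=tuple(20.0 * k for k in range(1, 7)),
        temporal=tuple(float(k) for k in range(1, 9)),
        spatial_tol=10.0,
    )
    cfg = NeighborhoodConfig(max_per_variable=16, spatial_radius=110.0,
                             temporal_radius=12.0)
    grid_xy = make_grid((0.0, 150.0, 0.0, 150.0), 6, 6)
    targets = np.column_stack([grid_xy, np.full(len(grid_xy), float(month))])
    probs = []
    for z in thresholds:
        ind = indicator_table(raw, z)
        ind_fit = fit_stlcm(ind, grid=grid_lags, min_pairs=10, n_components=1)
        res = indicator_krige(raw, z, ind_fit.model, targets, config=cfg)
        probs.append(res.values)
    P = np.column_stack(probs)
    corrected = correct_order_relations(P)
    diffs = np.diff(corrected, axis=1)
    return {
        "thresholds": thresholds,
        "n_nodes": int(len(grid_xy)),
        "prob_min": float(np.nanmin(corrected)),
        "prob_max": float(np.nanmax(corrected)),
        "n_nan": int(np.isnan(corrected).sum()),
        "monotonicity_violations": int((diffs > 1e-12).sum()),
        "raw_violations": int((np.diff(P, axis=1) > 1e-9).sum()),
    }


def reference_sill_check() -> dict:
    """Evaluate the published four-component Veneto model at the origin for
    the radon-flux variable (sum-of-contributions worked check)."""
    model = veneto_fitted_model()
    contributions = [
        float(b[0, 0]) * c.sill for b, c in zip(model.coreg, model.components)
    ]
    return {
        "rn_flux_sill": float(model.cov(0, 0, 0.0, 0.0)),
        "contributions": contributions,
        "component_sills": [c.sill for c in model.components],
    }
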