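"""ST-LCM identification and fitting.

The pipeline follows the joint-diagonalization route: one orthogonal matrix
Psi simultaneously (near-)diagonalizes the sample covariance matrices at all
lags; the diagonal entries across lags form p uncorrelated component
surfaces, each of which is modelled by a product-sum covariance; finally the
coregionalization matrices B_l are estimated and repaired to positive
semi-definiteness by zeroing negative eigenvalues.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .covariance import (
    STLCM,
    ExponentialMarginal,
    ProductSumComponent,
    check_admissibility,
    check_psd,
)
from .empirical import EmpiricalCovSet, LagGrid, assemble_matrices, estimate_cov
from .observations import ObservationTable

__all__ = [
    "DiagonalizationResult",
    "ComponentSurface",
    "ProductSumFitReport",
    "STLCMFit",
    "joint_diagonalize",
    "extract_components",
    "detect_scales",
    "fit_product_sum",
    "estimate_coregionalization",
    "repair_psd",
    "assemble_stlcm",
    "fit_stlcm",
]


# ---------------------------------------------------------------------------
# joint diagonalization (Jacobi rotations)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DiagonalizationResult:
    """Orthogonal Psi with the rotated matrices' diagonals per lag."""

    psi: np.ndarray  # (p, p), rows are the component directions
    diagonals: np.ndarray  # (K, p)
    criterion: list[float]  # summed squared off-diagonals per sweep
    n_sweeps: int
    converged: bool


def _off_criterion(mats: np.ndarray) -> float:
    p = mats.shape[-1]
    off = mats.copy()
    off[:, range(p), range(p)] = 0.0
    return float(np.sum(off**2))


def joint_diagonalize(
    matrices: Sequence[np.ndarray] | np.ndarray,
    tol: float = 1e-12,
    max_sweeps: int = 100,
    sym_tol: float = 1e-8,
) -> DiagonalizationResult:
    """Jointly diagonalize symmetric matrices with Jacobi rotations.

    Minimizes (to a local optimum) the summed squared off-diagonal entries of
    ``Psi M_k Psi^T`` over all k.  Each Givens rotation angle is the exact
    minimizer for its (i, j) plane, obtained from the dominant eigenvector of
    the 2x2 accumulation of [m_ii - m_jj, 2 m_ij] over the stack.  Stops when
    the largest rotation sine in a sweep falls below ``tol``.
    """
    mats = np.array(matrices, dtype=float)
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError(f"expected a (K, p, p) stack, got shape {mats.shape}")
    K, p, _ = mats.shape
    scale = max(float(np.abs(mats).max()), 1.0)
    if np.abs(mats - mats.transpose(0, 2, 1)).max() > sym_tol * scale:
        raise ValueError("input matrices are not symmetric within tolerance")
    mats = (mats + mats.transpose(0, 2, 1)) / 2.0

    psi = np.eye(p)
    criterion = [_off_criterion(mats)]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_sin = 0.0
        for i in range(p - 1):
            for j in range(i + 1, p):
                h1 = mats[:, i, i] - mats[:, j, j]
                h2 = 2.0 * mats[:, i, j]
                g11 = h1 @ h1
                g12 = h1 @ h2
                g22 = h2 @ h2
                # dominant eigenvector of [[g11, g12], [g12, g22]]
                diff = g11 - g22
                r = np.hypot(diff, 2.0 * g12)
                if r <= 0:
                    continue
                x = diff + r  # eigenvector direction (x, y), x >= 0
                y = 2.0 * g12
                norm = np.hypot(x, y)
                if norm == 0:
                    continue
                x, y = x / norm, y / norm
                c = np.sqrt((1.0 + x) / 2.0)
                s = y / (2.0 * c) if c > 0 else 1.0
                if abs(s) <= tol:
                    continue
                max_sin = max(max_sin, abs(s))
                rot = np.array([[c, s], [-s, c]])
                sub = mats[:, [i, j], :]
                mats[:, [i, j], :] = np.einsum("ab,kbc->kac", rot, sub)
                sub = mats[:, :, [i, j]]
                mats[:, :, [i, j]] = np.einsum("kcb,ab->kca", sub, rot)
                psi[[i, j], :] = rot @ psi[[i, j], :]
        criterion.append(_off_criterion(mats))
        if max_sin < tol:
            converged = True
            break

    diagonals = mats[:, range(p), range(p)].copy()
    return DiagonalizationResult(
        psi=psi, diagonals=diagonals, criterion=criterion,
        n_sweeps=sweeps, converged=converged,
    )


# ---------------------------------------------------------------------------
# component surfaces and scale detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ComponentSurface:
    """One uncorrelated component's sample covariance over the lag grid."""

    values: np.ndarray  # (ns, nt), NaN where the lag was not retained
    spatial_lags: np.ndarray
    temporal_lags: np.ndarray
    psi_row: np.ndarray
    spatial_scale: float = np.nan
    temporal_scale: float = np.nan
    spatial_censored: bool = False
    temporal_censored: bool = False

    @property
    def sill(self) -> float:
        return float(self.values[0, 0])


def detect_scales(
    surface: ComponentSurface, decay_fraction: float = 0.05
) -> tuple[float, float]:
    """Detect the spatial and temporal scale of a component surface.

    The spatial scale is the smallest grid lag rs where the marginal value
    c(rs, 0) has decayed to ``decay_fraction`` of c(0, 0); analogously in
    time.  If the surface never decays that far the maximum lag is returned
    and the corresponding ``censored`` flag set.  The rule is invariant to a
    positive rescaling of the surface.
    """
    c00 = surface.values[0, 0]
    if not np.isfinite(c00) or c00 <= 0:
        raise ValueError(f"component sill must be positive, got {c00}")
    threshold = decay_fraction * c00

    def _scan(lags: np.ndarray, vals: np.ndarray) -> tuple[float, bool]:
        for lag, v in zip(lags[1:], vals[1:]):
            if np.isfinite(v) and v <= threshold:
                return float(lag), False
        return float(lags[-1]), True

    s_scale, s_cens = _scan(surface.spatial_lags, surface.values[:, 0])
    t_scale, t_cens = _scan(surface.temporal_lags, surface.values[0, :])
    surface.spatial_scale, surface.spatial_censored = s_scale, s_cens
    surface.temporal_scale, surface.temporal_censored = t_scale, t_cens
    return s_scale, t_scale


def extract_components(
    result: DiagonalizationResult,
    grid_lags: list[tuple[float, float]],
    spatial_lags: np.ndarray,
    temporal_lags: np.ndarray,
    decay_fraction: float = 0.05,
) -> list[ComponentSurface]:
    """Arrange the diagonal entries into per-component lag surfaces.

    Components are ordered by ascending detected spatial scale (ties broken
    by temporal scale, then by original row), a convention the fitting stage
    relies on when pairing components with coregionalization matrices.
    """
    spatial_lags = np.asarray(spatial_lags, float)
    temporal_lags = np.asarray(temporal_lags, float)
    p = result.psi.shape[0]
    ns, nt = len(spatial_lags), len(temporal_lags)
    surfaces = []
    for l in range(p):
        vals = np.full((ns, nt), np.nan)
        for (rs, rt), d in zip(grid_lags, result.diagonals[:, l]):
            a = int(np.argmin(np.abs(spatial_lags - rs)))
            b = int(np.argmin(np.abs(temporal_lags - rt)))
            vals[a, b] = d
        surf = ComponentSurface(
            values=vals,
            spatial_lags=spatial_lags,
            temporal_lags=temporal_lags,
            psi_row=result.psi[l].copy(),
        )
        detect_scales(surf, decay_fraction)
        surfaces.append(surf)
    surfaces.sort(
        key=lambda s: (s.spatial_scale, s.temporal_scale, -s.sill)
    )
    return surfaces


# ---------------------------------------------------------------------------
# product-sum fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProductSumFitReport:
    component: ProductSumComponent
    rss: float
    rae: float
    rmae: float
    n_lags: int
    n_starts: int


_K_SPLITS = (
    (0.80, 0.10, 0.10),
    (1 / 3, 1 / 3, 1 / 3),
    (0.15, 0.70, 0.15),
    (0.15, 0.15, 0.70),
    (0.98, 0.01, 0.01),
)


def fit_product_sum(
    surface: ComponentSurface,
    weights: np.ndarray | None = None,
    range_factors: Sequence[float] = (0.6, 1.0, 1.6),
) -> ProductSumFitReport:
    """Weighted least-squares fit of a product-sum model to a surface.

    Parameters (k1, k2, k3, a, b) are optimized under the admissibility
    constraints k1 > 0, k2 >= 0, k3 >= 0, a, b > 0 with a deterministic
    multistart: range starts are the detected scales scaled by
    ``range_factors`` and the sill is split over (k1, k2, k3) in several
    fixed proportions.  Default weights are the pair counts when the caller
    provides them; otherwise uniform.
    """
    vals = surface.values
    finite = np.isfinite(vals)
    if finite.sum() < 5:
        raise ValueError("need at least 5 finite lag values to fit a product-sum model")
    if np.nanstd(vals) <= 1e-12 * max(abs(np.nanmean(vals)), 1.0):
        raise ValueError("degenerate surface: all values equal")
    hs = np.broadcast_to(surface.spatial_lags[:, None], vals.shape)[finite]
    ht = np.broadcast_to(surface.temporal_lags[None, :], vals.shape)[finite]
    y = vals[finite]
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, float)[finite]
        w = w / w.mean()
    sw = np.sqrt(w)

    if not np.isfinite(surface.spatial_scale):
        detect_scales(surface)
    sill0 = max(float(vals[0, 0]), 1e-12)

    def residual(x):
        k1, k2, k3, a, b = x
        cs = np.exp(-3.0 * hs / a)
        ct = np.exp(-3.0 * ht / b)
        return sw * (k1 * cs * ct + k2 * cs + k3 * ct - y)

    lo = [1e-10 * sill0, 0.0, 0.0, 1e-6, 1e-6]
    hi = [np.inf] * 5
    best = None
    n_starts = 0
    for fa in range_factors:
        for fb in range_factors:
            a0 = max(surface.spatial_scale * fa, 1e-3)
            b0 = max(surface.temporal_scale * fb, 1e-3)
            for s1, s2, s3 in _K_SPLITS:
                x0 = [max(s1 * sill0, lo[0] * 2), s2 * sill0, s3 * sill0, a0, b0]
                sol = least_squares(
                    residual, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
                )
                n_starts += 1
                if best is None or sol.cost < best.cost:
                    best = sol
    k1, k2, k3, a, b = best.x
    comp = ProductSumComponent(
        k1=float(k1), k2=float(k2), k3=float(k3),
        spatial=ExponentialMarginal(float(a)),
        temporal=ExponentialMarginal(float(b)),
    )
    if not check_admissibility(comp).positive_semi_definite:
        raise RuntimeError("fitted parameters violate admissibility constraints")
    fitted = comp(hs, ht)
    err = y - fitted
    return ProductSumFitReport(
        component=comp,
        rss=float(np.sum(w * err**2)),
        rae=float(np.sqrt(np.sum(err**2) / np.sum(y**2))),
        rmae=float(np.sum(np.abs(err)) / np.sum(np.abs(y))),
        n_lags=int(finite.sum()),
        n_starts=n_starts,
    )


# ---------------------------------------------------------------------------
# coregionalization matrices
# ---------------------------------------------------------------------------

def _nearest_lag_index(covset: EmpiricalCovSet, lag: tuple[float, float]) -> tuple[int, int]:
    a = int(np.argmin(np.abs(covset.spatial_lags - lag[0])))
    b = int(np.argmin(np.abs(covset.temporal_lags - lag[1])))
    return a, b


def estimate_coregionalization(
    covset: EmpiricalCovSet,
    components: Sequence[ProductSumComponent],
    method: Literal["least-squares", "sequential"] = "least-squares",
    scale_lags: Sequence[tuple[float, float]] | None = None,
) -> list[np.ndarray]:
    """Estimate the coregionalization matrices B_l (before PSD repair).

    ``"sequential"`` implements the classical rule: with scale lags ordered
    by ascending scale, b_ij^l is the drop of the empirical covariance
    between consecutive scale lags divided by the component sill,

        b_ij^l = [C_ij(lambda_{l-1}) - C_ij(lambda_l)] / c_l(0, 0),

    with lambda_0 = (0, 0).  This is only reliable when the scales are far
    apart, because a slower component that has already partly decayed at a
    faster component's scale lag leaks into the wrong matrix.

    ``"least-squares"`` (the pipeline default) regresses each empirical
    surface C_ij(k) on the fitted basic structures c_l(k) across all retained
    lags, weighted by pair counts, which stays consistent for overlapping
    scales.  Both return symmetric matrices; PSD is enforced later by
    ``repair_psd``.
    """
    p = covset.p
    L = len(components)
    sills = np.array([c.sill for c in components])
    if np.any(sills <= 0):
        raise ValueError("every component must have positive sill c_l(0,0)")

    if method == "sequential":
        if scale_lags is None:
            raise ValueError("sequential estimation needs the detected scale lags")
        if len(scale_lags) != L:
            raise ValueError("need exactly one scale lag per component")
        idx = [(0, 0)] + [_nearest_lag_index(covset, lag) for lag in scale_lags]
        out = []
        for l in range(L):
            a0, b0 = idx[l]
            a1, b1 = idx[l + 1]
            diff = covset.values[:, :, a0, b0] - covset.values[:, :, a1, b1]
            out.append((diff + diff.T) / (2.0 * sills[l]))
        return out

    if method != "least-squares":
        raise ValueError(f"unknown method {method!r}")

    retained = covset.retained & np.isfinite(covset.values).all(axis=(0, 1))
    aa, bb = np.nonzero(retained)
    if len(aa) < L:
        raise ValueError("fewer retained lags than components")
    hs = covset.spatial_lags[aa]
    ht = covset.temporal_lags[bb]
    X = np.column_stack([c(hs, ht) for c in components])  # (K, L)
    B = [np.zeros((p, p)) for _ in range(L)]
    for i in range(p):
        for j in range(i, p):
            y = covset.values[i, j, aa, bb]
            w = covset.counts[i, j, aa, bb].astype(float)
            w = np.where(w > 0, w, 0.0)
            sw = np.sqrt(w / max(w.mean(), 1e-300))
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            for l in range(L):
                B[l][i, j] = B[l][j, i] = coef[l]
    return B


def repair_psd(B: np.ndarray, tol: float = 1e-12, sym_tol: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by zeroing negative eigenvalues.

    Already-PSD inputs (within ``tol`` relative to the spectral radius) are
    returned unchanged, which makes the operation idempotent.
    """
    B = np.asarray(B, dtype=float)
    scale = max(float(np.abs(B).max()), 1.0)
    if np.abs(B - B.T).max() > sym_tol * scale:
        raise ValueError("repair_psd expects a symmetric matrix")
    sym = (B + B.T) / 2.0
    eig, vec = np.linalg.eigh(sym)
    eig_scale = max(float(np.abs(eig).max()), 1.0)
    if eig.min() >= -tol * eig_scale:
        return sym.copy()
    clipped = np.clip(eig, 0.0, None)
    return (vec * clipped) @ vec.T


def assemble_stlcm(
    components: Sequence[ProductSumComponent],
    coreg: Sequence[np.ndarray],
    variables: Sequence[str],
) -> STLCM:
    """Build a validated ST-LCM from fitted components and (repaired) B_l."""
    if len(components) != len(coreg):
        raise ValueError(
            f"{len(components)} components but {len(coreg)} coregionalization matrices"
        )
    if variables and len(components) > len(variables):
        raise ValueError(
            f"component selection must keep L <= p, got L={len(components)} "
            f"for p={len(variables)}"
        )
    for l, b in enumerate(coreg):
        report = check_psd(np.asarray(b, float))
        if not report.passed:
            raise RuntimeError(
                f"B_{l + 1} still indefinite after repair "
                f"(min eigenvalue {report.min_eigenvalue:.3e})"
            )
    return STLCM(variables, components, coreg)


# ---------------------------------------------------------------------------
# end-to-end fit
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class STLCMFit:
    model: STLCM
    covset: EmpiricalCovSet
    diagonalization: DiagonalizationResult
    surfaces: list[ComponentSurface]  # retained, in model component order
    all_surfaces: list[ComponentSurface]
    fit_reports: list[ProductSumFitReport]
    coreg_raw: list[np.ndarray]
    off_diagonal_ratio: float

    def summary(self) -> str:
        lines = [f"ST-LCM fit: p={self.model.p}, L={self.model.L}"]
        for l, (c, rep) in enumerate(zip(self.model.components, self.fit_reports), 1):
            lines.append(
                f"  component {l}: a={c.spatial_range:.1f} km, "
                f"b={c.temporal_range:.1f} mo, sill={c.sill:.4g}, "
                f"fit RAE={rep.rae:.3f}"
            )
        lines.append(
            f"  joint diagonalization: {self.diagonalization.n_sweeps} sweeps, "
            f"median |off|/|diag| = {self.off_diagonal_ratio:.3g}"
        )
        return "\n".join(lines)


def _median_off_ratio(diag_result: DiagonalizationResult, mats: np.ndarray) -> float:
    psi = diag_result.psi
    rotated = np.einsum("ab,kbc,dc->kad", psi, mats, psi)
    p = psi.shape[0]
    if p == 1:
        return 0.0
    off = rotated.copy()
    off[:, range(p), range(p)] = 0.0
    diag_norm = np.abs(rotated[:, range(p), range(p)]).mean(axis=1)
    off_norm = np.abs(off).sum(axis=(1, 2)) / (p * (p - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = off_norm / diag_norm
    return float(np.nanmedian(ratios))


def fit_stlcm(
    residuals: ObservationTable | EmpiricalCovSet,
    grid: LagGrid | None = None,
    n_components: int | None = None,
    min_pairs: int = 30,
    decay_fraction: float = 0.05,
    retention_fraction: float = 0.01,
    coreg_method: Literal["least-squares", "sequential"] = "least-squares",
) -> STLCMFit:
    """Full ST-LCM fit from residuals (or a precomputed covariance set).

    Stages: covariance estimation -> joint diagonalization -> component
    extraction and scale detection -> component retention -> product-sum fit
    per component -> coregionalization estimation -> PSD repair -> assembly.

    Retention keeps components whose sill exceeds ``retention_fraction`` of
    the largest and whose (spatial, temporal) scales are distinct within one
    grid step; ``n_components`` overrides the rule and keeps that many
    components with the largest scales (``n_components=1`` is the intrinsic
    coregionalization contender).
    """
    if isinstance(residuals, EmpiricalCovSet):
        covset = residuals if residuals.symmetrized else residuals.symmetrize()
    else:
        if grid is None:
            grid = LagGrid.default_for(residuals)
        covset = estimate_cov(residuals, grid, symmetrize=True, min_pairs=min_pairs)

    lags, mats = assemble_matrices(covset)
    diag_result = joint_diagonalize(mats)
    surfaces = extract_components(
        diag_result, lags, covset.spatial_lags, covset.temporal_lags,
        decay_fraction=decay_fraction,
    )

    # component retention
    max_sill = max(s.sill for s in surfaces)
    s_step = np.diff(covset.spatial_lags).min()
    t_step = np.diff(covset.temporal_lags).min()
    retained: list[ComponentSurface] = []
    for s in surfaces:
        if s.sill <= retention_fraction * max_sill:
            continue
        duplicate = None
        for other in retained:
            if (
                abs(other.spatial_scale - s.spatial_scale) <= s_step
                and abs(other.temporal_scale - s.temporal_scale) <= t_step
            ):
                duplicate = other
                break
        if duplicate is not None:
            if s.sill > duplicate.sill:
                retained[retained.index(duplicate)] = s
            continue
        retained.append(s)
    if n_components is not None:
        if not 1 <= n_components <= len(surfaces):
            raise ValueError(f"n_components must be in 1..{len(surfaces)}")
        pool = sorted(
            surfaces, key=lambda s: (s.spatial_scale, s.temporal_scale, -s.sill)
        )
        retained = pool[-n_components:]
    if not retained:
        raise RuntimeError("no component retained")
    retained.sort(key=lambda s: (s.spatial_scale, s.temporal_scale, -s.sill))

    counts_floor = covset.counts.min(axis=(0, 1)).astype(float)
    reports = [fit_product_sum(s, weights=counts_floor) for s in retained]
    components = [r.component for r in reports]

    scale_lags = [(s.spatial_scale, s.temporal_scale) for s in retained]
    coreg_raw = estimate_coregionalization(
        covset, components, method=coreg_method, scale_lags=scale_lags
    )
    coreg = [repair_psd(b) for b in coreg_raw]
    model = assemble_stlcm(components, coreg, covset.variables)
    return STLCMFit(
        model=model,
        covset=covset,
        diagonalization=diag_result,
        surfaces=retained,
        all_surfaces=surfaces,
        fit_reports=reports,
        coreg_raw=coreg_raw,
        off_diagonal_ratio=_median_off_ratio(diag_result, mats),
    )
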