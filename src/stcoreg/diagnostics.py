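"""Model-assumption diagnostics: symmetry, separability, non-separability.

The symmetry test compares the two orientations of the sample cross
covariance, C_ij(h) vs C_ji(h), over a user-chosen set of space-time lags.
Scaled by the record length the contrast vector is asymptotically Gaussian,
so the quadratic form

    TS = n (A G)^T (A V A^T)^{-1} (A G)

is asymptotically chi-squared with rank(A) degrees of freedom, where V is
the long-run covariance of the cross-covariance vector estimated by
overlapping temporal block subsampling.  The separability test uses the same
asymptotic framework on the log-covariance contrast

    log C(hs, ht) + log C(0, 0) - log C(hs, 0) - log C(0, ht),

which vanishes identically for separable covariances; the gradient of the
log transform enters through the delta method.  Non-separability ratios
r = C(hs, ht) C(0, 0) / (C(hs, 0) C(0, ht)) classify the departure:
uniformly below one indicates negative non-separability, the regime of the
product-sum class.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariance import ProductSumComponent
from .observations import ObservationTable

__all__ = [
    "SymmetryTestResult",
    "SeparabilityTestResult",
    "RatioSurface",
    "DiagnosticsError",
    "symmetry_test",
    "separability_test",
    "nonsep_ratio",
    "component_ratio_surface",
]


class DiagnosticsError(RuntimeError):
    """Raised when a diagnostic statistic cannot be computed."""


# ---------------------------------------------------------------------------
# shared machinery: windowed cross-covariance estimates
# ---------------------------------------------------------------------------

class _WideData:
    """Centered stations x months arrays per variable, plus pair masks."""

    def __init__(self, table: ObservationTable):
        self.variables = table.variables
        coords = table.station_coords().to_numpy(dtype=float)
        self.dist = np.hypot(
            coords[:, 0:1] - coords[:, 0:1].T, coords[:, 1:2] - coords[:, 1:2].T
        )
        self.values = {}
        self.masks = {}
        for v in self.variables:
            w = table.wide(v).to_numpy(dtype=float)
            obs = np.isfinite(w)
            self.values[v] = np.where(obs, w - np.nanmean(w), 0.0)
            self.masks[v] = obs.astype(float)
        self.T = next(iter(self.values.values())).shape[1]

    def pair_mask(self, rs: float, tol: float) -> np.ndarray:
        if rs == 0:
            return np.eye(self.dist.shape[0], dtype=bool)
        m = np.abs(self.dist - rs) < tol
        np.fill_diagonal(m, abs(rs) < tol)
        return m

    def cross_cov(self, vi: str, vj: str, mask: np.ndarray, ht: int,
                  t0: int, t1: int) -> float:
        """Mean of z_i(s_a, t + ht) z_j(s_b, t) over pairs in the window."""
        ht = int(ht)
        if ht < 0:
            return self.cross_cov(vj, vi, mask.T, -ht, t0, t1)
        if t1 - t0 <= ht:
            return np.nan
        Ai = self.values[vi][:, t0 + ht:t1]
        Aj = self.values[vj][:, t0:t1 - ht]
        Wi = self.masks[vi][:, t0 + ht:t1]
        Wj = self.masks[vj][:, t0:t1 - ht]
        s = float(((Ai @ Aj.T) * mask).sum())
        n = float(((Wi @ Wj.T) * mask).sum())
        return s / n if n > 0 else np.nan


def _block_estimates(wide: _WideData, entries, block_length: int) -> np.ndarray:
    """Stack of the statistic vector computed on overlapping temporal blocks.

    ``entries`` is a list of (vi, vj, mask, ht); each block estimate centres
    with the global means, the standard subsampling recipe.
    """
    T = wide.T
    n_blocks = T - block_length + 1
    out = np.full((n_blocks, len(entries)), np.nan)
    for b in range(n_blocks):
        for k, (vi, vj, mask, ht) in enumerate(entries):
            out[b, k] = wide.cross_cov(vi, vj, mask, ht, b, b + block_length)
    return out


def _subsample_covariance(blocks: np.ndarray, block_length: int) -> np.ndarray:
    ok = np.isfinite(blocks).all(axis=1)
    blocks = blocks[ok]
    if len(blocks) < 3:
        raise DiagnosticsError("too few valid blocks for the subsampling variance")
    centred = blocks - blocks.mean(axis=0)
    return block_length * (centred.T @ centred) / len(blocks)


def _quadratic_form(g: np.ndarray, V: np.ndarray, n: int) -> float:
    try:
        sol = np.linalg.solve(V, g)
    except np.linalg.LinAlgError as err:
        raise DiagnosticsError(
            "singular contrast covariance; try fewer lags in the lag set"
        ) from err
    if np.linalg.cond(V) > 1e12:
        raise DiagnosticsError(
            "ill-conditioned contrast covariance; try fewer lags in the lag set"
        )
    return float(n * g @ sol)


# ---------------------------------------------------------------------------
# symmetry test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SymmetryTestResult:
    statistic: float
    df: int
    pvalue: float
    lags: tuple[tuple[float, float], ...]
    pairs: tuple[tuple[str, str], ...]
    block_length: int
    n_time: int

    def reject(self, level: float = 0.05) -> bool:
        return self.pvalue < level


def symmetry_test(
    residuals: ObservationTable,
    lags: Sequence[tuple[float, float]] = ((0.0, 1.0),),
    pairs: Sequence[tuple[str, str]] | None = None,
    spatial_tol: float = 1e-9,
    block_length: int | None = None,
) -> SymmetryTestResult:
    """Test C_ij(h) = C_ji(h) over a lag set for the given variable pairs.

    Default lag set is the co-located one-month lag (rs = 0, rt = 1), the lag
    where cross-correlation is typically strongest for monthly data; default
    pairs are all unordered variable pairs.  The long-run covariance of the
    cross-covariance vector is estimated by overlapping temporal block
    subsampling with block length ``floor(sqrt(T))`` unless overridden.
    """
    if not lags:
        raise ValueError("lag set must be non-empty")
    variables = residuals.variables
    if pairs is None:
        pairs = [
            (variables[i], variables[j])
            for i in range(len(variables))
            for j in range(i + 1, len(variables))
        ]
    if not pairs:
        raise ValueError("need at least two variables (one pair) to test symmetry")
    wide = _WideData(residuals)
    T = wide.T
    if block_length is None:
        block_length = max(int(np.floor(np.sqrt(T))), 2)
    if T < 4 * block_length:
        raise ValueError(
            f"record length {T} too short for block length {block_length} "
            "(need at least 4 blocks' worth of data)"
        )

    entries = []
    for vi, vj in pairs:
        for rs, rt in lags:
            mask = wide.pair_mask(rs, spatial_tol)
            entries.append((vi, vj, mask, int(round(rt))))
            entries.append((vj, vi, mask, int(round(rt))))
    g_full = np.array(
        [wide.cross_cov(vi, vj, m, ht, 0, T) for vi, vj, m, ht in entries]
    )
    if not np.isfinite(g_full).all():
        raise DiagnosticsError("cross-covariance undefined at a requested lag")

    m = len(entries) // 2
    A = np.zeros((m, 2 * m))
    for k in range(m):
        A[k, 2 * k] = 1.0
        A[k, 2 * k + 1] = -1.0
    rank = np.linalg.matrix_rank(A, tol=1e-8)

    blocks = _block_estimates(wide, entries, block_length)
    V = _subsample_covariance(blocks, block_length)
    contrast = A @ g_full
    ts = _quadratic_form(contrast, A @ V @ A.T, T)
    ts = max(ts, 0.0)
    return SymmetryTestResult(
        statistic=ts,
        df=int(rank),
        pvalue=float(stats.chi2.sf(ts, rank)),
        lags=tuple((float(a), float(b)) for a, b in lags),
        pairs=tuple(pairs),
        block_length=block_length,
        n_time=T,
    )


# ---------------------------------------------------------------------------
# separability test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SeparabilityTestResult:
    statistic: float
    df: int
    pvalue: float
    lags: tuple[tuple[float, float], ...]
    variable: str
    block_length: int
    n_time: int

    def reject(self, level: float = 0.05) -> bool:
        return self.pvalue < level


def separability_test(
    residuals: ObservationTable,
    variable: str,
    lags: Sequence[tuple[float, float]],
    spatial_tol: float = 7.5,
    block_length: int | None = None,
) -> SeparabilityTestResult:
    """Test full separability of one variable's space-time covariance.

    For each tested lag (hs, ht), hs, ht > 0, the contrast
    ``log C(hs,ht) + log C(0,0) - log C(hs,0) - log C(0,ht)`` is zero under
    separability.  Covariances at all needed lags must be positive (the log
    is undefined otherwise).  Same subsampling framework as the symmetry
    test, with the delta-method gradient of the log transform.
    """
    if not lags:
        raise ValueError("lag set must be non-empty")
    for rs, rt in lags:
        if rs <= 0 or rt <= 0:
            raise ValueError("separability contrasts need strictly positive lags")
    wide = _WideData(residuals)
    T = wide.T
    if block_length is None:
        block_length = max(int(np.floor(np.sqrt(T))), 2)

    needed: list[tuple[float, float]] = [(0.0, 0.0)]
    for rs, rt in lags:
        for lag in ((rs, rt), (rs, 0.0), (0.0, rt)):
            if lag not in needed:
                needed.append(lag)
    entries = [
        (variable, variable, wide.pair_mask(rs, spatial_tol), int(round(rt)))
        for rs, rt in needed
    ]
    u = np.array([wide.cross_cov(vi, vj, m, ht, 0, T) for vi, vj, m, ht in entries])
    if not np.isfinite(u).all() or np.any(u <= 0):
        bad = [needed[k] for k in np.nonzero(~(np.isfinite(u) & (u > 0)))[0]]
        raise DiagnosticsError(
            f"non-positive covariance at lags {bad}: log contrast undefined"
        )

    pos = {lag: k for k, lag in enumerate(needed)}
    A = np.zeros((len(lags), len(needed)))
    for r, (rs, rt) in enumerate(lags):
        A[r, pos[(rs, rt)]] += 1.0
        A[r, pos[(0.0, 0.0)]] += 1.0
        A[r, pos[(rs, 0.0)]] -= 1.0
        A[r, pos[(0.0, rt)]] -= 1.0
    rank = np.linalg.matrix_rank(A, tol=1e-8)

    blocks = _block_estimates(wide, entries, block_length)
    V_u = _subsample_covariance(blocks, block_length)
    J = A * (1.0 / u)[None, :]  # delta method: d(log u)/du = 1/u
    contrast = A @ np.log(u)
    ts = max(_quadratic_form(contrast, J @ V_u @ J.T, T), 0.0)
    return SeparabilityTestResult(
        statistic=ts,
        df=int(rank),
        pvalue=float(stats.chi2.sf(ts, rank)),
        lags=tuple((float(a), float(b)) for a, b in lags),
        variable=variable,
        block_length=block_length,
        n_time=T,
    )


# ---------------------------------------------------------------------------
# non-separability ratios
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RatioSurface:
    """Non-separability ratios r(hs, ht) at strictly positive lags."""

    ratios: np.ndarray  # (ns - 1, nt - 1)
    spatial_lags: np.ndarray  # positive lags only
    temporal_lags: np.ndarray
    excluded: np.ndarray  # mask of lags dropped for non-positive denominators
    classification: str  # "uniformly negative" | "uniformly positive" | "mixed"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, rs in enumerate(self.spatial_lags):
            for b, rt in enumerate(self.temporal_lags):
                rows.append((rs, rt, self.ratios[a, b], bool(self.excluded[a, b])))
        return pd.DataFrame(rows, columns=["rs", "rt", "ratio", "excluded"])

    def grouped(self, by: str = "rs") -> pd.DataFrame:
        """Five-number summaries grouped by spatial or temporal lag, the
        tabular backing of the usual box-plot display."""
        df = self.to_frame()
        df = df[~df["excluded"] & np.isfinite(df["ratio"])]
        q = df.groupby(by)["ratio"].describe()[["min", "25%", "50%", "75%", "max"]]
        return q.reset_index()


def nonsep_ratio(
    values: np.ndarray,
    spatial_lags: np.ndarray,
    temporal_lags: np.ndarray,
) -> RatioSurface:
    """Compute r(hs,ht) = C(hs,ht) C(0,0) / (C(hs,0) C(0,ht)) on a surface.

    ``values`` is an (ns, nt) covariance surface whose first row/column hold
    the marginals (zero spatial/temporal lag).  Lags with non-positive
    denominators are excluded and reported rather than failing the whole
    surface; a non-positive C(0, 0) is an error.
    """
    values = np.asarray(values, dtype=float)
    spatial_lags = np.asarray(spatial_lags, float)
    temporal_lags = np.asarray(temporal_lags, float)
    c00 = values[0, 0]
    if not np.isfinite(c00) or c00 <= 0:
        raise ValueError(f"C(0,0) must be positive, got {c00}")
    cs = values[1:, 0]  # C(hs, 0)
    ct = values[0, 1:]  # C(0, ht)
    num = values[1:, 1:] * c00
    den = cs[:, None] * ct[None, :]
    excluded = ~(np.isfinite(den) & (den > 0) & np.isfinite(num))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(excluded, np.nan, num / den)
    valid = ratios[~excluded]
    if valid.size == 0:
        classification = "undefined"
    elif np.all(valid < 1.0):
        classification = "uniformly negative"
    elif np.all(valid > 1.0):
        classification = "uniformly positive"
    else:
        classification = "mixed"
    return RatioSurface(
        ratios=ratios,
        spatial_lags=spatial_lags[1:],
        temporal_lags=temporal_lags[1:],
        excluded=excluded,
        classification=classification,
    )


def component_ratio_surface(
    comp: ProductSumComponent,
    spatial_lags: np.ndarray,
    temporal_lags: np.ndarray,
) -> RatioSurface:
    """Non-separability ratios of a product-sum model on a dense lag grid.

    ``spatial_lags``/``temporal_lags`` are strictly positive; the zero lag is
    prepended internally.
    """
    hs = np.concatenate([[0.0], np.asarray(spatial_lags, float)])
    ht = np.concatenate([[0.0], np.asarray(temporal_lags, float)])
    values = comp(hs[:, None], ht[None, :])
    return nonsep_ratio(values, hs, ht)
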