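"""Empirical direct and cross covariances on a space-time lag grid.

For residuals z_i the estimator at lag (rs, rt) averages the centred products
[z_i(s + hs, t + ht) - m_i][z_j(s, t) - m_j] over all ordered pairs whose
spatial distance falls within Tol(rs) of rs and whose (integer) temporal
separation equals rt.  Means m_i are global per variable.  The zero lag is
always estimated from self-pairs only (Tol = 0), so C_ii(0,0) is the plug-in
variance.  The estimator is directional in ht; symmetrizing averages the two
orientations, C_ij <- (C_ij + C_ji)/2.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .observations import ObservationTable

__all__ = ["LagGrid", "EmpiricalCovSet", "estimate_cov", "assemble_matrices"]


@dataclasses.dataclass(frozen=True)
class LagGrid:
    """Strictly increasing positive spatial (km) and temporal (month) lags.

    Tolerances define the matching bins; each must be positive and no larger
    than half the smallest lag spacing so bins cannot overlap.  The zero lag
    is implicit and always matched exactly.
    """

    spatial: tuple[float, ...]
    temporal: tuple[float, ...]
    spatial_tol: float
    temporal_tol: float = 0.49

    def __post_init__(self) -> None:
        for name, lags in (("spatial", self.spatial), ("temporal", self.temporal)):
            arr = np.asarray(lags, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} lags must be non-empty")
            if np.any(arr <= 0):
                raise ValueError(f"{name} lags must be positive (zero lag is implicit)")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} lags must be strictly increasing")
        for name, tol, lags in (
            ("spatial", self.spatial_tol, self.spatial),
            ("temporal", self.temporal_tol, self.temporal),
        ):
            arr = np.asarray(lags, dtype=float)
            spacing = np.diff(np.concatenate([[0.0], arr])).min()
            if not 0 < tol <= spacing / 2 + 1e-12:
                raise ValueError(
                    f"{name} tolerance must be in (0, half lag spacing], got {tol}"
                )

    @classmethod
    def regular(cls, spatial_max: float, n_spatial: int = 8,
                n_temporal: int = 15) -> "LagGrid":
        """Evenly spaced lags: n_spatial spatial bins up to ``spatial_max`` km
        and monthly temporal lags 1..n_temporal, tolerances = half spacing."""
        step = spatial_max / n_spatial
        spatial = tuple(step * k for k in range(1, n_spatial + 1))
        temporal = tuple(float(k) for k in range(1, n_temporal + 1))
        return cls(spatial=spatial, temporal=temporal, spatial_tol=step / 2)

    @classmethod
    def default_for(cls, table: ObservationTable, n_spatial: int = 8,
                    n_temporal: int = 15) -> "LagGrid":
        """Grid mimicking the case-study geometry: spatial lags spanning about
        half the domain diameter, 15 monthly lags."""
        xy = table.station_coords().to_numpy(dtype=float)
        diameter = float(
            np.hypot(xy[:, 0].max() - xy[:, 0].min(), xy[:, 1].max() - xy[:, 1].min())
        )
        n_temporal = min(n_temporal, table.n_months - 2)
        return cls.regular(diameter / 2, n_spatial=n_spatial, n_temporal=n_temporal)

    # lags including the implicit origin, as used for storage
    @property
    def spatial_with_zero(self) -> np.ndarray:
        return np.concatenate([[0.0], np.asarray(self.spatial, float)])

    @property
    def temporal_with_zero(self) -> np.ndarray:
        return np.concatenate([[0.0], np.asarray(self.temporal, float)])


@dataclasses.dataclass
class EmpiricalCovSet:
    """Sample direct/cross covariances on a lag grid with pair counts.

    ``values[i, j, a, b]`` is C_ij at spatial lag ``spatial_lags[a]`` and
    temporal lag ``temporal_lags[b]`` (index 0 = zero lag); ``counts`` holds
    the number of pairs.  Lags where any variable pair has fewer than
    ``min_pairs`` pairs are flagged in ``retained``.
    """

    variables: tuple[str, ...]
    spatial_lags: np.ndarray
    temporal_lags: np.ndarray
    values: np.ndarray  # (p, p, ns, nt)
    counts: np.ndarray  # (p, p, ns, nt)
    means: np.ndarray  # (p,)
    min_pairs: int
    symmetrized: bool

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def retained(self) -> np.ndarray:
        """(ns, nt) mask of lags where every variable pair has enough pairs."""
        return (self.counts >= self.min_pairs).all(axis=(0, 1))

    def index(self, variable: str) -> int:
        return self.variables.index(variable)

    def value(self, i: int, j: int, rs: float, rt: float) -> float:
        a = int(np.argmin(np.abs(self.spatial_lags - rs)))
        b = int(np.argmin(np.abs(self.temporal_lags - rt)))
        return float(self.values[i, j, a, b])

    def surface(self, i: int, j: int) -> np.ndarray:
        return self.values[i, j].copy()

    def symmetrize(self) -> "EmpiricalCovSet":
        """Average the two orientations: C_ij <- (C_ij + C_ji) / 2."""
        values = (self.values + self.values.transpose(1, 0, 2, 3)) / 2.0
        counts = (self.counts + self.counts.transpose(1, 0, 2, 3) + 1) // 2
        return dataclasses.replace(
            self, values=values, counts=counts, symmetrized=True
        )

    def matrix_at(self, a: int, b: int) -> np.ndarray:
        return self.values[:, :, a, b].copy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation (i, j, rs, rt, value, npairs) for plotting."""
        rows = []
        for i, j in itertools.product(range(self.p), repeat=2):
            for a, rs in enumerate(self.spatial_lags):
                for b, rt in enumerate(self.temporal_lags):
                    rows.append(
                        (self.variables[i], self.variables[j], rs, rt,
                         self.values[i, j, a, b], int(self.counts[i, j, a, b]))
                    )
        return pd.DataFrame(
            rows, columns=["i", "j", "rs", "rt", "value", "npairs"]
        )


def _spatial_bin_masks(dist: np.ndarray, grid: LagGrid) -> np.ndarray:
    """Boolean (ns, S, S) masks selecting station pairs per spatial bin.

    Bin 0 is the exact zero lag (same station only)."""
    S = dist.shape[0]
    masks = np.zeros((len(grid.spatial) + 1, S, S), dtype=bool)
    masks[0] = np.eye(S, dtype=bool)
    for a, rs in enumerate(grid.spatial, start=1):
        masks[a] = np.abs(dist - rs) < grid.spatial_tol
        np.fill_diagonal(masks[a], np.abs(rs) < grid.spatial_tol)
    return masks


def estimate_cov(
    residuals: ObservationTable,
    grid: LagGrid,
    symmetrize: bool = True,
    min_pairs: int = 30,
) -> EmpiricalCovSet:
    """Estimate all direct/cross covariances of a residual table on a grid.

    Temporal lags are matched exactly (monthly data with tolerance < 1);
    spatial lags match on the Euclidean distance between stations.  With
    ``symmetrize`` the two temporal orientations are averaged, which is what
    the ST-LCM fitting stage requires once the symmetry assumption has been
    accepted.
    """
    variables = residuals.variables
    p = len(variables)
    if p == 0:
        raise ValueError("empty observation table")
    coords = residuals.station_coords().to_numpy(dtype=float)
    dist = np.hypot(
        coords[:, 0:1] - coords[:, 0:1].T, coords[:, 1:2] - coords[:, 1:2].T
    )
    masks = _spatial_bin_masks(dist, grid)
    ns, nt = masks.shape[0], len(grid.temporal) + 1

    wides, masks_obs, means = [], [], np.zeros(p)
    for k, v in enumerate(variables):
        w = residuals.wide(v).to_numpy(dtype=float)
        obs = np.isfinite(w)
        if not obs.any():
            raise ValueError(f"variable {v!r} has no observations")
        means[k] = np.nanmean(w)
        wides.append(np.where(obs, w - means[k], 0.0))
        masks_obs.append(obs.astype(float))

    temporal = [0] + [int(round(rt)) for rt in grid.temporal]
    T = wides[0].shape[1]
    values = np.full((p, p, ns, nt), np.nan)
    counts = np.zeros((p, p, ns, nt), dtype=int)
    for b, ht in enumerate(temporal):
        if ht >= T:
            continue
        for i in range(p):
            Ai = wides[i][:, ht:]
            Wi = masks_obs[i][:, ht:]
            for j in range(p):
                # z_i leads by ht: products z_i(s_a, t+ht) z_j(s_b, t)
                S_ij = Ai @ wides[j][:, : T - ht].T
                N_ij = Wi @ masks_obs[j][:, : T - ht].T
                s_bins = np.einsum("kab,ab->k", masks, S_ij)
                n_bins = np.einsum("kab,ab->k", masks, N_ij)
                with np.errstate(invalid="ignore", divide="ignore"):
                    values[i, j, :, b] = np.where(n_bins > 0, s_bins / n_bins, np.nan)
                counts[i, j, :, b] = np.rint(n_bins).astype(int)

    covset = EmpiricalCovSet(
        variables=variables,
        spatial_lags=grid.spatial_with_zero,
        temporal_lags=grid.temporal_with_zero,
        values=values,
        counts=counts,
        means=means,
        min_pairs=min_pairs,
        symmetrized=False,
    )
    return covset.symmetrize() if symmetrize else covset


def assemble_matrices(
    covset: EmpiricalCovSet,
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Collect the symmetric p x p covariance matrices at every retained lag.

    Returns the lag list [(rs, rt), ...] and a (K, p, p) stack, in row-major
    grid order with the zero lag first.  Requires a symmetrized set.
    """
    if not covset.symmetrized:
        raise ValueError("assemble_matrices requires a symmetrized EmpiricalCovSet")
    retained = covset.retained & np.isfinite(covset.values).all(axis=(0, 1))
    lags: list[tuple[float, float]] = []
    mats: list[np.ndarray] = []
    for a, rs in enumerate(covset.spatial_lags):
        for b, rt in enumerate(covset.temporal_lags):
            if retained[a, b]:
                lags.append((float(rs), float(rt)))
                m = covset.values[:, :, a, b]
                mats.append((m + m.T) / 2.0)
    if not mats:
        raise ValueError("no lag retained: all pair counts below min_pairs")
    return lags, np.stack(mats)
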