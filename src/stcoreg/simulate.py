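"""Exact simulation of multivariate space-time fields from a known ST-LCM.

The generator produces monthly, station-based observations with the exact
statistical structure the analysis assumes: per-station seasonal cycles on
top of a zero-mean multivariate Gaussian residual field whose matrix-valued
covariance is the supplied ST-LCM truth, plus optional white measurement
noise.  Each basic structure is normalized to unit sill inside the generator
(the coregionalization matrices carry the scale), so the residual covariance
is exactly ``sum_l B_l c_l(h) / c_l(0,0)``.

Simulation is exact via factorization of the covariance: the product-sum
structure splits into a separable space-time part (simulated through the
Kronecker identity ``chol(Cs x Ct) = chol(Cs) x chol(Ct)``), a purely
spatial, time-constant part and a purely temporal, space-constant part,
three independent Gaussian fields whose covariances add up to the
product-sum exactly.  Only the small S x S and T x T marginal factors are
ever decomposed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .covariance import STLCM, check_admissibility, check_psd
from .observations import ObservationTable, calendar_month

__all__ = [
    "SimulationSpec",
    "STLCMSimulator",
    "make_station_layout",
    "simulate_stlcm",
    "inject_asymmetry",
]

_DENSE_CAP = 5000


def make_station_layout(
    n: int,
    extent: tuple[float, float] = (250.0, 250.0),
    mode: str = "uniform",
    seed: int | np.random.Generator = 0,
    spacing: float | None = None,
) -> np.ndarray:
    """Reproducible station coordinates (n, 2) in km over a rectangle.

    ``grid`` mode places stations on a regular grid (cell size ``spacing``
    or the largest square spacing that fits n cells), mimicking a regular
    flux-inventory grid; ``uniform`` scatters them uniformly at random.
    """
    if n < 1:
        raise ValueError("need at least one station")
    ex, ey = float(extent[0]), float(extent[1])
    if n == 1:
        return np.array([[ex / 2, ey / 2]])
    if mode == "uniform":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return rng.uniform([0.0, 0.0], [ex, ey], size=(n, 2))
    if mode == "grid":
        if spacing is not None:
            nx = int(np.floor(ex / spacing)) + 1
            ny = int(np.floor(ey / spacing)) + 1
            if nx * ny < n:
                raise ValueError(
                    f"grid with {spacing} km spacing holds {nx * ny} stations < n={n}"
                )
            xs = np.arange(nx) * spacing
            ys = np.arange(ny) * spacing
        else:
            side = int(np.ceil(np.sqrt(n)))
            xs = np.linspace(0.0, ex, side)
            ys = np.linspace(0.0, ey, side)
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        return pts[:n]
    raise ValueError(f"unknown layout mode {mode!r}")


@dataclasses.dataclass
class SimulationSpec:
    """Study-condition description for one synthetic world.

    ``seasonal_amplitude`` and ``noise_sd`` map variable names to a seasonal
    cosine amplitude (variable units) and a white-noise standard deviation;
    missing variables default to zero.  Per-station amplitudes vary by +/-30%
    around the nominal value, reproducibly from the seed.  ``n_months`` must
    cover at least two full years so the monthly seasonal means are
    estimable from the simulated record.
    """

    model: STLCM
    coords: np.ndarray
    n_months: int
    mean: Mapping[str, float] = dataclasses.field(default_factory=dict)
    seasonal_amplitude: Mapping[str, float] = dataclasses.field(default_factory=dict)
    noise_sd: Mapping[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0
    peak_month: int = 7

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be (n_stations, 2)")
        if self.n_months < 24:
            raise ValueError("need at least 24 months (two full seasonal cycles)")
        n_points = len(self.coords) * self.n_months
        if n_points > _DENSE_CAP:
            raise ValueError(
                f"{n_points} space-time points exceed the exact-simulation cap "
                f"of {_DENSE_CAP}"
            )
        for comp in self.model.components:
            rep = check_admissibility(comp)
            if not rep.positive_semi_definite:
                raise ValueError(f"inadmissible truth component: {rep.reasons}")
        for l, b in enumerate(self.model.coreg):
            if not check_psd(b).passed:
                raise ValueError(f"truth B_{l + 1} is not positive semi-definite")


def _chol(corr: np.ndarray) -> np.ndarray:
    # tiny jitter guards against numerically semi-definite marginals
    return np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))


class STLCMSimulator:
    """Reusable exact sampler; factorizations are computed once.

    Useful for Monte Carlo studies that redraw many fields over the same
    station layout and time span.
    """

    def __init__(self, spec: SimulationSpec):
        self.spec = spec
        model = spec.model
        S = len(spec.coords)
        T = spec.n_months
        dx = spec.coords[:, 0:1] - spec.coords[:, 0:1].T
        dy = spec.coords[:, 1:2] - spec.coords[:, 1:2].T
        dist = np.hypot(dx, dy)
        tt = np.arange(T, dtype=float)
        dt = np.abs(tt[:, None] - tt[None, :])
        self._parts = []
        for comp in model.components:
            Ls = _chol(comp.spatial(dist))
            Lt = _chol(comp.temporal(dt))
            sill = comp.sill
            self._parts.append(
                (np.sqrt(comp.k1 / sill), np.sqrt(comp.k2 / sill),
                 np.sqrt(comp.k3 / sill), Ls, Lt)
            )
        # symmetric square roots A_l with A_l A_l^T = B_l
        self._roots = []
        for b in model.coreg:
            eig, vec = np.linalg.eigh(b)
            self._roots.append((vec * np.sqrt(np.clip(eig, 0.0, None))) @ vec.T)
        self.S, self.T = S, T

    def residual_fields(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """One draw of the residual field, stations x months per variable."""
        model = self.spec.model
        p = model.p
        S, T = self.S, self.T
        fields = {v: np.zeros((S, T)) for v in model.variables}
        for (w1, w2, w3, Ls, Lt), A in zip(self._parts, self._roots):
            latent = np.empty((p, S, T))
            for m in range(p):
                y = np.zeros((S, T))
                if w1 > 0:
                    y += w1 * (Ls @ rng.standard_normal((S, T)) @ Lt.T)
                if w2 > 0:
                    y += w2 * (Ls @ rng.standard_normal(S))[:, None]
                if w3 > 0:
                    y += w3 * (Lt @ rng.standard_normal(T))[None, :]
                latent[m] = y
            for vi, v in enumerate(model.variables):
                fields[v] += np.tensordot(A[vi], latent, axes=(0, 0))
        return fields

    def seasonal_fields(self) -> dict[str, np.ndarray]:
        """Deterministic per-station seasonal cycles (from the spec seed)."""
        spec = self.spec
        rng = np.random.default_rng(spec.seed + 1_000_003)
        months = calendar_month(np.arange(1, spec.n_months + 1))
        cyc = np.cos(2 * np.pi * (months - spec.peak_month) / 12.0)
        out = {}
        for v in spec.model.variables:
            amp = float(spec.seasonal_amplitude.get(v, 0.0))
            station_amp = amp * (1.0 + 0.3 * rng.uniform(-1, 1, size=self.S))
            out[v] = station_amp[:, None] * cyc[None, :]
        return out

    def simulate(self, rng: np.random.Generator | None = None
                 ) -> tuple[ObservationTable, ObservationTable]:
        """Draw one world; returns the raw table and the true residual table."""
        spec = self.spec
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        resid = self.residual_fields(rng)
        seasonal = self.seasonal_fields()
        rows_raw, rows_res = [], []
        stations = [f"s{k:03d}" for k in range(self.S)]
        for v in spec.model.variables:
            mean = float(spec.mean.get(v, 0.0))
            sd = float(spec.noise_sd.get(v, 0.0))
            noise = sd * rng.standard_normal((self.S, self.T)) if sd > 0 else 0.0
            z = mean + seasonal[v] + resid[v] + noise
            for k, st in enumerate(stations):
                x, y = spec.coords[k]
                for t in range(self.T):
                    rows_raw.append((st, x, y, t + 1, v, z[k, t]))
                    rows_res.append((st, x, y, t + 1, v, resid[v][k, t]))
        cols = ["station", "x", "y", "t", "variable", "value"]
        raw = ObservationTable(pd.DataFrame(rows_raw, columns=cols), role="raw")
        res = ObservationTable(pd.DataFrame(rows_res, columns=cols), role="residual")
        return raw, res


def simulate_stlcm(spec: SimulationSpec) -> ObservationTable:
    """Generate one raw observation table from the spec (reproducible)."""
    raw, _ = STLCMSimulator(spec).simulate()
    return raw


def inject_asymmetry(
    table: ObservationTable,
    pair: tuple[str, str],
    shift: int,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> ObservationTable:
    """Create a temporal lead-lag: the second variable of ``pair`` becomes
    the first shifted by ``shift`` months plus independent noise.

    This breaks the symmetry C_ij(h) = C_ji(h) and is the power case for the
    symmetry test.  The first ``shift`` months of the target variable are
    left unchanged (no earlier source values exist).
    """
    src, dst = pair
    shift = int(shift)
    if shift < 1:
        raise ValueError("shift must be at least 1 month")
    if shift >= table.n_months:
        raise ValueError(f"shift {shift} >= record length {table.n_months}")
    for v in (src, dst):
        if v not in table.variables:
            raise KeyError(f"unknown variable {v!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = table.data.copy()
    src_vals = df[df["variable"] == src].set_index(["station", "t"])["value"]
    is_dst = df["variable"] == dst
    keys = list(zip(df.loc[is_dst, "station"], df.loc[is_dst, "t"] - shift))
    shifted = np.array([src_vals.get(k, np.nan) for k in keys])
    new = np.where(
        np.isfinite(shifted),
        shifted + noise_sd * rng.standard_normal(len(shifted)),
        df.loc[is_dst, "value"].to_numpy(),
    )
    df.loc[is_dst, "value"] = new
    return ObservationTable(df, role=table.role)
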