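"""Space-time ordinary cokriging, kriging and indicator kriging.

Predictions are linear combinations of the data with weights solving the
ordinary (co)kriging system built from the fitted ST-LCM covariance: weights
of the target variable sum to one, weights of every auxiliary variable sum to
zero, and the error variance is minimized.  Systems are solved per target
point within a local space-time neighborhood.  Indicator kriging applies the
same machinery to 0/1 threshold exceedances and yields probability maps,
with order-relation violations across thresholds corrected by monotone
rearrangement.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .covariance import STLCM
from .observations import ObservationTable, SeasonalProfile

__all__ = [
    "NeighborhoodConfig",
    "PredictionResult",
    "CokrigingEngine",
    "solve_cokriging_system",
    "cokrige",
    "krige",
    "indicator_table",
    "indicator_krige",
    "correct_order_relations",
    "predict_maps",
    "make_grid",
    "SingularSystemError",
]


class SingularSystemError(RuntimeError):
    """Raised when a kriging system stays singular after fallback retries."""


@dataclasses.dataclass(frozen=True)
class NeighborhoodConfig:
    """Local search for the data entering each kriging system."""

    max_per_variable: int = 16
    spatial_radius: float = np.inf
    temporal_radius: float = np.inf
    nugget: float = 0.0  # optional measurement-error variance on the diagonal

    def __post_init__(self) -> None:
        if self.max_per_variable < 2:
            raise ValueError("max_per_variable must be >= 2")
        if self.spatial_radius <= 0 or self.temporal_radius <= 0:
            raise ValueError("search radii must be positive")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")

    @classmethod
    def for_model(cls, model: STLCM, max_per_variable: int = 16,
                  nugget: float = 0.0) -> "NeighborhoodConfig":
        """Radii set to the largest component scales of the model."""
        return cls(
            max_per_variable=max_per_variable,
            spatial_radius=max(c.spatial_range for c in model.components),
            temporal_radius=max(c.temporal_range for c in model.components),
            nugget=nugget,
        )


def solve_cokriging_system(
    cov_dd: np.ndarray,
    cov_d0: np.ndarray,
    var_index: np.ndarray,
    target_var: int,
    sill: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve one ordinary cokriging system.

    Parameters
    ----------
    cov_dd:
        (n, n) data-to-data covariance matrix.
    cov_d0:
        (n,) data-to-target covariances with the target variable.
    var_index:
        (n,) integer variable label of each datum.
    target_var:
        Label of the predicted variable (must occur in ``var_index``).
    sill:
        C_ii(0, 0) of the target variable, for the variance.

    Returns (weights, lagrange multipliers, kriging variance).  Raises
    ``np.linalg.LinAlgError`` for singular systems (callers implement the
    drop-and-retry fallback).
    """
    var_index = np.asarray(var_index)
    labels = np.unique(var_index)
    if target_var not in labels:
        raise ValueError("no datum of the target variable in the system")
    n = len(var_index)
    m = len(labels)
    Q = (var_index[:, None] == labels[None, :]).astype(float)
    e = (labels == target_var).astype(float)
    K = np.zeros((n + m, n + m))
    K[:n, :n] = cov_dd
    K[:n, n:] = Q
    K[n:, :n] = Q.T
    rhs = np.concatenate([cov_d0, e])
    sol = np.linalg.solve(K, rhs)
    resid = np.abs(K @ sol - rhs).max()
    scale = max(np.abs(rhs).max(), 1.0)
    if not np.isfinite(sol).all() or resid > 1e-6 * scale:
        raise np.linalg.LinAlgError("ill-conditioned cokriging system")
    w, mu = sol[:n], sol[n:]
    variance = float(sill - w @ cov_d0 - mu @ e)
    return w, mu, variance


@dataclasses.dataclass
class PredictionResult:
    """Per-target predictions with kriging variances and data usage."""

    frame: pd.DataFrame  # x, y, t, value, variance, n_data, flag

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    @property
    def variances(self) -> np.ndarray:
        return self.frame["variance"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.frame.rename(columns={"x": "x_km", "y": "y_km"})
        out.to_csv(path, index=False)


class CokrigingEngine:
    """Reusable ordinary cokriging solver over one residual table.

    Building the engine extracts the data arrays once; each call to
    :meth:`predict_point` selects a local neighborhood, assembles the
    covariance system from the ST-LCM and solves it.  ``exclude`` supports
    leave-one-out validation without rebuilding the table.
    """

    def __init__(
        self,
        model: STLCM,
        table: ObservationTable,
        config: NeighborhoodConfig | None = None,
    ) -> None:
        for v in table.variables:
            if v not in model.variables:
                raise ValueError(f"model does not cover variable {v!r}")
        self.model = model
        self.config = config or NeighborhoodConfig.for_model(model)
        df = table.data
        self.x = df["x"].to_numpy(dtype=float)
        self.y = df["y"].to_numpy(dtype=float)
        self.t = df["t"].to_numpy(dtype=float)
        self.z = df["value"].to_numpy(dtype=float)
        self.var = np.array([model.index(v) for v in df["variable"]])

    def _neighborhood(self, x, y, t, exclude) -> np.ndarray:
        cfg = self.config
        ds = np.hypot(self.x - x, self.y - y)
        dt = np.abs(self.t - t)
        ok = (ds <= cfg.spatial_radius) & (dt <= cfg.temporal_radius)
        if exclude is not None:
            ok = ok.copy()
            ok[exclude] = False
        idx = np.nonzero(ok)[0]
        if idx.size == 0:
            return idx
        # scaled space-time distance for ranking
        score = np.hypot(ds[idx] / cfg.spatial_radius if np.isfinite(cfg.spatial_radius) else ds[idx],
                         dt[idx] / cfg.temporal_radius if np.isfinite(cfg.temporal_radius) else dt[idx])
        keep = []
        for lab in np.unique(self.var[idx]):
            sub = idx[self.var[idx] == lab]
            sub_score = score[np.isin(idx, sub)]
            order = np.argsort(sub_score, kind="stable")
            keep.append(sub[order[: cfg.max_per_variable]])
        return np.concatenate(keep)

    def predict_point(
        self,
        x: float,
        y: float,
        t: float,
        target_variable: str,
        exclude: int | Sequence[int] | None = None,
        return_weights: bool = False,
    ):
        """Predict one target point; returns (value, variance, n_data[, details])."""
        i = self.model.index(target_variable)
        idx = self._neighborhood(x, y, t, exclude)
        if idx.size == 0 or not np.any(self.var[idx] == i):
            out = (np.nan, np.nan, 0)
            return out + ((None,) if return_weights else ())
        for attempt in range(4):
            ds = np.hypot(self.x[idx][:, None] - self.x[idx][None, :],
                          self.y[idx][:, None] - self.y[idx][None, :])
            dt = self.t[idx][:, None] - self.t[idx][None, :]
            vi = self.var[idx]
            cov_dd = np.zeros_like(ds)
            for a in range(self.model.p):
                for b in range(self.model.p):
                    sel = (vi[:, None] == a) & (vi[None, :] == b)
                    if sel.any():
                        cov_dd[sel] = self.model.cov(a, b, ds[sel], dt[sel])
            if self.config.nugget > 0:
                cov_dd[np.eye(len(idx), dtype=bool)] += self.config.nugget
            ds0 = np.hypot(self.x[idx] - x, self.y[idx] - y)
            dt0 = self.t[idx] - t
            cov_d0 = np.array(
                [self.model.cov(int(v), i, d, u) for v, d, u in zip(vi, ds0, dt0)]
            )
            sill = float(self.model.cov(i, i, 0.0, 0.0)) + self.config.nugget
            try:
                w, mu, var = solve_cokriging_system(cov_dd, cov_d0, vi, i, sill)
            except np.linalg.LinAlgError:
                if attempt == 3 or idx.size <= 2:
                    raise SingularSystemError(
                        f"cokriging system singular at ({x:g}, {y:g}, {t:g})"
                    )
                # drop the most distant datum and retry
                score = np.hypot(ds0, dt0)
                idx = np.delete(idx, int(np.argmax(score)))
                if not np.any(self.var[idx] == i):
                    raise SingularSystemError(
                        f"no target-variable datum left at ({x:g}, {y:g}, {t:g})"
                    )
                continue
            value = float(w @ self.z[idx])
            if return_weights:
                return value, var, idx.size, {"weights": w, "lagrange": mu,
                                              "indices": idx, "var_index": vi}
            return value, var, idx.size

    def predict(self, targets: np.ndarray, target_variable: str) -> PredictionResult:
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        rows = []
        for x, y, t in targets:
            try:
                value, var, n = self.predict_point(x, y, t, target_variable)
                flag = "" if n else "empty-neighborhood"
            except SingularSystemError:
                value, var, n, flag = np.nan, np.nan, 0, "singular"
            rows.append((x, y, t, value, var, n, flag))
        return PredictionResult(
            pd.DataFrame(
                rows, columns=["x", "y", "t", "value", "variance", "n_data", "flag"]
            )
        )


def cokrige(
    model: STLCM,
    residuals: ObservationTable,
    targets: np.ndarray,
    target_variable: str,
    config: NeighborhoodConfig | None = None,
) -> PredictionResult:
    """Ordinary space-time cokriging of residuals at target (x, y, t) points."""
    return CokrigingEngine(model, residuals, config).predict(targets, target_variable)


def krige(
    model: STLCM,
    table: ObservationTable,
    targets: np.ndarray,
    config: NeighborhoodConfig | None = None,
    target_variable: str | None = None,
) -> PredictionResult:
    """Univariate ordinary kriging (single unbiasedness constraint).

    If ``model`` covers several variables, ``target_variable`` selects the
    one to krige and both model and data are restricted to it.
    """
    if target_variable is None:
        if model.p != 1:
            raise ValueError("target_variable required for a multivariate model")
        target_variable = model.variables[0]
    sub_model = model if model.p == 1 else model.select([target_variable])
    sub_table = table.filter(variables=[target_variable])
    return cokrige(sub_model, sub_table, targets, target_variable, config)


# ---------------------------------------------------------------------------
# indicator kriging
# ---------------------------------------------------------------------------

def indicator_table(table: ObservationTable, threshold: float,
                    variable: str | None = None) -> ObservationTable:
    """0/1 transform: 1 where value > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    df = table.data.copy()
    if variable is not None:
        df = df[df["variable"] == variable].copy()
    df["value"] = (df["value"] > threshold).astype(float)
    return ObservationTable(df, role=table.role)


def indicator_krige(
    table: ObservationTable,
    threshold: float,
    indicator_model: STLCM,
    targets: np.ndarray,
    config: NeighborhoodConfig | None = None,
) -> PredictionResult:
    """Exceedance-probability map by ordinary kriging of indicator data.

    The data are transformed to I = 1{value > threshold}; the provided
    single-variable ``indicator_model`` must have been fitted to that
    indicator field.  Outputs are clamped to [0, 1].  Neighborhoods whose
    indicator data are all 0 or all 1 yield the degenerate probability with a
    flag.
    """
    if indicator_model.p != 1:
        raise ValueError("indicator kriging uses a single-variable model")
    variable = indicator_model.variables[0]
    ind = indicator_table(table, threshold, variable=variable)
    engine = CokrigingEngine(indicator_model, ind, config)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    rows = []
    for x, y, t in targets:
        idx = engine._neighborhood(x, y, t, None)
        flag = ""
        if idx.size == 0:
            value, var, n = np.nan, np.nan, 0
            flag = "empty-neighborhood"
        else:
            data = engine.z[idx]
            if np.all(data == data[0]):
                value, var, n = float(data[0]), 0.0, idx.size
                flag = "degenerate"
            else:
                try:
                    value, var, n = engine.predict_point(x, y, t, variable)
                    value = float(np.clip(value, 0.0, 1.0))
                except SingularSystemError:
                    value, var, n, flag = np.nan, np.nan, 0, "singular"
        rows.append((x, y, t, value, var, n, flag))
    return PredictionResult(
        pd.DataFrame(rows, columns=["x", "y", "t", "value", "variance", "n_data", "flag"])
    )


def correct_order_relations(probs: np.ndarray) -> np.ndarray:
    """Make exceedance probabilities monotone across increasing thresholds.

    ``probs`` has shape (n_targets, n_thresholds) with thresholds ascending.
    Violations are corrected by averaging the downward (running minimum) and
    upward (reversed running maximum) rearrangements, then clamping to [0, 1].
    """
    P = np.asarray(probs, dtype=float)
    down = np.minimum.accumulate(P, axis=-1)
    up = np.maximum.accumulate(P[..., ::-1], axis=-1)[..., ::-1]
    return np.clip((down + up) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# map production
# ---------------------------------------------------------------------------

def make_grid(extent: tuple[float, float, float, float], nx: int, ny: int) -> np.ndarray:
    """Regular (nx * ny, 2) grid of node coordinates over (x0, x1, y0, y1)."""
    x0, x1, y0, y1 = extent
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    return np.column_stack([gx.ravel(), gy.ravel()])


def predict_maps(
    model: STLCM,
    residuals: ObservationTable,
    profile: SeasonalProfile,
    grid_xy: np.ndarray,
    months: Sequence[int],
    target_variable: str,
    config: NeighborhoodConfig | None = None,
) -> pd.DataFrame:
    """Final-scale prediction maps: residual cokriging plus seasonality.

    Months may extend past the data record (forecasting).  Seasonal values at
    grid nodes come from inverse-distance interpolation of the station
    profiles.  Returns one row per (node, month) with residual, seasonal and
    final values.
    """
    engine = CokrigingEngine(model, residuals, config)
    grid_xy = np.atleast_2d(np.asarray(grid_xy, dtype=float))
    frames = []
    from .observations import calendar_month

    for month in months:
        targets = np.column_stack(
            [grid_xy, np.full(len(grid_xy), float(month))]
        )
        res = engine.predict(targets, target_variable).frame
        cal = int(calendar_month(month, profile.phase))
        seasonal = np.array(
            [
                profile.interpolate(x, y, target_variable, cal)
                for x, y in grid_xy
            ]
        )
        res["seasonal"] = seasonal
        res["residual"] = res["value"]
        res["value"] = res["residual"] + res["seasonal"]
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
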