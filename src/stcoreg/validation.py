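"""Model-adequacy metrics and validation procedures.

Two relative error measures summarize agreement between sample values and a
model's values: the root average error

    RAE = sqrt( sum e_k^2 / sum z_k^2 ),

the root of the squared-error sum over the squared-sample sum, and the
relative mean absolute error

    RMAE = sum |e_k| / sum |z_k|,

with e = sample - fitted.  Both are scale-free.  On top of these the module
implements covariance-surface fit metrics per variable pair, leave-one-out
cross-validation of the cokriging predictions, and a jackknife hold-out
forecast comparison across prediction methods (full ST-LCM cokriging,
intrinsic-model cokriging, univariate kriging).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariance import STLCM
from .empirical import EmpiricalCovSet, LagGrid
from .fitting import fit_stlcm
from .kriging import CokrigingEngine, NeighborhoodConfig
from .observations import ObservationTable, deseasonalize

__all__ = [
    "rae",
    "rmae",
    "covariance_fit_metrics",
    "loocv",
    "jackknife_holdout",
    "METHODS",
]

METHODS = ("cokriging-stlcm", "cokriging-intrinsic", "kriging")


def _check_errors(sample, fitted) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(sample, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if z.shape != f.shape:
        raise ValueError(f"length mismatch: {z.shape} vs {f.shape}")
    if not np.any(z != 0):
        raise ValueError("all sample values are zero; relative errors undefined")
    return z, f


def rae(sample_values, fitted_values) -> float:
    """Root average error: sqrt(sum of squared errors / sum of squared samples)."""
    z, f = _check_errors(sample_values, fitted_values)
    return float(np.sqrt(np.sum((z - f) ** 2) / np.sum(z**2)))


def rmae(sample_values, fitted_values) -> float:
    """Relative mean absolute error: sum |errors| / sum |samples|."""
    z, f = _check_errors(sample_values, fitted_values)
    return float(np.sum(np.abs(z - f)) / np.sum(np.abs(z)))


def covariance_fit_metrics(
    covset: EmpiricalCovSet,
    model: STLCM,
    lag_window: tuple[int, int] = (5, 8),
) -> pd.DataFrame:
    """RAE/RMAE between empirical and model covariances per variable pair.

    ``lag_window = (ws, wt)`` restricts the comparison to the first ws
    non-zero spatial and wt non-zero temporal lags (plus the marginals and
    the origin), the short-and-medium-range window where the sample
    covariance is best estimated.  One row per unordered pair.
    """
    ws, wt = lag_window
    if ws < 1 or wt < 1:
        raise ValueError("lag window must include at least one lag in each dimension")
    na = min(ws + 1, len(covset.spatial_lags))
    nb = min(wt + 1, len(covset.temporal_lags))
    hs = covset.spatial_lags[:na]
    ht = covset.temporal_lags[:nb]
    HS = np.broadcast_to(hs[:, None], (na, nb))
    HT = np.broadcast_to(ht[None, :], (na, nb))
    idx = {v: model.index(v) for v in covset.variables}
    rows = []
    for i in range(covset.p):
        for j in range(i, covset.p):
            emp = covset.values[i, j, :na, :nb]
            ok = np.isfinite(emp)
            if not ok.any():
                raise ValueError("empty lag window")
            mod = model.cov(
                idx[covset.variables[i]], idx[covset.variables[j]], HS[ok], HT[ok]
            )
            rows.append(
                (covset.variables[i], covset.variables[j],
                 rae(emp[ok], mod), rmae(emp[ok], mod))
            )
    return pd.DataFrame(rows, columns=["i", "j", "rae", "rmae"])


def loocv(
    model: STLCM,
    residuals: ObservationTable,
    target_variable: str,
    config: NeighborhoodConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out cross-validation of cokriging for one variable.

    Each observation of the target variable is removed in turn and predicted
    from all remaining data (only the target datum is dropped; co-located
    auxiliary values stay).  Returns (metric report, per-point predictions).
    The procedure is deterministic.
    """
    engine = CokrigingEngine(model, residuals, config)
    df = residuals.data
    target_rows = np.nonzero((df["variable"] == target_variable).to_numpy())[0]
    if len(target_rows) < 10:
        raise ValueError("need at least 10 observations of the target variable")
    preds = []
    for k in target_rows:
        x, y, t = df.loc[k, ["x", "y", "t"]]
        value, var, n = engine.predict_point(
            float(x), float(y), float(t), target_variable, exclude=int(k)
        )
        preds.append((x, y, t, df.loc[k, "value"], value, var, n))
    out = pd.DataFrame(
        preds, columns=["x", "y", "t", "observed", "predicted", "variance", "n_data"]
    )
    ok = np.isfinite(out["predicted"])
    obs = out.loc[ok, "observed"].to_numpy()
    est = out.loc[ok, "predicted"].to_numpy()
    report = pd.DataFrame(
        [
            {
                "variable": target_variable,
                "method": "cokriging-loocv",
                "correlation": float(np.corrcoef(obs, est)[0, 1]),
                "rae": rae(obs, est),
                "rmae": rmae(obs, est),
                "n": int(ok.sum()),
            }
        ]
    )
    return report, out


def jackknife_holdout(
    raw_table: ObservationTable,
    target_variable: str,
    holdout_months: int,
    methods: tuple[str, ...] = METHODS,
    grid: LagGrid | None = None,
    config: NeighborhoodConfig | None = None,
    min_pairs: int = 30,
) -> pd.DataFrame:
    """Hold-out forecast comparison at the end of the record.

    The last ``holdout_months`` of the *target* variable are withheld; the
    seasonal profiles and all covariance models are estimated from the
    training window only.  Auxiliary-variable observations in the hold-out
    window remain available to the cokriging predictor.  Predicted residuals
    are reseasonalized with the training profile and compared with the
    withheld raw values; one row of correlation/RAE/RMAE per method.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    t0, t1 = raw_table.time_range
    n_total = t1 - t0 + 1
    if holdout_months > n_total // 2:
        raise ValueError(
            f"holdout of {holdout_months} months exceeds half the record ({n_total})"
        )
    cut = t1 - holdout_months
    train_raw = raw_table.filter(months=range(t0, cut + 1))
    train_res, profile = deseasonalize(train_raw)

    # hold-out auxiliary residuals, deseasonalized with the training profile
    aux_vars = [v for v in raw_table.variables if v != target_variable]
    holdout_aux = raw_table.filter(
        variables=aux_vars, months=range(cut + 1, t1 + 1)
    )
    if len(holdout_aux):
        aux_df = holdout_aux.data.copy()
        aux_df["value"] = aux_df["value"] - profile.values_for(
            aux_df["station"], aux_df["variable"], aux_df["t"]
        )
        pred_data = ObservationTable(
            pd.concat([train_res.data, aux_df], ignore_index=True), role="residual"
        )
    else:
        pred_data = train_res

    truth = raw_table.filter(
        variables=[target_variable], months=range(cut + 1, t1 + 1)
    ).data
    targets = truth[["x", "y", "t"]].to_numpy(dtype=float)

    full_fit = fit_stlcm(train_res, grid=grid, min_pairs=min_pairs)
    models: dict[str, tuple[STLCM, ObservationTable]] = {}
    if "cokriging-stlcm" in methods:
        models["cokriging-stlcm"] = (full_fit.model, pred_data)
    if "cokriging-intrinsic" in methods:
        intrinsic = fit_stlcm(
            full_fit.covset, n_components=1, min_pairs=min_pairs
        )
        models["cokriging-intrinsic"] = (intrinsic.model, pred_data)
    if "kriging" in methods:
        uni_model = full_fit.model.select([target_variable])
        uni_data = pred_data.filter(variables=[target_variable])
        models["kriging"] = (uni_model, uni_data)

    rows = []
    for method in methods:  # caller's order; metrics are order-independent
        model, data = models[method]
        res = CokrigingEngine(model, data, config).predict(targets, target_variable)
        predicted = res.values + profile.values_for(
            truth["station"], truth["variable"], truth["t"]
        )
        observed = truth["value"].to_numpy(dtype=float)
        ok = np.isfinite(predicted)
        rows.append(
            {
                "method": method,
                "correlation": float(np.corrcoef(observed[ok], predicted[ok])[0, 1]),
                "rae": rae(observed[ok], predicted[ok]),
                "rmae": rmae(observed[ok], predicted[ok]),
                "n": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
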