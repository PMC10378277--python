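# stcoreg

Multivariate spatio-temporal geostatistics for monthly environmental
monitoring data: estimation of direct and cross space–time covariances,
fitting of a **space–time linear coregionalization model (ST-LCM)** by joint
diagonalization, symmetry/separability diagnostics, ordinary space–time
**cokriging**, and **indicator-kriging** exceedance-probability maps.

## The problem

Environmental variables observed at monitoring stations over many months —
the motivating case is radon flux over the Veneto region together with mean
temperature, minimum humidity and evapotranspiration — are cross-correlated
in space and time. Predicting one variable (and mapping the probability that
it exceeds hazard thresholds) benefits from modelling all of them jointly.
The joint model used here assumes that, after removing each station's
monthly seasonal cycle, the p residual fields are second-order stationary
with matrix-valued covariance

```
C(h) = Σ_{l=1..L} B_l c_l(h),        h = (h_s, h_t),
```

where each *basic structure* `c_l` is a product–sum covariance

```
c_l(h_s, h_t) = k1_l Cs_l(h_s) Ct_l(h_t) + k2_l Cs_l(h_s) + k3_l Ct_l(h_t)
```

with exponential marginals `Cs(h) = exp(-3h/a)`, `Ct(u) = exp(-3u/b)`
(practical ranges `a` km, `b` months), and the `B_l` are symmetric positive
semi-definite *coregionalization matrices*. Each `c_l` represents one scale
of joint variability; product–sum structures with `k2 + k3 > 0` are fully
symmetric and uniformly negatively non-separable, the regime the
non-separability ratio `r(h) = C(h_s,h_t) C(0,0) / (C(h_s,0) C(0,h_t)) < 1`
diagnoses.

Fitting proceeds by (1) estimating the sample covariance matrices on a
space–time lag grid, (2) finding one orthogonal matrix Ψ that jointly
diagonalizes them (Jacobi rotations), (3) reading off p uncorrelated
component surfaces from the rotated diagonals, detecting their scales, and
fitting a product–sum model to each, (4) estimating the `B_l` and repairing
them to the PSD cone by zeroing negative eigenvalues. Predictions use
ordinary cokriging with local neighborhoods (target-variable weights sum to
one, auxiliary weights to zero); risk maps use ordinary kriging of
threshold indicators with order-relation correction across thresholds.

Because a model of this kind is only appropriate when the cross-covariances
are symmetric, a χ²-type symmetry test (cross-covariance contrasts with a
block-subsampling long-run variance) guards the pipeline, and a companion
log-contrast test probes separability.

## Worked example

Simulate a two-variable world from a known two-scale truth (scales 20 km/2
months and 120 km/12 months, one negative cross-dependence entry), fit the
ST-LCM and compare prediction methods on a four-month hold-out:

```python
import stcoreg as sc
from stcoreg.experiments import default_truth, recovery_grid

truth = default_truth()
coords = sc.make_station_layout(50, (250.0, 250.0), "uniform", seed=42)
spec = sc.SimulationSpec(model=truth, coords=coords, n_months=60,
                         mean={"rn_flux": 20.0, "tm": 12.0},
                         seasonal_amplitude={"rn_flux": 5.0, "tm": 8.0}, seed=0)
raw = sc.simulate_stlcm(spec)
residuals, profile = sc.deseasonalize(raw)

sym = sc.symmetry_test(residuals)
print(f"symmetry: TS={sym.statistic:.3f}, df={sym.df}, p={sym.pvalue:.3f}")
fit = sc.fit_stlcm(residuals, grid=recovery_grid(), min_pairs=10)
print(fit.summary())
report = sc.jackknife_holdout(raw, "rn_flux", 4, grid=recovery_grid(), min_pairs=10)
print(report.round(3).to_string(index=False))
```

prints

```
symmetry: TS=3.387, df=1, p=0.066
ST-LCM fit: p=2, L=2
  component 1: a=15.3 km, b=2.1 mo, sill=1.563, fit RAE=0.295
  component 2: a=148.6 km, b=9.6 mo, sill=0.9006, fit RAE=0.444
  joint diagonalization: 2 sweeps, median |off|/|diag| = 0.296
             method  correlation   rae  rmae   n
    cokriging-stlcm        0.906 0.069 0.058 200
cokriging-intrinsic        0.819 0.095 0.078 200
            kriging        0.866 0.081 0.067 200
```

The symmetry test does not reject (p = 0.066), so the ST-LCM assumption
stands; the two detected components recover the generating scales; and on
the held-out months full cokriging (correlation 0.906) beats both the
intrinsic one-component model (0.819) and univariate kriging (0.866). The
recovered coregionalization contributions `B_l · c_l(0,0)` land close to the
generating matrices `[[1.5, 0.87], [0.87, 0.5]]` and
`[[0.25, −0.43], [−0.43, 0.75]]`.

The same analysis runs from a shell via the `stcoreg` CLI (subcommands
`simulate`, `fit`, `predict`, `risk`, `validate` driven by one YAML config;
see `stcoreg --help`). The published four-variable Veneto model is available
as `stcoreg.veneto_fitted_model()` — its radon-flux sill evaluates to 56.20
(kBq m⁻² s⁻¹)².

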