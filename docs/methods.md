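# Methods

This note records the statistical models implemented in `stcoreg`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Model

The data model is a p-variate space–time random field observed monthly at
fixed stations with projected km coordinates. Each variable decomposes as

```
Z_v(s, t) = m_v + season_v(s, month(t)) + Y_v(s, t) + ε_v(s, t),
```

a constant mean, a station-specific 12-month seasonal cycle, a zero-mean
stationary residual field, and optional white measurement noise. Only the
seasonal cycle is removed before covariance modelling (monthly means per
station and variable; no trend removal). Deseasonalize/reseasonalize are
exact inverses on the observed support; at unsampled grid nodes the seasonal
value is interpolated from station profiles by inverse-distance weighting
with power 2 (exact at stations) — the choice of grid-node rule is a design
decision, made because any pointwise seasonal surface must extend the
station profiles somehow and IDW is the simplest exact-interpolating option.

The residual covariance is the space–time linear coregionalization model
(ST-LCM) `C(h) = Σ_l B_l c_l(h)` with product–sum basic structures

```
c_l(hs, ht) = k1 Cs(hs) Ct(ht) + k2 Cs(hs) + k3 Ct(ht),
Cs(h) = exp(-3h/a),   Ct(u) = exp(-3|u|/b).
```

Parameters per component: `k1 > 0, k2 ≥ 0, k3 ≥ 0` (dimensionless; sill =
k1+k2+k3) and practical ranges `a` (km), `b` (months). The `exp(-3h/a)`
convention makes the correlation ≈ 0.05 at the practical range; "practical
range" alone does not pin the scaling, so the 3/a convention — the standard
geostatistical one — is recorded here as an assumption. Spatial lags are
isotropic Euclidean distances in km; anisotropy is not modelled. The basic
structures are kept in the (non-unit) sill scale delivered by
diagonalization; the coregionalization matrices `B_l` carry the physical
units. Serialization to YAML/JSON round-trips to better than 12 significant
digits.

## Empirical covariances

The estimator at lag (rs, rt) averages centred products
`[z_i(s+hs, t+ht) − m_i][z_j(s, t) − m_j]` over all ordered pairs with
`| ||hs|| − rs | < Tol(rs)` and (for monthly data) `ht = rt` exactly; means
are global per variable. The zero lag uses self-pairs only (Tol = 0), so
`C_ii(0,0)` is the plug-in variance. The estimator is directional in `ht`;
the two orientations are symmetrized only after the symmetry test has been
accepted, mirroring the order of operations of the analysis. The default
grid mimics the case-study geometry — 8 spatial lags spanning roughly half
the domain diameter and 15 monthly lags, tolerances equal to half the
spacing — and lags whose minimum pair count across variable pairs falls
below `min_pairs` (default 30) are flagged and excluded from fitting.
Missing values (heterotopic sampling) are handled by using available pairs.

## Joint diagonalization and component fitting

One orthogonal Ψ minimizes the summed squared off-diagonals of
`Ψ Ĉ_k Ψᵀ` over all retained lags via Jacobi sweeps; each Givens angle is
the exact plane minimizer (dominant eigenvector of the 2×2 accumulation of
`[m_ii − m_jj, 2 m_ij]`). Iteration stops when the largest rotation sine in
a sweep is below 1e−12 or after 100 sweeps; the objective is non-increasing
by construction and the terminal Ψ is orthogonal to 1e−10. The rotated
diagonals across lags form p component surfaces. Components are ordered by
ascending detected spatial scale (ties by temporal scale) — the data carry
no intrinsic component order, so this is a convention.

A component's scale is the smallest grid lag at which its marginal surface
has decayed to 5% of its sill (censored at the maximum lag when never
reached). Retention keeps components whose sill exceeds 1% of the largest
and whose scales are distinct beyond one grid step; forcing one component
(the intrinsic contender) keeps the largest-scale one.

Product–sum parameters are fitted by bounded weighted least squares
(weights = pair counts; `scipy.optimize.least_squares`, trf) with a
deterministic multistart: range starts at {0.6, 1, 1.6}× the detected
scales, sill split over (k1, k2, k3) in five fixed proportions. On
noiseless surfaces the fit reproduces generating parameters to well below
1%.

Coregionalization matrices: the classical sequential rule

```
b_ij^l = [Ĉ_ij(λ_{l−1}) − Ĉ_ij(λ_l)] / c_l(0,0),   λ_0 = (0,0),
```

with λ_l the detected scale lag of component l, is implemented
(`method="sequential"`) but is reliable only for widely separated scales: a
slower component that has already lost part of its sill at a faster
component's scale lag leaks into the wrong matrix (with two separable
exponential components at 20 km/2 mo and 120 km/12 mo, the slow component
has lost 63% of its sill at the fast component's scale lag). The pipeline
default therefore regresses each empirical surface on the fitted basic
structures across all retained lags (weighted by pair counts,
`method="least-squares"`), which stays consistent for overlapping scales.
Estimated matrices are projected to the PSD cone by zeroing negative
eigenvalues (idempotent; already-PSD inputs are returned unchanged).

## Diagnostics

*Symmetry.* For chosen lags and variable pairs the contrast
`Ĉ_ij(h) − Ĉ_ji(h)` is asymptotically Gaussian; the quadratic form
`TS = n (AĜ)ᵀ (A V̂ Aᵀ)^{-1} (AĜ)` is referred to χ² with rank(A) degrees
of freedom (numerical rank at 1e−8). The long-run covariance V̂ comes from
overlapping temporal block subsampling with block length ⌊√T⌋ (blocks use
global means); the block length is a default, not an optimized constant.
The default lag set is the co-located one-month lag, where monthly
cross-correlation is typically strongest. Calibration at the study size of
20 stations × 100 months: empirical size 4–6% at nominal 5% over 200
replicates, power ≈ 1 against a one-month lead–lag.

*Separability.* The contrast
`log C(hs,ht) + log C(0,0) − log C(hs,0) − log C(0,ht)` vanishes under full
separability; the same subsampling framework applies with the delta-method
gradient of the log. The statistic requires strictly positive covariances
at all needed lags and raises an explicit error otherwise — in practice the
tested lags must sit well inside the correlated range. This contrast-based
construction replaces test statistics from the literature whose formulas
were not available; it shares their asymptotic χ² logic.

*Non-separability ratios.* `r = C(hs,ht) C(0,0) / (C(hs,0) C(0,ht))`;
separable models give r ≡ 1, admissible product–sum models with k2+k3 > 0
give r < 1 at all strictly positive lags (approaching 1 from below near the
origin, where float evaluation plateaus at 1 to machine precision).

## Prediction

Ordinary cokriging solves, per target, the KKT system built from the fitted
ST-LCM over a local neighborhood: up to 16 data per variable within search
radii defaulting to the largest fitted spatial/temporal scales; candidates
are ranked by the radius-scaled space–time distance. Target-variable
weights sum to 1, auxiliary weights to 0 (residuals < 1e−9); predictions
are exact at data points when no nugget is configured (default nugget 0).
Singular systems trigger up to three drop-the-farthest-datum retries before
flagging the target. Indicator kriging applies the same machinery to
`1{value > z}` data with a univariately fitted indicator model, clamps to
[0, 1], flags all-0/all-1 neighborhoods as degenerate, and corrects order
relations across ascending thresholds by averaging the downward and upward
monotone rearrangements. Final maps add the (IDW-interpolated) seasonal
surface back to cokriged residuals.

*Validation.* RAE = sqrt(Σe²/Σz²) and RMAE = Σ|e|/Σ|z|; covariance-fit
metrics are computed per unordered variable pair over the first 5 spatial
and 8 temporal lags by default (the window where the sample covariance is
best estimated). Leave-one-out removes only the target variable's datum
(co-located auxiliaries stay — the alternative, removing all co-located
data, is stricter but was not the variant implemented). The jackknife
hold-out withholds the last months of the *primary* variable only;
auxiliary observations in the hold-out window stay available to the
predictor, since in practice meteorological covariates are observed when
the primary is forecast. Correlations are computed on the reseasonalized
scale.

## Synthetic-data generator

The generator is first-class: it produces exactly the structure the
analysis assumes. Components are normalized to unit sill inside the
generator (B_l carries the scale), so the residual covariance is
`Σ_l B_l c_l(h)/c_l(0,0)`. Simulation is exact by factorizing the
product–sum covariance into three independent Gaussian parts — a separable
space–time field via the Kronecker identity
`chol(Cs ⊗ Ct) = chol(Cs) ⊗ chol(Ct)`, a time-constant spatial field, and a
space-constant temporal field — so only S×S and T×T marginals are ever
decomposed (jitter 1e−10 on the diagonal). A cap of 5000 space–time points
per field keeps runs desk-scale. Seasonal cycles are cosines peaking in
July with per-station amplitudes varying ±30% around the nominal value,
reproducibly from the seed.

Default study conditions (chosen once): domain 250 × 250 km, 50 stations
placed uniformly (a fixed network drawn from a layout seed independent of
the field seed), 60 months, no measurement noise, lag grid 15–120 km in
15 km steps and 1–15 months; `min_pairs` is relaxed to 10 in the recovery
studies because this station density yields only ~25–30 pairs in the first
spatial bin. The default truth has two separable components at (20 km,
2 mo) and (120 km, 12 mo) with rank-one coregionalization matrices on
orthogonal directions (so the truth is exactly jointly diagonalizable) and
a negative cross-dependence entry; the strong-cross variant pushes the
origin cross-correlation to ≈ 0.88, near the admissibility bound.

What the generator does *not* emulate: non-Gaussian margins, space–time
trends beyond seasonality, measurement gaps with structure, anisotropy, and
covariance misspecification. Passing recovery tests therefore demonstrates
correctness of the estimators under their own assumptions, not robustness
to their violation on real data.

## Numerical choices and edge cases

- PSD checks: eigenvalue tolerance 1e−10 relative to the spectral radius;
  symmetry tolerance 1e−8 relative.
- Kriging systems are accepted only if the solve residual is below 1e−6
  relative; otherwise the singular-system fallback engages.
- Degenerate inputs raise explicit errors: all-equal component surfaces,
  non-positive component sills, empty calendar-month cells, non-positive
  covariances in log contrasts, holdouts longer than half the record.
- Detected scales are reported at grid resolution; summaries over
  replicates use medians.

## Known limitations

- The sequential coregionalization rule is exposed for completeness but is
  biased for overlapping scales; the least-squares route is the default.
- The first-crossing scale detector is noise-sensitive for slow components
  whose decay lag approaches the record length: at 50 stations × 60 months
  the median detected temporal scale of a 12-month component sits 0.5–2
  months early, because the empirical covariance at long temporal lags is
  slightly deflated when only ~5 effective temporal replicates exist.
- Indicator covariances for extreme thresholds are weakly correlated and
  can fit very short ranges; the risk-map driver therefore uses an explicit
  wide search neighborhood instead of model-derived radii.
- Local-neighborhood cokriging is not a global solve; predictions can be
  discontinuous where the neighborhood membership changes.
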