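# Methods

This note documents the signal models, parameter conventions, the realism
and limits of the synthetic generators, and the numerical design choices
of `rnoecest`. All claims about accuracy here are computed by the test
suite or by `scripts/acceptance.py`; nothing below is an empirical claim
about in-vivo tissue.

## Signal models

### Z-spectrum

The saturated signal normalized to a far-offset reference is modeled as
a sum of Lorentzian dips subtracted from unity:

```
Z(Δω) = 1 − Σ_i A_i · (Γ_i/2)² / ((Γ_i/2)² + (Δω − δ_i)²)
```

with one pool per dip. Pool parameters: center `δ` (ppm, water = 0),
amplitude `A ∈ [0, 1]` (dip depth), full width at half maximum `Γ > 0`
(ppm). Recognized labels: `water`, `mt` (semisolid magnetization
transfer), `amide` (+3.5 ppm), `amine` (+2 ppm), `rnoe35` (−3.5 ppm),
`rnoe16` (−1.6 ppm). The total dip amplitude must not exceed 1 (the
z-spectrum cannot go negative at any single pool's center under this
parameterization); specs violating this raise `InvalidSpecError`.

Defaults (`DEFAULT_POOLS`, placeholder values for fixtures, not
measurements): water 0.80/1.4 ppm at 0; MT 0.08/25 ppm at −2; amide
0.03/1.0 at +3.5; amine 0.02/1.5 at +2; rNOE 0.04/1.5 at −3.5; rNOE
0.015/0.6 at −1.6.

### T1 relaxometry

Saturation recovery (in-vivo protocol):

```
I(t) = I0 · (1 − exp(−t / T1))
```

This is the two-parameter form (no separate offset/efficiency term): the
variable-TR acquisition it models starts from saturated magnetization, so
the zero-crossing at t = 0 is structural. A third nuisance parameter
would be unidentifiable on the 8-point TR schedule and was deliberately
omitted.

Bi-exponential inversion recovery (homogenate protocol), on data
normalized to fully recovered signal:

```
I(t) = 1 − 2·(x_a·exp(−t/T1_a) + (1 − x_a)·exp(−t/T1_b))
```

with the amplitude-weighted average `T1_avg = x_a·T1_a + (1−x_a)·T1_b`.
Normalization divides by the mean of the two longest-delay points.
Components are reported with `T1_a ≤ T1_b`. When the two components are
numerically indistinguishable, the fit degrades gracefully to the
mono-exponential solution (`x_a = 1`, `T1_a = T1_b`) and sets a
`degenerate` flag rather than reporting an arbitrary split.

### B0 mapping and correction

WASSR sweeps (−1…1 ppm, 0.1-ppm steps) are fit with a single Lorentzian
dip; the fitted center is the B0 shift in ppm. A minimum at the sweep
edge raises `UnreliableFitError` (the center is then not bracketed).
Correction resamples the measured spectrum at `ω + b0` with a cubic
spline; the convention is `Z_meas(ω) = Z_true(ω − b0)`, so
`corrected(ω) = measured(ω + b0)`. Points that would fall outside the
acquired grid are held at the edge value (flat extrapolation) and an
`ExtrapolationWarning` is issued; |b0| > 1 ppm also warns.

### Two-pool background and AREX

The water + MT background is fit only where the CEST bands do not
contribute: |Δω| ≤ 0.8 ppm and |Δω| ≥ 6 ppm. The water center is fixed
at 0 (spectra are B0-corrected first); the MT center is free in
[−3, 0] ppm. The grid must include far-offset tails, otherwise the MT
width is unconstrained and the fit is refused (`InvalidInputError`).

The apparent-exchange-dependent relaxation residual is

```
AREX_resid(Δω) = (1/S_meas(Δω) − 1/S_fit(Δω)) · 1/(T1·(1 + f_m)) · 100
```

in % s⁻¹, with `f_m` the fitted MT amplitude. Nonpositive measured
signals yield NaN with the voxel flagged in `invalid_mask`, never an
exception mid-map.

### Gaussian deconvolution

In vivo, a single Gaussian `A·exp(−(Δω−μ)²/2σ²)` is fit to the AREX
spectrum over −6…−1 ppm with `μ ∈ [−3.9, −3.1]`, `σ ∈ [0.2, 1.5]`. Its
analytic area is `AUC = A·σ·√(2π)`. The rNOE(−1.6) signal is then the
integral of the residue (AREX minus fitted Gaussian) over
−1.9…−1.3 ppm, and its amplitude is the residue maximum in that band.
The residue integral defaults to the trapezoid rule with interpolated
band endpoints, which is invariant to grid refinement; a
`sum-times-spacing` compatibility mode reproduces the simpler Riemann
estimate and is exposed for comparison, not recommended.

For homogenates, two Gaussians are fit jointly: centers bounded in
[−3.9, −3.1] and [−1.9, −1.3] on the upfield side, [3.2, 3.8] and
[1.7, 2.3] on the downfield side. Fitted centers pinned at a bound
raise `BoundaryFitWarning`; centers closer than 0.5 ppm raise
`IdentifiabilityWarning`.

### NMR quantification

Band integrals use the trapezoid rule, optionally after subtracting a
linear baseline through the band endpoints. Default bands (ppm):
cholesterol C18 methyl 0.65–0.71, TMS −0.03…0.03, phosphocholine
N-methyl 3.28–3.38, bulk lipid methylene 1.45–1.65. The methylene band
was chosen as a deliberately generic lipid reference — wide enough to be
robust to small shift calibration errors, narrow enough to exclude the
water-adjacent region.

Concentration against the internal standard:

```
c_chol = (AUC_chol / AUC_TMS) · c_TMS · (12/3)
```

The 12/3 factor corrects for proton counts (TMS has 12 equivalent
protons, the cholesterol C18 singlet 3) and is applied by default; it
can be disabled to reproduce a raw-ratio convention. The standard's
molarity from a volume fraction is
`c = v · ρ / M` with ρ = 0.648 g/mL and M = 88.22 g/mol for TMS;
0.05 % v/v gives 3.67 mM.

### Statistics

`compare_groups` defaults to Welch's t-test (unequal variances are the
safe default for small unequal groups); Student's t and Mann-Whitney U
are available by name. Stars: `*` p < 0.05, `**` p < 0.001. Regression
is ordinary least squares via `scipy.stats.linregress`, cross-checked in
the tests against the normal equations. `regression_table` regresses the
per-group mean CEST metric on the per-group mean concentration by
default (`on_means=True`), matching the summary-table convention in
which each tissue condition contributes one point; per-sample regression
is available with `on_means=False`.

## Acquisition schedules (constants)

- In-vivo offsets: −10, −8, −6, −5, −4…4 in 0.1-ppm steps, 5, 6, 8,
  10 ppm (89 offsets) plus a 333-ppm reference.
- Homogenate offsets: dense 0.1-ppm sampling over the rNOE bands,
  0.2-ppm elsewhere in the labile range, sparse far offsets (63 offsets)
  plus a 250-ppm reference.
- WASSR: −1…1 ppm, 0.1-ppm steps (21 offsets).
- Saturation-recovery TRs: 0.05, 0.2, 0.5, 0.8, 1, 2, 4, 6 s.
- Inversion delays: 0.01, 0.05, 0.1, 0.25, 0.5, 1, 2, 4, 6, 10 s.

## Generator realism and limits

The simulators are built to exercise the analysis, not to replace spin
physics:

- Z-spectra come from the same Lorentzian family the background fitter
  assumes. There is no Bloch-McConnell exchange integration, no
  super-Lorentzian MT lineshape, and no direct-saturation/exchange
  coupling. Consequences: fits to synthetic data can be exact to solver
  tolerance, which is precisely what makes round-trip oracles sharp, but
  accuracy numbers do not transfer to scanner data.
- Saturation-power dependence is emulated by scaling pool amplitudes
  through a user-supplied table (`scale_pools`), treating power as an
  acquisition setting rather than simulating saturation efficiency.
- Noise is i.i.d. Gaussian per offset/voxel. No Rician floor, motion,
  drift, or spatially correlated noise.
- The default phantom is an elliptical "tissue" region with a circular
  "tumor" (region codes 0 background / 1 normal / 2 tumor), uniform
  pools per region, optional smooth B0 field, and per-region T1. Partial
  volume exists only at region boundaries via the B0 field; there is no
  coil profile.
- NMR spectra are sums of Gaussian peaks on a uniform ppm axis; no
  J-coupling, lineshape phase errors, or baseline roll (a linear baseline
  can be added explicitly). Peaks whose mass is visibly truncated by the
  axis raise `TruncatedPeakWarning`.

All generators take one integer seed and are bit-reproducible;
`scripts/acceptance.py` derives all sub-seeds from its single `--seed`.

## Numerical choices

- All nonlinear fits use `scipy.optimize.least_squares` with explicit
  bounds and **analytic Jacobians** (WASSR, two-pool, Gaussian
  deconvolution); this is what makes 64×64 voxelwise maps run in tens of
  seconds on one CPU.
- Multi-start: the two-pool fit tries MT widths {25, 12, 60} ppm and
  stops early when the residual reaches the noise-floor criterion
  (RMS ≈ 5·10⁻³ per point); the bi-exponential fit scans a 3×3 grid of
  `x_a` and T1 factors and keeps the best residual.
- Degenerate data are contract-governed: fewer than 3 points, all-zero
  signals, edge-pinned WASSR minima, zero-variance group comparisons and
  constant-x regressions all raise typed errors or return defined values
  (p = 1, refusal) rather than garbage.
- Voxelwise maps apply a 3×3 edge-replicated median filter. The default
  `filter_stage="maps"` smooths the final parameter maps, which preserves
  the nonlinearity of the per-voxel chain; `"raw"` instead smooths every
  offset image before fitting (the alternative reading of a
  filter-then-fit pipeline, trading noise for spatial blur);
  `"none"` disables smoothing so each map value equals the scalar
  pipeline applied to that voxel exactly — used by the equivalence tests.
  Voxel failures are flagged in `failure_mask` and set NaN, never fatal.
- Band integration is trapezoidal with interpolated endpoints so the
  value is stable under grid refinement (verified against fine-grid
  quadrature in the tests).

## Validation summary

The test suite validates against independent oracles: brute-force
Lorentzian sums, hand-evaluated AREX arithmetic (e.g. S_meas = 0.4,
S_fit = 0.5, T1 = 2 s, f_m = 0.25 → 20 % s⁻¹), analytic Gaussian areas,
fine-grid quadrature, normal-equation OLS, a brute-force median filter,
Monte-Carlo bias and type-I-rate calibration, and five-seed phantom
sign tests for tumor hypointensity at −1.6 ppm. Run
`python -m pytest -q tests/` and `python scripts/acceptance.py --seed 1
--out results/acceptance.json` to regenerate every number.
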