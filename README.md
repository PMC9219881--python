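# rnoecest

Quantification of relayed nuclear Overhauser effect (rNOE) CEST signals
at −3.5 and −1.6 ppm, with companion ¹H-NMR cholesterol quantification
and group statistics.

The −1.6 ppm rNOE band of the water-saturation z-spectrum is thought to
report on choline phospholipids and membrane cholesterol; in glioma it
drops relative to normal-appearing brain. This package implements the
complete analysis chain needed to measure that effect, plus seeded
synthetic generators for every input, so the whole pipeline can be
exercised and validated without scanner data.

## What it does

- **`synth`** — seeded generators: multi-pool Lorentzian z-spectra,
  saturation/inversion recovery curves, WASSR sweeps, two-region imaging
  phantoms (NIfTI), and Gaussian-peak NMR spectra (CSV).
- **`relaxometry`** — T1 from saturation recovery
  `I(t) = I0·(1 − exp(−t/T1))` and from bi-exponential inversion
  recovery, with the amplitude-weighted average
  `T1_avg = x_a·T1_a + (1 − x_a)·T1_b`; per-voxel T1 maps.
- **`zspectrum`** — normalization to a far-offset reference, WASSR B0
  estimation and cubic-spline B0 correction, two-pool (water + semisolid
  MT) background fitting on a masked grid (|Δω| ≤ 0.8 ppm ∪ |Δω| ≥ 6 ppm),
  and the AREX residual metric

  ```
  AREX_resid(Δω) = (1/S_meas − 1/S_fit) · 1 / (T1·(1 + f_m)) · 100   [% s⁻¹]
  ```

  where `f_m` is the fitted MT pool fraction.
- **`rnoe`** — Gaussian deconvolution of the AREX spectrum: a single
  Gaussian at −3.5 ppm over the −6…−1 ppm window in vivo (the −1.6 ppm
  signal is the residue integral over −1.9…−1.3 ppm), or a joint
  two-Gaussian fit for homogenate spectra; analytic area
  `AUC = A·σ·√(2π)` for fitted components.
- **`imaging`** — per-voxel orchestration of the whole chain into AREX
  parameter maps (AUC and amplitude at −3.5/−1.6 ppm, MT fraction, B0)
  with 3×3 median filtering, plus ROI-averaged z-spectra.
- **`nmr_quant`** — band integration of ¹H spectra and cholesterol
  concentration against a TMS internal standard (0.05 % v/v TMS in
  chloroform = 3.67 mM), with the 12/3 proton-count correction.
- **`stats_report`** — Welch/Student/Mann-Whitney group comparisons with
  significance stars (* p < 0.05, ** p < 0.001) and ordinary
  least-squares regression of CEST metrics on concentrations.

## Worked example

```python
import numpy as np
import rnoecest as rc

# 1. Simulate a six-pool in-vivo z-spectrum (noiseless for clarity)
offsets = rc.invivo_offsets()
z = rc.simulate_zspectrum(rc.DEFAULT_POOLS, offsets, noise_sd=0.0, seed=0)

# 2. Two-pool (water + MT) background fit on the masked grid
background = rc.fit_two_pool(z)
print(f"water amplitude  {background.water_amp:.3f}")
print(f"MT pool fraction {background.mt_amp:.3f}")

# 3. AREX residual spectrum (T1 = 1.8 s)
arex = rc.arex_resid(z, background, t1=1.8)

# 4. Gaussian deconvolution of the upfield window
dec = rc.deconvolve_invivo(arex)
print(f"rNOE(-3.5) AUC   {dec.auc_by_label['rnoe35']:.3f} % s^-1 ppm")
print(f"rNOE(-1.6) AUC   {dec.auc_by_label['rnoe16']:.3f} % s^-1 ppm")
print(f"rNOE(-1.6) amp   {dec.amplitude_by_label['rnoe16']:.3f} % s^-1")

# 5. NMR cholesterol quantification against the TMS internal standard
axis = np.arange(-0.5, 4.0, 0.0005)
spectrum = rc.simulate_nmr_spectrum(
    [rc.NMRPeakSpec(0.68, 3.0, 0.01), rc.NMRPeakSpec(0.0, 12.0, 0.01)],
    axis, noise_sd=0.0, seed=0)
quant = rc.cholesterol_concentration(spectrum, rc.tms_molarity())
print(f"cholesterol      {quant.concentration:.2f} mM")
```

Output:

```
water amplitude  0.799
MT pool fraction 0.086
rNOE(-3.5) AUC   5.451 % s^-1 ppm
rNOE(-1.6) AUC   0.358 % s^-1 ppm
rNOE(-1.6) amp   0.875 % s^-1
cholesterol      3.67 mM
```

(The fitted MT fraction, 0.086, slightly exceeds the generating value of
0.08 because the two-pool background absorbs part of the amide/amine/rNOE
dips; this is inherent to the background-envelope definition, and the
AREX residual quantifies exactly what remains.)

A command-line interface mirrors the library:
`rnoecest wassr|zfit|arex|deconv|maps|nmr-quant|stats --help`.

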