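"""Seeded generators for every input the analysis pipeline consumes.

The saturation signal model is a sum of Lorentzian dips subtracted from
unity,

    Z(dw) = 1 - sum_i A_i * (G_i/2)^2 / ((G_i/2)^2 + (dw - d_i)^2),

with one Lorentzian per saturable pool (water, semisolid MT background,
amide at 3.5 ppm, amine at 2 ppm, and the relayed-NOE bands at -3.5 and
-1.6 ppm).  This is deliberately the same model family the background
fitter uses; full Bloch-McConnell integration is out of scope.

Saturation-power dependence (0.3/0.6/0.9 uT) is emulated by scaling pool
amplitudes through a user-supplied table rather than by spin physics: the
analysis treats the saturation amplitude purely as an acquisition setting.

Every generator takes one explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InvalidSpecError, TruncatedPeakWarning

# ---------------------------------------------------------------------------
# Acquisition schedules (animal protocol at 7 T, homogenate protocol at 9.4 T)
# ---------------------------------------------------------------------------

#: Saturation recovery TR schedule for T1 mapping, seconds.
TR_LIST_S = np.array([0.05, 0.2, 0.5, 0.8, 1.0, 2.0, 4.0, 6.0])

#: Inversion-recovery delay schedule for homogenate T1, seconds.
INVERSION_DELAYS_S = np.array([0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0])

#: Reference (S0) saturation offsets, ppm.
INVIVO_REFERENCE_PPM = 333.0
HOMOGENATE_REFERENCE_PPM = 250.0

#: WASSR sweep: -1 ... 1 ppm in 0.1-ppm steps.
WASSR_OFFSETS_PPM = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)


def invivo_offsets() -> np.ndarray:
    """In-vivo CEST offset grid (without the 333-ppm reference), ascending.

    -10, -8, -6, -5, -4 ... 4 in 0.1-ppm steps, 5, 6, 8, 10 ppm.
    """
    fine = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.1), 10)
    coarse_neg = np.array([-10.0, -8.0, -6.0, -5.0])
    coarse_pos = np.array([5.0, 6.0, 8.0, 10.0])
    return np.concatenate([coarse_neg, fine, coarse_pos])


def homogenate_offsets() -> np.ndarray:
    """Homogenate CEST offset grid (without the 250-ppm reference), ascending.

    Dense 0.1-ppm sampling over the rNOE bands (-4..-3, -1.9..-1), 0.2-ppm
    sampling elsewhere in the labile range, sparse far offsets.
    """
    parts = [
        np.array([-20.0, -15.0, -10.0, -6.0, -5.0, -4.5]),
        np.round(np.arange(-4.0, -3.0 + 1e-9, 0.1), 10),
        np.round(np.arange(-2.8, -2.0 + 1e-9, 0.2), 10),
        np.round(np.arange(-1.9, -1.0 + 1e-9, 0.1), 10),
        np.round(np.arange(-0.8, 4.0 + 1e-9, 0.2), 10),
        np.array([4.5, 5.0, 6.0, 10.0, 15.0, 20.0]),
    ]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Pool and phantom specs
# ---------------------------------------------------------------------------

POOL_LABELS = ("water", "mt", "amide", "amine", "rnoe35", "rnoe16")


@dataclass(frozen=True)
class PoolSpec:
    """One saturable pool: a Lorentzian dip in the z-spectrum.

    Parameters
    ----------
    center : float
        Chemical-shift offset in ppm, water = 0.
    amplitude : float
        Peak saturation fraction in [0, 1] (depth of the dip at its center).
    fwhm : float
        Full width at half maximum, ppm (> 0).
    label : str
        One of ``water, mt, amide, amine, rnoe35, rnoe16``.
    """

    center: float
    amplitude: float
    fwhm: float
    label: str = "water"

    def __post_init__(self):
        if not 0.0 <= self.amplitude <= 1.0:
            raise InvalidSpecError(f"pool amplitude {self.amplitude} outside [0, 1]")
        if self.fwhm <= 0:
            raise InvalidSpecError(f"pool fwhm must be > 0, got {self.fwhm}")
        if self.label not in POOL_LABELS:
            raise InvalidSpecError(f"unknown pool label {self.label!r}")


#: Default pool sets used as test-fixture placeholders; in-vivo linewidths
#: are not established quantities and these are not measurement claims.
DEFAULT_POOLS = (
    PoolSpec(0.0, 0.80, 1.4, "water"),
    PoolSpec(-2.0, 0.08, 25.0, "mt"),
    PoolSpec(3.5, 0.03, 1.0, "amide"),
    PoolSpec(2.0, 0.02, 1.5, "amine"),
    PoolSpec(-3.5, 0.04, 1.5, "rnoe35"),
    PoolSpec(-1.6, 0.015, 0.6, "rnoe16"),
)


def scale_pools(pools, table: dict) -> tuple:
    """Scale pool amplitudes by label using ``table`` (label -> factor).

    Emulates changing the saturation amplitude (e.g. 0.3/0.6/0.9 uT) without
    any spin physics.  Labels absent from the table keep their amplitude.
    """
    return tuple(
        PoolSpec(p.center, p.amplitude * table.get(p.label, 1.0), p.fwhm, p.label)
        for p in pools
    )


def lorentzian(offsets, amplitude, center, fwhm):
    """L(dw) = A * (G/2)^2 / ((G/2)^2 + (dw - center)^2)."""
    hw2 = (fwhm / 2.0) ** 2
    return amplitude * hw2 / (hw2 + (np.asarray(offsets, float) - center) ** 2)


def _check_pool_sum(pools):
    total = sum(p.amplitude for p in pools)
    if total > 1.0 + 1e-12:
        raise InvalidSpecError(f"pool amplitudes sum to {total} > 1")


def simulate_zspectrum(pools, offsets, noise_sd: float = 0.0, seed: int = 0,
                       reference_offset: float = INVIVO_REFERENCE_PPM):
    """Simulate a normalized z-spectrum from a list of pools.

    Returns a :class:`rnoecest.zspectrum.ZSpectrum`.  Noise is additive
    Gaussian on the normalized intensity.
    """
    from .zspectrum import ZSpectrum  # local import: avoid cycle

    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise InvalidSpecError("offsets must be non-empty")
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    _check_pool_sum(pools)
    signal = np.ones_like(offsets)
    for p in pools:
        signal -= lorentzian(offsets, p.amplitude, p.center, p.fwhm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return ZSpectrum(offsets=offsets, signal=signal,
                     reference_offset=reference_offset)


# ---------------------------------------------------------------------------
# Relaxation recovery curves
# ---------------------------------------------------------------------------


def saturation_recovery_model(t, i0, t1):
    """I(t) = I0 * (1 - exp(-t/T1))."""
    t = np.asarray(t, float)
    return i0 * (1.0 - np.exp(-t / t1))


def inversion_recovery_biexp_model(t, x_a, t1_a, t1_b):
    """Normalized bi-exponential inversion recovery:

    I(t) = 1 - 2 * (x_a exp(-t/T1_a) + (1 - x_a) exp(-t/T1_b)).
    """
    t = np.asarray(t, float)
    return 1.0 - 2.0 * (x_a * np.exp(-t / t1_a) + (1.0 - x_a) * np.exp(-t / t1_b))


def simulate_recovery_curve(kind: str, params: dict, times, noise_sd: float = 0.0,
                            seed: int = 0):
    """Simulate a T1 recovery curve.

    ``kind='saturation'``: params I0, T1.
    ``kind='inversion'``: params x_a, T1_a, T1_b (normalized, I(inf)=1).
    """
    from .relaxometry import RecoveryCurve

    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise InvalidSpecError("recovery times must be > 0")
    if kind == "saturation":
        values = saturation_recovery_model(times, params["I0"], params["T1"])
    elif kind == "inversion":
        x_a = params["x_a"]
        if not 0.0 <= x_a <= 1.0:
            raise InvalidSpecError(f"x_a {x_a} outside [0, 1]")
        values = inversion_recovery_biexp_model(
            times, x_a, params["T1_a"], params.get("T1_b", params["T1_a"]))
    else:
        raise InvalidSpecError(f"unknown recovery kind {kind!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return RecoveryCurve(times=times, intensities=values, kind=kind)


# ---------------------------------------------------------------------------
# Imaging phantom
# ---------------------------------------------------------------------------

REGION_BACKGROUND, REGION_NORMAL, REGION_TUMOR = 0, 1, 2


@dataclass
class PhantomSpec:
    """Two-region (normal/tumor) imaging phantom with a B0 offset field.

    ``region_masks`` is an integer label map (0 background, 1 normal,
    2 tumor) partitioning the grid.  ``pools_by_region`` and
    ``t1_by_region`` map region label -> pool list / T1 (s).  ``b0_field``
    is the per-voxel frequency offset in ppm; ``noise_sd`` is the additive
    noise standard deviation as a fraction of S0.
    """

    shape: tuple
    region_masks: np.ndarray
    pools_by_region: dict
    t1_by_region: dict
    b0_field: np.ndarray = None
    noise_sd: float = 0.0
    seed: int = 0
    s0: float = 1000.0
    wassr_amplitude: float = 0.8
    wassr_fwhm: float = 0.5

    def __post_init__(self):
        self.region_masks = np.asarray(self.region_masks)
        if self.region_masks.shape != tuple(self.shape):
            raise InvalidSpecError("region_masks shape does not match spec shape")
        if self.b0_field is None:
            self.b0_field = np.zeros(self.shape)
        self.b0_field = np.asarray(self.b0_field, float)
        if self.b0_field.shape != tuple(self.shape):
            raise InvalidSpecError("b0_field shape does not match spec shape")
        if not np.all(np.isfinite(self.b0_field)):
            raise InvalidSpecError("b0_field must be finite")
        for label, t1 in self.t1_by_region.items():
            if t1 <= 0:
                raise InvalidSpecError(f"t1 for region {label} must be > 0")
        for label, pools in self.pools_by_region.items():
            _check_pool_sum(pools)


def default_phantom_spec(shape=(64, 64), tumor_rnoe16_amplitude=0.005,
                         normal_rnoe16_amplitude=0.015, noise_sd=0.002,
                         b0_field=None, seed=0) -> PhantomSpec:
    """Canonical two-region phantom: a centered disc of tumor inside normal
    tissue, differing only in rNOE(-1.6) pool amplitude and T1."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    masks = np.full(shape, REGION_BACKGROUND, dtype=int)
    tissue = ((rr - rows / 2) ** 2 / (0.42 * rows) ** 2
              + (cc - cols / 2) ** 2 / (0.42 * cols) ** 2) <= 1.0
    masks[tissue] = REGION_NORMAL
    tumor = ((rr - rows / 2) ** 2 + (cc - 0.68 * cols) ** 2) <= (0.16 * rows) ** 2
    masks[tumor & tissue] = REGION_TUMOR

    def pools(rnoe16_amp):
        return tuple(
            PoolSpec(p.center, rnoe16_amp if p.label == "rnoe16" else p.amplitude,
                     p.fwhm, p.label)
            for p in DEFAULT_POOLS
        )

    return PhantomSpec(
        shape=shape,
        region_masks=masks,
        pools_by_region={REGION_NORMAL: pools(normal_rnoe16_amplitude),
                         REGION_TUMOR: pools(tumor_rnoe16_amplitude)},
        t1_by_region={REGION_NORMAL: 1.8, REGION_TUMOR: 2.1},
        b0_field=b0_field,
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class PhantomResult:
    """Simulated acquisition plus the ground truth that generated it."""

    cest_stack: "object"      # imaging.OffsetImageStack
    wassr_stack: "object"     # imaging.OffsetImageStack
    t1_map: np.ndarray
    ground_truth: dict


def simulate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Simulate CEST + WASSR image stacks and a T1 map for a phantom.

    Each voxel's z-spectrum is the region's pool model with every pool
    center displaced by the voxel's B0 offset; intensities are scaled by S0
    and carry additive Gaussian noise of ``noise_sd * S0``.  The WASSR
    stack is a single narrow water dip at the same displaced center.
    """
    from .imaging import OffsetImageStack

    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    offsets = invivo_offsets()
    cest_offsets = np.concatenate([[INVIVO_REFERENCE_PPM], offsets])
    wassr_offsets = np.concatenate([[INVIVO_REFERENCE_PPM], WASSR_OFFSETS_PPM])

    cest = np.zeros((rows, cols, cest_offsets.size))
    wassr = np.zeros((rows, cols, wassr_offsets.size))
    t1_map = np.zeros(spec.shape)

    for label in np.unique(spec.region_masks):
        if label == REGION_BACKGROUND:
            continue
        mask = spec.region_masks == label
        pools = spec.pools_by_region[label]
        t1_map[mask] = spec.t1_by_region[label]
        b0 = spec.b0_field[mask]  # (n_vox,)
        # Z(dw) = 1 - sum L_i(dw - b0): pool centers shifted by +b0.
        dw = cest_offsets[None, :] - b0[:, None]
        z = np.ones_like(dw)
        for p in pools:
            z -= lorentzian(dw, p.amplitude, p.center, p.fwhm)
        cest[mask, :] = spec.s0 * z
        dww = wassr_offsets[None, :] - b0[:, None]
        wz = 1.0 - lorentzian(dww, spec.wassr_amplitude, 0.0, spec.wassr_fwhm)
        wassr[mask, :] = spec.s0 * wz

    if spec.noise_sd > 0:
        cest += rng.normal(0.0, spec.noise_sd * spec.s0, size=cest.shape)
        wassr += rng.normal(0.0, spec.noise_sd * spec.s0, size=wassr.shape)

    ground_truth = {
        "region_masks": spec.region_masks.copy(),
        "pools_by_region": {int(k): [vars(p) | {} for p in v]
                            for k, v in spec.pools_by_region.items()},
        "t1_by_region": {int(k): float(v) for k, v in spec.t1_by_region.items()},
        "b0_field": spec.b0_field.copy(),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "s0": spec.s0,
    }
    return PhantomResult(
        cest_stack=OffsetImageStack(volumes=cest, offsets=cest_offsets,
                                    reference_index=0),
        wassr_stack=OffsetImageStack(volumes=wassr, offsets=wassr_offsets,
                                     reference_index=0),
        t1_map=t1_map,
        ground_truth=ground_truth,
    )


def simulate_vtr_stack(t1_map: np.ndarray, i0: float = 1000.0,
                       tr_list=TR_LIST_S, noise_sd: float = 0.0, seed: int = 0):
    """Variable-TR saturation-recovery image stack from a true T1 map.

    Voxels with T1 <= 0 (background) produce zero signal.
    """
    rng = np.random.default_rng(seed)
    tr_list = np.asarray(tr_list, float)
    t1 = np.asarray(t1_map, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stack = np.where(t1[..., None] > 0,
                         i0 * (1.0 - np.exp(-tr_list / np.maximum(t1[..., None], 1e-12))),
                         0.0)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd * i0, size=stack.shape)
    return stack


# ---------------------------------------------------------------------------
# NMR spectra
# ---------------------------------------------------------------------------

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class NMRPeakSpec:
    """One NMR resonance with a specified integrated area."""

    center: float
    area: float
    fwhm: float
    lineshape: str = "gaussian"

    def __post_init__(self):
        if self.area < 0:
            raise InvalidSpecError("peak area must be >= 0")
        if self.fwhm <= 0:
            raise InvalidSpecError("peak fwhm must be > 0")
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise InvalidSpecError(f"unknown lineshape {self.lineshape!r}")


def _peak_profile(ppm, peak: NMRPeakSpec):
    x = ppm - peak.center
    if peak.lineshape == "gaussian":
        sigma = peak.fwhm / _GAUSS_FWHM
        return peak.area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * (x / sigma) ** 2)
    gamma = peak.fwhm / 2.0
    return peak.area * gamma / np.pi / (x ** 2 + gamma ** 2)


def simulate_nmr_spectrum(peaks, ppm_axis, noise_sd: float = 0.0, seed: int = 0):
    """Simulate a 1H-NMR trace as a sum of area-normalized peaks plus noise.

    Peaks whose centers lie outside the axis raise a
    :class:`TruncatedPeakWarning` and contribute only their in-range tail.
    """
    from .nmr_quant import NMRSpectrum

    ppm_axis = np.asarray(ppm_axis, float)
    d = np.diff(ppm_axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise InvalidSpecError("ppm_axis must be strictly monotone")
    lo, hi = min(ppm_axis[0], ppm_axis[-1]), max(ppm_axis[0], ppm_axis[-1])
    intensity = np.zeros_like(ppm_axis)
    for peak in peaks:
        if not lo <= peak.center <= hi:
            warnings.warn(f"peak at {peak.center} ppm outside axis "
                          f"[{lo}, {hi}]; truncated", TruncatedPeakWarning)
        intensity += _peak_profile(ppm_axis, peak)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return NMRSpectrum(ppm=ppm_axis, intensity=intensity)


# ---------------------------------------------------------------------------
# File emitters (CSV / NIfTI / JSON interchange)
# ---------------------------------------------------------------------------


def write_zspectrum_csv(z, path):
    pd.DataFrame({"offset_ppm": z.offsets, "intensity": z.signal}).to_csv(
        path, index=False)


def write_recovery_csv(curve, path):
    pd.DataFrame({"time_s": curve.times, "intensity": curve.intensities}).to_csv(
        path, index=False)


def write_nmr_csv(spectrum, path):
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(
        path, index=False)


def write_phantom(result: PhantomResult, outdir):
    """Write a simulated phantom to NIfTI stacks + JSON manifests/truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for name, stack in (("cest", result.cest_stack), ("wassr", result.wassr_stack)):
        nib.save(nib.Nifti1Image(stack.volumes.astype(np.float64), affine),
                 outdir / f"{name}.nii")
        manifest = {
            "offsets_ppm": [float(o) for o in stack.offsets],
            "reference_index": int(stack.reference_index),
            "orientation": "0-based row/column indices, volumes stacked on axis 2",
        }
        (outdir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=1))
    nib.save(nib.Nifti1Image(result.t1_map.astype(np.float64), affine),
             outdir / "t1_map.nii")
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in result.ground_truth.items()}
    (outdir / "ground_truth.json").write_text(json.dumps(truth))
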