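"""Z-spectrum signal chain: normalization, WASSR B0 correction, two-pool
Lorentzian background removal, and the AREX residual metric.

The background model is Z(dw) = 1 - L_water - L_MT with Lorentzians
L(dw) = A (G/2)^2 / ((G/2)^2 + (dw - d)^2); the water center is fixed at 0
after B0 correction and the MT center is fitted within [-3, 0] ppm.  The
fit uses only offsets with |dw| <= 0.8 ppm (pinning the water line) or
|dw| >= 6 ppm (pinning the MT tails), so every labile band (3.5, 2, -1.6,
-3.5 ppm) is excluded and survives in the residue.

AREX residual (in % s^-1, with normalized spectra so S0 = 1):

    AREX_resid(dw) = (1/S_meas(dw) - 1/S_fit(dw)) * 1/(T1 (1 + f_m)) * 100

where f_m is the MT Lorentzian amplitude (the MT pool size).  Dips below
the fitted background (S_meas < S_fit) give positive AREX.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .errors import (ExtrapolationWarning, FitFailureError, InvalidInputError,
                     UnreliableFitError)
from .synth import lorentzian

#: Two-pool fit mask: water core plus MT tails, labile bands excluded.
FIT_MASK_WATER_PPM = 0.8
FIT_MASK_TAIL_PPM = 6.0


@dataclass
class ZSpectrum:
    """Normalized saturation spectrum S(dw)/S0 on an offset grid (ppm,
    water = 0).  ``reference_offset`` records where S0 was acquired (far
    from water, |ref| >= 100 ppm); ``b0_shift`` is the applied B0
    correction (0 if uncorrected)."""

    offsets: np.ndarray
    signal: np.ndarray
    reference_offset: float = 333.0
    b0_shift: float = 0.0

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, float)
        self.signal = np.asarray(self.signal, float)
        if self.offsets.shape != self.signal.shape:
            raise InvalidInputError("offsets and signal differ in length")
        if not np.all(np.isfinite(self.offsets)):
            raise InvalidInputError("offsets must be finite")
        if abs(self.reference_offset) < 100:
            raise InvalidInputError(
                "reference offset must be far from water (|ref| >= 100 ppm)")
        if np.any(np.diff(self.offsets) <= 0):
            order = np.argsort(self.offsets)
            self.offsets = self.offsets[order]
            self.signal = self.signal[order]

    def to_csv(self, path):
        pd.DataFrame({"offset_ppm": self.offsets,
                      "intensity": self.signal}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reference_offset: float = 333.0):
        df = pd.read_csv(path)
        return cls(offsets=df["offset_ppm"].to_numpy(),
                   signal=df["intensity"].to_numpy(),
                   reference_offset=reference_offset)


@dataclass
class TwoPoolFit:
    """Water + MT Lorentzian background fit; ``mt_amp`` is f_m."""

    water_amp: float
    water_fwhm: float
    water_center: float
    mt_amp: float
    mt_fwhm: float
    mt_center: float
    fitted_curve: np.ndarray
    fit_mask: np.ndarray
    residual_norm: float = 0.0

    def evaluate(self, offsets) -> np.ndarray:
        offsets = np.asarray(offsets, float)
        return (1.0
                - lorentzian(offsets, self.water_amp, self.water_center,
                             self.water_fwhm)
                - lorentzian(offsets, self.mt_amp, self.mt_center, self.mt_fwhm))


@dataclass
class AREXSpectrum:
    """Per-offset AREX residual values in % s^-1, with the T1 (s) and MT
    pool size f_m used for the correction."""

    offsets: np.ndarray
    arex: np.ndarray
    t1: float
    f_m: float
    invalid_mask: np.ndarray = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, float)
        self.arex = np.asarray(self.arex, float)
        if self.invalid_mask is None:
            self.invalid_mask = ~np.isfinite(self.arex)


def normalize(raw, reference: float, offsets,
              reference_offset: float = 333.0) -> ZSpectrum:
    """Normalize raw per-offset intensities to the far-offset reference."""
    if reference <= 0:
        raise InvalidInputError(f"reference intensity must be > 0, got {reference}")
    raw = np.asarray(raw, float)
    return ZSpectrum(offsets=np.asarray(offsets, float), signal=raw / reference,
                     reference_offset=reference_offset)


def fit_wassr(wassr_spectrum: ZSpectrum) -> float:
    """B0 offset (ppm) from a WASSR sweep: the center of a Lorentzian
    fitted to the direct-saturation dip, at sub-grid resolution."""
    x, y = wassr_spectrum.offsets, wassr_spectrum.signal
    imin = int(np.argmin(y))
    if imin in (0, x.size - 1):
        raise UnreliableFitError(
            "WASSR minimum at the edge of the sampled range; "
            "the dip center is outside or at the boundary of the sweep")

    span = x[-1] - x[0]

    def resid(p):  # p = (amp, center, fwhm)
        return (1.0 - lorentzian(x, p[0], p[1], p[2])) - y

    def jac(p):
        a, d, g = p
        h = (g / 2.0) ** 2
        u = x - d
        denom = h + u ** 2
        j = np.empty((x.size, 3))
        j[:, 0] = -h / denom
        j[:, 1] = -a * h * 2.0 * u / denom ** 2
        j[:, 2] = -a * (u ** 2) / denom ** 2 * (g / 2.0)
        return j

    amp0 = max(1.0 - float(y[imin]), 1e-3)
    sol = least_squares(
        resid, x0=[amp0, float(x[imin]), 0.5], jac=jac,
        bounds=([1e-4, x[0], 0.02], [1.5, x[-1], 4 * span]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitFailureError("WASSR Lorentzian fit failed",
                              {"status": sol.status})
    return float(sol.x[1])


def apply_b0_correction(z: ZSpectrum, b0_offset: float) -> ZSpectrum:
    """Re-interpolate the spectrum onto the nominal grid shifted by the B0
    offset, so that the water line is re-centered at 0 ppm.

    The corrected value at nominal offset w is the measured signal at
    w + b0 (cubic interpolation; flat extrapolation at the edges with a
    warning).  |b0| > 1 ppm is flagged as suspect but still applied.
    """
    if abs(b0_offset) > 1.0:
        warnings.warn(f"B0 offset {b0_offset:+.3f} ppm exceeds 1 ppm; "
                      "correction applied but flagged", ExtrapolationWarning)
    if b0_offset == 0.0:
        return ZSpectrum(offsets=z.offsets.copy(), signal=z.signal.copy(),
                         reference_offset=z.reference_offset, b0_shift=0.0)
    spline = CubicSpline(z.offsets, z.signal, extrapolate=False)
    query = z.offsets + b0_offset
    corrected = spline(query)
    outside = ~np.isfinite(corrected)
    if np.any(outside):
        warnings.warn("B0 correction required support outside the sampled "
                      "range; edge values extended flat", ExtrapolationWarning)
        corrected[outside & (query < z.offsets[0])] = z.signal[0]
        corrected[outside & (query > z.offsets[-1])] = z.signal[-1]
    return ZSpectrum(offsets=z.offsets.copy(), signal=corrected,
                     reference_offset=z.reference_offset,
                     b0_shift=z.b0_shift + b0_offset)


def two_pool_fit_mask(offsets) -> np.ndarray:
    offsets = np.asarray(offsets, float)
    return (np.abs(offsets) <= FIT_MASK_WATER_PPM) | \
           (np.abs(offsets) >= FIT_MASK_TAIL_PPM)


def fit_two_pool(z: ZSpectrum) -> TwoPoolFit:
    """Two-pool (water + MT) Lorentzian background fit of a B0-corrected
    z-spectrum, restricted to the water-core/MT-tail mask."""
    mask = two_pool_fit_mask(z.offsets)
    x, y = z.offsets[mask], z.signal[mask]
    if not (np.any(np.abs(x) <= 1.0) and np.any(np.abs(x) >= 6.0)):
        raise InvalidInputError(
            "offset grid must sample both |dw| <= 1 ppm and |dw| >= 6 ppm")

    # p = (A_w, G_w, A_mt, G_mt, d_mt); water center fixed at 0.
    def model(p, offs):
        return (1.0 - lorentzian(offs, p[0], 0.0, p[1])
                - lorentzian(offs, p[2], p[4], p[3]))

    def resid(p):
        return model(p, x) - y

    def jac(p):
        aw, gw, amt, gmt, dmt = p
        j = np.empty((x.size, 5))
        hw = (gw / 2.0) ** 2
        uw = x  # water center fixed at 0
        dw = hw + uw ** 2
        j[:, 0] = -hw / dw
        j[:, 1] = -aw * (uw ** 2) / dw ** 2 * (gw / 2.0)
        hm = (gmt / 2.0) ** 2
        um = x - dmt
        dm = hm + um ** 2
        j[:, 2] = -hm / dm
        j[:, 3] = -amt * (um ** 2) / dm ** 2 * (gmt / 2.0)
        j[:, 4] = -amt * hm * 2.0 * um / dm ** 2
        return j

    aw0 = float(np.clip(1.0 - np.min(y), 0.05, 1.0))
    far = np.abs(x) >= FIT_MASK_TAIL_PPM
    amt0 = float(np.clip((1.0 - np.median(y[far])) / 0.7, 1e-4, 1.0)) \
        if np.any(far) else 0.05
    lo = [0.0, 0.2, 0.0, 5.5, -3.0]
    hi = [1.0, 5.0, 1.0, 300.0, 0.0]
    best = None
    # restart only if the masked offsets are not explained to noise level
    rms_ok = 0.5 * x.size * 5e-3 ** 2
    for gmt0 in (25.0, 12.0, 60.0):
        x0 = [aw0, 1.4, amt0, gmt0, -1.0]
        sol = least_squares(resid, x0=x0, jac=jac, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.success and best.cost < rms_ok:
            break
    if best is None or not best.success:
        raise FitFailureError("two-pool background fit did not converge",
                              {"status": getattr(best, "status", None)})
    p = best.x
    return TwoPoolFit(
        water_amp=float(p[0]), water_fwhm=float(p[1]), water_center=0.0,
        mt_amp=float(p[2]), mt_fwhm=float(p[3]), mt_center=float(p[4]),
        fitted_curve=model(p, z.offsets), fit_mask=mask,
        residual_norm=float(np.linalg.norm(best.fun)))


def arex_resid(z: ZSpectrum, fit: TwoPoolFit, t1: float) -> AREXSpectrum:
    """AREX residual spectrum in % s^-1 (S0 = 1 for normalized spectra).

    Offsets where S_meas <= 0 are set to NaN and flagged, never fatal.
    """
    if t1 <= 0:
        raise InvalidInputError(f"T1 must be > 0, got {t1}")
    s_meas = z.signal
    s_fit = fit.fitted_curve if fit.fitted_curve is not None \
        else fit.evaluate(z.offsets)
    s_fit = np.asarray(s_fit, float)
    if s_fit.shape != s_meas.shape:
        s_fit = fit.evaluate(z.offsets)
    f_m = fit.mt_amp
    invalid = s_meas <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        arex = (1.0 / s_meas - 1.0 / s_fit) / (t1 * (1.0 + f_m)) * 100.0
    arex[invalid] = np.nan
    return AREXSpectrum(offsets=z.offsets.copy(), arex=arex, t1=t1, f_m=f_m,
                        invalid_mask=invalid)
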