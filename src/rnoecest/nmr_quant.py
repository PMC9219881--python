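"""1H-NMR band integration and internal-standard quantification.

Peak areas are taken as proportional to proton concentration, so an
analyte concentration follows from the ratio of its band AUC to that of
the TMS internal standard:

    c_analyte = (AUC_band / AUC_TMS) * c_TMS * (12 / n_H),

where the 12/n_H factor corrects for TMS's 12 equivalent protons against
the analyte band's proton count (3 for the cholesterol C18 methyl).  The
proton correction defaults on but can be disabled, since a plain
AUC-proportionality convention is equally defensible.

Default bands: cholesterol methyl 0.68 +/- 0.03 ppm; TMS 0 +/- 0.03 ppm;
phosphatidylcholine choline methyls 3.28-3.38 ppm; total lipid alkyl
hydrogens 1.45-1.65 ppm (all configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, QuantificationError

TMS_PROTONS = 12
CHOLESTEROL_METHYL_PROTONS = 3

CHOLESTEROL_BAND = (0.65, 0.71)
TMS_BAND = (-0.03, 0.03)
PHOSPHATIDYLCHOLINE_BAND = (3.28, 3.38)
TOTAL_LIPID_BAND = (1.45, 1.65)

#: TMS physical constants for the volume-fraction -> molarity conversion.
TMS_DENSITY_G_PER_ML = 0.648
TMS_MOLAR_MASS_G_PER_MOL = 88.22


@dataclass
class NMRSpectrum:
    """A 1H trace: ppm axis (strictly monotone, either direction) and
    intensity in arbitrary units.  Stored ascending internally."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.ppm.shape != self.intensity.shape:
            raise InvalidInputError("ppm and intensity differ in length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("ppm axis must be strictly monotone")
        if d[0] < 0:  # descending axis allowed on input
            self.ppm = self.ppm[::-1]
            self.intensity = self.intensity[::-1]

    def to_csv(self, path):
        pd.DataFrame({"ppm": self.ppm, "intensity": self.intensity}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(ppm=df["ppm"].to_numpy(), intensity=df["intensity"].to_numpy())


@dataclass
class QuantResult:
    band: tuple
    auc: float
    ratio_to_standard: float
    concentration: float = float("nan")
    proton_correction_applied: bool = False


def tms_molarity(volume_fraction: float = 0.0005,
                 density_g_per_ml: float = TMS_DENSITY_G_PER_ML,
                 molar_mass_g_per_mol: float = TMS_MOLAR_MASS_G_PER_MOL) -> float:
    """Molarity (mM) of a TMS volume fraction in solvent.

    0.05% v/v with density 0.648 g/mL and M = 88.22 g/mol gives 3.67 mM.
    """
    if volume_fraction <= 0:
        raise InvalidInputError("volume_fraction must be > 0")
    grams_per_liter = volume_fraction * density_g_per_ml * 1000.0
    return grams_per_liter / molar_mass_g_per_mol * 1000.0


def integrate_band(spectrum: NMRSpectrum, band, baseline: str = "none") -> float:
    """Trapezoidal AUC over a ppm band with interpolated endpoints.

    ``baseline='linear-endpoints'`` first subtracts the straight line
    through the band's endpoint intensities, removing a sloped baseline.
    """
    lo, hi = sorted(band)
    x, y = spectrum.ppm, spectrum.intensity
    if lo < x[0] - 1e-12 or hi > x[-1] + 1e-12:
        raise InvalidInputError(
            f"band [{lo}, {hi}] outside axis [{x[0]}, {x[-1]}]")
    inner = (x > lo) & (x < hi)
    xs = np.concatenate([[lo], x[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]])
    if baseline == "linear-endpoints":
        ys = ys - (ys[0] + (ys[-1] - ys[0]) * (xs - lo) / (hi - lo))
    elif baseline != "none":
        raise InvalidInputError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(ys, xs))


def relative_band_ratio(spectrum: NMRSpectrum, target_band, reference_band,
                        baseline: str = "none") -> float:
    """AUC(target) / AUC(reference); used for phosphatidylcholine
    (3.28-3.38 ppm) and total lipid (1.45-1.65 ppm) relative to TMS."""
    ref = integrate_band(spectrum, reference_band, baseline=baseline)
    if ref <= 0:
        raise QuantificationError(
            f"reference band AUC must be > 0, got {ref}")
    return integrate_band(spectrum, target_band, baseline=baseline) / ref


def cholesterol_concentration(spectrum: NMRSpectrum, c_standard: float,
                              apply_proton_correction: bool = True,
                              chol_band=CHOLESTEROL_BAND, tms_band=TMS_BAND,
                              baseline: str = "none") -> QuantResult:
    """Cholesterol molarity from the C18-methyl (0.68 ppm) AUC against the
    TMS internal standard at 0 ppm."""
    if c_standard <= 0:
        raise InvalidInputError("c_standard must be > 0")
    auc_tms = integrate_band(spectrum, tms_band, baseline=baseline)
    if auc_tms <= 0:
        raise QuantificationError(
            f"TMS AUC must be > 0 for quantification, got {auc_tms}")
    auc_chol = integrate_band(spectrum, chol_band, baseline=baseline)
    ratio = auc_chol / auc_tms
    factor = (TMS_PROTONS / CHOLESTEROL_METHYL_PROTONS
              if apply_proton_correction else 1.0)
    return QuantResult(band=tuple(chol_band), auc=auc_chol,
                       ratio_to_standard=ratio,
                       concentration=ratio * factor * c_standard,
                       proton_correction_applied=apply_proton_correction)
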