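"""T1 estimation: per-voxel saturation recovery and homogenate
bi-exponential inversion recovery.

Saturation recovery fits I(t) = I0 (1 - exp(-t/T1)); inversion recovery
fits the normalized bi-exponential
I(t) = 1 - 2 (x_a exp(-t/T1a) + (1-x_a) exp(-t/T1b)), with the averaged
T1 for a homogenate defined as T1_avg = x_a T1a + (1-x_a) T1b.

The bi-exponential objective is multi-modal; fits run three deterministic
starts (x_a in {0.2, 0.5, 0.8}, time constants log-spaced around the curve's
zero-crossing time) and keep the best residual.  Bounds are physiological:
T1 in [1 ms, 20 s], x_a in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidInputError
from .synth import inversion_recovery_biexp_model, saturation_recovery_model

T1_BOUNDS = (1e-3, 20.0)


@dataclass
class RecoveryCurve:
    """A measured T1 recovery curve (saturation or inversion)."""

    times: np.ndarray
    intensities: np.ndarray
    kind: str  # "saturation" | "inversion"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times.shape != self.intensities.shape:
            raise InvalidInputError("times and intensities differ in length")
        if np.any(self.times <= 0):
            raise InvalidInputError("recovery times must be strictly positive")
        if np.any(np.diff(self.times) <= 0):
            order = np.argsort(self.times)
            self.times = self.times[order]
            self.intensities = self.intensities[order]

    @classmethod
    def from_csv(cls, path, kind: str):
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(),
                   intensities=df["intensity"].to_numpy(), kind=kind)


@dataclass
class T1Fit:
    I0: float
    T1: float
    residual_norm: float


@dataclass
class BiexpT1Fit:
    x_a: float
    T1_a: float
    T1_b: float
    T1_avg: float
    residual_norm: float
    degenerate: bool = False


def fit_saturation_recovery(curve: RecoveryCurve) -> T1Fit:
    """Least-squares (I0, T1) for I(t) = I0 (1 - exp(-t/T1))."""
    if curve.kind != "saturation":
        raise InvalidInputError(f"expected a saturation curve, got {curve.kind!r}")
    t, y = curve.times, curve.intensities
    if t.size < 3:
        raise InvalidInputError("need at least 3 points for a mono-exponential fit")
    if not np.any(np.abs(y) > 0):
        raise FitFailureError("all-zero signal", {"max_abs": 0.0})

    i0_guess = float(np.max(y))
    if i0_guess <= 0:
        raise FitFailureError("non-positive signal", {"max": i0_guess})
    # T1 guess: time at which the curve reaches 63% of its plateau.
    frac = y / i0_guess
    idx = np.searchsorted(np.clip(frac, 0, 1), 0.632)
    t1_guess = float(np.clip(t[min(idx, t.size - 1)], *T1_BOUNDS))

    def resid(p):
        return saturation_recovery_model(t, p[0], p[1]) - y

    best = None
    for t1_0 in (t1_guess, t1_guess / 4, t1_guess * 4):
        sol = least_squares(resid, x0=[i0_guess, np.clip(t1_0, *T1_BOUNDS)],
                            bounds=([0.0, T1_BOUNDS[0]], [np.inf, T1_BOUNDS[1]]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-24:
            break
    if best is None or not best.success:
        raise FitFailureError("saturation recovery fit did not converge",
                              {"status": getattr(best, "status", None)})
    return T1Fit(I0=float(best.x[0]), T1=float(best.x[1]),
                 residual_norm=float(np.linalg.norm(best.fun)))


def _fit_inversion_mono(t, y):
    """Mono-exponential inversion fit: I(t) = 1 - 2 exp(-t/T1)."""
    # zero-crossing time t0 satisfies T1 = t0/ln2
    sign_change = np.where(np.diff(np.signbit(y)))[0]
    t0 = t[sign_change[0]] if sign_change.size else np.median(t)
    t1_guess = float(np.clip(t0 / np.log(2.0), *T1_BOUNDS))

    def resid(p):
        return 1.0 - 2.0 * np.exp(-t / p[0]) - y

    sol = least_squares(resid, x0=[t1_guess], bounds=([T1_BOUNDS[0]], [T1_BOUNDS[1]]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return float(sol.x[0]), float(np.linalg.norm(sol.fun))


def normalize_inversion_curve(curve: RecoveryCurve) -> RecoveryCurve:
    """Normalize so the fully-recovered signal is 1: divide by the mean of
    the two longest-delay intensities."""
    scale = float(np.mean(curve.intensities[-2:]))
    if scale <= 0:
        raise InvalidInputError("cannot normalize: non-positive plateau signal")
    return RecoveryCurve(times=curve.times, intensities=curve.intensities / scale,
                         kind=curve.kind)


def fit_inversion_recovery_biexp(curve: RecoveryCurve,
                                 degeneracy_rtol: float = 1e-6) -> BiexpT1Fit:
    """Fit the normalized bi-exponential inversion recovery.

    Returns (x_a, T1_a, T1_b) with T1_a <= T1_b enforced by a post-hoc
    swap, and T1_avg = x_a T1_a + (1-x_a) T1_b.  Data that a single
    exponential explains within tolerance is not an error: the fit returns
    x_a = 1 with both time constants equal and the ``degenerate`` flag set.
    """
    if curve.kind != "inversion":
        raise InvalidInputError(f"expected an inversion curve, got {curve.kind!r}")
    t, y = curve.times, curve.intensities
    if t.size < 5:
        raise InvalidInputError("need at least 5 points for a bi-exponential fit")

    t1_mono, mono_res = _fit_inversion_mono(t, y)

    def resid(p):
        return inversion_recovery_biexp_model(t, p[0], p[1], p[2]) - y

    lo = [0.0, T1_BOUNDS[0], T1_BOUNDS[0]]
    hi = [1.0, T1_BOUNDS[1], T1_BOUNDS[1]]
    best = None
    for xa0 in (0.2, 0.5, 0.8):
        for fa, fb in ((0.25, 4.0), (0.1, 1.0), (1.0, 10.0)):
            x0 = [xa0, np.clip(t1_mono * fa, *T1_BOUNDS),
                  np.clip(t1_mono * fb, *T1_BOUNDS)]
            sol = least_squares(resid, x0=x0, bounds=(lo, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailureError("bi-exponential fit did not converge", {})
    bi_res = float(np.linalg.norm(best.fun))

    scale = max(float(np.linalg.norm(y)), 1e-30)
    degenerate = (mono_res <= bi_res * (1 + degeneracy_rtol)
                  or mono_res / scale < degeneracy_rtol)
    if degenerate:
        return BiexpT1Fit(x_a=1.0, T1_a=t1_mono, T1_b=t1_mono, T1_avg=t1_mono,
                          residual_norm=mono_res, degenerate=True)

    x_a, t1_a, t1_b = (float(v) for v in best.x)
    if t1_a > t1_b:  # convention T1_a <= T1_b
        t1_a, t1_b, x_a = t1_b, t1_a, 1.0 - x_a
    if abs(t1_a - t1_b) <= 1e-6 * t1_b:
        degenerate = True
    t1_avg = x_a * t1_a + (1.0 - x_a) * t1_b
    return BiexpT1Fit(x_a=x_a, T1_a=t1_a, T1_b=t1_b, T1_avg=float(t1_avg),
                      residual_norm=bi_res, degenerate=degenerate)


def fit_t1_map(stack: np.ndarray, tr_list) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise saturation-recovery T1 map.

    ``stack`` has shape (rows, cols, n_TR) with one volume per TR.  Returns
    (t1_map, failure_mask); failed voxels are NaN and flagged.
    """
    stack = np.asarray(stack, float)
    tr_list = np.asarray(tr_list, float)
    if stack.shape[-1] != tr_list.size:
        raise InvalidInputError(
            f"{stack.shape[-1]} volumes but {tr_list.size} TR values")
    rows, cols = stack.shape[:2]
    t1_map = np.full((rows, cols), np.nan)
    failure = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            y = stack[r, c, :]
            try:
                fit = fit_saturation_recovery(
                    RecoveryCurve(times=tr_list, intensities=y, kind="saturation"))
                t1_map[r, c] = fit.T1
            except (FitFailureError, InvalidInputError):
                failure[r, c] = True
    return t1_map, failure
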