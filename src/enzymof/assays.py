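"""Reduction of raw assay signals to the campaign's response variables.

Responses driving the optimization loop:

* **EE** (encapsulation efficiency, %): fraction of the enzyme mass put into a
  synthesis that is *not* recovered in the post-synthesis supernatant, measured
  by a BCA protein assay at 562 nm against a free-enzyme calibration line.
* **REA** (retained enzymatic activity, %): initial hydrolysis rate of the
  biocomposite relative to the free enzyme at equal nominal enzyme content,
  from absorbance kinetics at 348 nm.
* **PI** (performance index): EE × REA on the fractional scale, the scalarized
  target when encapsulation and activity must be balanced.

Also provided: protein loading, cumulative release percentages for buffer
stability studies, and second-derivative decomposition of fluorescence
emission spectra into component-band positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .design_space import Recipe
from .errors import AssayError

__all__ = [
    "CalibrationCurve",
    "KineticTrace",
    "Spectrum",
    "TrialResult",
    "fit_bca_calibration",
    "concentration_from_absorbance",
    "compute_ee",
    "compute_p_loading",
    "initial_rate",
    "compute_rea",
    "compute_pi",
    "compute_release",
    "second_derivative_peaks",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear BCA standard curve: absorbance = slope × concentration + intercept."""

    slope: float  # AU per (mg/mL)
    intercept: float  # AU
    r_squared: float


@dataclass(frozen=True)
class KineticTrace:
    """Absorbance-vs-time trace of a hydrolysis reaction (348 nm)."""

    times: np.ndarray  # s, strictly increasing
    absorbances: np.ndarray  # AU

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)
        if t.size != a.size:
            raise AssayError("times and absorbances must have equal length")
        if t.size < 5:
            raise AssayError("kinetic trace needs at least 5 points")
        if not np.all(np.diff(t) > 0):
            raise AssayError("times must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """Fluorescence emission spectrum on an ascending wavelength axis."""

    wavelengths: np.ndarray  # nm
    intensities: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)
        if w.size != i.size:
            raise AssayError("wavelengths and intensities must have equal length")
        if w.size < 11:
            raise AssayError("spectrum needs at least 11 points for derivative analysis")
        if not np.all(np.diff(w) > 0):
            raise AssayError("wavelengths must be strictly increasing")


@dataclass
class TrialResult:
    """A recipe plus its measured (or reduced) responses.

    ``ee`` and ``rea`` are percentages; ``pi`` is the fractional product
    (ee/100)·(rea/100); ``p_loading`` is enzyme weight-percent of the dried
    composite. ``status`` is "ok" or "failed" (failed trials stay in the audit
    log but are excluded from model fitting).
    """

    recipe: Recipe
    ee: float
    rea: Optional[float] = None
    pi: Optional[float] = field(default=None)
    p_loading: Optional[float] = None
    replicate_sd: Optional[float] = None
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok":
            if not 0.0 <= self.ee <= 100.0:
                raise AssayError(f"EE must lie in [0, 100], got {self.ee}")
            if self.rea is not None:
                if self.rea < 0:
                    raise AssayError(f"REA must be >= 0, got {self.rea}")
                if self.pi is None:
                    self.pi = compute_pi(self.ee, self.rea)

    def target_value(self, target: str) -> float:
        if target == "EE":
            return self.ee
        if target == "PI":
            if self.pi is None:
                raise AssayError("trial has no PI (REA missing)")
            return self.pi
        raise ValueError(f"unknown target {target!r}")


def fit_bca_calibration(
    standards: Sequence[tuple[float, float]],
) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, absorbance) standards.

    At least three standards with non-zero concentration variance are
    required; repeated concentrations are allowed.
    """
    if len(standards) < 3:
        raise AssayError("calibration needs at least 3 standards")
    conc = np.array([s[0] for s in standards], dtype=float)
    absb = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(conc) == 0:
        raise AssayError("standards have zero concentration variance")
    res = stats.linregress(conc, absb)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def concentration_from_absorbance(curve: CalibrationCurve, absorbance: float) -> float:
    """Invert the standard curve: (A − intercept)/slope, clipped below at 0."""
    if curve.slope == 0:
        raise AssayError("calibration slope is zero; curve cannot be inverted")
    conc = (absorbance - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"absorbance {absorbance} below the calibration intercept; clipping to 0",
            stacklevel=2,
        )
        return 0.0
    return float(conc)


def compute_ee(mass_used: float, supernatant_conc: float, supernatant_volume: float) -> float:
    """Encapsulation efficiency in percent.

    100 × (m_used − c_sup·V_sup) / m_used, clipped to [0, 100]: assay noise can
    push the supernatant estimate slightly past the input mass.
    """
    if mass_used <= 0:
        raise AssayError("mass_used must be strictly positive")
    if supernatant_conc < 0 or supernatant_volume < 0:
        raise AssayError("supernatant concentration/volume must be >= 0")
    residual = supernatant_conc * supernatant_volume
    ee = 100.0 * (mass_used - residual) / mass_used
    return float(np.clip(ee, 0.0, 100.0))


def compute_p_loading(encapsulated_mass: float, composite_mass: float) -> float:
    """Protein loading: enzyme mass as weight-percent of the dry composite."""
    if composite_mass <= 0:
        raise AssayError("composite mass must be strictly positive")
    if encapsulated_mass < 0:
        raise AssayError("encapsulated mass must be >= 0")
    return 100.0 * encapsulated_mass / composite_mass


def _initial_window(n: int, times: np.ndarray) -> int:
    # First 60 s or first 20% of points, whichever covers more points; never
    # fewer than 5 points, never more than the trace.
    n_60s = int(np.searchsorted(times, times[0] + 60.0, side="right"))
    n_frac = int(np.ceil(0.2 * n))
    return min(n, max(5, n_60s, n_frac))


def initial_rate(trace: KineticTrace) -> float:
    """Initial reaction rate (AU/s): OLS slope over the early linear window.

    The window is the first 60 s or the first 20% of points, whichever holds
    more points (minimum 5), because product accumulation bends the trace at
    longer times.
    """
    n = trace.times.size
    w = _initial_window(n, trace.times)
    if w < 5:
        raise AssayError("initial-rate window shorter than 5 points")
    t = trace.times[:w]
    a = trace.absorbances[:w]
    if np.ptp(a) == 0:
        return 0.0
    res = stats.linregress(t, a)
    return float(res.slope)


def compute_rea(rate_sample: float, rate_free: float) -> float:
    """Retained enzymatic activity: sample rate as a percent of the free-enzyme rate.

    Not clipped above 100: an immobilized enzyme can in principle out-perform
    the free enzyme under assay conditions.
    """
    if rate_free <= 0:
        raise AssayError("free-enzyme rate must be strictly positive")
    return 100.0 * rate_sample / rate_free


def compute_pi(ee: float, rea: float) -> float:
    """Performance index: the product of the EE and REA fractions, in [0, 1]
    when REA ≤ 100."""
    if ee < 0 or rea < 0:
        raise AssayError("EE and REA must be >= 0")
    return (ee / 100.0) * (rea / 100.0)


def compute_release(
    encapsulated_mass: float,
    released_mass_timeseries: Sequence[tuple[float, float]],
    tolerance: float = 1e-9,
) -> list[tuple[float, float]]:
    """Cumulative release percentages from a (hour, released mg) series.

    Percentages are clipped to [0, 100]. A decrease in cumulative released
    mass beyond ``tolerance`` triggers a warning (measurement artifact), and
    the running maximum is reported so the output stays non-decreasing.
    """
    if encapsulated_mass <= 0:
        raise AssayError("encapsulated mass must be strictly positive")
    out: list[tuple[float, float]] = []
    running = 0.0
    for hour, mass in released_mass_timeseries:
        if mass < running - tolerance:
            warnings.warn(
                f"cumulative released mass decreased at t={hour} h "
                f"({mass} < {running}); keeping the running maximum",
                stacklevel=2,
            )
        running = max(running, mass)
        pct = float(np.clip(100.0 * running / encapsulated_mass, 0.0, 100.0))
        out.append((hour, pct))
    return out


def second_derivative_peaks(
    spectrum: Spectrum,
    window: int = 11,
    poly_degree: int = 2,
    min_rel_prominence: float = 0.05,
) -> list[float]:
    """Component-band positions from the second derivative of an emission spectrum.

    The spectrum is smoothed and twice differentiated with a Savitzky–Golay
    filter (raw second differences amplify noise); component bands of an
    overlapped emission envelope appear as local *minima* of the second
    derivative. Minima whose prominence is below ``min_rel_prominence`` of the
    derivative's dynamic range are discarded, which makes the result invariant
    to uniform intensity scaling and empty for a flat spectrum.

    Returns the band wavelengths sorted ascending.
    """
    n = spectrum.wavelengths.size
    if window % 2 == 0:
        raise AssayError("smoothing window must be odd")
    if window < poly_degree + 2:
        raise AssayError("smoothing window must be at least poly_degree + 2")
    if window > n:
        raise AssayError(f"smoothing window {window} exceeds spectrum length {n}")
    dx = float(np.mean(np.diff(spectrum.wavelengths)))
    d2 = signal.savgol_filter(
        spectrum.intensities, window_length=window, polyorder=poly_degree, deriv=2, delta=dx
    )
    amp = float(np.ptp(d2))
    if amp == 0:
        return []
    peaks, _ = signal.find_peaks(-d2, prominence=min_rel_prominence * amp)
    return sorted(float(spectrum.wavelengths[i]) for i in peaks)
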