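"""Circular-dichroism and tryptophan-fluorescence analysis.

Covers three tasks around thermal transitions of isolated channel
domains:

* conversion of raw ellipticity to mean residue ellipticity,
  ``[theta]_MR = 100 * theta / (C * N * l)`` with C the molar protein
  concentration, N the residue count and l the path length in cm;
* nonlinear two-state melt fitting.  The observed signal is modelled as
  a baseline mixture ``s(T) = b_f(T)*(1-f_u) + b_u(T)*f_u`` with linear
  folded/unfolded baselines and a van't Hoff unfolded fraction

      f_u(T) = 1 / (1 + exp[(dH/R) * (1/T - 1/T_mid)]),

  so f_u(T_mid) = 1/2 by construction.  A negative dH describes a
  transition populated on cooling (the cold-sensing domain case);
* sub-nm emission-peak localisation and blue/red peak-shift series for
  intrinsic tryptophan fluorescence (295 nm excitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .constants import R_KCAL, celsius_to_kelvin
from .errors import DegenerateFitError

__all__ = [
    "CDSpectrum", "MeltCurve", "MeltFit", "EmissionSpectrum",
    "mean_residue_ellipticity", "unfolded_fraction", "two_state_signal",
    "fit_two_state_melt", "emission_peak", "peak_shift_series",
]


@dataclass
class CDSpectrum:
    """A far-UV CD spectrum at one temperature."""

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    concentration_M: float
    n_residues: int
    path_length_cm: float
    temperature_C: float

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        for name in ("concentration_M", "path_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_residues <= 0:
            raise ValueError("n_residues must be positive")

    def mean_residue_ellipticity(self):
        return mean_residue_ellipticity(
            self.ellipticity_mdeg, self.concentration_M,
            self.n_residues, self.path_length_cm)


@dataclass
class MeltCurve:
    """Signal (e.g. mean residue ellipticity at 222 nm) versus temperature."""

    temperature_C: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_C.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")
        if self.temperature_C.size < 5:
            raise ValueError("a melt needs >=5 temperatures spanning the transition")


@dataclass
class MeltFit:
    """Two-state melt fit: transition enthalpy, midpoint and baselines."""

    dH_unfold: float            # kcal/mol
    t_mid_C: float              # Celsius
    baseline_folded: tuple[float, float]    # intercept, slope (per deg C)
    baseline_unfolded: tuple[float, float]
    dH_ci95: float              # half-width of asymptotic 95% CI
    t_mid_ci95: float
    rmse: float
    n_points: int


@dataclass
class EmissionSpectrum:
    """An intrinsic fluorescence emission spectrum at one temperature."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    temperature_C: float
    excitation_nm: float = 295.0

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


def mean_residue_ellipticity(theta_mdeg, c_molar, n_residues, path_cm):
    """[theta]_MR = 100 * theta / (C * N * l), in deg.cm^2/dmol."""
    if c_molar <= 0 or n_residues <= 0 or path_cm <= 0:
        raise ValueError("concentration, residue count and path length must be positive")
    theta = np.asarray(theta_mdeg, dtype=float)
    out = 100.0 * theta / (c_molar * n_residues * path_cm)
    return float(out) if out.ndim == 0 else out


def unfolded_fraction(temperature_C, dH_kcal, t_mid_C):
    """Van't Hoff two-state unfolded fraction; equals 1/2 at t_mid."""
    t_k = celsius_to_kelvin(temperature_C)
    tm_k = celsius_to_kelvin(t_mid_C)
    arg = (dH_kcal / R_KCAL) * (1.0 / t_k - 1.0 / tm_k)
    out = 1.0 / (1.0 + np.exp(np.clip(arg, -500.0, 500.0)))
    return float(out) if out.ndim == 0 else out


def two_state_signal(temperature_C, dH_kcal, t_mid_C, bf0, bf1, bu0, bu1):
    """Baseline-weighted two-state melt signal."""
    t = np.asarray(temperature_C, dtype=float)
    fu = unfolded_fraction(t, dH_kcal, t_mid_C)
    return (bf0 + bf1 * t) * (1.0 - fu) + (bu0 + bu1 * t) * fu


def _initial_guesses(t, s):
    """Heuristic starting points; both dH signs are tried downstream."""
    k = max(2, t.size // 5)
    lo = np.polyfit(t[:k], s[:k], 1)      # cold-end baseline
    hi = np.polyfit(t[-k:], s[-k:], 1)    # warm-end baseline
    # steepest point of a lightly smoothed derivative locates t_mid
    ds = np.gradient(s, t)
    t_mid0 = float(t[np.argmax(np.abs(ds))])
    t_mid0 = float(np.clip(t_mid0, t.min() + 1e-6, t.max() - 1e-6))
    return lo, hi, t_mid0


#: |dH| starting values (kcal/mol) swept by the multistart
_DH_STARTS = (10.0, 25.0, 50.0, 100.0, 200.0)


def fit_two_state_melt(curve: MeltCurve,
                       populated_on: str = "cooling") -> MeltFit:
    """Nonlinear least-squares two-state fit of a melt curve.

    The model has an exact relabelling symmetry: negating dH while
    swapping the folded and unfolded baselines leaves the curve
    unchanged, so the sign of dH is a convention, not a fittable
    quantity.  ``populated_on='cooling'`` (default) reports the branch in
    which the transition is populated on cooling (dH <= 0, the
    cold-sensing-domain case); ``'heating'`` reports the classic heat
    melt (dH >= 0).

    A multistart over |dH| magnitudes, both baseline pairings and
    several midpoint guesses keeps the optimiser out of tilted-baseline
    local minima; the lowest-SSE solution wins.
    """
    if populated_on not in ("cooling", "heating"):
        raise ValueError("populated_on must be 'cooling' or 'heating'")
    t = curve.temperature_C
    s = curve.signal
    span = float(np.ptp(s))
    if span == 0 or span < 1e-12 * max(1.0, np.abs(s).max()):
        raise DegenerateFitError("flat signal: no transition to fit")
    lo, hi, t_mid_steep = _initial_guesses(t, s)
    tm_starts = {t_mid_steep,
                 float(np.percentile(t, 35)), float(np.percentile(t, 65))}

    def model(tt, dh, tm, bf1, bf0, bu1, bu0):
        return two_state_signal(tt, dh, tm, bf0, bf1, bu0, bu1)

    best = None
    for mag in _DH_STARTS:
        for sign in (-1.0, +1.0):
            for (bf, bu) in ((hi, lo), (lo, hi)):
                for tm0 in tm_starts:
                    try:
                        with warnings.catch_warnings():
                            # non-winning starts may sit on singular
                            # Jacobians; only the best fit's pcov is used
                            warnings.simplefilter("ignore", OptimizeWarning)
                            popt, pcov = curve_fit(
                                model, t, s,
                                p0=[sign * mag, tm0, bf[1], bf[0], bu[1], bu[0]],
                                maxfev=20000)
                    except RuntimeError:
                        continue
                    resid = s - model(t, *popt)
                    sse = float(resid @ resid)
                    if best is None or sse < best[0]:
                        best = (sse, popt, pcov)
    if best is None:
        raise DegenerateFitError("two-state melt fit did not converge")
    sse, popt, pcov = best
    dh, tm, bf1, bf0, bu1, bu0 = popt
    want_negative = populated_on == "cooling"
    if (dh > 0) == want_negative:
        # flip to the requested branch of the symmetry
        dh = -dh
        bf0, bf1, bu0, bu1 = bu0, bu1, bf0, bf1
    if not (t.min() <= tm <= t.max()):
        raise DegenerateFitError(
            f"fitted midpoint {tm:.1f} C lies outside the data range "
            f"[{t.min():.1f}, {t.max():.1f}] C")
    dof = max(1, t.size - 6)
    rmse = float(np.sqrt(sse / dof))
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return MeltFit(dH_unfold=float(dh), t_mid_C=float(tm),
                   baseline_folded=(float(bf0), float(bf1)),
                   baseline_unfolded=(float(bu0), float(bu1)),
                   dH_ci95=float(1.96 * perr[0]), t_mid_ci95=float(1.96 * perr[1]),
                   rmse=rmse, n_points=int(t.size))


def emission_peak(spectrum: EmissionSpectrum, half_window: int = 3) -> float:
    """Locate the emission maximum with sub-nm precision.

    A quadratic is fitted through the +/- ``half_window`` points around
    the argmax (on log intensity when all window points are positive,
    which is exact for Gaussian-shaped bands).  A plateau of equal maxima
    is resolved to its centroid.  A maximum on the spectrum edge raises
    :class:`DegenerateFitError` (monotone spectrum).
    """
    wl = spectrum.wavelength_nm
    y = spectrum.intensity
    if wl.size < 2 * half_window + 1:
        raise ValueError("spectrum too short for peak localisation")
    top = np.flatnonzero(y == y.max())
    center = int(round(top.mean()))  # plateau tie-break: centroid
    if center <= 0 or center >= wl.size - 1 or top[0] == 0 or top[-1] == wl.size - 1:
        raise DegenerateFitError("no interior maximum: spectrum is monotone at the edge")
    if top.size > 1:
        # flat plateau: the quadratic is degenerate, return the centroid
        return float(wl[top].mean())
    lo = max(0, center - half_window)
    hi = min(wl.size, center + half_window + 1)
    x = wl[lo:hi]
    yy = y[lo:hi]
    if np.all(yy > 0):
        coef = np.polyfit(x, np.log(yy), 2)
    else:
        coef = np.polyfit(x, yy, 2)
    if coef[0] >= 0:
        return float(wl[center])
    return float(-coef[1] / (2.0 * coef[0]))


def peak_shift_series(spectra: list[EmissionSpectrum], allow_replicates: bool = False):
    """Peak shifts relative to the highest-temperature spectrum.

    Returns ``(temperatures, shifts)`` sorted by temperature; negative
    shifts are blue shifts (peak moving to shorter wavelength on
    cooling).  Duplicate temperatures raise unless ``allow_replicates``.
    """
    if len(spectra) < 2:
        raise ValueError("need spectra at >=2 temperatures")
    temps = np.array([s.temperature_C for s in spectra], dtype=float)
    if not allow_replicates and np.unique(temps).size != temps.size:
        raise ValueError("duplicate temperatures; pass allow_replicates=True "
                         "if these are true replicates")
    order = np.argsort(temps, kind="stable")
    temps = temps[order]
    peaks = np.array([emission_peak(spectra[i]) for i in order])
    ref = peaks[-1]  # highest temperature
    return temps, peaks - ref
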