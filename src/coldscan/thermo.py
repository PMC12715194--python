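"""Gating thermodynamics of temperature-activated channels.

A temperature-ramped macroscopic current is converted to an open
probability Po by normalising to the current under a saturating agonist
(here 1 mM menthol, assumed to open every channel), Po is mapped to the
two-state open/closed equilibrium constant Keq = Po/(1-Po), and the
enthalpy and entropy of gating are read off a van't Hoff plot::

    ln Keq = -dH/(R*T) + dS/R

with T in Kelvin and R in kcal/(mol.K).  Cold-activated channels yield
negative dH and dS: cooling increases Keq.

The module also evaluates the heat-capacity extension of the gating free
energy,

    dG(T) = dH0 + dCp*(T - T0) - dS0*T - T*dCp*ln(T/T0),

whose curvature is d^2(dG)/dT^2 = -dCp/T: a positive dCp bends dG(T)
downward into a dome with a maximum at intermediate temperature and
activation (dG falling) on both the cold and the hot flank, while a
negative dCp produces the inverted, upward-bending shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import R_KCAL, celsius_to_kelvin
from .errors import DegenerateFitError

logger = logging.getLogger(__name__)

#: default clipping bound applied to Po before taking ln Keq
PO_EPS = 1e-4


@dataclass
class CurrentTrace:
    """A temperature-ramped current recording at +80 mV.

    ``menthol_max_current`` is the current under saturating (1 mM)
    menthol at the same potential, taken as the fully-open reference.
    """

    temperature_C: np.ndarray
    current: np.ndarray
    menthol_max_current: float

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.temperature_C.shape != self.current.shape:
            raise ValueError("temperature and current must have equal length")
        if not np.all(np.isfinite(self.temperature_C)):
            raise ValueError("temperatures must be finite")
        if self.menthol_max_current <= 0:
            raise ValueError("menthol_max_current must be positive")


@dataclass
class PoSeries:
    """Open-probability series with bookkeeping of clipped points."""

    temperature_C: np.ndarray
    po: np.ndarray
    clipped: np.ndarray  # bool mask of points pushed into (eps, 1-eps)


@dataclass
class ThermoFit:
    """Van't Hoff fit result: gating enthalpy and entropy."""

    dH: float  # kcal/mol
    dS: float  # kcal/(mol.K)
    r_squared: float
    n_points: int
    temperature_window: tuple[float, float]  # Celsius, inclusive


@dataclass
class GibbsModelParams:
    """Parameters of the dCp-dependent gating free-energy model."""

    dH0: float  # kcal/mol at the reference temperature t0
    dS0: float  # kcal/(mol.K) at t0
    dCp: float  # kcal/(mol.K)
    t0: float = 298.15  # Kelvin

    def __post_init__(self):
        if self.t0 <= 0:
            raise ValueError("reference temperature t0 must be positive (Kelvin)")


def normalize_to_po(trace: CurrentTrace, eps: float = PO_EPS,
                    negative_tolerance: float = 0.25) -> PoSeries:
    """Normalise a current trace to open probability.

    Po = current / menthol_max_current, clipped into ``(eps, 1-eps)`` so
    that ln Keq stays finite.  Clipped points are flagged and logged.
    Mildly negative currents (recording noise around a closed channel)
    are tolerated and clipped; currents more negative than
    ``-negative_tolerance * menthol_max`` indicate a polarity or leak
    problem and raise an error.
    """
    imax = trace.menthol_max_current
    if np.any(trace.current < -negative_tolerance * imax):
        raise ValueError("currents are negative beyond tolerance; check polarity")
    po = trace.current / imax
    clipped = (po < eps) | (po > 1.0 - eps)
    if clipped.any():
        logger.info("normalize_to_po: clipped %d/%d points into (%.1e, 1-%.1e)",
                    int(clipped.sum()), po.size, eps, eps)
    po = np.clip(po, eps, 1.0 - eps)
    return PoSeries(trace.temperature_C.copy(), po, clipped)


def keq_from_po(po):
    """Two-state open/closed equilibrium constant Keq = Po/(1-Po)."""
    po = np.asarray(po, dtype=float)
    if np.any((po <= 0) | (po >= 1)):
        raise ValueError("po must lie strictly in (0, 1)")
    out = po / (1.0 - po)
    return float(out) if out.ndim == 0 else out


def po_from_keq(keq):
    """Inverse of :func:`keq_from_po`."""
    keq = np.asarray(keq, dtype=float)
    out = keq / (1.0 + keq)
    return float(out) if out.ndim == 0 else out


def vant_hoff_fit(temperatures_K, keq, weights=None) -> ThermoFit:
    """Least squares of ln Keq against 1/T.

    The slope is -dH/R and the intercept dS/R.  At least two distinct
    temperatures are required.  Optional ``weights`` (relative inverse
    variances of ln Keq) turn the fit into weighted least squares; the
    unweighted default is plain OLS.
    """
    t_k = np.asarray(temperatures_K, dtype=float)
    keq = np.asarray(keq, dtype=float)
    if t_k.shape != keq.shape:
        raise ValueError("temperature and Keq series must have equal length")
    if np.any(keq <= 0):
        raise ValueError("Keq must be positive")
    if np.unique(t_k).size < 2:
        raise DegenerateFitError("van't Hoff fit needs >=2 distinct temperatures")
    x = 1.0 / t_k
    y = np.log(keq)
    if weights is None:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative, same length, not all 0")
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        yhat = slope * x + intercept
        sse = float(np.sum(w * (y - yhat) ** 2))
        ybar = float(np.sum(w * y) / np.sum(w))
        sst = float(np.sum(w * (y - ybar) ** 2))
        r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    dH = -slope * R_KCAL
    dS = intercept * R_KCAL
    t_c = t_k - 273.15
    return ThermoFit(dH=float(dH), dS=float(dS), r_squared=r2,
                     n_points=int(t_k.size),
                     temperature_window=(float(t_c.min()), float(t_c.max())))


def fit_current_trace(trace: CurrentTrace, window_C: tuple[float, float] | None = None,
                      eps: float = PO_EPS, exclude_clipped: bool = True,
                      method: str = "direct") -> ThermoFit:
    """Extract gating dH/dS from a temperature-ramped current.

    ``window_C`` restricts the fit to a temperature interval (inclusive);
    the default uses the whole ramp.

    ``method='direct'`` (default) fits the two-state current model
    ``i(T) = i_max / (1 + exp(dH/(R T) - dS/R))`` to the raw currents by
    nonlinear least squares -- the maximum-likelihood estimator under
    additive Gaussian recording noise, initialised from the linearised
    van't Hoff plot.  ``method='linearized'`` is that plot itself: OLS of
    ln Keq on 1/T with clipped Po points excluded and each remaining
    point weighted by the inverse variance that current noise propagates
    onto ln Keq, w = [Po(1-Po)]^2.  The two methods agree exactly on
    noiseless data; on noisy ramps the linearisation is markedly less
    efficient because ln Keq amplifies noise wherever Po nears 0 or 1.
    """
    if method not in ("direct", "linearized"):
        raise ValueError("method must be 'direct' or 'linearized'")
    series = normalize_to_po(trace, eps=eps)
    mask = np.ones(series.po.size, dtype=bool)
    if window_C is not None:
        lo, hi = min(window_C), max(window_C)
        mask &= (series.temperature_C >= lo) & (series.temperature_C <= hi)
    lin_mask = mask & ~series.clipped if exclude_clipped else mask
    if lin_mask.sum() < 2:
        raise DegenerateFitError("fewer than 2 usable points in the fit window")
    t_k = celsius_to_kelvin(series.temperature_C[lin_mask])
    po = series.po[lin_mask]
    weights = (po * (1.0 - po)) ** 2
    linear = vant_hoff_fit(t_k, keq_from_po(po), weights=weights)
    if method == "linearized":
        return linear

    from scipy.optimize import curve_fit

    imax = trace.menthol_max_current
    t_all = celsius_to_kelvin(series.temperature_C[mask])
    i_all = trace.current[mask]

    def model(t, dH, dS):
        arg = np.clip(dH / (R_KCAL * t) - dS / R_KCAL, -500, 500)
        return imax / (1.0 + np.exp(arg))

    try:
        popt, _ = curve_fit(model, t_all, i_all, p0=[linear.dH, linear.dS],
                            maxfev=10000)
    except RuntimeError:
        logger.warning("direct two-state fit did not converge; "
                       "falling back to the linearized estimate")
        return linear
    resid = i_all - model(t_all, *popt)
    sst = float(np.sum((i_all - i_all.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(resid @ resid) / sst
    t_c = t_all - 273.15
    return ThermoFit(dH=float(popt[0]), dS=float(popt[1]), r_squared=r2,
                     n_points=int(t_all.size),
                     temperature_window=(float(t_c.min()), float(t_c.max())))


def gibbs_curve(params: GibbsModelParams, temperatures_K):
    """Evaluate dG(T) = dH0 + dCp*(T-T0) - dS0*T - T*dCp*ln(T/T0)."""
    t = np.asarray(temperatures_K, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    p = params
    dg = p.dH0 + p.dCp * (t - p.t0) - p.dS0 * t - t * p.dCp * np.log(t / p.t0)
    return float(dg) if dg.ndim == 0 else dg
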