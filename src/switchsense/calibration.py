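"""Dose-response calibration linking decay constants to free Ca2+.

The decay constant tau of the OFF-switching signal is plotted against
log10 of the free Ca2+ concentration and fitted with a four-parameter
logistic (dose-response with Hill slope):

    tau(c) = tau_min + (tau_max - tau_min) / (1 + 10**((c - log_ec50) * h))

with ``c = log10(ca / 1 µM)``.  For ``h > 0`` tau decreases with Ca2+
(faster switching at higher occupancy); the fit accepts either slope sign.
When endpoints are fixed, tau_max/tau_min are solved so that the curve
passes exactly through the measured tau at the stated minimum and maximum
concentrations and only (log_ec50, hill_slope) remain free — with a 0 µM
anchor this reduces to pinning the zero-Ca2+ asymptote.

The module also contains the Hill-isotherm fit for equilibrium titrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import (
    ConfigurationError,
    FitError,
    InsufficientDataError,
    RangeError,
    UnidentifiableError,
)
from .kinetics import hill_fraction
from .synth import TitrationTable

__all__ = [
    "CalibrationModel",
    "InversionResult",
    "BindingFit",
    "fit_dose_response",
    "invert_tau",
    "fit_binding",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fixed-form dose-response linking tau (s) to log10 free Ca2+ (µM)."""

    tau_max: float  # zero-Ca2+ endpoint, s
    tau_min: float  # saturating endpoint, s
    log_ec50: float  # log10 µM
    hill_slope: float
    endpoints_fixed: bool = False

    def __post_init__(self) -> None:
        if not (self.tau_min > 0 and self.tau_max > 0):
            raise FitError("calibration endpoints must be positive")
        if self.tau_max <= self.tau_min:
            raise FitError("require tau_max > tau_min")
        if self.hill_slope == 0:
            raise FitError("hill_slope must be non-zero")

    def tau_at(self, ca) -> np.ndarray:
        """Model tau at free Ca2+ ``ca`` (µM; 0 maps to the tau_max endpoint)."""
        ca = np.asarray(ca, dtype=float)
        with np.errstate(divide="ignore"):
            c = np.log10(ca)
        return _logistic(c, self.log_ec50, self.hill_slope, self.tau_min, self.tau_max)

    def to_dict(self) -> dict:
        return {
            "tau_max": self.tau_max,
            "tau_min": self.tau_min,
            "log_ec50": self.log_ec50,
            "hill_slope": self.hill_slope,
            "endpoints_fixed": self.endpoints_fixed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**d)


class InversionResult(NamedTuple):
    ca: float  # µM (relative scale)
    clamped: bool


@dataclass(frozen=True)
class BindingFit:
    """Hill-isotherm fit of an equilibrium titration, with standard errors."""

    kd: float
    hill_n: float
    sat_signal: float
    base_signal: float
    kd_se: float
    hill_n_se: float
    sat_se: float
    base_se: float


def _logistic(c, log_ec50, h, tau_min, tau_max):
    w = 1.0 / (1.0 + 10.0 ** ((np.asarray(c, dtype=float) - log_ec50) * h))
    return tau_min + (tau_max - tau_min) * w


def _solve_anchored(c1, t1, c2, t2, log_ec50, h):
    """tau_min/tau_max such that the curve passes through both anchors."""
    if np.isneginf(c1):
        w1 = 1.0 if h > 0 else 0.0
    else:
        w1 = 1.0 / (1.0 + 10.0 ** ((c1 - log_ec50) * h))
    w2 = 1.0 / (1.0 + 10.0 ** ((c2 - log_ec50) * h))
    det = w1 - w2
    if abs(det) < 1e-12:
        return None
    # tau = tau_min (1 - w) + tau_max w  at the two anchors
    tau_max = (t1 * (1.0 - w2) - t2 * (1.0 - w1)) / det
    tau_min = (t2 * w1 - t1 * w2) / det
    return tau_min, tau_max


def fit_dose_response(
    tau_by_ca: Sequence[tuple[float, float]],
    fix_from: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Fit the dose-response model to (ca µM, tau s) pairs.

    With ``fix_from=(ca_lo, ca_hi)`` the curve is constrained to pass
    exactly through the measured tau at those two concentrations (``ca_lo``
    may be 0, pinning the zero-Ca2+ asymptote) and only (log_ec50,
    hill_slope) are fitted.  Without it, all four parameters are free and a
    0 µM sample is not representable.
    """
    pairs = [(float(ca), float(tau)) for ca, tau in tau_by_ca]
    ca = np.array([p[0] for p in pairs])
    tau = np.array([p[1] for p in pairs])
    if np.any(ca < 0) or np.any(tau <= 0):
        raise ValueError("need ca >= 0 and tau > 0")
    pos = ca > 0
    if pos.sum() < 4:
        raise InsufficientDataError("need >= 4 positive concentration points")
    if ca[pos].max() / ca[pos].min() <= 10.0:
        raise RangeError("concentrations must span more than one decade")
    if float(np.ptp(tau)) < 1e-9 * (1.0 + float(np.mean(tau))):
        raise UnidentifiableError("tau does not vary across concentrations")
    if np.any(~pos) and fix_from is None:
        raise ConfigurationError(
            "a 0 µM sample requires endpoint fixing (fix_from)"
        )

    with np.errstate(divide="ignore"):
        c = np.log10(ca)

    # initial guesses from the data
    slope_sign = 1.0 if tau[pos][np.argsort(c[pos])][0] >= tau[pos][np.argsort(c[pos])][-1] else -1.0
    le0 = float(np.median(c[pos]))

    if fix_from is None:
        def model(c, le, h, tmin, tmax):
            return _logistic(c, le, h, tmin, tmax)

        p0 = [le0, slope_sign, float(tau.min()), float(tau.max())]
        try:
            popt, _ = curve_fit(model, c, tau, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"dose-response fit did not converge: {exc}") from exc
        le, h, tmin, tmax = popt
        if tmax < tmin:
            # re-express with tau_max as the larger endpoint, flipping slope
            tmin, tmax, h = tmax, tmin, -h
        return CalibrationModel(float(tmax), float(tmin), float(le), float(h), False)

    ca_lo, ca_hi = fix_from
    t_lo = _measured_at(ca, tau, ca_lo)
    t_hi = _measured_at(ca, tau, ca_hi)
    c_lo = -np.inf if ca_lo == 0 else math.log10(ca_lo)
    c_hi = math.log10(ca_hi)
    if abs(t_lo - t_hi) < 1e-9 * (1.0 + abs(t_lo)):
        raise UnidentifiableError("endpoint taus coincide; flat response")

    free = pos & ~(np.isclose(ca, ca_lo) | np.isclose(ca, ca_hi))
    c_free, tau_free = c[free], tau[free]
    scale = abs(t_lo - t_hi)

    def resid(params):
        le, h = params
        sol = _solve_anchored(c_lo, t_lo, c_hi, t_hi, le, h)
        if sol is None:
            return np.full(max(len(c_free), 2), 1e6 * scale)
        tmin, tmax = sol
        r = _logistic(c_free, le, h, tmin, tmax) - tau_free
        if len(r) < 2:  # keep the solver happy with >= #params residuals
            r = np.concatenate([r, [0.0] * (2 - len(r))])
        return r

    best = None
    for h0 in (slope_sign, 2.0 * slope_sign):
        sol = least_squares(resid, x0=[le0, h0], method="lm", max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol
    le, h = best.x
    anchored = _solve_anchored(c_lo, t_lo, c_hi, t_hi, le, h)
    if anchored is None:
        raise FitError("dose-response fit did not converge (degenerate slope)")
    tmin, tmax = anchored
    if tmax < tmin:
        tmin, tmax, h = tmax, tmin, -h
    return CalibrationModel(float(tmax), float(tmin), float(le), float(h), True)


def _measured_at(ca: np.ndarray, tau: np.ndarray, target: float) -> float:
    hit = np.isclose(ca, target, rtol=1e-9, atol=1e-12)
    if not hit.any():
        raise ValueError(f"no measured tau at ca = {target} µM")
    return float(tau[hit].mean())


def invert_tau(calib: CalibrationModel, tau: float) -> InversionResult:
    """Closed-form inversion of the dose-response: tau (s) -> free Ca2+ (µM).

    tau outside the open interval (tau_min, tau_max) clamps to the
    corresponding concentration endpoint (0 at the slow end, infinity at the
    saturating end for a decreasing response) with ``clamped=True``.
    """
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    decreasing = calib.hill_slope > 0
    if tau >= calib.tau_max:
        return InversionResult(0.0 if decreasing else math.inf, True)
    if tau <= calib.tau_min:
        return InversionResult(math.inf if decreasing else 0.0, True)
    ratio = (calib.tau_max - tau) / (tau - calib.tau_min)
    ca = 10.0 ** (calib.log_ec50 + math.log10(ratio) / calib.hill_slope)
    return InversionResult(float(ca), False)


def fit_binding(titration: TitrationTable) -> BindingFit:
    """Hill-isotherm fit of an equilibrium titration.

    Model: ``S(ca) = base + (sat - base) * ca**n / (kd**n + ca**n)``.
    Standard errors come from the linearised covariance (Jacobian).  Raises
    :class:`UnidentifiableError` when the data contain no transition.
    """
    ca = titration.ca
    y = titration.mean_signal
    if len(ca) < 5:
        raise InsufficientDataError("need at least 5 titration points")
    span = float(np.ptp(y))
    if span < 1e-12 * (1.0 + float(np.mean(np.abs(y)))):
        raise UnidentifiableError("titration signal is flat; no transition")

    def model(x, kd, n, sat, base):
        return base + (sat - base) * hill_fraction(x, kd, n)

    base0, sat0 = float(y[0]), float(y[-1])
    half = 0.5 * (base0 + sat0)
    pos = ca > 0
    kd0 = float(np.interp(half, y[pos], ca[pos])) if sat0 > base0 else float(
        np.interp(half, y[pos][::-1], ca[pos][::-1])
    )
    kd0 = min(max(kd0, ca[pos].min()), ca[pos].max())
    try:
        popt, pcov = curve_fit(
            model, ca, y, p0=[kd0, 1.0, sat0, base0],
            bounds=([1e-12, 0.05, -np.inf, -np.inf], [np.inf, 20.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise UnidentifiableError(f"binding fit did not converge: {exc}") from exc
    kd, n, sat, base = popt
    lo, hi = ca[pos].min(), ca[pos].max()
    if not (lo / 100.0 <= kd <= hi * 100.0):
        raise UnidentifiableError(
            f"fitted Kd = {kd:.3g} µM lies far outside the titrated range"
        )
    se = np.sqrt(np.diag(pcov))
    return BindingFit(
        kd=float(kd), hill_n=float(n), sat_signal=float(sat), base_signal=float(base),
        kd_se=float(se[0]), hill_n_se=float(se[1]), sat_se=float(se[2]),
        base_se=float(se[3]),
    )
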