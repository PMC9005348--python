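"""Forward model of Ca2+-dependent photo-switching and bulk-kinetics fitting.

A reversibly switchable genetically encoded Ca2+ indicator (rsGEI) is
fluorescent/absorbing only in its Ca2+-bound state.  488-nm light drives the
bound sensor into a dark OFF state; 405/420-nm light switches it back ON.
Bulk OFF-switching of an ensemble is a mixture of (at least) two exponential
species whose proportions depend on Ca2+ occupancy, so the effective decay
constant of the bulk signal encodes the free Ca2+ concentration.

This module holds the sensor/illumination domain types, the seeded trace
simulator, and the exponential/biexponential fitting routines applied to
switching traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize

from .errors import (
    AlignmentError,
    InsufficientDataError,
    ParameterError,
    ScheduleError,
)

__all__ = [
    "SensorModel",
    "Phase",
    "IlluminationSchedule",
    "SwitchingTrace",
    "DecayFit",
    "BiexpFit",
    "hill_fraction",
    "simulate_trace",
    "fit_exponential",
    "effective_tau",
    "global_biexp",
    "global_single_exp",
    "measure_fatigue",
    "average_off_cycles",
    "off_sample_mask",
]

# Solver settings for all least-squares fits in this module.
_MAXFEV = 10_000
_FTOL = 1e-10

_ON_WAVELENGTHS = (405, 420)
_OFF_WAVELENGTH = 488


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorModel:
    """Photophysical and binding parameters of one sensor variant.

    Parameters
    ----------
    kd : float
        Dissociation constant, µM.
    hill_n : float
        Hill coefficient of the binding isotherm (dimensionless).
    brightness : float
        Signal scale of the Ca2+-bound ON state, a.u.
    eps_free : float
        Relative brightness of the Ca2+-free state (fraction of
        ``brightness``).  The free state does not photo-switch.
    sigma_fast, sigma_slow : float
        OFF-switching rate per unit 488-nm intensity for the fast/slow
        switchable species, s^-1 per intensity a.u.
    sigma_on : float
        ON-switching rate per unit 405/420-nm intensity, s^-1 per a.u.
    fatigue_per_cycle : float
        Fractional irreversible loss of switchable signal per full
        OFF/ON cycle.
    dark_offset : float
        Non-modulating residual signal, a.u. (detector/background offset).
    """

    kd: float
    hill_n: float = 1.0
    brightness: float = 100.0
    eps_free: float = 0.1
    sigma_fast: float = 1.0
    sigma_slow: float = 0.3
    sigma_on: float = 5.0
    fatigue_per_cycle: float = 0.0
    dark_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ParameterError(f"kd must be positive, got {self.kd}")
        if not self.hill_n > 0:
            raise ParameterError(f"hill_n must be positive, got {self.hill_n}")
        if not 0.0 <= self.eps_free <= 1.0:
            raise ParameterError(f"eps_free must be in [0, 1], got {self.eps_free}")
        if not (self.sigma_fast >= self.sigma_slow >= 0.0):
            raise ParameterError(
                "require sigma_fast >= sigma_slow >= 0, got "
                f"{self.sigma_fast}, {self.sigma_slow}"
            )
        if self.sigma_on < 0:
            raise ParameterError("sigma_on must be non-negative")
        if not 0.0 <= self.fatigue_per_cycle < 1.0:
            raise ParameterError(
                f"fatigue_per_cycle must be in [0, 1), got {self.fatigue_per_cycle}"
            )

    def bound_fraction(self, ca: float) -> float:
        """Equilibrium Ca2+ occupancy at free concentration ``ca`` (µM)."""
        return float(hill_fraction(ca, self.kd, self.hill_n))


@dataclass(frozen=True)
class Phase:
    """One illumination phase: a pulse train at a single wavelength."""

    wavelength: int  # nm, one of 488 / 420 / 405
    intensity: float  # a.u.; switching rates scale linearly with it
    n_pulses: int
    pulse_rate: float = 10.0  # Hz

    def __post_init__(self) -> None:
        if self.wavelength not in (488, 420, 405):
            raise ScheduleError(f"unsupported wavelength {self.wavelength} nm")
        if self.n_pulses < 1:
            raise ScheduleError("n_pulses must be >= 1")
        if not self.pulse_rate > 0:
            raise ScheduleError("pulse_rate must be positive")
        if self.intensity < 0:
            raise ScheduleError("intensity must be non-negative")

    @property
    def duration(self) -> float:
        return self.n_pulses / self.pulse_rate

    @property
    def is_off_switching(self) -> bool:
        return self.wavelength == _OFF_WAVELENGTH


@dataclass(frozen=True)
class IlluminationSchedule:
    """Ordered 488/420-nm pulse phases repeated over ``n_cycles`` cycles.

    The schedule defines the time base of every trace and stack: samples are
    laid on the pulse grid (pulse index / pulse rate) and averaged in blocks
    of ``pulses_per_frame`` consecutive pulses into frames.
    """

    phases: tuple[Phase, ...]
    n_cycles: int = 1
    pulses_per_frame: int = 1

    def __post_init__(self) -> None:
        if len(self.phases) == 0:
            raise ScheduleError("schedule has no phases")
        object.__setattr__(self, "phases", tuple(self.phases))
        if self.n_cycles < 1:
            raise ScheduleError("n_cycles must be >= 1")
        if self.pulses_per_frame < 1:
            raise ScheduleError("pulses_per_frame must be >= 1")
        for ph in self.phases:
            if ph.n_pulses % self.pulses_per_frame:
                raise ScheduleError(
                    f"pulses_per_frame={self.pulses_per_frame} does not divide "
                    f"phase pulse count {ph.n_pulses}"
                )

    @property
    def pulses_per_cycle(self) -> int:
        return sum(ph.n_pulses for ph in self.phases)

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.pulses_per_cycle // self.pulses_per_frame

    @property
    def cycle_duration(self) -> float:
        return sum(ph.duration for ph in self.phases)

    def frame_table(self) -> "FrameTable":
        return _frame_table(self)


@dataclass(frozen=True)
class FrameTable:
    """Per-frame annotation derived from an :class:`IlluminationSchedule`.

    ``t`` holds the mean pulse time of each frame; ``phase_global`` counts
    phases across cycles (cycle * len(phases) + phase index).
    """

    t: np.ndarray
    phase_global: np.ndarray
    phase_index: np.ndarray
    cycle: np.ndarray
    wavelength: np.ndarray
    is_off: np.ndarray


@lru_cache(maxsize=64)
def _frame_table(schedule: IlluminationSchedule) -> FrameTable:
    ts, wl, cyc, pidx, pglob = [], [], [], [], []
    t0 = 0.0
    for c in range(schedule.n_cycles):
        for j, ph in enumerate(schedule.phases):
            tp = t0 + np.arange(ph.n_pulses) / ph.pulse_rate
            ts.append(tp)
            wl.append(np.full(ph.n_pulses, ph.wavelength, dtype=int))
            cyc.append(np.full(ph.n_pulses, c, dtype=int))
            pidx.append(np.full(ph.n_pulses, j, dtype=int))
            pglob.append(np.full(ph.n_pulses, c * len(schedule.phases) + j, dtype=int))
            t0 += ph.duration
    ppf = schedule.pulses_per_frame
    t = np.concatenate(ts).reshape(-1, ppf).mean(axis=1)
    take = slice(0, None, ppf)  # frames never straddle phases (validated)
    wavelength = np.concatenate(wl)[take]
    return FrameTable(
        t=t,
        phase_global=np.concatenate(pglob)[take],
        phase_index=np.concatenate(pidx)[take],
        cycle=np.concatenate(cyc)[take],
        wavelength=wavelength,
        is_off=wavelength == _OFF_WAVELENGTH,
    )


@dataclass
class SwitchingTrace:
    """A (time, signal) series with per-sample phase labels."""

    t: np.ndarray
    s: np.ndarray
    phase_id: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.phase_id = np.asarray(self.phase_id, dtype=int)
        if not (len(self.t) == len(self.s) == len(self.phase_id)):
            raise ValueError("t, s and phase_id must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class DecayFit:
    """Result of a single-exponential fit ``A * exp(-t/tau) + y0``."""

    tau: float
    amplitude: float
    y0: float
    y0_fixed: bool
    r2: float
    valid: bool


@dataclass(frozen=True)
class BiexpFit:
    """Result of a global biexponential fit with shared rates.

    ``amps`` holds one ``(A_fast, A_slow, offset)`` triple per trace.
    """

    k_fast: float
    k_slow: float
    amps: tuple[tuple[float, float, float], ...]
    residual: float
    single_exp_residual: float


# ---------------------------------------------------------------------------
# binding isotherm
# ---------------------------------------------------------------------------


def hill_fraction(ca, kd: float, n: float):
    """Equilibrium bound fraction of a single-site Hill isotherm.

    ``ca^n / (kd^n + ca^n)``, evaluated stably for large ``ca``.  ``ca`` may
    be a scalar or array (µM); ``kd`` (µM) and ``n`` must be positive.
    """
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0):
        raise ParameterError("ca must be non-negative")
    if not kd > 0:
        raise ParameterError("kd must be positive")
    if not n > 0:
        raise ParameterError("hill coefficient must be positive")
    r = (ca_arr / kd) ** n
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    if np.isscalar(ca) or ca_arr.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------


def simulate_trace(
    sensor: SensorModel,
    schedule: IlluminationSchedule,
    ca: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    intensity_scale: float = 1.0,
) -> SwitchingTrace:
    """Simulate the bulk switching signal of a sensor under a pulse schedule.

    The Ca2+-bound pool (Hill fraction ``f``) is switchable and is itself a
    mixture of a fast and a slow species with hill-weighted mixing
    ``alpha = f``; during 488-nm phases each species decays exponentially at
    ``sigma * intensity``, during 405/420-nm phases both recover at
    ``sigma_on * intensity``.  The free pool contributes a constant dim
    signal ``eps_free * (1 - f) * brightness``; ``dark_offset`` is additive.
    The switchable amplitude shrinks by ``fatigue_per_cycle`` at every
    ON->OFF phase boundary after the first.

    ``intensity_scale`` multiplies all phase intensities (used for local
    fluence in phantoms).  One sample per frame (pulse-block average);
    additive Gaussian noise of ``noise_sd`` is applied per frame.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    f = sensor.bound_fraction(ca)
    alpha = f
    static = sensor.eps_free * (1.0 - f) * sensor.brightness + sensor.dark_offset

    x_fast = 1.0  # ON occupancy of each switchable species
    x_slow = 1.0
    amp = 1.0  # cumulative fatigue factor
    prev_on = False

    pulse_vals = []
    for _ in range(schedule.n_cycles):
        for ph in schedule.phases:
            inten = ph.intensity * intensity_scale
            tp = np.arange(ph.n_pulses) / ph.pulse_rate
            if ph.is_off_switching:
                if prev_on:
                    amp *= 1.0 - sensor.fatigue_per_cycle
                df = np.exp(-sensor.sigma_fast * inten * tp)
                ds = np.exp(-sensor.sigma_slow * inten * tp)
                sw = alpha * x_fast * df + (1.0 - alpha) * x_slow * ds
                x_fast *= math.exp(-sensor.sigma_fast * inten * ph.duration)
                x_slow *= math.exp(-sensor.sigma_slow * inten * ph.duration)
                prev_on = False
            else:
                rec = np.exp(-sensor.sigma_on * inten * tp)
                xf = 1.0 - (1.0 - x_fast) * rec
                xs = 1.0 - (1.0 - x_slow) * rec
                sw = alpha * xf + (1.0 - alpha) * xs
                end = math.exp(-sensor.sigma_on * inten * ph.duration)
                x_fast = 1.0 - (1.0 - x_fast) * end
                x_slow = 1.0 - (1.0 - x_slow) * end
                prev_on = True
            pulse_vals.append(amp * sensor.brightness * f * sw + static)

    signal = np.concatenate(pulse_vals).reshape(-1, schedule.pulses_per_frame)
    signal = signal.mean(axis=1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    ft = schedule.frame_table()
    return SwitchingTrace(
        t=ft.t.copy(),
        s=signal,
        phase_id=ft.phase_global.copy(),
        meta={"ca": float(ca), "source": "simulate_trace", "seed": seed},
    )


# ---------------------------------------------------------------------------
# phase extraction helpers
# ---------------------------------------------------------------------------


def off_sample_mask(trace: SwitchingTrace, schedule: IlluminationSchedule) -> np.ndarray:
    """Boolean mask of the samples lying in 488-nm (OFF-switching) phases."""
    n_ph = len(schedule.phases)
    wl = np.array([schedule.phases[g % n_ph].wavelength for g in trace.phase_id])
    return wl == _OFF_WAVELENGTH


def average_off_cycles(
    trace: SwitchingTrace, schedule: IlluminationSchedule
) -> SwitchingTrace:
    """Average the aligned 488-nm phases of all cycles into one decay trace.

    Returns a trace whose time axis is relative to the first OFF sample of a
    cycle.  Requires every cycle to contain the same number of OFF samples.
    """
    mask = off_sample_mask(trace, schedule)
    if not mask.any():
        raise InsufficientDataError("trace contains no 488-nm samples")
    n_ph = len(schedule.phases)
    cycles = trace.phase_id[mask] // n_ph
    t_off = trace.t[mask]
    s_off = trace.s[mask]
    n_cycles = int(cycles.max()) + 1
    per_cycle = np.bincount(cycles, minlength=n_cycles)
    if len(np.unique(per_cycle)) != 1:
        raise AlignmentError("cycles contain different numbers of OFF samples")
    length = per_cycle[0]
    s_avg = s_off.reshape(n_cycles, length).mean(axis=0)
    t_rel = t_off[:length] - t_off[0]
    return SwitchingTrace(
        t=t_rel,
        s=s_avg,
        phase_id=np.zeros(length, dtype=int),
        meta={**trace.meta, "cycles_averaged": n_cycles},
    )


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------


def _noise_floor(s: np.ndarray) -> float:
    """Amplitude validity floor: 3x a noise-sd estimate from the median
    absolute deviation of first differences (white noise: sd(diff) = sd*sqrt2)."""
    d = np.diff(s)
    mad = np.median(np.abs(d - np.median(d)))
    return 3.0 * 1.4826 * mad / math.sqrt(2.0)


def fit_exponential(
    t: np.ndarray,
    s: np.ndarray,
    y0_fixed: float | None = None,
    amplitude_floor: float | None = None,
) -> DecayFit:
    """Least-squares fit of ``A * exp(-t/tau) + y0`` to a decay trace.

    ``y0`` is free unless ``y0_fixed`` is given.  The fit is flagged
    ``valid=False`` (never an exception) when the amplitude is below the
    validity floor or the optimiser fails; the floor defaults to 3x the
    trace noise estimate.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(t) < 4:
        raise InsufficientDataError("need at least 4 samples for an exponential fit")
    fixed = y0_fixed is not None
    floor = _noise_floor(s) if amplitude_floor is None else float(amplitude_floor)
    invalid = DecayFit(np.nan, 0.0, y0_fixed if fixed else np.nan, fixed, np.nan, False)

    span = float(np.ptp(s))
    if span <= max(floor, 1e-12 * (1.0 + float(np.max(np.abs(s))))):
        return invalid

    tt = t - t[0]
    y0g = float(y0_fixed) if fixed else float(s[-1])
    a0 = float(s[0]) - y0g
    tau0 = _tau_init(tt, s - y0g) or (tt[-1] / 3.0)

    try:
        if fixed:
            def model(x, a, tau):
                return a * np.exp(-x / tau) + y0_fixed

            p0 = [a0 if a0 != 0 else span, tau0]
            popt, _ = curve_fit(
                model, tt, s, p0=p0,
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                maxfev=_MAXFEV, ftol=_FTOL, xtol=_FTOL,
            )
            a, tau = popt
            y0 = float(y0_fixed)
        else:
            def model(x, a, tau, y0):
                return a * np.exp(-x / tau) + y0

            p0 = [a0 if a0 != 0 else span, tau0, y0g]
            popt, _ = curve_fit(
                model, tt, s, p0=p0,
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=_MAXFEV, ftol=_FTOL, xtol=_FTOL,
            )
            a, tau, y0 = popt
    except (RuntimeError, ValueError):
        return invalid

    resid = s - (a * np.exp(-tt / tau) + y0)
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    valid = abs(a) > floor and np.isfinite(tau) and tau > 0
    if not valid:
        return invalid
    return DecayFit(float(tau), float(a), float(y0), fixed, r2, True)


def _tau_init(tt: np.ndarray, y: np.ndarray) -> float | None:
    """Log-linear decay-time estimate from the positive part of ``y``."""
    sign = 1.0 if y[0] >= 0 else -1.0
    yy = sign * y
    pos = yy > max(1e-12, 1e-6 * float(np.max(np.abs(yy))))
    if pos.sum() < 3:
        return None
    slope = np.polyfit(tt[pos], np.log(yy[pos]), 1)[0]
    if slope >= 0:
        return None
    return -1.0 / slope


def effective_tau(
    trace: SwitchingTrace,
    y0_fixed: float | None = None,
    amplitude_floor: float | None = None,
) -> DecayFit:
    """Single-exponential decay constant of one OFF-switching trace.

    The trace must already be restricted to a single 488-nm phase (or be a
    cycle average from :func:`average_off_cycles`).
    """
    return fit_exponential(trace.t, trace.s, y0_fixed, amplitude_floor)


# ---------------------------------------------------------------------------
# global biexponential fitting (variable projection)
# ---------------------------------------------------------------------------


def _design_cost(ks: Sequence[float], t: np.ndarray, S: np.ndarray):
    cols = [np.exp(-k * t) for k in ks] + [np.ones_like(t)]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, S.T, rcond=None)
    R = S.T - X @ coef
    return float(np.sum(R * R)), coef


def _check_alignment(traces: Sequence[SwitchingTrace]) -> tuple[np.ndarray, np.ndarray]:
    t0 = traces[0].t
    for tr in traces[1:]:
        if len(tr.t) != len(t0) or not np.allclose(tr.t, t0, rtol=1e-9, atol=1e-12):
            raise AlignmentError("traces do not share a common time base")
    S = np.vstack([tr.s for tr in traces])
    return t0 - t0[0], S


def global_single_exp(traces: Sequence[SwitchingTrace]) -> tuple[float, float]:
    """Best shared-rate single-exponential fit; returns ``(k, residual)``."""
    t, S = _check_alignment(traces)
    span = t[-1] - t[0]
    grid = np.geomspace(0.05 / span, 200.0 / span, 200)
    costs = [_design_cost([k], t, S)[0] for k in grid]
    k0 = grid[int(np.argmin(costs))]
    res = minimize(
        lambda p: _design_cost([math.exp(p[0])], t, S)[0],
        x0=[math.log(k0)],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
    )
    k = math.exp(res.x[0])
    return k, _design_cost([k], t, S)[0]


def global_biexp(traces: Sequence[SwitchingTrace]) -> BiexpFit:
    """Global biexponential fit with rates shared across all traces.

    Per-trace amplitudes and offsets are projected out analytically, so the
    non-linear search runs over the two shared rates only.  The biexponential
    residual is never larger than that of the best global single-exponential
    fit (the single-exponential is nested at equal rates).
    """
    if len(traces) < 2:
        raise InsufficientDataError("global fit needs at least 2 traces")
    t, S = _check_alignment(traces)
    k_single, cost_single = global_single_exp(traces)

    def cost(logks):
        return _design_cost(np.exp(logks), t, S)[0]

    best_x = np.log([k_single, k_single * (1.0 + 1e-9)])
    best_c = cost(best_x)  # nested single-exp point
    for ratio in (1.5, 4.0, 10.0):
        x0 = np.log([k_single * ratio, k_single / ratio])
        res = minimize(
            cost, x0=x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        if res.fun < best_c:
            best_c, best_x = res.fun, res.x
    # polish from the best point
    res = minimize(
        cost, x0=best_x, method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 4000},
    )
    if res.fun < best_c:
        best_c, best_x = res.fun, res.x

    k1, k2 = np.exp(best_x)
    final_cost, coef = _design_cost([k1, k2], t, S)
    if k1 < k2:
        k1, k2 = k2, k1
        coef = coef[[1, 0, 2], :]
    amps = tuple(
        (float(coef[0, j]), float(coef[1, j]), float(coef[2, j]))
        for j in range(S.shape[0])
    )
    residual = min(final_cost, cost_single)
    return BiexpFit(float(k1), float(k2), amps, residual, cost_single)


# ---------------------------------------------------------------------------
# photo-fatigue
# ---------------------------------------------------------------------------


def measure_fatigue(trace: SwitchingTrace, schedule: IlluminationSchedule) -> float:
    """Per-cycle fractional loss of switching amplitude.

    Fits the per-cycle OFF-phase amplitudes with a geometric decay
    ``A_c = A_0 (1 - q)^c`` and returns ``q`` in [0, 1).
    """
    mask = off_sample_mask(trace, schedule)
    n_ph = len(schedule.phases)
    cycles = trace.phase_id[mask] // n_ph
    n_cycles = int(cycles.max()) + 1 if mask.any() else 0
    if n_cycles < 3:
        raise InsufficientDataError("need at least 3 full cycles to measure fatigue")

    amps = []
    t_off = trace.t[mask]
    s_off = trace.s[mask]
    for c in range(n_cycles):
        sel = cycles == c
        tc, sc = t_off[sel], s_off[sel]
        fit = fit_exponential(tc, sc)
        amps.append(abs(fit.amplitude) if fit.valid else float(np.ptp(sc)))
    amps = np.asarray(amps)
    if np.any(amps <= 0):
        raise InsufficientDataError("non-positive cycle amplitude; cannot fit fatigue")
    slope = np.polyfit(np.arange(n_cycles), np.log(amps), 1)[0]
    q = 1.0 - math.exp(min(slope, 0.0))
    return min(max(q, 0.0), 1.0 - 1e-15)


# ---------------------------------------------------------------------------
# presets: the sensor variants and schedules the analyses are built around
# ---------------------------------------------------------------------------


def er_sensor(**overrides) -> SensorModel:
    """ER-targeted variant: Kd = 72 µM, suited to the ~500 µM ER lumen."""
    params = dict(
        kd=72.0, hill_n=1.0, brightness=100.0, eps_free=0.1,
        sigma_fast=1.0, sigma_slow=0.3, sigma_on=5.0,
        fatigue_per_cycle=0.005, dark_offset=0.5,
    )
    params.update(overrides)
    return SensorModel(**params)


def oa_sensor(**overrides) -> SensorModel:
    """Cytosolic-affinity variant used in the tomography experiments.

    Kd = 0.35 µM places the transition inside the 0-39 µM span of the
    Ca2+-calibration buffer series.
    """
    params = dict(
        kd=0.35, hill_n=1.0, brightness=100.0, eps_free=0.1,
        sigma_fast=1.0, sigma_slow=0.3, sigma_on=5.0,
        fatigue_per_cycle=0.005, dark_offset=0.5,
    )
    params.update(overrides)
    return SensorModel(**params)


def tomography_schedule(
    pulses_per_frame: int = 3, n_cycles: int = 10, intensity: float = 1.0
) -> IlluminationSchedule:
    """Ten cycles of 120 pulses at 488 nm plus 120 pulses at 420 nm, 10 Hz."""
    return IlluminationSchedule(
        phases=(
            Phase(488, intensity, 120, 10.0),
            Phase(420, intensity, 120, 10.0),
        ),
        n_cycles=n_cycles,
        pulses_per_frame=pulses_per_frame,
    )


def spectrometer_schedule(
    n_pulses: int = 240, intensity: float = 1.0
) -> IlluminationSchedule:
    """Single 488-nm decay recording at 10 Hz (spectrometer measurement)."""
    return IlluminationSchedule(
        phases=(Phase(488, intensity, n_pulses, 10.0),),
        n_cycles=1,
        pulses_per_frame=1,
    )
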