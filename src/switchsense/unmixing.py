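"""Per-pixel temporal unmixing of photo-switchable optoacoustic stacks.

Two measures identify pixels carrying photo-switchable signal: the relative
magnitude of the switching-cycle frequency in the pixel's Fourier spectrum
(a lock-in-style score) and the goodness of an exponential fit to the
cycle-averaged 488-nm decay.  Masked pixels are then fitted with a
fixed-offset exponential to produce a decay-constant (tau) map, the
Ca2+-encoding observable.  A proportional ON-OFF difference unmixer covers
the raster-scan mesoscopy readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, InsufficientDataError
from .kinetics import SwitchingTrace, fit_exponential
from .synth import ImageTimeSeries

__all__ = [
    "SwitchScoreMaps",
    "TauMap",
    "fourier_switch_score",
    "classify_pixels",
    "reference_offset",
    "fit_pixel_kinetics",
    "on_off_difference",
    "cycle_averaged_off",
]


@dataclass
class SwitchScoreMaps:
    """Per-pixel classification maps: Fourier score, fit r2 and the mask."""

    fourier_score: np.ndarray
    r2: np.ndarray
    mask: np.ndarray


@dataclass
class TauMap:
    """Per-pixel decay constant (s) and fitted amplitude; NaN outside mask."""

    tau: np.ndarray
    amplitude: np.ndarray


def _frame_values(trace_or_values) -> np.ndarray:
    if isinstance(trace_or_values, SwitchingTrace):
        return trace_or_values.s
    return np.asarray(trace_or_values, dtype=float)


def fourier_switch_score(trace_or_values, schedule) -> float:
    """Relative spectral weight of the switching-cycle frequency, in [0, 1].

    The per-frame signal is mean-subtracted and Fourier transformed; the
    score is the magnitude at the cycle frequency (``n_cycles`` periods over
    the record) divided by the summed magnitude of all non-zero frequencies.
    A constant trace scores 0.
    """
    if schedule.n_cycles < 2:
        raise InsufficientDataError("need at least 2 full cycles for the score")
    s = _frame_values(trace_or_values)
    if len(s) != schedule.n_frames:
        raise InsufficientDataError(
            f"trace has {len(s)} frames, schedule defines {schedule.n_frames}"
        )
    mag = np.abs(np.fft.rfft(s - s.mean()))
    denom = float(mag[1:].sum())
    if denom <= 1e-12 * (1.0 + float(np.abs(s).max())) * len(s):
        return 0.0
    return float(mag[schedule.n_cycles] / denom)


def cycle_averaged_off(stack: ImageTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Average the aligned 488-nm phases of all cycles, for every pixel.

    Returns ``(t_rel, data)`` where ``t_rel`` has shape [L] (seconds from
    the start of the OFF phase) and ``data`` has shape [L, H, W].
    """
    ft = stack.schedule.frame_table()
    idx = np.where(ft.is_off)[0]
    if idx.size == 0:
        raise InsufficientDataError("schedule contains no 488-nm frames")
    n_cycles = stack.schedule.n_cycles
    if idx.size % n_cycles:
        raise InsufficientDataError("OFF frames are not aligned across cycles")
    length = idx.size // n_cycles
    data = stack.frames[idx].reshape(n_cycles, length, *stack.frames.shape[1:])
    avg = data.mean(axis=0, dtype=np.float64)
    t_rel = ft.t[idx[:length]] - ft.t[idx[0]]
    return t_rel, avg


def classify_pixels(
    stack: ImageTimeSeries,
    theta_f: float = 0.2,
    theta_r: float = 0.8,
    switchable_r2_high: bool = True,
) -> SwitchScoreMaps:
    """Classify pixels as photo-switchable by two measures.

    A pixel enters the mask when its Fourier switch score is at least
    ``theta_f`` AND the r2 of a free-offset exponential fit to its
    cycle-averaged 488-nm decay passes ``theta_r``.  By default switchable
    pixels must fit the exponential well (r2 >= theta_r); set
    ``switchable_r2_high=False`` for the opposite polarity (r2 <= theta_r).
    Per-pixel fit failures are recorded as NaN / excluded, never raised.
    """
    if not (0.0 <= theta_f <= 1.0 and 0.0 <= theta_r <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    frames = stack.frames.astype(np.float64, copy=False)
    n_cycles = stack.schedule.n_cycles
    if n_cycles < 2:
        raise InsufficientDataError("need at least 2 cycles to classify pixels")

    mag = np.abs(np.fft.rfft(frames - frames.mean(axis=0), axis=0))
    denom = mag[1:].sum(axis=0)
    tiny = 1e-12 * (1.0 + np.abs(frames).max()) * frames.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(denom > tiny, mag[n_cycles] / denom, 0.0)

    r2 = np.full(score.shape, np.nan)
    candidates = score >= theta_f
    t_rel, avg = cycle_averaged_off(stack)
    for row, col in np.argwhere(candidates):
        fit = fit_exponential(t_rel, avg[:, row, col])
        if fit.valid:
            r2[row, col] = fit.r2
    with np.errstate(invalid="ignore"):
        passes_r2 = (r2 >= theta_r) if switchable_r2_high else (r2 <= theta_r)
    mask = candidates & np.isfinite(r2) & passes_r2
    return SwitchScoreMaps(fourier_score=score, r2=r2, mask=mask)


def _roi_mask(stack: ImageTimeSeries, roi) -> np.ndarray:
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != stack.frames.shape[1:]:
            raise ValueError("roi mask shape does not match the stack")
        return roi
    row, col, radius = roi
    H, W = stack.frames.shape[1:]
    if not (0 <= row < H and 0 <= col < W):
        raise ValueError("roi centre outside the image")
    rr, cc = np.ogrid[:H, :W]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def reference_offset(stack: ImageTimeSeries, roi) -> float:
    """Fitted exponential offset y0 of the ROI-mean 488-nm decay.

    The ROI should cover the sample with the highest free Ca2+; its fitted
    plateau serves as the fixed offset for all other pixels.  ``roi`` is a
    ``(row, col, radius)`` circle or a boolean mask.  Raises
    :class:`FitError` when the reference fit is not reliable.
    """
    m = _roi_mask(stack, roi)
    if not m.any():
        raise ValueError("roi selects no pixels")
    t_rel, avg = cycle_averaged_off(stack)
    mean_trace = avg[:, m].mean(axis=1)
    fit = fit_exponential(t_rel, mean_trace)
    if not fit.valid:
        raise FitError("reference-offset fit failed; choose a switching ROI")
    return fit.y0


def fit_pixel_kinetics(
    stack: ImageTimeSeries, mask: np.ndarray, y0: float
) -> TauMap:
    """Fixed-offset exponential fit of every masked pixel's averaged decay.

    Returns tau and amplitude maps (NaN outside the mask or where the fit
    is invalid).  ``y0`` is the reference offset shared by all pixels.
    """
    if not np.isfinite(y0):
        raise ValueError("y0 must be finite")
    H, W = stack.frames.shape[1:]
    tau = np.full((H, W), np.nan)
    amp = np.full((H, W), np.nan)
    if not np.any(mask):
        return TauMap(tau=tau, amplitude=amp)
    t_rel, avg = cycle_averaged_off(stack)
    for row, col in np.argwhere(mask):
        fit = fit_exponential(t_rel, avg[:, row, col], y0_fixed=y0)
        if fit.valid:
            tau[row, col] = fit.tau
            amp[row, col] = fit.amplitude
    return TauMap(tau=tau, amplitude=amp)


def on_off_difference(
    on_img: np.ndarray, off_img: np.ndarray, floor: float = 1e-12
) -> np.ndarray:
    """Proportional ON-OFF difference image ``(on - off) / on``.

    Pixels with ``on <= floor`` are set to 0.  Static absorbers (blood)
    cancel exactly; only photo-switching pixels retain contrast.
    """
    on = np.asarray(on_img, dtype=float)
    off = np.asarray(off_img, dtype=float)
    if on.shape != off.shape:
        raise ValueError(f"shape mismatch: {on.shape} vs {off.shape}")
    out = np.zeros_like(on)
    ok = on > floor
    out[ok] = (on[ok] - off[ok]) / on[ok]
    return out
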