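"""Seeded generators emulating the inputs of every analysis stage.

Three experiment types are emulated, each with embedded ground truth:

* fluorescence/absorbance Ca2+ titrations (binding-curve estimation),
* spectrometer OFF-switching decay series over a concentration ladder
  (kinetic calibration), and
* optoacoustic tomography phantoms: tubes of sensor at different free-Ca2+
  concentrations next to blood tubes, under depth-dependent fluence and
  488/420-nm pulse cycling.

All generators are bit-reproducible under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import LayoutError, ParameterError
from .kinetics import (
    IlluminationSchedule,
    SensorModel,
    SwitchingTrace,
    hill_fraction,
    simulate_trace,
    spectrometer_schedule,
    tomography_schedule,
)

__all__ = [
    "Region",
    "PhantomLayout",
    "ImageTimeSeries",
    "TitrationTable",
    "make_titration",
    "make_spectrometer_series",
    "make_phantom_stack",
    "default_layout",
    "calibration_ca_series",
]

#: Free-Ca2+ steps (µM) of an EGTA-buffered calibration ladder spanning the
#: 0-39 µM range; the working series used for kinetic calibration.
calibration_ca_series = (0.038, 0.1, 0.35, 1.35, 4.5, 39.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A circular tube cross-section in the phantom plane."""

    center: tuple[int, int]  # (row, col), pixels
    radius: float  # pixels
    kind: str  # "sensor" | "blood"
    ca: float | None = None  # µM, sensor regions only
    strength: float = 1.0  # a.u.

    def __post_init__(self) -> None:
        if self.kind not in ("sensor", "blood"):
            raise LayoutError(f"unknown region kind {self.kind!r}")
        if not self.radius > 0:
            raise LayoutError("region radius must be positive")
        if self.kind == "sensor":
            if self.ca is None or not np.isfinite(self.ca) or self.ca < 0:
                raise LayoutError("sensor regions need a finite ca >= 0")


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry and optics of a tube phantom.

    ``mu_eff`` is the effective optical attenuation (mm^-1); local fluence
    decays as ``exp(-mu_eff * depth)`` with depth measured from
    ``illum_side`` along the image axis.
    """

    height: int = 128
    width: int = 128
    pixel_size: float = 0.1  # mm per pixel
    regions: tuple[Region, ...] = ()
    mu_eff: float = 0.0  # mm^-1
    illum_side: str = "top"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if self.illum_side not in ("top", "bottom", "left", "right"):
            raise LayoutError(f"unknown illum_side {self.illum_side!r}")
        if self.mu_eff < 0:
            raise LayoutError("mu_eff must be non-negative")
        for reg in self.regions:
            r0, c0 = reg.center
            if (
                r0 - reg.radius < 0
                or r0 + reg.radius > self.height - 1
                or c0 - reg.radius < 0
                or c0 + reg.radius > self.width - 1
            ):
                raise LayoutError(f"region at {reg.center} extends outside the image")

    def region_mask(self, region: Region) -> np.ndarray:
        rr, cc = np.ogrid[: self.height, : self.width]
        r0, c0 = region.center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= region.radius**2

    def depth_map(self) -> np.ndarray:
        """Depth (mm) of each pixel from the illumination side."""
        rows = np.arange(self.height, dtype=float)[:, None]
        cols = np.arange(self.width, dtype=float)[None, :]
        if self.illum_side == "top":
            d = np.broadcast_to(rows, (self.height, self.width))
        elif self.illum_side == "bottom":
            d = np.broadcast_to(self.height - 1 - rows, (self.height, self.width))
        elif self.illum_side == "left":
            d = np.broadcast_to(cols, (self.height, self.width))
        else:
            d = np.broadcast_to(self.width - 1 - cols, (self.height, self.width))
        return d * self.pixel_size

    def fluence_map(self) -> np.ndarray:
        return np.exp(-self.mu_eff * self.depth_map())

    def sensor_mask(self) -> np.ndarray:
        m = np.zeros((self.height, self.width), dtype=bool)
        for reg in self.regions:
            if reg.kind == "sensor":
                m |= self.region_mask(reg)
        return m


@dataclass
class ImageTimeSeries:
    """A frame stack [T, H, W] tied to its illumination schedule."""

    frames: np.ndarray
    schedule: IlluminationSchedule
    layout_truth: PhantomLayout | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a [T, H, W] array")
        if self.frames.shape[0] != self.schedule.n_frames:
            raise ValueError(
                f"stack has {self.frames.shape[0]} frames but the schedule "
                f"defines {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def pixel_trace(self, row: int, col: int) -> SwitchingTrace:
        ft = self.schedule.frame_table()
        return SwitchingTrace(
            t=ft.t.copy(),
            s=self.frames[:, row, col].astype(float),
            phase_id=ft.phase_global.copy(),
            meta={"row": row, "col": col},
        )


@dataclass
class TitrationTable:
    """Replicate-averaged titration: signal versus free Ca2+ (µM)."""

    ca: np.ndarray
    mean_signal: np.ndarray
    sd_signal: np.ndarray
    n_rep: int

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.mean_signal = np.asarray(self.mean_signal, dtype=float)
        self.sd_signal = np.asarray(self.sd_signal, dtype=float)
        if np.any(self.ca < 0):
            raise ParameterError("ca values must be non-negative")
        if np.any(np.diff(self.ca) <= 0):
            raise ParameterError("ca values must be strictly increasing")
        if np.any(self.sd_signal < 0):
            raise ParameterError("sd_signal must be non-negative")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_titration(
    sensor: SensorModel,
    ca_grid: Sequence[float],
    n_rep: int = 3,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> TitrationTable:
    """Simulate an equilibrium fluorescence titration over ``ca_grid`` (µM).

    The noiseless signal is ``dark_offset + brightness * (eps_free +
    (1 - eps_free) * hill_fraction(ca))``; each replicate carries
    multiplicative Gaussian noise with coefficient of variation ``noise_cv``.
    """
    ca = np.asarray(ca_grid, dtype=float)
    if ca.size == 0:
        raise ParameterError("ca_grid must not be empty")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be non-negative")
    if n_rep < 1:
        raise ParameterError("n_rep must be >= 1")
    frac = hill_fraction(ca, sensor.kd, sensor.hill_n)
    truth = sensor.dark_offset + sensor.brightness * (
        sensor.eps_free + (1.0 - sensor.eps_free) * np.asarray(frac)
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        reps = truth[None, :] * (1.0 + noise_cv * rng.standard_normal((n_rep, ca.size)))
    else:
        reps = np.tile(truth, (n_rep, 1))
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if n_rep > 1 else np.zeros_like(mean)
    return TitrationTable(ca=ca, mean_signal=mean, sd_signal=sd, n_rep=n_rep)


def make_spectrometer_series(
    sensor: SensorModel,
    ca_list: Sequence[float],
    schedule: IlluminationSchedule | None = None,
    n_rep: int = 6,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[SwitchingTrace]:
    """Replicate-averaged, max-normalised OFF-switching decays per Ca2+ level.

    Per concentration, ``n_rep`` simulated decays are averaged and the
    average is normalised to its maximum (first sample = 1 for a noiseless
    decay), mirroring spectrometer practice of averaging six recordings per
    sample before fitting.
    """
    if len(ca_list) == 0:
        raise ParameterError("ca_list must not be empty")
    if schedule is None:
        schedule = spectrometer_schedule()
    rng = np.random.default_rng(seed)
    out = []
    for ca in ca_list:
        reps = []
        for _ in range(n_rep):
            sub = int(rng.integers(0, 2**31)) if noise_sd > 0 else None
            tr = simulate_trace(sensor, schedule, ca, noise_sd=noise_sd, seed=sub)
            reps.append(tr.s)
        avg = np.mean(reps, axis=0)
        peak = float(np.max(np.abs(avg)))
        if peak > 0:
            avg = avg / peak
        base = simulate_trace(sensor, schedule, ca, noise_sd=0.0)
        out.append(
            SwitchingTrace(
                t=base.t,
                s=avg,
                phase_id=base.phase_id,
                meta={"ca": float(ca), "n_rep": n_rep, "normalized": True},
            )
        )
    return out


def default_layout(
    sensor_cas: Sequence[float] = (0.1, 0.35, 1.35, 39.0),
    blood_strength: float = 50.0,
    mu_eff: float = 0.0,
    radius: float = 8.0,
) -> PhantomLayout:
    """128x128 phantom with four sensor tubes and two blood tubes.

    Mirrors the four-concentration tube experiment: sensor tubes at four
    free-Ca2+ levels plus two tubes of blood as the static background
    absorber.
    """
    if len(sensor_cas) != 4:
        raise LayoutError("default layout expects exactly 4 sensor concentrations")
    sensor_centers = [(40, 24), (40, 64), (40, 104), (88, 24)]
    blood_centers = [(88, 64), (88, 104)]
    regions = [
        Region(center=c, radius=radius, kind="sensor", ca=float(ca))
        for c, ca in zip(sensor_centers, sensor_cas)
    ] + [
        Region(center=c, radius=radius, kind="blood", strength=blood_strength)
        for c in blood_centers
    ]
    return PhantomLayout(
        height=128, width=128, pixel_size=0.1,
        regions=tuple(regions), mu_eff=mu_eff, illum_side="top",
    )


def make_phantom_stack(
    layout: PhantomLayout,
    sensor: SensorModel,
    schedule: IlluminationSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageTimeSeries:
    """Simulate a tomography frame stack for a tube phantom.

    Per pixel the local fluence ``I(x, y) = exp(-mu_eff * depth)`` scales
    both the switching rates and the signal amplitude (linear optoacoustic
    regime).  Sensor pixels follow :func:`simulate_trace`; blood pixels emit
    a constant ``strength * I``; background pixels are zero.  Frames are
    pulse-block averages per the schedule; additive Gaussian noise of sd
    ``noise_sd`` is applied per frame and pixel.  Ground truth is attached
    as ``layout_truth``.
    """
    if schedule is None:
        schedule = tomography_schedule()
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")

    # overlapping tubes are physically impossible
    masks = [layout.region_mask(reg) for reg in layout.regions]
    total = np.zeros((layout.height, layout.width), dtype=int)
    for m in masks:
        total += m
    if np.any(total > 1):
        raise LayoutError("phantom regions overlap")

    flu = layout.fluence_map()
    T = schedule.n_frames
    frames = np.zeros((T, layout.height, layout.width), dtype=np.float64)

    sensor_no_dark = replace(sensor, dark_offset=0.0)
    for reg, m in zip(layout.regions, masks):
        if reg.kind == "blood":
            frames[:, m] += reg.strength * flu[m][None, :]
            continue
        local_flu = flu[m]
        for v in np.unique(local_flu):
            tr = simulate_trace(
                sensor_no_dark, schedule, reg.ca, noise_sd=0.0, intensity_scale=float(v)
            )
            sel = np.zeros_like(m)
            sel[m] = local_flu == v
            frames[:, sel] = (
                reg.strength * v * tr.s[:, None] + sensor.dark_offset
            )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)

    return ImageTimeSeries(
        frames=frames.astype(np.float32),
        schedule=schedule,
        layout_truth=layout,
        meta={"sensor": sensor, "noise_sd": noise_sd, "seed": seed},
    )
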