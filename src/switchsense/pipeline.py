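"""End-to-end pipeline: phantom stack -> tau map -> relative Ca2+ map.

``run_pipeline`` chains the stages of the tomography analysis: (optional)
stack simulation, pixel classification, reference-offset extraction,
per-pixel kinetic fitting, dose-response calibration against the known tube
concentrations and per-pixel inversion to a relative Ca2+ map.  Every output
directory carries the resolved configuration, seeds and package version, so
a run is exactly reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calibration import fit_dose_response, invert_tau
from .errors import ConfigurationError
from .io import (
    layout_to_dict,
    read_stack,
    schedule_to_dict,
    write_stack,
)
from .kinetics import IlluminationSchedule, SensorModel, tomography_schedule
from .synth import ImageTimeSeries, PhantomLayout, default_layout, make_phantom_stack
from .unmixing import classify_pixels, fit_pixel_kinetics, reference_offset

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("switchsense")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one master seed."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    sensor: SensorModel
    schedule: IlluminationSchedule = field(default_factory=tomography_schedule)
    layout: PhantomLayout | None = None
    stack_path: str | None = None  # read instead of simulating
    noise_sd: float = 0.0
    seed: int = 0
    theta_f: float = 0.2
    theta_r: float = 0.8
    switchable_r2_high: bool = True
    y0_roi: tuple[int, int, float] | None = None  # (row, col, radius)
    fix_endpoints: bool = True
    outdir: str = "switchsense_run"


def _auto_reference_roi(layout: PhantomLayout) -> np.ndarray:
    sensors = [r for r in layout.regions if r.kind == "sensor"]
    if not sensors:
        raise ConfigurationError("layout has no sensor regions for the reference ROI")
    best = max(sensors, key=lambda r: r.ca)
    return layout.region_mask(best)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full unmixing + calibration pipeline; returns the outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    log.info("switchsense %s, seed=%d", __version__, config.seed)

    # stage 1: obtain the stack
    if config.stack_path is not None:
        stack = read_stack(config.stack_path)
        log.info("read stack %s: %s", config.stack_path, stack.frames.shape)
    else:
        layout = config.layout or default_layout()
        stack = make_phantom_stack(
            layout,
            config.sensor,
            config.schedule,
            noise_sd=config.noise_sd,
            seed=stage_seed(config.seed, "simulate"),
        )
        write_stack(stack, out / "stack.tif")
        log.info("simulated phantom stack %s", stack.frames.shape)

    # stage 2: classification
    maps = classify_pixels(
        stack, config.theta_f, config.theta_r, config.switchable_r2_high
    )
    log.info(
        "classified pixels: %d switchable (theta_f=%.3g, theta_r=%.3g, r2_high=%s)",
        int(maps.mask.sum()), config.theta_f, config.theta_r,
        config.switchable_r2_high,
    )

    # stage 3: reference offset from the highest-Ca2+ sample
    roi = config.y0_roi
    if roi is None:
        if stack.layout_truth is None:
            raise ConfigurationError("no y0_roi given and no layout truth available")
        roi = _auto_reference_roi(stack.layout_truth)
    y0 = reference_offset(stack, roi)
    log.info("reference offset y0 = %.6g", y0)

    # stage 4: per-pixel kinetics
    taumap = fit_pixel_kinetics(stack, maps.mask, y0)
    n_fit = int(np.isfinite(taumap.tau).sum())
    log.info("fitted tau for %d pixels", n_fit)

    # stage 5: calibration against the known tube concentrations + inversion
    rows = []
    ca_map = np.full(taumap.tau.shape, np.nan)
    calib = None
    truth = stack.layout_truth
    if truth is not None:
        region_tau = []
        for i, reg in enumerate(truth.regions):
            m = truth.region_mask(reg)
            in_mask = m & maps.mask & np.isfinite(taumap.tau)
            tau_vals = taumap.tau[in_mask]
            rows.append(
                {
                    "region": i,
                    "kind": reg.kind,
                    "ca_true_uM": reg.ca if reg.ca is not None else "",
                    "n_px": int(m.sum()),
                    "n_masked": int(in_mask.sum()),
                    "tau_mean_s": float(tau_vals.mean()) if tau_vals.size else "",
                    "tau_sd_s": float(tau_vals.std()) if tau_vals.size else "",
                }
            )
            if reg.kind == "sensor" and tau_vals.size:
                region_tau.append((reg.ca, float(tau_vals.mean()), i))
        try:
            pairs = [(ca, tau) for ca, tau, _ in region_tau]
            fix = None
            if config.fix_endpoints and pairs:
                cas = [p[0] for p in pairs]
                fix = (min(cas), max(cas))
            calib = fit_dose_response(pairs, fix_from=fix)
            log.info(
                "calibration: tau_max=%.4g tau_min=%.4g log_ec50=%.4g slope=%.4g",
                calib.tau_max, calib.tau_min, calib.log_ec50, calib.hill_slope,
            )
        except Exception as exc:  # calibration is optional when tubes are few
            log.warning("dose-response calibration skipped: %s", exc)
            calib = None
        if calib is not None:
            for ca, tau_mean, i in region_tau:
                rows[i]["ca_est_uM"] = invert_tau(calib, tau_mean).ca
            for r, c in np.argwhere(np.isfinite(taumap.tau)):
                ca_map[r, c] = invert_tau(calib, taumap.tau[r, c]).ca
            (out / "calib.json").write_text(
                json.dumps(calib.to_dict(), indent=1, sort_keys=True)
            )

    # outputs
    tifffile.imwrite(out / "mask.tif", maps.mask.astype(np.uint8))
    tifffile.imwrite(out / "fourier_score.tif", maps.fourier_score.astype(np.float32))
    tifffile.imwrite(out / "r2.tif", maps.r2.astype(np.float32))
    tifffile.imwrite(out / "tau.tif", taumap.tau.astype(np.float32))
    tifffile.imwrite(out / "amplitude.tif", taumap.amplitude.astype(np.float32))
    if calib is not None:
        tifffile.imwrite(out / "ca_map.tif", ca_map.astype(np.float32))
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)

    resolved = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate",)},
        "noise_sd": config.noise_sd,
        "theta_f": config.theta_f,
        "theta_r": config.theta_r,
        "switchable_r2_high": config.switchable_r2_high,
        "fix_endpoints": config.fix_endpoints,
        "y0": y0,
        "sensor": {
            k: getattr(config.sensor, k)
            for k in (
                "kd", "hill_n", "brightness", "eps_free", "sigma_fast",
                "sigma_slow", "sigma_on", "fatigue_per_cycle", "dark_offset",
            )
        },
        "schedule": schedule_to_dict(stack.schedule),
        "layout": layout_to_dict(truth) if truth is not None else None,
    }
    (out / "config.json").write_text(json.dumps(resolved, indent=1, sort_keys=True))
    log.info("outputs written to %s", out)
    return out
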