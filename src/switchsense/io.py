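"""Readers/writers for stacks, traces, titrations and configuration.

Stacks travel as multi-page TIFF (frame order = acquisition order) with a
JSON sidecar ``<name>.meta.json`` that round-trips the illumination schedule
and, when present, the phantom ground truth.  Traces and titrations are
plain CSV with documented headers.  Sensor/schedule/layout configuration is
YAML or JSON with field names matching the domain types.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ValidationError
from .kinetics import IlluminationSchedule, Phase, SensorModel, SwitchingTrace
from .synth import ImageTimeSeries, PhantomLayout, Region, TitrationTable

__all__ = [
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "read_titration",
    "write_titration",
    "sensor_from_dict",
    "schedule_from_dict",
    "layout_from_dict",
    "schedule_to_dict",
    "layout_to_dict",
    "load_config",
]

TRACE_HEADER = ["t_s", "signal", "phase_id"]


# ---------------------------------------------------------------------------
# config / dict round-trips
# ---------------------------------------------------------------------------


def sensor_from_dict(d: dict) -> SensorModel:
    return SensorModel(**d)


def schedule_to_dict(schedule: IlluminationSchedule) -> dict:
    return {
        "phases": [asdict(ph) for ph in schedule.phases],
        "n_cycles": schedule.n_cycles,
        "pulses_per_frame": schedule.pulses_per_frame,
    }


def schedule_from_dict(d: dict) -> IlluminationSchedule:
    return IlluminationSchedule(
        phases=tuple(Phase(**ph) for ph in d["phases"]),
        n_cycles=d.get("n_cycles", 1),
        pulses_per_frame=d.get("pulses_per_frame", 1),
    )


def layout_to_dict(layout: PhantomLayout) -> dict:
    return {
        "height": layout.height,
        "width": layout.width,
        "pixel_size": layout.pixel_size,
        "regions": [
            {
                "center": list(reg.center),
                "radius": reg.radius,
                "kind": reg.kind,
                "ca": reg.ca,
                "strength": reg.strength,
            }
            for reg in layout.regions
        ],
        "mu_eff": layout.mu_eff,
        "illum_side": layout.illum_side,
    }


def layout_from_dict(d: dict) -> PhantomLayout:
    return PhantomLayout(
        height=d["height"],
        width=d["width"],
        pixel_size=d["pixel_size"],
        regions=tuple(
            Region(
                center=tuple(r["center"]),
                radius=r["radius"],
                kind=r["kind"],
                ca=r.get("ca"),
                strength=r.get("strength", 1.0),
            )
            for r in d["regions"]
        ),
        mu_eff=d.get("mu_eff", 0.0),
        illum_side=d.get("illum_side", "top"),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_stack(series: ImageTimeSeries, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus its JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, series.frames)
    meta = {
        "version": __version__,
        "dtype": str(series.frames.dtype),
        "n_frames": int(series.frames.shape[0]),
        "schedule": schedule_to_dict(series.schedule),
        "layout_truth": (
            layout_to_dict(series.layout_truth) if series.layout_truth else None
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path: str | Path) -> ImageTimeSeries:
    """Read a multi-page TIFF stack and its mandatory metadata sidecar.

    Integer stacks are promoted to float32 (values unchanged, scale 1.0,
    recorded in ``meta``).  Raises :class:`ValidationError` when the frame
    count disagrees with the schedule.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar: expected {sidecar} next to {path}"
        )
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    schedule = schedule_from_dict(meta["schedule"])
    if frames.shape[0] != schedule.n_frames:
        raise ValidationError(
            f"stack {path} has {frames.shape[0]} frames but its schedule "
            f"defines {schedule.n_frames}"
        )
    extra = {}
    if np.issubdtype(frames.dtype, np.integer):
        extra = {"source_dtype": str(frames.dtype), "scale": 1.0}
        frames = frames.astype(np.float32)
    layout = meta.get("layout_truth")
    return ImageTimeSeries(
        frames=frames,
        schedule=schedule,
        layout_truth=layout_from_dict(layout) if layout else None,
        meta={**extra, "version": meta.get("version")},
    )


# ---------------------------------------------------------------------------
# traces and titrations
# ---------------------------------------------------------------------------


def write_trace(trace: SwitchingTrace, path: str | Path) -> Path:
    """Write a trace as CSV with header ``t_s,signal,phase_id``."""
    path = Path(path)
    df = pd.DataFrame(
        {"t_s": trace.t, "signal": trace.s, "phase_id": trace.phase_id}
    )
    df.to_csv(path, index=False)
    return path


def read_trace(path: str | Path) -> SwitchingTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_HEADER if c not in df.columns]
    if missing:
        raise ValidationError(f"trace CSV {path} lacks columns {missing}")
    return SwitchingTrace(
        t=df["t_s"].to_numpy(),
        s=df["signal"].to_numpy(),
        phase_id=df["phase_id"].to_numpy(),
        meta={"source": str(path)},
    )


def write_titration(table: TitrationTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "ca_uM": table.ca,
            "mean_signal": table.mean_signal,
            "sd_signal": table.sd_signal,
            "n_rep": table.n_rep,
        }
    ).to_csv(path, index=False)
    return path


def read_titration(path: str | Path) -> TitrationTable:
    df = pd.read_csv(path)
    return TitrationTable(
        ca=df["ca_uM"].to_numpy(),
        mean_signal=df["mean_signal"].to_numpy(),
        sd_signal=df["sd_signal"].to_numpy(),
        n_rep=int(df["n_rep"].iloc[0]),
    )
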