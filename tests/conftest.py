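"""Shared fixtures: sensor presets, fast schedules and small phantom layouts."""

import numpy as np
import pytest

from switchsense import (
    IlluminationSchedule,
    Phase,
    PhantomLayout,
    Region,
    er_sensor,
    oa_sensor,
    spectrometer_schedule,
    tomography_schedule,
)


@pytest.fixture
def er():
    return er_sensor()


@pytest.fixture
def oa():
    return oa_sensor()


@pytest.fixture
def tomo10():
    """Full 10x(120+120) pulse schedule averaged to 240 frames."""
    return tomography_schedule(pulses_per_frame=10)


@pytest.fixture
def spectro():
    """Single 24-s 488-nm decay at 10 Hz (240 samples)."""
    return spectrometer_schedule()


@pytest.fixture
def off_schedule_single():
    """One short 488-nm phase: the minimal OFF-switching recording."""
    return IlluminationSchedule(phases=(Phase(488, 1.0, 120, 10.0),), n_cycles=1)


def two_tube_layout(ca_pair=(1.35, 39.0), strengths=(1.0, 1.0), blood=True,
                    mu_eff=0.0, illum_side="top"):
    """32x32 layout with two sensor tubes (and optionally one blood tube)."""
    regions = [
        Region(center=(10, 10), radius=5, kind="sensor", ca=ca_pair[0],
               strength=strengths[0]),
        Region(center=(10, 24), radius=5, kind="sensor", ca=ca_pair[1],
               strength=strengths[1]),
    ]
    if blood:
        regions.append(Region(center=(24, 16), radius=5, kind="blood",
                              strength=50.0))
    return PhantomLayout(height=32, width=32, pixel_size=0.1,
                         regions=tuple(regions), mu_eff=mu_eff,
                         illum_side=illum_side)


def grid_search_tau(t, s, y0, n_grid=1000):
    """Independent grid-search oracle for the fixed-offset exponential fit.

    For each tau on a log grid the optimal amplitude has the closed form of
    a 1-D linear least-squares problem, so the search is exhaustive over tau.
    Two refinement stages give ~1e-5 relative resolution.
    """
    t = np.asarray(t, float) - t[0]
    y = np.asarray(s, float) - y0

    def sse_for(taus):
        out = np.empty(len(taus))
        for i, tau in enumerate(taus):
            basis = np.exp(-t / tau)
            a = float(basis @ y) / float(basis @ basis)
            out[i] = float(np.sum((y - a * basis) ** 2))
        return out

    lo, hi = (t[-1] - t[0]) / 1e3, (t[-1] - t[0]) * 1e2
    grid = np.geomspace(lo, hi, n_grid)
    best = int(np.argmin(sse_for(grid)))
    lo2 = grid[max(best - 1, 0)]
    hi2 = grid[min(best + 1, n_grid - 1)]
    grid2 = np.geomspace(lo2, hi2, n_grid)
    best2 = int(np.argmin(sse_for(grid2)))
    return float(grid2[best2])
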