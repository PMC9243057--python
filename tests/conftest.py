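"""Shared fixtures: geometry, pass batches, and a small analyzed cohort."""
from __future__ import annotations

import numpy as np
import pytest

from vtesync.synthetic import (
    TrajectoryParams,
    default_geometry,
    simulate_cohort,
    simulate_pass,
)
from vtesync.trajectory import (
    IdPhiParams,
    PositionTrack,
    compute_idphi,
    detect_head_sweep,
    segment_passes,
    smooth_track,
)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


def pass_kinematics(kind: str, seed: int, noise_sd: float, geometry, arm: str = "R"):
    """Generate one pass and run the IdPhi chain on its segmented window.

    Returns (ChoicePointPass, analytic heading change, head-sweep call).
    """
    params = TrajectoryParams(seed=seed, noise_sd=noise_sd)
    t, x, y, turn = simulate_pass(params, kind, arm)
    track = PositionTrack(t, x, y)
    ip = IdPhiParams()
    bounds = segment_passes(smooth_track(track, ip.smooth_window), geometry)
    assert len(bounds) == 1
    start, stop, exit_arm = bounds[0]
    a = max(start - ip.pre_pad, 0)
    b = min(stop + ip.post_pad, len(track) - 1)
    cp = compute_idphi(t[a : b + 1], x[a : b + 1], y[a : b + 1], ip)
    cp.exit_arm = exit_arm
    swept, flags = detect_head_sweep(cp, geometry)
    cp.qc_flags |= flags
    return cp, turn, swept


@pytest.fixture(scope="session")
def pass_batch(geometry):
    """100 passes (80 ballistic / 20 VTE) at two noise levels, with truth."""
    out = {}
    for noise in (0.0, 0.5):
        records = []
        for i in range(80):
            cp, turn, swept = pass_kinematics("ballistic", i, noise, geometry)
            records.append({"idphi": cp.idphi, "swept": swept, "vte": False})
        for i in range(20):
            kind = "vte_sweep" if i % 2 == 0 else "vte_pause"
            cp, turn, swept = pass_kinematics(kind, 1000 + i, noise, geometry)
            records.append({"idphi": cp.idphi, "swept": swept, "vte": True})
        out[noise] = records
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """Three rats, full condition grid, with the planted muscimol deficits."""
    return simulate_cohort(n_rats=3, seed=11, n_trials=20, lfp_rate=500)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def planted_ar4(cross: float = 0.3) -> np.ndarray:
    """A stable bivariate AR(4) with identical own-dynamics and x->y coupling
    at lag 4; the lag-4 coefficients are large enough that order selection
    has a well-defined true answer."""
    own = [0.6, -0.5, 0.3, -0.35]
    coeffs = np.zeros((4, 2, 2))
    for i, v in enumerate(own):
        coeffs[i, 0, 0] = coeffs[i, 1, 1] = v
    coeffs[3, 1, 0] = cross
    return coeffs
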