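"""Shared analysis constants.

Single source of truth for the frequency conventions used across the
spectral and Granger modules: the theta band is 5-10 Hz (defined from the
power spectra of maze-running rats) and all coherence / directional
estimates are evaluated on a 1-20 Hz grid in 0.5 Hz steps.
"""
from __future__ import annotations

import numpy as np

#: Theta band in Hz, inclusive at both edges.
THETA_BAND: tuple[float, float] = (5.0, 10.0)

#: Frequency grid for coherence and spectral Granger estimates (Hz).
FREQ_GRID: np.ndarray = np.round(np.arange(1.0, 20.0 + 0.25, 0.5), 4)

#: zlnIdPhi threshold separating ballistic from deliberative passes.
VTE_Z_THRESHOLD: float = 0.0

#: Trials with an LFP clipping fraction at or above this are excluded.
CLIPPING_THRESHOLD: float = 0.01

#: Minimum trials per VTE class for a defined per-rat accuracy / LFP value.
MIN_TRIALS_PER_CLASS: int = 2

#: Physical speed cap (cm/s) above which tracking jumps are flagged.
TRACKING_SPEED_CAP: float = 150.0


def theta_mask(frequencies: np.ndarray, band: tuple[float, float] = THETA_BAND) -> np.ndarray:
    """Boolean mask of grid frequencies inside the (inclusive) theta band."""
    frequencies = np.asarray(frequencies, dtype=float)
    return (frequencies >= band[0]) & (frequencies <= band[1])
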