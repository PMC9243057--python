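"""Choice-point LFP screening, power spectra, and theta coherence.

LFP from the mPFC and dorsal hippocampus is extracted during choice-point
passes, screened for clipping artifacts (runs of repeated voltage values
from amplifier saturation; any trial with >= 1% clipped samples is
dropped), and concatenated by VTE class.  Magnitude-squared coherence is
estimated by segment-averaged cross/auto spectra with rectangular
(untapered) segments and zero overlap, evaluated on a 1-20 Hz grid in
0.5 Hz steps; theta summaries average the 5-10 Hz bins after z-scoring
across the grid (which removes between-subject differences in absolute
signal amplitude and electrode depth).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .defaults import CLIPPING_THRESHOLD, FREQ_GRID, THETA_BAND, theta_mask

__all__ = [
    "LfpTrace",
    "LfpSegmentSet",
    "SpectralResult",
    "detect_clipping",
    "exclude_clipped_trials",
    "power_spectrum",
    "coherence",
    "normalize_over_frequencies",
    "theta_band_mean",
]


@dataclass
class LfpTrace:
    """A sampled voltage series from one region (mPFC or dHPC)."""

    samples: np.ndarray
    sampling_rate: float
    region: str = "mPFC"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise ValueError("samples must be a nonempty 1-D array")


@dataclass
class LfpSegmentSet:
    """Per-trial paired LFP segments for one session, grouped by VTE class.

    ``segments`` maps trial_index -> {region: samples}; ``is_vte`` gives
    each trial's class.  Excluded trials are listed with a reason and
    appear in no concatenation.
    """

    sampling_rate: float
    segments: dict[int, dict[str, np.ndarray]]
    is_vte: dict[int, bool]
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def trial_ids(self) -> list[int]:
        excluded = {t for t, _ in self.excluded}
        return [t for t in sorted(self.segments) if t not in excluded]

    def concatenated(self, region: str, vte: bool) -> np.ndarray:
        """Concatenate retained segments of one class and region in trial order."""
        parts = [
            self.segments[t][region]
            for t in self.trial_ids()
            if self.is_vte[t] == vte
        ]
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)

    def time_spent(self, vte: bool) -> float:
        """Total duration (s) of retained segments of one class."""
        region = next(iter(next(iter(self.segments.values())).keys()))
        return len(self.concatenated(region, vte)) / self.sampling_rate


@dataclass
class SpectralResult:
    """Frequency-resolved values: log-power or squared coherence."""

    frequencies: np.ndarray
    values: np.ndarray
    kind: str                    # "log_power" | "coherence"
    normalized: bool = False
    theta_band: tuple[float, float] = THETA_BAND

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.kind == "coherence" and not self.normalized:
            if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
                raise ValueError("squared coherence must lie in [0, 1]")


def detect_clipping(samples: np.ndarray, min_run: int = 2) -> float:
    """Fraction of samples inside runs of >= min_run identical consecutive values.

    Clipping (saturation) shows up as repeated voltage values; min_run=2
    counts any immediate repeat as clipped.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) == 0:
        raise ValueError("empty trace")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if len(samples) == 1:
        return 0.0
    same = np.diff(samples) == 0
    # run lengths of consecutive identical values
    boundaries = np.flatnonzero(np.diff(same.astype(int)))
    edges = np.concatenate(([0], boundaries + 1, [len(same)]))
    clipped = 0
    for a, b in zip(edges[:-1], edges[1:]):
        if same[a]:
            run = (b - a) + 1  # number of identical samples
            if run >= min_run:
                clipped += run
    return clipped / len(samples)


def exclude_clipped_trials(
    segments: LfpSegmentSet,
    threshold: float = CLIPPING_THRESHOLD,
    min_run: int = 2,
) -> LfpSegmentSet:
    """Drop trials whose clipped fraction reaches the threshold on either region.

    The comparison is inclusive: a trial at exactly the threshold (default
    1%) is excluded.  Raises if nothing survives.
    """
    excluded = list(segments.excluded)
    already = {t for t, _ in excluded}
    for t in sorted(segments.segments):
        if t in already:
            continue
        for region, samp in segments.segments[t].items():
            frac = detect_clipping(samp, min_run=min_run)
            if frac >= threshold:
                excluded.append((t, f"clipping {frac:.4f} in {region}"))
                break
    out = LfpSegmentSet(
        sampling_rate=segments.sampling_rate,
        segments=segments.segments,
        is_vte=segments.is_vte,
        excluded=excluded,
    )
    if not out.trial_ids():
        raise ValueError("all trials excluded by the clipping screen")
    return out


def power_spectrum(samples: np.ndarray, rate: float) -> SpectralResult:
    """Natural-log power spectral density by averaged periodograms.

    Rectangular 2-second segments (0.5 Hz resolution), zero overlap, mean
    removed per segment.  Requires >= 2 s of signal.
    """
    samples = np.asarray(samples, dtype=float)
    nperseg = int(round(2 * rate))
    if len(samples) < nperseg:
        raise ValueError("need at least 2 s of signal for a power spectrum")
    freqs, pxx = sps.welch(
        samples, fs=rate, window="boxcar", nperseg=nperseg, noverlap=0,
        detrend="constant",
    )
    keep = freqs > 0
    return SpectralResult(freqs[keep], np.log(pxx[keep]), kind="log_power")


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    grid: np.ndarray = FREQ_GRID,
    min_segments: int = 8,
    segment_seconds: float = 2.0,
) -> SpectralResult:
    """Magnitude-squared coherence on the analysis grid.

    Cross/auto spectra are averaged over rectangular (no taper) segments
    with zero overlap.  The segment length is ``segment_seconds`` (default
    2 s, 0.5 Hz native resolution) when the signal allows at least
    ``min_segments`` of them, otherwise one-``min_segments``-th of the
    signal; estimates are then linearly interpolated onto the requested
    grid.  When comparing conditions with very different amounts of data,
    pass a ``segment_seconds`` both can support, so the estimator's
    resolution bandwidth (and hence its bias) is matched across them.  A
    single segment's coherence is identically 1, so fewer than
    ``min_segments`` segments is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    nperseg = min(int(round(segment_seconds * rate)), n // min_segments)
    if nperseg < 8:
        raise ValueError(
            f"signal too short for {min_segments} coherence segments (n={n})"
        )
    freqs, cxy = sps.coherence(
        x, y, fs=rate, window="boxcar", nperseg=nperseg, noverlap=0,
        detrend="constant",
    )
    grid = np.asarray(grid, dtype=float)
    values = np.interp(grid, freqs, cxy)
    return SpectralResult(grid, np.clip(values, 0.0, 1.0), kind="coherence")


def normalize_over_frequencies(result: SpectralResult) -> SpectralResult:
    """z-score the values across frequency bins (mean 0, SD 1 over the grid).

    Removes between-subject differences in overall level; idempotent, and
    invariant to affine transforms of the input values.
    """
    if np.all(result.values == result.values[0]):
        raise ValueError("zero variance across frequency bins")
    sd = np.std(result.values)
    z = (result.values - result.values.mean()) / sd
    return SpectralResult(result.frequencies, z, kind=result.kind,
                          normalized=True, theta_band=result.theta_band)


def theta_band_mean(result: SpectralResult) -> float:
    """Mean of values at grid frequencies inside the theta band (inclusive)."""
    mask = theta_mask(result.frequencies, result.theta_band)
    if not np.any(mask):
        raise ValueError("grid does not cover the theta band")
    return float(result.values[mask].mean())
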