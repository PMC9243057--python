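"""Trajectory-based detection of vicarious trial and error (VTE) events.

A VTE is a pause-and-reorient behavior at a maze choice point, widely read
as overt deliberation.  Detection here follows the IdPhi procedure: head
position is smoothed, velocities dX/dY are estimated with a discrete
time-adaptive windowing method, the movement orientation Phi = atan2(dY, dX)
is unwrapped, its rate of change dPhi is estimated the same way, and IdPhi
is the integral of |dPhi| over the choice-point pass.  The z-score of
ln(IdPhi) (zlnIdPhi) is thresholded at 0 to label VTE trials.  A
complementary head-sweep extractor recovers fast sweeps that produce low
IdPhi: trials where the head enters both goal-arm regions while still
within (a small margin around) the choice point.  The final VTE label is
the union of the two detectors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .defaults import TRACKING_SPEED_CAP, VTE_Z_THRESHOLD

__all__ = [
    "PositionTrack",
    "Rect",
    "ChoicePointRegion",
    "ChoicePointPass",
    "VteLabel",
    "smooth_track",
    "adaptive_derivative",
    "compute_phi",
    "compute_idphi",
    "classify_vte",
    "detect_head_sweep",
    "segment_passes",
]


@dataclass
class PositionTrack:
    """Timestamped 2-D head coordinates for one session.

    Parameters
    ----------
    timestamps : array of float
        Seconds, strictly increasing.
    x, y : array of float
        Head position in cm.
    nominal_rate : float
        Nominal sampling rate in samples/s (LED tracking, ~30).
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.timestamps) == len(self.x) == len(self.y)):
            raise ValueError("timestamps, x and y must have equal length")
        if len(self.timestamps) == 0:
            raise ValueError("empty track")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, arr in (("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in maze coordinates (cm)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError("degenerate rectangle")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)

    def expanded(self, fraction: float) -> "Rect":
        """Rectangle grown by `fraction` of its size on every side."""
        dx = fraction * (self.x_max - self.x_min)
        dy = fraction * (self.y_max - self.y_min)
        return Rect(self.x_min - dx, self.x_max + dx, self.y_min - dy, self.y_max + dy)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x_max <= other.x_min
            or other.x_max <= self.x_min
            or self.y_max <= other.y_min
            or other.y_max <= self.y_min
        )


@dataclass(frozen=True)
class ChoicePointRegion:
    """T-junction geometry: the square choice point plus both goal-arm regions.

    The choice point is the square space surrounding the divergence in
    trajectory toward the goal arms.  ``margin`` (a fraction of the region
    size) defines both the head-sweep search box around the choice point
    and the depth into an arm region that counts as commitment.
    """

    choice: Rect
    left_arm: Rect
    right_arm: Rect
    margin: float = 0.1

    def __post_init__(self) -> None:
        if self.left_arm.overlaps(self.right_arm):
            raise ValueError("left and right arm regions must be disjoint")
        if not 0 <= self.margin < 1:
            raise ValueError("margin must be in [0, 1)")

    @property
    def search_box(self) -> Rect:
        """Choice-point box expanded by the margin; head sweeps must stay inside."""
        return self.choice.expanded(self.margin)

    def commit_depth(self) -> float:
        """Distance into an arm (beyond the search box) that counts as commitment."""
        return self.margin * (self.choice.x_max - self.choice.x_min)

    def in_arm(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.left_arm.contains(x, y) | self.right_arm.contains(x, y)

    def arm_committed(self, x: float, y: float) -> str | None:
        """'L'/'R' if (x, y) is inside an arm region and outside the search box."""
        box = self.search_box
        inside_box = box.contains(np.array([x]), np.array([y]))[0]
        if inside_box:
            return None
        if self.left_arm.contains(np.array([x]), np.array([y]))[0]:
            return "L"
        if self.right_arm.contains(np.array([x]), np.array([y]))[0]:
            return "R"
        return None


@dataclass
class ChoicePointPass:
    """One trial's trajectory segment through the choice point, with kinematics.

    ``idphi`` is the integral of |dphi| (rad/s) over the pass, using the
    per-sample time step, so it is robust to the tracking rate.
    """

    trial_index: int
    start: int                      # sample index into the session track
    stop: int                       # inclusive
    timestamps: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)          # smoothed
    y: np.ndarray = field(repr=False)
    raw_x: np.ndarray = field(repr=False)      # as tracked (for region tests)
    raw_y: np.ndarray = field(repr=False)
    dx: np.ndarray = field(repr=False)         # cm/s
    dy: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)        # unwrapped, rad
    dphi: np.ndarray = field(repr=False)       # rad/s
    idphi: float = 0.0                         # rad
    time_spent: float = 0.0                    # s
    exit_arm: str | None = None
    qc_flags: set[str] = field(default_factory=set)


@dataclass
class VteLabel:
    """Final per-trial VTE call: IdPhi-threshold OR head-sweep positive."""

    trial_index: int
    zln_idphi: float
    is_vte_idphi: bool
    is_head_sweep: bool
    qc_flags: set[str] = field(default_factory=set)

    @property
    def is_vte(self) -> bool:
        return self.is_vte_idphi or self.is_head_sweep


def smooth_track(track: PositionTrack, window: int = 30) -> PositionTrack:
    """Gaussian-weighted centered moving average of x and y.

    The default window of 30 samples matches a ~30 samples/s tracking rate
    (about one second of data).  The Gaussian kernel standard deviation is
    window/5; at the track edges the truncated window is renormalized so
    the weights always sum to one.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    window = min(window, len(track))  # np.convolve 'same' needs kernel <= signal
    if window == 1 or len(track) == 1:
        return PositionTrack(track.timestamps.copy(), track.x.copy(), track.y.copy(),
                             track.nominal_rate)
    offsets = np.arange(window) - window // 2
    sigma = window / 5.0
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)

    def _smooth(v: np.ndarray) -> np.ndarray:
        num = np.convolve(v, kernel[::-1], mode="same")
        den = np.convolve(np.ones_like(v), kernel[::-1], mode="same")
        return num / den

    return PositionTrack(track.timestamps.copy(), _smooth(track.x), _smooth(track.y),
                         track.nominal_rate)


def adaptive_derivative(
    values: np.ndarray,
    timestamps: np.ndarray,
    tolerance: float,
    max_window: int = 15,
    min_window: int = 3,
) -> np.ndarray:
    """Per-sample slope via discrete time-adaptive windowing.

    For each sample a window centered on it is grown from ``min_window``
    samples per side until the residual of the best-fit line exceeds
    ``tolerance`` (same units as ``values``) or ``max_window`` samples per
    side are reached; the slope of the largest admissible window is
    reported.  Centering keeps the estimate unbiased where the signal
    curves (a trailing window lags the true rate there); near the track
    edges the window is truncated to what exists.  This trades noise
    suppression against responsiveness: straight stretches get long
    windows, turns get short ones.
    """
    values = np.asarray(values, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    half_min = max(min_window // 2, 1)
    half_max = max(max_window // 2, half_min)

    out = np.empty(n)

    def _fit_slope(i0: int, i1: int) -> tuple[float, float]:
        """Least-squares line over samples [i0, i1]; returns (slope, max |residual|)."""
        t = timestamps[i0 : i1 + 1]
        v = values[i0 : i1 + 1]
        tc = t - t.mean()
        denom = np.dot(tc, tc)
        if denom == 0.0:
            return 0.0, 0.0
        slope = np.dot(tc, v - v.mean()) / denom
        resid = v - (v.mean() + slope * tc)
        return slope, float(np.max(np.abs(resid)))

    for i in range(n):
        lo = max(i - half_min, 0)
        hi = min(i + half_min, n - 1)
        best = _fit_slope(lo, hi)[0]
        for w in range(half_min + 1, half_max + 1):
            lo = max(i - w, 0)
            hi = min(i + w, n - 1)
            slope, resid = _fit_slope(lo, hi)
            if resid > tolerance:
                break
            best = slope
        out[i] = best
    return out


def compute_phi(dx: np.ndarray, dy: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unwrapped movement orientation from velocity components.

    Phi is the four-quadrant arctangent of (dY, dX), unwrapped so that
    successive differences lie in (-pi, pi].  Samples with both components
    zero have no defined orientation; the previous sample's angle is
    carried forward and the event is flagged (returned boolean).
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise ValueError("dx and dy must have equal length")
    phi = np.arctan2(dy, dx)
    zero = (dx == 0.0) & (dy == 0.0)
    flagged = bool(np.any(zero))
    if flagged:
        # carry forward the last defined angle
        idx = np.where(~zero, np.arange(len(phi)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(~zero) if np.any(~zero) else 0
        idx[idx < 0] = first
        phi = phi[idx]
    return np.unwrap(phi), flagged


@dataclass(frozen=True)
class IdPhiParams:
    """Tunables of the IdPhi pipeline.

    Tolerances for the adaptive-windowing derivative: 1 cm for position,
    0.1 rad for orientation; windows 3-15 samples (~0.1-0.5 s at 30 Hz),
    short enough to track a head sweep.
    """

    smooth_window: int = 30
    position_tolerance: float = 1.0     # cm
    phi_tolerance: float = 0.1          # rad
    min_window: int = 3
    max_window: int = 15
    #: samples prepended before choice-region entry (data immediately
    #: preceding entry) and appended after arm commitment, so the smoothed
    #: turn into the arm completes inside the kinematic window
    pre_pad: int = 10
    post_pad: int = 20


def compute_idphi(
    timestamps: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    params: IdPhiParams = IdPhiParams(),
    trial_index: int = 0,
    start: int = 0,
) -> ChoicePointPass:
    """Full IdPhi kinematics for one choice-point pass.

    Pipeline: Gaussian smoothing -> adaptive-window dX, dY -> Phi =
    unwrap(atan2(dY, dX)) -> adaptive-window dPhi -> IdPhi = integral of
    |dPhi| dt (trapezoidal, per-sample time step).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) < 3:
        raise ValueError("pass too short: need >= 3 samples inside the choice region")
    track = PositionTrack(timestamps, x, y)
    sm = smooth_track(track, params.smooth_window)
    dx = adaptive_derivative(sm.x, timestamps, params.position_tolerance,
                             params.max_window, params.min_window)
    dy = adaptive_derivative(sm.y, timestamps, params.position_tolerance,
                             params.max_window, params.min_window)
    phi, zero_flagged = compute_phi(dx, dy)
    dphi = adaptive_derivative(phi, timestamps, params.phi_tolerance,
                               params.max_window, params.min_window)
    idphi = float(np.trapezoid(np.abs(dphi), timestamps))
    flags: set[str] = set()
    if zero_flagged:
        flags.add("zero_velocity_samples")

    # QC: pauses well after the choice point, and physically impossible jumps
    speed = np.hypot(dx, dy)
    slow = speed < 5.0
    if np.any(slow):
        q3 = timestamps[0] + 0.75 * (timestamps[-1] - timestamps[0])
        dt = np.gradient(timestamps)
        slow_time = float(np.sum(dt[slow]))
        late_slow_time = float(np.sum(dt[slow & (timestamps >= q3)]))
        if slow_time > 0 and late_slow_time / slow_time > 0.5:
            flags.add("late_pause_suspect")
    step_speed = np.hypot(np.diff(track.x), np.diff(track.y)) / np.diff(timestamps)
    if np.any(step_speed > TRACKING_SPEED_CAP):
        flags.add("tracking_error_suspect")

    cp = ChoicePointPass(
        trial_index=trial_index,
        start=start,
        stop=start + len(timestamps) - 1,
        timestamps=timestamps,
        x=sm.x,
        y=sm.y,
        raw_x=track.x,
        raw_y=track.y,
        dx=dx,
        dy=dy,
        phi=phi,
        dphi=dphi,
        idphi=idphi,
        time_spent=float(timestamps[-1] - timestamps[0]),
    )
    cp.qc_flags |= flags
    return cp


def zln_scores(idphi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score of ln(IdPhi) over the pooling scope.

    Non-positive IdPhi values (possible only for a constant-orientation
    pass) are floored to the smallest positive score in the pool, or to
    machine epsilon if none exists, and flagged.  Returns (zln, floored
    mask).  The z-score uses the sample standard deviation (ddof=1).
    """
    idphi = np.asarray(idphi, dtype=float)
    if len(idphi) < 2:
        raise ValueError("need >= 2 trials to z-score")
    floored = idphi <= 0
    vals = idphi.copy()
    if np.any(floored):
        positive = vals[~floored]
        floor = positive.min() if len(positive) else np.finfo(float).eps
        vals[floored] = floor
    ln = np.log(vals)
    if np.all(ln == ln[0]):
        raise ValueError("all IdPhi scores identical: z-scores undefined")
    sd = np.std(ln, ddof=1)
    return (ln - ln.mean()) / sd, floored


def classify_vte(
    idphi: np.ndarray,
    head_sweep: np.ndarray | None = None,
    threshold: float = VTE_Z_THRESHOLD,
    trial_indices: np.ndarray | None = None,
    qc_flags: list[set[str]] | None = None,
) -> list[VteLabel]:
    """Label trials as VTE from pooled IdPhi scores plus head-sweep calls.

    zlnIdPhi > ``threshold`` (default 0, where the ballistic component of
    the distribution tapers) marks the IdPhi-positive trials; the final
    label is the union with the head-sweep detector, which recovers fast
    sweeps whose IdPhi is low.
    """
    idphi = np.asarray(idphi, dtype=float)
    n = len(idphi)
    if head_sweep is None:
        head_sweep = np.zeros(n, dtype=bool)
    head_sweep = np.asarray(head_sweep, dtype=bool)
    if len(head_sweep) != n:
        raise ValueError("head_sweep length mismatch")
    if trial_indices is None:
        trial_indices = np.arange(n)
    zln, floored = zln_scores(idphi)
    labels = []
    for i in range(n):
        flags = set(qc_flags[i]) if qc_flags is not None else set()
        if floored[i]:
            flags.add("idphi_floored")
        labels.append(
            VteLabel(
                trial_index=int(trial_indices[i]),
                zln_idphi=float(zln[i]),
                is_vte_idphi=bool(zln[i] > threshold),
                is_head_sweep=bool(head_sweep[i]),
                qc_flags=flags,
            )
        )
    return labels


def detect_head_sweep(
    cp_pass: ChoicePointPass, geometry: ChoicePointRegion
) -> tuple[bool, set[str]]:
    """Head-sweep VTE call: the head visits both goal-arm regions pre-commitment.

    Only excursions inside the choice-point search box (choice rectangle
    plus margin) count; arm visits beyond it are a committed run or a
    tracking artifact, not a sweep, and are rejected with a QC flag.
    Region tests use the raw (unsmoothed) coordinates — a brief sweep into
    an arm survives there but can be attenuated below the arm boundary by
    smoothing; commitment is read from the smoothed path for robustness
    to tracking jitter.
    """
    box = geometry.search_box
    # final commitment: first smoothed sample inside an arm beyond the box
    sm_committed = geometry.in_arm(cp_pass.x, cp_pass.y) & ~box.contains(cp_pass.x, cp_pass.y)
    commit_at = int(np.argmax(sm_committed)) if np.any(sm_committed) else len(cp_pass.x)
    x, y = cp_pass.raw_x[:commit_at], cp_pass.raw_y[:commit_at]
    in_box = box.contains(x, y)
    left = geometry.left_arm.contains(x, y)
    right = geometry.right_arm.contains(x, y)
    flags: set[str] = set()
    swept = bool(np.any(left & in_box)) and bool(np.any(right & in_box))
    outside_excursion = bool(np.any((left | right) & ~in_box))
    if outside_excursion and not swept:
        flags.add("sweep_outside_choice_point")
    return swept, flags


def segment_passes(
    track: PositionTrack,
    geometry: ChoicePointRegion,
    expected_trials: int | None = None,
) -> list[tuple[int, int, str]]:
    """Split a session track into ordered choice-point passes.

    A pass starts at the first sample inside the choice region after the
    previous trial's arm commitment and ends at commitment: the first
    sample inside an arm region beyond the search-box margin.  Returns
    (start, stop, exit_arm) index triples, disjoint and ordered.
    """
    x, y = track.x, track.y
    n = len(track)
    passes: list[tuple[int, int, str]] = []
    i = 0
    in_choice = geometry.choice.contains(x, y)
    while i < n:
        # find next entry into the choice region
        while i < n and not in_choice[i]:
            i += 1
        if i >= n:
            break
        start = i
        # find commitment
        commit = None
        j = i
        while j < n:
            arm = geometry.arm_committed(x[j], y[j])
            if arm is not None:
                commit = (j, arm)
                break
            j += 1
        if commit is None:
            break  # run ends mid-pass; drop the fragment
        stop, arm = commit
        passes.append((start, stop, arm))
        i = stop + 1
    if not passes:
        warnings.warn("track never crosses the choice-point region", stacklevel=2)
    if expected_trials is not None and len(passes) != expected_trials:
        raise ValueError(
            f"segmented {len(passes)} passes but metadata lists {expected_trials} trials"
        )
    return passes


def extract_passes(
    track: PositionTrack,
    geometry: ChoicePointRegion,
    params: IdPhiParams = IdPhiParams(),
    expected_trials: int | None = None,
) -> tuple[list[ChoicePointPass], list[bool]]:
    """Segment one session and compute per-pass kinematics and sweep calls.

    Segmentation runs on the smoothed track (jitter-robust commitment
    detection); IdPhi kinematics use windows padded by ``pre_pad`` /
    ``post_pad`` samples so the smoothed turn into the arm completes
    inside the window; the head-sweep extractor sees raw coordinates.
    ``time_spent`` covers only the in-region part of each pass (entry to
    commitment), not the padding.
    """
    sm = smooth_track(track, params.smooth_window)
    bounds = segment_passes(sm, geometry, expected_trials)
    passes: list[ChoicePointPass] = []
    sweeps: list[bool] = []
    for trial, (start, stop, arm) in enumerate(bounds):
        a = max(start - params.pre_pad, 0)
        b = min(stop + params.post_pad, len(track) - 1)
        cp = compute_idphi(
            track.timestamps[a : b + 1], track.x[a : b + 1], track.y[a : b + 1],
            params, trial_index=trial, start=a,
        )
        cp.exit_arm = arm
        cp.time_spent = float(track.timestamps[stop] - track.timestamps[start])
        swept, flags = detect_head_sweep(cp, geometry)
        cp.qc_flags |= flags
        passes.append(cp)
        sweeps.append(swept)
    return passes, sweeps


def analyze_track(
    track: PositionTrack,
    geometry: ChoicePointRegion,
    params: IdPhiParams = IdPhiParams(),
    threshold: float = VTE_Z_THRESHOLD,
    expected_trials: int | None = None,
) -> tuple[list[ChoicePointPass], list[VteLabel]]:
    """Full VTE detection on one session track.

    Runs :func:`extract_passes`, then z-scores ln(IdPhi) within the
    session to label VTE trials at the configured threshold.  (The
    pipeline instead pools IdPhi across a whole study before z-scoring,
    which keeps sessions without genuine deliberative passes from having
    half their ballistic trials land above the relative threshold.)
    """
    passes, sweeps = extract_passes(track, geometry, params, expected_trials)
    labels = classify_vte(
        np.array([p.idphi for p in passes]),
        head_sweep=np.array(sweeps, dtype=bool),
        threshold=threshold,
        qc_flags=[p.qc_flags for p in passes],
    )
    return passes, labels
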