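"""Synthetic T-maze sessions with known ground truth.

No public recording accompanies the study design this package targets, so
every downstream stage is exercised on simulated sessions: choice-point
trajectory passes (ballistic, head-sweeping, or pause-and-reorient),
delayed-alternation choice sequences with injectable perseveration, and
theta-band coupled LFP pairs with controllable coherence and lead/lag
direction, plus clipping-artifact injection.

Trajectories are parameterized by heading angle and integrated to
positions, so the total absolute heading change — the quantity IdPhi
estimates — is known analytically for every pass.  LFP pairs default to
an explicit stable bivariate autoregressive process with a resonance near
theta, which gives closed-form-checkable Granger structure; a
phase-lagged filtered-noise mode is available for coherence-only tests.
Every generator is a pure function of its parameter record including the
seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import Condition, Epoch
from .trajectory import ChoicePointRegion, PositionTrack, Rect

__all__ = [
    "default_geometry",
    "TrajectoryParams",
    "LfpSimParams",
    "TrialTruth",
    "SyntheticSession",
    "simulate_pass",
    "simulate_choice_sequence",
    "simulate_coupled_lfp",
    "inject_clipping",
    "simulate_session",
    "simulate_cohort",
]


def default_geometry() -> ChoicePointRegion:
    """A 12-cm square choice point with 30-cm goal arms and a 30-cm stem."""
    return ChoicePointRegion(
        choice=Rect(-6, 6, -6, 6),
        left_arm=Rect(-36, -6, -6, 6),
        right_arm=Rect(6, 36, -6, 6),
        margin=0.1,
    )


@dataclass(frozen=True)
class TrajectoryParams:
    """Choice-point pass generator settings.

    ``sweep_count`` head reorientations are inserted for VTE passes
    (0 gives a ballistic pass); ``noise_sd`` is isotropic Gaussian
    tracking jitter in cm per sample.
    """

    sampling_rate: float = 30.0
    pass_duration: float = 1.5          # s; pause length for vte_pause passes
    ballistic_speed: float = 30.0       # cm/s
    sweep_count: int = 2
    sweep_angle: float = np.pi          # rad turned per reorientation
    noise_sd: float = 0.0               # cm
    seed: int = 0
    geometry: ChoicePointRegion = field(default_factory=default_geometry)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sweep_count < 0:
            raise ValueError("sweep_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LfpSimParams:
    """Coupled theta-oscillator LFP settings.

    The default mode is a stable bivariate AR(2) pair with poles near
    ``theta_freq``; ``coupling_strength`` in [0, 1] scales the x->y (or
    y->x) coefficient at ``coupling_lag`` samples.  Strength 0 makes the
    channels statistically independent.  ``mode='filtered'`` instead
    mixes a shared band-passed noise source with a pure sample delay,
    for coherence-only ground truth.
    """

    sampling_rate: float = 2000.0
    duration: float = 60.0
    theta_freq: float = 8.0
    coupling_direction: str = "x_leads_y"   # x_leads_y | y_leads_x | none
    coupling_strength: float = 0.8
    #: coupling in the direction opposite to coupling_direction, same lag;
    #: a constant reverse pathway keeps the weak direction's Granger
    #: estimate dominated by true structure rather than estimation leak
    reverse_strength: float = 0.0
    coupling_lag: int = 5                   # samples
    noise_sd: float = 1.0
    #: -3 dB width of the theta resonance; the AR(2) pole radius is
    #: exp(-pi * bandwidth / rate), so the oscillator quality is the same
    #: at any sampling rate.  Set pole_radius to override directly.
    resonance_bandwidth: float = 2.0        # Hz
    pole_radius: float | None = None
    #: broadband sensor noise added after simulation, as a fraction of each
    #: channel's RMS; 0 keeps the exact VAR structure for Granger tests,
    #: nonzero desaturates coherence at the resonance so it tracks
    #: coupling_strength (as real LFP coherence does)
    measurement_noise_frac: float = 0.0
    mode: str = "var"                       # var | filtered
    ar_coefficients: np.ndarray | None = None   # (k, 2, 2) explicit VAR
    seed: int = 0

    def __post_init__(self) -> None:
        if not 5.0 <= self.theta_freq <= 10.0:
            raise ValueError("theta_freq must lie in [5, 10] Hz")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if not 0.0 <= self.reverse_strength <= 1.0:
            raise ValueError("reverse_strength must lie in [0, 1]")
        if self.coupling_direction not in ("x_leads_y", "y_leads_x", "none"):
            raise ValueError(f"bad coupling_direction {self.coupling_direction!r}")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1 sample")


@dataclass
class TrialTruth:
    """Sidecar ground truth for one simulated trial (test use only)."""

    trial_index: int
    arm: str
    kind: str                        # ballistic | vte_sweep | vte_pause
    is_vte: bool
    heading_change: float            # analytic total |d heading|, rad
    pass_start_s: float
    pass_end_s: float
    coupling_strength: float
    coupling_direction: str


@dataclass
class SyntheticSession:
    """One simulated recording session with ground-truth labels."""

    rat_id: str
    condition: Condition
    epoch: Epoch
    position: PositionTrack
    lfp_mpfc: np.ndarray
    lfp_hpc: np.ndarray
    lfp_rate: float
    lfp_rate_hpc: float              # differs only for a planted bad rat
    geometry: ChoicePointRegion
    truth: list[TrialTruth]


def _rng(seed, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *salt]))


# ---------------------------------------------------------------------------
# trajectory passes
# ---------------------------------------------------------------------------

def simulate_pass(
    params: TrajectoryParams, kind: str, arm: str = "R"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One choice-point pass: stem -> choice point -> committed goal arm.

    ``kind`` is 'ballistic' (single turn into the arm), 'vte_sweep'
    (``sweep_count`` reorientations that dip into each arm region before
    committing) or 'vte_pause' (a near-stationary pause with slow head
    reorientation before committing).  The trajectory is built by
    integrating a prescribed heading/speed profile, so the returned total
    absolute heading change is exact.  Turns are pivots: the animal slows
    to ~1 cm/s while rotating, so reversals happen nearly in place.
    Returns (timestamps, x, y, analytic total |d heading|).
    """
    if kind not in ("ballistic", "vte_sweep", "vte_pause"):
        raise ValueError(f"invalid pass kind {kind!r}")
    if arm not in ("L", "R"):
        raise ValueError("arm must be 'L' or 'R'")
    geom = params.geometry
    rng = _rng(params.seed, 11, {"ballistic": 0, "vte_sweep": 1, "vte_pause": 2}[kind])
    rate = params.sampling_rate
    dt = 1.0 / rate
    speed = params.ballistic_speed
    sweep_speed = 0.5 * speed
    pivot_speed = 1.0           # cm/s while rotating
    turn_rate = 5.0 * np.pi     # rad/s while rotating

    cx = 0.5 * (geom.choice.x_min + geom.choice.x_max)
    cy = 0.5 * (geom.choice.y_min + geom.choice.y_max)
    arm_sign = -1.0 if arm == "L" else 1.0
    arm_heading = np.pi if arm == "L" else 0.0
    # sweep excursions dip just past the arm boundary but stay well inside
    # the head-sweep search box (choice rect + margin)
    dip = (geom.choice.x_max - cx) + 0.3 * geom.commit_depth()
    commit_x = (geom.right_arm.x_max if arm == "R" else -geom.left_arm.x_min) - 2.0

    pos = np.array([cx, geom.choice.y_min - 25.0])
    heading = np.pi / 2  # up the stem
    xs, ys = [pos[0]], [pos[1]]
    total_turn = 0.0

    def step(h: float, spd: float) -> None:
        nonlocal pos
        pos = pos + spd * dt * np.array([np.cos(h), np.sin(h)])
        xs.append(pos[0])
        ys.append(pos[1])

    def turn_to(target: float) -> None:
        """Pivot from the current heading to ``target`` (shortest way)."""
        nonlocal heading, total_turn
        delta = (target - heading + np.pi) % (2 * np.pi) - np.pi
        n = max(int(np.ceil(abs(delta) / (turn_rate * dt))), 1)
        for i in range(1, n + 1):
            step(heading + delta * i / n, pivot_speed)
        total_turn += abs(delta)
        heading = target

    def run(until, spd: float) -> None:
        while not until(pos):
            step(heading, spd)

    # up the stem to the choice-point center
    run(lambda p: p[1] >= cy, speed)

    if kind == "vte_sweep":
        for _ in range(params.sweep_count):
            sides = ("L", "R") if rng.random() < 0.5 else ("R", "L")
            for side in sides:
                out_h = np.pi if side == "L" else 0.0
                turn_to(out_h)
                run(lambda p: abs(p[0] - cx) >= dip, sweep_speed)
                turn_to(0.0 if side == "L" else np.pi)
                run(lambda p: abs(p[0] - cx) <= 0.5, sweep_speed)
    elif kind == "vte_pause":
        # near-stationary wiggle: slow drift with the heading sweeping back
        # and forth, as when the head scans the arms without locomotion
        n_pause = max(int(params.pass_duration * rate), 6)
        cycles = 1.5
        phase = 2 * np.pi * cycles * np.arange(1, n_pause + 1) / n_pause
        for ph in phase:
            h = np.pi / 2 + params.sweep_angle * np.sin(ph)
            total_turn += abs(h - heading)
            heading = h
            step(h, 2.0)

    # commit to the goal arm
    turn_to(arm_heading)
    run(lambda p: arm_sign * p[0] >= commit_x, speed)

    x = np.asarray(xs)
    y = np.asarray(ys)
    if params.noise_sd > 0:
        x = x + rng.normal(0, params.noise_sd, len(x))
        y = y + rng.normal(0, params.noise_sd, len(y))
    t = np.arange(len(x)) / rate
    return t, x, y, total_turn


def simulate_choice_sequence(n_trials: int, p_perseverate: float, seed: int) -> list[str]:
    """Goal-arm labels under a perseveration-injectable alternation policy.

    Each trial after the first repeats the previous arm with probability
    ``p_perseverate`` and alternates otherwise, so p = 0 is perfect
    alternation and p = 1 is a single repeated arm.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= p_perseverate <= 1.0:
        raise ValueError("p_perseverate must lie in [0, 1]")
    rng = _rng(seed, 23)
    arms = ["L" if rng.random() < 0.5 else "R"]
    for _ in range(1, n_trials):
        if rng.random() < p_perseverate:
            arms.append(arms[-1])
        else:
            arms.append("R" if arms[-1] == "L" else "L")
    return arms


# ---------------------------------------------------------------------------
# coupled LFP
# ---------------------------------------------------------------------------

def _theta_ar2(theta_freq: float, rate: float, radius: float) -> tuple[float, float]:
    """AR(2) coefficients with complex poles at radius*exp(+-i 2 pi f/fs)."""
    w = 2 * np.pi * theta_freq / rate
    return 2 * radius * np.cos(w), -(radius**2)


def _companion_radius(coeffs: np.ndarray) -> float:
    k = coeffs.shape[0]
    comp = np.zeros((2 * k, 2 * k))
    for i in range(k):
        comp[0:2, 2 * i : 2 * i + 2] = coeffs[i]
    if k > 1:
        comp[2:, :-2] = np.eye(2 * (k - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def var_coefficients(params: LfpSimParams) -> np.ndarray:
    """The (k, 2, 2) coefficient stack the default generator simulates."""
    if params.ar_coefficients is not None:
        coeffs = np.asarray(params.ar_coefficients, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[1:] != (2, 2):
            raise ValueError("ar_coefficients must have shape (k, 2, 2)")
        return coeffs
    k = max(2, params.coupling_lag)
    coeffs = np.zeros((k, 2, 2))
    radius = (params.pole_radius if params.pole_radius is not None
              else float(np.exp(-np.pi * params.resonance_bandwidth / params.sampling_rate)))
    a1, a2 = _theta_ar2(params.theta_freq, params.sampling_rate, radius)
    coeffs[0, 0, 0] = coeffs[0, 1, 1] = a1
    coeffs[1, 0, 0] = coeffs[1, 1, 1] = a2
    # normalize the cross-coefficient by the driving channel's resonance
    # gain, so coupling_strength sets the coupled-to-intrinsic amplitude
    # ratio at the theta peak (coherence there ~ s^2/(1+s^2)) instead of
    # letting the doubly-filtered shared component swamp the receiver
    w0 = 2 * np.pi * params.theta_freq / params.sampling_rate
    gain = 1.0 / abs(1.0 - a1 * np.exp(-1j * w0) - a2 * np.exp(-2j * w0))
    c = params.coupling_strength / gain
    rev = params.reverse_strength / gain
    lag = params.coupling_lag - 1
    if params.coupling_direction == "x_leads_y":
        coeffs[lag, 1, 0] = c
        coeffs[lag, 0, 1] = rev
    elif params.coupling_direction == "y_leads_x":
        coeffs[lag, 0, 1] = c
        coeffs[lag, 1, 0] = rev
    return coeffs


def simulate_coupled_lfp(params: LfpSimParams) -> tuple[np.ndarray, np.ndarray]:
    """A pair of theta-resonant voltage series with known coupling.

    VAR mode simulates the explicit coefficient stack from
    :func:`var_coefficients` (checked stable) with unit-diagonal Gaussian
    innovations scaled by ``noise_sd``.  Filtered mode band-passes a
    shared noise source around ``theta_freq`` and mixes it, delayed by
    ``coupling_lag`` samples into the lagging channel, with independent
    noise in proportion to ``coupling_strength``.
    """
    rate = params.sampling_rate
    n = int(round(params.duration * rate))
    rng = _rng(params.seed, 37)
    if params.mode == "filtered":
        from scipy import signal as sps

        pad = 4 * params.coupling_lag + int(rate)
        src = rng.normal(0, 1.0, n + pad)
        ny = rate / 2
        lo = max((params.theta_freq - 1.5) / ny, 1e-3)
        hi = min((params.theta_freq + 1.5) / ny, 0.99)
        b, a = sps.butter(2, [lo, hi], btype="band")
        shared = sps.lfilter(b, a, src)
        c = params.coupling_strength
        nx = rng.normal(0, 1.0, n + pad)
        my = rng.normal(0, 1.0, n + pad)
        nx = sps.lfilter(b, a, nx)
        my = sps.lfilter(b, a, my)
        lagged = np.roll(shared, params.coupling_lag)
        x = np.sqrt(c) * shared + np.sqrt(1 - c) * nx
        y = np.sqrt(c) * lagged + np.sqrt(1 - c) * my
        if params.coupling_direction == "y_leads_x":
            x, y = y, x
        scale = params.noise_sd
        return scale * x[pad:], scale * y[pad:]

    if params.mode != "var":
        raise ValueError(f"unknown mode {params.mode!r}")
    coeffs = var_coefficients(params)
    radius = _companion_radius(coeffs)
    if radius >= 1.0:
        raise ValueError(f"unstable autoregressive system (spectral radius {radius:.3f})")
    k = coeffs.shape[0]
    burn = 2000
    innov = rng.normal(0, params.noise_sd, (n + burn + k, 2))
    out = np.zeros((n + burn + k, 2))
    for t in range(k, n + burn + k):
        acc = innov[t].copy()
        for lag in range(k):
            acc += coeffs[lag] @ out[t - lag - 1]
        out[t] = acc
    series = out[burn + k :]
    x, y = series[:, 0].copy(), series[:, 1].copy()
    if params.measurement_noise_frac > 0:
        x = x + rng.normal(0, params.measurement_noise_frac * x.std(), n)
        y = y + rng.normal(0, params.measurement_noise_frac * y.std(), n)
    return x, y


def inject_clipping(
    trace: np.ndarray, fraction: float, run_length: int = 10, seed: int = 0
) -> np.ndarray:
    """Overwrite random stretches with constant values (saturation artifact).

    Inserts non-overlapping runs of ``run_length`` identical samples until
    at least ``fraction`` of the trace is covered; placement is seeded.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if run_length < 2:
        raise ValueError("run_length must be >= 2")
    trace = np.asarray(trace, dtype=float).copy()
    if fraction == 0.0:
        return trace
    n = len(trace)
    n_runs = int(np.ceil(fraction * n / run_length))
    rng = _rng(seed, 53)
    starts: list[int] = []
    taken = np.zeros(n, dtype=bool)
    attempts = 0
    while len(starts) < n_runs and attempts < 100 * n_runs:
        s = int(rng.integers(0, max(n - run_length, 1)))
        if not taken[s : s + run_length].any():
            starts.append(s)
            taken[max(s - 1, 0) : s + run_length + 1] = True
        attempts += 1
    for s in starts:
        trace[s : s + run_length] = trace[s]
    return trace


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionParams:
    """Study-condition settings for one simulated session.

    Defaults emulate asymptotic delayed-alternation performance: ~24
    free-choice trials, occasional deliberative passes, strong
    theta-band mPFC-leading coupling.  Muscimol-testing sessions raise
    perseveration and VTE rates and (for VTE trials only) weaken the
    coupling — the planted deficit the pipeline must recover.
    """

    n_trials: int = 24
    p_perseverate: float = 0.08
    p_vte: float = 0.25
    p_pause_given_vte: float = 0.3
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    lfp_rate: float = 500.0
    control_coupling: float = 0.8
    vte_coupling: float = 0.8            # mPFC-leading coupling during VTE passes
    reverse_coupling: float = 0.25       # constant dHPC->mPFC pathway
    coupling_direction: str = "x_leads_y"
    inter_trial_gap: float = 2.0         # s of LFP between passes
    clip_fraction: float = 0.0           # background clipping per trial


_MUSCIMOL_TESTING = SessionParams(
    p_perseverate=0.4, p_vte=0.4, vte_coupling=0.3
)


def simulate_session(
    rat_id: str,
    condition: Condition,
    epoch: Epoch,
    params: SessionParams | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """One full session: position track, paired LFP, and sidecar truth.

    The position track chains choice-point passes with return runs that
    skirt the maze perimeter (never re-entering the choice region), so
    pass segmentation sees exactly one pass per trial.  LFP is generated
    piecewise: each pass window gets a coupled pair with that trial's
    ground-truth regime; inter-trial gaps use the session's control
    regime.
    """
    if params is None:
        params = (
            _MUSCIMOL_TESTING
            if (condition == Condition.MUSCIMOL and epoch == Epoch.TESTING)
            else SessionParams()
        )
    rng = _rng(seed, 71)
    geom = params.trajectory.geometry
    rate = params.trajectory.sampling_rate
    dt = 1.0 / rate

    arms = simulate_choice_sequence(params.n_trials, params.p_perseverate,
                                    seed=int(rng.integers(2**31)))
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    ts: list[np.ndarray] = []
    truths: list[TrialTruth] = []
    t_cursor = 0.0
    lfp_plan: list[tuple[float, float, float, str]] = []  # start, end, strength, dir

    for idx, arm in enumerate(arms):
        is_vte = rng.random() < params.p_vte
        if is_vte:
            kind = "vte_pause" if rng.random() < params.p_pause_given_vte else "vte_sweep"
        else:
            kind = "ballistic"
        traj_params = replace(params.trajectory, seed=int(rng.integers(2**31)))
        pt, px, py, turn = simulate_pass(traj_params, kind, arm)
        ts.append(pt + t_cursor)
        xs.append(px)
        ys.append(py)
        pass_start = t_cursor
        pass_end = t_cursor + pt[-1]
        strength = params.vte_coupling if is_vte else params.control_coupling
        lfp_plan.append((pass_start, pass_end, strength, params.coupling_direction))
        truths.append(
            TrialTruth(
                trial_index=idx, arm=arm, kind=kind, is_vte=(kind != "ballistic"),
                heading_change=turn, pass_start_s=pass_start, pass_end_s=pass_end,
                coupling_strength=strength,
                coupling_direction=params.coupling_direction,
            )
        )
        t_cursor = pass_end + dt
        # return run: from the arm end around the perimeter back to the stem
        rx, ry = _return_run(arm, geom, params.trajectory, rate)
        rt = t_cursor + np.arange(len(rx)) * dt
        ts.append(rt)
        xs.append(rx)
        ys.append(ry)
        t_cursor = rt[-1] + dt

    t = np.concatenate(ts)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if params.trajectory.noise_sd > 0:
        noise = _rng(seed, 72)
        x = x + noise.normal(0, params.trajectory.noise_sd, len(x))
        y = y + noise.normal(0, params.trajectory.noise_sd, len(y))
    track = PositionTrack(t, x, y, nominal_rate=rate)

    # piecewise LFP covering the whole session timeline
    lfp_rate = params.lfp_rate
    n_lfp = int(np.ceil((t[-1] + dt) * lfp_rate)) + 1
    mpfc = np.zeros(n_lfp)
    hpc = np.zeros(n_lfp)
    cursor = 0
    chunk_seed = _rng(seed, 73)
    for start_s, end_s, strength, direction in lfp_plan:
        a = int(start_s * lfp_rate)
        b = min(int(np.ceil(end_s * lfp_rate)) + 1, n_lfp)
        # gap before the pass: control regime
        for lo, hi, s_eff in ((cursor, a, params.control_coupling), (a, b, strength)):
            if hi <= lo:
                continue
            seg = LfpSimParams(
                sampling_rate=lfp_rate,
                duration=(hi - lo) / lfp_rate,
                coupling_direction=direction if s_eff > 0 else "none",
                coupling_strength=s_eff,
                reverse_strength=params.reverse_coupling if s_eff > 0 else 0.0,
                seed=int(chunk_seed.integers(2**31)),
            )
            sx, sy = simulate_coupled_lfp(seg)
            mpfc[lo : lo + len(sx)] = sx[: hi - lo]
            hpc[lo : lo + len(sy)] = sy[: hi - lo]
        cursor = b
    if cursor < n_lfp:
        seg = LfpSimParams(
            sampling_rate=lfp_rate, duration=(n_lfp - cursor) / lfp_rate,
            coupling_direction=params.coupling_direction,
            coupling_strength=params.control_coupling,
            reverse_strength=params.reverse_coupling,
            seed=int(chunk_seed.integers(2**31)),
        )
        sx, sy = simulate_coupled_lfp(seg)
        mpfc[cursor:] = sx[: n_lfp - cursor]
        hpc[cursor:] = sy[: n_lfp - cursor]

    if params.clip_fraction > 0:
        mpfc = inject_clipping(mpfc, params.clip_fraction, seed=int(chunk_seed.integers(2**31)))

    return SyntheticSession(
        rat_id=rat_id, condition=condition, epoch=epoch, position=track,
        lfp_mpfc=mpfc, lfp_hpc=hpc, lfp_rate=lfp_rate, lfp_rate_hpc=lfp_rate,
        geometry=geom, truth=truths,
    )


def _return_run(
    arm: str, geom: ChoicePointRegion, tp: TrajectoryParams, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Perimeter path from the goal-arm end back to the stem base.

    Skirts outside the choice region so segmentation never sees it.
    """
    sign = -1.0 if arm == "L" else 1.0
    x_end = sign * ((geom.right_arm.x_max if arm == "R" else -geom.left_arm.x_min) - 2.0)
    y_arm = 0.5 * (geom.choice.y_min + geom.choice.y_max)
    y_base = geom.choice.y_min - 25.0
    waypoints = [
        (x_end, y_arm),
        (x_end, y_base),
        (0.0, y_base),
    ]
    speed = tp.ballistic_speed
    step = speed / rate
    xs: list[float] = []
    ys: list[float] = []
    pos = np.array(waypoints[0], dtype=float)
    for target in waypoints[1:]:
        target = np.array(target, dtype=float)
        dist = np.linalg.norm(target - pos)
        n = max(int(np.ceil(dist / step)), 1)
        for i in range(1, n + 1):
            p = pos + (target - pos) * i / n
            xs.append(p[0])
            ys.append(p[1])
        pos = target
    return np.asarray(xs), np.asarray(ys)


def simulate_cohort(
    n_rats: int = 7,
    seed: int = 0,
    n_trials: int = 24,
    lfp_rate: float = 500.0,
    include_mismatched_rate_rat: bool = False,
    include_sparse_vte_rat: bool = False,
) -> list[SyntheticSession]:
    """A full study cohort: each rat runs baseline + testing under each condition.

    Muscimol-testing sessions carry the planted deficits (raised
    perseveration/VTE rates; weakened theta coupling on VTE passes).
    Optional extra rats reproduce the study's exclusion cases: one whose
    two LFP channels were digitized at different rates, and one that
    contributes a single VTE trial.
    """
    sessions: list[SyntheticSession] = []
    root = np.random.SeedSequence([int(seed) % (2**31), 97])
    rat_seeds = root.generate_state(n_rats + 2)

    def _rat_sessions(rat_id: str, rat_seed: int, override=None) -> None:
        sub = np.random.default_rng(np.random.SeedSequence([int(rat_seed) % (2**31)]))
        for condition in Condition:
            for epoch in Epoch:
                is_musc_test = condition == Condition.MUSCIMOL and epoch == Epoch.TESTING
                base = _MUSCIMOL_TESTING if is_musc_test else SessionParams()
                params = replace(base, n_trials=n_trials, lfp_rate=lfp_rate)
                if override is not None:
                    params = override(params, is_musc_test)
                sessions.append(
                    simulate_session(rat_id, condition, epoch, params,
                                     seed=int(sub.integers(2**31)))
                )

    for r in range(n_rats):
        _rat_sessions(f"rat{r + 1}", int(rat_seeds[r]))

    if include_mismatched_rate_rat:
        _rat_sessions(f"rat{n_rats + 1}", int(rat_seeds[n_rats]))
        for s in sessions[-6:]:
            s.lfp_rate_hpc = s.lfp_rate * 2  # planted acquisition fault

    if include_sparse_vte_rat:
        def sparse(params: SessionParams, _musc: bool) -> SessionParams:
            return replace(params, p_vte=0.0)

        _rat_sessions(f"rat{n_rats + 2}", int(rat_seeds[n_rats + 1]), override=sparse)
    return sessions
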