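"""Synthetic maze sessions with scripted ground truth.

Generates pose tracks, annotation tables, and interleaved two-channel
photometry for a plus-maze session whose risk-ranked bouts follow a
user-supplied script, so every downstream stage (zoning, segmentation,
preprocessing, alignment, inference) can be verified offline against
known truth.

Bout kinematics are piecewise constant-speed paths between zone
waypoints with small Gaussian jitter. Risk-assessment annotations are
point events emitted at pause onsets in the proximal open arm. Both
photometry channels share a multiplicative smoothed-random-walk motion
artifact and a single-exponential bleach trend; calcium-like transients
are locked to each bout's alignment event on the signal channel only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze import MazeGeometry, PoseTrack
from .perievent import AlignmentRule
from .photometry import CH_REFERENCE, CH_SIGNAL, PhotometrySession, smooth_gaussian
from .sequences import (
    SEQ_CC,
    SEQ_CO,
    SEQ_GO,
    SEQ_NOGO,
    SEQUENCE_TYPES,
    make_event_table,
)

__all__ = [
    "SimConfig",
    "ScriptedBout",
    "GroundTruth",
    "default_script",
    "simulate_trajectory",
    "simulate_photometry",
    "simulate_session",
]

_BODY_LENGTH = 2.5  # centroid-to-head distance, cm
_BASE_WIDTH = 3.0
_BASE_HEIGHT = 6.0


@dataclass(frozen=True)
class SimConfig:
    """All knobs of a simulated session; the seed fully determines every
    output.

    ``effect_amplitudes`` are peak fractional dF/F deflections per
    sequence type (the realized zdF/F profile, which depends on the
    session variance, is reported in the ground truth).
    """

    session_duration: float = 600.0
    video_rate: float = 30.0
    photometry_rate: float = 40.0
    sequence_script: tuple[tuple[str, float], ...] = ()
    n_risk_events_per_sequence: int = 2
    effect_amplitudes: dict = field(
        default_factory=lambda: {SEQ_CC: 0.0, SEQ_NOGO: 0.0, SEQ_GO: 0.0, SEQ_CO: 0.0}
    )
    transient_tau_rise: float = 0.1
    transient_tau_decay: float = 0.6
    artifact_amplitude: float = 0.05
    bleach_tau: float = 1200.0
    noise_sd: float = 0.5
    seed: int = 0
    travel_speed: float = 14.0  # cm/s along waypoints
    jitter_sd: float = 0.05  # cm, per-frame Gaussian keypoint jitter
    baseline_signal: float = 200.0
    baseline_reference: float = 160.0

    def __post_init__(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if self.video_rate <= 0 or self.photometry_rate <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_risk_events_per_sequence < 1:
            raise ValueError("n_risk_events_per_sequence must be >= 1")
        starts = [t for _, t in self.sequence_script]
        if any(np.diff(starts) <= 0):
            raise ValueError("scripted start times must be strictly increasing")
        for st, _ in self.sequence_script:
            if st not in SEQUENCE_TYPES:
                raise ValueError(f"unknown scripted sequence type {st!r}")


@dataclass
class ScriptedBout:
    """Ground-truth timestamps of one scripted bout."""

    type: str
    t_start: float
    t_center: float
    t_first_risk: float | None
    t_stop: float

    @property
    def anchor(self) -> float:
        """Alignment event: first risk event for NoGo/Go, center crossing
        otherwise."""
        if self.type in (SEQ_NOGO, SEQ_GO):
            assert self.t_first_risk is not None
            return self.t_first_risk
        return self.t_center


@dataclass
class GroundTruth:
    """Scripted bouts plus, after photometry simulation, the noise-free
    per-type mean zdF/F profile over the peri-event window."""

    bouts: list[ScriptedBout] = field(default_factory=list)
    true_timecourse: dict[str, np.ndarray] | None = None
    bin_times: np.ndarray | None = None

    def types(self) -> list[str]:
        return [b.type for b in self.bouts]


def default_script(
    counts: dict[str, int], t_first: float = 15.0, spacing: float = 14.0
) -> tuple[tuple[str, float], ...]:
    """Deterministic round-robin script with the requested per-type
    counts and uniform spacing."""
    remaining = {k: int(v) for k, v in counts.items() if v > 0}
    order = [tp for tp in SEQUENCE_TYPES if tp in remaining]
    script = []
    t = t_first
    while remaining:
        for tp in list(order):
            if tp not in remaining:
                continue
            script.append((tp, t))
            t += spacing
            remaining[tp] -= 1
            if remaining[tp] == 0:
                del remaining[tp]
    return tuple(script)


def _arm_vec(arm: str) -> np.ndarray:
    sign = 1.0 if arm[0] == "+" else -1.0
    return np.array([sign, 0.0]) if arm[1] == "x" else np.array([0.0, sign])


def _bout_plan(
    bout_type: str,
    t0: float,
    origin: str,
    open_arm: str,
    config: SimConfig,
    geometry: MazeGeometry,
) -> dict:
    """Waypoint schedule plus ground-truth timestamps for one bout.

    Returns waypoints [(time, xy)], the bout's settle time (animal back
    to an idle closed-distal position), the terminal closed arm for the
    next bout, and the truth record.
    """
    v = config.travel_speed
    hc = geometry.half_center
    L = geometry.arm_length
    d_idle = hc + 0.75 * L
    d_pause = hc + 0.30 * L
    d_open_end = hc + 0.65 * L
    stop = geometry.stop_distance
    opposite = ("-" if origin[0] == "+" else "+") + origin[1]
    a_o = _arm_vec(origin)
    a_b = _arm_vec(opposite)
    a_open = _arm_vec(open_arm)
    origin_pt = np.zeros(2)

    pause_dur = 0.3 * config.n_risk_events_per_sequence + 0.3
    dwell = 1.0

    wps: list[tuple[float, np.ndarray]] = [(t0, a_o * d_idle)]
    # center-cross quantized to the video frame grid: the first frame whose
    # position lies inside the center platform, matching what a frame-wise
    # detector (or annotator) can observe
    t_center = (
        np.ceil((t0 + (d_idle - hc) / v) * config.video_rate) / config.video_rate
    )
    risk_times: list[float] = []

    def walk(p_from, p_to, t_from):
        return t_from + float(np.linalg.norm(p_to - p_from)) / v

    if bout_type == SEQ_CC:
        tA = walk(a_o * d_idle, origin_pt, t0)
        wps.append((tA, origin_pt))
        t_stop = tA + stop / v
        t_settle = tA + d_idle / v
        wps.append((t_settle, a_b * d_idle))
        terminal = opposite
    elif bout_type == SEQ_NOGO:
        tA = walk(a_o * d_idle, origin_pt, t0)
        wps.append((tA, origin_pt))
        tP = tA + d_pause / v
        wps.append((tP, a_open * d_pause))
        tPe = tP + pause_dur
        wps.append((tPe, a_open * d_pause))
        risk_times = [tP + 0.15 + 0.3 * k for k in range(config.n_risk_events_per_sequence)]
        tB = tPe + d_pause / v
        wps.append((tB, origin_pt))
        t_stop = tB + stop / v
        t_settle = tB + d_idle / v
        wps.append((t_settle, a_b * d_idle))
        terminal = opposite
    elif bout_type in (SEQ_GO, SEQ_CO):
        tA = walk(a_o * d_idle, origin_pt, t0)
        wps.append((tA, origin_pt))
        if bout_type == SEQ_GO:
            tP = tA + d_pause / v
            wps.append((tP, a_open * d_pause))
            tPe = tP + pause_dur
            wps.append((tPe, a_open * d_pause))
            risk_times = [tP + 0.15 + 0.3 * k for k in range(config.n_risk_events_per_sequence)]
            t_stop = tPe + (stop - d_pause) / v
            tE = tPe + (d_open_end - d_pause) / v
        else:
            t_stop = tA + stop / v
            tE = tA + d_open_end / v
        wps.append((tE, a_open * d_open_end))
        wps.append((tE + dwell, a_open * d_open_end))
        tR = tE + dwell + d_open_end / v
        wps.append((tR, origin_pt))
        t_settle = tR + d_idle / v
        wps.append((t_settle, a_b * d_idle))
        terminal = opposite
    else:  # pragma: no cover - guarded by SimConfig validation
        raise ValueError(bout_type)

    truth = ScriptedBout(
        type=bout_type,
        t_start=t0,
        t_center=t_center,
        t_first_risk=risk_times[0] if bout_type in (SEQ_NOGO, SEQ_GO) else None,
        t_stop=t_stop,
    )
    return {
        "waypoints": wps,
        "settle": t_settle,
        "terminal": terminal,
        "truth": truth,
        "risk_times": risk_times,
    }


def simulate_trajectory(
    config: SimConfig, geometry: MazeGeometry | None = None
) -> tuple[PoseTrack, pd.DataFrame, GroundTruth]:
    """Realize the scripted session as a pose track plus annotations.

    Raises if a scripted bout would start before the previous bout has
    resolved (message names the bout index), or would overrun the
    session.
    """
    geometry = geometry or MazeGeometry()
    rng = np.random.default_rng([config.seed, 0])
    closed_arms = ("+" + geometry.closed_axis, "-" + geometry.closed_axis)
    open_arms = ("+" + geometry.open_axis, "-" + geometry.open_axis)

    current_arm = closed_arms[0]
    d_idle = geometry.half_center + 0.75 * geometry.arm_length
    waypoints: list[tuple[float, np.ndarray]] = [(0.0, _arm_vec(current_arm) * d_idle)]
    truth = GroundTruth()
    events: list[tuple[float, str]] = []
    prev_settle = 0.0
    for i, (bout_type, t0) in enumerate(config.sequence_script):
        if t0 < prev_settle + 0.5:
            raise ValueError(
                f"scripted bout {i} at t={t0} s overlaps the previous bout "
                f"(resolved at t={prev_settle:.2f} s)"
            )
        plan = _bout_plan(
            bout_type, t0, current_arm, open_arms[i % 2], config, geometry
        )
        if plan["settle"] > config.session_duration:
            raise ValueError(
                f"scripted bout {i} at t={t0} s overruns the session "
                f"({plan['settle']:.2f} s > {config.session_duration} s)"
            )
        waypoints.append((t0, waypoints[-1][1]))  # hold idle until bout start
        waypoints.extend(plan["waypoints"][1:])
        b: ScriptedBout = plan["truth"]
        truth.bouts.append(b)
        events.append((b.t_start, "sequence_start"))
        events.append((b.t_center, "center_cross"))
        events.extend((rt, "risk_assessment") for rt in plan["risk_times"])
        events.append((b.t_stop, "sequence_stop"))
        current_arm = plan["terminal"]
        prev_settle = plan["settle"]
    waypoints.append((config.session_duration, waypoints[-1][1]))

    n_frames = int(round(config.session_duration * config.video_rate))
    t = np.arange(n_frames) / config.video_rate
    wt = np.array([w[0] for w in waypoints])
    wx = np.array([w[1][0] for w in waypoints])
    wy = np.array([w[1][1] for w in waypoints])
    # waypoint times are non-decreasing by construction; np.interp handles ties
    ideal = np.column_stack([np.interp(t, wt, wx), np.interp(t, wt, wy)])

    vel = np.zeros_like(ideal)
    vel[1:] = np.diff(ideal, axis=0) * config.video_rate
    if n_frames > 1:
        vel[0] = vel[1]
    speed = np.linalg.norm(vel, axis=1)
    moving = speed > 2.0
    heading_unit = np.zeros_like(ideal)
    heading_unit[moving] = vel[moving] / speed[moving, None]
    still = ~moving
    radial = np.linalg.norm(ideal, axis=1)
    outward_ok = still & (radial > 1e-6)
    heading_unit[outward_ok] = ideal[outward_ok] / radial[outward_ok, None]
    # degenerate (still at origin) frames keep a fixed heading
    heading_unit[still & ~outward_ok] = np.array([1.0, 0.0])

    centroid = ideal + rng.normal(0.0, config.jitter_sd, size=ideal.shape)
    head = ideal + heading_unit * _BODY_LENGTH + rng.normal(
        0.0, config.jitter_sd, size=ideal.shape
    )
    tailbase = ideal - heading_unit * 1.2 * _BODY_LENGTH + rng.normal(
        0.0, config.jitter_sd, size=ideal.shape
    )
    # stretched posture while pausing in an open arm (risk assessment)
    in_open = np.abs(ideal[:, 0 if geometry.open_axis == "x" else 1]) > geometry.half_center
    stretch = np.where(still & in_open, 1.5, 0.0)
    bbox_height = _BASE_HEIGHT + stretch + rng.normal(0.0, config.jitter_sd, n_frames)
    bbox_width = _BASE_WIDTH + rng.normal(0.0, config.jitter_sd, n_frames)

    track = PoseTrack(
        time=t,
        centroid=centroid,
        head=head,
        tailbase=tailbase,
        bbox_width=np.maximum(bbox_width, 0.5),
        bbox_height=np.maximum(bbox_height, 0.5),
    )
    events.sort(key=lambda e: e[0])
    event_table = make_event_table(
        [e[0] for e in events], [e[1] for e in events], source="simulated"
    )
    return track, event_table, truth


def _transient_kernel(s: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak rise/decay double exponential, zero for s < 0."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    pos = s >= 0
    sp = s[pos]
    raw = np.exp(-sp / tau_decay) - np.exp(-sp / tau_rise)
    s_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-s_peak / tau_decay) - np.exp(-s_peak / tau_rise)
    out[pos] = raw / peak
    return out


def _dff_true(times: np.ndarray, truth: GroundTruth, config: SimConfig) -> np.ndarray:
    d = np.zeros_like(times, dtype=float)
    for b in truth.bouts:
        amp = float(config.effect_amplitudes.get(b.type, 0.0))
        if amp == 0.0:
            continue
        d += amp * _transient_kernel(
            times - b.anchor, config.transient_tau_rise, config.transient_tau_decay
        )
    return d


def simulate_photometry(
    config: SimConfig,
    truth: GroundTruth,
    animal: str = "animal0",
    hemisphere: str = "left",
) -> PhotometrySession:
    """Emit the interleaved two-channel record stream for one fiber.

    The signal channel carries transients locked to each bout's anchor;
    the reference channel does not. Both share a multiplicative motion
    artifact and an exponential bleach trend. Fills
    ``truth.true_timecourse`` with the noise-free per-type zdF/F profile
    on the peri-event bin grid (zeros when no variance is injected).
    """
    rate = config.photometry_rate
    n = int(round(config.session_duration * rate))
    if any(
        not (0.0 <= b.t_start and b.t_stop <= config.session_duration)
        for b in truth.bouts
    ):
        raise ValueError("ground-truth timestamps must lie within the session")
    rng = np.random.default_rng([config.seed, 1])

    half = 0.5 / rate
    t_sig = np.arange(n) / rate
    t_ref = t_sig + half
    t_all = np.empty(2 * n)
    t_all[0::2] = t_sig
    t_all[1::2] = t_ref

    bleach = np.exp(-t_all / config.bleach_tau)
    walk = np.cumsum(rng.normal(size=2 * n))
    walk = smooth_gaussian(walk, sigma=rate)
    sd = walk.std()
    walk = (walk - walk.mean()) / sd if sd > 0 else walk * 0.0
    artifact = np.clip(1.0 + config.artifact_amplitude * walk, 0.05, None)

    dff_sig = _dff_true(t_sig, truth, config)
    f = np.empty(2 * n)
    f[0::2] = config.baseline_signal * bleach[0::2] * artifact[0::2] * (1.0 + dff_sig)
    f[1::2] = config.baseline_reference * bleach[1::2] * artifact[1::2]
    f += rng.normal(0.0, config.noise_sd, size=2 * n)

    channel = np.empty(2 * n, dtype=object)
    channel[0::2] = CH_SIGNAL
    channel[1::2] = CH_REFERENCE
    records = pd.DataFrame(
        {
            "frame_counter": np.arange(2 * n),
            "time": t_all,
            "channel": channel,
            "fluorescence": f,
        }
    )

    # ground-truth zdF/F profiles on the peri-event bin grid, mirroring the
    # documented smoothing/binning convention analytically. The z scale uses
    # the expected session sd of dF/F: transient variance plus the
    # closed-form contribution of measurement noise after zero-phase
    # low-pass filtering (|H|^4 variance gain) and the isosbestic fit.
    rule = AlignmentRule()
    mu = float(dff_sig.mean())
    sigma2_true = float(dff_sig.var())
    if config.noise_sd > 0:
        cutoff, order, nyq = 10.0, 4, rate / 2.0
        u = np.linspace(0.0, 1.0, 4097)
        gain = np.trapezoid(1.0 / (1.0 + (u * nyq / cutoff) ** (2 * order)) ** 2, u)
        slope0 = config.baseline_signal / config.baseline_reference
        fitted = config.baseline_signal * bleach[0::2] * artifact[0::2]
        sigma2_noise = (
            gain * config.noise_sd**2 * (1.0 + slope0**2) * float(np.mean(1.0 / fitted**2))
        )
    else:
        sigma2_noise = 0.0
    sigma = float(np.sqrt(sigma2_true + sigma2_noise))
    profiles: dict[str, list[np.ndarray]] = {}
    lo, hi = rule.window
    for b in truth.bouts:
        mask = (t_sig >= b.anchor + lo) & (t_sig < b.anchor + hi)
        if sigma < 1e-15 or not mask.any():
            prof = np.zeros(rule.n_bins)
        else:
            zw = smooth_gaussian((dff_sig[mask] - mu) / sigma, rule.smooth_sigma)
            idx = np.clip(
                np.floor((t_sig[mask] - b.anchor - lo) / rule.bin_width).astype(int),
                0,
                rule.n_bins - 1,
            )
            sums = np.bincount(idx, weights=zw, minlength=rule.n_bins)
            cnts = np.bincount(idx, minlength=rule.n_bins)
            prof = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
        profiles.setdefault(b.type, []).append(prof)
    truth.true_timecourse = {
        tp: np.mean(np.stack(ps), axis=0) for tp, ps in profiles.items()
    }
    truth.bin_times = rule.bin_centers

    return PhotometrySession(
        records=records,
        animal=animal,
        hemisphere=hemisphere,
        channel_rate=rate,
        extras={
            "artifact": artifact[0::2].copy(),
            "dff_true": dff_sig,
        },
    )


def simulate_session(
    config: SimConfig,
    geometry: MazeGeometry | None = None,
    animal: str = "animal0",
    hemisphere: str = "left",
) -> tuple[PoseTrack, pd.DataFrame, GroundTruth, PhotometrySession]:
    """Trajectory + photometry in one call."""
    track, events, truth = simulate_trajectory(config, geometry)
    session = simulate_photometry(config, truth, animal=animal, hemisphere=hemisphere)
    return track, events, truth, session
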