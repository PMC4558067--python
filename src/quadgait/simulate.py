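"""Synthetic gait generator.

Produces trial-level footfall events and nose/tail-base landmark trajectories
with the statistical structure the downstream analysis assumes: a symmetrical
lateral-sequence gait with per-limb phases and duty factors, forward COM
motion with sinusoidal mediolateral sway, gender-specific linear-in-day
treatment drift, per-mouse random intercepts, and a cohort-staggered day
schedule.  Every generated dataset carries its generating parameters so
recovery tests can close the loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from quadgait.kinematics import LandmarkTrack
from quadgait.strides import LIMBS, ContactInterval

__all__ = [
    "GaitPattern",
    "EffectModel",
    "StudyDesign",
    "StudyDataset",
    "default_walk_pattern",
    "simulate_stride_events",
    "simulate_trajectory",
    "simulate_study",
    "simulate_daily_records",
    "DEFAULT_DAY_SCHEDULE",
    "PARAM_FIELDS",
]

logger = logging.getLogger(__name__)

#: Lateral-sequence walk touchdown phases (reference limb LH at 0).
WALK_PHASES = {"LH": 0.0, "LF": 0.25, "RH": 0.5, "RF": 0.75}

#: Staggered day schedule per cohort: all cohorts at baseline (day 0) and
#: day 7; cohort 1 on days 1-4, cohort 2 on days 1, 2, 5, 6, cohort 3 on
#: days 3-6.
DEFAULT_DAY_SCHEDULE: dict[int, tuple[int, ...]] = {
    1: (0, 1, 2, 3, 4, 7),
    2: (0, 1, 2, 5, 6, 7),
    3: (0, 3, 4, 5, 6, 7),
}

#: Per-stride gait parameters the longitudinal effect model acts on.
PARAM_FIELDS = ("speed", "stride_length", "duty_factor", "sway_amplitude", "trunk_length")

#: Truncation bounds keeping drawn parameters physically meaningful.
_PARAM_BOUNDS = {
    "speed": (0.5, math.inf),
    "stride_length": (0.1, math.inf),
    "duty_factor": (0.05, 1.0),
    "sway_amplitude": (0.0, math.inf),
    "trunk_length": (0.5, math.inf),
}

GENDERS = ("F", "M")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GaitPattern:
    """Kinematic parameters of one (or a run of identical) stride cycles."""

    stride_duration: float
    stride_length: float
    limb_phases: dict[str, float] = field(default_factory=lambda: dict(WALK_PHASES))
    duty_factors: dict[str, float] = field(
        default_factory=lambda: {limb: 0.6 for limb in LIMBS}
    )
    sway_amplitude: float = 0.0
    trunk_length: float = 7.0

    def __post_init__(self) -> None:
        if not (self.stride_duration > 0 and math.isfinite(self.stride_duration)):
            raise ValueError("stride_duration must be a positive finite number")
        if not (self.stride_length >= 0 and math.isfinite(self.stride_length)):
            raise ValueError("stride_length must be non-negative and finite")
        if self.sway_amplitude < 0 or not math.isfinite(self.sway_amplitude):
            raise ValueError("sway_amplitude must be non-negative and finite")
        if self.trunk_length <= 0 or not math.isfinite(self.trunk_length):
            raise ValueError("trunk_length must be positive and finite")
        for limb in LIMBS:
            phase = self.limb_phases.get(limb)
            if phase is None or not 0.0 <= phase < 1.0:
                raise ValueError(f"limb phase for {limb} must lie in [0, 1)")
            duty = self.duty_factors.get(limb)
            if duty is None or not 0.0 < duty <= 1.0:
                raise ValueError(f"duty factor for {limb} must lie in (0, 1]")

    @property
    def speed(self) -> float:
        return self.stride_length / self.stride_duration


def default_walk_pattern(
    speed: float = 20.0,
    stride_length: float = 5.0,
    duty_factor: float = 0.6,
    sway_amplitude: float = 0.15,
    trunk_length: float = 7.0,
) -> GaitPattern:
    """Canonical lateral-sequence walk (phases 0/0.25/0.5/0.75)."""
    return GaitPattern(
        stride_duration=stride_length / speed,
        stride_length=stride_length,
        limb_phases=dict(WALK_PHASES),
        duty_factors={limb: duty_factor for limb in LIMBS},
        sway_amplitude=sway_amplitude,
        trunk_length=trunk_length,
    )


# ---------------------------------------------------------------------------
# Footfall events
# ---------------------------------------------------------------------------


def _events_for_sequence(
    patterns: list[GaitPattern], frame_rate: float
) -> list[ContactInterval]:
    """Footfall events for a sequence of per-stride patterns.

    Stride k spans [t_k, t_k + T_k) with t_k the cumulative duration of
    preceding strides.  Each limb touches down at round((t_k + phase*T_k)*fps)
    and stays down round(duty*T_k*fps) frames; rounding is half-up.  A contact
    reaching into the limb's next touchdown is clipped to keep same-limb
    intervals disjoint (a duty factor of exactly 1 can collide after
    quantization).
    """
    fps = frame_rate
    starts = np.concatenate([[0.0], np.cumsum([p.stride_duration for p in patterns])])
    raw: dict[str, list[tuple[int, int]]] = {limb: [] for limb in LIMBS}
    # k = -1 is a warm-up cycle: the animal enters the trial mid-gait, so
    # limbs whose contact wraps across the first reference touchdown are
    # already on the ground.  Warm-up touchdown frames may be negative; only
    # the part overlapping the trial matters (stride windows clip contacts).
    for k in range(-1, len(patterns)):
        pat = patterns[max(k, 0)]
        T = pat.stride_duration
        t0 = starts[k] if k >= 0 else -T
        for limb in LIMBS:
            contact = _round_half_up(pat.duty_factors[limb] * T * fps)
            if contact < 1:
                raise ValueError(
                    f"duty factor {pat.duty_factors[limb]} of limb {limb} yields a "
                    f"zero-frame contact at {fps} fps (stride duration {T} s)"
                )
            td = _round_half_up((t0 + pat.limb_phases[limb] * T) * fps)
            if k < 0 and td + contact <= 0:
                continue
            raw[limb].append((td, td + contact))
    events: list[ContactInterval] = []
    for limb in LIMBS:
        ivals = sorted(raw[limb])
        for i, (td, lo) in enumerate(ivals):
            if i + 1 < len(ivals):
                lo = min(lo, ivals[i + 1][0])
            events.append(ContactInterval(limb=limb, touchdown_frame=td, liftoff_frame=lo))
    events.sort(key=lambda c: (c.touchdown_frame, c.limb))
    return events


def simulate_stride_events(
    pattern: GaitPattern,
    n_strides: int,
    frame_rate: float = 200.0,
    rng: np.random.Generator | None = None,
) -> list[ContactInterval]:
    """Deterministic footfall events for ``n_strides`` identical cycles.

    Emits one contact interval per limb per stride; the final reference
    touchdown opens no complete cycle, so segmentation recovers exactly
    ``n_strides - 1`` strides.  ``rng`` is accepted for interface symmetry
    but unused (event times are deterministic given the pattern).
    """
    del rng
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    return _events_for_sequence([pattern] * n_strides, frame_rate)


# ---------------------------------------------------------------------------
# Landmark trajectories
# ---------------------------------------------------------------------------


def _track_for_sequence(
    patterns: list[GaitPattern],
    frame_rate: float,
    com_fraction: float,
    noise_sd: float,
    rng: np.random.Generator | None,
) -> LandmarkTrack:
    """Landmark track for a sequence of per-stride patterns.

    The COM advances at each stride's speed and sways sinusoidally with one
    full period per stride (phase continuous across strides).  The nose sits
    ``com_fraction * trunk_length`` ahead of the COM along the instantaneous
    travel direction and the tail base ``(1 - com_fraction) * trunk_length``
    behind, so recomputing the COM from the landmarks at the same fraction is
    exact (before noise).  Frames extend one stride past the last cycle so
    every emitted contact lies inside the track.
    """
    if not 0.0 < com_fraction < 1.0:
        raise ValueError("com_fraction must lie in (0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    durations = np.array([p.stride_duration for p in patterns])
    t_bounds = np.concatenate([[0.0], np.cumsum(durations)])
    x_bounds = np.concatenate(
        [[0.0], np.cumsum([p.stride_length for p in patterns])]
    )
    total_time = t_bounds[-1] + durations[-1]  # one trailing stride of margin
    n_frames = _round_half_up(total_time * frame_rate) + 1
    frames = np.arange(n_frames, dtype=np.int64)
    t = frames / frame_rate

    # Stride index per frame; frames past the last cycle extrapolate it.
    k = np.clip(np.searchsorted(t_bounds, t, side="right") - 1, 0, len(patterns) - 1)
    T_k = durations[k]
    v_k = np.array([p.speed for p in patterns])[k]
    A_k = np.array([p.sway_amplitude for p in patterns])[k]
    L_k = np.array([p.trunk_length for p in patterns])[k]
    local = t - t_bounds[k]

    x = x_bounds[k] + v_k * local
    theta = 2.0 * np.pi * (k + local / T_k)
    y = A_k * np.sin(theta)

    vx = v_k
    vy = A_k * (2.0 * np.pi / T_k) * np.cos(theta)
    norm = np.hypot(vx, vy)
    d_hat = np.stack([vx / norm, vy / norm], axis=1)

    com = np.stack([x, y], axis=1)
    nose = com + (com_fraction * L_k)[:, None] * d_hat
    tail = com - ((1.0 - com_fraction) * L_k)[:, None] * d_hat
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        nose = nose + rng.normal(0.0, noise_sd, nose.shape)
        tail = tail + rng.normal(0.0, noise_sd, tail.shape)
    return LandmarkTrack(
        frame_rate=frame_rate, frames=frames, nose=nose, tail_base=tail
    )


def simulate_trajectory(
    pattern: GaitPattern,
    n_strides: int,
    frame_rate: float = 200.0,
    com_fraction: float = 0.415,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LandmarkTrack:
    """Landmark trajectory for ``n_strides`` identical cycles."""
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    return _track_for_sequence(
        [pattern] * n_strides, frame_rate, com_fraction, noise_sd, rng
    )


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------


def _zero_params() -> dict[str, float]:
    return {f: 0.0 for f in PARAM_FIELDS}


def _default_baseline() -> dict[str, dict[str, float]]:
    base = {
        "speed": 20.0,
        "stride_length": 5.0,
        "duty_factor": 0.6,
        "sway_amplitude": 0.15,
        "trunk_length": 7.0,
    }
    return {"F": dict(base), "M": {**base, "trunk_length": 7.5}}


@dataclass
class EffectModel:
    """Longitudinal effect structure: baseline + slope·day + mouse + noise.

    All maps are keyed by the parameter names in :data:`PARAM_FIELDS`.
    ``baseline`` and ``per_day_slopes`` are additionally keyed by gender
    ('F'/'M').
    """

    baseline: dict[str, dict[str, float]] = field(default_factory=_default_baseline)
    per_day_slopes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: _zero_params() for g in GENDERS}
    )
    mouse_intercept_sd: dict[str, float] = field(default_factory=_zero_params)
    residual_sd: dict[str, float] = field(default_factory=_zero_params)

    def __post_init__(self) -> None:
        for name, sds in (
            ("mouse_intercept_sd", self.mouse_intercept_sd),
            ("residual_sd", self.residual_sd),
        ):
            for f in PARAM_FIELDS:
                if sds.get(f, 0.0) < 0:
                    raise ValueError(f"{name}[{f}] must be >= 0")
        for g in GENDERS:
            if g not in self.baseline or g not in self.per_day_slopes:
                raise ValueError(f"baseline and per_day_slopes must cover gender {g}")


def _default_mice() -> dict[str, tuple[str, int]]:
    """mouse_id -> (gender, cohort); 5 males and 4 females over 3 cohorts."""
    return {
        "M1": ("M", 1),
        "M2": ("M", 2),
        "M3": ("M", 2),
        "M4": ("M", 3),
        "M5": ("M", 3),
        "F1": ("F", 1),
        "F2": ("F", 1),
        "F3": ("F", 2),
        "F4": ("F", 3),
    }


@dataclass
class StudyDesign:
    """Who is measured when, and how the camera samples it."""

    mice: dict[str, tuple[str, int]] = field(default_factory=_default_mice)
    day_schedule: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_DAY_SCHEDULE.items()}
    )
    strides_per_day: tuple[int, int] = (15, 25)
    frame_rate: float = 200.0
    seed: int = 0
    landmark_noise_sd: float = 0.0
    com_fraction: dict[str, float] = field(
        default_factory=lambda: {"M": 0.415, "F": 0.455}
    )

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        lo, hi = self.strides_per_day
        if lo < 1 or hi < lo:
            raise ValueError("strides_per_day must satisfy 1 <= lo <= hi")
        for mouse, (gender, cohort) in self.mice.items():
            if gender not in GENDERS:
                raise ValueError(f"mouse {mouse}: unknown gender {gender!r}")
            days = self.day_schedule.get(cohort)
            if days is None:
                raise ValueError(f"mouse {mouse}: cohort {cohort} has no day schedule")
            if 0 not in days or 7 not in days:
                raise ValueError(
                    f"cohort {cohort} schedule must include baseline (0) and day 7"
                )

    def n_mice(self, gender: str | None = None) -> int:
        if gender is None:
            return len(self.mice)
        return sum(1 for g, _ in self.mice.values() if g == gender)


@dataclass
class StudyDataset:
    """Simulated study: per-trial metadata, events, tracks, and ground truth."""

    metadata: pd.DataFrame
    contacts: dict[str, list[ContactInterval]]
    tracks: dict[str, LandmarkTrack]
    ground_truth: dict

    def trial_ids(self) -> list[str]:
        return list(self.metadata["trial_id"])


def _truncate(values: dict[str, float]) -> tuple[dict[str, float], int]:
    out = {}
    hits = 0
    for f, v in values.items():
        lo, hi = _PARAM_BOUNDS[f]
        clipped = min(max(v, lo), hi)
        if clipped != v:
            hits += 1
        out[f] = clipped
    return out, hits


def simulate_study(design: StudyDesign, effects: EffectModel) -> StudyDataset:
    """Simulate footfall events and landmark tracks for a full study.

    Per mouse, a random intercept vector is drawn once; each stride's
    parameters are baseline + slope·day + mouse offset + residual noise,
    truncated to physical bounds (a warning is logged if truncation hits
    more than 10% of draws).  Reproducible given ``design.seed``; baseline
    is coded as day 0.
    """
    rng = np.random.default_rng(design.seed)
    intercepts = {
        mouse: {
            f: rng.normal(0.0, effects.mouse_intercept_sd[f]) for f in PARAM_FIELDS
        }
        for mouse in design.mice
    }
    meta_rows = []
    contacts: dict[str, list[ContactInterval]] = {}
    tracks: dict[str, LandmarkTrack] = {}
    total_draws = 0
    truncated = 0
    lo, hi = design.strides_per_day
    for mouse, (gender, cohort) in design.mice.items():
        for day in design.day_schedule[cohort]:
            trial_id = f"{mouse}_d{day}"
            n_strides = int(rng.integers(lo, hi + 1))
            patterns = []
            for _ in range(n_strides):
                raw = {
                    f: (
                        effects.baseline[gender][f]
                        + effects.per_day_slopes[gender][f] * day
                        + intercepts[mouse][f]
                        + rng.normal(0.0, effects.residual_sd[f])
                    )
                    for f in PARAM_FIELDS
                }
                params, hits = _truncate(raw)
                total_draws += len(PARAM_FIELDS)
                truncated += hits
                patterns.append(
                    GaitPattern(
                        stride_duration=params["stride_length"] / params["speed"],
                        stride_length=params["stride_length"],
                        limb_phases=dict(WALK_PHASES),
                        duty_factors={
                            limb: params["duty_factor"] for limb in LIMBS
                        },
                        sway_amplitude=params["sway_amplitude"],
                        trunk_length=params["trunk_length"],
                    )
                )
            contacts[trial_id] = _events_for_sequence(patterns, design.frame_rate)
            tracks[trial_id] = _track_for_sequence(
                patterns,
                design.frame_rate,
                design.com_fraction[gender],
                design.landmark_noise_sd,
                rng,
            )
            meta_rows.append(
                {
                    "trial_id": trial_id,
                    "mouse_id": mouse,
                    "gender": gender,
                    "cohort": cohort,
                    "day": day,
                    "frame_rate": design.frame_rate,
                    "px_to_cm": 1.0,
                    "excluded": False,
                    "exclusion_reason": "",
                }
            )
    if total_draws and truncated / total_draws > 0.10:
        logger.warning(
            "parameter truncation hit %.1f%% of draws; generating parameters sit "
            "too close to their physical bounds",
            100.0 * truncated / total_draws,
        )
    ground_truth = {
        "seed": design.seed,
        "frame_rate": design.frame_rate,
        "strides_per_day": list(design.strides_per_day),
        "landmark_noise_sd": design.landmark_noise_sd,
        "com_fraction": dict(design.com_fraction),
        "baseline": {g: dict(v) for g, v in effects.baseline.items()},
        "per_day_slopes": {g: dict(v) for g, v in effects.per_day_slopes.items()},
        "mouse_intercept_sd": dict(effects.mouse_intercept_sd),
        "residual_sd": dict(effects.residual_sd),
        "mice": {m: {"gender": g, "cohort": c} for m, (g, c) in design.mice.items()},
        "day_schedule": {str(k): list(v) for k, v in design.day_schedule.items()},
    }
    return StudyDataset(
        metadata=pd.DataFrame(meta_rows),
        contacts=contacts,
        tracks=tracks,
        ground_truth=ground_truth,
    )


def simulate_daily_records(
    design: StudyDesign,
    baselines: dict[str, dict[str, float]],
    slopes: dict[str, dict[str, float]],
    intercept_sd: dict[str, float],
    residual_sd: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw mouse-day records directly from the linear mixed model.

    Fast record-level counterpart of :func:`simulate_study` for statistical
    calibration work (e.g. confidence-interval coverage), where the quantity
    under test is the mixed-model machinery rather than the kinematic
    pipeline.  Response columns are the keys of ``intercept_sd``.
    """
    metrics = list(intercept_sd)
    rows = []
    for mouse, (gender, cohort) in design.mice.items():
        offs = {m: rng.normal(0.0, intercept_sd[m]) for m in metrics}
        for day in design.day_schedule[cohort]:
            row = {"mouse_id": mouse, "gender": gender, "cohort": cohort, "day": day}
            for m in metrics:
                row[m] = (
                    baselines[gender][m]
                    + slopes[gender][m] * day
                    + offs[m]
                    + rng.normal(0.0, residual_sd[m])
                )
            row["n_strides"] = int(rng.integers(*design.strides_per_day) + 1)
            rows.append(row)
    return pd.DataFrame(rows)
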