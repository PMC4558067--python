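"""Per-stride locomotor performance measures.

Five measures per stride: speed (cm/s), stride length (cm), stride frequency
(Hz), mean support number (time-weighted average number of supporting limbs),
and the sway index (100 × COM path distance / straight-line displacement;
100 means a perfectly straight path).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from quadgait.kinematics import (
    ComTrajectory,
    LandmarkTrack,
    SplineSettings,
    compute_com,
    path_length,
    smooth_track,
)
from quadgait.strides import (
    DEFAULT_SYMMETRY_EPSILON,
    SYMMETRICAL,
    ContactInterval,
    Stride,
    SupportTimeline,
    annotate_strides,
    build_support_timeline,
    segment_strides,
)

__all__ = [
    "stride_length",
    "stride_speed",
    "stride_frequency",
    "mean_support_number",
    "sway_index",
    "support_from_duty_factors",
    "compute_all",
    "DEFAULT_MIN_SWAY_DISPLACEMENT",
]

logger = logging.getLogger(__name__)

#: Strides displacing the COM less than this (cm) are unusable for sway.
DEFAULT_MIN_SWAY_DISPLACEMENT = 0.1


def stride_length(com: ComTrajectory, stride: Stride) -> float:
    """Net COM displacement (cm) between the stride's start and end frames."""
    p0 = com.positions[com.index_of(stride.start_frame)]
    p1 = com.positions[com.index_of(stride.end_frame)]
    return float(np.hypot(*(p1 - p0)))


def stride_speed(com: ComTrajectory, stride: Stride) -> float:
    """Mean speed over the stride: net displacement / duration (cm/s)."""
    duration = stride.duration
    if duration <= 0:
        raise ValueError("stride duration must be positive")
    return stride_length(com, stride) / duration


def stride_frequency(stride: Stride) -> float:
    """Inverse of stride duration (Hz)."""
    duration = stride.duration
    if duration <= 0:
        raise ValueError("stride duration must be positive")
    return 1.0 / duration


def mean_support_number(timeline: SupportTimeline) -> float:
    """Time-weighted mean number of supporting limbs over a stride.

    Equals %single·1 + %double·2 + %triple·3 + %quadruple·4 expressed on the
    fraction scale; aerial (zero-support) segments carry weight 0.
    """
    fractions = timeline.support_fractions()
    return float(sum(k * frac for k, frac in fractions.items()))


def support_from_duty_factors(
    contacts: list[ContactInterval], stride: Stride
) -> float:
    """Mean support number via the duty-factor identity.

    The time-weighted mean support count equals the sum over limbs of
    (contact duration clipped to the stride window) / (window length).
    Kept as an independent computation path for validation.
    """
    window = stride.n_frames
    total = 0
    for c in contacts:
        lo = max(c.touchdown_frame, stride.start_frame)
        hi = min(c.liftoff_frame, stride.end_frame)
        if hi > lo:
            total += hi - lo
    return total / window


def sway_index(
    com: ComTrajectory,
    stride: Stride,
    min_displacement: float = DEFAULT_MIN_SWAY_DISPLACEMENT,
) -> float:
    """100 × (COM path distance over the stride) / (net displacement).

    Equals 100 for a perfectly linear path, larger with mediolateral sway.
    Raises ``ValueError`` when the net displacement falls below
    ``min_displacement`` (a stationary or turning animal), which callers
    treat as "stride unusable for sway".
    """
    disp = stride_length(com, stride)
    if disp <= min_displacement:
        raise ValueError(
            f"net COM displacement {disp:.4g} cm is below the minimum "
            f"{min_displacement} cm; sway index undefined"
        )
    return 100.0 * path_length(com, stride.start_frame, stride.end_frame) / disp


def _metric_row(
    contacts: list[ContactInterval],
    com: ComTrajectory,
    stride: Stride,
    min_sway_displacement: float,
) -> dict:
    timeline = build_support_timeline(contacts, stride)
    fractions = timeline.support_fractions()
    msn = mean_support_number(timeline)
    msn_duty = support_from_duty_factors(contacts, stride)
    if abs(msn - msn_duty) > 1e-9:  # the two routes must agree exactly
        raise AssertionError(
            f"support-number identity violated: timeline {msn!r} vs duty {msn_duty!r}"
        )
    length = stride_length(com, stride)
    freq = stride_frequency(stride)
    row = {
        "start_frame": stride.start_frame,
        "end_frame": stride.end_frame,
        "classification": stride.classification,
        "speed_cm_s": length * freq,
        "stride_length_cm": length,
        "stride_frequency_hz": freq,
        "mean_support_number": msn,
        "sway_index": np.nan,
        "sway_usable": False,
    }
    for k in range(5):
        row[f"pct_support_{k}"] = 100.0 * fractions[k]
    try:
        row["sway_index"] = sway_index(com, stride, min_sway_displacement)
        row["sway_usable"] = True
    except ValueError as exc:
        logger.info("stride [%d, %d): %s", stride.start_frame, stride.end_frame, exc)
    return row


def compute_all(
    contacts: list[ContactInterval],
    track: LandmarkTrack,
    com_fraction: float,
    *,
    reference_limb: str = "LH",
    spline_settings: SplineSettings | None = None,
    symmetry_epsilon: float = DEFAULT_SYMMETRY_EPSILON,
    min_sway_displacement: float = DEFAULT_MIN_SWAY_DISPLACEMENT,
    trial_id: str = "",
) -> pd.DataFrame:
    """Full per-trial pipeline: smooth → COM → segment → classify → measure.

    Returns one row per stride (included symmetrical strides flagged
    ``included=True``; asymmetrical strides are carried with their exclusion
    reason).  All metrics are computed on the smoothed COM trajectory.
    """
    smoothed = smooth_track(track, spline_settings)
    com = compute_com(smoothed, com_fraction)
    strides = segment_strides(contacts, reference_limb, track.frame_rate)
    annotate_strides(contacts, strides, epsilon=symmetry_epsilon)
    rows = []
    for idx, stride in enumerate(strides):
        row = _metric_row(contacts, com, stride, min_sway_displacement)
        included = stride.classification == SYMMETRICAL and not stride.excluded
        reason = ""
        if stride.excluded:
            reason = stride.exclusion_reason or "excluded in metadata"
        elif stride.classification != SYMMETRICAL:
            reason = "asymmetrical gait"
        row.update(
            {
                "trial_id": trial_id,
                "stride_index": idx,
                "included": included,
                "exclusion_reason": reason,
            }
        )
        rows.append(row)
    columns = [
        "trial_id",
        "stride_index",
        "start_frame",
        "end_frame",
        "classification",
        "included",
        "exclusion_reason",
        "speed_cm_s",
        "stride_length_cm",
        "stride_frequency_hz",
        "pct_support_0",
        "pct_support_1",
        "pct_support_2",
        "pct_support_3",
        "pct_support_4",
        "mean_support_number",
        "sway_index",
        "sway_usable",
    ]
    return pd.DataFrame(rows, columns=columns)
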