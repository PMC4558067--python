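"""Stride segmentation, gait-symmetry classification, and support timelines.

Contact intervals are half-open in frames: touchdown is the first frame of
ground contact, liftoff the first subsequent frame without contact.  Strides
run from one touchdown of a reference limb to the next touchdown of the same
limb, again half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIMBS",
    "ContactInterval",
    "Stride",
    "SupportTimeline",
    "segment_strides",
    "limb_phase",
    "classify_stride",
    "build_support_timeline",
    "DEFAULT_SYMMETRY_EPSILON",
]

logger = logging.getLogger(__name__)

#: Limb codes: left/right hindlimb, left/right forelimb.
LIMBS = ("LH", "LF", "RH", "RF")

#: Girdle pairs whose touchdowns must be ~half a cycle apart in a
#: symmetrical gait.
GIRDLES = (("LH", "RH"), ("LF", "RF"))

DEFAULT_SYMMETRY_EPSILON = 0.1

SYMMETRICAL = "symmetrical"
ASYMMETRICAL = "asymmetrical"


@dataclass(frozen=True)
class ContactInterval:
    """One limb's continuous ground-contact episode, frames [touchdown, liftoff)."""

    limb: str
    touchdown_frame: int
    liftoff_frame: int

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb code {self.limb!r}; expected one of {LIMBS}")
        if self.liftoff_frame <= self.touchdown_frame:
            raise ValueError(
                f"liftoff_frame must exceed touchdown_frame "
                f"({self.limb}: [{self.touchdown_frame}, {self.liftoff_frame}))"
            )

    @property
    def duration_frames(self) -> int:
        return self.liftoff_frame - self.touchdown_frame


@dataclass
class Stride:
    """A reference-limb-to-reference-limb cycle window, frames [start, end)."""

    reference_limb: str
    start_frame: int
    end_frame: int
    frame_rate: float
    classification: str | None = None
    limb_phases: dict[str, float | None] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def duration(self) -> float:
        """Stride duration in seconds."""
        return (self.end_frame - self.start_frame) / self.frame_rate

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SupportTimeline:
    """Instantaneous support counts over a stride window.

    ``breakpoints`` (len m+1) partition the window into m half-open segments;
    ``counts`` (len m) is the number of limbs in ground contact on each
    segment.  Segments with equal counts are deliberately not merged.
    """

    breakpoints: np.ndarray
    counts: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.breakpoints.shape[0] != self.counts.shape[0] + 1:
            raise ValueError("need one more breakpoint than segment counts")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any((self.counts < 0) | (self.counts > 4)):
            raise ValueError("support counts must lie in 0..4")

    @property
    def segment_frames(self) -> np.ndarray:
        return np.diff(self.breakpoints)

    def support_fractions(self) -> dict[int, float]:
        """Fraction of the window spent at each support count 0..4."""
        total = self.breakpoints[-1] - self.breakpoints[0]
        out = {k: 0.0 for k in range(5)}
        for seg, count in zip(self.segment_frames, self.counts):
            out[int(count)] += seg / total
        return out


def _check_contacts(contacts: list[ContactInterval]) -> None:
    by_limb: dict[str, list[ContactInterval]] = {}
    for c in contacts:
        by_limb.setdefault(c.limb, []).append(c)
    for limb, ivals in by_limb.items():
        ivals = sorted(ivals, key=lambda c: c.touchdown_frame)
        for a, b in zip(ivals, ivals[1:]):
            if b.touchdown_frame < a.liftoff_frame:
                raise ValueError(
                    f"overlapping contact intervals for limb {limb}: "
                    f"[{a.touchdown_frame}, {a.liftoff_frame}) and "
                    f"[{b.touchdown_frame}, {b.liftoff_frame})"
                )


def segment_strides(
    contacts: list[ContactInterval],
    reference_limb: str = "LH",
    frame_rate: float = 200.0,
) -> list[Stride]:
    """Cut strides at consecutive touchdowns of the reference limb.

    Returns one stride per consecutive touchdown pair, ordered in time; the
    trailing touchdown opens no partial stride.  Fewer than two reference
    touchdowns yields an empty list (logged, not an error).
    """
    if reference_limb not in LIMBS:
        raise ValueError(f"unknown reference limb {reference_limb!r}")
    _check_contacts(contacts)
    touchdowns = sorted(
        c.touchdown_frame for c in contacts if c.limb == reference_limb
    )
    if len(touchdowns) < 2:
        logger.info(
            "fewer than 2 touchdowns of reference limb %s: no strides emitted",
            reference_limb,
        )
        return []
    return [
        Stride(
            reference_limb=reference_limb,
            start_frame=td0,
            end_frame=td1,
            frame_rate=frame_rate,
        )
        for td0, td1 in zip(touchdowns, touchdowns[1:])
    ]


def limb_phase(
    contacts: list[ContactInterval], stride: Stride, limb: str
) -> float | None:
    """Touchdown phase of ``limb`` within the stride cycle, in [0, 1).

    Phase is (first touchdown of the limb at or after the stride start −
    stride start) / window length; ``None`` if the limb never touches down
    inside the window.
    """
    tds = sorted(
        c.touchdown_frame
        for c in contacts
        if c.limb == limb
        and stride.start_frame <= c.touchdown_frame < stride.end_frame
    )
    if not tds:
        return None
    return (tds[0] - stride.start_frame) / stride.n_frames


def classify_stride(
    phases: dict[str, float | None],
    epsilon: float = DEFAULT_SYMMETRY_EPSILON,
) -> str:
    """Classify a stride as symmetrical or asymmetrical from limb phases.

    Symmetrical iff all four limbs have a phase and, within each girdle
    (LH/RH and LF/RF), the circular phase difference lies within 0.5 ± ε
    (inclusive).  A missing limb phase forces an asymmetrical call.
    """
    for limb in LIMBS:
        if phases.get(limb) is None:
            logger.debug("limb %s has no touchdown in window: asymmetrical", limb)
            return ASYMMETRICAL
    for a, b in GIRDLES:
        d = abs(phases[a] - phases[b])  # type: ignore[operator]
        d = min(d, 1.0 - d)  # circular difference, in [0, 0.5]
        if d < 0.5 - epsilon - 1e-12:
            return ASYMMETRICAL
    return SYMMETRICAL


def build_support_timeline(
    contacts: list[ContactInterval], stride: Stride
) -> SupportTimeline:
    """Event-based support-count timeline over the stride window.

    Contact intervals are clipped to [start, end); breakpoints are the sorted
    unique clipped event frames plus the window ends; each segment's count is
    the number of limbs whose clipped interval covers it.  Zero-support
    (aerial) segments are kept explicitly.
    """
    start, end = stride.start_frame, stride.end_frame
    clipped: list[tuple[int, int]] = []
    events = {start, end}
    for c in contacts:
        lo = max(c.touchdown_frame, start)
        hi = min(c.liftoff_frame, end)
        if lo >= hi:
            continue
        clipped.append((lo, hi))
        events.add(lo)
        events.add(hi)
    breakpoints = np.array(sorted(events), dtype=np.int64)
    counts = np.zeros(breakpoints.shape[0] - 1, dtype=np.int64)
    for lo, hi in clipped:
        i = np.searchsorted(breakpoints, lo)
        j = np.searchsorted(breakpoints, hi)
        counts[i:j] += 1
    return SupportTimeline(
        breakpoints=breakpoints, counts=counts, frame_rate=stride.frame_rate
    )


def annotate_strides(
    contacts: list[ContactInterval],
    strides: list[Stride],
    epsilon: float = DEFAULT_SYMMETRY_EPSILON,
) -> list[Stride]:
    """Fill limb phases and symmetry classification on each stride in place."""
    for stride in strides:
        phases = {limb: limb_phase(contacts, stride, limb) for limb in LIMBS}
        stride.limb_phases = phases
        stride.classification = classify_stride(phases, epsilon=epsilon)
    return strides
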