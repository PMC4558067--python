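"""Landmark-track smoothing, center-of-mass construction, and path geometry.

Tracks hold the dorsal-view 2D positions of two landmarks (nose tip and tail
base) on an integer frame clock.  The center of mass (COM) is modeled as a
fixed fraction along the nose-to-tail-base vector; smoothing uses a quintic
smoothing spline with an absolute sum-of-squared-residuals tolerance applied
per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate

__all__ = [
    "LandmarkTrack",
    "ComTrajectory",
    "SplineSettings",
    "smooth_track",
    "compute_com",
    "trunk_length_cv",
    "path_length",
]

#: Minimum number of valid frames for a quintic (degree-5) spline fit.
MIN_VALID_FRAMES = 6


@dataclass
class LandmarkTrack:
    """Nose and tail-base positions for one trial, in cm, on a frame clock.

    Parameters
    ----------
    frame_rate
        Frames per second.
    frames
        Strictly increasing integer frame indices, shape (n,).
    nose, tail_base
        Per-frame 2D positions, shape (n, 2), cm.
    valid_mask
        Per-frame flag; ``False`` marks occluded frames whose coordinates
        are ignored by smoothing.  Defaults to all valid.
    """

    frame_rate: float
    frames: np.ndarray
    nose: np.ndarray
    tail_base: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.nose = np.asarray(self.nose, dtype=float)
        self.tail_base = np.asarray(self.tail_base, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.frames.shape[0], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frames.ndim != 1 or np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        n = self.frames.shape[0]
        for name, arr in (("nose", self.nose), ("tail_base", self.tail_base)):
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape (n, 2)")
        if self.valid_mask.shape != (n,):
            raise ValueError("valid_mask must have shape (n,)")
        if int(self.valid_mask.sum()) < MIN_VALID_FRAMES:
            raise ValueError(
                f"at least {MIN_VALID_FRAMES} valid frames are required, "
                f"got {int(self.valid_mask.sum())}"
            )
        coords = np.concatenate(
            [self.nose[self.valid_mask], self.tail_base[self.valid_mask]]
        )
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ComTrajectory:
    """Per-frame 2D COM positions sharing the frame domain of a source track."""

    frame_rate: float
    frames: np.ndarray
    positions: np.ndarray
    com_fraction: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.frames.shape[0], 2):
            raise ValueError("positions must have shape (n, 2)")
        if not 0.0 < self.com_fraction < 1.0:
            raise ValueError("com_fraction must lie in (0, 1)")

    def index_of(self, frame: int) -> int:
        """Array index of a frame number; raises if the frame is absent."""
        idx = int(np.searchsorted(self.frames, frame))
        if idx >= self.frames.shape[0] or self.frames[idx] != frame:
            raise KeyError(f"frame {frame} not in trajectory domain")
        return idx


@dataclass(frozen=True)
class SplineSettings:
    """Quintic smoothing-spline settings.

    ``tolerance`` is the upper bound on the per-coordinate sum of squared
    residuals over valid frames, in cm² (default 0.01 cm² = 1 mm²).
    """

    tolerance: float = 0.01
    order: int = 5

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.order != 5:
            raise ValueError("only quintic (order 5) splines are supported")


def _smooth_column(
    t_valid: np.ndarray,
    y_valid: np.ndarray,
    t_all: np.ndarray,
    settings: SplineSettings,
) -> np.ndarray:
    tck = interpolate.splrep(t_valid, y_valid, k=settings.order, s=settings.tolerance)
    return interpolate.splev(t_all, tck)


def smooth_track(track: LandmarkTrack, settings: SplineSettings | None = None) -> LandmarkTrack:
    """Smooth each landmark coordinate with a quintic smoothing spline.

    Each of the four coordinate series (nose x/y, tail x/y) is fit on the
    valid frames subject to sum-of-squared-residuals ≤ ``settings.tolerance``
    and evaluated on every frame, filling occluded frames by spline
    evaluation.  The returned track has ``valid_mask`` all true.
    """
    settings = settings or SplineSettings()
    t_all = track.frames.astype(float) / track.frame_rate
    t_valid = t_all[track.valid_mask]
    nose = np.empty_like(track.nose)
    tail = np.empty_like(track.tail_base)
    for j in range(2):
        nose[:, j] = _smooth_column(
            t_valid, track.nose[track.valid_mask, j], t_all, settings
        )
        tail[:, j] = _smooth_column(
            t_valid, track.tail_base[track.valid_mask, j], t_all, settings
        )
    return replace(
        track,
        nose=nose,
        tail_base=tail,
        valid_mask=np.ones(track.n_frames, dtype=bool),
    )


def compute_com(track: LandmarkTrack, com_fraction: float) -> ComTrajectory:
    """COM proxy: per frame, ``nose + com_fraction * (tail_base - nose)``.

    ``com_fraction`` is the fraction of the nose-to-tail-base vector at which
    the point mass sits (0.415 for males, 0.455 for females by default
    elsewhere in this package).
    """
    if not 0.0 < com_fraction < 1.0:
        raise ValueError("com_fraction must lie in (0, 1)")
    vec = track.tail_base - track.nose
    degenerate = np.hypot(vec[:, 0], vec[:, 1]) == 0.0
    if np.any(degenerate):
        frame = int(track.frames[np.argmax(degenerate)])
        raise ValueError(f"nose and tail base coincide at frame {frame}")
    positions = track.nose + com_fraction * vec
    return ComTrajectory(
        frame_rate=track.frame_rate,
        frames=track.frames.copy(),
        positions=positions,
        com_fraction=com_fraction,
    )


def trunk_length_cv(
    track: LandmarkTrack, window: tuple[int, int] | None = None
) -> float:
    """Coefficient of variation (%) of the nose-to-tail-base distance.

    ``window`` is an inclusive (start_frame, end_frame) pair; ``None`` uses
    the whole track.  The SD uses the n−1 denominator.
    """
    if window is None:
        sel = np.ones(track.n_frames, dtype=bool)
    else:
        start, end = window
        sel = (track.frames >= start) & (track.frames <= end)
    if int(sel.sum()) < 2:
        raise ValueError("window must contain at least 2 frames")
    lengths = np.linalg.norm(track.tail_base[sel] - track.nose[sel], axis=1)
    mean = lengths.mean()
    if mean == 0.0:
        raise ValueError("mean trunk length is zero over the window")
    return 100.0 * lengths.std(ddof=1) / mean


def path_length(traj: ComTrajectory, start_frame: int, end_frame: int) -> float:
    """Total path distance travelled between two frames (inclusive ends).

    Sums Euclidean distances between consecutive per-frame positions over
    [start_frame, end_frame].
    """
    if start_frame >= end_frame:
        raise ValueError("start_frame must precede end_frame")
    i = traj.index_of(start_frame)
    j = traj.index_of(end_frame)
    seg = np.diff(traj.positions[i : j + 1], axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())
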