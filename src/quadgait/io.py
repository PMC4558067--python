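"""CSV schemas, pipeline configuration, and provenance.

All tabular I/O is UTF-8 CSV with a header row; frames are 0-based integers
and windows half-open.  Positions may be stored in pixels (converted once at
read time via each trial's ``px_to_cm``) or in cm (scale 1.0).  Every output
directory gets a provenance JSON recording config hash, seed, and package
version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from quadgait import __version__
from quadgait.kinematics import LandmarkTrack
from quadgait.strides import LIMBS, ContactInterval

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "read_contacts",
    "write_contacts",
    "read_landmarks",
    "write_landmarks",
    "read_metadata",
    "write_metadata",
    "read_metrics",
    "write_metrics",
    "read_daily",
    "write_daily",
    "write_provenance",
]

GENDERS = ("F", "M")


class SchemaError(ValueError):
    """Raised when an input file violates its schema; lists offending rows."""


@dataclass
class PipelineConfig:
    """End-to-end analysis settings, serialized alongside every output."""

    com_fraction: dict[str, float] = field(
        default_factory=lambda: {"M": 0.415, "F": 0.455}
    )
    spline_tolerance_cm2: float = 0.01
    symmetry_epsilon: float = 0.1
    min_sway_displacement_cm: float = 0.1
    reference_limb: str = "LH"
    baseline_day_value: float = 0.0
    reml: bool = True
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, frac in self.com_fraction.items():
            if not 0.0 < frac < 1.0:
                raise ValueError(f"com_fraction[{g}] must lie in (0, 1)")
        if self.spline_tolerance_cm2 <= 0:
            raise ValueError("spline_tolerance_cm2 must be positive")
        if not 0.0 <= self.symmetry_epsilon < 0.5:
            raise ValueError("symmetry_epsilon must lie in [0, 0.5)")
        if self.min_sway_displacement_cm < 0:
            raise ValueError("min_sway_displacement_cm must be non-negative")
        if self.reference_limb not in LIMBS:
            raise ValueError(f"reference_limb must be one of {LIMBS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _check_int(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() | (vals != vals.round())
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise SchemaError(f"{what}: non-integer {column} at rows {rows}")
    return vals.astype(np.int64)


# ---------------------------------------------------------------------------
# contacts.csv: trial_id, limb, touchdown_frame, liftoff_frame
# ---------------------------------------------------------------------------


def read_contacts(path: str | Path) -> dict[str, list[ContactInterval]]:
    df = pd.read_csv(path, dtype={"trial_id": str})
    _require_columns(
        df, ["trial_id", "limb", "touchdown_frame", "liftoff_frame"], "contacts"
    )
    if df.empty:
        return {}
    bad_limb = ~df["limb"].isin(LIMBS)
    if bad_limb.any():
        rows = df.index[bad_limb].tolist()[:10]
        codes = df.loc[bad_limb, "limb"].unique().tolist()
        raise SchemaError(f"contacts: unknown limb codes {codes} at rows {rows}")
    df["touchdown_frame"] = _check_int(df, "touchdown_frame", "contacts")
    df["liftoff_frame"] = _check_int(df, "liftoff_frame", "contacts")
    dup = df.duplicated(subset=["trial_id", "limb", "touchdown_frame"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise SchemaError(
            f"contacts: duplicate (trial_id, limb, touchdown_frame) keys at rows {rows}"
        )
    out: dict[str, list[ContactInterval]] = {}
    for row in df.itertuples(index=True):
        try:
            ival = ContactInterval(
                limb=row.limb,
                touchdown_frame=int(row.touchdown_frame),
                liftoff_frame=int(row.liftoff_frame),
            )
        except ValueError as exc:
            raise SchemaError(f"contacts: row {row.Index}: {exc}") from exc
        out.setdefault(row.trial_id, []).append(ival)
    return out


def write_contacts(contacts: dict[str, list[ContactInterval]], path: str | Path) -> None:
    rows = [
        {
            "trial_id": trial,
            "limb": c.limb,
            "touchdown_frame": c.touchdown_frame,
            "liftoff_frame": c.liftoff_frame,
        }
        for trial, ivals in contacts.items()
        for c in ivals
    ]
    pd.DataFrame(
        rows, columns=["trial_id", "limb", "touchdown_frame", "liftoff_frame"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# landmarks.csv: trial_id, frame, nose_x, nose_y, tail_x, tail_y, valid
# ---------------------------------------------------------------------------

_LANDMARK_COLS = ["trial_id", "frame", "nose_x", "nose_y", "tail_x", "tail_y", "valid"]


def read_landmarks(
    path: str | Path, metadata: pd.DataFrame
) -> dict[str, LandmarkTrack]:
    """Read landmark tracks, converting px → cm per trial via metadata."""
    df = pd.read_csv(path, dtype={"trial_id": str})
    _require_columns(df, _LANDMARK_COLS, "landmarks")
    if df.empty:
        return {}
    df["frame"] = _check_int(df, "frame", "landmarks")
    meta = metadata.set_index("trial_id")
    out: dict[str, LandmarkTrack] = {}
    for trial, grp in df.groupby("trial_id", sort=False):
        if trial not in meta.index:
            raise SchemaError(f"landmarks: trial {trial!r} absent from metadata")
        scale = float(meta.loc[trial, "px_to_cm"])
        frame_rate = float(meta.loc[trial, "frame_rate"])
        grp = grp.sort_values("frame")
        out[trial] = LandmarkTrack(
            frame_rate=frame_rate,
            frames=grp["frame"].to_numpy(),
            nose=grp[["nose_x", "nose_y"]].to_numpy(dtype=float) * scale,
            tail_base=grp[["tail_x", "tail_y"]].to_numpy(dtype=float) * scale,
            valid_mask=grp["valid"].astype(bool).to_numpy(),
        )
    return out


def write_landmarks(tracks: dict[str, LandmarkTrack], path: str | Path) -> None:
    """Write landmark tracks in cm (px_to_cm = 1.0 convention)."""
    frames = []
    for trial, track in tracks.items():
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial,
                    "frame": track.frames,
                    "nose_x": track.nose[:, 0],
                    "nose_y": track.nose[:, 1],
                    "tail_x": track.tail_base[:, 0],
                    "tail_y": track.tail_base[:, 1],
                    "valid": track.valid_mask,
                }
            )
        )
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=_LANDMARK_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metadata.csv
# ---------------------------------------------------------------------------

_METADATA_COLS = [
    "trial_id",
    "mouse_id",
    "gender",
    "cohort",
    "day",
    "frame_rate",
    "px_to_cm",
    "excluded",
    "exclusion_reason",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"trial_id": str, "mouse_id": str}, keep_default_na=False
    )
    _require_columns(df, _METADATA_COLS, "metadata")
    if df.empty:
        return df
    bad = ~df["gender"].isin(GENDERS)
    if bad.any():
        raise SchemaError(
            f"metadata: gender must be one of {GENDERS}; offending rows "
            f"{df.index[bad].tolist()[:10]}"
        )
    df["cohort"] = _check_int(df, "cohort", "metadata")
    df["day"] = _check_int(df, "day", "metadata")
    if ((df["day"] < 0) | (df["day"] > 7)).any():
        raise SchemaError("metadata: day must lie in 0..7")
    for col in ("frame_rate", "px_to_cm"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] <= 0).any():
            raise SchemaError(f"metadata: {col} must be positive")
    if df["trial_id"].duplicated().any():
        dups = df.loc[df["trial_id"].duplicated(), "trial_id"].tolist()
        raise SchemaError(f"metadata: duplicate trial ids {dups}")
    df["excluded"] = df["excluded"].astype(str).str.lower().isin(["true", "1"])
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False, columns=_METADATA_COLS)


# ---------------------------------------------------------------------------
# metrics.csv and daily.csv (pass-through with light validation)
# ---------------------------------------------------------------------------

_METRIC_COLS = [
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


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trial_id": str}, keep_default_na=False)
    _require_columns(df, _METRIC_COLS, "metrics")
    if df.empty:
        return df
    for col in ("included", "sway_usable"):
        df[col] = df[col].astype(str).str.lower().isin(["true", "1"])
    for col in _METRIC_COLS[7:16]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["sway_index"] = pd.to_numeric(df["sway_index"].replace("", np.nan))
    return df


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, index=False, columns=_METRIC_COLS)


_DAILY_COLS = [
    "mouse_id",
    "gender",
    "cohort",
    "day",
    "n_strides",
    "speed",
    "stride_length",
    "stride_frequency",
    "mean_support_number",
    "sway_index",
]


def read_daily(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mouse_id": str})
    _require_columns(df, _DAILY_COLS, "daily")
    if df.empty:
        return df
    df["cohort"] = _check_int(df, "cohort", "daily")
    df["day"] = _check_int(df, "day", "daily")
    df["n_strides"] = _check_int(df, "n_strides", "daily")
    if (df["n_strides"] < 1).any():
        raise SchemaError("daily: n_strides must be >= 1")
    return df


def write_daily(daily: pd.DataFrame, path: str | Path) -> None:
    daily.to_csv(path, index=False, columns=_DAILY_COLS)


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------


def write_provenance(
    out_dir: str | Path, config: PipelineConfig, extra: dict | None = None
) -> Path:
    payload = {
        "package": "quadgait",
        "version": __version__,
        "config_digest": config.digest(),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
    }
    if extra:
        payload.update(extra)
    path = Path(out_dir) / "provenance.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path
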