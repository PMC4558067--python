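"""Orchestration helpers tying the modules into the CLI pipeline."""

from __future__ import annotations

import logging

import pandas as pd

from quadgait.io import PipelineConfig
from quadgait.kinematics import LandmarkTrack, SplineSettings
from quadgait.metrics import compute_all
from quadgait.simulate import (
    DEFAULT_DAY_SCHEDULE,
    EffectModel,
    StudyDesign,
)
from quadgait.stats import (
    METRIC_COLUMNS,
    daily_means,
    fit_gait_ancova,
    fit_speed_adjusted,
)
from quadgait.strides import ContactInterval

__all__ = [
    "design_from_config",
    "effects_from_config",
    "compute_study_metrics",
    "run_analysis",
    "render_tables",
]

logger = logging.getLogger(__name__)

#: Responses re-analyzed in males with speed as a covariate.
SPEED_ADJUSTED_RESPONSES = (
    "stride_length",
    "stride_frequency",
    "mean_support_number",
    "sway_index",
)


def design_from_config(config: PipelineConfig) -> StudyDesign:
    sim = config.simulation or {}
    kwargs: dict = {"seed": config.seed, "com_fraction": dict(config.com_fraction)}
    if "mice" in sim:
        kwargs["mice"] = {m: (v["gender"], int(v["cohort"])) for m, v in sim["mice"].items()}
    if "day_schedule" in sim:
        kwargs["day_schedule"] = {
            int(k): tuple(v) for k, v in sim["day_schedule"].items()
        }
    else:
        kwargs["day_schedule"] = {k: tuple(v) for k, v in DEFAULT_DAY_SCHEDULE.items()}
    for key in ("strides_per_day", "frame_rate", "landmark_noise_sd"):
        if key in sim:
            kwargs[key] = tuple(sim[key]) if key == "strides_per_day" else sim[key]
    return StudyDesign(**kwargs)


def effects_from_config(config: PipelineConfig) -> EffectModel:
    sim = config.simulation or {}
    kwargs = {}
    for key in ("baseline", "per_day_slopes", "mouse_intercept_sd", "residual_sd"):
        if key in sim:
            kwargs[key] = sim[key]
    model = EffectModel()
    if "baseline" in kwargs:
        for g, vals in kwargs["baseline"].items():
            model.baseline[g].update(vals)
    if "per_day_slopes" in kwargs:
        for g, vals in kwargs["per_day_slopes"].items():
            model.per_day_slopes[g].update(vals)
    if "mouse_intercept_sd" in kwargs:
        model.mouse_intercept_sd.update(kwargs["mouse_intercept_sd"])
    if "residual_sd" in kwargs:
        model.residual_sd.update(kwargs["residual_sd"])
    return model


def compute_study_metrics(
    contacts: dict[str, list[ContactInterval]],
    tracks: dict[str, LandmarkTrack],
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-stride metrics for every trial in the metadata table.

    Trials flagged ``excluded`` in metadata are carried through with their
    strides marked not-included (the manual-exclusion pathway, e.g. walking
    on the side mirrors).
    """
    config = config or PipelineConfig()
    settings = SplineSettings(tolerance=config.spline_tolerance_cm2)
    frames = []
    for row in metadata.itertuples():
        trial = row.trial_id
        if trial not in contacts or trial not in tracks:
            logger.warning("trial %s missing contacts or landmarks; skipped", trial)
            continue
        table = compute_all(
            contacts[trial],
            tracks[trial],
            com_fraction=config.com_fraction[row.gender],
            reference_limb=config.reference_limb,
            spline_settings=settings,
            symmetry_epsilon=config.symmetry_epsilon,
            min_sway_displacement=config.min_sway_displacement_cm,
            trial_id=trial,
        )
        if bool(row.excluded):
            table["included"] = False
            reason = str(getattr(row, "exclusion_reason", "") or "trial excluded")
            table["exclusion_reason"] = reason
        frames.append(table)
    if not frames:
        raise ValueError("no trials could be processed")
    return pd.concat(frames, ignore_index=True)


def run_analysis(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Daily averaging plus the full statistical layer.

    Returns the mouse-day records and a results dict with one gender × day
    ANCOVA per metric and, for the non-speed metrics, the male-only
    speed-adjusted partial regression.
    """
    config = config or PipelineConfig()
    daily = daily_means(metrics, metadata)
    results: dict = {"ancova": {}, "speed_adjusted": {}}
    for metric in METRIC_COLUMNS:
        res = fit_gait_ancova(
            daily,
            metric,
            baseline_day_value=config.baseline_day_value,
            reml=config.reml,
        )
        results["ancova"][metric] = res.to_dict()
    males = daily[daily["gender"] == "M"]
    for metric in SPEED_ADJUSTED_RESPONSES:
        try:
            res = fit_speed_adjusted(
                males,
                metric,
                baseline_day_value=config.baseline_day_value,
                reml=config.reml,
            )
            results["speed_adjusted"][metric] = res.to_dict()
        except ValueError as exc:
            logger.warning("speed-adjusted fit for %s failed: %s", metric, exc)
            results["speed_adjusted"][metric] = {"error": str(exc)}
    return daily, results


def render_tables(results: dict) -> str:
    """Human-readable summary mirroring the ANCOVA / partial-regression tables."""
    lines = ["Gender x treatment-day ANCOVA (response ~ gender * day, random mouse intercept)", ""]
    header = (
        f"{'variable':<22}{'interaction':>12}{'F':>8}{'df':>10}{'p':>9}"
        f"{'female slope [95% CI]':>32}{'male slope [95% CI]':>32}"
    )
    lines.append(header)
    for metric, r in results["ancova"].items():
        fci = r["slope_female_ci"]
        mci = r["slope_male_ci"]
        lines.append(
            f"{metric:<22}{r['interaction_estimate']:>12.4g}{r['interaction_F']:>8.3g}"
            f"{str(r['df']):>10}{r['interaction_p']:>9.3g}"
            f"{r['slope_female']:>12.4g} [{fci[0]:.4g}, {fci[1]:.4g}]".rjust(32)
            + f"{r['slope_male']:>12.4g} [{mci[0]:.4g}, {mci[1]:.4g}]".rjust(32)
        )
    lines += ["", "Male-only day effect controlling for speed", ""]
    lines.append(f"{'variable':<22}{'day coef':>12}{'95% CI':>28}{'p':>9}")
    for metric, r in results["speed_adjusted"].items():
        if "error" in r:
            lines.append(f"{metric:<22}  unavailable: {r['error']}")
            continue
        ci = r["day_ci"]
        lines.append(
            f"{metric:<22}{r['day_estimate']:>12.4g}"
            + f"[{ci[0]:.4g}, {ci[1]:.4g}]".rjust(28)
            + f"{r['day_p']:>9.3g}"
        )
    return "\n".join(lines) + "\n"
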