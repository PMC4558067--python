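"""Longitudinal statistics: mixed-effects ANCOVA, speed-adjusted partial
regressions, rank-based Welch tests, and dopamine percent-change arithmetic.

The unit of analysis is the per-mouse per-day average of each gait metric.
The main model is a linear mixed model with fixed effects gender, treatment
day (continuous, baseline coded 0) and their interaction, and a random
intercept per mouse, fit by REML.  Interaction F-tests use containment
denominator degrees of freedom (observations − mice − number of fixed-effect
terms varying within mouse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "MouseDayRecord",
    "AncovaResult",
    "PartialRegressionResult",
    "RankWelchResult",
    "METRIC_COLUMNS",
    "daily_means",
    "fit_gait_ancova",
    "fit_speed_adjusted",
    "rank_welch_test",
    "da_percent_change",
    "DEFAULT_DA_CONTROL_MEAN",
]

logger = logging.getLogger(__name__)

#: Gait metric columns carried on mouse-day records.
METRIC_COLUMNS = (
    "speed",
    "stride_length",
    "stride_frequency",
    "mean_support_number",
    "sway_index",
)

#: Striatal dopamine control-group mean (detector units) used for percent
#: change when no control values are supplied.
DEFAULT_DA_CONTROL_MEAN = 19037.0


@dataclass(frozen=True)
class MouseDayRecord:
    """Average response of one mouse on one testing day."""

    mouse_id: str
    gender: str
    cohort: int
    day: int
    means: dict[str, float]
    n_strides: int

    def __post_init__(self) -> None:
        if not 0 <= self.day <= 7:
            raise ValueError("day must lie in 0..7")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")


@dataclass
class AncovaResult:
    """Gender × day mixed-effects ANCOVA summary for one response."""

    response: str
    interaction_estimate: float  # male slope - female slope
    interaction_se: float
    interaction_F: float
    df_num: int
    df_den: int
    interaction_p: float
    slope_female: float
    slope_female_ci: tuple[float, float]
    slope_male: float
    slope_male_ci: tuple[float, float]
    gender_estimate: float
    reml: bool = True
    random_effects: str = "intercept per mouse"
    converged: bool = True

    def __post_init__(self) -> None:
        for est, (lo, hi) in (
            (self.slope_female, self.slope_female_ci),
            (self.slope_male, self.slope_male_ci),
        ):
            if not lo <= est <= hi:
                raise ValueError("confidence interval must bracket its estimate")

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "interaction_estimate": self.interaction_estimate,
            "interaction_se": self.interaction_se,
            "interaction_F": self.interaction_F,
            "df": [self.df_num, self.df_den],
            "interaction_p": self.interaction_p,
            "slope_female": self.slope_female,
            "slope_female_ci": list(self.slope_female_ci),
            "slope_male": self.slope_male,
            "slope_male_ci": list(self.slope_male_ci),
            "reml": self.reml,
            "random_effects": self.random_effects,
            "converged": self.converged,
        }


@dataclass
class PartialRegressionResult:
    """Day effect controlling for speed (mixed-effects multiple regression)."""

    response: str
    day_estimate: float
    day_ci: tuple[float, float]
    day_p: float
    speed_estimate: float
    speed_p: float
    df_den: int
    converged: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.day_ci
        if not lo <= self.day_estimate <= hi:
            raise ValueError("confidence interval must bracket its estimate")

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "day_estimate": self.day_estimate,
            "day_ci": list(self.day_ci),
            "day_p": self.day_p,
            "speed_estimate": self.speed_estimate,
            "speed_p": self.speed_p,
            "df_den": self.df_den,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class RankWelchResult:
    statistic: float
    df: float
    pvalue: float


# ---------------------------------------------------------------------------
# Daily averaging
# ---------------------------------------------------------------------------

_METRIC_SOURCE = {
    "speed": "speed_cm_s",
    "stride_length": "stride_length_cm",
    "stride_frequency": "stride_frequency_hz",
    "mean_support_number": "mean_support_number",
    "sway_index": "sway_index",
}


def daily_means(metrics: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Average included strides within each mouse-day.

    ``metrics`` is the per-stride table from :func:`quadgait.metrics.compute_all`
    (stacked over trials); ``metadata`` maps trial_id to mouse/gender/cohort/day.
    Sway means additionally exclude sway-unusable strides.  Mouse-days with no
    included stride are omitted with a warning.
    """
    merged = metrics.merge(
        metadata[["trial_id", "mouse_id", "gender", "cohort", "day"]],
        on="trial_id",
        how="left",
        validate="many_to_one",
    )
    if merged["mouse_id"].isna().any():
        missing = merged.loc[merged["mouse_id"].isna(), "trial_id"].unique()
        raise ValueError(f"metrics reference unknown trial ids: {list(missing)}")
    rows = []
    for (mouse, gender, cohort, day), grp in merged.groupby(
        ["mouse_id", "gender", "cohort", "day"], sort=True
    ):
        inc = grp[grp["included"]]
        if inc.empty:
            logger.warning(
                "mouse %s day %s has no included strides; record omitted", mouse, day
            )
            continue
        row = {
            "mouse_id": mouse,
            "gender": gender,
            "cohort": int(cohort),
            "day": int(day),
            "n_strides": int(len(inc)),
        }
        for metric, source in _METRIC_SOURCE.items():
            if metric == "sway_index":
                usable = inc[inc["sway_usable"]]
                row[metric] = float(usable[source].mean()) if not usable.empty else np.nan
            else:
                row[metric] = float(inc[source].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------


def _containment_df(exog: np.ndarray, groups: np.ndarray) -> int:
    """Observations − groups − number of fixed-effect columns varying within
    any group (the containment convention for within-group effects)."""
    n_obs = exog.shape[0]
    n_groups = len(np.unique(groups))
    n_within = 0
    for j in range(exog.shape[1]):
        varies = False
        for g in np.unique(groups):
            col = exog[groups == g, j]
            if np.ptp(col) > 0:
                varies = True
                break
        if varies:
            n_within += 1
    return n_obs - n_groups - n_within


def _fit_mixedlm(
    endog: np.ndarray, exog: np.ndarray, groups: np.ndarray, reml: bool
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fixed effects and their covariance from a random-intercept model.

    Returns ``(beta, cov_beta, converged)``.  Degenerate inputs are handled
    before the iterative fit: a response exactly in the fixed-effects column
    space (zero residuals, e.g. noise-free synthetic data) yields the exact
    least-squares coefficients with zero covariance.  Otherwise the response
    is rescaled to unit variance for numerical conditioning and several
    optimizers are tried in turn.
    """
    import warnings

    k = exog.shape[1]
    beta_ls, *_ = np.linalg.lstsq(exog, endog, rcond=None)
    resid = endog - exog @ beta_ls
    yscale = max(1.0, float(np.max(np.abs(endog))))
    if np.max(np.abs(resid)) <= 1e-10 * yscale:
        beta_ls[np.abs(beta_ls) <= 1e-12 * yscale] = 0.0  # suppress lstsq dust
        return beta_ls, np.zeros((k, k)), True

    scale = float(endog.std())
    model = sm.MixedLM(endog / scale, exog, groups=groups)
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                result = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if result.converged:
                beta = np.asarray(result.fe_params) * scale
                cov = np.asarray(result.cov_params())[:k, :k] * scale**2
                return beta, cov, True
    raise ValueError(f"singular mixed-model fit: {last_exc or 'no optimizer converged'}")


def fit_gait_ancova(
    records: pd.DataFrame,
    response: str,
    *,
    baseline_day_value: float = 0.0,
    reml: bool = True,
    conf_level: float = 0.95,
) -> AncovaResult:
    """Gender × day linear mixed-effects ANCOVA with random mouse intercepts.

    Fixed effects: intercept, gender (female reference), day (continuous,
    baseline recoded to ``baseline_day_value``), gender×day.  The interaction
    estimate is the male slope minus the female slope; its F-test uses
    containment denominator df.  Slope confidence intervals are t-based on
    the same df.
    """
    data = records.dropna(subset=[response]).copy()
    if data.empty:
        raise ValueError(f"no records with non-missing {response}")
    genders = set(data["gender"])
    if genders != {"F", "M"}:
        raise ValueError(f"need both genders present, got {sorted(genders)}")
    for g in ("F", "M"):
        if data.loc[data["gender"] == g, "mouse_id"].nunique() < 2:
            raise ValueError(f"need at least 2 mice of gender {g}")
    if data["day"].nunique() < 2:
        raise ValueError("need at least 2 distinct days")

    day = data["day"].to_numpy(dtype=float)
    day = np.where(data["day"].to_numpy() == 0, baseline_day_value, day)
    male = (data["gender"] == "M").to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(data)), male, day, male * day])
    endog = data[response].to_numpy(dtype=float)
    groups = data["mouse_id"].to_numpy()

    beta, cov, converged = _fit_mixedlm(endog, exog, groups, reml)

    df_den = _containment_df(exog, groups)
    tcrit = sps.t.ppf(0.5 + conf_level / 2.0, df_den)

    slope_f = beta[2]
    se_f = float(np.sqrt(max(cov[2, 2], 0.0)))
    c_m = np.array([0.0, 0.0, 1.0, 1.0])
    slope_m = float(c_m @ beta)
    se_m = float(np.sqrt(max(c_m @ cov @ c_m, 0.0)))

    inter = float(beta[3])
    se_i = float(np.sqrt(max(cov[3, 3], 0.0)))
    if se_i == 0.0:  # exact fit: the test degenerates
        F = 0.0 if inter == 0.0 else np.inf
        p = 1.0 if inter == 0.0 else 0.0
    else:
        F = (inter / se_i) ** 2
        p = float(sps.f.sf(F, 1, df_den))

    return AncovaResult(
        response=response,
        interaction_estimate=inter,
        interaction_se=se_i,
        interaction_F=float(F),
        df_num=1,
        df_den=df_den,
        interaction_p=p,
        slope_female=float(slope_f),
        slope_female_ci=(slope_f - tcrit * se_f, slope_f + tcrit * se_f),
        slope_male=slope_m,
        slope_male_ci=(slope_m - tcrit * se_m, slope_m + tcrit * se_m),
        gender_estimate=float(beta[1]),
        reml=reml,
        converged=converged,
    )


def fit_speed_adjusted(
    records: pd.DataFrame,
    response: str,
    *,
    speed_column: str = "speed",
    baseline_day_value: float = 0.0,
    reml: bool = True,
    conf_level: float = 0.95,
) -> PartialRegressionResult:
    """Day effect on a male-mouse response controlling for speed.

    Mixed model ``response ~ day + speed`` with a random intercept per mouse,
    fit to the supplied records (callers restrict to males).  Returns the
    partial day coefficient with t-based CI and p on containment df.
    """
    data = records.dropna(subset=[response, speed_column]).copy()
    if data.empty:
        raise ValueError(f"no usable records for {response}")
    day = data["day"].to_numpy(dtype=float)
    day = np.where(data["day"].to_numpy() == 0, baseline_day_value, day)
    speed = data[speed_column].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(data)), day, speed])
    if np.linalg.matrix_rank(exog) < 3:
        raise ValueError(
            "design is rank deficient (day and speed are collinear); the day "
            "effect is unidentifiable"
        )
    endog = data[response].to_numpy(dtype=float)
    groups = data["mouse_id"].to_numpy()

    beta, cov, converged = _fit_mixedlm(endog, exog, groups, reml)

    df_den = _containment_df(exog, groups)
    tcrit = sps.t.ppf(0.5 + conf_level / 2.0, df_den)
    day_est = float(beta[1])
    day_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    speed_est = float(beta[2])
    speed_se = float(np.sqrt(max(cov[2, 2], 0.0)))

    def _pval(est: float, se: float) -> float:
        if se == 0.0:
            return 1.0 if est == 0.0 else 0.0
        return float(2.0 * sps.t.sf(abs(est / se), df_den))

    return PartialRegressionResult(
        response=response,
        day_estimate=day_est,
        day_ci=(day_est - tcrit * day_se, day_est + tcrit * day_se),
        day_p=_pval(day_est, day_se),
        speed_estimate=speed_est,
        speed_p=_pval(speed_est, speed_se),
        df_den=df_den,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Rank-based Welch test and dopamine arithmetic
# ---------------------------------------------------------------------------


def rank_welch_test(group_a, group_b) -> RankWelchResult:
    """Welch's t-test on mid-ranks of the pooled data.

    Both groups are pooled, ranked (ties get mid-ranks), and Welch's unequal-
    variance t with Satterthwaite df is computed on the ranks.  All values
    identical across both groups gives t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        logger.info("all values identical across groups; p = 1 by convention")
        return RankWelchResult(0.0, float(a.size + b.size - 2), 1.0)
    ranks = sps.rankdata(pooled)
    ra, rb = ranks[: a.size], ranks[a.size :]
    va, vb = ra.var(ddof=1), rb.var(ddof=1)
    diff = ra.mean() - rb.mean()
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        # constant ranks within each group but different between: t -> inf
        return RankWelchResult(
            float(np.sign(diff) * np.inf), float(a.size + b.size - 2), 0.0
        )
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    t = diff / np.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return RankWelchResult(float(t), float(df), float(p))


def da_percent_change(
    records: pd.DataFrame,
    control_mean: float = DEFAULT_DA_CONTROL_MEAN,
    control_values: np.ndarray | None = None,
) -> dict[str, dict]:
    """Per-gender mean percent change of striatal dopamine vs a control mean.

    ``records`` needs columns mouse_id, gender, striatal_da (all values
    positive).  Percent change per mouse is 100·(value − control_mean) /
    control_mean (negative = loss).  When ``control_values`` is given, each
    gender is additionally compared to the control group with the rank-based
    Welch test.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    if (records["striatal_da"] <= 0).any():
        bad = records.loc[records["striatal_da"] <= 0, "mouse_id"].tolist()
        raise ValueError(f"non-positive dopamine values for mice {bad}")
    out: dict[str, dict] = {}
    for gender, grp in records.groupby("gender"):
        pct = 100.0 * (grp["striatal_da"] - control_mean) / control_mean
        entry: dict = {
            "n": int(len(grp)),
            "mean_percent_change": float(pct.mean()),
            "per_mouse": dict(zip(grp["mouse_id"], pct.round(12))),
        }
        if control_values is not None:
            test = rank_welch_test(grp["striatal_da"].to_numpy(), control_values)
            entry["test_vs_control"] = {
                "t": test.statistic,
                "df": test.df,
                "p": test.pvalue,
            }
        out[str(gender)] = entry
    return out
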