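"""Calibration of bat counts against acoustic parameters.

The core of the census method is a log-linear calibration: over the part of
the emergence dense enough for a coherent stream, the logarithm of the
instantaneous bat count is linear in the RMS sound level of the stream
(incoherent summation of N roughly equal sources raises power by a factor N,
i.e. the level by 10*log10(N) dB, so the theoretical slope of log10(count) on
level is 1/10 per dB).

This module fits the simple per-feature regressions, tests slope homogeneity
across groups (caves, or days within a cave) with an ANCOVA interaction
F-test, scores reciprocal cross-validation between caves, and runs the paired
t-tests (Bonferroni-adjusted) used to compare census totals.

Counts are log10-transformed for the two pressure features; the base is a
convention only — R², p-values and back-transformed predictions are identical
in any base. Total-energy models are conventionally fit on untransformed
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .audio import FEATURE_NAMES, AcousticFeatures

__all__ = [
    "Observation",
    "LinearFit",
    "AncovaResult",
    "CrossValidation",
    "PairedTestResult",
    "fit_count_model",
    "ancova_slope_homogeneity",
    "cross_validate",
    "feature_correlations",
    "paired_t_bonferroni",
    "per_day_interaction",
    "observations_to_frame",
    "observations_from_frame",
    "read_observations_csv",
    "write_observations_csv",
    "default_log_transform",
]

# Pressure-level features are fit on log10(count); total energy on raw counts.
_LOG_BY_DEFAULT = {"rms_db": True, "p2p_db": True, "total_energy": False}


def default_log_transform(feature_name: str) -> bool:
    return _LOG_BY_DEFAULT[feature_name]


@dataclass(frozen=True)
class Observation:
    """One sampled instant: a bat count paired with its acoustic parameters."""

    time: float
    cave_id: str
    day: int
    bat_count: int
    features: AcousticFeatures

    def __post_init__(self) -> None:
        if self.bat_count <= 0:
            raise ValueError(
                f"bat_count must be positive (log transform must be defined), "
                f"got {self.bat_count}"
            )

    def feature(self, feature_name: str) -> float:
        return self.features.value(feature_name)


@dataclass(frozen=True)
class LinearFit:
    """An OLS calibration line for one acoustic parameter."""

    feature_name: str
    log_transformed: bool
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_stderr: float = float("nan")


@dataclass(frozen=True)
class AncovaResult:
    """Slope-homogeneity test: full (per-group slopes) vs reduced (common
    slope) model, compared by an F-test on the interaction terms."""

    interaction_p: float
    f_statistic: float
    df_num: int
    df_den: int


@dataclass(frozen=True)
class CrossValidation:
    """Out-of-group predictive skill of a calibration line.

    ``r_squared`` is the squared Pearson correlation between predicted and
    observed (transformed) counts — bounded in [0, 1]. ``r_squared_sse``
    is the test-set 1 - SSE/SST, which can go negative for a badly
    transferred line; it is reported as a secondary diagnostic.
    """

    r_squared: float
    r_squared_sse: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test with a Bonferroni-adjusted p-value."""

    t_statistic: float
    df: int
    raw_p: float
    adjusted_p: float
    n_comparisons: int


def _design(observations: Sequence[Observation], feature_name: str, log_transform: bool):
    x = np.array([obs.feature(feature_name) for obs in observations], dtype=float)
    counts = np.array([obs.bat_count for obs in observations], dtype=float)
    y = np.log10(counts) if log_transform else counts
    return x, y


def fit_count_model(
    observations: Sequence[Observation],
    feature_name: str,
    log_transform: bool | None = None,
) -> LinearFit:
    """OLS fit of (possibly log10-transformed) bat count on one feature.

    ``log_transform=None`` selects the convention for the feature: counts are
    log-transformed for the pressure-level features, untransformed for total
    energy.
    """
    if log_transform is None:
        log_transform = default_log_transform(feature_name)
    if len(observations) < 3:
        raise ValueError(f"need at least 3 observations, got {len(observations)}")
    x, y = _design(observations, feature_name, log_transform)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {feature_name!r} is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        feature_name=feature_name,
        log_transformed=log_transform,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=len(observations),
        slope_stderr=float(model.bse[1]),
    )


def _group_key(observations: Sequence[Observation], grouping: str):
    if grouping == "cave_id":
        return [obs.cave_id for obs in observations]
    if grouping == "day":
        return [obs.day for obs in observations]
    raise ValueError(f"grouping must be 'cave_id' or 'day', got {grouping!r}")


def ancova_slope_homogeneity(
    observations: Sequence[Observation],
    feature_name: str,
    grouping: str = "cave_id",
    log_transform: bool | None = None,
) -> AncovaResult:
    """Test homogeneity of calibration slopes across groups.

    Compares the full model (separate slope and intercept per group) against
    the reduced model (common slope, separate intercepts) with an F-test; the
    returned p-value is the significance of the feature-by-group interaction.
    A non-significant interaction supports pooling: one calibration line
    transfers across groups.
    """
    if log_transform is None:
        log_transform = default_log_transform(feature_name)
    keys = _group_key(observations, grouping)
    levels = sorted(set(keys))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    x, y = _design(observations, feature_name, log_transform)
    codes = np.array([levels.index(k) for k in keys])
    for g, level in enumerate(levels):
        in_g = codes == g
        if in_g.sum() < 3:
            raise ValueError(f"group {level!r} has fewer than 3 observations")
        if np.ptp(x[in_g]) == 0:
            raise ValueError(f"predictor is constant within group {level!r}")

    n, g = len(x), len(levels)
    intercepts = (codes[:, None] == np.arange(g)).astype(float)
    slopes = intercepts * x[:, None]
    full = sm.OLS(y, np.hstack([intercepts, slopes])).fit()
    reduced = sm.OLS(y, np.hstack([intercepts, x[:, None]])).fit()
    f_stat, p_value, df_num = full.compare_f_test(reduced)
    return AncovaResult(
        interaction_p=float(p_value),
        f_statistic=float(f_stat),
        df_num=int(df_num),
        df_den=int(n - 2 * g),
    )


def per_day_interaction(
    observations: Sequence[Observation],
    feature_name: str,
    log_transform: bool | None = None,
) -> dict[str, AncovaResult]:
    """Slope-homogeneity across days, run separately within each cave.

    A significant interaction means the count-vs-level slope drifts from night
    to night (e.g. because each night samples a different range of stream
    densities), arguing for pooling data across days when calibrating.
    """
    out: dict[str, AncovaResult] = {}
    for cave in sorted({obs.cave_id for obs in observations}):
        cave_obs = [obs for obs in observations if obs.cave_id == cave]
        out[cave] = ancova_slope_homogeneity(
            cave_obs, feature_name, grouping="day", log_transform=log_transform
        )
    return out


def cross_validate(
    fit: LinearFit, observations: Sequence[Observation]
) -> CrossValidation:
    """Score a calibration line on data from the *other* group.

    Predictions are made on the fit's transformed scale; the headline score is
    the squared Pearson correlation between predicted and observed transformed
    counts, with the test-set 1 - SSE/SST as a secondary field.
    """
    if len(observations) < 3:
        raise ValueError(f"need at least 3 observations, got {len(observations)}")
    x, y = _design(observations, fit.feature_name, fit.log_transformed)
    predicted = fit.intercept + fit.slope * x
    r, _ = stats.pearsonr(predicted, y)
    sse = float(np.sum((y - predicted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return CrossValidation(
        r_squared=float(r**2),
        r_squared_sse=1.0 - sse / sst,
        n=len(observations),
    )


def feature_correlations(
    observations: Sequence[Observation],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise Pearson r (with two-sided p) among the three features.

    The parameters are all monotone proxies of stream intensity and are
    expected to be strongly mutually correlated — the reason a multiple
    regression over them is not part of the method.
    """
    if len(observations) < 4:
        raise ValueError("need at least 4 observations")
    columns = {
        name: np.array([obs.feature(name) for obs in observations])
        for name in FEATURE_NAMES
    }
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(FEATURE_NAMES):
        for b in FEATURE_NAMES[i + 1 :]:
            if np.ptp(columns[a]) == 0 or np.ptp(columns[b]) == 0:
                raise ValueError(f"feature {a if np.ptp(columns[a]) == 0 else b} is constant")
            r, p = stats.pearsonr(columns[a], columns[b])
            out[(a, b)] = (float(r), float(p))
    return out


def paired_t_bonferroni(
    x: Sequence[float], y: Sequence[float], n_comparisons: int
) -> PairedTestResult:
    """Two-sided paired t-test with Bonferroni adjustment.

    Pairs with a missing member (NaN) are dropped before testing; the adjusted
    p-value is ``min(1, raw_p * n_comparisons)``.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    complete = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[complete], y[complete]
    if xs.size < 2:
        raise ValueError(f"need at least 2 complete pairs, got {xs.size}")
    if np.ptp(xs - ys) == 0:
        raise ValueError("all paired differences are identical; t-test undefined")
    t, p = stats.ttest_rel(xs, ys)
    return PairedTestResult(
        t_statistic=float(t),
        df=int(xs.size - 1),
        raw_p=float(p),
        adjusted_p=min(1.0, float(p) * n_comparisons),
        n_comparisons=n_comparisons,
    )


# ---------------------------------------------------------------------------
# Tabular interchange

_CSV_COLUMNS = ["time_s", "cave", "day", "count", "rms_db", "p2p_db", "total_energy"]


def observations_to_frame(observations: Iterable[Observation]) -> pd.DataFrame:
    rows = [
        {
            "time_s": obs.time,
            "cave": obs.cave_id,
            "day": obs.day,
            "count": obs.bat_count,
            "rms_db": obs.features.rms_db,
            "p2p_db": obs.features.p2p_db,
            "total_energy": obs.features.total_energy,
        }
        for obs in observations
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def observations_from_frame(df: pd.DataFrame) -> list[Observation]:
    return [
        Observation(
            time=float(row["time_s"]),
            cave_id=str(row["cave"]),
            day=int(row["day"]),
            bat_count=int(row["count"]),
            features=AcousticFeatures(
                rms_db=float(row["rms_db"]),
                p2p_db=float(row["p2p_db"]),
                total_energy=float(row["total_energy"]),
                time=float(row["time_s"]),
            ),
        )
        for row in df.to_dict("records")
    ]


def read_observations_csv(path: str | Path) -> list[Observation]:
    return observations_from_frame(pd.read_csv(path))


def write_observations_csv(
    observations: Iterable[Observation], path: str | Path
) -> None:
    observations_to_frame(observations).to_csv(path, index=False)
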