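"""Census estimation: from a calibration line to a colony-size estimate.

The visible part of the emergence yields a *total sampled bat count* (TSBC):
the plain sum of per-frame bat counts over the sampled frames, computed either
from video counts or from the calibration model's predictions. TSBC is a
comparison statistic, not yet a population estimate: frames are sampled every
``sampling_interval`` seconds and each frame sees a bat for only its
field-of-view crossing time.

Extrapolating to a total population applies two factors to the summed counts:

* a **correction factor** ``clip_duration / crossing_time`` — a bat crossing
  the field of view in 0.7 s is visible in only 70% of a 1-s window, so each
  frame count under-represents the per-second passage rate by that ratio
  (0.7 s gives the factor 1/0.7 ≈ 1.43);
* the **sampling interval** — one sampled second stands for ``interval``
  seconds of emergence.

Predictions from a log-transformed fit are back-transformed as
``10**(intercept + slope*x)`` with no retransformation (smearing) bias
correction, matching how the reference census tables are constructed.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import LinearFit, PairedTestResult, paired_t_bonferroni

__all__ = [
    "CensusEstimate",
    "TableSummary",
    "predict_counts",
    "tsbc",
    "correction_factor",
    "extrapolate_total",
    "summarize_daily",
    "load_table1",
    "DEFAULT_CROSSING_TIME",
    "DEFAULT_SAMPLING_INTERVAL",
]

DEFAULT_CROSSING_TIME = 0.7  # s per field-of-view transit
DEFAULT_SAMPLING_INTERVAL = 10.0  # s between sampled frames


@dataclass(frozen=True)
class CensusEstimate:
    """A population estimate and the quantities it was assembled from."""

    tsbc: float
    correction_factor: float
    sampling_interval: float
    total_population: float
    source: str = "video"

    def __post_init__(self) -> None:
        if self.tsbc < 0:
            raise ValueError("tsbc must be non-negative")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be positive")


def predict_counts(fit: LinearFit, features: Sequence[float]) -> np.ndarray:
    """Predicted bat counts for feature values ``x`` under a calibration fit.

    Log-transformed fits return ``10**(intercept + slope*x)``; untransformed
    fits return the linear prediction directly.
    """
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    linear = fit.intercept + fit.slope * x
    return np.power(10.0, linear) if fit.log_transformed else linear


def tsbc(counts: Sequence[float]) -> float:
    """Total sampled bat count: the plain sum of per-frame counts.

    No crossing-time or interval factor is applied here — TSBC is the raw
    summed sample, the statistic the daily census tables tabulate.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    return float(counts.sum())


def correction_factor(
    crossing_time: float = DEFAULT_CROSSING_TIME, clip_duration: float = 1.0
) -> float:
    """Per-frame count multiplier ``clip_duration / crossing_time``.

    The default 0.7-s crossing gives 1/0.7 ≈ 1.43 (full precision is used in
    computation; 1.43 is the display rounding).
    """
    if crossing_time <= 0:
        raise ValueError(f"crossing_time must be positive, got {crossing_time}")
    if clip_duration <= 0:
        raise ValueError(f"clip_duration must be positive, got {clip_duration}")
    return clip_duration / crossing_time


def extrapolate_total(
    counts: Sequence[float],
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    correction: float = 1.0 / DEFAULT_CROSSING_TIME,
    source: str = "video",
) -> CensusEstimate:
    """Extrapolate sampled per-frame counts to a total population.

    ``total = (sum(counts) * correction) * sampling_interval``.
    """
    if sampling_interval <= 0:
        raise ValueError(f"sampling_interval must be positive, got {sampling_interval}")
    total_sample = tsbc(counts)
    return CensusEstimate(
        tsbc=total_sample,
        correction_factor=correction,
        sampling_interval=sampling_interval,
        total_population=total_sample * correction * sampling_interval,
        source=source,
    )


@dataclass(frozen=True)
class TableSummary:
    """Summary rows of a days-by-methods TSBC table."""

    means: dict[str, float]
    standard_errors: dict[str, float]
    n_days: dict[str, int]
    tests: dict[str, PairedTestResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "mean": self.means,
            "se": self.standard_errors,
            "n": self.n_days,
            "adjusted_p": {
                col: test.adjusted_p for col, test in self.tests.items()
            },
        }
        return pd.DataFrame(rows).T


def _default_video_column(column: str, columns: Sequence[str]) -> str | None:
    """Video counterpart of a model column under the '<cave>_<method>' naming:
    N_N and N_S pair with N_v, S_N and S_S with S_v."""
    if column.endswith("_v"):
        return None
    prefix = column.split("_")[0]
    candidate = f"{prefix}_v"
    return candidate if candidate in columns else None


def summarize_daily(
    tsbc_table: pd.DataFrame,
    n_comparisons: int = 4,
    video_columns: Mapping[str, str] | None = None,
) -> TableSummary:
    """Column means, standard errors and model-vs-video paired tests.

    ``tsbc_table`` has one row per day and one column per counting method
    (e.g. N_v, N_N, N_S, S_v, S_N, S_S); missing cells are NaN and are dropped
    casewise for means and pairwise for tests. The standard error uses the
    sample (n-1) standard deviation. ``n_comparisons`` defaults to 4: two
    model-vs-video comparisons per cave, two caves.
    """
    means: dict[str, float] = {}
    ses: dict[str, float] = {}
    n_days: dict[str, int] = {}
    for col in tsbc_table.columns:
        values = tsbc_table[col].astype(float).dropna()
        if values.size < 2:
            raise ValueError(f"column {col!r} has fewer than 2 values")
        means[col] = float(values.mean())
        ses[col] = float(values.std(ddof=1) / np.sqrt(values.size))
        n_days[col] = int(values.size)

    if video_columns is None:
        video_columns = {
            col: video
            for col in tsbc_table.columns
            if (video := _default_video_column(col, list(tsbc_table.columns)))
        }
    tests = {
        model_col: paired_t_bonferroni(
            tsbc_table[video_col].astype(float),
            tsbc_table[model_col].astype(float),
            n_comparisons=n_comparisons,
        )
        for model_col, video_col in video_columns.items()
    }
    return TableSummary(means=means, standard_errors=ses, n_days=n_days, tests=tests)


def load_table1() -> pd.DataFrame:
    """The packaged reference table of daily TSBC values.

    Columns: day (index), then per-cave video and model estimates N_v, N_N,
    N_S, S_v, S_N, S_S; the day-1 South cells are missing (NA).
    """
    resource = importlib.resources.files("batcensus.data").joinpath("table1.csv")
    with importlib.resources.as_file(resource) as path:
        return pd.read_csv(path, na_values=["NA"]).set_index("day")


def census_report(estimates: Sequence[CensusEstimate]) -> str:
    """JSON report of census estimates (machine-readable)."""
    return json.dumps(
        [
            {
                "source": e.source,
                "tsbc": e.tsbc,
                "correction_factor": e.correction_factor,
                "sampling_interval": e.sampling_interval,
                "total_population": e.total_population,
            }
            for e in estimates
        ],
        indent=2,
    )
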