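"""Validation experiments for the acoustic-census method.

Each function here runs one self-contained study on synthetic data (or on the
packaged reference table) and returns the quantity that validates a step of
the method:

* :func:`table1_reproduction` — recompute the summary rows of the reference
  daily-census table from its day-level cells;
* :func:`slope_recovery` — check that a simulated emergence reproduces the
  incoherent-summation law (slope of log10 count on RMS level ≈ 1/10 per dB);
* :func:`transfer_relative_errors` — calibrate at one simulated "cave" and
  predict the sampled census total of another;
* :func:`ancova_type_i_rate` — verify the slope-homogeneity F-test holds its
  nominal size under the null of equal slopes.
"""

from __future__ import annotations

import numpy as np

from .audio import AcousticFeatures
from .calibration import (
    Observation,
    ancova_slope_homogeneity,
    fit_count_model,
    LinearFit,
)
from .census import load_table1, predict_counts, summarize_daily, tsbc, TableSummary
from .simulate import desk_config, simulate_emergence
from .workflow import observations_from_recording

__all__ = [
    "table1_reproduction",
    "slope_recovery",
    "transfer_relative_errors",
    "ancova_type_i_rate",
    "simulated_line_observations",
]


def table1_reproduction(n_comparisons: int = 4) -> TableSummary:
    """Column means, standard errors and adjusted p-values of the packaged
    daily TSBC table, recomputed from its day-level cells."""
    return summarize_daily(load_table1(), n_comparisons=n_comparisons)


def slope_recovery(
    seed: int,
    peak_rate: float = 60.0,
    count_threshold: int = 10,
    use_truth_counts: bool = True,
) -> LinearFit:
    """Fit log10(bat count) on RMS level over one desk-scale emergence.

    With equal-power incoherent sources at a fixed range, clip power is
    proportional to the number of bats in view, so the expected slope is
    exactly 1/10 per dB. Uses the simulator's exact counts by default so the
    check isolates the acoustic model from spot-counting error.
    """
    recording = simulate_emergence(desk_config(seed, peak_rate=peak_rate))
    observations = observations_from_recording(
        recording,
        count_threshold=count_threshold,
        use_truth_counts=use_truth_counts,
    )
    return fit_count_model(observations, "rms_db", log_transform=True)


def transfer_relative_errors(
    base_seed: int,
    n_pairs: int = 20,
    peak_rate_a: float = 45.0,
    peak_rate_b: float = 70.0,
    noise_tolerance: float = 30.0,
    count_threshold: int = 10,
) -> np.ndarray:
    """Cross-"cave" transfer error of the calibration.

    For each seed pair, two emergences are simulated that differ only in seed
    and peak arrival rate. The calibration (log10 video count on RMS level) is
    fit at cave A and applied to cave B's acoustics; the relative error
    compares the predicted total sampled bat count against B's video-count
    total over the same retained frames. Returns one relative error per pair.
    """
    rng = np.random.default_rng(base_seed)
    errors = np.empty(n_pairs)
    for k in range(n_pairs):
        seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)
        rec_a = simulate_emergence(desk_config(int(seed_a), peak_rate=peak_rate_a))
        rec_b = simulate_emergence(desk_config(int(seed_b), peak_rate=peak_rate_b))
        obs_a = observations_from_recording(
            rec_a, noise_tolerance=noise_tolerance, count_threshold=count_threshold
        )
        obs_b = observations_from_recording(
            rec_b, noise_tolerance=noise_tolerance, count_threshold=count_threshold
        )
        fit_a = fit_count_model(obs_a, "rms_db", log_transform=True)
        x_b = [obs.feature("rms_db") for obs in obs_b]
        predicted_tsbc = tsbc(predict_counts(fit_a, x_b))
        video_tsbc = tsbc([obs.bat_count for obs in obs_b])
        errors[k] = abs(predicted_tsbc - video_tsbc) / video_tsbc
    return errors


def simulated_line_observations(
    rng: np.random.Generator,
    n: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    cave_id: str = "A",
    day: int = 1,
    x_range: tuple[float, float] = (-40.0, -10.0),
) -> list[Observation]:
    """Observations drawn from a known calibration line.

    RMS levels are uniform on ``x_range``; log10 counts are the line plus
    Gaussian noise, exponentiated and rounded to integer counts (kept >= 1).
    Intended for regression/ANCOVA null and alternative simulations where the
    generative line is known exactly.
    """
    x = rng.uniform(*x_range, size=n)
    log_counts = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    counts = np.maximum(np.rint(10.0**log_counts), 1).astype(int)
    return [
        Observation(
            time=float(i),
            cave_id=cave_id,
            day=day,
            bat_count=int(c),
            features=AcousticFeatures(
                rms_db=float(xi), p2p_db=float(xi) + 6.0, total_energy=10.0 ** (xi / 10.0), time=float(i)
            ),
        )
        for i, (xi, c) in enumerate(zip(x, counts))
    ]


def ancova_type_i_rate(
    seed: int,
    n_sims: int = 1000,
    n_per_group: int = 60,
    alpha: float = 0.05,
    slope: float = 0.1,
    intercept: float = 6.0,
    noise_sd: float = 0.1,
) -> float:
    """Empirical size of the slope-homogeneity F-test under the null.

    Both groups are drawn from the identical calibration line; the fraction of
    simulations with interaction p < alpha estimates the type-I error rate,
    which should sit at the nominal level.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        obs = simulated_line_observations(
            rng, n_per_group, slope, intercept, noise_sd, cave_id="N"
        ) + simulated_line_observations(
            rng, n_per_group, slope, intercept, noise_sd, cave_id="S"
        )
        result = ancova_slope_homogeneity(obs, "rms_db", grouping="cave_id")
        if result.interaction_p < alpha:
            rejections += 1
    return rejections / n_sims
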