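"""Pipeline orchestration: from raw recordings to observations and reports.

The field protocol pairs one video frame with the 1-s audio clip starting at
the frame's timestamp, every ``sampling_interval`` seconds. This module joins
the two streams on that grid, applies the low-count filter, and provides the
configured end-to-end steps the command-line interface wraps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .audio import AudioClip, compute_features
from .calibration import Observation, fit_count_model
from .census import DEFAULT_CROSSING_TIME, DEFAULT_SAMPLING_INTERVAL
from .maxima import Frame, filter_low_counts, find_maxima
from .simulate import SyntheticRecording

logger = logging.getLogger("batcensus")

__all__ = ["PipelineConfig", "extract_observations", "observations_from_recording"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the census pipeline, defaulting to the field protocol:
    a 1-s clip every 10 s, counts above 10 retained, 0.7-s crossing time."""

    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL
    clip_duration: float = 1.0
    noise_tolerance: float = 30.0
    count_threshold: int = 10
    crossing_time: float = DEFAULT_CROSSING_TIME
    feature: str = "rms_db"
    seed: int = 0
    audio_path: str | None = None
    frames_path: str | None = None
    out_dir: str | None = None

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def extract_observations(
    waveform: np.ndarray,
    sample_rate: float,
    frames: Sequence[Frame],
    config: PipelineConfig = PipelineConfig(),
    cave_id: str = "A",
    day: int = 1,
    apply_filter: bool = True,
) -> list[Observation]:
    """Join per-frame bat counts with per-clip acoustic features.

    Frames on the sampling grid (timestamps that are multiples of
    ``sampling_interval``, within half a sample) are paired with the 1-s clip
    starting at the frame timestamp. Frames whose clip would run past the end
    of the recording are dropped; frames counting zero bats cannot enter the
    calibration (the count is log-transformed) and are skipped. With
    ``apply_filter`` the low-count filter (> threshold) is applied.
    """
    n_clip = int(round(config.clip_duration * sample_rate))
    tol = 0.5 / sample_rate
    duration = waveform.size / sample_rate
    bad_times = [
        f.timestamp for f in frames if f.timestamp < 0 or f.timestamp >= duration
    ]
    if bad_times:
        raise ValueError(
            f"{len(bad_times)} frame timestamps fall outside the {duration:.3f}-s "
            f"recording: {bad_times[:10]}"
        )
    observations: list[Observation] = []
    off_grid: list[float] = []
    for frame in frames:
        t = frame.timestamp
        k = round(t / config.sampling_interval)
        if abs(t - k * config.sampling_interval) > max(tol, 1e-9):
            off_grid.append(t)
            continue
        i0 = int(round(t * sample_rate))
        if i0 + n_clip > waveform.size:
            # final partial window: dropped, like clip extraction truncation
            continue
        count = find_maxima(frame, config.noise_tolerance).count
        if count < 1:
            continue
        clip = AudioClip(waveform[i0 : i0 + n_clip], sample_rate, start_time=t)
        observations.append(
            Observation(
                time=t,
                cave_id=cave_id,
                day=day,
                bat_count=count,
                features=compute_features(clip),
            )
        )
    if off_grid:
        logger.info(
            "%d frames off the %.3g-s sampling grid were skipped (first at t=%.3f s)",
            len(off_grid),
            config.sampling_interval,
            off_grid[0],
        )
    if apply_filter:
        observations = filter_low_counts(observations, config.count_threshold)
    if not observations:
        logger.warning("no observations above the count threshold")
    logger.info("extracted %d observations", len(observations))
    return observations


def observations_from_recording(
    recording: SyntheticRecording,
    noise_tolerance: float = 30.0,
    count_threshold: int = 10,
    clip_duration: float = 1.0,
    use_truth_counts: bool = False,
    cave_id: str = "A",
    day: int = 1,
) -> list[Observation]:
    """Observations from a synthetic recording, sampling *every* frame.

    The desk-scale simulations render frames every ``frame_interval`` seconds;
    pairing each frame with the clip that starts at its timestamp uses the
    whole simulated emergence as calibration data. ``use_truth_counts``
    substitutes the simulator's exact in-view counts for the video counts.
    """
    config = PipelineConfig(
        sampling_interval=recording.config.frame_interval,
        clip_duration=clip_duration,
        noise_tolerance=noise_tolerance,
        count_threshold=count_threshold,
    )
    if not use_truth_counts:
        return extract_observations(
            recording.audio,
            recording.sample_rate,
            recording.frames,
            config,
            cave_id=cave_id,
            day=day,
        )
    n_clip = int(round(clip_duration * recording.sample_rate))
    observations: list[Observation] = []
    for t, count in zip(recording.truth.frame_times, recording.truth.frame_counts):
        i0 = int(round(t * recording.sample_rate))
        if count < 1 or i0 + n_clip > recording.audio.size:
            continue
        clip = AudioClip(
            recording.audio[i0 : i0 + n_clip], recording.sample_rate, start_time=float(t)
        )
        observations.append(
            Observation(
                time=float(t),
                cave_id=cave_id,
                day=day,
                bat_count=int(count),
                features=compute_features(clip),
            )
        )
    return filter_low_counts(observations, count_threshold)
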