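"""Acoustic parameters of an emerging bat stream.

A 1-s clip of the stream recording is summarized by three scalar acoustic
parameters:

* **RMS pressure** ``20 * log10(sd(waveform))`` in dB re full scale,
* **peak-to-peak pressure** ``20 * log10(max(waveform) - min(waveform))``
  in dB re full scale,
* **total energy** ``sum(waveform**2)`` (dimensionless).

The dB reference is the digital full-scale amplitude 1.0: the recordings are
uncalibrated, so levels are relative, and a constant reference shift only
moves the calibration intercept, never its slope or R².

Clips are cut from the full recording on a regular sampling grid (the field
protocol pairs one video frame with one 1-s audio clip every 10 s).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile


class DegenerateClipError(ValueError):
    """Raised when a clip is constant, so a dB level is undefined."""


@dataclass(frozen=True)
class AudioClip:
    """A fixed-length window of waveform samples.

    Parameters
    ----------
    samples
        Amplitude values, dimensionless, full scale +/-1.0.
    sample_rate
        Sampling rate in Hz.
    start_time
        Clip start in seconds from the beginning of the recording.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("clip must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("clip contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class AcousticFeatures:
    """The three acoustic parameters of one clip, tagged with its time."""

    rms_db: float
    p2p_db: float
    total_energy: float
    time: float

    def value(self, feature_name: str) -> float:
        if feature_name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {feature_name!r}; expected one of {FEATURE_NAMES}")
        return getattr(self, feature_name)


FEATURE_NAMES = ("rms_db", "p2p_db", "total_energy")


def compute_rms_db(clip: AudioClip) -> float:
    """RMS pressure of a clip: ``20 * log10(sd(samples))`` in dB re full scale.

    The standard deviation uses the population convention (divide by n); at
    field clip lengths (250 000 samples) the n vs n-1 difference is far below
    any other source of variation, and fixing the convention keeps results
    reproducible.

    Raises
    ------
    DegenerateClipError
        If the clip is constant (sd = 0), where the level would be -inf.
    """
    sd = float(np.std(clip.samples))
    if sd == 0.0:
        raise DegenerateClipError(
            f"clip at t={clip.start_time}s is constant; RMS level undefined"
        )
    return 20.0 * np.log10(sd)


def compute_p2p_db(clip: AudioClip) -> float:
    """Peak-to-peak pressure: ``20 * log10(max - min)`` in dB re full scale."""
    span = float(np.max(clip.samples) - np.min(clip.samples))
    if span == 0.0:
        raise DegenerateClipError(
            f"clip at t={clip.start_time}s is constant; peak-to-peak level undefined"
        )
    return 20.0 * np.log10(span)


def compute_total_energy(clip: AudioClip) -> float:
    """Total energy: sum of squared amplitudes over the clip."""
    return float(np.sum(np.square(clip.samples)))


def compute_features(clip: AudioClip) -> AcousticFeatures:
    """All three acoustic parameters of one clip."""
    return AcousticFeatures(
        rms_db=compute_rms_db(clip),
        p2p_db=compute_p2p_db(clip),
        total_energy=compute_total_energy(clip),
        time=clip.start_time,
    )


def extract_clips(
    waveform: np.ndarray,
    sample_rate: float,
    interval: float,
    clip_duration: float = 1.0,
    start_offset: float = 0.0,
) -> list[AudioClip]:
    """Cut fixed-length clips from a recording on a regular sampling grid.

    Clips start at ``start_offset, start_offset + interval, ...``; each holds
    exactly ``clip_duration * sample_rate`` samples. A final window that would
    run past the end of the recording is dropped.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty recording")
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    if clip_duration <= 0 or clip_duration > interval:
        raise ValueError("require interval >= clip_duration > 0")

    n_clip = int(round(clip_duration * sample_rate))
    clips: list[AudioClip] = []
    k = 0
    while True:
        t0 = start_offset + k * interval
        i0 = int(round(t0 * sample_rate))
        if i0 + n_clip > waveform.size:
            break
        clips.append(
            AudioClip(waveform[i0 : i0 + n_clip], sample_rate, start_time=t0)
        )
        k += 1
    if not clips:
        raise ValueError("recording too short for a single clip")
    return clips


# Full-scale magnitude per integer PCM dtype; +full-scale maps just below 1.0.
_PCM_FULL_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,  # WAV uint8 is offset-binary around 128
}


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file, rescaling integer PCM to [-1, 1).

    Returns ``(waveform, sample_rate)`` with the waveform as float64. Float
    files pass through unscaled; integer PCM is divided by the format's
    full-scale magnitude (32768 for 16-bit). Multi-channel files are rejected.
    """
    sample_rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype.kind == "f":
        waveform = data.astype(np.float64)
    elif data.dtype == np.uint8:
        waveform = (data.astype(np.float64) - 128.0) / _PCM_FULL_SCALE[data.dtype]
    elif data.dtype in _PCM_FULL_SCALE:
        waveform = data.astype(np.float64) / _PCM_FULL_SCALE[data.dtype]
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return waveform, int(sample_rate)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a float32 mono WAV file."""
    wavfile.write(str(path), int(sample_rate), np.asarray(waveform, dtype=np.float32))


def write_features_csv(features: Sequence[AcousticFeatures], path: str | Path) -> None:
    """Write a features table with columns time_s, rms_db, p2p_db, total_energy."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "rms_db", "p2p_db", "total_energy"])
        for f in features:
            writer.writerow([f.time, f.rms_db, f.p2p_db, f.total_energy])
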