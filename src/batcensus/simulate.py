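"""Synthetic bat-emergence generator: paired audio, frames and ground truth.

The generator emulates the statistical structure the census method relies on,
so the whole pipeline can be exercised and validated without field data:

* bats arrive by an inhomogeneous Poisson process whose rate ramps linearly
  from emergence onset to a peak and then decays exponentially (real
  emergences peak in density a few minutes after onset and tail off);
* each bat crosses the camera/microphone field of view in about 0.7 s,
  emitting a train of downward FM echolocation calls at a fixed repetition
  interval with a random train phase;
* each call reaches the microphone attenuated by spherical spreading
  (amplitude ∝ 1/r for slant range r); independent call timing makes the
  summation incoherent, so acoustic *power* grows linearly with the number of
  bats in view — the physical basis of the 10·log10(N) calibration law;
* video frames show one radially symmetric Gaussian bright spot per in-view
  bat over a noisy background, and the ground truth records the exact
  in-view count at every frame time.

All randomness flows from one seeded generator: a fixed seed reproduces the
recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .maxima import Frame

__all__ = [
    "CallParams",
    "EmergenceConfig",
    "GroundTruth",
    "SyntheticRecording",
    "generate_call",
    "render_frame",
    "simulate_emergence",
    "arrival_rate",
    "expected_total_arrivals",
    "desk_config",
    "paper_like_config",
    "write_dataset",
]


@dataclass(frozen=True)
class CallParams:
    """A single echolocation call: a linear downward FM sweep.

    Frequencies in Hz, duration and interval (time between call onsets within
    one bat's train) in seconds; source_amplitude is the peak amplitude at the
    reference range (the flight height, i.e. a bat directly overhead).
    """

    f_start: float = 18000.0
    f_end: float = 9000.0
    duration: float = 0.005
    interval: float = 0.1
    source_amplitude: float = 0.02


@dataclass(frozen=True)
class EmergenceConfig:
    """Full description of one synthetic emergence.

    Defaults describe a field-scale emergence (90 min at 250 kHz, density
    peaking 5½ min after onset); :func:`desk_config` returns the compact
    120-s / 50-kHz configuration used throughout the test suite.
    """

    seed: int
    duration: float = 5400.0  # s
    onset: float = 0.0  # s, first arrivals
    peak_offset: float = 330.0  # s after onset at which density peaks
    peak_rate: float = 150.0  # bats/s at the peak
    decay_time: float = 900.0  # s, exponential decay constant after the peak
    crossing_time_mean: float = 0.7  # s in the field of view
    crossing_time_sd: float = 0.1
    flight_height: float = 10.0  # m above the microphone
    fov_width: float = 5.0  # m spanned by the camera at flight height
    call: CallParams = field(default_factory=CallParams)
    noise_amplitude: float = 5e-4  # ambient white-noise s.d.
    sample_rate: float = 250000.0  # Hz
    frame_interval: float = 10.0  # s between rendered frames
    frame_rows: int = 96
    frame_cols: int = 96
    spot_radius: float = 1.6  # px, Gaussian sigma of a bat spot
    spot_peak_intensity: float = 180.0
    frame_background: float = 10.0
    pixel_noise_sd: float = 2.0

    def validate(self) -> None:
        positive = {
            "duration": self.duration,
            "peak_offset": self.peak_offset,
            "decay_time": self.decay_time,
            "crossing_time_mean": self.crossing_time_mean,
            "flight_height": self.flight_height,
            "fov_width": self.fov_width,
            "sample_rate": self.sample_rate,
            "frame_interval": self.frame_interval,
            "spot_radius": self.spot_radius,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.peak_rate < 0:
            raise ValueError(f"peak_rate must be non-negative, got {self.peak_rate}")
        if self.onset < 0 or self.onset >= self.duration:
            raise ValueError("onset must lie within [0, duration)")
        if not 0 < self.call.f_end < self.call.f_start:
            raise ValueError("call must sweep downward: 0 < f_end < f_start")
        if self.call.f_start >= self.sample_rate / 2:
            raise ValueError(
                f"call start frequency {self.call.f_start} Hz is at or above "
                f"Nyquist ({self.sample_rate / 2} Hz)"
            )
        if self.frame_rows < 3 or self.frame_cols < 3:
            raise ValueError("frames must be at least 3x3")


@dataclass(frozen=True)
class GroundTruth:
    """Exact in-view counts and per-bat transit times of one simulation."""

    frame_times: np.ndarray
    frame_counts: np.ndarray
    entry_times: np.ndarray
    exit_times: np.ndarray

    @property
    def total_bats(self) -> int:
        return int(self.entry_times.size)


@dataclass(frozen=True)
class SyntheticRecording:
    audio: np.ndarray
    sample_rate: float
    frames: list[Frame]
    truth: GroundTruth
    config: EmergenceConfig


def arrival_rate(t: np.ndarray | float, config: EmergenceConfig) -> np.ndarray:
    """Bat arrival rate (bats/s): linear ramp to the peak, then exponential
    decay."""
    t = np.asarray(t, dtype=float)
    peak_time = config.onset + config.peak_offset
    ramp = config.peak_rate * (t - config.onset) / config.peak_offset
    decay = config.peak_rate * np.exp(-(t - peak_time) / config.decay_time)
    rate = np.where(t < peak_time, ramp, decay)
    return np.where(t < config.onset, 0.0, rate)


def expected_total_arrivals(config: EmergenceConfig) -> float:
    """Integral of the arrival-rate profile over the recording."""
    peak_time = config.onset + config.peak_offset
    ramp_area = 0.5 * config.peak_rate * config.peak_offset
    tail = max(config.duration - peak_time, 0.0)
    decay_area = config.peak_rate * config.decay_time * (1.0 - np.exp(-tail / config.decay_time))
    return float(ramp_area + decay_area)


def generate_call(call: CallParams, sample_rate: float) -> np.ndarray:
    """One linear downward FM chirp with a raised-cosine amplitude envelope.

    The instantaneous frequency sweeps linearly from ``f_start`` to ``f_end``
    over ``duration``; the envelope peaks at ``source_amplitude``.
    """
    if not 0 < call.f_end < call.f_start:
        raise ValueError("require 0 < f_end < f_start (downward sweep)")
    if call.f_start >= sample_rate / 2:
        raise ValueError(
            f"f_start {call.f_start} Hz is at or above Nyquist ({sample_rate / 2} Hz)"
        )
    n = int(round(call.duration * sample_rate))
    t = np.arange(n) / sample_rate
    sweep_rate = (call.f_end - call.f_start) / call.duration
    phase = 2.0 * np.pi * (call.f_start * t + 0.5 * sweep_rate * t**2)
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / call.duration))
    return call.source_amplitude * envelope * np.sin(phase)


def render_frame(
    row_positions: Sequence[float],
    col_positions: Sequence[float],
    config: EmergenceConfig,
    rng: np.random.Generator,
    timestamp: float = 0.0,
) -> Frame:
    """Render one frame: background + one Gaussian spot per bat + pixel noise.

    Intensities are quantised to the integer 0–255 range, as in 8-bit video.
    """
    rows, cols = config.frame_rows, config.frame_cols
    img = np.full((rows, cols), config.frame_background, dtype=float)
    sigma = config.spot_radius
    reach = int(np.ceil(3.5 * sigma))
    for r0, c0 in zip(row_positions, col_positions):
        r_lo, r_hi = max(int(r0) - reach, 0), min(int(r0) + reach + 1, rows)
        c_lo, c_hi = max(int(c0) - reach, 0), min(int(c0) + reach + 1, cols)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        img[r_lo:r_hi, c_lo:c_hi] += config.spot_peak_intensity * np.exp(
            -(rr**2 + cc**2) / (2.0 * sigma**2)
        )
    if config.pixel_noise_sd > 0:
        img += rng.normal(0.0, config.pixel_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0.0, 255.0)
    return Frame(img, timestamp=timestamp)


def _sample_arrivals(config: EmergenceConfig, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson arrival times by thinning a homogeneous process."""
    span = config.duration - config.onset
    if config.peak_rate == 0:
        return np.empty(0)
    n_candidates = rng.poisson(config.peak_rate * span)
    times = config.onset + rng.uniform(0.0, span, size=n_candidates)
    keep = rng.uniform(0.0, config.peak_rate, size=n_candidates) < arrival_rate(
        times, config
    )
    return np.sort(times[keep])


def simulate_emergence(config: EmergenceConfig) -> SyntheticRecording:
    """Generate one synthetic emergence: audio, frames and ground truth.

    Raises
    ------
    ValueError
        On invalid configuration, or if the summed audio clips (|sample| > 1),
        which indicates the source amplitude is too high for the simulated
        density.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sr = config.sample_rate

    entry = _sample_arrivals(config, rng)
    n_bats = entry.size
    crossing = np.clip(
        rng.normal(config.crossing_time_mean, config.crossing_time_sd, size=n_bats),
        0.2,
        None,
    )
    exit_ = entry + crossing
    # Transverse (row) position of each bat's track, fixed over its transit.
    track_rows = rng.uniform(0.12, 0.88, size=n_bats) * (config.frame_rows - 1)

    # --- audio -------------------------------------------------------------
    n_samples = int(round(config.duration * sr))
    audio = np.zeros(n_samples)
    base_call = generate_call(replace(config.call, source_amplitude=1.0), sr)
    n_call = base_call.size
    amp = config.call.source_amplitude
    half_w = config.fov_width / 2.0
    for i in range(n_bats):
        # Random train phase makes overlapping trains incoherent.
        t_call = entry[i] + rng.uniform(0.0, config.call.interval)
        while t_call + config.call.duration <= exit_[i]:
            # Horizontal position along the transit -> slant range -> 1/r loss,
            # referenced to the flight height (overhead bat = factor 1).
            frac = (t_call - entry[i]) / crossing[i]
            x = (frac - 0.5) * config.fov_width if crossing[i] > 0 else 0.0
            r = np.hypot(config.flight_height, x)
            i0 = int(round(t_call * sr))
            if i0 + n_call > n_samples:
                break
            audio[i0 : i0 + n_call] += (amp * config.flight_height / r) * base_call
            t_call += config.call.interval
    if config.noise_amplitude > 0:
        audio += rng.normal(0.0, config.noise_amplitude, size=n_samples)
    peak = float(np.max(np.abs(audio))) if n_samples else 0.0
    if peak > 1.0:
        raise ValueError(
            f"synthesised audio clips (peak |sample| = {peak:.2f}); "
            "lower call.source_amplitude or peak_rate"
        )

    # --- frames and truth --------------------------------------------------
    frame_times = np.arange(0.0, config.duration, config.frame_interval)
    frames: list[Frame] = []
    counts = np.zeros(frame_times.size, dtype=int)
    for j, t in enumerate(frame_times):
        in_view = (entry <= t) & (t < exit_)
        counts[j] = int(in_view.sum())
        frac = (t - entry[in_view]) / crossing[in_view]
        cols_px = frac * (config.frame_cols - 1)
        frames.append(
            render_frame(track_rows[in_view], cols_px, config, rng, timestamp=float(t))
        )
    truth = GroundTruth(
        frame_times=frame_times,
        frame_counts=counts,
        entry_times=entry,
        exit_times=exit_,
    )
    return SyntheticRecording(
        audio=audio, sample_rate=sr, frames=frames, truth=truth, config=config
    )


def desk_config(seed: int, peak_rate: float = 60.0, **overrides) -> EmergenceConfig:
    """Compact desk-scale configuration: a 120-s emergence at 50 kHz.

    Keeps every structural feature of the field-scale default (ramp/decay
    arrival profile, 0.7-s crossings, FM call trains, spherical spreading)
    while running in seconds; the acoustic parameters are sample-rate
    independent, which the test suite asserts separately.
    """
    params = dict(
        seed=seed,
        duration=120.0,
        onset=0.0,
        peak_offset=30.0,
        peak_rate=peak_rate,
        decay_time=60.0,
        sample_rate=50000.0,
        frame_interval=0.5,
        call=CallParams(),
    )
    params.update(overrides)
    return EmergenceConfig(**params)


def paper_like_config(seed: int) -> EmergenceConfig:
    """Field-scale configuration: 90-min emergence, 250-kHz audio, density
    peak 5½ min after onset, 0.7-s crossings, 50→25 kHz calls."""
    return EmergenceConfig(
        seed=seed,
        duration=5400.0,
        peak_offset=330.0,
        peak_rate=150.0,
        decay_time=900.0,
        sample_rate=250000.0,
        frame_interval=10.0,
        call=CallParams(f_start=50000.0, f_end=25000.0, duration=0.01, interval=0.1),
    )


def write_dataset(recording: SyntheticRecording, out_dir: str | Path) -> dict[str, Path]:
    """Write WAV + zero-padded PNG sequence + truth CSV + config YAML."""
    import imageio.v3 as iio
    import yaml

    from .audio import write_wav

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wav_path = out_dir / "emergence.wav"
    write_wav(wav_path, recording.audio, int(recording.sample_rate))

    frame_dir = out_dir / "frames"
    frame_dir.mkdir(exist_ok=True)
    for i, frame in enumerate(recording.frames):
        iio.imwrite(frame_dir / f"frame_{i:05d}.png", frame.pixels.astype(np.uint8))

    truth_path = out_dir / "truth.csv"
    with open(truth_path, "w") as fh:
        fh.write("time_s,true_count\n")
        for t, c in zip(recording.truth.frame_times, recording.truth.frame_counts):
            fh.write(f"{t},{c}\n")

    config_path = out_dir / "config.yaml"
    config_dict = asdict(recording.config)
    with open(config_path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)
    return {
        "wav": wav_path,
        "frames": frame_dir,
        "truth": truth_path,
        "config": config_path,
    }
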