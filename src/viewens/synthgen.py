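"""Synthetic labeled multichannel pseudo-ECG generator.

Produces quasi-periodic multichannel signals with class-dependent
morphology so that filtering, augmentation, training and evaluation can
all be exercised without clinical data.  Each record is a latent beat
train (Gaussian-bump P/QRS/T morphology, jittered RR intervals) rendered
through channel-specific gains and delays, plus baseline wander
(low-frequency sinusoid), powerline interference (mains-frequency
sinusoid) and white noise.  The abnormal class differs by a configurable
effect: a beat-amplitude shift, extra RR irregularity, or T-wave
inversion.  The morphology is deliberately minimal — enough to carry a
learnable class signal through the pipeline, with no claim to clinical
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .records import Dataset, TimeSeriesRecord

__all__ = [
    "BeatParams",
    "SynthConfig",
    "beat_template",
    "generate_dataset",
    "preset",
    "easy_benchmark",
]


@dataclass(frozen=True)
class BeatParams:
    """Gaussian-bump amplitudes (dimensionless), centers and widths (s)."""

    amplitudes: tuple[float, ...] = (0.15, -0.1, 1.0, -0.15, 0.3)  # P, Q, R, S, T
    centers: tuple[float, ...] = (0.08, 0.19, 0.22, 0.25, 0.42)
    widths: tuple[float, ...] = (0.025, 0.01, 0.012, 0.01, 0.04)
    duration: float = 0.6

    def __post_init__(self) -> None:
        if not (len(self.amplitudes) == len(self.centers) == len(self.widths)):
            raise ValueError("amplitudes, centers and widths must have equal length")
        if any(w <= 0 for w in self.widths) or self.duration <= 0:
            raise ValueError("widths and duration must be positive")


def beat_template(params: BeatParams = BeatParams(), rate: float = 500.0,
                  t_wave_scale: float = 1.0) -> np.ndarray:
    """Single-beat waveform, normalized so the dominant deflection is 1.

    ``t_wave_scale`` rescales the last (T-like) bump; -1 inverts it.
    """
    t = np.arange(int(round(params.duration * rate))) / rate
    wave = np.zeros_like(t)
    n = len(params.amplitudes)
    for i, (a, c, w) in enumerate(zip(params.amplitudes, params.centers, params.widths)):
        if i == n - 1:
            a = a * t_wave_scale
        wave += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak
    return wave


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults target 8 x 4750 records at 500 Hz
    (1900 samples per channel once downsampled to 200 Hz)."""

    n_per_class: tuple[int, int] = (50, 50)
    n_channels: int = 8
    rate: float = 500.0
    duration: float = 9.5
    beat_rate_mean: float = 70.0  # bpm
    beat_rate_sd: float = 5.0
    rr_jitter_sd: float = 0.02  # s
    class_effect: str = "amplitude_shift"  # {amplitude_shift, rr_irregularity, wave_inversion}
    effect_magnitude: float = 0.5
    baseline_amp: float = 0.2
    baseline_hz: float = 0.33
    powerline_amp: float = 0.05
    powerline_hz: float = 50.0
    white_noise_sd: float = 0.05
    gain_jitter: float = 0.1  # per-record multiplicative spread around lead gains
    beat: BeatParams = field(default_factory=BeatParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_effect not in ("amplitude_shift", "rr_irregularity", "wave_inversion"):
            raise ValueError(f"unknown class_effect {self.class_effect!r}")
        for v in (self.effect_magnitude, self.baseline_amp, self.powerline_amp,
                  self.white_noise_sd, self.rr_jitter_sd):
            if v < 0:
                raise ValueError("magnitudes must be nonnegative")
        if abs(self.rate * self.duration - round(self.rate * self.duration)) > 1e-9:
            raise ValueError("rate * duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration))


def _render_record(cfg: SynthConfig, label: int, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_samples
    rr_sd = cfg.rr_jitter_sd
    amp = 1.0
    t_scale = 1.0
    if label == 1:
        if cfg.class_effect == "amplitude_shift":
            amp = 1.0 + cfg.effect_magnitude
        elif cfg.class_effect == "rr_irregularity":
            rr_sd = cfg.rr_jitter_sd + cfg.effect_magnitude
        else:  # wave_inversion: interpolate toward a flipped T wave
            t_scale = 1.0 - 2.0 * cfg.effect_magnitude
    template = beat_template(cfg.beat, cfg.rate, t_wave_scale=t_scale) * amp

    bpm = rng.normal(cfg.beat_rate_mean, cfg.beat_rate_sd)
    mean_rr = 60.0 / max(bpm, 20.0)
    latent = np.zeros(n + len(template))
    t0 = rng.uniform(0, mean_rr)
    while t0 < cfg.duration:
        i0 = int(round(t0 * cfg.rate))
        latent[i0 : i0 + len(template)] += template
        t0 += max(0.2, rng.normal(mean_rr, rr_sd))
    latent = latent[:n]

    data = np.empty((cfg.n_channels, n))
    tt = np.arange(n) / cfg.rate
    # lead gains: a fixed projection pattern (anatomy-like), jittered per record
    base_gains = 0.6 + 0.5 * np.cos(np.arange(cfg.n_channels) * np.pi / max(1, cfg.n_channels))
    for c in range(cfg.n_channels):
        gain = base_gains[c] * rng.uniform(1 - cfg.gain_jitter, 1 + cfg.gain_jitter)
        delay = int(rng.integers(0, max(1, int(0.01 * cfg.rate)) + 1))
        sig = gain * np.roll(latent, delay)
        sig = sig + cfg.baseline_amp * np.sin(
            2 * np.pi * cfg.baseline_hz * tt + rng.uniform(0, 2 * np.pi)
        )
        sig = sig + cfg.powerline_amp * np.sin(
            2 * np.pi * cfg.powerline_hz * tt + rng.uniform(0, 2 * np.pi)
        )
        sig = sig + rng.normal(0, cfg.white_noise_sd, n)
        data[c] = sig
    return data


def generate_dataset(cfg: SynthConfig) -> Dataset:
    """Labeled dataset with the configured per-class counts, deterministic
    given ``cfg.seed``.  Records are interleaved (normal, abnormal, ...)
    then kept in generation order."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    counts = {0: cfg.n_per_class[0], 1: cfg.n_per_class[1]}
    k = 0
    while counts[0] > 0 or counts[1] > 0:
        for label in (0, 1):
            if counts[label] > 0:
                data = _render_record(cfg, label, rng)
                records.append(TimeSeriesRecord(f"rec{k:05d}", data, cfg.rate, label))
                counts[label] -= 1
                k += 1
    meta = asdict(cfg)
    meta["beat"] = asdict(cfg.beat)
    return Dataset(records, {"generator": meta})


_PRESETS = {
    # small, clean and strongly separated: for fast learnability checks
    "easy": SynthConfig(
        n_per_class=(230, 230),
        n_channels=2,
        rate=100.0,
        duration=2.0,
        class_effect="amplitude_shift",
        effect_magnitude=0.5,
        baseline_amp=0.1,
        powerline_hz=40.0,
        powerline_amp=0.02,
        white_noise_sd=0.05,
        rr_jitter_sd=0.02,
        seed=2024,
    ),
    "medium": SynthConfig(
        n_per_class=(150, 150),
        n_channels=4,
        rate=200.0,
        duration=4.0,
        effect_magnitude=0.25,
        baseline_amp=0.2,
        powerline_amp=0.05,
        white_noise_sd=0.1,
        seed=2024,
    ),
    "hard": SynthConfig(
        n_per_class=(150, 150),
        n_channels=8,
        rate=500.0,
        duration=9.5,
        effect_magnitude=0.1,
        baseline_amp=0.3,
        powerline_amp=0.1,
        white_noise_sd=0.2,
        seed=2024,
    ),
}


def preset(name: str, **overrides) -> SynthConfig:
    """Named generation preset ('easy', 'medium', 'hard'), optionally overridden."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    cfg = _PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def easy_benchmark(seed: int = 2024):
    """The packaged easy benchmark: 200 train / 60 val / 200 test records.

    Two channels at 100 Hz, 200 samples per channel, abnormal class =
    1.5x beat amplitude.  Returns (train, val, test) datasets.  The tiny
    network and training settings that pair with it live in
    :func:`viewens.model.tiny_config`.
    """
    from .records import SplitSpec, split_dataset

    cfg = replace(preset("easy"), seed=seed)
    ds = generate_dataset(cfg)
    return split_dataset(ds, SplitSpec(200, 60, 200, shuffle_seed=seed))
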