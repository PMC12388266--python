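"""Synthetic throat-vibration signals with controlled noise.

Emulates the phenomenology of vocal-fold vibration as recorded by a
throat-attached piezoelectric film: voiced stretches are a harmonic series
at the glottal fundamental (amplitudes decaying as 1/k) gated by smooth
raised-cosine onsets and offsets; unvoiced stretches are near-silent.  Noise
is the superposition of broadband high-frequency perturbation (white
Gaussian) and a slow sinusoidal baseline drift, both scaled relative to the
voiced RMS.  Two sensor channels with different gains add linearly.

This generator reproduces amplitude structure, onset edges and the two
noise mechanisms; it is a surrogate, not a physiological glottal-flow
model, and carries no articulatory or phonetic content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_prep import (TimeSeries, build_trajectory_matrix,
                          normalize_columns)

__all__ = ["Segment", "SyntheticConfig", "generate_clean", "add_noise",
           "superpose_channels", "pvdf_charge", "make_training_set",
           "make_benchmark"]


@dataclass(frozen=True)
class Segment:
    start: float          # seconds
    end: float
    kind: str             # "voiced" | "unvoiced"
    gain: float = 1.0


def _default_segments() -> tuple[Segment, ...]:
    # alternating phonation and pauses, ending louder (raised tone)
    return (Segment(0.00, 0.50, "voiced", 1.0),
            Segment(0.50, 0.80, "unvoiced", 0.03),
            Segment(0.80, 1.40, "voiced", 0.8),
            Segment(1.40, 1.60, "unvoiced", 0.03),
            Segment(1.60, 2.00, "voiced", 1.2))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults give a 2 s utterance at 8 kHz.

    Noise levels are relative to the voiced-segment RMS: white perturbation
    with standard deviation ``hf_noise_sigma`` x RMS and a baseline drift
    sinusoid of amplitude ``lf_amp`` x RMS at ``lf_freq`` Hz.
    """

    rate: float = 8000.0
    duration: float = 2.0
    f0: float = 120.0
    n_harmonics: int = 8
    amplitude: float = 1.0
    segments: tuple[Segment, ...] = field(default_factory=_default_segments)
    onset_ms: float = 20.0
    hf_noise_sigma: float = 0.1
    lf_amp: float = 0.2
    lf_freq: float = 2.0
    channel_gains: tuple[float, float] = (1.0, 0.6)
    phase_jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.rate <= 0:
            problems.append(f"rate must be > 0 (got {self.rate})")
        if self.rate <= 2.0 * self.f0 * self.n_harmonics:
            problems.append(
                f"rate {self.rate} violates the Nyquist bound for "
                f"{self.n_harmonics} harmonics of f0={self.f0}")
        if self.duration < 0:
            problems.append("duration must be >= 0")
        if min(self.channel_gains) < 0 or self.hf_noise_sigma < 0 \
                or self.lf_amp < 0:
            problems.append("gains and noise levels must be >= 0")
        last = 0.0
        for seg in self.segments:
            if seg.kind not in ("voiced", "unvoiced"):
                problems.append(f"unknown segment kind {seg.kind!r}")
            if seg.start < last - 1e-12 or seg.end > self.duration + 1e-12:
                problems.append(
                    f"segment ({seg.start}, {seg.end}) overlaps or exceeds "
                    f"duration {self.duration}")
            last = max(last, seg.end)
        if problems:
            raise ValueError("invalid synthetic config: "
                             + "; ".join(problems))


def _envelope(cfg: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    """Per-sample gain: segment gains with raised-cosine onsets/offsets."""
    env = np.zeros_like(t)
    ramp = cfg.onset_ms / 1000.0
    for seg in cfg.segments:
        # unvoiced segments carry only their (small) residual gain
        gain = seg.gain
        g = np.zeros_like(t)
        inside = (t >= seg.start) & (t < seg.end)
        g[inside] = 1.0
        if ramp > 0:
            rise = inside & (t < seg.start + ramp)
            g[rise] = 0.5 - 0.5 * np.cos(np.pi * (t[rise] - seg.start)
                                         / ramp)
            fall = inside & (t >= seg.end - ramp)
            g[fall] = 0.5 - 0.5 * np.cos(np.pi * (seg.end - t[fall]) / ramp)
        env += gain * g
    return env


def generate_clean(cfg: SyntheticConfig) -> TimeSeries:
    """Harmonic pulse-train surrogate of vocal-fold vibration.

    Sum of ``n_harmonics`` sinusoids at multiples of ``f0`` with 1/k
    amplitude decay, gated by the segment envelope.  Deterministic for a
    given seed; ``phase_jitter`` > 0 draws seeded random initial phases.
    """
    cfg.validate()
    n = int(round(cfg.rate * cfg.duration))
    t = np.arange(n) / cfg.rate
    if n == 0:
        return TimeSeries(samples=np.empty(0), rate=cfg.rate)
    rng = np.random.default_rng(cfg.seed)
    phases = (cfg.phase_jitter * rng.uniform(0, 2 * np.pi, cfg.n_harmonics)
              if cfg.phase_jitter > 0 else np.zeros(cfg.n_harmonics))
    wave = np.zeros(n)
    for k in range(1, cfg.n_harmonics + 1):
        wave += (1.0 / k) * np.sin(2 * np.pi * k * cfg.f0 * t
                                   + phases[k - 1])
    return TimeSeries(samples=cfg.amplitude * _envelope(cfg, t) * wave,
                      rate=cfg.rate)


def voiced_rms(cfg: SyntheticConfig) -> float:
    """RMS of the clean signal over voiced segments (noise scale anchor)."""
    clean = generate_clean(cfg)
    t = np.arange(len(clean)) / cfg.rate
    mask = np.zeros(len(clean), dtype=bool)
    for seg in cfg.segments:
        if seg.kind == "voiced":
            mask |= (t >= seg.start) & (t < seg.end)
    if not mask.any():
        return float(np.sqrt(np.mean(clean.samples ** 2))) if len(clean) \
            else 0.0
    return float(np.sqrt(np.mean(clean.samples[mask] ** 2)))


def add_noise(clean: TimeSeries, cfg: SyntheticConfig,
              rng: np.random.Generator | None = None) -> TimeSeries:
    """Add high-frequency white perturbation and low-frequency drift."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = len(clean)
    t = np.arange(n) / clean.rate
    scale = voiced_rms(cfg)
    noisy = clean.samples.copy()
    if cfg.hf_noise_sigma > 0:
        noisy = noisy + cfg.hf_noise_sigma * scale * rng.standard_normal(n)
    if cfg.lf_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noisy = noisy + cfg.lf_amp * scale * np.sin(
            2 * np.pi * cfg.lf_freq * t + phase)
    return TimeSeries(samples=noisy, rate=clean.rate)


def superpose_channels(ch1: TimeSeries, ch2: TimeSeries) -> TimeSeries:
    """Linear superposition of the two sensor channels."""
    if len(ch1) != len(ch2) or ch1.rate != ch2.rate:
        raise ValueError("channels must share length and sampling rate")
    return TimeSeries(samples=ch1.samples + ch2.samples, rate=ch1.rate)


def pvdf_charge(force, d: float):
    """Charge generated by a PVDF film under force ``F``: ``Q = d F``.

    ``d`` is the piezoelectric coefficient in C/N (material property, must
    be supplied by the user); the sign of the charge follows the sign of
    the applied force.
    """
    if d <= 0:
        raise ValueError("piezoelectric coefficient d must be > 0")
    return d * np.asarray(force, float) if np.ndim(force) else d * force


def two_channel_noisy(cfg: SyntheticConfig) -> tuple[TimeSeries, TimeSeries]:
    """Clean fused signal and its noisy two-channel superposition.

    Each channel is the clean source scaled by its gain with independent
    noise realizations; channels add linearly.
    """
    clean = generate_clean(cfg)
    g1, g2 = cfg.channel_gains
    rng = np.random.default_rng(cfg.seed + 1)
    ch1 = add_noise(TimeSeries(g1 * clean.samples, clean.rate), cfg, rng)
    ch2 = add_noise(TimeSeries(g2 * clean.samples, clean.rate), cfg, rng)
    fused_clean = TimeSeries((g1 + g2) * clean.samples, clean.rate)
    return fused_clean, superpose_channels(ch1, ch2)


def make_training_set(cfg: SyntheticConfig, n_examples: int, L: int = 64,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (noisy, clean) window pairs for supervised fine-tuning.

    Both signals are embedded as trajectory matrices; ``n_examples`` columns
    are sampled (without replacement where possible).  Windows are z-scored
    with the *noisy* window statistics on both sides, matching what the
    denoiser sees at inference time.  Returns two ``(n_examples, L)``
    arrays.
    """
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    clean, noisy = two_channel_noisy(cfg)
    Xn = normalize_columns(build_trajectory_matrix(noisy, L))
    Xc = build_trajectory_matrix(clean, L)
    K = Xn.n_columns
    idx = (rng.choice(K, size=n_examples, replace=False) if n_examples <= K
           else rng.integers(0, K, size=n_examples))
    noisy_w = Xn.values[:, idx].T
    clean_w = ((Xc.values[:, idx] - Xn.column_means[idx])
               / Xn.column_stds[idx]).T
    return noisy_w, clean_w


def make_benchmark(cfg: SyntheticConfig | None = None
                   ) -> tuple[TimeSeries, TimeSeries]:
    """The default (clean, noisy) evaluation pair used across tests."""
    cfg = SyntheticConfig() if cfg is None else cfg
    return two_channel_noisy(cfg)
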