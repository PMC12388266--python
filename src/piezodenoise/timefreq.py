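"""STFT analysis/synthesis with Hanning windowing and optional masking.

Frames start at sample 0 with hop ``H`` and no centering or padding:
``X[m, k] = sum_n x[n + mH] w[n] exp(-2j pi k n / N)``.  The inverse applies
a per-frame inverse DFT, windows again, overlap-adds, and divides by the
accumulated squared window, so interior samples are recovered exactly for
any hop with bounded overlap.  Masking (off by default) applies a soft
magnitude threshold per frequency bin against a noise floor estimated as a
quantile of that bin's magnitudes across frames; phase is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_prep import TimeSeries

__all__ = ["Spectrogram", "MaskConfig", "hanning_window", "stft",
           "apply_mask", "istft"]


@dataclass
class Spectrogram:
    """Complex STFT coefficients indexed ``(frame, bin)`` with provenance."""

    coeffs: np.ndarray       # shape (frame_count, fft_size), complex
    fft_size: int
    hop: int
    window: np.ndarray
    rate: float = 1.0

    @property
    def frame_count(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class MaskConfig:
    """Spectral-mask settings.

    method : ``"none"`` (bit-exact passthrough) or ``"soft_threshold"``.
    floor_quantile : quantile of per-bin magnitude used as noise floor.
    gain_floor : minimum retained gain, keeps weak bins audible.
    """

    method: str = "none"
    floor_quantile: float = 0.10
    gain_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in ("none", "soft_threshold"):
            raise ValueError(f"unknown mask method {self.method!r}")
        if not 0.0 <= self.floor_quantile < 1.0:
            raise ValueError("floor_quantile must lie in [0, 1)")
        if not 0.0 <= self.gain_floor <= 1.0:
            raise ValueError("gain_floor must lie in [0, 1]")


def hanning_window(N: int) -> np.ndarray:
    """Symmetric raised-cosine taper ``0.5 - 0.5 cos(2 pi n / (N-1))``."""
    if N < 2:
        raise ValueError(f"window length must be >= 2, got {N}")
    n = np.arange(N)
    w = 0.5 - 0.5 * np.cos(2.0 * np.pi * n / (N - 1))
    w[0] = w[-1] = 0.0
    return w


def _frames(x: np.ndarray, N: int, H: int) -> np.ndarray:
    T = x.size
    M = (T - N) // H + 1
    idx = np.arange(N)[None, :] + H * np.arange(M)[:, None]
    return x[idx]


def stft(x: TimeSeries | np.ndarray, N: int = 256, H: int = 64,
         window: np.ndarray | None = None) -> Spectrogram:
    """Short-time Fourier transform over full frames only (no padding)."""
    if isinstance(x, TimeSeries):
        samples, rate = x.samples, x.rate
    else:
        samples, rate = np.asarray(x, dtype=float).ravel(), 1.0
    if not 1 <= H <= N:
        raise ValueError(f"hop H={H} must satisfy 1 <= H <= N={N}")
    if samples.size < N:
        raise ValueError(
            f"signal of length {samples.size} shorter than FFT size {N}")
    w = hanning_window(N) if window is None else np.asarray(window, float)
    if w.size != N:
        raise ValueError(f"window length {w.size} != FFT size {N}")
    coeffs = np.fft.fft(_frames(samples, N, H) * w, axis=1)
    return Spectrogram(coeffs=coeffs, fft_size=N, hop=H, window=w, rate=rate)


def apply_mask(S: Spectrogram, cfg: MaskConfig) -> Spectrogram:
    """Attenuate low-magnitude time-frequency cells below a per-bin floor.

    Gain is ``clamp((|X| - tau) / |X|, gain_floor, 1)`` with ``tau`` the
    ``floor_quantile`` quantile of that bin's magnitudes over frames; the
    output magnitude never exceeds the input's and phase is untouched.
    """
    if cfg.method == "none":
        return S
    mag = np.abs(S.coeffs)
    tau = np.quantile(mag, cfg.floor_quantile, axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(mag > 0, (mag - tau) / np.where(mag > 0, mag, 1.0), 0.0)
    gain = np.clip(gain, cfg.gain_floor, 1.0)
    return Spectrogram(coeffs=S.coeffs * gain, fft_size=S.fft_size,
                       hop=S.hop, window=S.window, rate=S.rate)


def istft(S: Spectrogram) -> TimeSeries:
    """Windowed overlap-add inverse of :func:`stft`.

    Interior samples (covered by a full complement of overlapping frames)
    reconstruct the analyzed signal to rounding error; edge samples carry
    the usual taper bias removed by the squared-window normalizer.
    """
    N, H, w = S.fft_size, S.hop, S.window
    M = S.frame_count
    T = N + H * (M - 1)
    frames = np.fft.ifft(S.coeffs, axis=1).real * w
    out = np.zeros(T)
    norm = np.zeros(T)
    w2 = w * w
    for m in range(M):
        out[m * H:m * H + N] += frames[m]
        norm[m * H:m * H + N] += w2
    interior = norm > 1e-12
    if T > N and not interior[N // 2:T - N // 2].all():
        raise ValueError(
            "degenerate overlap: squared-window sum vanishes on the interior "
            f"(N={N}, H={H})")
    out[interior] /= norm[interior]
    return TimeSeries(samples=out, rate=S.rate)
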