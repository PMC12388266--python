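"""Denoising quality metrics and the weighted composite score.

Four quantities summarize a denoising run: spectral flatness of the output
(geometric over arithmetic mean of the power spectrum; near 0 for tonal
signals, 1 for white noise), Pearson correlation with the reference
waveform, local noise energy (mean per-frame variance over short
non-overlapping frames, sensitive to residual high-frequency jitter), and
the output/input energy ratio.  The first three combine into a 0-100 score

    score = 100 [ W1 rho + W2 (1 - min(1, flatness/0.1))
                         + W3 (1 - min(1, LNE/0.1)) ]

with default weights (0.4, 0.3, 0.3); flatness and LNE saturate at 0.1,
beyond which they contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signal_prep import TimeSeries

__all__ = ["MetricReport", "spectral_flatness", "ppmcc",
           "local_noise_energy", "energy_ratio", "composite_score",
           "evaluate", "comparison_table"]

DEFAULT_WEIGHTS = (0.4, 0.3, 0.3)
#: flatness/LNE value at which the corresponding score term saturates
SATURATION = 0.1
#: power-spectrum floor applied before the log (flatness of silence -> 0)
PSD_FLOOR = 1e-20


def _samples(x) -> np.ndarray:
    return x.samples if isinstance(x, TimeSeries) else \
        np.asarray(x, float).ravel()


def spectral_flatness(x) -> float:
    """Geometric/arithmetic mean ratio of the periodogram (DC excluded)."""
    s = _samples(x)
    if s.size < 2:
        raise ValueError("spectral flatness needs at least 2 samples")
    P = np.abs(np.fft.rfft(s)[1:]) ** 2
    if np.all(P <= PSD_FLOOR):
        return 0.0
    P = np.maximum(P, PSD_FLOOR)
    return float(np.exp(np.mean(np.log(P))) / np.mean(P))


def ppmcc(x, y) -> float:
    """Pearson product-moment correlation between two signals."""
    xs, ys = _samples(x), _samples(y)
    if xs.size != ys.size or xs.size < 2:
        raise ValueError("ppmcc needs two equal-length signals (length >= 2)")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("correlation undefined for a constant signal")
    return float(stats.pearsonr(xs, ys).statistic)


def local_noise_energy(x, frame_length: int = 100) -> float:
    """Mean of per-frame population variances over non-overlapping frames.

    The trailing partial frame is discarded.
    """
    s = _samples(x)
    if frame_length < 2:
        raise ValueError("frame_length must be >= 2")
    M = s.size // frame_length
    if M < 1:
        raise ValueError(
            f"signal of length {s.size} shorter than one frame "
            f"({frame_length})")
    frames = s[:M * frame_length].reshape(M, frame_length)
    return float(np.mean(np.var(frames, axis=1)))


def energy_ratio(original, denoised) -> float:
    """Output energy as a fraction of input energy."""
    xo, xd = _samples(original), _samples(denoised)
    if xo.size != xd.size:
        raise ValueError("signals must have equal length")
    eo = float(np.sum(xo ** 2))
    if eo == 0.0:
        raise ValueError("original signal has zero energy")
    return float(np.sum(xd ** 2)) / eo


def composite_score(ppmcc_value: float, flatness: float, lne: float,
                    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
                    ) -> float:
    """Weighted 0-100 combination of correlation, flatness and LNE."""
    W1, W2, W3 = weights
    if min(weights) < 0:
        raise ValueError("weights must be non-negative")
    return 100.0 * (W1 * ppmcc_value
                    + W2 * (1.0 - min(1.0, flatness / SATURATION))
                    + W3 * (1.0 - min(1.0, lne / SATURATION)))


@dataclass(frozen=True)
class MetricReport:
    """All metrics of one (reference, denoised) pair."""

    spectral_flatness: float
    ppmcc: float
    local_noise_energy: float
    energy_ratio: float
    composite_score: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    lne_frame_length: int = 100

    def as_dict(self) -> dict:
        return {
            "spectral_flatness": self.spectral_flatness,
            "ppmcc": self.ppmcc,
            "local_noise_energy": self.local_noise_energy,
            "energy_ratio": self.energy_ratio,
            "composite_score": self.composite_score,
        }

    def __str__(self) -> str:
        lines = [f"{k} = {v:.6f}" for k, v in self.as_dict().items()
                 if k != "composite_score"]
        lines.append(f"composite_score = {self.composite_score:.2f}")
        return "\n".join(lines)


def evaluate(original, denoised, frame_length: int = 100,
             weights: tuple[float, float, float] = DEFAULT_WEIGHTS
             ) -> MetricReport:
    """Full metric suite: flatness and LNE on the denoised signal, PPMCC
    and energy ratio against the reference."""
    fl = spectral_flatness(denoised)
    rho = ppmcc(original, denoised)
    lne = local_noise_energy(denoised, frame_length)
    er = energy_ratio(original, denoised)
    return MetricReport(spectral_flatness=fl, ppmcc=rho,
                        local_noise_energy=lne, energy_ratio=er,
                        composite_score=composite_score(rho, fl, lne,
                                                        weights),
                        weights=weights, lne_frame_length=frame_length)


def comparison_table(reports: dict[str, MetricReport]) -> str:
    """Delimited table with one column per method, rows in the usual
    flatness / PPMCC / LNE / score order."""
    names = list(reports)
    rows = [("Spectral Flatness", "spectral_flatness", "{:.6f}"),
            ("PPMCC", "ppmcc", "{:.4f}"),
            ("Local Noise Energy", "local_noise_energy", "{:.6f}"),
            ("Composite Score", "composite_score", "{:.2f}")]
    lines = ["Parameter\t" + "\t".join(names)]
    for label, attr, fmt in rows:
        vals = [fmt.format(getattr(reports[n], attr)) for n in names]
        lines.append(label + "\t" + "\t".join(vals))
    return "\n".join(lines)
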