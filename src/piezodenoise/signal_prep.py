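"""Trajectory-matrix embedding of 1-D vibration signals.

A signal of length ``T`` is embedded as an ``L x K`` Hankel (trajectory)
matrix whose column ``j`` is the window ``x[j : j+L]`` (``K = T - L + 1``).
Columns are z-scored so every window is modelled on the same scale, and the
exact inverse of the embedding is diagonal (anti-diagonal) averaging, which
maps any ``L x K`` matrix back to a length ``L + K - 1`` series.  For a true
Hankel matrix the round trip is the identity; for a matrix of per-window
network reconstructions it averages the overlapping estimates of each sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "TrajectoryMatrix",
    "build_trajectory_matrix",
    "normalize_columns",
    "denormalize_columns",
    "diagonal_average",
    "anti_diagonal_counts",
]

#: smallest admissible column standard deviation; constant columns are
#: floored here so normalization never divides by zero
SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Sensor voltage samples (arbitrary units), finite.
    rate : float
        Sampling rate in samples/second, strictly positive.
    """

    samples: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class TrajectoryMatrix:
    """Hankel embedding of a signal with optional per-column z-scoring."""

    values: np.ndarray
    rate: float = 1.0
    normalized: bool = False
    column_means: np.ndarray | None = None
    column_stds: np.ndarray | None = None

    window_length: int = field(init=False)
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("trajectory matrix must be non-empty")
        self.window_length, self.n_columns = self.values.shape


def build_trajectory_matrix(x: TimeSeries | np.ndarray, L: int,
                            rate: float = 1.0) -> TrajectoryMatrix:
    """Embed ``x`` as the ``L x (T - L + 1)`` sliding-window Hankel matrix.

    Column ``j`` holds ``x[j : j+L]``; anti-diagonals are constant.
    """
    if isinstance(x, TimeSeries):
        samples, rate = x.samples, x.rate
    else:
        samples = np.asarray(x, dtype=float).ravel()
    T = samples.size
    if L < 1 or L > T:
        raise ValueError(
            f"window length L={L} invalid for signal of length T={T} "
            f"(need 1 <= L <= T)")
    K = T - L + 1
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    return TrajectoryMatrix(values=samples[idx], rate=rate)


def normalize_columns(X: TrajectoryMatrix) -> TrajectoryMatrix:
    """z-score each column (population std); stores the stats for inversion.

    Columns whose std falls below ``SIGMA_FLOOR`` (constant windows) are
    mapped to zeros rather than raising.
    """
    if X.normalized:
        raise ValueError("trajectory matrix is already normalized")
    mu = X.values.mean(axis=0)
    sigma = np.maximum(X.values.std(axis=0), SIGMA_FLOOR)
    vals = (X.values - mu) / sigma
    return TrajectoryMatrix(values=vals, rate=X.rate, normalized=True,
                            column_means=mu, column_stds=sigma)


def denormalize_columns(X: TrajectoryMatrix) -> TrajectoryMatrix:
    """Invert :func:`normalize_columns` using the stored column stats."""
    if not X.normalized or X.column_means is None or X.column_stds is None:
        raise ValueError(
            "cannot denormalize: matrix is not normalized or stats missing")
    vals = X.values * X.column_stds + X.column_means
    return TrajectoryMatrix(values=vals, rate=X.rate, normalized=False)


def anti_diagonal_counts(L: int, K: int) -> np.ndarray:
    """Number of matrix entries on each anti-diagonal of an ``L x K`` matrix.

    Anti-diagonal ``t`` (1-based, ``t = 1..L+K-1``) collects entries with
    1-based indices satisfying ``i + j = t + 1``; its size ramps up to
    ``min(L, K)``, stays flat, then ramps down.
    """
    t = np.arange(1, L + K)
    lo, hi = min(L, K), max(L, K)
    return np.minimum(np.minimum(t, lo), L + K - t)


def diagonal_average(X: TrajectoryMatrix | np.ndarray,
                     rate: float | None = None) -> TimeSeries:
    """Collapse a matrix to a series by averaging its anti-diagonals.

    Output element ``t`` (0-based) is the mean of ``values[i, j]`` over
    ``i + j = t``; the output has length ``L + K - 1``.  Exact inverse of
    :func:`build_trajectory_matrix` on Hankel input.
    """
    if isinstance(X, TrajectoryMatrix):
        vals = X.values
        rate = X.rate if rate is None else rate
    else:
        vals = np.atleast_2d(np.asarray(X, dtype=float))
        rate = 1.0 if rate is None else rate
    if vals.size == 0:
        raise ValueError("cannot diagonal-average an empty matrix")
    L, K = vals.shape
    sums = np.zeros(L + K - 1)
    # accumulate each row shifted by its row index: row i contributes to
    # output positions i..i+K-1
    for i in range(L):
        sums[i:i + K] += vals[i]
    counts = anti_diagonal_counts(L, K)
    return TimeSeries(samples=sums / counts, rate=rate)
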