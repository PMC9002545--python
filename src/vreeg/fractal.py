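"""Higuchi fractal dimension of EEG time series.

The Higuchi method estimates the fractal dimension ``D`` of a sampled curve
from the scaling of reconstructed curve lengths: for each lag ``k`` the series
is decimated into ``k`` interleaved sub-curves, their normalised lengths are
averaged into ``L(k)``, and if the series is fractal ``L(k) ∝ k^-D``.  ``D``
is read off as minus the slope of an ordinary least-squares fit of
``ln L(k)`` on ``ln k`` for ``k = 1..kmax``.  For a smooth curve D = 1; for
uncorrelated noise D approaches 2.

EEG complexity is summarised per channel as the mean FD over consecutive
non-overlapping windows of fixed length (default 256 samples, i.e. 2 s at
128 Hz, giving 10 windows per 20 s epoch).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signal_io import EEGSegment

logger = logging.getLogger(__name__)

__all__ = [
    "HiguchiConfig",
    "curve_length",
    "higuchi_fd",
    "windowed_fd",
    "build_fd_table",
]


@dataclass(frozen=True)
class HiguchiConfig:
    """Parameters of the windowed Higuchi FD estimator.

    kmax
        Largest lag used in the log-log fit.  6 suffices to estimate the
        slope on EEG-length windows.
    window_samples
        Fixed length of the non-overlapping analysis windows.  Must leave
        enough points per decimated sub-curve (> 4*kmax).
    """

    kmax: int = 6
    window_samples: int = 256
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError(f"kmax must be >= 2, got {self.kmax}")
        if self.window_samples <= 4 * self.kmax:
            raise ValueError(
                f"window_samples={self.window_samples} too small for "
                f"kmax={self.kmax} (need > {4 * self.kmax})"
            )
        if self.aggregation != "mean":
            raise ValueError(f"unsupported aggregation {self.aggregation!r}")


def curve_length(x: Sequence[float], m: int, k: int) -> float:
    """Normalised length ``L_m(k)`` of the m-th decimated sub-curve.

    With 1-based indices X(1..N), the sub-curve starts at X(m) and steps by
    k.  Writing M = floor((N-m)/k) (the Gauss bracket),

        L_m(k) = (1/k) * [ sum_{i=1..M} |X(m+ik) - X(m+(i-1)k)| ] * (N-1)/(M*k)

    The trailing factor renormalises the decimated length to the time span
    of the full series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 1 <= m <= k:
        raise ValueError(f"m must be in [1, k]; got m={m}, k={k}")
    n_steps = (n - m) // k
    if n_steps < 1:
        raise ValueError(f"k={k} too large for series of length {n} with m={m}")
    pts = x[m - 1 :: k][: n_steps + 1]
    total = float(np.sum(np.abs(np.diff(pts))))
    return total * (n - 1) / (n_steps * k) / k


def _mean_curve_lengths(x: np.ndarray, kmax: int) -> np.ndarray:
    """L(k) = (1/k) sum_{m=1..k} L_m(k) for k = 1..kmax."""
    return np.array(
        [np.mean([curve_length(x, m, k) for m in range(1, k + 1)]) for k in range(1, kmax + 1)]
    )


def higuchi_fd(x: Sequence[float], cfg: HiguchiConfig | None = None) -> float:
    """Higuchi fractal dimension of a single series.

    Fits ln L(k) against ln k over k = 1..kmax by ordinary least squares and
    returns minus the slope.  Raises on constant input, where every curve
    length is zero and the FD is undefined.
    """
    cfg = cfg or HiguchiConfig()
    x = np.asarray(x, dtype=float)
    if x.size <= 4 * cfg.kmax:
        raise ValueError(f"series of length {x.size} too short for kmax={cfg.kmax}")
    lk = _mean_curve_lengths(x, cfg.kmax)
    if np.any(lk <= 0):
        raise ValueError("constant (or piecewise-flat) input: L(k) = 0, FD undefined")
    k = np.arange(1, cfg.kmax + 1)
    slope = np.polyfit(np.log(k), np.log(lk), 1)[0]
    return float(-slope)


def windowed_fd(x: Sequence[float], cfg: HiguchiConfig | None = None) -> tuple[float, int]:
    """Mean Higuchi FD over consecutive non-overlapping windows.

    The series is cut into ``floor(N / window_samples)`` full windows; the
    trailing remainder is discarded.  Returns ``(mean FD, n_windows)``.
    """
    cfg = cfg or HiguchiConfig()
    x = np.asarray(x, dtype=float)
    n_windows = x.size // cfg.window_samples
    if n_windows < 1:
        raise ValueError(
            f"series of length {x.size} shorter than one window ({cfg.window_samples})"
        )
    fds = [
        higuchi_fd(x[w * cfg.window_samples : (w + 1) * cfg.window_samples], cfg)
        for w in range(n_windows)
    ]
    return float(np.mean(fds)), n_windows


def build_fd_table(
    segments: Iterable[EEGSegment], cfg: HiguchiConfig | None = None
) -> pd.DataFrame:
    """Per (subject, condition, channel) windowed FD, as a tidy DataFrame.

    Columns: subject, condition, channel, fd, n_windows.  Constant channels
    (undefined FD) are flagged with a warning and excluded.  Row order is
    deterministic: segments in input order, channels in segment order.
    """
    cfg = cfg or HiguchiConfig()
    rows = []
    for seg in segments:
        for ci, ch in enumerate(seg.channel_labels):
            try:
                fd, nw = windowed_fd(seg.data[ci], cfg)
            except ValueError as exc:
                logger.warning(
                    "excluding subject=%s condition=%s channel=%s: %s",
                    seg.subject_id, seg.condition, ch, exc,
                )
                continue
            rows.append(
                {
                    "subject": seg.subject_id,
                    "condition": seg.condition,
                    "channel": ch,
                    "fd": fd,
                    "n_windows": nw,
                }
            )
    return pd.DataFrame(rows, columns=["subject", "condition", "channel", "fd", "n_windows"])
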