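"""Whistle contour container and shape-comparison primitives.

A contour is the fundamental-frequency trajectory of one whistle (one loop
of a multi-loop whistle counts as one contour).  Shape comparison works on
time-resampled, per-contour z-normalised frequency vectors so that a uniform
time shift, a constant frequency offset, and overall duration do not affect
the distance; what remains is the frequency-modulation *shape*, which is the
cue observers use when matching contours against a catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WhistleContour:
    """A traced fundamental-frequency trajectory.

    Parameters
    ----------
    session_id : str
        Recording session the contour belongs to.
    times : array of float
        Sample times in seconds, strictly increasing (absolute session time).
    freqs : array of float
        Fundamental frequency in Hz at each sample time.
    grade : int
        Quality grade: 1 (contour not clearly discernible; discarded),
        2 (clearly visible start to end) or 3 (predominant).
    snr : float
        Estimated signal-to-noise ratio in dB (NaN when unknown, e.g. for
        event-level synthetic contours).
    """

    session_id: str
    times: np.ndarray
    freqs: np.ndarray
    grade: int = 3
    snr: float = float("nan")
    identity: str | None = None  # ground-truth label, synthetic data only

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.freqs.shape:
            raise ValueError("times and freqs must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("contour times must be strictly increasing")
        if np.any(self.freqs <= 0):
            raise ValueError("contour frequencies must be positive")
        if self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1, 2 or 3, got {self.grade}")

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def shifted(self, dt: float) -> "WhistleContour":
        """Return a copy displaced by ``dt`` seconds."""
        return WhistleContour(self.session_id, self.times + dt, self.freqs,
                              self.grade, self.snr, self.identity)


def resample_shape(times: np.ndarray, freqs: np.ndarray, n: int) -> np.ndarray:
    """Resample a contour onto ``n`` points over its own (normalised) time span."""
    times = np.asarray(times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two samples to resample a contour")
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("contour has zero time span")
    u = (times - times[0]) / span
    return np.interp(np.linspace(0.0, 1.0, n), u, freqs)


def znorm(x: np.ndarray) -> np.ndarray:
    """Z-normalise; an exactly constant vector maps to all zeros."""
    x = np.asarray(x, dtype=float)
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def shape_vector(times: np.ndarray, freqs: np.ndarray, n: int = 64) -> np.ndarray:
    """Resampled, z-normalised shape vector (the znorm_rms comparison space)."""
    return znorm(resample_shape(times, freqs, n))


def shape_distance(a: WhistleContour | tuple, b: WhistleContour | tuple,
                   n: int = 64, metric: str = "znorm_rms") -> float:
    """Shape distance between two contours.

    ``znorm_rms`` (default): RMS difference of time-resampled, z-normalised
    frequency vectors.  ``dtw``: dynamic-time-warping distance on the same
    normalised vectors (per-step mean cost), tolerant of local time warping.
    """
    ta, fa = (a.times, a.freqs) if isinstance(a, WhistleContour) else a
    tb, fb = (b.times, b.freqs) if isinstance(b, WhistleContour) else b
    xa = znorm(resample_shape(ta, fa, n))
    xb = znorm(resample_shape(tb, fb, n))
    if metric == "znorm_rms":
        return float(np.sqrt(np.mean((xa - xb) ** 2)))
    if metric == "dtw":
        return _dtw(xa, xb)
    raise ValueError(f"unknown contour metric {metric!r}")


def _dtw(x: np.ndarray, y: np.ndarray) -> float:
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        c = cost[i - 1]
        prev = acc[i - 1]
        row = acc[i]
        for j in range(1, m + 1):
            row[j] = c[j - 1] + min(prev[j], prev[j - 1], row[j - 1])
    return float(acc[n, m] / (n + m))
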