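"""Single-channel current estimation from prepulse activity.

The segment is low-pass filtered at 1 kHz (4-pole Bessel, the
electrophysiology standard), slow baseline drift is removed with a
piecewise-linear baseline through per-window medians of the
closed-level samples, an all-points amplitude histogram is built with
the Freedman-Diaconis bin width ``2*IQR/N^(1/3)``, and the histogram is
fitted with a double Gaussian

    y = y0 + a1*exp(-((x-x1)/w1)^2) + a2*exp(-((x-x2)/w2)^2).

The distance between the two centres is the single-channel current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .synthetic_data import PatchTrace

__all__ = [
    "AmplitudeHistogram",
    "DoubleGaussianFit",
    "NoOpeningsError",
    "lowpass_filter",
    "subtract_baseline",
    "freedman_diaconis_histogram",
    "fit_double_gaussian",
    "estimate_single_channel_current",
    "prepulse_open_probability",
]


class NoOpeningsError(RuntimeError):
    """Raised when the amplitude histogram shows no second level.

    The practical fallback is to re-record (or re-analyse) a segment at
    slightly stronger suction until single-channel openings appear.
    """


@dataclass
class AmplitudeHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class DoubleGaussianFit:
    y0: float
    a1: float
    a2: float
    x1: float
    x2: float
    w1: float
    w2: float
    histogram: AmplitudeHistogram | None = None

    @property
    def single_channel_current(self) -> float:
        return abs(self.x2 - self.x1)

    @property
    def level_low(self) -> float:
        """The lower of the two fitted centres (the closed level for
        positive-going openings)."""
        return min(self.x1, self.x2)

    @property
    def level_high(self) -> float:
        return max(self.x1, self.x2)


def lowpass_filter(
    current: np.ndarray,
    sample_rate: float,
    cutoff: float = 1.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 4-pole Bessel low-pass; rates in kHz."""
    nyquist = sample_rate / 2.0
    if cutoff >= nyquist:
        return np.asarray(current, dtype=float).copy()
    sos = signal.bessel(order, cutoff / nyquist, output="sos")
    return signal.sosfiltfilt(sos, current)


def subtract_baseline(
    time: np.ndarray,
    current: np.ndarray,
    window_ms: float = 250.0,
    quantile: float = 0.25,
) -> np.ndarray:
    """Remove slow drift via a piecewise-linear baseline.

    The baseline is interpolated through per-window closed-level
    estimates (the ``quantile`` of each window, i.e. the median of the
    lower half of the samples by default).  A lower quantile rather
    than the plain median keeps the estimate inside the closed-level
    cloud even when openings are frequent; for pure noise it only
    introduces a constant offset, which cancels in amplitude
    differences.  Window width is exposed because the appropriate value
    depends on the drift timescale.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    duration = time[-1] - time[0]
    n_windows = max(1, int(round(duration / window_ms)))
    edges = np.linspace(time[0], time[-1], n_windows + 1)
    centers, levels = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (time >= lo) & (time <= hi)
        if mask.any():
            centers.append(0.5 * (lo + hi))
            levels.append(np.quantile(current[mask], quantile))
    if len(centers) == 1:
        return current - levels[0]
    baseline = np.interp(time, centers, levels)
    return current - baseline


def freedman_diaconis_histogram(values: np.ndarray) -> AmplitudeHistogram:
    """All-points histogram with bin width ``2*IQR/N^(1/3)`` and bins
    evenly spaced between the minimum and maximum sample."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 samples for a histogram")
    q75, q25 = np.percentile(values, [75, 25])
    width = 2.0 * (q75 - q25) / n ** (1.0 / 3.0)
    if width <= 0:
        raise ValueError("zero interquartile range; cannot bin")
    lo, hi = values.min(), values.max()
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    edges = lo + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return AmplitudeHistogram(bin_edges=edges, counts=counts, bin_width=float(width))


def _double_gaussian(x, y0, a1, a2, x1, x2, w1, w2):
    x = np.asarray(x, dtype=float)
    return (
        y0
        + a1 * np.exp(-(((x - x1) / w1) ** 2))
        + a2 * np.exp(-(((x - x2) / w2) ** 2))
    )


def fit_double_gaussian(
    hist: AmplitudeHistogram,
    min_separation_bins: int = 3,
    min_peak_counts: int = 4,
) -> DoubleGaussianFit:
    """Fit the amplitude histogram with a double Gaussian.

    The first component is initialised at the histogram mode, the
    second at the tallest local maximum outside the mode peak itself
    (at least ``min_separation_bins`` bins away, and clear of the mode
    peak's own flanks as judged by its half width; ties broken toward
    larger separation).  Raises :class:`NoOpeningsError` for unimodal
    histograms.
    """
    counts = hist.counts.astype(float)
    centers = hist.centers
    mode = int(np.argmax(counts))

    # half-width (in bins) of the mode peak, to keep the second-peak
    # search out of the first peak's flanks when FD bins are very fine
    half = counts[mode] / 2.0
    right = mode
    while right + 1 < counts.size and counts[right + 1] > half:
        right += 1
    left = mode
    while left - 1 >= 0 and counts[left - 1] > half:
        left -= 1
    hw_bins = max(1, right - mode, mode - left)
    exclusion = max(min_separation_bins, 4 * hw_bins)

    smoothed = uniform_filter1d(counts, size=3, mode="nearest")
    local_max = np.ones(counts.size, dtype=bool)
    if counts.size > 1:
        local_max[1:] = smoothed[1:] >= smoothed[:-1]
        local_max[:-1] &= smoothed[:-1] >= smoothed[1:]
    candidates = [
        i
        for i in range(counts.size)
        if local_max[i] and abs(i - mode) >= exclusion and counts[i] >= min_peak_counts
    ]
    if not candidates:
        raise NoOpeningsError(
            "amplitude histogram is unimodal; no opening level detected "
            "(try a segment recorded at stronger suction)"
        )
    best = max(candidates, key=lambda i: (smoothed[i], abs(i - mode)))

    w0 = max(2.0 * hist.bin_width, 1.2 * hw_bins * hist.bin_width)
    p0 = (0.0, counts[mode], counts[best], centers[mode], centers[best], w0, w0)
    bounds = (
        [-np.inf, 0.0, 0.0, -np.inf, -np.inf, 1e-9, 1e-9],
        [np.inf, np.inf, np.inf, np.inf, np.inf, np.inf, np.inf],
    )
    try:
        popt, _ = curve_fit(
            _double_gaussian, centers, counts, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise NoOpeningsError(f"double-Gaussian fit did not converge: {exc}") from exc
    return DoubleGaussianFit(*(float(v) for v in popt), histogram=hist)


def estimate_single_channel_current(
    trace: PatchTrace,
    cutoff: float = 1.0,
    baseline_window_ms: float = 250.0,
    baseline: bool = True,
) -> DoubleGaussianFit:
    """Full prepulse pipeline: filter, de-drift, histogram, fit.

    ``trace`` should be the prepulse segment (constant pressure).  The
    fitted :attr:`DoubleGaussianFit.single_channel_current` is
    ``|x2 - x1|``.
    """
    current = lowpass_filter(trace.current, trace.sample_rate, cutoff=cutoff)
    if baseline:
        current = subtract_baseline(trace.time, current, window_ms=baseline_window_ms)
    hist = freedman_diaconis_histogram(current)
    return fit_double_gaussian(hist)


def prepulse_open_probability(mean_current: float, i: float, n: int) -> float:
    """Resting open probability ``Po = mean_current / (i * n)``.

    ``mean_current`` is the baseline-subtracted mean prepulse current;
    ``i * n`` is the current with every channel open (Po = 1).  Values
    outside [0, 1] are clamped with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if i <= 0:
        raise ValueError("single-channel current must be positive")
    po = mean_current / (i * n)
    if po < 0.0 or po > 1.0:
        warnings.warn(f"open probability {po:.3g} outside [0, 1]; clamped", stacklevel=2)
    return float(np.clip(po, 0.0, 1.0))
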