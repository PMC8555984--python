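"""Pressure-ramp analysis: binning, leak subtraction, Boltzmann fits,
channel counting and idealised open-probability curves.

The pipeline mirrors how staircase-ramp recordings are quantified:
current is averaged within each 1 mmHg pressure dwell, the linear
leak/capacitance background fitted to the pre-opening bins is
subtracted, and the corrected current-pressure relationship is fitted
with

    I(P) = i_min + i_max / (1 + exp((p50 - P) / k)),

from which the channel count is ``n = round(i_max / i)`` with ``i`` the
single-channel reference current.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_data import PatchTrace

__all__ = [
    "PressureResponse",
    "BoltzmannFit",
    "LeakFit",
    "IdealizedTrace",
    "IdealizedAverage",
    "bin_current_by_pressure",
    "leak_subtract",
    "fit_boltzmann",
    "count_channels",
    "reference_current_from_single_channel_patches",
    "idealize_trace",
    "idealize_and_average",
]

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_CURRENT = 0.98  # pA


def _round_half_away(x):
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def boltzmann(P, i_min, i_max, p50, k):
    """I(P) = i_min + i_max / (1 + exp((p50 - P)/k))."""
    with np.errstate(over="ignore"):
        return i_min + i_max / (1.0 + np.exp((p50 - np.asarray(P, dtype=float)) / k))


def sigmoid_po(P, p50, k):
    """Po(P) = 1 / (1 + exp((p50 - P)/k))."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp((p50 - np.asarray(P, dtype=float)) / k))


@dataclass
class BoltzmannFit:
    i_min: float
    i_max: float
    p50: float
    slope_k: float
    residual_norm: float
    saturated: bool = True

    def __call__(self, P):
        return boltzmann(P, self.i_min, self.i_max, self.p50, self.slope_k)


@dataclass
class LeakFit:
    """Line fitted to the pre-opening bins: leak(P) = offset + slope * P."""

    slope: float
    offset: float
    first_opening_bin: int | None
    n_fit_bins: int

    def __call__(self, P):
        return self.offset + self.slope * np.asarray(P, dtype=float)


@dataclass
class PressureResponse:
    """Mean current per 1 mmHg pressure bin, ordered 0 -> max suction."""

    pressure: np.ndarray
    current: np.ndarray
    fit: BoltzmannFit | None = None
    leak: LeakFit | None = None

    def __post_init__(self) -> None:
        if len(self.pressure) != len(self.current):
            raise ValueError("pressure and current must have equal length")


@dataclass
class IdealizedTrace:
    pressure: np.ndarray
    open_count: np.ndarray  # mean open channels per bin
    n_channels: int

    @property
    def open_probability(self) -> np.ndarray:
        return self.open_count / self.n_channels


@dataclass
class IdealizedAverage:
    pressure: np.ndarray
    mean_po: np.ndarray
    n_channels: int
    n_patches: int
    p50: float
    slope_k: float


def bin_current_by_pressure(
    trace: PatchTrace, include_positive: bool = False
) -> PressureResponse:
    """Mean current per pressure level, ordered by decreasing pressure.

    Positive (prepulse) pressures are excluded by default so the bins
    span the ramp itself.
    """
    pressure = np.asarray(trace.pressure, dtype=float)
    current = np.asarray(trace.current, dtype=float)
    if pressure.size == 0:
        raise ValueError("trace has no pressure channel")
    mask = np.ones(pressure.size, dtype=bool) if include_positive else pressure <= 0
    if not mask.any():
        raise ValueError("no non-positive pressure samples in trace")
    levels = np.unique(pressure[mask])[::-1]  # decreasing pressure
    means = np.array([current[mask & (pressure == lev)].mean() for lev in levels])
    return PressureResponse(pressure=levels, current=means)


def _line_plus_boltzmann(P, a, b, i_max, p50, k):
    with np.errstate(over="ignore"):
        return a + b * P + i_max / (1.0 + np.exp((p50 - np.asarray(P, dtype=float)) / k))


def leak_subtract(
    resp: PressureResponse,
    reference_current: float = DEFAULT_REFERENCE_CURRENT,
    min_pre_bins: int = 5,
    refine: bool = True,
) -> PressureResponse:
    """Fit and subtract the linear pre-opening background.

    The first opening is the first bin whose residual from a line
    through the initial bins exceeds half the single-channel reference
    current for two consecutive bins; a provisional background line is
    then refitted to all bins up to two bins before that candidate.  If
    an opening is detected within the first three bins a warning is
    issued and the minimal available span is used.

    Because the activation curve has an exponential foot, bins just
    before the detected opening still carry a fraction of a channel of
    mean current, which biases a line fitted only to pre-opening bins.
    When ``refine`` is true (default) and an opening was detected, the
    line is therefore re-estimated jointly with a Boltzmann component
    (``I = a + b*P + i_max * sigmoid(P)``) over all bins, and only the
    linear part is subtracted.  The corrected response is ~0 before the
    first opening either way.
    """
    P, I = resp.pressure, resp.current
    if P.size < min_pre_bins:
        raise ValueError(f"need at least {min_pre_bins} bins for leak fitting")
    threshold = 0.5 * reference_current

    seed_n = min(min_pre_bins, P.size)
    coef = np.polyfit(P[:seed_n], I[:seed_n], 1)
    resid = I - np.polyval(coef, P)
    first_opening = None
    for i in range(P.size - 1):
        if resid[i] > threshold and resid[i + 1] > threshold:
            first_opening = i
            break

    if first_opening is None:
        span = P.size
    else:
        span = first_opening - 2
        if span < 3:
            warnings.warn(
                "channel opening detected within the first 3 pressure bins; "
                "leak fit uses a minimal span",
                stacklevel=2,
            )
            span = max(2, min(3, first_opening if first_opening > 0 else 2))
        if span < min_pre_bins:
            logger.info("only %d pre-opening bins available for leak fit", span)
    coef = np.polyfit(P[:span], I[:span], 1)
    slope, offset = float(coef[0]), float(coef[1])

    if refine and first_opening is not None:
        prov = I - (offset + slope * P)
        i_max0 = max(float(prov[-1]), reference_current)
        half = i_max0 / 2.0
        cross = np.nonzero(prov >= half)[0]
        p50_0 = float(P[cross[0]]) if cross.size else float(P[first_opening])
        try:
            popt, _ = curve_fit(
                _line_plus_boltzmann,
                P,
                I,
                p0=(offset, slope, i_max0, p50_0, -4.0),
                maxfev=20000,
            )
            offset, slope = float(popt[0]), float(popt[1])
        except RuntimeError:
            logger.info("joint leak refinement failed; keeping pre-opening line")

    leak = LeakFit(
        slope=slope,
        offset=offset,
        first_opening_bin=first_opening,
        n_fit_bins=int(span),
    )
    return PressureResponse(
        pressure=P.copy(), current=I - leak(P), fit=resp.fit, leak=leak
    )


def fit_boltzmann(resp: PressureResponse) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a (leak-subtracted)
    current-pressure relationship.

    Fits are flagged non-saturated when the model has not reached 95%
    of its plateau at the largest applied suction.
    """
    P, I = resp.pressure, resp.current
    if P.size < 5:
        raise ValueError("need at least 5 bins to fit a Boltzmann")
    i_min0 = float(np.mean(I[: min(5, I.size)]))
    i_max0 = float(I[-1] - I[0])
    if abs(i_max0) < 1e-12:
        i_max0 = 1e-6
    half = i_min0 + i_max0 / 2.0
    cross = np.nonzero((I - half) * np.sign(i_max0) >= 0)[0]
    p50_0 = float(P[cross[0]]) if cross.size else float(P[P.size // 2])
    p0 = (i_min0, i_max0, p50_0, -4.0)
    popt, _ = curve_fit(boltzmann, P, I, p0=p0, maxfev=20000)
    i_min, i_max, p50, k = (float(v) for v in popt)
    pred = boltzmann(P, *popt)
    residual_norm = float(np.sqrt(np.mean((I - pred) ** 2)))
    plateau_frac = (pred[-1] - i_min) / i_max if i_max != 0 else 0.0
    saturated = bool(plateau_frac >= 0.95)
    if not saturated:
        logger.info("Boltzmann fit flagged non-saturated (plateau %.2f)", plateau_frac)
    return BoltzmannFit(i_min, i_max, p50, k, residual_norm, saturated)


def count_channels(
    i_max: float,
    reference_current: float,
    negative_tolerance: float | None = None,
) -> int:
    """Channel count ``n = round(i_max / reference_current)``, floored at 0.

    Raises ``ValueError`` when ``i_max`` is negative beyond the noise
    tolerance (half the reference current unless given).
    """
    if reference_current <= 0:
        raise ValueError("reference_current must be positive")
    if negative_tolerance is None:
        negative_tolerance = 0.5 * reference_current
    if i_max < -negative_tolerance:
        raise ValueError(f"i_max={i_max:.3g} pA is negative beyond tolerance")
    return int(max(0, _round_half_away(i_max / reference_current)))


def reference_current_from_single_channel_patches(
    fits: list[BoltzmannFit], is_single: list[bool]
) -> float:
    """Mean ``i_max`` over the patches flagged as single-channel."""
    if len(fits) != len(is_single):
        raise ValueError("fits and is_single must have equal length")
    vals = [f.i_max for f, s in zip(fits, is_single) if s]
    if not vals:
        raise ValueError(
            "no single-channel patches; supply an external reference current"
        )
    return float(np.mean(vals))


def idealize_trace(
    trace: PatchTrace,
    reference_current: float,
    n_channels: int,
    leak: LeakFit,
) -> IdealizedTrace:
    """Convert a ramp trace to per-bin mean open-channel counts.

    The leak line is evaluated at each sample's pressure and
    subtracted; each corrected sample is rounded to an integer number
    of open channels (clamped to [0, n]); the open counts are then
    averaged within each pressure bin, so a bin's open probability is
    the fraction of time (x channels) spent open at that pressure.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1 for idealisation")
    pressure = np.asarray(trace.pressure, dtype=float)
    mask = pressure <= 0
    corrected = trace.current[mask] - leak(pressure[mask])
    open_samples = np.clip(
        _round_half_away(corrected / reference_current), 0, n_channels
    )
    levels = np.unique(pressure[mask])[::-1]
    sub = pressure[mask]
    open_count = np.array([open_samples[sub == lev].mean() for lev in levels])
    return IdealizedTrace(pressure=levels, open_count=open_count, n_channels=n_channels)


def idealize_and_average(
    traces: list[PatchTrace],
    reference_current: float,
    max_channels: int = 5,
) -> dict[int, IdealizedAverage]:
    """Group idealised ramps by channel number and average them.

    Each trace is binned, leak-subtracted and Boltzmann-fitted to infer
    its channel count; traces with 1..``max_channels`` channels are
    idealised sample-by-sample and the per-pressure mean open
    probability across patches of equal channel number is fitted with
    ``Po(P) = 1/(1 + exp((p50 - P)/k))``.  Patches inferred to hold no
    channels, or more than ``max_channels``, are excluded and logged.
    """
    groups: dict[int, list[IdealizedTrace]] = {}
    for idx, trace in enumerate(traces):
        resp = bin_current_by_pressure(trace)
        corrected = leak_subtract(resp, reference_current)
        fit = fit_boltzmann(corrected)
        n = count_channels(fit.i_max, reference_current)
        if n == 0:
            logger.info("trace %d excluded from idealisation: n inferred as 0", idx)
            continue
        if n > max_channels:
            logger.info("trace %d excluded from idealisation: n=%d > %d", idx, n, max_channels)
            continue
        ideal = idealize_trace(trace, reference_current, n, corrected.leak)
        groups.setdefault(n, []).append(ideal)

    out: dict[int, IdealizedAverage] = {}
    for n, ideals in sorted(groups.items()):
        pressure = ideals[0].pressure
        po = np.mean([it.open_probability for it in ideals], axis=0)
        popt, _ = curve_fit(
            sigmoid_po, pressure, po, p0=(-25.0, -4.0), maxfev=20000
        )
        out[n] = IdealizedAverage(
            pressure=pressure,
            mean_po=po,
            n_channels=n,
            n_patches=len(ideals),
            p50=float(popt[0]),
            slope_k=float(popt[1]),
        )
    return out
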