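"""Pressure-step analysis: peak/steady-state measurement, per-patch
pressure-response fits, and normalized mean response curves binned by
channel number.

The small leak background of step recordings (a few pA) is not
subtracted by default; it is minor relative to the currents of
interest and is absorbed by the fit's baseline term.  A flag enables
baseline subtraction from the pre-step window for small-current
patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .ramp_analysis import BoltzmannFit, _round_half_away, boltzmann
from .synthetic_data import PatchTrace

__all__ = [
    "StepMeasurement",
    "StepResponseFit",
    "PatchResponse",
    "BinnedResponse",
    "analyze_step_current",
    "pressure_response_from_steps",
    "normalized_mean_response",
    "default_bin_edges",
]

logger = logging.getLogger(__name__)


@dataclass
class StepMeasurement:
    """Peak (0.5 ms rolling average, signed per voltage polarity),
    steady state (mean of the last 10 ms) and their ratio in percent."""

    peak_current: float
    steady_state: float
    inactivation_ratio: float
    test_pressure: float


@dataclass
class StepResponseFit:
    fit: BoltzmannFit
    n_channels: int | None
    saturated: bool
    flagged_zero: bool = False


@dataclass
class PatchResponse:
    """Per-patch peak currents over the step family."""

    n_channels: int
    pressures: np.ndarray
    peaks: np.ndarray


@dataclass
class BinnedResponse:
    bin_label: str
    pressures: np.ndarray
    mean_normalized: np.ndarray
    n_patches: int
    p50: float
    slope_k: float
    amplitude: float


def _step_window(trace: PatchTrace, step_window) -> tuple[int, int]:
    if step_window is not None:
        t0, t1 = step_window
    else:
        segments = trace.metadata.get("segments")
        if not segments:
            raise ValueError("no step_window given and trace metadata has no segments")
        t1 = sum(s["duration"] for s in segments)
        t0 = t1 - segments[-1]["duration"]
    i0 = int(np.searchsorted(trace.time, t0, side="left"))
    i1 = int(np.searchsorted(trace.time, t1, side="left"))
    return i0, i1


def analyze_step_current(
    trace: PatchTrace,
    step_window: tuple[float, float] | None = None,
    rolling_ms: float = 0.5,
    steady_ms: float = 10.0,
    subtract_baseline: bool = False,
    baseline_ms: float = 50.0,
) -> StepMeasurement:
    """Measure peak and steady-state current during the test step.

    ``step_window`` is (start_ms, end_ms); by default the last protocol
    segment recorded in the trace metadata.  The peak is taken from a
    centred rolling average of ``rolling_ms`` width; "peak" means the
    maximum for depolarised (positive-voltage) steps and the minimum
    for hyperpolarised ones.  ``subtract_baseline`` removes the mean
    current of the ``baseline_ms`` immediately preceding the step.
    """
    i0, i1 = _step_window(trace, step_window)
    fs = trace.sample_rate  # kHz
    if (i1 - i0) / fs < steady_ms:
        raise ValueError(f"step shorter than {steady_ms} ms")
    current = np.asarray(trace.current, dtype=float)
    baseline = 0.0
    if subtract_baseline:
        nb = max(1, int(round(baseline_ms * fs)))
        baseline = float(current[max(0, i0 - nb) : i0].mean()) if i0 > 0 else 0.0
    window = max(1, int(round(rolling_ms * fs)))
    smoothed = uniform_filter1d(current, size=window, mode="nearest")[i0:i1] - baseline
    positive = trace.voltage[i0] >= 0
    peak = float(smoothed.max() if positive else smoothed.min())
    n_steady = int(round(steady_ms * fs))
    steady = float(current[i1 - n_steady : i1].mean()) - baseline
    ratio = float(steady / peak * 100.0) if peak != 0 else np.nan
    return StepMeasurement(
        peak_current=peak,
        steady_state=steady,
        inactivation_ratio=ratio,
        test_pressure=float(trace.pressure[i0]),
    )


def pressure_response_from_steps(
    sweeps: list[StepMeasurement],
    single_channel_current: float | None = None,
    zero_current_threshold: float = 1.0,
) -> StepResponseFit:
    """Boltzmann fit of peak current against test pressure.

    Requires >= 6 sweeps.  When all peaks are below
    ``zero_current_threshold`` (pA) the family is flagged as empty and
    n = 0 is returned without fitting.  The channel count is
    ``round(i_max / single_channel_current)`` when a per-patch
    single-channel current is supplied.
    """
    if len(sweeps) < 6:
        raise ValueError("need at least 6 sweeps to fit a pressure response")
    order = np.argsort([-m.test_pressure for m in sweeps])
    P = np.array([sweeps[i].test_pressure for i in order])
    I = np.array([sweeps[i].peak_current for i in order])

    if np.max(np.abs(I)) < zero_current_threshold:
        fit = BoltzmannFit(0.0, 0.0, np.nan, np.nan, float(np.std(I)), saturated=False)
        return StepResponseFit(fit=fit, n_channels=0, saturated=False, flagged_zero=True)

    i_min0 = float(I[0])
    i_max0 = float(I[-1] - I[0])
    half = i_min0 + i_max0 / 2.0
    cross = np.nonzero((I - half) * np.sign(i_max0) >= 0)[0]
    p50_0 = float(P[cross[0]]) if cross.size else float(P[P.size // 2])
    popt, _ = curve_fit(
        boltzmann, P, I, p0=(i_min0, i_max0, p50_0, -6.0), maxfev=20000
    )
    i_min, i_max, p50, k = (float(v) for v in popt)
    pred = boltzmann(P, *popt)
    residual = float(np.sqrt(np.mean((I - pred) ** 2)))
    plateau_frac = (pred[-1] - i_min) / i_max if i_max != 0 else 0.0
    saturated = bool(plateau_frac >= 0.95)
    if not saturated:
        logger.info("step family flagged non-saturating (plateau %.2f)", plateau_frac)
    fit = BoltzmannFit(i_min, i_max, p50, k, residual, saturated)
    n = None
    if single_channel_current is not None:
        n = int(max(0, _round_half_away(i_max / single_channel_current)))
    return StepResponseFit(fit=fit, n_channels=n, saturated=saturated)


def default_bin_edges(max_channels: int = 200, width: int = 10) -> list[tuple[int, float]]:
    """Channel-number bins: (1-10), (11-20), ..., (>max_channels)."""
    edges = [(lo, lo + width - 1) for lo in range(1, max_channels + 1, width)]
    edges.append((max_channels + 1, np.inf))
    return edges


def _amp_sigmoid(P, amplitude, p50, k):
    with np.errstate(over="ignore"):
        return amplitude / (1.0 + np.exp((p50 - np.asarray(P, dtype=float)) / k))


def normalized_mean_response(
    patches: list[PatchResponse],
    bin_edges: list[tuple[int, float]] | None = None,
) -> dict[str, BinnedResponse]:
    """Per-bin mean of self-normalized pressure-response curves.

    Each patch's peaks are divided by the patch's own maximum-magnitude
    peak, patches are grouped by channel number into ``bin_edges``
    (inclusive ranges), normalized peaks are averaged per pressure and
    each bin average is fitted with an amplitude-scaled sigmoid.
    Empty bins are omitted with a log entry.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    groups: dict[str, list[PatchResponse]] = {}
    for patch in patches:
        for lo, hi in bin_edges:
            if lo <= patch.n_channels <= hi:
                label = f"{lo}-{hi}" if np.isfinite(hi) else f">{lo - 1}"
                groups.setdefault(label, []).append(patch)
                break

    for lo, hi in bin_edges:
        label = f"{lo}-{hi}" if np.isfinite(hi) else f">{lo - 1}"
        if label not in groups:
            logger.info("channel-number bin %s is empty; omitted", label)

    out: dict[str, BinnedResponse] = {}
    for label, members in groups.items():
        by_pressure: dict[float, list[float]] = {}
        for patch in members:
            scale = np.max(np.abs(patch.peaks))
            if scale == 0:
                logger.info("patch with all-zero peaks skipped in bin %s", label)
                continue
            norm = patch.peaks / scale
            for p, v in zip(patch.pressures, norm):
                by_pressure.setdefault(float(p), []).append(float(v))
        if not by_pressure:
            continue
        pressures = np.array(sorted(by_pressure, reverse=True))
        mean_norm = np.array([np.mean(by_pressure[p]) for p in pressures])
        half = mean_norm[-1] / 2.0
        cross = np.nonzero(mean_norm >= half)[0]
        p50_0 = float(pressures[cross[0]]) if cross.size else float(pressures[-1]) / 2
        popt, _ = curve_fit(
            _amp_sigmoid, pressures, mean_norm, p0=(1.0, p50_0, -6.0), maxfev=20000
        )
        out[label] = BinnedResponse(
            bin_label=label,
            pressures=pressures,
            mean_normalized=mean_norm,
            n_patches=len(members),
            p50=float(popt[1]),
            slope_k=float(popt[2]),
            amplitude=float(popt[0]),
        )
    return out
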