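"""Ground-truth synthetic patch-clamp traces and membrane-outline images.

Traces are generated from a stochastic gating model: each channel is an
independent continuous-time two-state Markov chain whose equilibrium
open probability follows a Boltzmann in applied pressure,

    Po_eq(P) = 1 / (1 + exp((p50 - P) / k)),

with opening rate ``alpha(P) = Po_eq(P) * total_rate`` and closing rate
``beta(P) = (1 - Po_eq(P)) * total_rate``.  An optional third,
inactivated state is entered from the open state and recovers only at
non-negative pressures.  The measured current is

    I(t) = leak_offset + leak_slope * P(t) + sign(V) * i * N_open(t) + noise,

so that openings at depolarised (positive) holding potentials are
positive-going.  Chains are simulated with exact exponential event
times and read out at the sample grid, which avoids time-step bias.

Pressures are in mmHg (suction negative), durations in ms, voltages in
mV, currents in pA, sample rates in kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ProtocolSegment",
    "PressureProtocol",
    "GatingParams",
    "TraceNoise",
    "PatchTrace",
    "build_ramp_protocol",
    "build_step_protocol",
    "simulate_patch_trace",
    "simulate_step_peaks",
    "simulate_membrane_profile",
]


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-pressure, constant-voltage epoch."""

    pressure: float  # mmHg
    duration: float  # ms
    voltage: float  # mV

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class PressureProtocol:
    """Ordered pressure/voltage segments sampled at ``sample_rate`` kHz."""

    segments: tuple[ProtocolSegment, ...]
    sample_rate: float = 5.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def segment_samples(self) -> np.ndarray:
        """Number of samples in each segment."""
        return np.array(
            [int(round(s.duration * self.sample_rate)) for s in self.segments],
            dtype=np.int64,
        )

    @property
    def n_samples(self) -> int:
        return int(self.segment_samples().sum())

    @property
    def total_duration(self) -> float:
        """Total duration in ms."""
        return float(sum(s.duration for s in self.segments))

    def waveforms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (time_ms, pressure, voltage) arrays on the sample grid."""
        counts = self.segment_samples()
        n = int(counts.sum())
        time = np.arange(n) / self.sample_rate
        pressure = np.repeat([s.pressure for s in self.segments], counts)
        voltage = np.repeat([s.voltage for s in self.segments], counts)
        return time, pressure, voltage


@dataclass(frozen=True)
class GatingParams:
    """Stochastic gating model parameters.

    ``p50``/``slope_k`` (both mmHg, both negative for suction-activated
    channels) define the equilibrium Boltzmann.  ``total_rate`` is
    ``alpha + beta`` in 1/s; the equilibrium is independent of it, so it
    is a free synthetic parameter (no kinetic rates are prescribed by
    the equilibrium fits it emulates).  ``inactivation_rate`` (1/s)
    enables an open -> inactivated transition; recovery happens at rate
    ``recovery_rate`` only while the pressure is >= 0.
    ``resting_po``, when set, replaces the Boltzmann open probability at
    non-negative (non-suction) pressures, emulating the relief of
    resting membrane tension by a positive prepulse.
    """

    p50: float = -25.0
    slope_k: float = -4.0
    total_rate: float = 1000.0
    inactivation_rate: float = 0.0
    recovery_rate: float = 10.0
    single_channel_current: float = 0.98
    n_channels: int = 1
    resting_po: float | None = None

    def __post_init__(self) -> None:
        if self.total_rate <= 0:
            raise ValueError("total_rate must be positive")
        if self.inactivation_rate < 0 or self.recovery_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.single_channel_current <= 0:
            raise ValueError("single_channel_current must be positive")
        if self.n_channels < 0:
            raise ValueError("n_channels must be non-negative")
        if self.resting_po is not None and not (0.0 <= self.resting_po <= 1.0):
            raise ValueError("resting_po must be in [0, 1]")

    def po_eq(self, pressure) -> np.ndarray | float:
        """Equilibrium open probability at the given pressure(s)."""
        p = np.asarray(pressure, dtype=float)
        po = 1.0 / (1.0 + np.exp((self.p50 - p) / self.slope_k))
        if self.resting_po is not None:
            po = np.where(p >= 0, self.resting_po, po)
        return float(po) if po.ndim == 0 else po


@dataclass(frozen=True)
class TraceNoise:
    """Linear leak/capacitance background and Gaussian sampling noise."""

    leak_slope: float = 0.0  # pA per mmHg
    leak_offset: float = 0.0  # pA
    noise_sd: float = 0.0  # pA
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PatchTrace:
    """One recorded (or simulated) cell-attached sweep."""

    time: np.ndarray  # ms
    pressure: np.ndarray  # mmHg
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.pressure) == len(self.voltage) == len(self.current) == n):
            raise ValueError("trace channels must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        """Sample rate in kHz inferred from the time base."""
        if "sample_rate" in self.metadata:
            return float(self.metadata["sample_rate"])
        return 1.0 / float(np.median(np.diff(self.time)))


def build_ramp_protocol(
    start: float = 0.0,
    stop: float = -60.0,
    increment: float = -1.0,
    dwell: float = 50.0,
    step_pressure: float = -60.0,
    step_duration: float = 200.0,
    voltage: float = 60.0,
    sample_rate: float = 5.0,
    prepulse: bool = False,
    prepulse_pressure: float = 5.0,
    prepulse_duration: float = 2000.0,
) -> PressureProtocol:
    """Staircase ramp (default 0 to -60 mmHg in -1 mmHg, 50 ms dwells)
    followed by a saturating step, optionally preceded by a positive
    prepulse.  The default ramp portion lasts 61 * 50 ms = 3.05 s.
    """
    if increment >= 0 and stop < start:
        raise ValueError("increment must be negative for a downward ramp")
    levels = np.arange(start, stop + increment / 2, increment)
    segments = []
    if prepulse:
        segments.append(ProtocolSegment(prepulse_pressure, prepulse_duration, voltage))
    segments.extend(ProtocolSegment(float(p), dwell, voltage) for p in levels)
    segments.append(ProtocolSegment(step_pressure, step_duration, voltage))
    return PressureProtocol(tuple(segments), sample_rate)


def build_step_protocol(
    start: float = 0.0,
    stop: float = -80.0,
    increment: float = -5.0,
    test_duration: float = 250.0,
    test_voltage: float = 60.0,
    prepulse_pressure: float = 5.0,
    sample_rate: float = 5.0,
) -> list[PressureProtocol]:
    """Family of step sweeps (default 17 sweeps, 0 to -80 mmHg in -5).

    Every sweep starts with a 5 s prepulse at ``prepulse_pressure``
    split into 4 s at -80 mV and 1 s at the test voltage, then the test
    step.
    """
    pressures = np.arange(start, stop + increment / 2, increment)
    sweeps = []
    for p in pressures:
        segments = (
            ProtocolSegment(prepulse_pressure, 4000.0, -80.0),
            ProtocolSegment(prepulse_pressure, 1000.0, test_voltage),
            ProtocolSegment(float(p), test_duration, test_voltage),
        )
        sweeps.append(PressureProtocol(segments, sample_rate))
    return sweeps


def _two_state_segment(
    open0: np.ndarray,
    alpha: float,
    beta: float,
    duration_s: float,
    sample_times: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-event simulation of independent two-state chains.

    ``open0`` is the boolean open/closed state of each channel at the
    segment start.  Returns the number of open channels at each of the
    (segment-relative, seconds) ``sample_times`` and the final states.
    Dwell times are exact exponentials; the read-out at sample times is
    therefore unbiased for any sample rate.
    """
    n = open0.size
    n_open0 = int(open0.sum())
    if n == 0 or (alpha <= 0 and beta <= 0):
        return np.full(sample_times.size, n_open0, dtype=np.int64), open0.copy()
    switch_rate = 2.0 * alpha * beta / (alpha + beta)
    m = duration_s * switch_rate
    k = int(m + 6.0 * np.sqrt(m + 1.0) + 16.0)
    while True:
        raw = rng.exponential(size=(n, k))
        parity = (np.arange(k) % 2).astype(bool)
        state_during = open0[:, None] ^ parity[None, :]
        rates = np.where(state_during, beta, alpha)
        with np.errstate(divide="ignore"):
            dwell = raw / rates
        times = np.cumsum(dwell, axis=1)
        if np.all(times[:, -1] >= duration_s):
            break
        k *= 2
    valid = times < duration_s
    event_times = times[valid]
    deltas = np.where(state_during[valid], -1, 1)
    order = np.argsort(event_times, kind="stable")
    event_times = event_times[order]
    cum = np.concatenate(([0], np.cumsum(deltas[order])))
    idx = np.searchsorted(event_times, sample_times, side="right")
    n_open = n_open0 + cum[idx]
    n_switch = valid.sum(axis=1)
    final = open0 ^ (n_switch % 2 == 1)
    return n_open.astype(np.int64), final


def _three_state_segment(
    states: np.ndarray,
    alpha: float,
    beta: float,
    iota: float,
    rho: float,
    duration_s: float,
    sample_times: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel event loop for chains with inactivation.

    States: 0 closed, 1 open, 2 inactivated.  Slower than the two-state
    path; used only when ``inactivation_rate > 0``.
    """
    event_times: list[float] = []
    event_deltas: list[int] = []
    final = states.copy()
    for j in range(states.size):
        s = int(states[j])
        t = 0.0
        while True:
            if s == 0:
                rate = alpha
            elif s == 1:
                rate = beta + iota
            else:
                rate = rho
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= duration_s:
                break
            if s == 0:
                s = 1
                event_times.append(t)
                event_deltas.append(1)
            elif s == 1:
                s = 2 if rng.random() < iota / (beta + iota) else 0
                event_times.append(t)
                event_deltas.append(-1)
            else:
                s = 0
        final[j] = s
    n_open0 = int(np.sum(states == 1))
    if not event_times:
        return np.full(sample_times.size, n_open0, dtype=np.int64), final
    order = np.argsort(event_times, kind="stable")
    ets = np.asarray(event_times)[order]
    cum = np.concatenate(([0], np.cumsum(np.asarray(event_deltas)[order])))
    idx = np.searchsorted(ets, sample_times, side="right")
    return (n_open0 + cum[idx]).astype(np.int64), final


def simulate_patch_trace(
    protocol: PressureProtocol,
    gating: GatingParams,
    noise: TraceNoise,
    seed: int | None = None,
) -> PatchTrace:
    """Simulate one sweep of the gating model under ``protocol``.

    Channels start in equilibrium at the first segment's pressure.
    Output is bit-reproducible given (protocol, gating, noise, seed);
    ``seed`` overrides ``noise.seed`` when given.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    counts = protocol.segment_samples()
    n = gating.n_channels
    use_three_state = gating.inactivation_rate > 0

    po0 = float(gating.po_eq(protocol.segments[0].pressure))
    if use_three_state:
        chan = (rng.random(n) < po0).astype(np.int8)  # 0 closed, 1 open
    else:
        chan = rng.random(n) < po0

    open_chunks = []
    current_chunks = []
    for seg, n_samp in zip(protocol.segments, counts):
        dur_s = seg.duration / 1000.0
        rel_t = np.arange(n_samp) / (protocol.sample_rate * 1000.0)
        po = float(gating.po_eq(seg.pressure))
        alpha = po * gating.total_rate
        beta = (1.0 - po) * gating.total_rate
        if n == 0:
            n_open = np.zeros(n_samp, dtype=np.int64)
        elif use_three_state:
            rho = gating.recovery_rate if seg.pressure >= 0 else 0.0
            n_open, chan = _three_state_segment(
                chan, alpha, beta, gating.inactivation_rate, rho, dur_s, rel_t, rng
            )
        else:
            n_open, chan = _two_state_segment(chan, alpha, beta, dur_s, rel_t, rng)
        open_chunks.append(n_open)
        sign = 1.0 if seg.voltage >= 0 else -1.0
        seg_current = (
            noise.leak_offset
            + noise.leak_slope * seg.pressure
            + sign * gating.single_channel_current * n_open
        )
        if noise.noise_sd > 0:
            seg_current = seg_current + rng.normal(0.0, noise.noise_sd, n_samp)
        else:
            seg_current = seg_current.astype(float)
        current_chunks.append(seg_current)

    time, pressure, voltage = protocol.waveforms()
    metadata = {
        "sample_rate": protocol.sample_rate,
        "segments": [
            {"pressure": s.pressure, "duration": s.duration, "voltage": s.voltage}
            for s in protocol.segments
        ],
        "gating": {
            "p50": gating.p50,
            "slope_k": gating.slope_k,
            "total_rate": gating.total_rate,
            "inactivation_rate": gating.inactivation_rate,
            "recovery_rate": gating.recovery_rate,
            "single_channel_current": gating.single_channel_current,
            "n_channels": gating.n_channels,
            "resting_po": gating.resting_po,
        },
        "noise": {
            "leak_slope": noise.leak_slope,
            "leak_offset": noise.leak_offset,
            "noise_sd": noise.noise_sd,
        },
        "seed": noise.seed if seed is None else seed,
        "n_open": np.concatenate(open_chunks),
    }
    return PatchTrace(
        time=time,
        pressure=pressure,
        voltage=voltage,
        current=np.concatenate(current_chunks),
        metadata=metadata,
    )


def simulate_step_peaks(
    test_pressures: np.ndarray,
    gating: GatingParams,
    noise: TraceNoise,
    seed: int | None = None,
    peak_noise_sd: float = 0.3,
) -> np.ndarray:
    """Equilibrium-level generator of step-family peak currents.

    For each test pressure the number of channels recruited at the peak
    is one Binomial(n, Po_eq(P)) draw — the gating state of the patch
    when the ensemble transient tops out — so per-patch stochastic
    variability scales correctly with channel number while the
    generating truth (p50, k) is shared by every patch.  The measured
    peak is that gating draw plus the linear leak background evaluated
    at the test pressure and Gaussian measurement noise of
    ``peak_noise_sd`` (pA).

    This generator is the right probe for pressure-response fitting:
    running a maximum-statistic over a long *stationary* stochastic
    trace (as :func:`simulate_patch_trace` output would require)
    overestimates the foot of the activation curve by an extreme-value
    bias that real, inactivation-limited recordings do not show.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    P = np.asarray(test_pressures, dtype=float)
    po = np.asarray(gating.po_eq(P))
    n_open = rng.binomial(gating.n_channels, po)
    peaks = (
        noise.leak_offset
        + noise.leak_slope * P
        + gating.single_channel_current * n_open
    )
    if peak_noise_sd > 0:
        peaks = peaks + rng.normal(0.0, peak_noise_sd, P.shape)
    return peaks


def simulate_membrane_profile(
    radius: float,
    pixel_scale: float = 61.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
    arc_halfangle_deg: float = 60.0,
    band_halfwidth_px: float = 2.0,
    background: float = 1000.0,
    depth: float = 600.0,
    margin_px: int = 12,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Synthetic membrane-dome outline image for circle-fitting tests.

    A dark circular-arc band (the membrane, spanning
    ``±arc_halfangle_deg`` around the bulge axis) on a brighter
    background, plus Gaussian pixel noise.  ``radius`` is in µm,
    ``pixel_scale`` in px/µm.  Returns ``(image, metadata)`` where the
    metadata records the ground-truth centre/radius in pixels.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    r_px = radius * pixel_scale
    theta = np.deg2rad(arc_halfangle_deg)
    half_h = r_px * np.sin(theta)
    cx = margin_px - r_px * np.cos(theta)
    if shape is None:
        height = int(np.ceil(2 * half_h)) + 2 * margin_px
        width = int(np.ceil(cx + r_px)) + margin_px
        shape = (height, width)
    height, width = shape
    cy = height / 2.0
    if cx + r_px + band_halfwidth_px > width or 2 * half_h + 2 > height:
        raise ValueError("arc does not fit in the requested image shape")
    yy, xx = np.mgrid[0:height, 0:width]
    dist = np.hypot(xx - cx, yy - cy)
    ang_ok = np.abs(np.arctan2(yy - cy, xx - cx)) <= theta
    image = background - np.where(
        ang_ok, depth * np.exp(-(((dist - r_px) / band_halfwidth_px) ** 2)), 0.0
    )
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)
    metadata = {
        "radius_um": radius,
        "radius_px": r_px,
        "center_px": (cx, cy),
        "pixel_scale": pixel_scale,
        "arc_halfangle_deg": arc_halfangle_deg,
        "band_halfwidth_px": band_halfwidth_px,
        "background": background,
        "depth": depth,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return image, metadata
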