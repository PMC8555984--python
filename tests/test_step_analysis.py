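import numpy as np
import pytest
from scipy.linalg import expm

from mechpatch.step_analysis import (
    PatchResponse,
    StepMeasurement,
    analyze_step_current,
    default_bin_edges,
    normalized_mean_response,
    pressure_response_from_steps,
)
from mechpatch.ramp_analysis import boltzmann
from mechpatch.synthetic_data import (
    GatingParams,
    PatchTrace,
    PressureProtocol,
    ProtocolSegment,
    TraceNoise,
    simulate_patch_trace,
    simulate_step_peaks,
)

FS = 5.0  # kHz


def make_step_trace(current, pre_ms=100.0, step_ms=250.0, voltage=60.0, pressure=-40.0):
    n_pre = int(pre_ms * FS)
    n_step = int(step_ms * FS)
    total = n_pre + n_step
    time = np.arange(total) / FS
    pressures = np.concatenate([np.full(n_pre, 5.0), np.full(n_step, pressure)])
    voltages = np.full(total, voltage)
    cur = np.concatenate([np.zeros(n_pre), current])
    meta = {
        "sample_rate": FS,
        "segments": [
            {"pressure": 5.0, "duration": pre_ms, "voltage": voltage},
            {"pressure": pressure, "duration": step_ms, "voltage": voltage},
        ],
    }
    return PatchTrace(time=time, pressure=pressures, voltage=voltages, current=cur, metadata=meta)


class TestAnalyzeStepCurrent:
    def test_constant_step(self):
        trace = make_step_trace(np.full(int(250 * FS), 10.0))
        m = analyze_step_current(trace)
        assert m.peak_current == pytest.approx(10.0)
        assert m.steady_state == pytest.approx(10.0)
        assert m.inactivation_ratio == pytest.approx(100.0)
        assert m.test_pressure == -40.0

    def test_exponential_decay(self):
        t = np.arange(int(250 * FS)) / FS
        trace = make_step_trace(5.0 + 5.0 * np.exp(-t / 10.0))
        m = analyze_step_current(trace)
        assert m.peak_current == pytest.approx(10.0, rel=0.01)
        assert m.steady_state == pytest.approx(5.0, rel=0.01)
        assert m.inactivation_ratio == pytest.approx(50.0, rel=0.02)

    def test_negative_voltage_polarity(self):
        t = np.arange(int(250 * FS)) / FS
        trace = make_step_trace(-8.0 * np.exp(-t / 50.0), voltage=-80.0)
        m = analyze_step_current(trace)
        assert m.peak_current == pytest.approx(-8.0, rel=0.02)

    def test_short_step_errors(self):
        trace = make_step_trace(np.full(int(250 * FS), 1.0))
        with pytest.raises(ValueError, match="shorter"):
            analyze_step_current(trace, step_window=(100.0, 105.0))

    def test_baseline_subtraction_flag(self):
        trace = make_step_trace(np.full(int(250 * FS), 10.0))
        trace.current += 2.0  # constant offset everywhere
        m = analyze_step_current(trace, subtract_baseline=True)
        assert m.peak_current == pytest.approx(10.0, abs=1e-6)

    def test_inactivating_ensemble_matches_markov_oracle(self):
        # oracle: matrix-exponential occupancies of the C/O/I chain
        alpha, beta, iota = 400.0, 100.0, 8.0
        n = 400
        po_eq = alpha / (alpha + beta)
        gating = GatingParams(
            p50=-40.0 + 4.0 * np.log(4.0),  # Po_eq(-40) = 0.8
            slope_k=-4.0,
            total_rate=alpha + beta,
            inactivation_rate=iota,
            n_channels=n,
            single_channel_current=1.0,
        )
        assert gating.po_eq(-40.0) == pytest.approx(po_eq)
        proto = PressureProtocol(
            (
                ProtocolSegment(5.0, 100.0, 60.0),
                ProtocolSegment(-40.0, 250.0, 60.0),
            ),
            sample_rate=FS,
        )
        trace = simulate_patch_trace(proto, gating, TraceNoise(noise_sd=0.1, seed=8))
        m = analyze_step_current(trace)

        Q = np.array(
            [
                [-alpha, alpha, 0.0],
                [beta, -(beta + iota), iota],
                [0.0, 0.0, 0.0],
            ]
        )
        p0 = np.array([1.0 - gating.po_eq(5.0), gating.po_eq(5.0), 0.0])
        times = np.linspace(0.0, 0.25, 2501)
        occ_open = np.array([(p0 @ expm(Q * t))[1] for t in times])
        oracle_peak = n * occ_open.max()
        oracle_steady = n * occ_open[times >= 0.24].mean()
        assert m.peak_current == pytest.approx(oracle_peak, rel=0.10)
        assert m.steady_state == pytest.approx(oracle_steady, rel=0.15)
        assert m.inactivation_ratio == pytest.approx(
            100.0 * oracle_steady / oracle_peak, abs=10.0
        )
        assert m.peak_current > m.steady_state


class TestPressureResponseFromSteps:
    @staticmethod
    def noiseless_family(i_min, i_max, p50, k):
        pressures = np.arange(0.0, -80.1, -5.0)
        return [
            StepMeasurement(float(boltzmann(p, i_min, i_max, p50, k)), 0.0, 100.0, p)
            for p in pressures
        ]

    def test_exact_recovery(self):
        sweeps = self.noiseless_family(0.0, 100.0, -21.0, -7.0)
        resp = pressure_response_from_steps(sweeps, single_channel_current=1.0)
        assert resp.fit.i_max == pytest.approx(100.0, rel=1e-6)
        assert resp.fit.p50 == pytest.approx(-21.0, rel=1e-6)
        assert resp.fit.slope_k == pytest.approx(-7.0, rel=1e-6)
        assert resp.n_channels == 100

    def test_all_zero_flagged(self):
        pressures = np.arange(0.0, -80.1, -5.0)
        sweeps = [StepMeasurement(0.0, 0.0, np.nan, p) for p in pressures]
        resp = pressure_response_from_steps(sweeps, single_channel_current=1.0)
        assert resp.flagged_zero
        assert resp.n_channels == 0

    def test_too_few_sweeps(self):
        sweeps = self.noiseless_family(0.0, 10.0, -21.0, -7.0)[:4]
        with pytest.raises(ValueError):
            pressure_response_from_steps(sweeps)

    def test_non_saturating_flagged(self):
        sweeps = self.noiseless_family(0.0, 100.0, -75.0, -10.0)
        resp = pressure_response_from_steps(sweeps)
        assert not resp.saturated

    def test_median_p50_recovery_small_ensembles(self):
        # generator-truth oracle over a 20-patch cohort
        test_P = np.arange(0.0, -80.1, -5.0)
        p50s = []
        for seed in range(20):
            gating = GatingParams(
                p50=-21.5, slope_k=-8.0, n_channels=15, single_channel_current=0.98,
                resting_po=0.005,
            )
            peaks = simulate_step_peaks(
                test_P, gating, TraceNoise(seed=seed), peak_noise_sd=0.3
            )
            sweeps = [StepMeasurement(pk, pk, 100.0, p) for pk, p in zip(peaks, test_P)]
            resp = pressure_response_from_steps(sweeps)
            p50s.append(resp.fit.p50)
        assert np.median(p50s) == pytest.approx(-21.5, abs=1.5)


class TestNormalizedMeanResponse:
    @staticmethod
    def patch(n, scale=1.0, p50=-21.0, k=-7.0):
        pressures = np.arange(0.0, -80.1, -5.0)
        peaks = scale * boltzmann(pressures, 0.0, 1.0, p50, k)
        return PatchResponse(n_channels=n, pressures=pressures, peaks=peaks)

    def test_identical_patches_mean_equals_individual(self):
        patches = [self.patch(5), self.patch(5)]
        out = normalized_mean_response(patches)
        binned = out["1-10"]
        expected = self.patch(5).peaks / self.patch(5).peaks.max()
        np.testing.assert_allclose(binned.mean_normalized, expected)

    def test_normalized_maximum_is_one(self):
        out = normalized_mean_response([self.patch(5, scale=37.0)])
        assert out["1-10"].mean_normalized.max() == pytest.approx(1.0)

    def test_scaling_invariance(self):
        a = normalized_mean_response([self.patch(5, scale=1.0), self.patch(15, scale=2.0)])
        b = normalized_mean_response([self.patch(5, scale=40.0), self.patch(15, scale=0.5)])
        for label in a:
            np.testing.assert_allclose(
                a[label].mean_normalized, b[label].mean_normalized
            )

    def test_identical_truth_across_bins(self, rng):
        # two bins generated from the same gating truth: fitted p50s agree
        test_P = np.arange(0.0, -80.1, -5.0)
        patches = []
        for j in range(12):
            n = 5 if j < 6 else 150
            gating = GatingParams(
                p50=-21.5, slope_k=-8.0, n_channels=n, single_channel_current=0.98,
                resting_po=0.005,
            )
            peaks = simulate_step_peaks(
                test_P, gating, TraceNoise(seed=int(rng.integers(2**31)))
            )
            patches.append(PatchResponse(n_channels=n, pressures=test_P, peaks=peaks))
        out = normalized_mean_response(patches)
        labels = [lab for lab in out]
        assert len(labels) == 2
        p50s = [out[lab].p50 for lab in labels]
        assert abs(p50s[0] - p50s[1]) < 3.0

    def test_empty_bins_omitted(self):
        out = normalized_mean_response([self.patch(5)])
        assert list(out) == ["1-10"]

    def test_default_bin_edges(self):
        edges = default_bin_edges()
        assert edges[0] == (1, 10)
        assert edges[1] == (11, 20)
        assert edges[-1][1] == np.inf
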