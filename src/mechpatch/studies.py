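"""End-to-end study drivers.

``run_spatial_study`` reproduces the spatial-statistics workflow:
clustered channel fields at matched density, virtual-pipette sampling
with current-conversion noise, count histograms and nearest-neighbour
summaries for cluster sizes 1, 1.6 and 5.

``run_recording_study`` generates synthetic patch-clamp cohorts with
known ground truth, pushes them through the full analysis pipeline and
reports parameter-recovery tables plus the null-trend regressions
(fitted p50 and resting open probability against channel number).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
from scipy import stats

from . import ramp_analysis, single_channel, spatial_model, step_analysis, tension_geometry
from .synthetic_data import (
    GatingParams,
    PressureProtocol,
    ProtocolSegment,
    TraceNoise,
    build_ramp_protocol,
    simulate_patch_trace,
    simulate_step_peaks,
    simulate_membrane_profile,
)
from .traceio import config_hash, dump_json

__all__ = [
    "DEFAULT_SPATIAL_CONFIG",
    "DEFAULT_RECORDING_CONFIG",
    "run_spatial_study",
    "run_recording_study",
    "slope_confidence_interval",
]

logger = logging.getLogger(__name__)

DEFAULT_SPATIAL_CONFIG = {
    "arena_side": 50.0,
    "channel_density": 1.75,
    "displacement_sigma": 50.0,
    "nn_cutoff": 100.0,
    "scenarios": {
        "cluster_1": {"cluster_mode": "fixed_one"},
        "cluster_1.6": {"cluster_mode": "poisson", "poisson_mean": 1.0},
        "cluster_5": {"cluster_mode": "poisson", "poisson_mean": 5.0},
    },
    "sampler": {
        "n_circles": 1000,
        "radius_mean": 0.8,
        "radius_sd": 0.15,
        "current_mean": 0.98,
        "current_sd": 0.22,
        "reference_current": 0.98,
    },
}

DEFAULT_RECORDING_CONFIG = {
    "ramp": {
        "n_patches": 100,
        "n_channels_range": [1, 10],
        "p50": -25.0,
        "slope_k": -4.0,
        "total_rate": 1000.0,
        "single_channel_current": 0.98,
        "noise_sd": 0.2,
        "sample_rate": 5.0,
    },
    "idealization": {
        "n_patches": 35,
        "p50": -23.2,
        "slope_k": -3.3,
        "total_rate": 1000.0,
        "single_channel_current": 0.98,
        "noise_sd": 0.2,
        "sample_rate": 5.0,
    },
    "step": {
        "n_patches": 24,
        "n_mean": 89.0,
        "n_sd": 50.0,
        "n_max": 200,
        "p50": -21.5,
        "slope_k": -8.0,
        "total_rate": 200.0,
        "resting_po": 0.005,
        "current_mean": 0.98,
        "current_sd": 0.22,
        "leak_slope": 0.01,
        "noise_sd": 0.3,
        "peak_noise_sd": 0.3,
        "sample_rate": 5.0,
        "n_sweep_repeats": 17,
    },
    "tension": {
        "n_patches": 10,
        "t50": 2.4,
        "slope_k": 0.8,
        "radius_mean": 1.4,
        "radius_sd": 0.15,
        "densities": [10.0, 70.0],
        "current_noise_sd": 2.0,
        "image_noise_sd": 40.0,
    },
}


def slope_confidence_interval(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> dict:
    """OLS slope with a heteroscedasticity-consistent (HC3) t interval.

    Per-patch estimates are far noisier for small channel numbers, so
    homoscedastic standard errors would understate the slope's sampling
    variance; HC3 keeps the interval honest.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a slope CI")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    xtx_inv = np.linalg.inv(design.T @ design)
    leverage = np.einsum("ij,jk,ik->i", design, xtx_inv, design)
    adj = resid / np.clip(1.0 - leverage, 1e-8, None)
    cov = xtx_inv @ (design.T * adj**2) @ design @ xtx_inv
    slope = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, x.size - 2)
    lo, hi = slope - tcrit * se, slope + tcrit * se
    return {
        "slope": slope,
        "stderr": se,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "contains_zero": bool(lo < 0.0 < hi),
        "n": int(x.size),
    }


def run_spatial_study(
    seed: int = 0, out_dir: str | Path | None = None, config: dict | None = None
) -> dict:
    """Simulate and sample clustered fields for all cluster scenarios."""
    cfg = DEFAULT_SPATIAL_CONFIG if config is None else config
    t_start = time.perf_counter()
    results = {}
    for idx, (name, scen) in enumerate(cfg["scenarios"].items()):
        params = spatial_model.ClusterModelParams(
            arena_side=cfg["arena_side"],
            channel_density=cfg["channel_density"],
            cluster_mode=scen.get("cluster_mode", "fixed_one"),
            poisson_mean=scen.get("poisson_mean", 1.0),
            displacement_sigma=cfg["displacement_sigma"],
            seed=seed + idx,
        )
        field = spatial_model.simulate_channel_field(params)
        if field.n_points >= 2:
            nn = spatial_model.nearest_neighbor_stats(field, cutoff=cfg["nn_cutoff"])
            mean_nn, frac_within = nn.mean_nn, nn.fraction_within
        else:
            mean_nn = frac_within = None
        sampler = spatial_model.PatchSamplerParams(seed=seed + 1000 + idx, **cfg["sampler"])
        samples = spatial_model.sample_patches(field, sampler)
        _, reverted = spatial_model.counts_to_currents_to_counts(
            samples.counts, sampler, seed=seed + 2000 + idx
        )
        values, freqs = spatial_model.channel_count_histogram(reverted)
        results[name] = {
            "n_channels": field.n_points,
            "realized_density": field.realized_density,
            "mean_nn_nm": mean_nn,
            "fraction_within_cutoff": frac_within,
            "nn_cutoff_nm": cfg["nn_cutoff"],
            "zero_patch_fraction": float(np.mean(reverted == 0)),
            "mean_channels_per_patch": float(np.mean(reverted)),
            "count_histogram": {int(v): float(f) for v, f in zip(values, freqs)},
        }
        logger.info("spatial scenario %s done", name)
    report = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "scenarios": results,
        "elapsed_s": time.perf_counter() - t_start,
    }
    if out_dir is not None:
        dump_json(report, Path(out_dir) / "spatial_study.json")
    return report


def _run_ramp_stage(cfg: dict, rng: np.random.Generator) -> dict:
    protocol = build_ramp_protocol(sample_rate=cfg["sample_rate"])
    lo, hi = cfg["n_channels_range"]
    true_n, est_n, p50s, fits, singles = [], [], [], [], []
    for _ in range(cfg["n_patches"]):
        n = int(rng.integers(lo, hi + 1))
        gating = GatingParams(
            p50=cfg["p50"],
            slope_k=cfg["slope_k"],
            total_rate=cfg["total_rate"],
            n_channels=n,
            single_channel_current=cfg["single_channel_current"],
        )
        noise = TraceNoise(
            leak_slope=float(rng.uniform(0.02, 0.06)),
            leak_offset=float(rng.uniform(-1.0, 1.0)),
            noise_sd=cfg["noise_sd"],
            seed=int(rng.integers(2**31)),
        )
        trace = simulate_patch_trace(protocol, gating, noise)
        resp = ramp_analysis.leak_subtract(ramp_analysis.bin_current_by_pressure(trace))
        fit = ramp_analysis.fit_boltzmann(resp)
        n_hat = ramp_analysis.count_channels(fit.i_max, cfg["single_channel_current"])
        true_n.append(n)
        est_n.append(n_hat)
        p50s.append(fit.p50)
        fits.append(fit)
        singles.append(n_hat == 1)
    try:
        reference = ramp_analysis.reference_current_from_single_channel_patches(fits, singles)
    except ValueError:
        reference = None
    true_n = np.array(true_n)
    est_n = np.array(est_n)
    return {
        "n_patches": cfg["n_patches"],
        "true_single_channel_current": cfg["single_channel_current"],
        "estimated_reference_current": reference,
        "fraction_n_exact": float(np.mean(true_n == est_n)),
        "median_p50": float(np.median(p50s)),
        "true_p50": cfg["p50"],
        "p50_vs_n": slope_confidence_interval(true_n, np.array(p50s)),
        "true_n": true_n.tolist(),
        "estimated_n": est_n.tolist(),
    }


def _run_idealization_stage(cfg: dict, rng: np.random.Generator) -> dict:
    protocol = build_ramp_protocol(sample_rate=cfg["sample_rate"])
    gating = GatingParams(
        p50=cfg["p50"],
        slope_k=cfg["slope_k"],
        total_rate=cfg["total_rate"],
        n_channels=1,
        single_channel_current=cfg["single_channel_current"],
    )
    traces = []
    for _ in range(cfg["n_patches"]):
        noise = TraceNoise(
            leak_slope=float(rng.uniform(0.02, 0.06)),
            leak_offset=float(rng.uniform(-0.5, 0.5)),
            noise_sd=cfg["noise_sd"],
            seed=int(rng.integers(2**31)),
        )
        traces.append(simulate_patch_trace(protocol, gating, noise))
    averaged = ramp_analysis.idealize_and_average(traces, cfg["single_channel_current"])
    out = {"true_p50": cfg["p50"], "true_slope_k": cfg["slope_k"], "groups": {}}
    for n, avg in averaged.items():
        out["groups"][str(n)] = {
            "n_patches": avg.n_patches,
            "fitted_p50": avg.p50,
            "fitted_slope_k": avg.slope_k,
        }
    return out


def _run_step_stage(cfg: dict, rng: np.random.Generator) -> dict:
    test_pressures = np.arange(0.0, -80.1, -5.0)
    prepulse_proto = PressureProtocol(
        (ProtocolSegment(5.0, 1000.0, 60.0),), cfg["sample_rate"]
    )
    rows = []
    for _ in range(cfg["n_patches"]):
        n = int(np.clip(round(rng.normal(cfg["n_mean"], cfg["n_sd"])), 1, cfg["n_max"]))
        i_true = max(0.3, float(rng.normal(cfg["current_mean"], cfg["current_sd"])))
        gating = GatingParams(
            p50=cfg["p50"],
            slope_k=cfg["slope_k"],
            total_rate=cfg["total_rate"],
            n_channels=n,
            single_channel_current=i_true,
            resting_po=cfg["resting_po"],
        )
        noise = TraceNoise(
            leak_slope=cfg["leak_slope"],
            leak_offset=float(rng.uniform(-1.0, 1.0)),
            noise_sd=cfg["noise_sd"],
            seed=int(rng.integers(2**31)),
        )
        peaks = simulate_step_peaks(
            test_pressures,
            gating,
            noise,
            seed=int(rng.integers(2**31)),
            peak_noise_sd=cfg["peak_noise_sd"],
        )
        # pre-step baseline window (the +5 mmHg prepulse) removes the
        # leak offset, as the subtract-baseline analysis flag would
        baseline = noise.leak_offset + noise.leak_slope * 5.0
        peaks = peaks - baseline
        measurements = [
            step_analysis.StepMeasurement(pk, pk, 100.0, p)
            for pk, p in zip(peaks, test_pressures)
        ]
        prepulse = np.concatenate(
            [
                simulate_patch_trace(
                    prepulse_proto, gating, noise, seed=int(rng.integers(2**31))
                ).current
                for _ in range(cfg["n_sweep_repeats"])
            ]
        )
        filtered = single_channel.lowpass_filter(prepulse, cfg["sample_rate"])
        row = {"n": n, "i_true": i_true}
        try:
            hist = single_channel.freedman_diaconis_histogram(filtered)
            dg = single_channel.fit_double_gaussian(hist)
            i_hat = dg.single_channel_current
            closed_level = dg.level_low
        except single_channel.NoOpeningsError:
            logger.info("no prepulse openings resolved for a patch (n=%d)", n)
            rows.append(row)
            continue
        if not (0.3 <= i_hat <= 3.0):
            logger.info("implausible single-channel estimate %.2f pA; patch excluded", i_hat)
            rows.append(row)
            continue
        resp = step_analysis.pressure_response_from_steps(
            measurements, single_channel_current=i_hat
        )
        n_hat = max(1, int(round(float(np.max(peaks)) / i_hat)))
        po_hat = single_channel.prepulse_open_probability(
            float(np.mean(filtered - closed_level)), i_hat, n_hat
        )
        row.update(
            i_hat=i_hat,
            n_hat=n_hat,
            p50_hat=resp.fit.p50,
            k_hat=resp.fit.slope_k,
            po_hat=po_hat,
        )
        rows.append(row)

    valid = [
        r
        for r in rows
        if "p50_hat" in r and np.isfinite(r["p50_hat"]) and -60.0 < r["p50_hat"] < 0.0
    ]
    ns = np.array([r["n"] for r in valid])
    out = {
        "true_p50": cfg["p50"],
        "true_slope_k": cfg["slope_k"],
        "true_resting_po": cfg["resting_po"],
        "n_patches": cfg["n_patches"],
        "n_valid": len(valid),
        "patches": rows,
    }
    if len(valid) >= 3:
        out["p50_vs_n"] = slope_confidence_interval(
            ns, np.array([r["p50_hat"] for r in valid])
        )
        out["po_vs_n"] = slope_confidence_interval(
            ns, np.array([r["po_hat"] for r in valid])
        )
        out["median_p50"] = float(np.median([r["p50_hat"] for r in valid]))
        out["mean_po"] = float(np.mean([r["po_hat"] for r in valid]))
        out["mean_abs_n_error"] = float(
            np.mean([abs(r["n_hat"] - r["n"]) / r["n"] for r in valid])
        )
    return out


def _run_tension_stage(cfg: dict, rng: np.random.Generator) -> dict:
    tensions_grid = np.linspace(0.5, 6.0, 12)
    radius_errors, t50s, densities = [], [], []
    for j in range(cfg["n_patches"]):
        radius = max(0.5, float(rng.normal(cfg["radius_mean"], cfg["radius_sd"])))
        image, meta = simulate_membrane_profile(
            radius, noise_sd=cfg["image_noise_sd"], seed=int(rng.integers(2**31))
        )
        geom = tension_geometry.fit_patch_circle(
            image, pixel_scale=meta["pixel_scale"]
        )
        radius_errors.append(abs(geom.radius - radius) / radius)
        density = float(rng.uniform(*cfg["densities"]))
        i_max = density * 2.0 * 0.98  # dome area ~2 µm²
        truth = tension_geometry.TensionFit(
            t50=cfg["t50"], slope_k=cfg["slope_k"], i_max=i_max, residual_norm=0.0
        )
        currents = truth(tensions_grid) + rng.normal(
            0.0, cfg["current_noise_sd"], tensions_grid.shape
        )
        fit = tension_geometry.fit_tension_sigmoid(tensions_grid, currents)
        t50s.append(fit.t50)
        densities.append(density)
    out = {
        "true_t50": cfg["t50"],
        "true_slope_k": cfg["slope_k"],
        "median_t50": float(np.median(t50s)),
        "max_radius_error": float(np.max(radius_errors)),
        "t50_vs_density": slope_confidence_interval(
            np.array(densities), np.array(t50s)
        ),
    }
    return out


def run_recording_study(
    seed: int = 0, out_dir: str | Path | None = None, config: dict | None = None
) -> dict:
    """Generate synthetic cohorts and run the full analysis pipeline.

    Returns a report with per-stage recovery summaries; stage failures
    are caught and reported as per-stage status.
    """
    cfg = DEFAULT_RECORDING_CONFIG if config is None else config
    rng = np.random.default_rng(seed)
    t_start = time.perf_counter()
    report: dict = {"seed": seed, "config_hash": config_hash(cfg), "stages": {}}
    stage_runners = {
        "ramp": _run_ramp_stage,
        "idealization": _run_idealization_stage,
        "step": _run_step_stage,
        "tension": _run_tension_stage,
    }
    for stage_index, (name, runner) in enumerate(stage_runners.items()):
        stage_rng = np.random.default_rng([seed, stage_index])
        t0 = time.perf_counter()
        try:
            result = runner(cfg[name], stage_rng)
            report["stages"][name] = {
                "status": "ok",
                "elapsed_s": time.perf_counter() - t0,
                **result,
            }
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
    report["elapsed_s"] = time.perf_counter() - t_start
    if out_dir is not None:
        dump_json(report, Path(out_dir) / "report.json")
    return report
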