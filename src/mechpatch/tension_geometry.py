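"""Patch-dome geometry, Laplace tension, and footprint coverage.

Membrane outlines are located by line scans across the image (rolling
minimum-intensity localisation), fitted with an algebraic (Kasa)
circle fit, converted to membrane tension via Laplace's law
``T = R * p / 2``, and the dome surface is treated as a spherical cap.
Footprint/coverage arithmetic treats channels as non-overlapping discs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "MMHG_TO_PA",
    "CircleFitError",
    "PatchGeometry",
    "TensionFit",
    "FootprintParams",
    "CoverageResult",
    "ScanConfig",
    "fit_circle_to_points",
    "fit_patch_circle",
    "laplace_tension",
    "spherical_cap_area",
    "channel_density",
    "fit_tension_sigmoid",
    "footprint_and_coverage",
]

MMHG_TO_PA = 133.322  # 1 mmHg in pascal


class CircleFitError(RuntimeError):
    pass


@dataclass
class PatchGeometry:
    """Fitted membrane geometry.  Radii/coordinates in µm unless the
    image scale is unknown, in which case they are in pixels."""

    radius: float
    center: tuple[float, float]
    n_points: int
    units: str = "um"


@dataclass
class TensionFit:
    """Sigmoid fit of current against tension:
    I(T) = i_max / (1 + exp((t50 - T)/k)), slope_k > 0 for activation
    by tension."""

    t50: float
    slope_k: float
    i_max: float
    residual_norm: float
    saturated: bool = True

    def __call__(self, T):
        with np.errstate(over="ignore"):
            return self.i_max / (1.0 + np.exp((self.t50 - np.asarray(T, float)) / self.slope_k))


@dataclass(frozen=True)
class FootprintParams:
    """Channel dome/footprint geometry (nm, nm²; patch area in µm²)."""

    dome_radius: float = 10.0
    decay_length: float = 14.0
    decay_multiple: float = 3.0
    in_plane_area: float = 400.0
    footprint_area: float = 7800.0
    patch_area: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "dome_radius",
            "decay_length",
            "decay_multiple",
            "in_plane_area",
            "footprint_area",
            "patch_area",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CoverageResult:
    footprint_radius_nm: float
    channel_coverage_pct: float
    footprint_coverage_pct: float
    saturated: bool


@dataclass(frozen=True)
class ScanConfig:
    """Line-scan settings for membrane localisation.

    ``rolling_window`` is the rolling-average width in pixels (5-9 per
    the acquisition convention); scans run along image rows.  Rows are
    used when their smoothed minimum is darker than ``threshold``
    (default: halfway between the global minimum and the median).
    """

    rolling_window: int = 7
    row_range: tuple[int, int] | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.rolling_window < 1:
            raise ValueError("rolling_window must be >= 1")


def fit_circle_to_points(points: np.ndarray, refine: bool = False) -> PatchGeometry:
    """Algebraic (Kasa) least-squares circle fit.

    Solves the linear system ``x*c0 + y*c1 + c2 = x² + y²``; exact for
    points sampled on a circle.  ``refine`` runs a geometric
    (orthogonal-distance) refinement.  Raises :class:`CircleFitError`
    for fewer than 5 points or degenerate (collinear) configurations.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 5:
        raise CircleFitError("need at least 5 outline points")
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise CircleFitError("outline points are collinear")
    cx, cy = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise CircleFitError("degenerate circle fit")
    r = float(np.sqrt(r2))
    if refine:

        def resid(p):
            return np.hypot(x - p[0], y - p[1]) - p[2]

        sol = least_squares(resid, x0=[cx, cy, r])
        cx, cy, r = sol.x
    return PatchGeometry(radius=float(r), center=(float(cx), float(cy)), n_points=len(x), units="px")


def fit_patch_circle(
    image: np.ndarray,
    scan_config: ScanConfig | None = None,
    pixel_scale: float | None = None,
) -> PatchGeometry:
    """Locate the membrane band by per-row line scans and fit a circle.

    Each image row is smoothed with a rolling average and the position
    of its minimum intensity is taken as an outline point; rows whose
    minimum is not dark enough (no membrane crossing) are skipped.
    Returns the fitted geometry in µm when ``pixel_scale`` (px/µm) is
    given, otherwise in pixels.
    """
    if scan_config is None:
        scan_config = ScanConfig()
    image = np.asarray(image, dtype=float)
    smoothed = uniform_filter1d(image, size=scan_config.rolling_window, axis=1, mode="nearest")
    if scan_config.row_range is not None:
        lo, hi = scan_config.row_range
    else:
        lo, hi = 0, image.shape[0]
    rows = np.arange(lo, hi)
    row_min = smoothed[lo:hi].min(axis=1)
    if scan_config.threshold is not None:
        threshold = scan_config.threshold
    else:
        threshold = 0.5 * (smoothed.min() + np.median(smoothed))
    keep = row_min < threshold
    ys = rows[keep]
    xs = smoothed[ys].argmin(axis=1)
    geom = fit_circle_to_points(np.column_stack([xs, ys]).astype(float))
    if pixel_scale is not None:
        geom = PatchGeometry(
            radius=geom.radius / pixel_scale,
            center=(geom.center[0] / pixel_scale, geom.center[1] / pixel_scale),
            n_points=geom.n_points,
            units="um",
        )
    return geom


def laplace_tension(radius: float, pressure: float) -> float:
    """Membrane tension in mN/m from Laplace's law ``T = R*p/2``.

    ``radius`` in µm, ``pressure`` in mmHg; tension is reported
    positive for suction (the magnitude convention).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pascals = abs(pressure) * MMHG_TO_PA
    tension_n_per_m = radius * 1e-6 * pascals / 2.0
    return tension_n_per_m * 1e3


def spherical_cap_area(radius: float, contact_chord: float) -> float:
    """Spherical-cap area (µm²) of a dome with the given sphere radius
    and base chord (the membrane-pipette contact separation).

    ``h = R - sqrt(R² - (chord/2)²)``; ``area = 2*pi*R*h``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if contact_chord < 0:
        raise ValueError("contact_chord must be non-negative")
    half = contact_chord / 2.0
    if half > radius:
        raise ValueError("contact chord cannot exceed the sphere diameter")
    h = radius - np.sqrt(radius**2 - half**2)
    return float(2.0 * np.pi * radius * h)


def channel_density(n_channels: float, dome_area: float) -> float:
    """Channels per µm² from a channel count and dome area (µm²)."""
    if dome_area <= 0:
        raise ValueError("dome_area must be positive")
    return n_channels / dome_area


def _tension_sigmoid(T, i_max, t50, k):
    with np.errstate(over="ignore"):
        return i_max / (1.0 + np.exp((t50 - np.asarray(T, dtype=float)) / k))


def fit_tension_sigmoid(tensions: np.ndarray, currents: np.ndarray) -> TensionFit:
    """Least-squares sigmoid fit of current against tension (>= 6 points)."""
    T = np.asarray(tensions, dtype=float)
    I = np.asarray(currents, dtype=float)
    if T.size < 6 or T.size != I.size:
        raise ValueError("need at least 6 matched (tension, current) points")
    order = np.argsort(T)
    T, I = T[order], I[order]
    i_max0 = float(I[-1])
    half = i_max0 / 2.0
    cross = np.nonzero(I >= half)[0]
    t50_0 = float(T[cross[0]]) if cross.size else float(np.median(T))
    popt, _ = curve_fit(
        _tension_sigmoid, T, I, p0=(i_max0, t50_0, 0.8), maxfev=20000
    )
    i_max, t50, k = (float(v) for v in popt)
    pred = _tension_sigmoid(T, *popt)
    residual = float(np.sqrt(np.mean((I - pred) ** 2)))
    plateau = pred[-1] / i_max if i_max != 0 else 0.0
    saturated = bool(plateau >= 0.95)
    return TensionFit(t50=t50, slope_k=k, i_max=i_max, residual_norm=residual, saturated=saturated)


def footprint_and_coverage(
    params: FootprintParams, n_channels: int
) -> CoverageResult:
    """Footprint radius and membrane coverage percentages.

    Footprint radius = dome radius + decay_multiple * decay length.
    Coverage assumes evenly spaced, non-overlapping channels:
    ``n * area / patch_area``.  Coverage above 100% is reported as
    saturated with a warning.
    """
    if n_channels < 0:
        raise ValueError("n_channels must be non-negative")
    footprint_radius = params.dome_radius + params.decay_multiple * params.decay_length
    patch_area_nm2 = params.patch_area * 1e6
    channel_pct = 100.0 * n_channels * params.in_plane_area / patch_area_nm2
    footprint_pct = 100.0 * n_channels * params.footprint_area / patch_area_nm2
    saturated = footprint_pct > 100.0 or channel_pct > 100.0
    if saturated:
        warnings.warn("coverage exceeds 100%: non-overlap assumption is saturated", stacklevel=2)
    return CoverageResult(
        footprint_radius_nm=float(footprint_radius),
        channel_coverage_pct=float(channel_pct),
        footprint_coverage_pct=float(footprint_pct),
        saturated=saturated,
    )
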