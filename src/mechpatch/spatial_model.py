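"""Clustered channel fields and virtual patch sampling.

Channel positions are modelled as a Thomas-type cluster process: cluster
centres ("parents") are scattered uniformly over a square arena at a
density chosen so that the *expected channel density* matches the
requested value, each parent receives either exactly one channel or a
Poisson-distributed number of channels, and every channel is displaced
from its parent by an isotropic per-axis Gaussian.

The field is then interrogated the way a patch pipette would interrogate
a membrane: circles with Gaussian-distributed radii are dropped
uniformly over the arena and the channels inside each circle are
counted.  Counts can additionally be pushed through a
count -> current -> count round trip that mimics cell-to-cell
variability in single-channel current.

Units: coordinates and radii are in micrometres (µm); nearest-neighbour
distances and the displacement sigma are in nanometres (nm); currents in
picoamperes (pA).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ClusterMode",
    "ClusterModelParams",
    "ChannelField",
    "PatchSamplerParams",
    "PatchSamples",
    "NNStats",
    "simulate_channel_field",
    "sample_patches",
    "counts_to_currents_to_counts",
    "nearest_neighbor_stats",
    "channel_count_histogram",
    "zero_truncated_poisson_mean",
]

NM_PER_UM = 1000.0


class ClusterMode(str, enum.Enum):
    """How many channels a parent receives."""

    FIXED_ONE = "fixed_one"
    POISSON = "poisson"


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ClusterModelParams:
    """Parameters of the clustered channel-position process.

    Parameters
    ----------
    arena_side:
        Side length of the square arena, µm.
    channel_density:
        Target channel density, channels/µm².  The parent density is
        derived from this so that the expected total number of channels
        is ``channel_density * arena_side**2`` in both cluster modes.
    cluster_mode:
        ``fixed_one`` places exactly one channel per parent;
        ``poisson`` draws the per-parent channel count from
        ``Poisson(poisson_mean)``.
    poisson_mean:
        Mean of the per-parent channel-count distribution (only used in
        ``poisson`` mode).  Note that the mean size of *populated*
        clusters is the zero-truncated Poisson mean
        ``lam / (1 - exp(-lam))`` (≈1.58 for ``lam=1``).
    displacement_sigma:
        Per-axis standard deviation of the Gaussian displacement of a
        channel from its parent, nm.
    seed:
        Seed for the pseudo-random generator.
    """

    arena_side: float = 50.0
    channel_density: float = 1.75
    cluster_mode: ClusterMode = ClusterMode.FIXED_ONE
    poisson_mean: float = 1.0
    displacement_sigma: float = 50.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.arena_side <= 0:
            raise ValueError("arena_side must be positive")
        if self.channel_density <= 0:
            raise ValueError("channel_density must be positive")
        if self.displacement_sigma < 0:
            raise ValueError("displacement_sigma must be non-negative")
        mode = ClusterMode(self.cluster_mode)
        object.__setattr__(self, "cluster_mode", mode)
        if mode is ClusterMode.POISSON and self.poisson_mean <= 0:
            raise ValueError("poisson_mean must be positive in poisson mode")

    @property
    def parent_density(self) -> float:
        """Parent density (parents/µm²) implied by the target channel density."""
        if self.cluster_mode is ClusterMode.FIXED_ONE:
            return self.channel_density
        return self.channel_density / self.poisson_mean

    @property
    def arena_area(self) -> float:
        return self.arena_side**2


@dataclass
class ChannelField:
    """A realisation of the cluster process.

    ``points`` is an ``(N, 2)`` array of channel coordinates in µm;
    ``parent_index[i]`` is the id of the cluster that point ``i``
    belongs to.  Channels displaced across the arena border are kept.
    """

    points: np.ndarray
    parent_index: np.ndarray
    params: ClusterModelParams

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def realized_density(self) -> float:
        return self.n_points / self.params.arena_area


@dataclass(frozen=True)
class PatchSamplerParams:
    """Virtual-pipette sampling parameters.

    ``radius_mean``/``radius_sd`` (µm) describe the patch-dome radius
    distribution; radii are redrawn until positive (at most
    ``max_radius_attempts`` times per circle).  ``current_mean`` /
    ``current_sd`` (pA) describe the per-patch single-channel current
    used to convert counts to currents; ``reference_current`` (pA) is
    the divisor used to revert currents back to counts.
    """

    n_circles: int = 1000
    radius_mean: float = 0.8
    radius_sd: float = 0.15
    current_mean: float = 0.98
    current_sd: float = 0.22
    reference_current: float = 0.98
    seed: int | None = None
    max_radius_attempts: int = 100

    def __post_init__(self) -> None:
        if self.n_circles < 1:
            raise ValueError("n_circles must be >= 1")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        if self.radius_sd < 0:
            raise ValueError("radius_sd must be non-negative")
        if self.current_mean <= 0:
            raise ValueError("current_mean must be positive")
        if self.reference_current <= 0:
            raise ValueError("reference_current must be positive")


@dataclass
class PatchSamples:
    """Per-circle sampling result (centres and radii in µm)."""

    centers: np.ndarray
    radii: np.ndarray
    counts: np.ndarray

    @property
    def zero_fraction(self) -> float:
        return float(np.mean(self.counts == 0))


@dataclass
class NNStats:
    """Nearest-neighbour summary; distances in nm."""

    distances: np.ndarray
    mean_nn: float
    cutoff: float
    fraction_within: float


def simulate_channel_field(params: ClusterModelParams) -> ChannelField:
    """Draw one realisation of the cluster process.

    The number of parents is Poisson with mean
    ``parent_density * arena_area``; parents are uniform in the arena.
    Each parent receives one channel (``fixed_one``) or a
    ``Poisson(poisson_mean)`` number of channels; every channel is
    offset from its parent by independent per-axis
    ``N(0, displacement_sigma)`` draws.  Channels pushed outside the
    arena by the offset are kept.
    """
    rng = np.random.default_rng(params.seed)
    n_parents = rng.poisson(params.parent_density * params.arena_area)
    parents = rng.uniform(0.0, params.arena_side, size=(n_parents, 2))
    if params.cluster_mode is ClusterMode.FIXED_ONE:
        n_daughters = np.ones(n_parents, dtype=np.int64)
    else:
        n_daughters = rng.poisson(params.poisson_mean, size=n_parents)
    parent_index = np.repeat(np.arange(n_parents), n_daughters)
    sigma_um = params.displacement_sigma / NM_PER_UM
    offsets = rng.normal(0.0, sigma_um, size=(parent_index.size, 2))
    points = parents[parent_index] + offsets
    return ChannelField(points=points, parent_index=parent_index, params=params)


def sample_patches(
    field: ChannelField,
    sampler: PatchSamplerParams,
    rng: np.random.Generator | None = None,
) -> PatchSamples:
    """Count channels inside circles dropped uniformly over the arena.

    Each circle's radius is Gaussian ``(radius_mean, radius_sd)``
    truncated to positive values by redrawing.  Circles near the arena
    edge are neither clipped nor wrapped.
    """
    if rng is None:
        rng = np.random.default_rng(sampler.seed)
    side = field.params.arena_side
    centers = rng.uniform(0.0, side, size=(sampler.n_circles, 2))
    radii = rng.normal(sampler.radius_mean, sampler.radius_sd, size=sampler.n_circles)
    for _ in range(sampler.max_radius_attempts):
        bad = radii <= 0
        if not bad.any():
            break
        radii[bad] = rng.normal(sampler.radius_mean, sampler.radius_sd, size=int(bad.sum()))
    else:
        raise RuntimeError("could not draw positive patch radii")
    if field.n_points == 0:
        counts = np.zeros(sampler.n_circles, dtype=np.int64)
    else:
        tree = cKDTree(field.points)
        counts = np.asarray(
            tree.query_ball_point(centers, radii, return_length=True), dtype=np.int64
        )
    return PatchSamples(centers=centers, radii=radii, counts=counts)


def counts_to_currents_to_counts(
    counts: np.ndarray,
    sampler: PatchSamplerParams,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Count -> current -> count round trip with per-patch current noise.

    One single-channel-current value is drawn per patch (not per
    channel): current variability is attributed to per-cell
    membrane-potential differences, which scale the whole patch.
    Reverted counts are ``round(current / reference_current)``
    (half away from zero) clamped at 0.

    Returns ``(currents_pA, reverted_counts)``.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng(sampler.seed if seed is None else seed)
    per_patch_i = rng.normal(sampler.current_mean, sampler.current_sd, size=counts.shape)
    currents = counts * per_patch_i
    reverted = _round_half_away(currents / sampler.reference_current)
    reverted = np.maximum(reverted, 0.0).astype(np.int64)
    return currents, reverted


def nearest_neighbor_stats(field: ChannelField, cutoff: float = 100.0) -> NNStats:
    """Per-point nearest-neighbour distances (nm) without edge correction.

    ``cutoff`` is in nm.  Raises ``ValueError`` for fields with fewer
    than two points, where the statistic is undefined.
    """
    if field.n_points < 2:
        raise ValueError("nearest-neighbour statistics need at least 2 points")
    tree = cKDTree(field.points)
    dist, _ = tree.query(field.points, k=2)
    distances_nm = dist[:, 1] * NM_PER_UM
    return NNStats(
        distances=distances_nm,
        mean_nn=float(distances_nm.mean()),
        cutoff=float(cutoff),
        fraction_within=float(np.mean(distances_nm <= cutoff)),
    )


def channel_count_histogram(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer-binned relative frequencies of channels per patch.

    Returns ``(values, frequencies)`` with one bin per integer from 0 to
    ``max(counts)``; frequencies sum to 1.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty count array")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    values = np.arange(counts.max() + 1)
    freqs = np.bincount(counts, minlength=values.size) / counts.size
    return values, freqs


def zero_truncated_poisson_mean(lam: float) -> float:
    """Mean of a Poisson(lam) conditioned on being positive."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    return lam / (1.0 - np.exp(-lam))
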