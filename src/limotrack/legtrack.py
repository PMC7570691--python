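"""Particle-filter tracking of the two lower-leg point clusters.

State is per-leg 2D (ground plane), constant-position motion with
Gaussian diffusion, and a Gaussian likelihood on the distance between a
particle and the observed leg-cluster centroid.  The simplest filter
consistent with tracking the leg observation inside the real-time cloud.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .clouds import euclidean_clusters
from .errors import EmptyCloudError, InvalidArgumentError
from .skeleton import JOINT_INDEX, Skeleton
from .types import PointCloudFrame, PoseFrame

log = logging.getLogger(__name__)

DEFAULT_N_PARTICLES = 200
DEFAULT_PROCESS_NOISE = 0.5      # m / sqrt(s)
DEFAULT_LIKELIHOOD_SIGMA = 0.1   # m
DEFAULT_LEG_CLUSTER_DISTANCE = 0.15
MIN_CLUSTER_POINTS = 4


@dataclass
class ParticleFilterState:
    """Weighted ground-plane particle set for one tracked leg."""

    particles: np.ndarray          # (N, 2)
    weights: np.ndarray            # (N,), sums to 1
    last_timestamp: float = 0.0
    process_noise: float = DEFAULT_PROCESS_NOISE
    likelihood_sigma: float = DEFAULT_LIKELIHOOD_SIGMA

    def __post_init__(self) -> None:
        self.particles = np.asarray(self.particles, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.particles) < 10:
            raise InvalidArgumentError("need at least 10 particles")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("weights must be non-negative and sum to 1")

    @property
    def estimate(self) -> np.ndarray:
        """Weighted-mean ground-plane position."""
        return self.weights @ self.particles


def init_state(position: np.ndarray, n_particles: int = DEFAULT_N_PARTICLES,
               spread: float = 0.05, seed: int = 0,
               process_noise: float = DEFAULT_PROCESS_NOISE,
               likelihood_sigma: float = DEFAULT_LIKELIHOOD_SIGMA,
               timestamp: float = 0.0) -> ParticleFilterState:
    """Particles drawn around an initial ground-plane position."""
    rng = np.random.default_rng(seed)
    position = np.asarray(position, dtype=np.float64)[:2]
    particles = position + rng.normal(0.0, spread, size=(n_particles, 2))
    weights = np.full(n_particles, 1.0 / n_particles)
    return ParticleFilterState(particles, weights, timestamp,
                               process_noise, likelihood_sigma)


def pf_predict(state: ParticleFilterState, dt: float,
               seed: int) -> ParticleFilterState:
    """Diffuse particles by zero-mean Gaussian noise with std sigma*sqrt(dt)."""
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    rng = np.random.default_rng(seed)
    std = state.process_noise * np.sqrt(dt)
    noise = rng.normal(0.0, std, size=state.particles.shape) if std > 0 else 0.0
    return replace(state,
                   particles=state.particles + noise,
                   weights=state.weights.copy(),
                   last_timestamp=state.last_timestamp + dt)


def _systematic_resample(particles: np.ndarray, weights: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    indexes = np.searchsorted(np.cumsum(weights), positions)
    return particles[np.clip(indexes, 0, n - 1)]


def _cylinder_corrected_mean(points: np.ndarray, origins: np.ndarray,
                             radius: float, axis: np.ndarray,
                             iterations: int = 3) -> np.ndarray:
    """Mean limb-axis point recovered from surface returns.

    Each return lies on the sensor-facing side of the limb cylinder; the
    inward depth along the (horizontal) ray is sqrt(r^2 - l^2) where l is
    the point's lateral offset from the axis.  The axis position is not
    known up front, so start from a mean-arc-depth guess (pi/4 * r) and
    iterate.  Steep (overhead) rays violate the horizontal-circle
    geometry and are excluded when enough shallow returns exist.
    """
    d3 = points - origins
    r3 = np.linalg.norm(d3, axis=1)
    shallow = np.abs(d3[:, 2]) < 0.5 * np.maximum(r3, 1e-9)
    if shallow.sum() >= 5:
        points = points[shallow]
        origins = origins[shallow]
    h = points - origins
    h[:, 2] = 0.0
    hn = np.linalg.norm(h, axis=1, keepdims=True)
    h = np.where(hn > 1e-9, h / np.maximum(hn, 1e-9), 0.0)
    a_h = np.array([axis[0], axis[1], 0.0])
    est = points.mean(axis=0) + (np.pi / 4.0) * radius * h.mean(axis=0)
    for _ in range(iterations):
        # horizontal offset of each point from the axis line through est
        dz = points[:, 2] - est[2]
        axis_at = est[None, :2] + np.outer(
            dz / axis[2] if abs(axis[2]) > 1e-6 else dz * 0.0, a_h[:2])
        e = points[:, :2] - axis_at
        # lateral component perpendicular to the ray
        lat = e[:, 0] * h[:, 1] - e[:, 1] * h[:, 0]
        depth = np.sqrt(np.maximum(radius ** 2 - lat ** 2, 0.0))
        corrected = points + h * depth[:, None]
        est = corrected.mean(axis=0)
    return est


def ankle_from_cluster(points: np.ndarray, floor_z: float = 0.0,
                       max_extrapolation: float = 0.6,
                       axis: np.ndarray | None = None,
                       origins: np.ndarray | None = None,
                       radius: float = 0.0,
                       prior_ankle: np.ndarray | None = None) -> np.ndarray:
    """Ground-plane ankle estimate from a lower-leg cluster.

    Intersects the shin axis through the cluster's recovered axis point
    with the floor plane; this removes the centroid bias that appears
    when the knee is flexed.  The axis is the known shin direction when
    supplied (e.g. from the IMU orientation), otherwise the cluster's
    first principal component.  When per-point sensor origins and the
    limb radius are available, surface returns are first corrected onto
    the limb axis (iterative cylinder fit).  A ``prior_ankle`` ground
    position gates out points far from the predicted shin line (knee or
    thigh contamination).  Falls back to the plain xy centroid for
    degenerate (near-horizontal or tiny) clusters.
    """
    points = np.asarray(points, dtype=np.float64)
    xy = points[:, :2].mean(axis=0)
    if len(points) < 5 and axis is None:
        return xy
    if axis is not None:
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
    else:
        centered = points - points.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    if axis[2] > 0:
        axis = -axis
    if abs(axis[2]) < 0.3:
        return xy
    if prior_ankle is not None and abs(axis[2]) > 0.3:
        expected = (np.asarray(prior_ankle, dtype=np.float64)[None, :2]
                    + np.outer((points[:, 2] - floor_z) / axis[2], axis[:2]))
        keep = np.linalg.norm(points[:, :2] - expected, axis=1) < \
            max(2.5 * radius, 0.12)
        if keep.sum() >= max(5, len(points) // 4):
            points = points[keep]
            if origins is not None:
                origins = origins[keep]
    if origins is not None and radius > 0:
        mean = _cylinder_corrected_mean(points, origins, radius, axis)
    else:
        mean = points.mean(axis=0)
    t = (floor_z - mean[2]) / axis[2]
    if abs(t) > max_extrapolation / max(abs(axis[2]), 1e-9):
        return mean[:2]
    return mean[:2] + t * axis[:2]


def pf_update(state: ParticleFilterState, leg_cloud: PointCloudFrame,
              seed: int = 0, target: np.ndarray | None = None) -> ParticleFilterState:
    """Reweight by distance to the leg observation on the ground plane.

    The observation defaults to the leg-cloud ground-plane centroid; a
    refined target (e.g. the shin-axis floor intersection) may be passed
    instead.  Weights ~ exp(-d^2 / (2 sigma^2)); systematic resampling
    kicks in when the effective sample size drops below N/2.  If every
    weight underflows, particles are reinitialized around the observation.
    """
    if len(leg_cloud) == 0:
        raise EmptyCloudError("pf_update needs a non-empty leg cloud")
    rng = np.random.default_rng(seed)
    if target is None:
        target = leg_cloud.points[:, :2].mean(axis=0)
    target = np.asarray(target, dtype=np.float64)[:2]
    d2 = np.sum((state.particles - target) ** 2, axis=1)
    raw = np.exp(-d2 / (2.0 * state.likelihood_sigma ** 2))
    total = raw.sum()
    if total <= 0 or not np.isfinite(total):
        log.warning("pf_update: weight underflow; reinitializing around observation")
        particles = target + rng.normal(0.0, state.likelihood_sigma,
                                        size=state.particles.shape)
        weights = np.full(len(particles), 1.0 / len(particles))
        return replace(state, particles=particles, weights=weights)
    weights = raw / total
    particles = state.particles
    ess = 1.0 / np.sum(weights ** 2)
    if ess < len(weights) / 2.0:
        particles = _systematic_resample(particles, weights, rng)
        weights = np.full(len(particles), 1.0 / len(particles))
    return replace(state, particles=particles.copy(), weights=weights)


@dataclass
class LegObservation:
    """Result of clustering one real-time frame into leg clouds."""

    left: PointCloudFrame | None
    right: PointCloudFrame | None
    merged: bool = False
    occluded: bool = False
    extra: dict = field(default_factory=dict)


def _compensate_radius(cloud: PointCloudFrame, radius: float) -> np.ndarray:
    """Push surface points toward the limb axis along the horizontal ray.

    Lidar returns sample the sensor-facing side of a leg; shifting each
    point along its (horizontal) ray direction removes most of the
    resulting centroid bias.  The shift is radius * pi/4: returns sample
    the visible arc roughly uniformly across the limb width, so the mean
    inward depth to the axis is the mean cosine over the arc, pi/4 of the
    radius.  No-op without origins.
    """
    pts = cloud.points.copy()
    if cloud.origins is None or radius <= 0:
        return pts
    d3 = pts - cloud.origins
    r3 = np.linalg.norm(d3, axis=1)
    d = d3.copy()
    d[:, 2] = 0.0
    norms = np.linalg.norm(d, axis=1)
    # only near-horizontal rays see the limb side-on; steep (overhead)
    # rays graze the top surface and must not be shifted sideways
    ok = (norms > 1e-9) & (np.abs(d3[:, 2]) < 0.6 * np.maximum(r3, 1e-9))
    pts[ok] += (d[ok] / norms[ok, None]) * (radius * np.pi / 4.0)
    return pts


def cluster_leg_points(user_cloud: PointCloudFrame, skeleton: Skeleton,
                      prior_pose: PoseFrame,
                      cluster_distance: float = DEFAULT_LEG_CLUSTER_DISTANCE,
                      leg_radius: float = 0.0,
                      floor_z: float = 0.0,
                      gate_radius: float = 0.8) -> LegObservation:
    """Split the below-knee band of the user cloud into left/right legs.

    The band spans [floor, floor + 2 head units] (the lower-leg
    proportion).  Clusters farther than ``gate_radius`` from both prior
    knees are discarded (stray change-detection leaks); the survivors are
    assigned left/right by proximity to the prior knee positions.  A
    single surviving cluster flags both legs merged, zero clusters flag
    occlusion.
    """
    if user_cloud.frame != "world":
        raise InvalidArgumentError("leg clustering expects a world-frame cloud")
    band_top = floor_z + 2.0 * skeleton.head_unit
    if len(user_cloud) == 0:
        return LegObservation(None, None, occluded=True)
    mask = (user_cloud.points[:, 2] >= floor_z - 1e-6) & \
           (user_cloud.points[:, 2] <= band_top)
    band = user_cloud.select(mask, variant="leg")
    if len(band) < MIN_CLUSTER_POINTS:
        return LegObservation(None, None, occluded=True)
    if leg_radius > 0:
        band = PointCloudFrame(_compensate_radius(band, leg_radius),
                               timestamp=band.timestamp, variant="leg",
                               frame=band.frame, origins=band.origins)
    labels = euclidean_clusters(band.points, cluster_distance)
    counts = np.bincount(labels)
    big = np.flatnonzero(counts >= MIN_CLUSTER_POINTS)
    big = big[np.argsort(counts[big])[::-1]]
    lknee = prior_pose.positions[JOINT_INDEX["LKnee"], :2]
    rknee = prior_pose.positions[JOINT_INDEX["RKnee"], :2]
    if gate_radius > 0 and len(big):
        keep = []
        for b in big:
            c = band.points[labels == b, :2].mean(axis=0)
            if min(np.linalg.norm(c - lknee), np.linalg.norm(c - rknee)) <= gate_radius:
                keep.append(b)
        big = np.asarray(keep, dtype=int)
    big = big[:2]
    if len(big) == 0:
        return LegObservation(None, None, occluded=True)
    if len(big) == 1:
        merged_cloud = band.select(labels == big[0], variant="leg")
        return LegObservation(merged_cloud, merged_cloud, merged=True)
    clusters = [band.select(labels == b, variant="leg") for b in big]
    cents = np.array([c.points[:, :2].mean(axis=0) for c in clusters])
    # two assignments possible; pick the one minimizing total distance
    cost_a = np.linalg.norm(cents[0] - lknee) + np.linalg.norm(cents[1] - rknee)
    cost_b = np.linalg.norm(cents[1] - lknee) + np.linalg.norm(cents[0] - rknee)
    if cost_a <= cost_b:
        return LegObservation(left=clusters[0], right=clusters[1])
    return LegObservation(left=clusters[1], right=clusters[0])


def foot_positions(left_state: ParticleFilterState,
                   right_state: ParticleFilterState,
                   floor_z: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-leg estimates projected onto the floor plane (left, right)."""
    left = np.append(left_state.estimate, floor_z)
    right = np.append(right_state.estimate, floor_z)
    return left, right
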