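"""Point-cloud processing: user extraction, ground point, floor slope, and
body-height estimation from the ceiling lidar.

Height estimation is evaluated literally in the L1 sensor frame, where +y
points down toward the floor, so the floor carries the *maximal* y
coordinate and the top of the head the minimal one.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, EmptyCloudError, FrameMismatchError
from .types import PointCloudFrame

log = logging.getLogger(__name__)

#: Default voxel edge for octree-style change detection (meters).
DEFAULT_VOXEL_RESOLUTION = 0.10
#: Default Euclidean cluster distance for the largest-cluster post-filter.
DEFAULT_CLUSTER_DISTANCE = 0.25


# ---------------------------------------------------------------------------
# voxel differencing + clustering

_KEY_OFFSET = 1 << 20  # supports |voxel index| < 2^20


def _voxel_keys(points: np.ndarray, resolution: float) -> np.ndarray:
    """Voxel indices packed into a single int64 key per point."""
    idx = np.floor(points / resolution).astype(np.int64) + _KEY_OFFSET
    return (idx[:, 0] << 42) | (idx[:, 1] << 21) | idx[:, 2]


def _dilated_keys(keys: np.ndarray, dilate: int,
                  dilate_z_up: bool = False) -> np.ndarray:
    """Occupancy keys expanded by a neighborhood of voxels.

    By default the expansion skips the +z direction: noisy floor returns
    only leak sideways or below the floor plane (walls occupy full
    columns already), and dilating upward would eat the user's feet.
    """
    keys = np.unique(keys)
    if dilate <= 0:
        return keys
    shifts = np.arange(-dilate, dilate + 1, dtype=np.int64)
    z_shifts = shifts if dilate_z_up else np.arange(-dilate, 1, dtype=np.int64)
    offs = ((shifts[:, None, None] << 42) + (shifts[None, :, None] << 21)
            + z_shifts[None, None, :]).ravel()
    return np.unique(keys[:, None] + offs[None, :])

def euclidean_clusters(points: np.ndarray, distance: float) -> np.ndarray:
    """Connected-component labels under a pairwise distance threshold."""
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(distance, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = sparse.csgraph.connected_components(graph, directed=False)
    return labels


def extract_user_cloud(reference: PointCloudFrame,
                       observed: PointCloudFrame,
                       voxel_resolution: float = DEFAULT_VOXEL_RESOLUTION,
                       cluster_distance: float = DEFAULT_CLUSTER_DISTANCE,
                       realtime: bool = False,
                       dilate: int = 1) -> PointCloudFrame:
    """Voxel-occupancy change detection followed by a largest-cluster filter.

    Returns the observed points lying in voxels unoccupied by the
    reference cloud, restricted to the largest Euclidean cluster (the
    user).  Tagged ``user`` (or ``realtime`` when requested).

    ``dilate`` expands the reference occupancy by that many voxels in
    every direction before differencing; range noise at grazing incidence
    otherwise leaks boundary-voxel surface points into the change set.
    Set ``dilate=0`` for the strict occupancy difference.
    """
    if voxel_resolution <= 0:
        raise ValueError("voxel_resolution must be positive")
    if reference.frame != observed.frame:
        raise FrameMismatchError(
            f"reference frame {reference.frame!r} != observed frame {observed.frame!r}")
    variant = "realtime" if realtime else "user"
    if len(observed) == 0:
        log.warning("extract_user_cloud: observed cloud is empty")
        return observed.select(np.zeros(0, dtype=int), variant=variant)
    if len(reference) == 0:
        changed = np.ones(len(observed), dtype=bool)
    else:
        ref_keys = _dilated_keys(_voxel_keys(reference.points, voxel_resolution),
                                 dilate)
        obs_keys = _voxel_keys(observed.points, voxel_resolution)
        changed = ~np.isin(obs_keys, ref_keys)
    candidate = observed.select(changed, variant=variant)
    if len(candidate) == 0:
        return candidate
    labels = euclidean_clusters(candidate.points, cluster_distance)
    counts = np.bincount(labels)
    return candidate.select(labels == np.argmax(counts), variant=variant)


# ---------------------------------------------------------------------------
# ground point, slope, height (L1 frame)

def centroid(cloud: PointCloudFrame) -> np.ndarray:
    """Arithmetic mean of the points."""
    if len(cloud) == 0:
        raise EmptyCloudError("centroid of an empty cloud")
    return cloud.points.mean(axis=0)


def ground_point(full_cloud: PointCloudFrame) -> np.ndarray:
    """The point with maximal y (floor under the ceiling lidar).

    Ties break on smallest x, then smallest z, so the result is
    deterministic for grid-sampled floors.
    """
    if len(full_cloud) == 0:
        raise EmptyCloudError("ground_point of an empty cloud")
    pts = full_cloud.points
    order = np.lexsort((pts[:, 2], pts[:, 0], -pts[:, 1]))
    return pts[order[0]].copy()


def floor_slope(user_cloud: PointCloudFrame, g: np.ndarray) -> float:
    """m = (maxy - gy) / (maxx - gx) over the user cloud, literally."""
    if len(user_cloud) == 0:
        raise EmptyCloudError("floor_slope of an empty cloud")
    g = np.asarray(g, dtype=np.float64)
    maxx = user_cloud.points[:, 0].max()
    maxy = user_cloud.points[:, 1].max()
    if maxx == g[0]:
        raise DegenerateGeometryError("maxx equals gx: vertical reference line")
    return float((maxy - g[1]) / (maxx - g[0]))


def floor_slope_from_reference(reference: PointCloudFrame, g: np.ndarray,
                               band: float = 0.25) -> float:
    """Least-squares floor slope fitted to near-floor reference points.

    Alternative to the literal user-cloud formula: points whose y lies
    within ``band`` of the ground point are treated as floor samples and
    a line y = a + m*x is fitted.  Useful because voxel differencing
    strips near-floor user points, which biases the literal estimate by
    roughly one voxel.
    """
    if len(reference) == 0:
        raise EmptyCloudError("floor_slope_from_reference of an empty cloud")
    g = np.asarray(g, dtype=np.float64)
    pts = reference.points
    mask = pts[:, 1] > g[1] - band
    floor = pts[mask]
    if len(floor) < 2:
        raise DegenerateGeometryError("too few near-floor points to fit a slope")
    x = floor[:, 0]
    y = floor[:, 1]
    m, _ = np.polyfit(x, y, 1)
    return float(m)


def estimate_height(user_cloud: PointCloudFrame, g: np.ndarray,
                    m: float) -> float:
    """Ah = (gy - miny) + cx * m.

    ``miny`` is the top of the head in the L1 frame and ``cx`` the x
    component of the user-cloud centroid.  A non-positive result is
    returned with a warning (implausible geometry upstream).
    """
    if len(user_cloud) == 0:
        raise EmptyCloudError("estimate_height of an empty cloud")
    g = np.asarray(g, dtype=np.float64)
    miny = user_cloud.points[:, 1].min()
    cx = centroid(user_cloud)[0]
    ah = float((g[1] - miny) + cx * m)
    if ah <= 0:
        log.warning("estimate_height: implausible height %.3f m", ah)
    return ah


def calibrate_height(reference: PointCloudFrame,
                     full_clouds: list[PointCloudFrame],
                     voxel_resolution: float = DEFAULT_VOXEL_RESOLUTION,
                     slope_source: str = "user_cloud") -> float:
    """Average the per-frame height estimate over calibration frames.

    ``slope_source`` selects the literal Eq.-style slope from the user
    cloud extrema (``"user_cloud"``) or the reference-floor fit
    (``"floor"``).
    """
    if not full_clouds:
        raise EmptyCloudError("no calibration frames")
    heights = []
    for full in full_clouds:
        g = ground_point(full)
        user = extract_user_cloud(reference, full, voxel_resolution)
        if len(user) == 0:
            log.warning("calibrate_height: no user points in a calibration frame")
            continue
        if slope_source == "floor":
            m = floor_slope_from_reference(reference, g)
        else:
            m = floor_slope(user, g)
        heights.append(estimate_height(user, g, m))
    if not heights:
        raise EmptyCloudError("user not found in any calibration frame")
    return float(np.mean(heights))
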