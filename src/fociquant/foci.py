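"""Measurement core: sub-volume extraction, clip-and-threshold segmentation,
centroiding, 3D distances, volumes, Pearson colocalization and triple angles.

The segmentation recipe quantifies a FISH focus from a small crop (default
20 x 20 pixels x 7 z-steps) centred on a manually or synthetically seeded
position:

1. *clip* — intensities above the nearest-rank 96.5th percentile of the crop
   are saturated to that percentile value, suppressing isolated hot pixels
   (a fraction-of-maximum clip mode is also available);
2. *threshold* — the mask is every voxel at or above 90% of the post-clip
   maximum;
3. one 26-connected component is kept;
4. the centroid is the post-clip intensity-weighted mean voxel position,
   reported in the parent stack's physical frame (nm);
5. the volume is the masked voxel count times the voxel volume (um^3).

Degenerate segmentations (too few voxels, mask touching the crop border, or
covering more than half the crop) are flagged rather than discarded here;
summaries exclude flagged rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imgio import ImageStack3D, SeedPoint, VoxelSize, physical_position

__all__ = [
    "SegmentationParams",
    "SubVolume",
    "FocusSegmentation",
    "PairMeasurement",
    "TripleAngle",
    "extract_subvolume",
    "segment_focus",
    "pair_distance",
    "pearson_pair",
    "angle_at_vertex",
    "triple_angle",
    "random_angle_baseline",
    "measure_pair",
    "nearest_rank_percentile",
]

DEFAULT_CROP = (20, 20, 7)  # (nx, ny, nz)


@dataclass(frozen=True)
class SegmentationParams:
    """Clip-and-threshold segmentation settings.

    clip_percentile : percentile (nearest-rank) above which intensities are
        saturated; in ``fraction_of_max`` mode the same number is used as a
        percentage of the crop maximum.
    threshold_fraction : mask threshold as a fraction of the post-clip max.
    min_voxels : masks smaller than this are flagged degenerate.
    component_policy : which 26-connected component to keep — ``largest``
        (ties broken by proximity to the crop centre) or ``nearest_center``.
    """

    clip_percentile: float = 96.5
    threshold_fraction: float = 0.90
    clip_mode: str = "percentile"  # "percentile" | "fraction_of_max"
    min_voxels: int = 5
    component_policy: str = "largest"  # "largest" | "nearest_center"

    def __post_init__(self) -> None:
        if not (0 < self.clip_percentile <= 100):
            raise ValueError("clip_percentile must be in (0, 100]")
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.clip_mode not in ("percentile", "fraction_of_max"):
            raise ValueError(f"unknown clip_mode {self.clip_mode!r}")
        if self.component_policy not in ("largest", "nearest_center"):
            raise ValueError(f"unknown component_policy {self.component_policy!r}")


@dataclass
class SubVolume:
    """A crop of one channel of a parent stack.

    ``origin`` is the (x, y, z) voxel index of the crop's low corner in the
    parent stack; ``data`` is indexed (z, y, x) and owns its memory (mutating
    it never alters the parent stack).
    """

    origin: tuple[int, int, int]
    data: np.ndarray
    voxel: VoxelSize
    channel_index: int = 0
    stack_id: str = ""
    locus_id: str = ""

    @property
    def size(self) -> tuple[int, int, int]:
        """(nx, ny, nz)."""
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)


@dataclass
class FocusSegmentation:
    mask: np.ndarray  # boolean, congruent with the sub-volume (z, y, x)
    clip_value: float
    threshold: float
    centroid_nm: np.ndarray  # (X, Y, Z) in the parent stack's physical frame
    n_voxels: int
    volume_um3: float
    degenerate: bool
    stack_id: str = ""
    locus_id: str = ""
    channel_index: int = 0


@dataclass
class PairMeasurement:
    """One row of the measurement table: a two-channel signal pair."""

    stack_id: str
    locus_id: str
    distance_nm: float
    pearson_r: float
    volume_um3_ch0: float
    volume_um3_ch1: float
    degenerate_ch0: bool
    degenerate_ch1: bool
    pearson_undefined: bool
    threshold_ch0: float
    threshold_ch1: float


@dataclass
class TripleAngle:
    """Vertex angle of a probe triple, via the law of cosines.

    a, b are the arm lengths from the vertex centroid to the two flanking
    centroids, c the base between the flanking centroids, and
    theta = arccos((a^2 + b^2 - c^2) / (2ab)) in degrees.
    """

    vertex_nm: np.ndarray
    arm1_nm: np.ndarray
    arm2_nm: np.ndarray
    a_nm: float
    b_nm: float
    c_nm: float
    theta_deg: float


class BoundaryError(ValueError):
    """A crop centred on a seed would cross the stack boundary."""


def extract_subvolume(
    stack: ImageStack3D,
    seed: SeedPoint,
    size: tuple[int, int, int] = DEFAULT_CROP,
) -> SubVolume:
    """Extract a crop of ``size`` (nx, ny, nz) centred on a seed point.

    For even sizes the seed sits at index ``n // 2`` of the crop.  Crops
    that would cross the stack boundary are rejected (interior loci only).
    """
    nx, ny, nz = size
    nzs, nys, nxs = stack.shape
    if not (0 <= seed.channel_index < stack.n_channels):
        raise ValueError(f"seed references channel {seed.channel_index} of a "
                         f"{stack.n_channels}-channel stack")
    x0, y0, z0 = seed.x - nx // 2, seed.y - ny // 2, seed.z - nz // 2
    if x0 < 0 or y0 < 0 or z0 < 0 or x0 + nx > nxs or y0 + ny > nys or z0 + nz > nzs:
        raise BoundaryError(
            f"crop {size} centred on seed (x={seed.x}, y={seed.y}, z={seed.z}) "
            f"[{seed.stack_id}/{seed.locus_id}] crosses the bounds of a "
            f"stack of shape (z,y,x)={stack.shape}"
        )
    data = stack.channels[seed.channel_index][z0 : z0 + nz, y0 : y0 + ny, x0 : x0 + nx]
    return SubVolume(
        origin=(x0, y0, z0),
        data=np.array(data, dtype=np.float64, copy=True),
        voxel=stack.voxel,
        channel_index=seed.channel_index,
        stack_id=seed.stack_id,
        locus_id=seed.locus_id,
    )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(q/100 * N) (1-based)
    of the ascending sorted list."""
    flat = np.sort(np.asarray(values).ravel())
    n = flat.size
    rank = int(math.ceil(q / 100.0 * n))
    rank = min(max(rank, 1), n)
    return float(flat[rank - 1])


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _select_component(labels: np.ndarray, n_comp: int, policy: str) -> np.ndarray:
    """Keep one 26-connected component of the thresholded mask."""
    nz, ny, nx = labels.shape
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    sizes = ndimage.sum_labels(
        np.ones_like(labels), labels, index=np.arange(1, n_comp + 1)
    )
    centroids = np.array(ndimage.center_of_mass(
        np.ones_like(labels, dtype=float), labels, index=np.arange(1, n_comp + 1)
    ))
    dists = np.linalg.norm(centroids - center, axis=1)
    if policy == "largest":
        best_size = sizes.max()
        tied = np.flatnonzero(sizes == best_size)
        pick = tied[np.argmin(dists[tied])] + 1
    else:  # nearest_center
        pick = int(np.argmin(dists)) + 1
    return labels == pick


def segment_focus(
    sub: SubVolume, params: SegmentationParams | None = None
) -> FocusSegmentation:
    """Segment one focus from a sub-volume by clip-and-threshold.

    Raises ``ValueError`` on an all-zero crop.  A constant nonzero crop (or
    any mask failing the QC rules) yields a flagged *degenerate* result, not
    an exception.
    """
    params = params or SegmentationParams()
    data = np.asarray(sub.data, dtype=np.float64)
    if not np.any(data > 0):
        raise ValueError(
            f"sub-volume {sub.stack_id}/{sub.locus_id} is all zero; nothing to segment"
        )

    if params.clip_mode == "percentile":
        clip_value = nearest_rank_percentile(data, params.clip_percentile)
    else:
        clip_value = params.clip_percentile / 100.0 * float(data.max())
    clipped = np.minimum(data, clip_value)

    threshold = params.threshold_fraction * float(clipped.max())
    mask = clipped >= threshold

    labels, n_comp = ndimage.label(mask, structure=_CONN26)
    if n_comp > 1:
        mask = _select_component(labels, n_comp, params.component_policy)

    n_vox = int(mask.sum())
    weights = clipped[mask]
    zz, yy, xx = np.nonzero(mask)
    wsum = weights.sum()
    local = np.array(
        [np.dot(weights, xx) / wsum, np.dot(weights, yy) / wsum, np.dot(weights, zz) / wsum]
    )
    parent_vox = np.array(sub.origin, dtype=float) + local
    centroid_nm = physical_position(parent_vox, sub.voxel)

    volume_um3 = n_vox * sub.voxel.volume_nm3 / 1e9

    # Border QC applies to the lateral faces only: the crop's axial extent
    # (7 planes x 150 nm ~ +-1.5 sigma_z of the spot model) is intentionally
    # tight, so a mask reaching the first/last plane is the norm of this
    # imaging regime, not a truncated signal.
    touches_border = bool(
        mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    degenerate = (
        n_vox < params.min_voxels or touches_border or n_vox > 0.5 * mask.size
    )

    return FocusSegmentation(
        mask=mask,
        clip_value=float(clip_value),
        threshold=float(threshold),
        centroid_nm=centroid_nm,
        n_voxels=n_vox,
        volume_um3=volume_um3,
        degenerate=degenerate,
        stack_id=sub.stack_id,
        locus_id=sub.locus_id,
        channel_index=sub.channel_index,
    )


def pair_distance(seg1: FocusSegmentation, seg2: FocusSegmentation) -> float:
    """Euclidean 3D distance (nm) between two focus centroids.

    Degenerate inputs yield NaN (a flagged result excluded from summaries)
    rather than an exception.
    """
    if seg1.degenerate or seg2.degenerate:
        return float("nan")
    return float(np.linalg.norm(seg1.centroid_nm - seg2.centroid_nm))


def pearson_pair(sub1: SubVolume, sub2: SubVolume) -> float:
    """Pearson correlation of two congruent raw-intensity sub-volumes.

    Computed on the raw (unclipped, unthresholded) intensities of crops from
    the two channels taken at the same origin.  Zero variance in either crop
    gives NaN (undefined, excluded from summaries).
    """
    if sub1.data.shape != sub2.data.shape:
        raise ValueError("sub-volumes are not congruent")
    if sub1.origin != sub2.origin:
        raise ValueError(f"sub-volumes have different origins: {sub1.origin} vs {sub2.origin}")
    a = sub1.data.ravel().astype(np.float64)
    b = sub2.data.ravel().astype(np.float64)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, r))


def angle_at_vertex(vertex, p1, p2) -> np.ndarray | float:
    """Angle at ``vertex`` subtended by points ``p1`` and ``p2``, in degrees,
    by the law of cosines on the side lengths a, b, c.

    Broadcasts over leading axes (inputs of shape (..., 3)); the cosine is
    clamped to [-1, 1] against floating error.  Coincident vertex and arm
    raises ``ValueError``.
    """
    vertex = np.asarray(vertex, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    a = np.linalg.norm(p1 - vertex, axis=-1)
    b = np.linalg.norm(p2 - vertex, axis=-1)
    c = np.linalg.norm(p2 - p1, axis=-1)
    if np.any(a == 0) or np.any(b == 0):
        raise ValueError("angle undefined: an arm coincides with the vertex")
    cos_theta = (a**2 + b**2 - c**2) / (2.0 * a * b)
    cos_theta = np.clip(cos_theta, -1.0, 1.0)
    out = np.degrees(np.arccos(cos_theta))
    return float(out) if out.ndim == 0 else out


def triple_angle(
    vertex: FocusSegmentation,
    arm1: FocusSegmentation,
    arm2: FocusSegmentation,
) -> TripleAngle:
    """Vertex angle of a probe triple from three segmented centroids."""
    for seg, name in ((vertex, "vertex"), (arm1, "arm1"), (arm2, "arm2")):
        if seg.degenerate:
            raise ValueError(f"{name} segmentation is degenerate; angle not computed")
    v, q1, q2 = vertex.centroid_nm, arm1.centroid_nm, arm2.centroid_nm
    a = float(np.linalg.norm(q1 - v))
    b = float(np.linalg.norm(q2 - v))
    c = float(np.linalg.norm(q2 - q1))
    theta = angle_at_vertex(v, q1, q2)
    return TripleAngle(
        vertex_nm=v, arm1_nm=q1, arm2_nm=q2, a_nm=a, b_nm=b, c_nm=c, theta_deg=theta
    )


def random_angle_baseline(n: int, seed: int = 0) -> tuple[float, float]:
    """Mean and median vertex angle (degrees) for ``n`` random point triples.

    Each triple is three points drawn i.i.d. uniform in the unit cube; the
    angle is measured at the middle (second) point.  By exchangeability of
    the three labels and the 180-degree angle sum of a triangle, the
    expectation is 60 degrees — the null against which measured probe-triple
    angles are compared.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3, 3))
    angles = angle_at_vertex(pts[:, 1], pts[:, 0], pts[:, 2])
    angles = np.atleast_1d(angles)
    return float(np.mean(angles)), float(np.median(angles))


def _midpoint_seed(seed1: SeedPoint, seed2: SeedPoint) -> tuple[int, int, int]:
    return (
        int(round((seed1.x + seed2.x) / 2.0)),
        int(round((seed1.y + seed2.y) / 2.0)),
        int(round((seed1.z + seed2.z) / 2.0)),
    )


def measure_pair(
    stack: ImageStack3D,
    seed_ch0: SeedPoint,
    seed_ch1: SeedPoint,
    params: SegmentationParams | None = None,
    crop: tuple[int, int, int] = DEFAULT_CROP,
) -> PairMeasurement:
    """Measure one signal pair: per-channel segmentation around each seed,
    inter-centroid distance, volumes, and Pearson correlation of congruent
    raw crops anchored at the rounded midpoint of the two seeds."""
    params = params or SegmentationParams()
    sub0 = extract_subvolume(stack, seed_ch0, crop)
    sub1 = extract_subvolume(stack, seed_ch1, crop)
    seg0 = segment_focus(sub0, params)
    seg1 = segment_focus(sub1, params)
    dist = pair_distance(seg0, seg1)

    mx, my, mz = _midpoint_seed(seed_ch0, seed_ch1)
    try:
        p0 = extract_subvolume(
            stack,
            SeedPoint(seed_ch0.stack_id, seed_ch0.locus_id, seed_ch0.channel_index, mx, my, mz),
            crop,
        )
        p1 = extract_subvolume(
            stack,
            SeedPoint(seed_ch1.stack_id, seed_ch1.locus_id, seed_ch1.channel_index, mx, my, mz),
            crop,
        )
        r = pearson_pair(p0, p1)
    except BoundaryError:
        r = float("nan")

    return PairMeasurement(
        stack_id=seed_ch0.stack_id,
        locus_id=seed_ch0.locus_id,
        distance_nm=dist,
        pearson_r=r,
        volume_um3_ch0=seg0.volume_um3,
        volume_um3_ch1=seg1.volume_um3,
        degenerate_ch0=seg0.degenerate,
        degenerate_ch1=seg1.degenerate,
        pearson_undefined=bool(np.isnan(r)),
        threshold_ch0=seg0.threshold,
        threshold_ch1=seg1.threshold,
    )
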