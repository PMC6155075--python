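"""Chromatic-aberration calibration from fiducial bead fields.

Multi-colour fiducial beads appear displaced between colour channels by the
instrument's chromatic aberration.  The apparent offset is estimated as the
mean centroid displacement of beads matched across channels, and removed by
translating the moving channel before any distance measurement.

The model is translation-only (a single shift per channel pair); no
field-dependent or scale/rotation terms are fitted.  Correction is applied
to the whole channel by trilinear interpolation; a coordinate-level fast
path (:func:`correct_centroid`) gives the same answer for point positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .foci import SegmentationParams, extract_subvolume, segment_focus, BoundaryError
from .imgio import ImageStack3D, SeedPoint, VoxelSize

__all__ = [
    "ChromaticOffset",
    "CalibrationError",
    "estimate_offset",
    "apply_offset",
    "correct_centroid",
    "detect_beads",
]


class CalibrationError(RuntimeError):
    """Raised when a bead field cannot support a valid calibration."""


@dataclass
class ChromaticOffset:
    """Mean apparent displacement (nm) of a moving channel relative to a
    reference channel, with calibration quality metadata."""

    channel_pair: tuple[int, int]  # (reference index, moving index)
    offset_nm: tuple[float, float, float]  # (dx, dy, dz)
    n_beads_used: int
    residual_nm: float  # RMS residual displacement after removing the mean

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "channel_pair": list(self.channel_pair),
                    "offset_nm": list(self.offset_nm),
                    "n_beads_used": self.n_beads_used,
                    "residual_nm": self.residual_nm,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromaticOffset":
        d = json.loads(Path(path).read_text())
        return cls(
            channel_pair=tuple(d["channel_pair"]),
            offset_nm=tuple(d["offset_nm"]),
            n_beads_used=int(d["n_beads_used"]),
            residual_nm=float(d["residual_nm"]),
        )


def detect_beads(
    stack: ImageStack3D,
    channel: int,
    min_distance_vox: int = 8,
    threshold_rel: float = 0.3,
) -> np.ndarray:
    """Integer (z, y, x) local-maximum positions of beads in one channel.

    Peaks are found on a lightly smoothed copy, above background by
    ``threshold_rel`` of the background-to-max range.
    """
    img = np.asarray(stack.channels[channel], dtype=np.float64)
    smooth = ndimage.gaussian_filter(img, sigma=(0.7, 1.0, 1.0))
    bg = float(np.median(smooth))
    thr = bg + threshold_rel * (float(smooth.max()) - bg)
    # borders are handled by the crop-boundary check during centroiding
    return peak_local_max(
        smooth, min_distance=min_distance_vox, threshold_abs=thr, exclude_border=False
    )


def _bead_centroids(
    stack: ImageStack3D,
    channel: int,
    crop: tuple[int, int, int] = (20, 20, 7),
) -> np.ndarray:
    """Refined bead centroids (nm) via the focus-segmentation machinery."""
    peaks = detect_beads(stack, channel)
    params = SegmentationParams()
    out = []
    for pz, py, px in peaks:
        seed = SeedPoint(stack.stack_id, f"bead_z{pz}y{py}x{px}", channel,
                         int(px), int(py), int(pz))
        try:
            seg = segment_focus(extract_subvolume(stack, seed, crop), params)
        except (BoundaryError, ValueError):
            continue
        if not seg.degenerate:
            out.append(seg.centroid_nm)
    return np.array(out) if out else np.empty((0, 3))


def _mutual_nearest(ref: np.ndarray, mov: np.ndarray, gate_nm: float) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour matches within a distance gate."""
    if len(ref) == 0 or len(mov) == 0:
        return []
    d = np.linalg.norm(ref[:, None, :] - mov[None, :, :], axis=-1)
    pairs = []
    for i in range(len(ref)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= gate_nm and int(np.argmin(d[:, j])) == i:
            pairs.append((i, j))
    return pairs


def estimate_offset(
    bead_stack: ImageStack3D,
    channel_pair: tuple[int, int] = (0, 1),
    gate_nm: float = 500.0,
) -> ChromaticOffset:
    """Estimate the chromatic offset of the moving channel from a bead field.

    Beads are detected and centroided independently in each channel, matched
    by mutual nearest neighbour within ``gate_nm``, and the mean displacement
    (moving minus reference) is returned together with the RMS residual.
    Unmatched beads are simply excluded.  Fewer than three matches is a
    calibration failure; collinear beads are fine since only a translation
    is fitted.
    """
    ref_idx, mov_idx = channel_pair
    ref = _bead_centroids(bead_stack, ref_idx)
    mov = _bead_centroids(bead_stack, mov_idx)
    pairs = _mutual_nearest(ref, mov, gate_nm)
    if len(pairs) < 3:
        raise CalibrationError(
            f"only {len(pairs)} beads matched between channels {channel_pair} "
            f"(need >= 3); detected {len(ref)} / {len(mov)} beads"
        )
    disp = np.array([mov[j] - ref[i] for i, j in pairs])
    offset = disp.mean(axis=0)
    residual = float(np.sqrt(np.mean(np.sum((disp - offset) ** 2, axis=1))))
    return ChromaticOffset(
        channel_pair=channel_pair,
        offset_nm=tuple(float(v) for v in offset),
        n_beads_used=len(pairs),
        residual_nm=residual,
    )


def apply_offset(stack: ImageStack3D, offset: ChromaticOffset) -> ImageStack3D:
    """Translate the moving channel by minus the estimated offset.

    Sub-voxel shifts use trilinear interpolation; voxels shifted in from
    outside the field are filled with the channel's background median
    (avoiding artificial dark rims at the borders).  The reference channel
    is untouched.  An exactly zero offset returns the stack unchanged
    bit-for-bit.
    """
    _, mov_idx = offset.channel_pair
    if not (0 <= mov_idx < stack.n_channels):
        raise ValueError(f"moving channel {mov_idx} not present in stack")
    vx = stack.voxel
    shift_vox = np.array(
        [
            -offset.offset_nm[2] / vx.dz_nm,  # z
            -offset.offset_nm[1] / vx.dy_nm,  # y
            -offset.offset_nm[0] / vx.dx_nm,  # x
        ]
    )
    if np.any(np.abs(shift_vox) >= np.array(stack.shape)):
        raise ValueError(
            f"offset {offset.offset_nm} nm exceeds the stack extent {stack.shape}"
        )
    out = stack.copy()
    if np.all(shift_vox == 0):
        return out
    ch = np.asarray(out.channels[mov_idx], dtype=np.float64)
    fill = float(np.median(ch))
    shifted = ndimage.shift(ch, shift_vox, order=1, mode="constant", cval=fill)
    out.channels[mov_idx] = np.clip(shifted, 0.0, None).astype(
        stack.channels[mov_idx].dtype
        if np.issubdtype(stack.channels[mov_idx].dtype, np.floating)
        else np.float32
    )
    return out


def correct_centroid(centroid_nm, offset: ChromaticOffset) -> np.ndarray:
    """Coordinate-level fast path: remove the offset from a moving-channel
    centroid instead of resampling the image."""
    return np.asarray(centroid_nm, dtype=float) - np.asarray(offset.offset_nm)
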