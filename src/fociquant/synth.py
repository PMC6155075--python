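"""Synthetic 3D microscopy scenes with known ground truth.

This module emulates the imaging regime the measurement pipeline was built
for: deconvolved widefield z-stacks at 64.5 x 64.5 x 150 nm voxels in which
genomic FISH probes appear as compact, bright, near-Gaussian foci on a low
background.  Two scene families are generated:

* **bead fields** — multi-colour fiducial beads (0.1 um for chromatic
  calibration, 500 nm for volume validation) rendered identically in two
  channels except for a known chromatic translation;
* **spot scenes** — nuclei-like fields of paired or triple probe signals
  with known true separations and vertex angles, plus a seed-point table
  emulating manual click selection.

Every generator is deterministic under a fixed seed and records its ground
truth (:class:`SceneTruth`), which downstream tests treat as the oracle.

The spot model is an anisotropic 3D Gaussian (sigma_xy 130 nm, sigma_z
300 nm by default), a reasonable stand-in for a deconvolved widefield PSF;
beads larger than the PSF are rendered as blurred spheres.  Noise is
Poisson shot noise on the signal plus Gaussian readout background
(mean 5, sd 2 counts by default — deconvolved stacks have little
background).  None of this models STED depletion physics, chromatin
texture or a real deconvolution algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .imgio import ImageStack3D, SeedPoint, VoxelSize

__all__ = [
    "SceneParams",
    "BeadFieldParams",
    "SceneTruth",
    "make_spot_scene",
    "make_bead_field",
    "resample_zstep",
]

SeparationModel = float | tuple[float, float]


def _draw(model: SeparationModel, rng: np.random.Generator) -> float:
    """Draw from a separation/arm-length/angle model: scalar = fixed value,
    2-tuple = uniform over [lo, hi]."""
    if isinstance(model, (int, float)):
        return float(model)
    lo, hi = model
    return float(rng.uniform(lo, hi))


@dataclass
class SceneParams:
    """Parameters of a synthetic paired/triple FISH scene.

    Distances are nm; ``shape`` is voxel counts (z, y, x). ``separation_nm``
    and ``arm_nm`` accept a scalar (fixed) or a ``(lo, hi)`` uniform range.
    """

    shape: tuple[int, int, int] = (21, 64, 64)
    voxel: VoxelSize = field(default_factory=VoxelSize)
    spot_sigma_xy_nm: float = 130.0
    spot_sigma_z_nm: float = 300.0
    peak_intensity: float = 200.0
    background_mean: float = 5.0
    background_sd: float = 2.0
    shot_noise: bool = True
    chromatic_offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_loci: int = 1
    separation_nm: SeparationModel = (300.0, 1000.0)
    geometry: str = "pair"  # "pair" | "triple"
    arm_nm: SeparationModel = (300.0, 800.0)  # triple arm lengths
    angle_deg: SeparationModel = (10.0, 170.0)  # triple vertex angle
    seed_jitter_vox: int = 2
    crop_size: tuple[int, int, int] = (20, 20, 7)  # (nx, ny, nz), for margins
    seed: int = 0
    stack_id: str = "scene"

    def __post_init__(self) -> None:
        if self.spot_sigma_xy_nm <= 0 or self.spot_sigma_z_nm <= 0:
            raise ValueError("spot sigmas must be positive")
        if self.peak_intensity <= 0:
            raise ValueError("peak_intensity must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be nonnegative")
        if self.geometry not in ("pair", "triple"):
            raise ValueError(f"geometry must be 'pair' or 'triple', got {self.geometry!r}")


@dataclass
class BeadFieldParams:
    """Parameters of a two-channel fiducial bead field.

    ``bead_diameter_nm`` defaults to 100 (calibration beads); use 500 for
    the volume-validation beads. ``applied_offset_nm`` is the translation of
    channel 1 relative to channel 0 that a calibration should recover.
    Beads are kept at least four diameters apart.
    """

    n_beads: int = 12
    bead_diameter_nm: float = 100.0
    applied_offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    peak_intensity: float = 200.0
    background_mean: float = 2.0
    background_sd: float = 1.0
    shot_noise: bool = True
    psf_sigma_xy_nm: float = 130.0
    psf_sigma_z_nm: float = 300.0
    stack_id: str = "beads"

    def __post_init__(self) -> None:
        if self.bead_diameter_nm <= 0:
            raise ValueError("bead_diameter_nm must be positive")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")


@dataclass
class SceneTruth:
    """Ground truth for a synthetic scene.

    ``spots``: one row per rendered signal — stack_id, locus_id,
    channel_index, x_nm, y_nm, z_nm (true, aberration-free positions).
    ``loci``: one row per locus — separation_nm and, for triples, arm
    lengths a_nm/b_nm, base c_nm and vertex angle_deg.
    ``offset_nm``: the chromatic translation applied to channel 1 at render
    time (the truth a calibration should recover).
    """

    spots: pd.DataFrame
    loci: pd.DataFrame
    offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def table(self) -> pd.DataFrame:
        """Flat per-spot table joining locus truth and the scene offset."""
        out = self.spots.merge(self.loci, on=["stack_id", "locus_id"], how="left")
        out["offset_dx_nm"] = self.offset_nm[0]
        out["offset_dy_nm"] = self.offset_nm[1]
        out["offset_dz_nm"] = self.offset_nm[2]
        return out

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering primitives


def _sigma_vox(voxel: VoxelSize, sigma_xy_nm: float, sigma_z_nm: float):
    return (
        sigma_z_nm / voxel.dz_nm,
        sigma_xy_nm / voxel.dy_nm,
        sigma_xy_nm / voxel.dx_nm,
    )


def _add_gaussian(vol, center_zyx, amp, sigma_zyx, nsigma=4.0):
    """Add an anisotropic Gaussian into `vol` over a +-nsigma window."""
    nz, ny, nx = vol.shape
    lo, hi, grids = [], [], []
    for dim, (c, s, n) in enumerate(zip(center_zyx, sigma_zyx, (nz, ny, nx))):
        a = max(0, int(math.floor(c - nsigma * s)))
        b = min(n, int(math.ceil(c + nsigma * s)) + 1)
        if a >= b:
            return
        lo.append(a)
        hi.append(b)
        grids.append(np.arange(a, b, dtype=np.float64))
    zz = ((grids[0] - center_zyx[0]) / sigma_zyx[0]) ** 2
    yy = ((grids[1] - center_zyx[1]) / sigma_zyx[1]) ** 2
    xx = ((grids[2] - center_zyx[2]) / sigma_zyx[2]) ** 2
    g = amp * np.exp(-0.5 * (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]))
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += g


def _add_bead(vol, center_zyx, amp, radius_nm, voxel, sigma_xy_nm, sigma_z_nm):
    """Add a PSF-blurred solid sphere (erfc radial edge profile).

    The z axis is rescaled by the PSF anisotropy so axial blur exceeds
    lateral blur, matching widefield imaging.
    """
    from scipy.special import erfc

    stretch = sigma_z_nm / sigma_xy_nm
    ext_xy = radius_nm + 4 * sigma_xy_nm
    ext_z = radius_nm * stretch + 4 * sigma_z_nm
    nz, ny, nx = vol.shape
    scale = (voxel.dz_nm, voxel.dy_nm, voxel.dx_nm)
    ext = (ext_z, ext_xy, ext_xy)
    lo, hi, grids = [], [], []
    for c, s, n, e in zip(center_zyx, scale, (nz, ny, nx), ext):
        a = max(0, int(math.floor(c - e / s)))
        b = min(n, int(math.ceil(c + e / s)) + 1)
        if a >= b:
            return
        lo.append(a)
        hi.append(b)
        grids.append((np.arange(a, b, dtype=np.float64) - c) * s)
    dz = grids[0] / stretch  # compress z so blur is isotropic in this frame
    dy, dx = grids[1], grids[2]
    r = np.sqrt(
        dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    )
    profile = 0.5 * erfc((r - radius_nm) / (math.sqrt(2.0) * sigma_xy_nm))
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * profile


def _finalize_channels(signals, rng, background_mean, background_sd, shot_noise):
    """Apply shot noise to the rendered signal and add readout background."""
    out = []
    for sig in signals:
        if shot_noise:
            sig = rng.poisson(sig).astype(np.float64)
        if background_sd > 0:
            bg = rng.normal(background_mean, background_sd, size=sig.shape)
        else:
            bg = background_mean
        out.append(np.clip(sig + bg, 0.0, None).astype(np.float32))
    return out


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _perpendicular_unit(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v = v - np.dot(v, u) * u
    n = np.linalg.norm(v)
    while n < 1e-9:  # pragma: no cover
        v = rng.normal(size=3)
        v = v - np.dot(v, u) * u
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# spot scenes


def _locus_centers(params: SceneParams, rng: np.random.Generator) -> list[np.ndarray]:
    """Lay loci out on a jittered xy grid; validate each tile is big enough.

    Returns centres in voxel coordinates (x, y, z) as float arrays.
    """
    nz, ny, nx = params.shape
    vx = params.voxel
    if params.n_loci == 0:
        return []
    grid = int(math.ceil(math.sqrt(params.n_loci)))
    tile_y, tile_x = ny / grid, nx / grid

    # worst-case lateral half-extent a locus needs inside its tile
    if params.geometry == "pair":
        max_reach_nm = _model_max(params.separation_nm) / 2.0
    else:
        max_reach_nm = _model_max(params.arm_nm)
    need_xy = (
        max_reach_nm / min(vx.dx_nm, vx.dy_nm)
        + max(params.crop_size[0], params.crop_size[1]) / 2.0
        + params.seed_jitter_vox
    )
    if tile_x / 2.0 < need_xy or tile_y / 2.0 < need_xy:
        raise ValueError(
            f"scene geometry infeasible: tiles of {tile_y:.0f}x{tile_x:.0f} voxels "
            f"cannot hold loci needing a half-extent of {need_xy:.1f} voxels; "
            "enlarge shape or reduce n_loci/separation"
        )
    centers = []
    for i in range(params.n_loci):
        gy, gx = divmod(i, grid)
        cy = (gy + 0.5) * tile_y + rng.uniform(-2, 2)
        cx = (gx + 0.5) * tile_x + rng.uniform(-2, 2)
        cz = (nz - 1) / 2.0 + rng.uniform(-1, 1)
        centers.append(np.array([cx, cy, cz]))
    return centers


def _model_max(model: SeparationModel) -> float:
    return float(model if isinstance(model, (int, float)) else model[1])


def make_spot_scene(
    params: SceneParams,
) -> tuple[ImageStack3D, SceneTruth, list[SeedPoint]]:
    """Render a two-channel scene of paired or triple FISH-like foci.

    Pairs place one spot per channel separated by a drawn true distance in a
    uniformly random 3D direction.  Triples place the vertex probe in
    channel 1 and the two flanking (arm) probes in channel 0, with drawn arm
    lengths and vertex angle.  Channel 1 is rendered translated by
    ``chromatic_offset_nm`` (the aberration the calibration stage removes);
    truth records aberration-free positions.  Returned seed points are the
    apparent spot positions rounded to voxels and jittered by up to
    ``seed_jitter_vox`` voxels per axis, emulating manual clicking, then
    clamped so the analysis crop fits inside the stack.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    vx = params.voxel
    scale = np.array([vx.dx_nm, vx.dy_nm, vx.dz_nm])
    sig_vox = _sigma_vox(vx, params.spot_sigma_xy_nm, params.spot_sigma_z_nm)
    offset = np.asarray(params.chromatic_offset_nm, dtype=float)

    signals = [np.zeros(params.shape, dtype=np.float64) for _ in range(2)]
    spot_rows, locus_rows = [], []
    # (channel, locus_id, true position nm) for later seed generation
    placed: list[tuple[int, str, np.ndarray]] = []

    for i, center_vox in enumerate(_locus_centers(params, rng)):
        locus_id = f"L{i:04d}"
        center_nm = center_vox * scale
        if params.geometry == "pair":
            d = _draw(params.separation_nm, rng)
            u = _unit_vector(rng)
            positions = {0: center_nm - 0.5 * d * u, 1: center_nm + 0.5 * d * u}
            locus_rows.append(
                dict(stack_id=params.stack_id, locus_id=locus_id, separation_nm=d)
            )
        else:
            a = _draw(params.arm_nm, rng)
            b = _draw(params.arm_nm, rng)
            theta = math.radians(_draw(params.angle_deg, rng))
            u1 = _unit_vector(rng)
            v = _perpendicular_unit(u1, rng)
            u2 = math.cos(theta) * u1 + math.sin(theta) * v
            arm1 = center_nm + a * u1
            arm2 = center_nm + b * u2
            positions = {(0, "arm1"): arm1, (0, "arm2"): arm2, (1, "vertex"): center_nm}
            c = float(np.linalg.norm(arm1 - arm2))
            locus_rows.append(
                dict(
                    stack_id=params.stack_id,
                    locus_id=locus_id,
                    a_nm=a,
                    b_nm=b,
                    c_nm=c,
                    angle_deg=math.degrees(theta),
                )
            )

        for key, pos_nm in positions.items():
            ch = key if isinstance(key, int) else key[0]
            role = locus_id if isinstance(key, int) else f"{locus_id}:{key[1]}"
            apparent = pos_nm + (offset if ch == 1 else 0.0)
            center_zyx = (apparent / scale)[::-1]
            _add_gaussian(signals[ch], center_zyx, params.peak_intensity, sig_vox)
            spot_rows.append(
                dict(
                    stack_id=params.stack_id,
                    locus_id=locus_id,
                    role=role,
                    channel_index=ch,
                    x_nm=pos_nm[0],
                    y_nm=pos_nm[1],
                    z_nm=pos_nm[2],
                )
            )
            placed.append((ch, role, apparent))

    channels = _finalize_channels(
        signals, rng, params.background_mean, params.background_sd, params.shot_noise
    )
    stack = ImageStack3D(channels, voxel=vx, stack_id=params.stack_id)

    # seed points: apparent position, voxel-rounded, jittered, crop-clamped
    ncx, ncy, ncz = params.crop_size
    seeds = []
    for ch, role, apparent in placed:
        idx = np.round(apparent / scale).astype(int)
        j = params.seed_jitter_vox
        if j > 0:
            idx = idx + rng.integers(-j, j + 1, size=3)
        x = int(np.clip(idx[0], ncx // 2, nx - 1 - (ncx - 1 - ncx // 2)))
        y = int(np.clip(idx[1], ncy // 2, ny - 1 - (ncy - 1 - ncy // 2)))
        z = int(np.clip(idx[2], ncz // 2, nz - 1 - (ncz - 1 - ncz // 2)))
        seeds.append(
            SeedPoint(
                stack_id=params.stack_id,
                locus_id=role,
                channel_index=ch,
                x=x,
                y=y,
                z=z,
            )
        )

    spot_cols = ["stack_id", "locus_id", "role", "channel_index", "x_nm", "y_nm", "z_nm"]
    locus_cols = (
        ["stack_id", "locus_id", "separation_nm"]
        if params.geometry == "pair"
        else ["stack_id", "locus_id", "a_nm", "b_nm", "c_nm", "angle_deg"]
    )
    truth = SceneTruth(
        spots=pd.DataFrame(spot_rows, columns=spot_cols),
        loci=pd.DataFrame(locus_rows, columns=locus_cols),
        offset_nm=tuple(float(o) for o in offset),
    )
    return stack, truth, seeds


# ---------------------------------------------------------------------------
# bead fields


def make_bead_field(
    params: BeadFieldParams,
    voxel: VoxelSize | None = None,
    shape: tuple[int, int, int] = (21, 128, 128),
) -> tuple[ImageStack3D, SceneTruth]:
    """Render a two-channel fiducial bead field with a known chromatic offset.

    Channel 0 holds beads at random positions (pairwise separation at least
    four bead diameters, and clear of the borders); channel 1 holds the same
    beads translated by ``applied_offset_nm``.  Small beads (diameter below
    half the lateral PSF FWHM) render as Gaussians; larger beads as
    PSF-blurred spheres.
    """
    vx = voxel or VoxelSize()
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = shape
    scale = np.array([vx.dx_nm, vx.dy_nm, vx.dz_nm])
    # at least four diameters apart, and never closer than the analysis crop
    # is wide: calibration slides are sparse, and two beads inside one
    # 20x20-pixel sub-volume would corrupt each other's centroids
    min_sep_nm = max(4.0 * params.bead_diameter_nm, 20.0 * vx.dx_nm + 2 * params.psf_sigma_xy_nm)

    # margins: analysis crop half-size plus bead/PSF extent, plus offset room
    off = np.asarray(params.applied_offset_nm, dtype=float)
    margin_xy = 12 + math.ceil(
        (params.bead_diameter_nm / 2 + 2 * params.psf_sigma_xy_nm + abs(off[:2]).max())
        / min(vx.dx_nm, vx.dy_nm)
    )
    margin_z = 4 + math.ceil(
        (params.bead_diameter_nm / 2 + params.psf_sigma_z_nm + abs(off[2]))
        / vx.dz_nm
    )
    lo = np.array([margin_xy, margin_xy, margin_z], dtype=float)
    hi = np.array([nx - 1 - margin_xy, ny - 1 - margin_xy, nz - 1 - margin_z])
    if np.any(hi <= lo):
        raise ValueError(f"shape {shape} too small for bead margins ({margin_xy}, {margin_z})")

    positions_nm: list[np.ndarray] = []
    attempts = 0
    while len(positions_nm) < params.n_beads and attempts < 200 * params.n_beads:
        attempts += 1
        cand = rng.uniform(lo, hi) * scale
        if all(np.linalg.norm(cand - p) >= min_sep_nm for p in positions_nm):
            positions_nm.append(cand)
    if len(positions_nm) < params.n_beads:
        raise ValueError(
            f"could not pack {params.n_beads} beads at >= {min_sep_nm:.0f} nm spacing "
            f"into shape {shape}; achievable count: {len(positions_nm)}"
        )

    signals = [np.zeros(shape, dtype=np.float64) for _ in range(2)]
    small = params.bead_diameter_nm < 1.2 * params.psf_sigma_xy_nm
    sig_vox = _sigma_vox(vx, params.psf_sigma_xy_nm, params.psf_sigma_z_nm)
    spot_rows = []
    for i, pos in enumerate(positions_nm):
        for ch in range(2):
            apparent = pos + (off if ch == 1 else 0.0)
            center_zyx = (apparent / scale)[::-1]
            if small:
                _add_gaussian(signals[ch], center_zyx, params.peak_intensity, sig_vox)
            else:
                _add_bead(
                    signals[ch],
                    center_zyx,
                    params.peak_intensity,
                    params.bead_diameter_nm / 2.0,
                    vx,
                    params.psf_sigma_xy_nm,
                    params.psf_sigma_z_nm,
                )
            spot_rows.append(
                dict(
                    stack_id=params.stack_id,
                    locus_id=f"B{i:03d}",
                    role=f"B{i:03d}",
                    channel_index=ch,
                    x_nm=pos[0],
                    y_nm=pos[1],
                    z_nm=pos[2],
                )
            )
    channels = _finalize_channels(
        signals, rng, params.background_mean, params.background_sd, params.shot_noise
    )
    stack = ImageStack3D(channels, voxel=vx, stack_id=params.stack_id)
    truth = SceneTruth(
        spots=pd.DataFrame(spot_rows),
        loci=pd.DataFrame(columns=["stack_id", "locus_id"]),
        offset_nm=tuple(float(o) for o in off),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# z-step resampling


def resample_zstep(stack: ImageStack3D, new_dz_nm: float) -> ImageStack3D:
    """Linearly resample a stack's planes at a new z spacing.

    The physical depth spanned by the plane centres is preserved; the output
    has ``floor(depth / new_dz) + 1`` planes at positions ``j * new_dz``.
    Used to compare measurements at 100 / 150 / 200 nm z-steps.
    """
    if new_dz_nm <= 0:
        raise ValueError("new_dz_nm must be positive")
    nz = stack.shape[0]
    depth = (nz - 1) * stack.voxel.dz_nm
    if new_dz_nm > depth:
        raise ValueError(
            f"new z spacing {new_dz_nm} nm exceeds the stack depth {depth} nm"
        )
    n_new = int(math.floor(depth / new_dz_nm)) + 1
    pos = np.arange(n_new) * new_dz_nm / stack.voxel.dz_nm  # fractional old index
    k = np.minimum(pos.astype(int), nz - 2)
    w = (pos - k)[:, None, None]
    new_channels = []
    for c in stack.channels:
        out = (1.0 - w) * c[k] + w * c[k + 1]
        new_channels.append(out.astype(np.float32))
    new_voxel = VoxelSize(stack.voxel.dx_nm, stack.voxel.dy_nm, new_dz_nm)
    return ImageStack3D(new_channels, voxel=new_voxel, stack_id=stack.stack_id)
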