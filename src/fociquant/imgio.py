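"""Image-stack and probe data model, physical-geometry conversions and file I/O.

Conventions used throughout the package
---------------------------------------
* Intensity arrays are indexed ``(z, y, x)`` internally (the microscopy
  stacking order); user-facing coordinates are reported ``(x, y, z)``.
* Voxel indices are 0-based and refer to voxel *centres*; a fractional
  index is a sub-voxel position.
* Physical positions are in nanometres, obtained by multiplying the index
  by the voxel edge length on each axis.
* Genomic probe coordinates are 1-based inclusive (genome-browser display
  convention), so a probe spanning a single base has length 1 bp.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelSize",
    "ImageStack3D",
    "ProbeRecord",
    "SeedPoint",
    "read_stack",
    "write_stack",
    "physical_position",
    "genomic_span",
    "read_seed_points",
    "write_seed_points",
    "write_probes_bed",
]

#: default widefield acquisition geometry: 64.5 nm pixels, 150 nm z-step
DEFAULT_VOXEL_NM = (64.5, 64.5, 150.0)


@dataclass(frozen=True)
class VoxelSize:
    """Physical edge lengths of one voxel, in nanometres."""

    dx_nm: float = DEFAULT_VOXEL_NM[0]
    dy_nm: float = DEFAULT_VOXEL_NM[1]
    dz_nm: float = DEFAULT_VOXEL_NM[2]

    def __post_init__(self) -> None:
        for name in ("dx_nm", "dy_nm", "dz_nm"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"VoxelSize.{name} must be strictly positive, got {v!r}")

    @property
    def volume_nm3(self) -> float:
        """Volume of one voxel in nm^3 (exact product of the edges)."""
        return self.dx_nm * self.dy_nm * self.dz_nm

    @property
    def volume_um3(self) -> float:
        """Volume of one voxel in um^3. Default geometry: 6.240375e-4."""
        return self.volume_nm3 / 1e9

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx_nm, self.dy_nm, self.dz_nm)


@dataclass
class ImageStack3D:
    """A multi-channel 3D intensity grid with physical voxel geometry.

    ``channels`` is an ordered list of nonnegative arrays, each indexed
    ``(z, y, x)``; all channels share one shape.
    """

    channels: list[np.ndarray]
    voxel: VoxelSize = field(default_factory=VoxelSize)
    stack_id: str = ""

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("ImageStack3D needs at least one channel")
        self.channels = [np.asarray(c) for c in self.channels]
        shape0 = self.channels[0].shape
        if len(shape0) != 3:
            raise ValueError(f"channels must be 3D (z, y, x); got shape {shape0}")
        for i, c in enumerate(self.channels):
            if c.shape != shape0:
                raise ValueError(
                    f"channel {i} shape {c.shape} differs from channel 0 shape {shape0}"
                )
            if c.size and float(c.min()) < 0:
                raise ValueError(f"channel {i} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) of every channel."""
        return self.channels[0].shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def copy(self) -> "ImageStack3D":
        return ImageStack3D(
            [c.copy() for c in self.channels], voxel=self.voxel, stack_id=self.stack_id
        )


@dataclass(frozen=True)
class ProbeRecord:
    """A FISH probe as a genomic interval (1-based inclusive coordinates)."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(f"start_bp must be >= 1, got {self.start_bp}")
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"start_bp ({self.start_bp}) must not exceed end_bp ({self.end_bp})"
            )


@dataclass(frozen=True)
class SeedPoint:
    """A manually (or synthetically) identified candidate focus position.

    ``x, y, z`` are 0-based integer voxel indices into the referenced stack.
    """

    stack_id: str
    locus_id: str
    channel_index: int
    x: int
    y: int
    z: int


def physical_position(
    index_xyz: Sequence[float], voxel: VoxelSize
) -> np.ndarray:
    """Convert a (possibly fractional) voxel index (x, y, z) to nm (X, Y, Z).

    Positions refer to voxel centres; the map is componentwise linear.
    """
    idx = np.asarray(index_xyz, dtype=float)
    scale = np.array([voxel.dx_nm, voxel.dy_nm, voxel.dz_nm])
    return idx * scale


def genomic_span(probe: ProbeRecord) -> tuple[int, int]:
    """Return (span_bp, span_kb) of a probe.

    span_bp counts both endpoints (1-based inclusive interval); span_kb is
    span_bp/1000 rounded half-up to the nearest integer, the convention used
    when quoting probe sizes like "64 kb" or "~7 kb".
    """
    span_bp = probe.end_bp - probe.start_bp + 1
    span_kb = int(np.floor(span_bp / 1000 + 0.5))
    return span_bp, span_kb


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(stack: ImageStack3D, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with voxel size embedded as physical-size
    metadata (micrometres, the OME convention). Integer data are lossless.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = np.stack(stack.channels)  # (C, Z, Y, X)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.voxel.dx_nm / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.voxel.dy_nm / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.voxel.dz_nm / 1000.0,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path


def _voxel_from_ome(ome_xml: str) -> VoxelSize | None:
    """Extract physical voxel size (nm) from OME-XML, or None if absent."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pixels is None:
        return None
    sizes = {}
    for ax in ("X", "Y", "Z"):
        v = pixels.get(f"PhysicalSize{ax}")
        if v is None:
            return None
        unit = pixels.get(f"PhysicalSize{ax}Unit", "µm")
        factor = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "mm": 1e6}.get(unit)
        if factor is None:
            return None
        sizes[ax] = float(v) * factor
    return VoxelSize(dx_nm=sizes["X"], dy_nm=sizes["Y"], dz_nm=sizes["Z"])


def read_stack(
    path: str | Path,
    voxel: VoxelSize | None = None,
    stack_id: str | None = None,
) -> ImageStack3D:
    """Read a multi-page TIFF / OME-TIFF into an :class:`ImageStack3D`.

    Channel and z ordering follow the axes declared in the file metadata
    (series axes such as ``CZYX`` or ``ZYX``). A ``voxel`` argument always
    overrides any physical-size metadata found in the file; if the file has
    no usable metadata and no override is given, an error names the missing
    field rather than guessing.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        file_voxel = _voxel_from_ome(tif.ome_metadata) if tif.ome_metadata else None

    # normalise to (C, Z, Y, X)
    axes = axes.replace("S", "C").replace("I", "Z").replace("Q", "Z")
    if set(axes) - set("CZYX"):
        raise ValueError(f"unsupported TIFF axes {axes!r} in {path}")
    for missing in set("CZYX") - set(axes):
        data = np.expand_dims(data, 0)
        axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    use_voxel = voxel or file_voxel
    if use_voxel is None:
        raise ValueError(
            f"{path}: no physical voxel size in metadata and no 'voxel' override "
            "supplied (missing field: PhysicalSizeX/Y/Z)"
        )
    return ImageStack3D(
        [np.ascontiguousarray(data[c]) for c in range(data.shape[0])],
        voxel=use_voxel,
        stack_id=stack_id if stack_id is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# Seed-point tables and probe export

SEED_COLUMNS = ["stack_id", "locus_id", "channel_index", "x", "y", "z"]


def write_seed_points(seeds: Iterable[SeedPoint], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(s.stack_id, s.locus_id, s.channel_index, s.x, s.y, s.z) for s in seeds],
        columns=SEED_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_seed_points(path: str | Path) -> list[SeedPoint]:
    df = pd.read_csv(path)
    missing = [c for c in SEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"seed-point table {path} missing columns: {missing}")
    return [
        SeedPoint(
            stack_id=str(r.stack_id),
            locus_id=str(r.locus_id),
            channel_index=int(r.channel_index),
            x=int(r.x),
            y=int(r.y),
            z=int(r.z),
        )
        for r in df.itertuples()
    ]


def write_probes_bed(probes: Iterable[ProbeRecord], path: str | Path) -> Path:
    """Export probes as BED (0-based half-open) for genome-browser display."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p.chrom}\t{p.start_bp - 1}\t{p.end_bp}\t{p.name}\n")
    return path
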