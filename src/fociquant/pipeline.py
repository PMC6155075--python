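"""End-to-end orchestration: simulate -> calibrate -> measure -> stats.

A :class:`RunConfig` describes one reproducible run, either on synthetic
scenes (the generator parameters) or on real inputs (stack + seed table +
optional saved calibration).  Every run is deterministic under its seed and
writes a provenance sidecar echoing the full configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chromatic, foci, statsmod, synth
from .imgio import ImageStack3D, SeedPoint, VoxelSize, read_seed_points, read_stack, write_stack

__all__ = ["RunConfig", "run_pipeline", "measurement_table", "measure_at_zsteps"]

log = logging.getLogger("fociquant")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (generator parameters) or ``inputs``
    (paths to a stack and a seed table) must be set.
    """

    out_dir: str = "fociquant_out"
    seed: int = 0
    simulate: dict | None = None  # kwargs for synth.SceneParams
    inputs: dict | None = None  # {"stack": path, "seeds": path, "calibration": path?}
    voxel_nm: tuple[float, float, float] = (64.5, 64.5, 150.0)
    crop: tuple[int, int, int] = (20, 20, 7)
    segmentation: dict = field(default_factory=dict)  # kwargs for SegmentationParams
    calibrate: bool = False  # simulate a bead field and correct before measuring
    bead_field: dict = field(default_factory=dict)  # kwargs for synth.BeadFieldParams
    qc_images: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        active = [k for k in ("simulate", "inputs") if getattr(self, k) is not None]
        if len(active) != 1:
            raise ValueError(
                f"exactly one of 'simulate' or 'inputs' must be set; got {active or 'neither'}"
            )
        if self.inputs is not None:
            missing = {"stack", "seeds"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs config missing keys: {sorted(missing)}")
        bad = set(self.segmentation) - {
            f.name for f in dataclasses.fields(foci.SegmentationParams)
        }
        if bad:
            raise ValueError(f"unknown segmentation keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        for name in ("voxel_nm", "crop"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_nm"] = list(self.voxel_nm)
        d["crop"] = list(self.crop)
        return d


def _pair_seeds(seeds: Sequence[SeedPoint]) -> list[tuple[SeedPoint, SeedPoint]]:
    """Group seeds into (channel 0, channel 1) pairs by locus id."""
    by_locus: dict[str, dict[int, SeedPoint]] = {}
    for s in seeds:
        by_locus.setdefault(s.locus_id, {})[s.channel_index] = s
    pairs = []
    for locus in sorted(by_locus):
        chans = by_locus[locus]
        if 0 in chans and 1 in chans:
            pairs.append((chans[0], chans[1]))
    return pairs


MEASUREMENT_COLUMNS = [
    "stack_id", "locus_id", "distance_nm", "pearson_r",
    "volume_um3_ch0", "volume_um3_ch1",
    "degenerate_ch0", "degenerate_ch1", "pearson_undefined",
    "threshold_ch0", "threshold_ch1",
]


def measurement_table(
    stack: ImageStack3D,
    seeds: Sequence[SeedPoint],
    params: foci.SegmentationParams | None = None,
    crop: tuple[int, int, int] = foci.DEFAULT_CROP,
) -> pd.DataFrame:
    """Measure every (channel 0, channel 1) seed pair in a stack.

    Loci whose crop crosses the stack boundary are skipped with a warning;
    degenerate segmentations are kept as flagged rows.
    """
    rows = []
    for s0, s1 in _pair_seeds(seeds):
        try:
            m = foci.measure_pair(stack, s0, s1, params, crop)
        except foci.BoundaryError as e:
            log.warning("skipping locus: %s", e)
            continue
        rows.append(dataclasses.asdict(m))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def measure_at_zsteps(
    stack: ImageStack3D,
    seeds: Sequence[SeedPoint],
    zsteps_nm: Sequence[float] = (100.0, 150.0, 200.0),
    params: foci.SegmentationParams | None = None,
    crop: tuple[int, int, int] = foci.DEFAULT_CROP,
) -> dict[float, pd.DataFrame]:
    """Re-measure the same loci on z-resampled copies of a stack.

    Seed z indices are rescaled to the new plane spacing.  Used to quantify
    the z-step tolerance of the distance measurements.
    """
    out = {}
    for dz in zsteps_nm:
        if abs(dz - stack.voxel.dz_nm) < 1e-9:
            variant, factor = stack, 1.0
        else:
            variant = synth.resample_zstep(stack, dz)
            factor = stack.voxel.dz_nm / dz
        nz = variant.shape[0]
        zlo, zhi = crop[2] // 2, nz - 1 - (crop[2] - 1 - crop[2] // 2)
        reseeds = [
            SeedPoint(
                s.stack_id, s.locus_id, s.channel_index, s.x, s.y,
                int(np.clip(round(s.z * factor), zlo, zhi)),
            )
            for s in seeds
        ]
        out[dz] = measurement_table(variant, reseeds, params, crop)
    return out


def _qc_montage(stack, s0, s1, seg0, seg1, crop, path):
    """Mid-plane montage of both channel crops with mask outline + centroid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(6, 3))
    for ax, seed, seg in ((axes[0], s0, seg0), (axes[1], s1, seg1)):
        sub = foci.extract_subvolume(stack, seed, crop)
        mid = sub.data.shape[0] // 2
        ax.imshow(sub.data[mid], cmap="magma")
        ax.contour(seg.mask[mid].astype(float), levels=[0.5], colors="cyan", linewidths=0.8)
        cx = seg.centroid_nm[0] / sub.voxel.dx_nm - sub.origin[0]
        cy = seg.centroid_nm[1] / sub.voxel.dy_nm - sub.origin[1]
        ax.plot(cx, cy, "g+", markersize=10)
        ax.set_title(f"ch{seed.channel_index} {seed.locus_id}", fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> (calibrate) -> measure -> stats and write outputs.

    Returns a dict of the in-memory results (measurements DataFrame, summary
    DataFrame, recovery report if truth is available, output paths).
    Flagged loci never abort a run; configuration errors raise before any
    output is written.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    voxel = VoxelSize(*config.voxel_nm)
    seg_params = foci.SegmentationParams(**config.segmentation)
    rng_seq = np.random.SeedSequence(config.seed)
    child = [int(s) % (2**31) for s in rng_seq.generate_state(4)]

    truth = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", child[0])
        sim_kwargs["voxel"] = voxel
        if "shape" in sim_kwargs:
            sim_kwargs["shape"] = tuple(sim_kwargs["shape"])
        params = synth.SceneParams(**sim_kwargs)
        stack, truth, seeds = synth.make_spot_scene(params)
        write_stack(stack, out / "scene.ome.tif")
        truth.to_csv(out / "truth.csv")
        from .imgio import write_seed_points

        write_seed_points(seeds, out / "seeds.csv")
        log.info("simulated %d loci into %s", params.n_loci, out)
    else:
        stack = read_stack(config.inputs["stack"], voxel=voxel)
        seeds = read_seed_points(config.inputs["seeds"])
        if config.inputs.get("calibration"):
            offset = chromatic.ChromaticOffset.from_json(config.inputs["calibration"])
            stack = chromatic.apply_offset(stack, offset)
            log.info("applied saved calibration %s", offset.offset_nm)

    calibration = None
    if config.calibrate:
        bead_kwargs = dict(config.bead_field)
        bead_kwargs.setdefault("seed", child[1])
        if config.simulate is not None:
            # the bead field must carry the same aberration as the scene
            bead_kwargs.setdefault(
                "applied_offset_nm",
                tuple(config.simulate.get("chromatic_offset_nm", (0.0, 0.0, 0.0))),
            )
        bead_params = synth.BeadFieldParams(**bead_kwargs)
        bead_stack, _ = synth.make_bead_field(bead_params, voxel=voxel)
        calibration = chromatic.estimate_offset(bead_stack)
        calibration.to_json(out / "calibration.json")
        stack = chromatic.apply_offset(stack, calibration)
        log.info(
            "calibrated offset %s nm from %d beads (residual %.1f nm)",
            tuple(round(v, 1) for v in calibration.offset_nm),
            calibration.n_beads_used,
            calibration.residual_nm,
        )

    measurements = measurement_table(stack, seeds, seg_params, config.crop)
    measurements.to_csv(out / "measurements.csv", index=False)

    summary = statsmod.summarize_pairs(measurements) if len(measurements) else pd.DataFrame()
    summary.to_csv(out / "summary.csv", index=False)

    recovery = None
    if truth is not None and len(measurements) and len(truth.loci):
        if "separation_nm" in truth.loci.columns:
            recovery = statsmod.evaluate_recovery(measurements, truth.loci)
            (out / "recovery.json").write_text(
                json.dumps(dataclasses.asdict(recovery), indent=2)
            )

    if config.qc_images and len(measurements):
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        for s0, s1 in _pair_seeds(seeds):
            try:
                sub0 = foci.extract_subvolume(stack, s0, config.crop)
                sub1 = foci.extract_subvolume(stack, s1, config.crop)
                seg0 = foci.segment_focus(sub0, seg_params)
                seg1 = foci.segment_focus(sub1, seg_params)
                _qc_montage(stack, s0, s1, seg0, seg1, config.crop,
                            qc_dir / f"{s0.locus_id}.png")
            except (foci.BoundaryError, ValueError):
                continue

    provenance = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_loci_measured": int(len(measurements)),
        "calibration": dataclasses.asdict(calibration) if calibration else None,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    return {
        "measurements": measurements,
        "summary": summary,
        "recovery": recovery,
        "calibration": calibration,
        "out_dir": out,
    }
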