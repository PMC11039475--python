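"""End-to-end pipeline driver.

Runs simulate → (optional CT round trip) → segment → zonate → measure →
report, writing every stage's outputs plus seeds and a configuration hash
into a canonical run-directory layout so runs are reproducible and
resumable stage by stage:

    run_dir/{phantom, recon, segmentation, zones, measurements, report}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import phantom as ph
from . import recon as rc
from .errors import ConfigurationError
from .morphometry import measure_infarcts, summarize_lobe
from .segmentation import (SegmentationConfig, label_components,
                           segment_infarcts_threshold,
                           segment_vessels_region_growing)
from .volume import VoxelVolume, write_volume
from .zonation import equal_volume_zonation

log = logging.getLogger("infarct3d")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run."""

    scale: str = "lobe"                 # "lobe" | "submicron"
    day: str = "1"
    grid: int = 96
    seed: int = 0
    out_dir: str = "run"
    microchannels: bool = False         # submicron only
    do_recon: bool = False              # full CT round trip before analysis
    n_angles: int = 200
    noise_photons: float = 20000.0
    zonation_tol: float = 0.005
    grow_tolerance: float = 0.08
    min_component_um3: float | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scale not in ("lobe", "submicron"):
            raise ConfigurationError(f"scale must be 'lobe' or 'submicron', got {self.scale!r}")
        if self.day not in ph.DAYS:
            raise ConfigurationError(f"day must be one of {ph.DAYS}, got {self.day!r}")
        if self.scale == "lobe" and self.microchannels:
            raise ConfigurationError(
                "microchannels are sub-voxel at the lobe scale (3.25 µm); "
                "enable them only with scale='submicron'")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _params_for(config: PipelineConfig) -> ph.PhantomParams:
    if config.scale == "lobe":
        return ph.lobe_preset(config.day, grid=config.grid, seed=config.seed)
    p = ph.submicron_preset(config.day, grid=config.grid, seed=config.seed)
    if not config.microchannels:
        p = p.replace(microchannel_count_mean=0.0)
    return p


def _seed_voxels(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """One deterministic interior seed (EDT maximum) per connected piece of
    a mask — the stand-in for the manual per-vessel seed clicks."""
    from scipy import ndimage
    if not mask.any():
        return []
    lbl, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 3))
    edt = ndimage.distance_transform_edt(mask)
    seeds = []
    for i in range(1, n + 1):
        piece = lbl == i
        masked = np.where(piece, edt, -1.0)
        seeds.append(tuple(int(v) for v in
                           np.unravel_index(np.argmax(masked), mask.shape)))
    return seeds


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the paths of the stage outputs."""
    logging.basicConfig(level=config.log_level)
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config.to_yaml())
    chash = config.config_hash
    meta = {"config_hash": chash, "seed": config.seed}
    paths = {"run_dir": run_dir}

    def _stage(name):
        d = run_dir / name
        d.mkdir(exist_ok=True)
        return d

    try:
        stage = "phantom"
        params = _params_for(config)
        truth, zones_true, volume = ph.generate_phantom(params, config.zonation_tol)
        d = _stage("phantom")
        truth.save(d / "truth")
        write_volume(volume, d / "grayscale.tif", day=config.day, **meta)
        paths["phantom"] = d

        analysis_volume = volume
        if config.do_recon:
            stage = "recon"
            d = _stage("recon")
            geo_preset = rc.LOBE_GEOMETRY if config.scale == "lobe" else rc.SUBMICRON_GEOMETRY
            geo = rc.BeamGeometry(energy_keV=geo_preset.energy_keV,
                                  distance_cm=geo_preset.distance_cm,
                                  pixel_size_um=geo_preset.pixel_size_um,
                                  n_angles=config.n_angles)
            optical = rc.grayscale_to_optical(volume)
            rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 91]))
            acq = rc.simulate_projections(optical, geo, config.noise_photons, rng=rng)
            corrected = rc.correct_projection_set(acq)
            retrieved = rc.phase_retrieve(corrected, rc.DELTA_BETA_RATIO_TISSUE)
            mu = rc.fbp_reconstruct(retrieved)
            write_volume(mu, d / "mu.tif", **meta)
            # rescale μ back to the grayscale range for downstream segmentation
            lo, hi = np.percentile(mu.data, [0.5, 99.5])
            rescaled = np.clip((mu.data - lo) / max(hi - lo, 1e-12), 0, 1) \
                * float(volume.data.max())
            analysis_volume = VoxelVolume(rescaled, volume.voxel_size_um)
            paths["recon"] = d

        stage = "segmentation"
        d = _stage("segmentation")
        seeds = []
        for name, mask in (("portal", truth.portal_mask),
                           ("central", truth.central_mask),
                           ("sinusoid", truth.sinusoid_mask)):
            seeds.extend((name, sv) for sv in _seed_voxels(mask))
        min_comp = config.min_component_um3
        if min_comp is None:
            min_comp = SegmentationConfig().min_component_um3 \
                if config.scale == "lobe" else 50.0
        seg_cfg = SegmentationConfig(vessel_seeds=seeds,
                                     grow_tolerance=config.grow_tolerance,
                                     min_component_um3=min_comp)
        vessels = segment_vessels_region_growing(analysis_volume, seg_cfg)
        vessel_mask = vessels.labels > 0
        exclude = vessel_mask
        if config.do_recon:
            # everything outside the reconstructed cylinder is rim/air, not tissue
            nz, ny, nx = analysis_volume.shape
            yy, xx = np.mgrid[0:ny, 0:nx]
            outside = (yy - ny // 2) ** 2 + (xx - nx // 2) ** 2 \
                >= (min(ny, nx) / 2.0 - 3.0) ** 2
            exclude = vessel_mask | np.broadcast_to(outside[None], (nz, ny, nx))
        infarct_mask = segment_infarcts_threshold(analysis_volume, seg_cfg, exclude)
        labeled, comp_table = label_components(infarct_mask, params.voxel_size_um, seg_cfg)
        tifffile.imwrite(d / "vessels.tif", vessels.labels.astype(np.int16))
        tifffile.imwrite(d / "infarcts.tif", labeled.astype(np.int32))
        comp_table.to_csv(d / "components.csv", index=False)
        paths["segmentation"] = d

        stage = "zones"
        d = _stage("zones")
        name_to_label = {n: i + 1 for i, n in enumerate(vessels.label_names)}
        central = vessels.labels == name_to_label.get("central", -1)
        portal = vessels.labels == name_to_label.get("portal", -1)
        parenchyma = ~vessel_mask & ~infarct_mask
        zones = equal_volume_zonation(parenchyma, central, portal,
                                      params.voxel_size_um, tol=config.zonation_tol)
        tifffile.imwrite(d / "zones.tif", zones.zones)
        (d / "zones.json").write_text(json.dumps({
            "r3_um": zones.r3_um, "r2_um": zones.r2_um,
            "fractions": list(zones.achieved_fractions), **meta}, indent=1))
        paths["zones"] = d

        stage = "measurements"
        d = _stage("measurements")
        kw = {}
        if config.microchannels:
            sin_mask = vessels.labels == name_to_label.get("sinusoid", -1)
            lumen_thr = params.gray_levels["channel"] + 0.5 * (
                params.gray_levels["infarct"] - params.gray_levels["channel"])
            kw = {"sinusoid_mask": sin_mask,
                  "lumen_mask": np.asarray(analysis_volume.data) < lumen_thr}
        records = measure_infarcts(labeled, params.voxel_size_um, zones, **kw)
        rec_df = pd.DataFrame([{
            "id": r.id, "volume_um3": r.V, "surface_um2": r.A, "sphericity": r.psi,
            "zone": r.zone, "confluence": r.confluence, "n_cores": r.n_cores,
            "n_channels": r.n_channels, "border": r.border} for r in records])
        rec_df.to_csv(d / "infarcts.csv", index=False)
        paths["measurements"] = d

        stage = "report"
        d = _stage("report")
        lobe_vol = float(parenchyma.sum() + infarct_mask.sum()) * params.voxel_size_um ** 3
        summary = summarize_lobe(records, lobe_vol, zones)
        (d / "summary.json").write_text(json.dumps({
            "day": config.day, "n_infarcts": summary.n_infarcts,
            "total_volume_um3": summary.total_volume_um3,
            "lobe_volume_um3": summary.lobe_volume_um3,
            "volume_ratio": summary.volume_ratio,
            "confluent_fraction": summary.confluent_fraction,
            "mean_channels_per_infarct": summary.mean_channels_per_infarct,
            "per_zone": {str(z): {k: v for k, v in pz.items() if k != "sphericities"}
                         for z, pz in summary.per_zone.items()},
            **meta}, indent=1, default=float))
        paths["report"] = d
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed (config {chash}): {exc}") \
            from exc
    log.info("pipeline complete: %s (config %s)", run_dir, chash)
    return paths
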