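"""Parameter-recovery experiments at the study conditions.

These protocols regenerate phantoms from the day presets, run the analysis
pipeline on them, and compare what the pipeline measures against what the
generator put in.  They back both the validation suite and the
reproduction script; sizes default to desk-scale grids that keep each
protocol in the minutes range on one CPU (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from . import recon as rc
from .morphometry import classify_confluence, detect_microchannels, \
    estimate_tube_diameter
from .phantom import generate_phantom, lobe_preset, rasterize_tube, \
    submicron_preset
from .segmentation import SegmentationConfig, label_components, \
    segment_infarcts_threshold
from .zonation import assign_infarct_zones

__all__ = [
    "microchannel_recovery", "tube_diameter_recovery", "lobe_recovery",
    "confluence_summary", "growth_summary", "detectability", "type_i_error",
]


def microchannel_recovery(day: str, seeds, n_infarcts: int = 25,
                          grid: int = 160) -> pd.DataFrame:
    """Generate submicron phantoms and re-detect their microchannels.

    Returns one row per lesion component per seed with the true and the
    detected channel count.
    """
    rows = []
    for seed in seeds:
        params = submicron_preset(day, grid=grid, seed=int(seed),
                                  n_infarcts=n_infarcts)
        truth, _, vol = generate_phantom(params)
        comp = truth.infarct_components()
        g = params.gray_levels
        lumen = np.asarray(vol.data) < (g["channel"] + g["infarct"]) / 2.0
        det = detect_microchannels(
            comp, truth.sinusoid_mask, lumen, truth.voxel_size_um,
            exclude_mask=truth.portal_mask | truth.central_mask)
        found = dict(zip(det.infarct_id, det.n_channels))
        diam = dict(zip(det.infarct_id, det.diam_mean_um))
        for _, r in truth.component_table().iterrows():
            cid = int(r.cluster_id)
            rows.append({"day": day, "seed": int(seed), "component": cid,
                         "true_channels": int(r.n_channels),
                         "detected_channels": int(found.get(cid, 0)),
                         "detected_diam_um": diam.get(cid, np.nan)})
    return pd.DataFrame(rows)


def tube_diameter_recovery(seed: int, n_tubes: int = 50,
                           diameter_um: float = 3.41,
                           voxel_size_um: float = 0.65) -> np.ndarray:
    """Diameter estimates for randomly oriented rasterized tubes at the
    generator's channel calibre."""
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    out = []
    for _ in range(n_tubes):
        grid = np.zeros((48, 48, 48), np.int32)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        c = np.array([24.0, 24.0, 24.0])
        rasterize_tube(grid, c - 18 * d, c + 18 * d,
                       diameter_um / 2.0 / voxel_size_um, 1)
        est, _, _ = estimate_tube_diameter(grid > 0, voxel_size_um)
        out.append(est)
    return np.asarray(out)


def lobe_recovery(day: str, seeds, grid: int = 128) -> pd.DataFrame:
    """Full lobe-scale recovery: generate, segment, label, zone and classify.

    Returns one row per segmented component with measured volume, assigned
    zone, predicted confluence and (via majority voxel overlap) the truth
    component it corresponds to.
    """
    rows = []
    for seed in seeds:
        params = lobe_preset(day, grid=grid, seed=int(seed))
        truth, zones, vol = generate_phantom(params)
        cfg = SegmentationConfig()
        mask = segment_infarcts_threshold(vol, cfg, vessel_mask=truth.vessel_mask)
        labeled, table = label_components(mask, params.voxel_size_um, cfg)
        zone_t = assign_infarct_zones(labeled, zones).set_index("id") \
            if len(table) else None
        truth_comp = truth.infarct_components()
        truth_conf = dict(zip(truth.component_table().cluster_id,
                              truth.component_table().confluent))
        for _, r in table.iterrows():
            cid = int(r.id)
            m = labeled == cid
            cls, n_cores = classify_confluence(m, params.voxel_size_um)
            overlap = truth_comp[m]
            overlap = overlap[overlap > 0]
            true_id = int(np.bincount(overlap).argmax()) if overlap.size else 0
            rows.append({
                "day": day, "seed": int(seed), "component": cid,
                "volume_um3": float(r.volume_um3),
                "zone": int(zone_t.loc[cid, "zone"]) if zone_t is not None else 0,
                "confluent_pred": cls == "confluent",
                "confluent_true": bool(truth_conf.get(true_id, False)),
            })
    return pd.DataFrame(rows)


def confluence_summary(recovery: pd.DataFrame) -> dict:
    """Pooled confluent fraction, binomial SE and truth accuracy."""
    n = len(recovery)
    frac = float(recovery.confluent_pred.mean()) if n else np.nan
    acc = float((recovery.confluent_pred == recovery.confluent_true).mean()) \
        if n else np.nan
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n)) if n else np.nan
    return {"confluent_fraction": frac, "se": se, "accuracy": acc, "n": n}


def growth_summary(day1: pd.DataFrame, day7: pd.DataFrame) -> dict:
    """Total-volume growth ratio and per-zone count fractions."""
    tot1 = day1.groupby("seed").volume_um3.sum().mean()
    tot7 = day7.groupby("seed").volume_um3.sum().mean()
    out = {"total_volume_day1_um3": float(tot1),
           "total_volume_day7_um3": float(tot7),
           "volume_ratio_day7_day1": float(tot7 / tot1)}
    for name, df in (("day1", day1), ("day7", day7)):
        for z in (1, 2, 3):
            out[f"{name}_zone{z}_count_fraction"] = float((df.zone == z).mean())
    return out


def _sphere_ladder_phantom(grid: int = 64, contrast: float = 0.3,
                           delta_par: float = rc.DELTA_TISSUE):
    """Parenchyma cylinder with darker spheres of 2..6 voxel diameters.

    Returns the optical phantom and the sphere centres/diameters (voxels).
    """
    n = grid
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = n // 2
    cyl = (yy - c) ** 2 + (xx - c) ** 2 <= (n // 2 - 4) ** 2
    delta = np.where(cyl, delta_par, 0.0)
    spheres = []
    ring_r = n // 4
    diams = [2, 3, 4, 5, 6]
    for i, dv in enumerate(diams):
        ang = 2 * np.pi * i / len(diams)
        cz = c + (i - 2) * max(n // 12, 3)
        cy = c + ring_r * np.sin(ang)
        cx = c + ring_r * np.cos(ang)
        ball = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) \
            <= (dv / 2.0) ** 2
        delta[ball] = delta_par * (1.0 - contrast)
        spheres.append({"diameter_vox": dv, "center": (cz, cy, cx)})
    phantom = rc.OpticalPhantom(delta=delta,
                                beta=delta / rc.DELTA_BETA_RATIO_TISSUE,
                                voxel_size_um=3.25)
    return phantom, spheres


def detectability(seeds, grid: int = 64, n_angles: int = 240,
                  noise_photons: float = 20000.0,
                  contrast: float = 0.3) -> dict:
    """Smallest sphere diameter surviving the full imaging chain.

    Simulates lobe-scale acquisitions of sphere ladders (6.5-19.5 µm in
    one-voxel steps), reconstructs, threshold-segments at the midpoint of
    the two known material attenuations, and reports the smallest diameter
    detected in at least 90 % of the seeds.
    """
    geo = rc.BeamGeometry(energy_keV=16.0, distance_cm=28.0,
                          pixel_size_um=3.25, n_angles=n_angles)
    phantom, spheres = _sphere_ladder_phantom(grid, contrast)
    mu_par = float(rc.mu_from_beta(
        rc.DELTA_TISSUE / rc.DELTA_BETA_RATIO_TISSUE, geo.wavelength_um))
    threshold = mu_par * (1.0 - contrast / 2.0)
    hits = {s["diameter_vox"]: 0 for s in spheres}
    for seed in seeds:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        acq = rc.simulate_projections(phantom, geo, noise_photons, rng=rng)
        retrieved = rc.phase_retrieve(rc.correct_projection_set(acq),
                                      rc.DELTA_BETA_RATIO_TISSUE)
        mu = rc.fbp_reconstruct(retrieved).data
        dark = mu < threshold
        for s in spheres:
            cz, cy, cx = (int(round(v)) for v in s["center"])
            r = max(int(np.ceil(s["diameter_vox"] / 2)), 1)
            region = dark[max(cz - r, 0):cz + r + 1, max(cy - r, 0):cy + r + 1,
                          max(cx - r, 0):cx + r + 1]
            if region.sum() >= 2:
                hits[s["diameter_vox"]] += 1
    n = len(list(seeds))
    rates = {d: h / n for d, h in hits.items()}
    reliable = [d for d, r in sorted(rates.items()) if r >= 0.9]
    smallest = min(reliable) * 3.25 if reliable else np.nan
    return {"rates": rates, "smallest_reliable_um": smallest}


def type_i_error(n_pairs: int = 5000, n: int = 6, seed: int = 0,
                 alpha: float = 0.05) -> float:
    """Empirical false-positive rate of the two-branch procedure under the
    normal null."""
    from .stats_report import compare_groups
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    hits = 0
    for _ in range(n_pairs):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        hits += compare_groups(a, b, alpha=alpha).significant
    return hits / n_pairs
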