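"""Per-infarct and per-lobe morphometry.

Implements the quantities reported for each lesion: volume ``V`` (voxel
count times voxel volume), surface area ``A`` (triangulated 0.5-isosurface,
which unlike voxel-face counting converges to the true area and keeps the
sphericity of a ball near 1), sphericity

    Ψ = π^(1/3) (6 V)^(2/3) / A,

acinus-zone assignment, an operational confluence classifier (interior
distance-transform cores via h-maxima + watershed — a testable surrogate
for the visual individual/confluent call), and skeleton-based detection and
calibre estimation of infarct-sinusoidal microchannels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area
from skimage.morphology import h_maxima, skeletonize
from skimage.segmentation import watershed

from .zonation import ZoneMap, assign_infarct_zones

__all__ = [
    "InfarctRecord", "LobeSummary", "sphericity", "measure_component",
    "classify_confluence", "detect_microchannels", "estimate_tube_diameter",
    "measure_infarcts", "summarize_lobe",
]

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def sphericity(volume_um3: float, area_um2: float) -> float:
    """Ψ = π^(1/3) (6V)^(2/3) / A — 1 for a ball, lower for rough shapes."""
    return float(np.pi ** (1 / 3) * (6.0 * volume_um3) ** (2 / 3) / area_um2)


def measure_component(mask: np.ndarray, voxel_size_um: float):
    """Volume, surface area and sphericity of one binary component.

    Returns ``(V_um3, A_um2, psi, border_flag)``; ``border_flag`` marks
    components touching the grid border (their surface is truncated, so the
    sphericity is unreliable).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("component is empty")
    border = bool(mask[0].any() or mask[-1].any()
                  or mask[:, 0].any() or mask[:, -1].any()
                  or mask[:, :, 0].any() or mask[:, :, -1].any())
    V = float(mask.sum()) * voxel_size_um ** 3
    # anti-aliased isosurface: 2x supersampling plus a Gaussian at the
    # discretization scale removes the staircase area inflation (~8 % for a
    # ball) that voxel-exact marching cubes suffers on binary masks
    padded = np.pad(mask, 2).astype(np.float32)
    up = ndimage.zoom(padded, 2, order=1)
    smoothed = ndimage.gaussian_filter(up, 1.2)
    if smoothed.max() <= 0.5:
        smoothed = up   # single-voxel-thin component: smoothing erases it
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5,
                                        spacing=(voxel_size_um / 2.0,) * 3)
    A = float(mesh_surface_area(verts, faces))
    return V, A, sphericity(V, A), border


def classify_confluence(mask: np.ndarray, voxel_size_um: float,
                        h_voxels: float = 0.75, min_core_fraction: float = 0.1,
                        upsample: int = 2):
    """Individual-vs-confluent call for one lesion component.

    The interior Euclidean distance transform of a fused cluster has one
    local maximum per original lesion core separated by a shallower neck;
    cores are found as h-maxima (depth ``h_voxels``, in original-voxel
    units) and grown by watershed on the negated distance.  The component
    is *confluent* iff at least two cores hold a basin of
    ``min_core_fraction`` of its volume.  The crop is upsampled 2x before
    the distance transform: lobe-scale lesions are only a few voxels in
    radius and their necks are sub-voxel features.  The defaults were
    calibrated against generator truth across the day presets.

    Returns ``("confluent"|"individual", n_cores)``.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("component is empty")
    obj = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
    crop = np.pad(mask[obj], 1)
    if upsample > 1:
        crop = ndimage.zoom(crop.astype(np.float32), upsample, order=1) > 0.5
    dist = ndimage.distance_transform_edt(crop)
    peaks = h_maxima(dist, h_voxels * upsample)
    markers, n_markers = ndimage.label(peaks, structure=_STRUCT26)
    if n_markers < 2:
        return "individual", max(n_markers, 1)
    basins = watershed(-dist, markers=markers, mask=crop)
    total = float(crop.sum())
    sizes = np.bincount(basins.ravel())[1:]
    n_cores = int((sizes >= min_core_fraction * total).sum())
    return ("confluent" if n_cores >= 2 else "individual"), max(n_cores, 1)


def estimate_tube_diameter(lumen_mask: np.ndarray, voxel_size_um: float):
    """Mean and minimum calibre of a tubular lumen from its skeleton.

    Diameter at a skeleton voxel is twice its Euclidean distance to the
    nearest non-lumen voxel.

    Returns ``(mean_um, min_um, per_voxel_um)``.
    """
    lumen_mask = np.asarray(lumen_mask).astype(bool)
    skel = skeletonize(lumen_mask)
    if not skel.any():
        return np.nan, np.nan, np.array([])
    edt = ndimage.distance_transform_edt(lumen_mask)
    d = 2.0 * edt[skel] * voxel_size_um
    return float(d.mean()), float(d.min()), d


def detect_microchannels(infarct_labels: np.ndarray, sinusoid_mask: np.ndarray,
                         lumen_mask: np.ndarray, voxel_size_um: float,
                         shell_um: float = 25.0,
                         exclude_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Count and size the microchannels of every labeled infarct component.

    The lumen mask (dark sub-threshold voxels outside both the infarcts and
    the sinusoids; pass the segmented portal/central lumina as
    ``exclude_mask`` so macro-vessels are not mistaken for channel lumen) is
    restricted to a shell of ``shell_um`` around each
    component and skeletonized; a *microchannel* is a connected skeleton
    piece bridging the infarct surface and a sinusoid surface.  Its calibre
    is twice the skeleton-averaged distance to the nearest non-lumen
    voxel; channels thinner than two voxels are flagged unreliable.

    Returns one row per infarct id: ``(infarct_id, n_channels,
    diam_mean_um, diam_min_um, n_unreliable)``.
    """
    infarct_labels = np.asarray(infarct_labels)
    sinusoid_mask = np.asarray(sinusoid_mask).astype(bool)
    lumen_mask = np.asarray(lumen_mask).astype(bool)
    if not sinusoid_mask.any():
        raise ValueError("sinusoid mask is empty; microchannel detection "
                         "requires the submicron sinusoid segmentation")
    lumen_mask = lumen_mask & ~sinusoid_mask & (infarct_labels == 0)
    if exclude_mask is not None:
        lumen_mask = lumen_mask & ~np.asarray(exclude_mask).astype(bool)
    shell_vox = shell_um / voxel_size_um
    shape = np.asarray(infarct_labels.shape)
    rows = []
    for cid in np.unique(infarct_labels[infarct_labels > 0]):
        comp_full = infarct_labels == cid
        obj = ndimage.find_objects(comp_full.astype(np.int8), max_label=1)[0]
        pad = int(np.ceil(shell_vox)) + 2
        lo = np.maximum([s.start for s in obj] - np.array([pad] * 3), 0)
        hi = np.minimum([s.stop for s in obj] + np.array([pad] * 3), shape)
        crop = tuple(slice(lo[i], hi[i]) for i in range(3))
        comp = comp_full[crop]
        near_comp = ndimage.distance_transform_edt(~comp) <= shell_vox
        lum = lumen_mask[crop] & near_comp
        n_channels = 0
        n_unreliable = 0
        diams = []
        if lum.any():
            # a channel is a connected lumen piece abutting both the lesion
            # and a sinusoid; its skeleton (which retracts from the open
            # ends by about one radius) only provides the calibre samples
            skel = skeletonize(lum)
            comp_touch = ndimage.binary_dilation(comp, structure=_STRUCT26)
            sin_touch = ndimage.binary_dilation(sinusoid_mask[crop],
                                                structure=_STRUCT26)
            # calibre = distance to the tissue wall; the mouths where the
            # lumen opens into the lesion or a sinusoid are not walls, so
            # they are treated as free space in the distance transform
            edt = ndimage.distance_transform_edt(lum | comp | sinusoid_mask[crop])
            pieces, n_pieces = ndimage.label(lum, structure=_STRUCT26)
            for k in range(1, n_pieces + 1):
                piece = pieces == k
                if not (piece & comp_touch).any() or not (piece & sin_touch).any():
                    continue
                n_channels += 1
                sk = skel & piece
                d = 2.0 * edt[sk] * voxel_size_um if sk.any() \
                    else 2.0 * edt[piece].max() * voxel_size_um * np.ones(1)
                diams.append(float(d.mean()))
                if d.mean() < 2.0 * voxel_size_um:
                    n_unreliable += 1
        rows.append({"infarct_id": int(cid), "n_channels": n_channels,
                     "diam_mean_um": float(np.mean(diams)) if diams else np.nan,
                     "diam_min_um": float(np.min(diams)) if diams else np.nan,
                     "n_unreliable": n_unreliable})
    return pd.DataFrame(rows, columns=["infarct_id", "n_channels", "diam_mean_um",
                                       "diam_min_um", "n_unreliable"])


@dataclass
class InfarctRecord:
    """All measured quantities for one lesion component."""

    id: int
    V: float                    # µm³
    A: float                    # µm²
    psi: float
    zone: int                   # 1|2|3 (0 = unassignable)
    confluence: str             # "individual" | "confluent"
    n_cores: int = 1
    n_channels: int = 0
    channel_diams_um: list = field(default_factory=list)
    border: bool = False

    def __post_init__(self) -> None:
        if not (self.V > 0 and self.A > 0):
            raise ValueError("V and A must be positive")
        if not 0 < self.psi <= 1.05:  # small discretization excess allowed
            raise ValueError(f"implausible sphericity {self.psi}")


@dataclass
class LobeSummary:
    """Lobe-level aggregation of a set of infarct records."""

    n_infarcts: int
    total_volume_um3: float
    lobe_volume_um3: float
    volume_ratio: float
    confluent_fraction: float
    per_zone: dict               # zone -> {count_fraction, total_volume_um3, sphericities}
    mean_channels_per_infarct: float = np.nan


def measure_infarcts(labeled: np.ndarray, voxel_size_um: float,
                     zones: ZoneMap | None = None,
                     sinusoid_mask: np.ndarray | None = None,
                     lumen_mask: np.ndarray | None = None,
                     h_voxels: float = 0.75,
                     min_core_fraction: float = 0.1) -> list[InfarctRecord]:
    """Measure every component of a labeled infarct grid."""
    ids = np.unique(labeled[labeled > 0])
    zone_of = {}
    if zones is not None:
        zt = assign_infarct_zones(labeled, zones)
        zone_of = dict(zip(zt["id"], zt["zone"]))
    chan = None
    if sinusoid_mask is not None and lumen_mask is not None:
        chan = detect_microchannels(labeled, sinusoid_mask, lumen_mask,
                                    voxel_size_um).set_index("infarct_id")
    records = []
    objects = ndimage.find_objects(labeled)
    for cid in ids:
        obj = objects[int(cid) - 1]
        pad_obj = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, labeled.shape[i]))
                        for i, s in enumerate(obj))
        comp = labeled[pad_obj] == cid
        V, A, psi, border = measure_component(comp, voxel_size_um)
        cls, n_cores = classify_confluence(comp, voxel_size_um, h_voxels,
                                           min_core_fraction)
        rec = InfarctRecord(
            id=int(cid), V=V, A=A, psi=min(psi, 1.05), zone=int(zone_of.get(int(cid), 0)),
            confluence=cls, n_cores=n_cores, border=border)
        if chan is not None and int(cid) in chan.index:
            rec.n_channels = int(chan.loc[int(cid), "n_channels"])
            dm = chan.loc[int(cid), "diam_mean_um"]
            rec.channel_diams_um = [] if np.isnan(dm) else [float(dm)]
        records.append(rec)
    return records


def summarize_lobe(records: list[InfarctRecord], lobe_volume_um3: float,
                   zones: ZoneMap | None = None) -> LobeSummary:
    """Aggregate per-lesion records into the lobe-level summary."""
    n = len(records)
    total = float(sum(r.V for r in records))
    per_zone = {}
    for z in (1, 2, 3):
        rs = [r for r in records if r.zone == z]
        per_zone[z] = {
            "count_fraction": len(rs) / n if n else 0.0,
            "total_volume_um3": float(sum(r.V for r in rs)),
            # border-touching components are counted but excluded from the
            # sphericity distribution (truncated surfaces)
            "sphericities": [r.psi for r in rs if not r.border],
        }
    chans = [r.n_channels for r in records]
    return LobeSummary(
        n_infarcts=n,
        total_volume_um3=total,
        lobe_volume_um3=float(lobe_volume_um3),
        volume_ratio=total / lobe_volume_um3 if lobe_volume_um3 > 0 else 0.0,
        confluent_fraction=(sum(r.confluence == "confluent" for r in records) / n
                            if n else 0.0),
        per_zone=per_zone,
        mean_channels_per_infarct=float(np.mean(chans)) if n else np.nan,
    )
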