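"""Bile-infarct placement.

Infarcts are perturbed spheres (low-order spherical-harmonic surface
roughness) whose centres are drawn zone-by-zone according to the preset
placement weights, emulating the periportal onset and pericentral migration
of the lesions over the disease course.  A preset fraction of lesions is
generated as *fused clusters* of 2-3 overlapping blobs sharing a cluster id;
members are guaranteed 26-connected.  Lesions never invade vessel lumina and
distinct lesion units never touch, so segmentation components correspond
one-to-one to generated units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import sph_harm_y

from ..errors import CapacityError
from ..zonation import ZoneMap
from .params import PhantomParams
from .truth import LabelCodes, PhantomTruth

__all__ = ["place_infarcts"]

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def _harmonic_field(rng: np.random.Generator):
    """Random unit-RMS angular perturbation from degree 3-6 harmonics:
    many shallow surface bumps (uneven necrosis margin) rather than a few
    deep lobes that would mimic fused cores."""
    terms = []
    for ell in (3, 4, 5, 6):
        for m in range(-ell, ell + 1):
            terms.append((ell, m, rng.normal()))

    def evaluate(theta, phi):
        f = np.zeros_like(theta)
        for ell, m, a in terms:
            y = sph_harm_y(ell, abs(m), theta, phi)
            f = f + a * (np.sqrt(2) * (y.imag if m < 0 else y.real) if m != 0 else y.real)
        return f

    return evaluate


def _blob_voxels(center, r_vox: float, roughness: float, rng, shape):
    """Voxel coordinates of one perturbed-sphere blob clipped to the grid."""
    pad = r_vox * (1 + 2.2 * roughness) + 1.5
    lo = np.maximum(np.floor(np.asarray(center) - pad).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(center) + pad).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    off = np.stack(grids, axis=-1) - np.asarray(center, dtype=float)
    rr = np.sqrt((off ** 2).sum(axis=-1))
    if roughness > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(off[..., 0] / np.maximum(rr, 1e-12), -1, 1))
            phi = np.arctan2(off[..., 1], off[..., 2])
        f = _harmonic_field(rng)(theta, phi)
        f = f / max(float(f.std()), 1e-12)
        radius = r_vox * (1.0 + roughness * np.clip(f, -2.0, 2.0))
    else:
        radius = r_vox
    inside = rr <= radius
    coords = np.argwhere(inside) + lo
    return coords


def _unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def place_infarcts(params: PhantomParams, vessels: PhantomTruth,
                   zones: ZoneMap) -> PhantomTruth:
    """Add ``params.n_infarcts`` lesion units to a vessel phantom.

    Each unit is an individual blob or, with probability
    ``params.confluent_fraction``, a fused cluster of 2-3 overlapping blobs.
    Centres are sampled from the parenchyma of a zone drawn with
    ``params.zone_placement_weights``.  Raises
    :class:`~infarct3d.errors.CapacityError` when the requested load cannot
    be placed under the parenchyma occupancy cap.
    """
    labels = vessels.labels.copy()
    shape = labels.shape
    vs = params.voxel_size_um
    rng = params.rng(2)
    n_parenchyma = int((labels == LabelCodes.PARENCHYMA).sum())
    cap_voxels = params.occupancy_cap * n_parenchyma

    zone_coords = {z: np.argwhere((zones.zones == z) & (labels == LabelCodes.PARENCHYMA))
                   for z in (1, 2, 3)}
    # voxels within one step of an existing lesion; candidate units must avoid
    # these so distinct units never 26-touch
    blocked = np.zeros(shape, dtype=bool)
    rows = []
    blob_counter = 0
    infarct_voxels = 0

    def _cluster_geometry(center, r0):
        k = int(rng.integers(2, 4))
        sep_factor = rng.uniform(1.75, 1.95)
        dirs = _unit_vectors(rng, k - 1)
        if k == 3:  # push the two satellites apart
            d0, d1 = dirs
            if float(d0 @ d1) > 0.0:
                dirs[1] = d1 - 2 * float(d0 @ d1) * d0
                dirs[1] /= np.linalg.norm(dirs[1])
        members = [(center, r0)]
        for j in range(k - 1):
            rj = r0 * rng.uniform(0.85, 1.0)
            sep = sep_factor * (r0 + rj) / 2.0
            members.append((center + dirs[j] * sep, rj))
        return members

    lo_um, hi_um = params.infarct_radius_um_range
    for unit in range(params.n_infarcts):
        cluster_id = unit + 1
        is_cluster = rng.random() < params.confluent_fraction
        r0 = rng.uniform(lo_um, hi_um) / vs
        zone = int(rng.choice([1, 2, 3], p=params.zone_placement_weights))
        coords = zone_coords[zone]

        members = blob_sets = None
        for _ in range(150):
            center = coords[rng.integers(len(coords))].astype(float)
            cand_members = [(center, r0)] if not is_cluster \
                else _cluster_geometry(center, r0)
            # rasterize, shrinking separations until the cluster is 26-connected
            for _attempt in range(6):
                cand_sets = [
                    _blob_voxels(c, r, params.sphericity_roughness, rng, shape)
                    for c, r in cand_members]
                if len(cand_members) == 1:
                    break
                union = np.zeros(shape, dtype=bool)
                for cset in cand_sets:
                    union[tuple(cset.T)] = True
                _, ncomp = ndimage.label(union, structure=_STRUCT26)
                if ncomp == 1:
                    break
                cand_members = [(center + (np.asarray(c) - center) * 0.9, r)
                                for c, r in cand_members]
            all_coords = np.concatenate(cand_sets, axis=0)
            if not blocked[tuple(all_coords.T)].any():
                members, blob_sets = cand_members, cand_sets
                break
        if members is None:
            raise CapacityError(
                f"could not place lesion unit {unit + 1}/{params.n_infarcts} "
                f"without touching existing units (grid {shape})")

        # claim voxels blob-by-blob; vessels and earlier blobs keep their label
        unit_voxels = 0
        for cset in blob_sets:
            blob_counter += 1
            code = LabelCodes.INFARCT_BASE + blob_counter
            zsl, ysl, xsl = cset[:, 0], cset[:, 1], cset[:, 2]
            free = labels[zsl, ysl, xsl] == LabelCodes.PARENCHYMA
            labels[zsl[free], ysl[free], xsl[free]] = code
            nvox = int(free.sum())
            unit_voxels += nvox
            rows.append({"infarct_id": blob_counter, "cluster_id": cluster_id,
                         "origin_zone": zone, "volume_um3": nvox * vs ** 3,
                         "n_channels": 0, "channel_diam_um": np.nan})
        infarct_voxels += unit_voxels
        if infarct_voxels > cap_voxels:
            raise CapacityError(
                f"lesion load exceeds occupancy cap "
                f"({infarct_voxels} > {cap_voxels:.0f} parenchyma voxels)")
        # extend the blocked region by the new unit dilated one step
        lo = np.maximum(all_coords.min(axis=0) - 2, 0)
        hi = np.minimum(all_coords.max(axis=0) + 3, shape)
        crop = tuple(slice(lo[i], hi[i]) for i in range(3))
        unit_mask = np.zeros(tuple(hi - lo), dtype=bool)
        unit_mask[tuple((all_coords - lo).T)] = True
        blocked[crop] |= ndimage.binary_dilation(unit_mask, structure=_STRUCT26)

    table = pd.DataFrame(rows, columns=["infarct_id", "cluster_id", "origin_zone",
                                        "volume_um3", "n_channels", "channel_diam_um"]) \
        if rows else vessels.infarct_table.copy()
    return PhantomTruth(labels=labels, voxel_size_um=vs, day=params.day,
                        seed=params.seed, infarct_table=table,
                        channel_table=vessels.channel_table.copy())
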