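"""Infarct-sinusoidal microchannel placement (submicron scale only).

Each lesion component receives a Poisson-distributed number of thin tubular
channels running from its surface to the nearest hepatic sinusoid,
emulating the bile-leakage conduits seen at 0.65 µm resolution.  Channels
are only meaningful at the submicron scale — at 3.25 µm voxels a ~3.4 µm
lumen is sub-voxel and the operation refuses to run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from ..errors import ScaleError
from .params import PhantomParams
from .trees import rasterize_tube
from .truth import LabelCodes, PhantomTruth

__all__ = ["place_microchannels"]


def place_microchannels(params: PhantomParams, truth: PhantomTruth,
                        counts: int | dict | None = None,
                        max_length_vox: float = 30.0) -> PhantomTruth:
    """Add microchannels to every lesion component of a submicron phantom.

    Parameters
    ----------
    counts
        Override for the Poisson draw: an int forces the same count for
        every component; a dict maps ``cluster_id -> count``.
    max_length_vox
        Surface exit points farther than this from any sinusoid are not
        used (channels are short, local structures).
    """
    vs = params.voxel_size_um
    if vs > 1.5:
        raise ScaleError(
            f"microchannels (~{params.microchannel_diameter_um} µm lumen) are "
            f"sub-voxel at {vs} µm voxels; generate them on the submicron phantom")
    if not truth.sinusoid_mask.any():
        raise ValueError("phantom has no sinusoid labels; build the submicron "
                         "vessel network first")

    labels = truth.labels.copy()
    rng = params.rng(3)
    r_ch = params.microchannel_diameter_um / 2.0 / vs
    min_sep = max(4.0 * r_ch, 8.0)

    # distance to (and identity of) the nearest sinusoid voxel, everywhere
    sin_dist, sin_idx = ndimage.distance_transform_edt(
        labels != LabelCodes.SINUSOID, return_indices=True)

    components = truth.infarct_components()
    table = truth.infarct_table.copy()
    ch_rows = list(truth.channel_table.to_dict("records"))
    ch_counter = len(ch_rows)
    n_per_cluster: dict[int, int] = {}
    diam_per_cluster: dict[int, list] = {}

    cluster_ids = sorted(truth.infarct_table["cluster_id"].unique())
    for cid in cluster_ids:
        if isinstance(counts, dict):
            k = int(counts.get(cid, 0))
        elif counts is not None:
            k = int(counts)
        else:
            k = int(rng.poisson(params.microchannel_count_mean))
        n_per_cluster[int(cid)] = 0
        diam_per_cluster[int(cid)] = []
        if k == 0:
            continue
        comp = components == cid
        # surface voxels opening into parenchyma
        eroded = ndimage.binary_erosion(comp, border_value=0)
        surface = np.argwhere(comp & ~eroded)
        if len(surface) == 0:
            continue
        surface = surface[rng.permutation(len(surface))]
        accepted: list[np.ndarray] = []

        def _try_place(p, sep) -> bool:
            nonlocal ch_counter
            pz, py, px = p
            # a genuine lumen needs a real tissue gap to tunnel through
            if not 2.0 <= sin_dist[pz, py, px] <= max_length_vox:
                return False
            if accepted and np.min(np.linalg.norm(
                    np.asarray(accepted) - p, axis=1)) < sep:
                return False
            target = sin_idx[:, pz, py, px].astype(float)
            u = target - p
            length = np.linalg.norm(u)
            u = u / max(length, 1e-9)
            start = p - 2.0 * u
            end = target + 2.0 * u
            # reject paths that cut through other structures
            ts = np.linspace(0.0, 1.0, max(int(length) * 2, 4))
            pts = np.clip(np.round(p + ts[:, None] * (target - p)).astype(int), 0,
                          np.asarray(labels.shape) - 1)
            path_lab = labels[pts[:, 0], pts[:, 1], pts[:, 2]]
            path_comp = components[pts[:, 0], pts[:, 1], pts[:, 2]]
            bad = ((path_lab == LabelCodes.PORTAL) | (path_lab == LabelCodes.CENTRAL)
                   | ((path_comp > 0) & (path_comp != cid)))
            if bad.any():
                return False
            ch_counter += 1
            code = LabelCodes.CHANNEL_BASE + ch_counter
            nset = rasterize_tube(labels, start, end, r_ch, code,
                                  overwrite=LabelCodes.PARENCHYMA)
            # verify the rasterized lumen really bridges lesion and sinusoid
            # (it can fail to when neighbouring structures squeeze the path)
            ok = nset > 0
            if ok:
                lo = np.maximum(np.floor(np.minimum(start, end) - r_ch - 2).astype(int), 0)
                hi = np.minimum(np.ceil(np.maximum(start, end) + r_ch + 2).astype(int) + 1,
                                labels.shape)
                box = tuple(slice(lo[i], hi[i]) for i in range(3))
                sub = labels[box]
                ch = sub == code
                halo = ndimage.binary_dilation(ch, structure=np.ones((3, 3, 3), bool))
                ok = (halo & (sub == LabelCodes.SINUSOID)).any() \
                    and (halo & (components[box] == cid)).any() \
                    and not (halo & (sub >= LabelCodes.CHANNEL_BASE)
                             & (sub != code)).any()
                if not ok:
                    sub[ch] = LabelCodes.PARENCHYMA
            if not ok:
                ch_counter -= 1
                return False
            accepted.append(p.astype(float))
            n_per_cluster[int(cid)] += 1
            diam_per_cluster[int(cid)].append(params.microchannel_diameter_um)
            ch_rows.append({"channel_id": code, "cluster_id": int(cid),
                            "diameter_um": params.microchannel_diameter_um,
                            "length_um": float(length * vs)})
            return True

        # second pass relaxes the exit-point spacing when the drawn count
        # cannot be placed at the preferred separation
        for sep in (min_sep, min_sep / 2.0):
            for p in surface:
                if len(accepted) >= k:
                    break
                _try_place(p, sep)
            if len(accepted) >= k:
                break

    # attribute the per-component counts to the first blob of each cluster
    for cid, n in n_per_cluster.items():
        first = table.index[table["cluster_id"] == cid][0]
        table.loc[first, "n_channels"] = n
        if diam_per_cluster[cid]:
            table.loc[first, "channel_diam_um"] = float(np.mean(diam_per_cluster[cid]))
    table["n_channels"] = table["n_channels"].astype(int)

    channel_table = pd.DataFrame(
        ch_rows, columns=["channel_id", "cluster_id", "diameter_um", "length_um"]) \
        if ch_rows else truth.channel_table.copy()
    return PhantomTruth(labels=labels, voxel_size_um=vs, day=params.day,
                        seed=params.seed, infarct_table=table,
                        channel_table=channel_table)
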