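"""Grayscale rendering of a phantom truth.

Maps every tissue class to its configured gray level (bile infarcts darker
than parenchyma, vascular and channel lumina darkest) and adds Gaussian
noise.  Rendering is deterministic for a fixed parameter set.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from ..volume import VoxelVolume
from .params import PhantomParams
from .truth import LabelCodes, PhantomTruth

__all__ = ["render_grayscale"]


def _present_classes(truth: PhantomTruth) -> list[str]:
    present = ["parenchyma"]
    lab = truth.labels
    if (lab == LabelCodes.PORTAL).any():
        present.append("portal")
    if (lab == LabelCodes.CENTRAL).any():
        present.append("central")
    if (lab == LabelCodes.SINUSOID).any():
        present.append("sinusoid")
    if truth.infarct_mask.any():
        present.append("infarct")
    if truth.channel_mask.any():
        present.append("channel")
    return present


def render_grayscale(truth: PhantomTruth, params: PhantomParams) -> VoxelVolume:
    """Render a truth label grid into a float32 grayscale volume."""
    levels = params.gray_levels
    for cls in _present_classes(truth):
        if cls not in levels:
            raise ConfigurationError(
                f"gray_levels lacks an intensity for class {cls!r}")
    lab = truth.labels
    out = np.full(lab.shape, levels["parenchyma"], dtype=np.float32)
    if "portal" in levels:
        out[lab == LabelCodes.PORTAL] = levels["portal"]
    if "central" in levels:
        out[lab == LabelCodes.CENTRAL] = levels["central"]
    if "sinusoid" in levels:
        out[lab == LabelCodes.SINUSOID] = levels["sinusoid"]
    out[truth.infarct_mask] = levels["infarct"]
    if "channel" in levels:
        out[truth.channel_mask] = levels["channel"]
    if params.noise_sd > 0:
        rng = params.rng(4)
        out = out + rng.normal(0.0, params.noise_sd, size=lab.shape).astype(np.float32)
    return VoxelVolume(data=out, voxel_size_um=truth.voxel_size_um)
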