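"""Seeded synthetic liver phantoms with full ground truth.

The generator builds, in order: vascular trees, the equal-volume acinus
zonation of the resulting parenchyma, zone-weighted infarct units
(individual blobs or fused clusters), optionally infarct-sinusoidal
microchannels (submicron scale), and finally a grayscale rendering.
"""

from __future__ import annotations

from ..zonation import ZoneMap, equal_volume_zonation
from .lesions import place_infarcts
from .microchannels import place_microchannels
from .params import (DAYS, DEFAULT_GRAY_LEVELS, LOBE_VOXEL_UM,
                     SUBMICRON_VOXEL_UM, PhantomParams, lobe_preset,
                     submicron_preset)
from .render import render_grayscale
from .trees import build_vessel_trees, rasterize_tube
from .truth import LabelCodes, PhantomTruth

__all__ = [
    "PhantomParams", "PhantomTruth", "LabelCodes", "DAYS",
    "DEFAULT_GRAY_LEVELS", "LOBE_VOXEL_UM", "SUBMICRON_VOXEL_UM",
    "lobe_preset", "submicron_preset", "build_vessel_trees", "rasterize_tube",
    "place_infarcts", "place_microchannels", "render_grayscale",
    "generate_phantom",
]


def generate_phantom(params: PhantomParams, zonation_tol: float = 0.005):
    """Run the full generator.

    Returns ``(truth, zones, volume)``: the ground-truth labels and tables,
    the acinus zone map computed from the true vessel masks, and the
    rendered grayscale volume.
    """
    truth = build_vessel_trees(params)
    zones = equal_volume_zonation(
        parenchyma=truth.parenchyma_mask,
        central_veins=truth.central_mask,
        portal_veins=truth.portal_mask,
        voxel_size_um=params.voxel_size_um,
        tol=zonation_tol,
    )
    if params.n_infarcts > 0:
        truth = place_infarcts(params, truth, zones)
        if params.is_submicron and params.microchannel_count_mean > 0:
            truth = place_microchannels(params, truth)
    volume = render_grayscale(truth, params)
    return truth, zones, volume
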