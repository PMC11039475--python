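"""Phantom parameters and per-day presets.

The presets encode the study conditions the generator emulates: numbers of
bile infarcts rising roughly linearly over post-ligation days 1/3/5/7, total
infarct volume rising ~exponentially (9-fold from day 1 to day 7), confluent
fractions of 8/15/21/25 %, infarct-sinusoidal microchannel counts per infarct
with means 1.86/2.47/3.38/5.47, channel lumen diameter 3.41 µm, and a
periportal-to-pericentral shift of the lesions (zone-I majority on day 1,
zone-III plurality by day 7).  Absolute per-lobe infarct counts are not
reported numerically anywhere; the preset counts 10/20/30/40 are
order-of-magnitude choices (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomParams",
    "DAYS",
    "LOBE_VOXEL_UM",
    "SUBMICRON_VOXEL_UM",
    "DEFAULT_GRAY_LEVELS",
    "lobe_preset",
    "submicron_preset",
]

LOBE_VOXEL_UM = 3.25
SUBMICRON_VOXEL_UM = 0.65

DAYS = ("control", "1", "3", "5", "7")

#: Grayscale rendering levels per tissue class (arbitrary units in [0, 1]);
#: infarcts darker than parenchyma, lumina darkest.
DEFAULT_GRAY_LEVELS = {
    "parenchyma": 0.60,
    "infarct": 0.35,
    "sinusoid": 0.18,
    "portal": 0.12,
    "central": 0.12,
    "channel": 0.08,
}

# Expected total-volume multiplier day d over day 1 follows 9**((d-1)/6):
# 1, 9^(1/3), 9^(2/3), 9 for days 1/3/5/7, i.e. day7/day1 = 9.  Counts are
# 10/20/30/40 and radii uniform on [a, 1.5a]; the base radii below were
# calibrated by Monte-Carlo of the generator itself (16 seeds per day) so
# the *expected generated* totals — including the extra volume carried by
# multi-blob fused clusters and by surface roughness — realize those
# multipliers.  Later days gain volume mostly through count, confluence
# and roughness, so the radius schedule is nearly flat.
_DAY_TABLE = {
    #  day:  (n, confl, chan_mean, a_um, roughness, (wI, wII, wIII))
    "control": (0, 0.0, 0.0, 12.0, 0.00, (1 / 3, 1 / 3, 1 / 3)),
    "1": (10, 0.08, 1.86, 12.0, 0.06, (0.60, 0.25, 0.15)),
    "3": (20, 0.15, 2.47, 11.679, 0.10, (0.45, 0.30, 0.25)),
    "5": (30, 0.21, 3.38, 12.721, 0.15, (0.33, 0.32, 0.35)),
    "7": (40, 0.25, 5.47, 14.529, 0.20, (0.25, 0.30, 0.45)),
}


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of a synthetic liver volume."""

    day: str = "1"
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = LOBE_VOXEL_UM
    n_infarcts: int = 10
    zone_placement_weights: tuple[float, float, float] = (0.60, 0.25, 0.15)
    confluent_fraction: float = 0.08
    microchannel_count_mean: float = 0.0
    microchannel_diameter_um: float = 3.41
    infarct_radius_um_range: tuple[float, float] = (12.0, 18.0)
    sphericity_roughness: float = 0.06
    gray_levels: dict = field(default_factory=lambda: dict(DEFAULT_GRAY_LEVELS))
    noise_sd: float = 0.02
    seed: int = 0
    # structural knobs with anatomy-motivated defaults
    lobule_spacing_vox: int = 48       # lobe scale: lattice period of vessel trunks
    occupancy_cap: float = 0.40        # max infarct fraction of parenchyma
    sinusoid_radius_um: float = 3.25   # submicron scale only (6.5 µm lumen)

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValueError(f"day must be one of {DAYS}, got {self.day!r}")
        w = self.zone_placement_weights
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"zone_placement_weights must sum to 1, got {w}")
        if not 0.0 <= self.confluent_fraction <= 1.0:
            raise ValueError("confluent_fraction must lie in [0, 1]")
        for name in ("voxel_size_um", "microchannel_diameter_um", "sinusoid_radius_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.infarct_radius_um_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid infarct_radius_um_range {self.infarct_radius_um_range}")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError(f"invalid grid_shape {self.grid_shape}")

    @property
    def is_submicron(self) -> bool:
        return self.voxel_size_um < 1.5

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream for a pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, stage]))

    def replace(self, **kw) -> "PhantomParams":
        return replace(self, **kw)


def _day_fields(day: str) -> dict:
    n, confl, chan, a, rough, weights = _DAY_TABLE[day]
    return dict(
        day=day,
        n_infarcts=n,
        confluent_fraction=confl,
        microchannel_count_mean=chan,
        infarct_radius_um_range=(a, 1.5 * a),
        sphericity_roughness=rough,
        zone_placement_weights=weights,
    )


def lobe_preset(day: str, grid: int | tuple[int, int, int] = 128, seed: int = 0,
                **overrides) -> PhantomParams:
    """Lobe-scale preset (3.25 µm voxels): vessel trees + infarcts, no
    sinusoids or microchannels (those are sub-resolution at this scale)."""
    shape = (grid,) * 3 if np.isscalar(grid) else tuple(grid)
    kw = _day_fields(day)
    kw["microchannel_count_mean"] = 0.0  # sub-voxel at 3.25 µm
    kw.update(grid_shape=shape, voxel_size_um=LOBE_VOXEL_UM, seed=seed)
    kw.update(overrides)
    return PhantomParams(**kw)


def submicron_preset(day: str, grid: int | tuple[int, int, int] = 160, seed: int = 0,
                     n_infarcts: int = 25, **overrides) -> PhantomParams:
    """Submicron-scale preset (0.65 µm voxels): a miniature lobule region with
    a central-vein trunk, corner portal trunks, a sinusoid network, and
    infarcts carrying microchannels.

    ``n_infarcts`` defaults to 25, the per-group sample size used for the
    microchannel statistics.  Infarct radii are kept at 6-10 µm independent of
    day (the high-resolution field of view covers a small region of interest;
    lesion growth across days is a lobe-scale quantity).
    """
    shape = (grid,) * 3 if np.isscalar(grid) else tuple(grid)
    kw = _day_fields(day)
    kw.update(
        grid_shape=shape,
        voxel_size_um=SUBMICRON_VOXEL_UM,
        n_infarcts=n_infarcts,
        infarct_radius_um_range=(6.0, 10.0),
        seed=seed,
    )
    kw.update(overrides)
    return PhantomParams(**kw)
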