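"""Synthetic vascular trees.

Lobe scale: the classic lobular arrangement is emulated by a jittered square
lattice in the (y, x) plane — central/hepatic-vein trunks run along z at cell
centres, portal trunks at cell corners — with tapering side branches (two
branch generations below the trunk).  The interdigitated dual lattice
guarantees that every parenchyma voxel is within roughly half a lattice
period of both systems, which the distance-based zonation relies on.

Submicron scale: a miniature single-lobule region — one central trunk at the
grid centre, portal trunks at the corners, and a radial sinusoid network
spoking out from the central vein.
"""

from __future__ import annotations

import numpy as np

from scipy import ndimage

from ..errors import PlacementError
from .params import PhantomParams
from .truth import LabelCodes, PhantomTruth

__all__ = ["build_vessel_trees", "rasterize_tube"]

_GUARD = 9  # transient code keeping distinct vessel systems from touching
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def _guard_existing(labels: np.ndarray) -> None:
    """Mark the 1-voxel halo of everything already placed as off-limits, so
    the next system neither overlaps nor 26-touches it (region growing must
    not be able to leak between same-intensity lumina)."""
    placed = labels > 0
    halo = ndimage.binary_dilation(placed, structure=_STRUCT26) & ~placed
    labels[halo & (labels == LabelCodes.PARENCHYMA)] = _GUARD


def _clear_guard(labels: np.ndarray) -> None:
    labels[labels == _GUARD] = LabelCodes.PARENCHYMA


def rasterize_tube(labels: np.ndarray, p0, p1, radius: float, code: int,
                   overwrite: int = LabelCodes.PARENCHYMA) -> int:
    """Rasterize a cylindrical tube between two points (voxel coordinates).

    A voxel belongs to the tube iff its centre lies within ``radius`` of the
    segment.  Only voxels currently holding ``overwrite`` are claimed, so
    earlier structures take precedence.  Returns the number of voxels set.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int) + 1,
                    labels.shape)
    if np.any(lo >= hi):
        return 0
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)  # (bz,by,bx,3)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = ((pts - p0) ** 2).sum(axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist2 = ((pts - closest) ** 2).sum(axis=-1)
    inside = dist2 <= radius * radius
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    claim = inside & (sub == overwrite)
    sub[claim] = code
    return int(claim.sum())


def _trunk_polyline(rng, z_extent: int, y0: float, x0: float, amp: float):
    """Vertical trunk with sinusoidal jitter, as a list of segment endpoints."""
    phase = rng.uniform(0, 2 * np.pi, size=2)
    nseg = max(2, z_extent // 8)
    zs = np.linspace(0, z_extent - 1, nseg + 1)
    ys = y0 + amp * np.sin(2 * np.pi * zs / z_extent + phase[0])
    xs = x0 + amp * np.sin(2 * np.pi * zs / z_extent + phase[1])
    return [((zs[i], ys[i], xs[i]), (zs[i + 1], ys[i + 1], xs[i + 1]))
            for i in range(nseg)]


def _grow_trunk(labels, rng, code, y0, x0, trunk_radius, branch_len, jitter_amp):
    """Rasterize one trunk plus two generations of tapering side branches.

    Branch endpoints are clamped into the grid interior so every rasterized
    voxel stays 26-connected to its trunk (no clipped fragments)."""
    nz = labels.shape[0]
    interior_lo = np.array([1.0, 1.0, 1.0])
    interior_hi = np.asarray(labels.shape, dtype=float) - 2.0
    n = 0
    for a, b in _trunk_polyline(rng, nz, y0, x0, jitter_amp):
        n += rasterize_tube(labels, a, b, trunk_radius, code)
    n_branches = max(2, int(rng.poisson(max(1.0, nz / 24.0))) + 1)
    for _ in range(n_branches):
        z = rng.uniform(0.1 * nz, 0.9 * nz)
        az = rng.uniform(0, 2 * np.pi)
        tilt = rng.uniform(-0.35, 0.35)
        length = branch_len * rng.uniform(0.6, 0.9)
        start = np.array([z, y0, x0])
        direction = np.array([np.sin(tilt),
                              np.cos(tilt) * np.sin(az),
                              np.cos(tilt) * np.cos(az)])
        end = np.clip(start + length * direction, interior_lo, interior_hi)
        r1 = max(1.2, trunk_radius * 0.6)
        n += rasterize_tube(labels, start, end, r1, code)
        if rng.random() < 0.6:  # second generation
            az2 = az + rng.uniform(0.7, 1.2) * rng.choice([-1.0, 1.0])
            tilt2 = tilt + rng.uniform(-0.3, 0.3)
            d2 = np.array([np.sin(tilt2),
                           np.cos(tilt2) * np.sin(az2),
                           np.cos(tilt2) * np.cos(az2)])
            end2 = np.clip(end + 0.6 * length * d2, interior_lo, interior_hi)
            n += rasterize_tube(labels, end, end2, max(1.0, r1 * 0.6), code)
    return n


def _lattice_positions(extent: int, spacing: int, offset: float):
    pos = np.arange(offset, extent, spacing, dtype=float)
    return pos if len(pos) else np.array([extent / 2.0])


def _build_lobe_trees(params: PhantomParams, labels: np.ndarray) -> None:
    nz, ny, nx = labels.shape
    s = int(min(params.lobule_spacing_vox, max(ny, nx)))
    rng = params.rng(1)
    jitter = min(4.0, s / 8.0)
    central_r, portal_r = 4.5, 3.5
    # portal trunks at lattice nodes (rasterized first: portal wins conflicts)
    for y0 in _lattice_positions(ny, s, 0.0):
        for x0 in _lattice_positions(nx, s, 0.0):
            _grow_trunk(labels, rng, LabelCodes.PORTAL, y0, x0,
                        portal_r, s / 2.0, jitter)
    _guard_existing(labels)
    # central trunks at cell centres
    for y0 in _lattice_positions(ny, s, s / 2.0):
        for x0 in _lattice_positions(nx, s, s / 2.0):
            _grow_trunk(labels, rng, LabelCodes.CENTRAL, y0, x0,
                        central_r, s / 2.0, jitter)
    _clear_guard(labels)


def _build_submicron_trees(params: PhantomParams, labels: np.ndarray) -> None:
    nz, ny, nx = labels.shape
    rng = params.rng(1)
    central_r = 12.0
    portal_r = 9.0
    _grow_trunk(labels, rng, LabelCodes.PORTAL, 2.0, 2.0, portal_r, ny / 4.0, 2.0)
    _grow_trunk(labels, rng, LabelCodes.PORTAL, ny - 3.0, nx - 3.0, portal_r,
                ny / 4.0, 2.0)
    _guard_existing(labels)
    _grow_trunk(labels, rng, LabelCodes.CENTRAL, ny / 2.0, nx / 2.0, central_r,
                ny / 3.0, 2.0)
    _guard_existing(labels)
    # radial sinusoid spokes around (but not touching) the central trunk
    sin_r = params.sinusoid_radius_um / params.voxel_size_um
    z_step = 26
    n_az = 14
    cy, cx = ny / 2.0, nx / 2.0
    rmax = float(np.hypot(ny, nx))
    for z0 in np.arange(z_step / 2, nz, z_step):
        for k in range(n_az):
            az = 2 * np.pi * (k + rng.uniform(-0.25, 0.25)) / n_az
            zj = z0 + rng.uniform(-4, 4)
            drift = rng.uniform(-8, 8)
            start = np.array([zj, cy + (central_r + 4) * np.sin(az),
                              cx + (central_r + 4) * np.cos(az)])
            end = np.array([zj + drift, cy + rmax * np.sin(az), cx + rmax * np.cos(az)])
            rasterize_tube(labels, start, end, sin_r, LabelCodes.SINUSOID)
    _clear_guard(labels)


def build_vessel_trees(params: PhantomParams) -> PhantomTruth:
    """Generate the vascular label grid (portal, central, sinusoids).

    Portal and central labels are disjoint by construction (portal is
    rasterized first and never overwritten).  Raises
    :class:`~infarct3d.errors.PlacementError` if the grid is too small to
    hold non-overlapping trees.
    """
    shape = tuple(params.grid_shape)
    if min(shape) < 16:
        raise PlacementError(
            f"grid {shape} too small to place non-overlapping portal and "
            "central trees (need at least 16 voxels per axis)")
    labels = np.zeros(shape, dtype=np.int32)
    if params.is_submicron:
        _build_submicron_trees(params, labels)
    else:
        _build_lobe_trees(params, labels)
    for code, name in ((LabelCodes.PORTAL, "portal"), (LabelCodes.CENTRAL, "central")):
        if not np.any(labels == code):
            raise PlacementError(f"failed to place the {name} tree on grid {shape}")
    return PhantomTruth(labels=labels, voxel_size_um=params.voxel_size_um,
                        day=params.day, seed=params.seed)
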