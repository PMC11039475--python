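"""The universal 3D image carrier and its on-disk representation.

A :class:`VoxelVolume` is a 3D scalar grid in ``(z, y, x)`` order with an
isotropic physical voxel size in micrometres.  Volumes are stored as
multi-page TIFF stacks (one page per z-slice) with a JSON sidecar holding
the physical metadata; the pair round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import MetadataError

__all__ = ["VoxelVolume", "read_volume", "write_volume"]


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic physical voxel size.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``, 0-based.
    voxel_size_um
        Physical edge length of one voxel in micrometres (isotropic).
    origin_um
        Physical offset of voxel ``(0, 0, 0)``; physical position of index
        ``i`` is ``i * voxel_size_um + origin_um``.
    """

    data: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all grid extents must be >= 1, got {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        self.origin_um = tuple(float(v) for v in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of a single voxel in µm³."""
        return float(self.voxel_size_um) ** 3

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_um for s in self.data.shape)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: VoxelVolume, path: str | Path, **sidecar_extra) -> Path:
    """Write a volume as a multi-page TIFF plus JSON metadata sidecar.

    Extra keyword arguments are stored verbatim in the sidecar (e.g. the
    generating seed, a configuration hash, a label dictionary).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data)
    meta = {
        "voxel_size_um": float(volume.voxel_size_um),
        "origin_um": list(volume.origin_um),
        "dtype": str(volume.data.dtype),
        "shape": list(volume.data.shape),
    }
    meta.update(sidecar_extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a TIFF stack written by :func:`write_volume`.

    Raises
    ------
    MetadataError
        If the sidecar is missing, lacks a voxel size, or declares an
        anisotropic voxel (the pipeline assumes isotropic voxels).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"no metadata sidecar {sidecar.name!r} next to {path.name!r}; "
            "a voxel size is required and never defaulted silently"
        )
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise MetadataError(f"sidecar {sidecar.name!r} lacks 'voxel_size_um'")
    vs = meta["voxel_size_um"]
    if isinstance(vs, (list, tuple)):
        if len(set(float(v) for v in vs)) != 1:
            raise MetadataError(
                f"anisotropic voxel size {vs} not supported: the pipeline "
                "assumes isotropic voxels; resample the volume first"
            )
        vs = float(vs[0])
    data = tifffile.imread(path)
    if data.ndim == 2:  # single-page stack
        data = data[None]
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    return VoxelVolume(data=data, voxel_size_um=float(vs), origin_um=origin)
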