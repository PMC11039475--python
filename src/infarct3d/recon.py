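"""Miniature parallel-beam propagation-based phase-contrast CT.

The X-ray refractive index of the sample is n = 1 − δ + iβ.  Soft tissue
has δ up to three orders of magnitude larger than β, which is what makes
free-space propagation (edge fringes) such a strong contrast mechanism.

Forward model: for each projection angle the complex transmission of the
sample is built from line integrals of δ (phase φ = −(2π/λ)∫δ ds) and β
(amplitude exp(−(2π/λ)∫β ds)), the wave is propagated to the detector by
the paraxial Fresnel kernel, the intensity |u|² is blurred by a Gaussian
detector PSF, modulated by an illumination (flat) profile, offset by a dark
level, and optionally Poisson-sampled.

Inverse chain: flat/dark correction, single-distance phase–attenuation
duality retrieval (divide the frame spectrum by 1 + π λ D (δ/β) |f|², then
−log — valid for a single material with proportional δ and β), and
slice-wise filtered back-projection over 180°.

The forward projector reproduces ``skimage.transform.radon`` exactly
(rotation by −θ about (n//2, n//2), summation along the first axis), so
``iradon`` is a consistent inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import iradon

from .errors import (CorrectionError, FieldOfViewError, GeometryError,
                     InsufficientDataError)
from .volume import VoxelVolume

__all__ = [
    "HC_UM_KEV", "BeamGeometry", "OpticalPhantom", "ProjectionSet",
    "SimulatedAcquisition", "LOBE_GEOMETRY", "SUBMICRON_GEOMETRY",
    "simulate_projections", "flat_dark_correct", "correct_projection_set",
    "phase_retrieve", "fbp_reconstruct", "beta_from_mu", "mu_from_beta",
    "grayscale_to_optical",
]

#: hc in µm·keV: wavelength_um = HC_UM_KEV / energy_keV
#: (1.23984193 eV·µm; 16 keV -> 0.775 Å)
HC_UM_KEV = 1.23984193e-3

#: Soft-tissue-like refractive index decrement used for invented fixtures;
#: δ/β ≈ 2000 at these energies.
DELTA_TISSUE = 7.0e-7
DELTA_BETA_RATIO_TISSUE = 2000.0


@dataclass(frozen=True)
class BeamGeometry:
    """Parallel-beam acquisition geometry."""

    energy_keV: float
    distance_cm: float          # sample-to-detector propagation distance D
    pixel_size_um: float
    n_angles: int               # projections uniformly spanning 180°

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise GeometryError(f"propagation distance must be > 0 cm, got {self.distance_cm}")
        if self.energy_keV <= 0 or self.pixel_size_um <= 0:
            raise GeometryError("energy and pixel size must be positive")
        if self.n_angles < 1:
            raise GeometryError("need at least one projection angle")

    @property
    def wavelength_um(self) -> float:
        return HC_UM_KEV / self.energy_keV

    @property
    def distance_um(self) -> float:
        return self.distance_cm * 1.0e4

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * 180.0 / self.n_angles


#: Acquisition presets for the two experimental scales.
LOBE_GEOMETRY = BeamGeometry(energy_keV=16.0, distance_cm=28.0,
                             pixel_size_um=3.25, n_angles=1200)
SUBMICRON_GEOMETRY = BeamGeometry(energy_keV=14.0, distance_cm=16.0,
                                  pixel_size_um=0.65, n_angles=900)


@dataclass
class OpticalPhantom:
    """δ/β grids defining the complex refractive index n = 1 − δ + iβ."""

    delta: np.ndarray
    beta: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.delta.shape != self.beta.shape:
            raise ValueError("delta and beta grids must share one shape")
        if (self.delta < 0).any() or (self.beta < 0).any():
            raise ValueError("delta and beta must be non-negative")


@dataclass
class ProjectionSet:
    """Stack of detector frames indexed by angle."""

    frames: np.ndarray          # (n_angles, nz, nx)
    geometry: BeamGeometry
    corrected: bool = False
    retrieved: bool = False

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.geometry.n_angles:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != n_angles {self.geometry.n_angles}")


@dataclass
class SimulatedAcquisition:
    """Raw projections plus the reference frames needed for correction."""

    raw: ProjectionSet
    flats: np.ndarray           # (n_flats, nz, nx)
    darks: np.ndarray           # (n_darks, nz, nx)


def _rotate_zyx(volume: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the z axis by −angle about (n//2, n//2), matching the
    skimage radon convention."""
    a = np.deg2rad(-angle_deg)
    c, s = np.cos(a), np.sin(a)
    m = np.array([[1.0, 0, 0], [0, c, s], [0, -s, c]])
    ctr = np.array([0.0, volume.shape[1] // 2, volume.shape[2] // 2])
    offset = ctr - m @ ctr
    return ndimage.affine_transform(volume, m, offset=offset, order=1)


def project_volume(volume: np.ndarray, angles_deg: np.ndarray,
                   voxel_size_um: float) -> np.ndarray:
    """Parallel-beam line integrals ∫f ds (µm units) for each angle.

    Output shape ``(n_angles, nz, nx)``; slice ``[i, z, :]`` equals
    ``skimage.transform.radon`` of the (y, x) slice at that z.
    """
    out = np.empty((len(angles_deg),) + (volume.shape[0], volume.shape[2]),
                   dtype=np.float64)
    for i, ang in enumerate(angles_deg):
        out[i] = _rotate_zyx(volume, ang).sum(axis=1) * voxel_size_um
    return out


def _freq_grid(nz: int, nx: int, pixel_size_um: float) -> np.ndarray:
    fz = np.fft.fftfreq(nz, d=pixel_size_um)
    fx = np.fft.fftfreq(nx, d=pixel_size_um)
    return fz[:, None] ** 2 + fx[None, :] ** 2


def _gaussian_psf(frame: np.ndarray, fwhm_px: float) -> np.ndarray:
    if fwhm_px <= 0:
        return frame
    return ndimage.gaussian_filter(frame, sigma=fwhm_px / 2.3548200450309493)


def _flat_profile(nz: int, nx: int) -> np.ndarray:
    """Smooth illumination inhomogeneity (fixed, beam-like vertical falloff
    plus a broad Gaussian hot spot)."""
    z = np.linspace(-1, 1, nz)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    return 1.0 + 0.08 * np.exp(-(z ** 2 + x ** 2) / 0.8) - 0.04 * z ** 2


def simulate_projections(phantom: OpticalPhantom, geometry: BeamGeometry,
                         noise_photons: float = 0.0, psf_fwhm_px: float = 1.0,
                         n_flats: int = 10, n_darks: int = 5,
                         rng: np.random.Generator | None = None) -> SimulatedAcquisition:
    """Simulate a full acquisition: raw frames, flat fields and dark fields.

    ``noise_photons`` is the mean photon count per detector pixel in the
    flat beam; 0 disables noise entirely (raw = flat·I + dark exactly).
    """
    if phantom.voxel_size_um != geometry.pixel_size_um:
        raise GeometryError(
            f"phantom voxel size {phantom.voxel_size_um} µm must equal the "
            f"detector pixel size {geometry.pixel_size_um} µm (parallel beam)")
    nz, ny, nx = phantom.delta.shape
    # the object must stay inside the inscribed cylinder so every projection
    # sees all of it
    yy, xx = np.mgrid[0:ny, 0:nx]
    outside = (yy - ny // 2) ** 2 + (xx - nx // 2) ** 2 > (min(ny, nx) / 2.0 - 1.0) ** 2
    material = phantom.delta + phantom.beta
    if float((material * outside[None, :, :]).max()) > 1e-6 * float(material.max() or 1.0):
        raise FieldOfViewError(
            "phantom extends beyond the inscribed cylinder of the grid; it "
            "would leave the detector field of view during rotation")
    lam = geometry.wavelength_um
    k2pi = 2.0 * np.pi / lam
    f2 = _freq_grid(nz, nx, geometry.pixel_size_um)
    fresnel = np.exp(-1j * np.pi * lam * geometry.distance_um * f2)
    pd_delta = project_volume(phantom.delta, geometry.angles_deg,
                              geometry.pixel_size_um)
    beta_sum = float(phantom.beta.sum())
    if beta_sum > 0 and phantom.delta.sum() > 0 \
            and np.allclose(phantom.beta * (phantom.delta.sum() / beta_sum),
                            phantom.delta, rtol=1e-9, atol=1e-30):
        # single material: β strictly proportional to δ, reuse the projection
        pd_beta = pd_delta * (beta_sum / phantom.delta.sum())
    else:
        pd_beta = project_volume(phantom.beta, geometry.angles_deg,
                                 geometry.pixel_size_um)
    frames = np.empty_like(pd_delta)
    for i in range(geometry.n_angles):
        u = np.exp(1j * (-k2pi * pd_delta[i]) - k2pi * pd_beta[i])
        u_det = np.fft.ifft2(np.fft.fft2(u) * fresnel)
        frames[i] = _gaussian_psf(np.abs(u_det) ** 2, psf_fwhm_px)

    photons = noise_photons if noise_photons > 0 else 1.0
    flat = photons * _flat_profile(nz, nx)
    dark_level = 0.01 * photons
    if noise_photons > 0:
        rng = rng if rng is not None else np.random.default_rng()
        raw = rng.poisson(flat[None] * frames).astype(np.float64) + dark_level
        flats = rng.poisson(np.broadcast_to(flat, (n_flats, nz, nx))
                            ).astype(np.float64) + dark_level
        darks = np.full((n_darks, nz, nx), dark_level, dtype=np.float64)
    else:
        raw = flat[None] * frames + dark_level
        flats = np.broadcast_to(flat, (n_flats, nz, nx)).copy() + dark_level
        darks = np.full((n_darks, nz, nx), dark_level, dtype=np.float64)
    return SimulatedAcquisition(
        raw=ProjectionSet(frames=raw, geometry=geometry, corrected=False),
        flats=flats, darks=darks)


def flat_dark_correct(raw: np.ndarray, flat: np.ndarray,
                      dark: np.ndarray) -> np.ndarray:
    """Normalize one frame: (raw − dark) / (flat − dark).

    Pixels where flat − dark ≤ 0 are replaced by the median of their
    neighbourhood after correction.  Raises
    :class:`~infarct3d.errors.CorrectionError` when no pixel is usable.
    """
    raw = np.asarray(raw, dtype=np.float64)
    flat = np.asarray(flat, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    if not (raw.shape == flat.shape == dark.shape):
        raise ValueError("raw, flat and dark frames must share one shape")
    denom = flat - dark
    bad = denom <= 0
    if bad.all():
        raise CorrectionError("flat - dark is non-positive everywhere")
    out = np.empty_like(raw)
    np.divide(raw - dark, denom, out=out, where=~bad)
    if bad.any():
        med = ndimage.median_filter(np.where(bad, 0.0, out), size=3)
        out[bad] = med[bad]
    return out


def correct_projection_set(acq: SimulatedAcquisition) -> ProjectionSet:
    """Flat/dark-correct every raw frame using the mean references."""
    flat = acq.flats.mean(axis=0)
    dark = acq.darks.mean(axis=0)
    frames = np.stack([flat_dark_correct(fr, flat, dark) for fr in acq.raw.frames])
    return ProjectionSet(frames=np.clip(frames, 0.0, None),
                         geometry=acq.raw.geometry, corrected=True)


def phase_retrieve(projections: ProjectionSet,
                   delta_beta_ratio: float) -> ProjectionSet:
    """Single-distance phase–attenuation duality retrieval.

    Each corrected frame is filtered in frequency space by
    ``1 / (1 + π λ D (δ/β) |f|²)`` and −log-transformed, yielding a map of
    the projected attenuation ∫μ ds with μ = (4π/λ)β.  As δ/β → 0 the
    filter reduces to the identity (plain −log absorption).
    """
    if not projections.corrected:
        raise RuntimeError("projections must be flat/dark-corrected before "
                           "phase retrieval")
    if delta_beta_ratio <= 0:
        raise ValueError(f"delta_beta_ratio must be > 0, got {delta_beta_ratio}")
    geo = projections.geometry
    _, nz, nx = projections.frames.shape
    f2 = _freq_grid(nz, nx, geo.pixel_size_um)
    denom = 1.0 + np.pi * geo.wavelength_um * geo.distance_um * delta_beta_ratio * f2
    out = np.empty_like(projections.frames)
    for i, frame in enumerate(projections.frames):
        filt = np.fft.ifft2(np.fft.fft2(frame) / denom).real
        out[i] = -np.log(np.clip(filt, 1e-12, None))
    return ProjectionSet(frames=out, geometry=geo, corrected=True, retrieved=True)


def fbp_reconstruct(projections: ProjectionSet,
                    filter_name: str = "ramp") -> VoxelVolume:
    """Slice-wise filtered back-projection of retrieved projections.

    Returns the μ volume in µm⁻¹ on the detector pixel grid.
    """
    if projections.geometry.n_angles < 2:
        raise InsufficientDataError(
            "filtered back-projection needs more than one projection angle")
    if filter_name not in ("ramp", "shepp-logan"):
        raise ValueError(f"unknown filter {filter_name!r}")
    geo = projections.geometry
    n_angles, nz, nx = projections.frames.shape
    angles = geo.angles_deg
    out = np.empty((nz, nx, nx), dtype=np.float64)
    for z in range(nz):
        sino = projections.frames[:, z, :].T          # (nx, n_angles)
        rec = iradon(sino, theta=angles, filter_name=filter_name,
                     output_size=nx, circle=True)
        out[z] = rec / geo.pixel_size_um              # line integrals were in µm
    return VoxelVolume(data=out, voxel_size_um=geo.pixel_size_um)


def beta_from_mu(mu_per_um: np.ndarray, wavelength_um: float) -> np.ndarray:
    """β = μ λ / 4π."""
    return np.asarray(mu_per_um) * wavelength_um / (4.0 * np.pi)


def mu_from_beta(beta: np.ndarray, wavelength_um: float) -> np.ndarray:
    """μ = 4π β / λ (per µm)."""
    return 4.0 * np.pi * np.asarray(beta) / wavelength_um


def grayscale_to_optical(volume: VoxelVolume,
                         delta_scale: float = DELTA_TISSUE,
                         delta_beta_ratio: float = DELTA_BETA_RATIO_TISSUE
                         ) -> OpticalPhantom:
    """Map a rendered grayscale phantom onto a single-material δ/β phantom.

    Intensity is interpreted as relative tissue density: δ is proportional
    to the gray level (scaled so parenchyma-bright voxels sit near
    ``delta_scale``), β = δ / ratio, and everything outside the inscribed
    cylinder is cleared so the object fits the field of view.
    """
    g = np.clip(np.asarray(volume.data, dtype=np.float64), 0.0, None)
    delta = delta_scale * g / max(float(g.max()), 1e-12)
    nz, ny, nx = delta.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    inside = (yy - ny // 2) ** 2 + (xx - nx // 2) ** 2 <= (min(ny, nx) / 2.0 - 1.5) ** 2
    delta *= inside[None]
    return OpticalPhantom(delta=delta, beta=delta / delta_beta_ratio,
                          voxel_size_um=volume.voxel_size_um)
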