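"""Simulate a phase-contrast acquisition and reconstruct it.

A homogeneous soft-tissue-like blob (δ/β = 2000) is projected with full
Fresnel propagation at the lobe-scale geometry (16 keV, 28 cm, 3.25 µm),
flat/dark-corrected, phase-retrieved with the single-distance duality
filter and reconstructed by filtered back-projection.  The reconstructed
attenuation map should match the ground truth almost perfectly — the
round trip is the self-consistency check of the whole imaging chain.
"""

import numpy as np
from scipy import ndimage

from infarct3d import recon as rc

n = 64
zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
c = n / 2 - 0.5
blob = (((zz - c) ** 2 / (0.6 * n / 4) ** 2 + (yy - c) ** 2 / (n / 4) ** 2
         + (xx - c) ** 2 / (0.8 * n / 4) ** 2) <= 1.0).astype(float)
delta = 7e-7 * ndimage.gaussian_filter(blob, 2.0)   # soft tissue δ; max phase ≈ 1 rad
phantom = rc.OpticalPhantom(delta, delta / rc.DELTA_BETA_RATIO_TISSUE, 3.25)

geo = rc.BeamGeometry(energy_keV=16.0, distance_cm=28.0,
                      pixel_size_um=3.25, n_angles=200)
acq = rc.simulate_projections(phantom, geo, noise_photons=20000.0,
                              rng=np.random.default_rng(0))
retrieved = rc.phase_retrieve(rc.correct_projection_set(acq),
                              rc.DELTA_BETA_RATIO_TISSUE)
vol = rc.fbp_reconstruct(retrieved)

mu_true = rc.mu_from_beta(phantom.beta, geo.wavelength_um)
corr = np.corrcoef(vol.data.ravel(), mu_true.ravel())[0, 1]
print(f"wavelength {geo.wavelength_um * 1e4:.3f} Å "
      f"({geo.wavelength_um:.3e} µm), {geo.n_angles} angles over 180°")
print(f"reconstruction/truth correlation: {corr:.4f}")
print("(> 0.99 means the simulate→correct→retrieve→FBP chain is "
      "self-consistent at this phase strength)")
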