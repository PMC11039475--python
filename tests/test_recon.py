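"""Phase-contrast CT chain: forward model, correction, duality retrieval,
filtered back-projection, and their round-trip consistency."""

import numpy as np
import pytest
from scipy import ndimage

from infarct3d.errors import (CorrectionError, FieldOfViewError, GeometryError,
                              InsufficientDataError)
from infarct3d.recon import (DELTA_BETA_RATIO_TISSUE, LOBE_GEOMETRY,
                             SUBMICRON_GEOMETRY, BeamGeometry, OpticalPhantom,
                             ProjectionSet, correct_projection_set,
                             fbp_reconstruct, flat_dark_correct, mu_from_beta,
                             phase_retrieve, project_volume,
                             simulate_projections)


def _geometry(n_angles=60, px=3.25):
    return BeamGeometry(energy_keV=16.0, distance_cm=28.0, pixel_size_um=px,
                        n_angles=n_angles)


def _smooth_blob(n, amplitude, sigma=2.0):
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = n / 2 - 0.5
    blob = (((zz - c) ** 2 / (0.6 * n / 4) ** 2 + (yy - c) ** 2 / (n / 4) ** 2
             + (xx - c) ** 2 / (0.8 * n / 4) ** 2) <= 1.0).astype(float)
    return amplitude * ndimage.gaussian_filter(blob, sigma)


class TestGeometry:
    def test_wavelength_energy_relation(self):
        assert LOBE_GEOMETRY.wavelength_um \
            == pytest.approx(1.23984193e-3 / 16.0, rel=1e-12)
        assert SUBMICRON_GEOMETRY.wavelength_um \
            == pytest.approx(1.23984193e-3 / 14.0, rel=1e-12)

    def test_presets_match_acquisition_table(self):
        assert (LOBE_GEOMETRY.energy_keV, LOBE_GEOMETRY.distance_cm,
                LOBE_GEOMETRY.pixel_size_um, LOBE_GEOMETRY.n_angles) \
            == (16.0, 28.0, 3.25, 1200)
        assert (SUBMICRON_GEOMETRY.energy_keV, SUBMICRON_GEOMETRY.distance_cm,
                SUBMICRON_GEOMETRY.pixel_size_um, SUBMICRON_GEOMETRY.n_angles) \
            == (14.0, 16.0, 0.65, 900)

    def test_non_positive_distance_rejected(self):
        with pytest.raises(GeometryError):
            BeamGeometry(16.0, 0.0, 3.25, 100)

    def test_phantom_wider_than_field_of_view_rejected(self):
        delta = np.zeros((8, 16, 16))
        delta[:, 0, 0] = 1e-7       # outside the inscribed cylinder
        ph = OpticalPhantom(delta, delta, voxel_size_um=3.25)
        with pytest.raises(FieldOfViewError):
            simulate_projections(ph, _geometry(4))


class TestForwardModel:
    def test_empty_phantom_gives_unit_frames(self):
        n = 24
        ph = OpticalPhantom(np.zeros((n, n, n)), np.zeros((n, n, n)), 3.25)
        acq = simulate_projections(ph, _geometry(8), noise_photons=0)
        corr = correct_projection_set(acq)
        assert np.allclose(corr.frames, 1.0, atol=1e-9)

    def test_pure_absorption_matches_beer_lambert_at_contact(self):
        # D -> 0: no propagation contrast, frames are exp(-∫µ ds)
        n = 32
        beta = np.zeros((n, n, n))
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        c = n / 2 - 0.5
        beta[((yy - c) ** 2 + (xx - c) ** 2) <= (n / 5) ** 2] = 3.5e-10
        geo = BeamGeometry(16.0, 1e-6, 3.25, 12)
        ph = OpticalPhantom(np.zeros_like(beta), beta, 3.25)
        acq = simulate_projections(ph, geo, noise_photons=0, psf_fwhm_px=0.0)
        corr = correct_projection_set(acq)
        mu_proj = project_volume(mu_from_beta(beta, geo.wavelength_um),
                                 geo.angles_deg, 3.25)
        assert np.allclose(corr.frames, np.exp(-mu_proj), atol=1e-6)

    def test_pure_phase_rod_shows_edge_fringes(self):
        # a non-absorbing object is invisible at contact but fringes appear
        # after 28 cm of propagation
        n = 48
        delta = np.zeros((n, n, n))
        delta[:, n // 2 - 3:n // 2 + 3, n // 2 - 3:n // 2 + 3] = 7e-7
        ph = OpticalPhantom(delta, np.zeros_like(delta), 3.25)
        acq = simulate_projections(ph, _geometry(1), noise_photons=0)
        corr = correct_projection_set(acq)
        assert corr.frames[0].var() > 1e-5
        assert corr.frames[0].max() > 1.02 and corr.frames[0].min() < 0.98


class TestCorrection:
    def test_uniform_arithmetic(self):
        raw = np.full((8, 8), 150.0)
        dark = np.full((8, 8), 50.0)
        flat = np.full((8, 8), 250.0)
        assert np.allclose(flat_dark_correct(raw, flat, dark), 0.5)

    def test_raw_equal_flat_gives_unity(self, rng):
        flat = rng.uniform(100, 200, (8, 8))
        dark = rng.uniform(0, 10, (8, 8))
        assert np.allclose(flat_dark_correct(flat, flat, dark), 1.0)

    def test_matches_elementwise_oracle(self, rng):
        raw = rng.uniform(0, 300, (16, 16))
        flat = rng.uniform(100, 300, (16, 16))
        dark = rng.uniform(0, 20, (16, 16))
        out = flat_dark_correct(raw, flat, dark)
        assert np.array_equal(out, (raw - dark) / (flat - dark))

    def test_degenerate_references_raise(self):
        z = np.zeros((4, 4))
        with pytest.raises(CorrectionError):
            flat_dark_correct(z, z, z)

    def test_dead_pixels_filled_from_neighbours(self):
        raw = np.full((8, 8), 150.0)
        dark = np.full((8, 8), 50.0)
        flat = np.full((8, 8), 250.0)
        flat[3, 3] = 0.0            # dead pixel: flat - dark < 0
        out = flat_dark_correct(raw, flat, dark)
        assert out[3, 3] == pytest.approx(0.5)


class TestRetrieval:
    def test_flat_frames_retrieve_to_zero(self):
        geo = _geometry(4)
        ps = ProjectionSet(np.ones((4, 16, 16)), geo, corrected=True)
        out = phase_retrieve(ps, 1000.0)
        assert np.allclose(out.frames, 0.0, atol=1e-9)

    def test_vanishing_ratio_reduces_to_log_absorption(self, rng):
        geo = _geometry(4)
        frames = rng.uniform(0.5, 1.0, (4, 16, 16))
        ps = ProjectionSet(frames, geo, corrected=True)
        out = phase_retrieve(ps, 1e-12)
        assert np.allclose(out.frames, -np.log(frames), atol=1e-6)

    def test_uncorrected_input_is_a_state_error(self):
        ps = ProjectionSet(np.ones((4, 8, 8)), _geometry(4), corrected=False)
        with pytest.raises(RuntimeError):
            phase_retrieve(ps, 100.0)
        with pytest.raises(ValueError):
            phase_retrieve(ProjectionSet(np.ones((4, 8, 8)), _geometry(4),
                                         corrected=True), -1.0)

    def test_filter_is_low_pass_and_monotone_in_ratio(self, rng):
        geo = _geometry(1)
        frame = 1.0 + 0.05 * rng.standard_normal((64, 64))
        ps = ProjectionSet(frame[None], geo, corrected=True)

        def hf_power(ratio):
            out = np.exp(-phase_retrieve(ps, ratio).frames[0])
            spec = np.abs(np.fft.fft2(out - out.mean())) ** 2
            f2 = np.add.outer(np.fft.fftfreq(64) ** 2, np.fft.fftfreq(64) ** 2)
            return spec[f2 > 0.1 ** 2].sum()

        raw_power = hf_power(1e-12)
        powers = [hf_power(r) for r in (10.0, 100.0, 1000.0)]
        assert powers[0] <= raw_power * (1 + 1e-9)
        assert powers == sorted(powers, reverse=True)

    def test_homogeneous_round_trip_recovers_projected_attenuation(self):
        # simulate with the same δ/β the filter assumes: retrieved maps must
        # equal the true ∫µ ds within 2 % RMS away from support edges
        n = 48
        delta = _smooth_blob(n, 7e-7)
        ph = OpticalPhantom(delta, delta / DELTA_BETA_RATIO_TISSUE, 3.25)
        geo = _geometry(8)
        acq = simulate_projections(ph, geo, noise_photons=0)
        ret = phase_retrieve(correct_projection_set(acq), DELTA_BETA_RATIO_TISSUE)
        mu_proj = project_volume(mu_from_beta(ph.beta, geo.wavelength_um),
                                 geo.angles_deg, 3.25)
        interior = mu_proj > 0.7 * mu_proj.max()
        rms = np.sqrt(((ret.frames - mu_proj)[interior] ** 2).mean())
        assert rms / mu_proj[interior].mean() < 0.02


class TestFBP:
    def test_zero_sinogram_reconstructs_zero(self):
        geo = _geometry(30)
        ps = ProjectionSet(np.zeros((30, 4, 32)), geo, corrected=True,
                           retrieved=True)
        vol = fbp_reconstruct(ps)
        assert np.allclose(vol.data, 0.0)

    def test_single_angle_is_insufficient(self):
        geo = _geometry(1)
        ps = ProjectionSet(np.zeros((1, 4, 32)), geo, corrected=True)
        with pytest.raises(InsufficientDataError):
            fbp_reconstruct(ps)

    def test_uniform_disk_interior_within_two_percent(self):
        n = 64
        geo = _geometry(400, px=1.0)
        f = np.zeros((1, n, n))
        yy, xx = np.mgrid[0:n, 0:n]
        disk = ((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= (n // 5) ** 2
        f[0][disk] = 0.02
        sino = project_volume(f, geo.angles_deg, 1.0)
        ps = ProjectionSet(sino, geo, corrected=True, retrieved=True)
        rec = fbp_reconstruct(ps).data[0]
        core = ndimage.binary_erosion(disk, iterations=3)
        rms = np.sqrt(((rec[core] - 0.02) ** 2).mean())
        assert rms / 0.02 < 0.02

    def test_point_impulse_reconstructs_at_true_location(self):
        n = 48
        geo = _geometry(200, px=1.0)
        f = np.zeros((1, n, n))
        f[0, 30, 19] = 1.0
        sino = project_volume(f, geo.angles_deg, 1.0)
        ps = ProjectionSet(sino, geo, corrected=True, retrieved=True)
        rec = fbp_reconstruct(ps).data[0]
        assert np.unravel_index(np.argmax(rec), rec.shape) == (30, 19)

    def test_linearity(self, rng):
        geo = _geometry(40, px=1.0)
        s1 = rng.random((40, 2, 24))
        s2 = rng.random((40, 2, 24))
        r = lambda s: fbp_reconstruct(
            ProjectionSet(s, geo, corrected=True, retrieved=True)).data
        assert np.allclose(r(s1 + 2 * s2), r(s1) + 2 * r(s2), atol=1e-9)


class TestRoundTrip:
    def test_full_chain_correlates_with_truth(self):
        # scaled-down version of the flagship consistency check
        n = 64
        delta = _smooth_blob(n, 7e-7)
        ph = OpticalPhantom(delta, delta / DELTA_BETA_RATIO_TISSUE, 3.25)
        geo = _geometry(120)
        acq = simulate_projections(ph, geo, noise_photons=0)
        ret = phase_retrieve(correct_projection_set(acq), DELTA_BETA_RATIO_TISSUE)
        rec = fbp_reconstruct(ret)
        mu_true = mu_from_beta(ph.beta, geo.wavelength_um)
        corr = np.corrcoef(rec.data.ravel(), mu_true.ravel())[0, 1]
        assert corr > 0.95
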