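"""Morphometry: sphericity oracles, confluence classifier, microchannel
detection and calibre estimation, lobe summaries."""

import numpy as np
import pytest
from scipy import ndimage

from infarct3d.morphometry import (classify_confluence, detect_microchannels,
                                   estimate_tube_diameter, measure_component,
                                   measure_infarcts, sphericity,
                                   summarize_lobe)
from infarct3d.phantom import rasterize_tube


def _ball(radius, pad=2):
    n = int(2 * radius) + 2 * pad + 1
    c = n // 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


class TestSphericity:
    def test_formula_identity_for_analytic_sphere(self):
        r = 7.0
        V = 4 / 3 * np.pi * r ** 3
        A = 4 * np.pi * r ** 2
        assert sphericity(V, A) == pytest.approx(1.0, rel=1e-12)

    def test_cube_closed_form(self):
        a = 12.0
        assert sphericity(a ** 3, 6 * a ** 2) \
            == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-12)

    @pytest.mark.parametrize("radius, tol", [(12, 0.05), (20, 0.03)])
    def test_voxelized_sphere_converges_to_one(self, radius, tol):
        V, A, psi, border = measure_component(_ball(radius), 1.0)
        assert not border
        assert psi == pytest.approx(1.0, abs=tol)
        assert V == pytest.approx(4 / 3 * np.pi * radius ** 3, rel=0.02)

    def test_voxelized_cube_near_closed_form(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:18, 2:18, 2:18] = True
        _, _, psi, _ = measure_component(mask, 1.0)
        assert psi == pytest.approx((np.pi / 6) ** (1 / 3), rel=0.05)

    def test_scale_invariance_of_psi(self):
        mask = _ball(10)
        psi1 = measure_component(mask, 1.0)[2]
        psi2 = measure_component(mask, 3.25)[2]
        assert psi2 == pytest.approx(psi1, rel=0.02)

    def test_border_touching_component_is_flagged(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[0:4, 3:7, 3:7] = True
        assert measure_component(mask, 1.0)[3] is True


class TestConfluence:
    def test_single_sphere_is_individual(self):
        cls, cores = classify_confluence(_ball(10), 1.0)
        assert (cls, cores) == ("individual", 1)

    def test_two_overlapping_spheres_are_confluent(self):
        r = 10
        n = 60
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        c1 = np.array([30, 30, 22])
        c2 = c1 + np.array([0, 0, int(1.6 * r)])
        mask = (((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2) <= r * r) \
            | (((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2) <= r * r)
        cls, cores = classify_confluence(mask, 1.0)
        assert (cls, cores) == ("confluent", 2)

    def test_stricter_core_fraction_never_creates_confluence(self):
        # monotonicity: raising min_core_fraction can only demote
        r = 10
        n = 60
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        mask = (((zz - 30) ** 2 + (yy - 30) ** 2 + (xx - 22) ** 2) <= r * r) \
            | (((zz - 30) ** 2 + (yy - 30) ** 2 + (xx - 38) ** 2) <= r * r)
        previous = 2
        for frac in (0.05, 0.2, 0.4, 0.6):
            _, cores = classify_confluence(mask, 1.0, min_core_fraction=frac)
            assert cores <= previous
            previous = cores

    def test_phantom_classification_accuracy(self, lobe_day3_noiseless):
        # vs truth cluster ids on a mid-course phantom
        _, truth, _, _ = lobe_day3_noiseless
        comp = truth.infarct_components()
        ct = truth.component_table().set_index("cluster_id")
        correct = total = 0
        for cid in ct.index:
            cls, _ = classify_confluence(comp == cid, truth.voxel_size_um)
            correct += (cls == "confluent") == bool(ct.loc[cid, "confluent"])
            total += 1
        assert correct / total >= 0.9


class TestMicrochannels:
    def _straight_channel_scene(self, diam_vox=5.0, gap=12):
        """Infarct slab and sinusoid slab bridged by one tube."""
        n = 40
        infarct = np.zeros((n, n, n), np.int32)
        infarct[:, :, :8] = 1
        sinusoid = np.zeros((n, n, n), bool)
        sinusoid[:, :, 8 + gap:] = True
        lumen = np.zeros((n, n, n), np.int32)
        rasterize_tube(lumen, (20, 20, 6), (20, 20, 8 + gap + 2), diam_vox / 2, 1)
        lumen = (lumen > 0) & (infarct == 0) & ~sinusoid
        return infarct, sinusoid, lumen

    def test_no_lumen_means_no_channels(self):
        infarct, sinusoid, lumen = self._straight_channel_scene()
        t = detect_microchannels(infarct, sinusoid, np.zeros_like(lumen), 1.0)
        assert t.n_channels.tolist() == [0]

    def test_single_bridge_counted_once_with_correct_calibre(self):
        infarct, sinusoid, lumen = self._straight_channel_scene(diam_vox=5.0)
        t = detect_microchannels(infarct, sinusoid, lumen, 1.0)
        assert t.n_channels.tolist() == [1]
        assert t.diam_mean_um.iloc[0] == pytest.approx(5.0, abs=1.0)

    def test_count_invariant_to_padding_and_relabeling(self):
        infarct, sinusoid, lumen = self._straight_channel_scene()
        t1 = detect_microchannels(infarct, sinusoid, lumen, 1.0)
        pad = [(4, 4)] * 3
        t2 = detect_microchannels(np.pad(infarct * 7, pad),
                                  np.pad(sinusoid, pad), np.pad(lumen, pad), 1.0)
        assert t1.n_channels.tolist() == t2.n_channels.tolist()

    def test_phantom_channels_recovered_per_component(self, submicron_small):
        params, truth, _, vol = submicron_small
        comp = truth.infarct_components()
        g = params.gray_levels
        lumen = np.asarray(vol.data) < (g["channel"] + g["infarct"]) / 2
        t = detect_microchannels(comp, truth.sinusoid_mask, lumen,
                                 truth.voxel_size_um,
                                 exclude_mask=truth.portal_mask | truth.central_mask)
        found = dict(zip(t.infarct_id, t.n_channels))
        ct = truth.component_table()
        expected = dict(zip(ct.cluster_id, ct.n_channels))
        matches = sum(found.get(c, 0) == expected[c] for c in expected)
        assert matches >= 0.75 * len(expected)
        assert sum(found.values()) == pytest.approx(sum(expected.values()),
                                                    abs=0.15 * max(sum(expected.values()), 1))

    def test_rasterized_tube_diameter_estimator(self, rng):
        # randomly oriented tubes at the physical channel calibre
        vs = 0.65
        diam = 3.41
        errs = []
        for _ in range(10):
            grid = np.zeros((48, 48, 48), np.int32)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            c = np.array([24.0, 24, 24])
            rasterize_tube(grid, c - 18 * d, c + 18 * d, diam / 2 / vs, 1)
            est, _, _ = estimate_tube_diameter(grid > 0, vs)
            errs.append(est - diam)
        assert abs(np.mean(errs)) <= vs  # within one voxel


class TestSummary:
    def test_volume_ratio_arithmetic(self):
        from infarct3d.morphometry import InfarctRecord
        rec = InfarctRecord(id=1, V=1000.0, A=500.0, psi=0.97, zone=1,
                            confluence="individual")
        s = summarize_lobe([rec], lobe_volume_um3=1e6)
        assert s.volume_ratio == pytest.approx(1e-3)
        assert s.n_infarcts == 1
        assert s.per_zone[1]["count_fraction"] == 1.0

    def test_empty_record_list_gives_zeroed_summary(self):
        s = summarize_lobe([], lobe_volume_um3=1e6)
        assert s.n_infarcts == 0 and s.total_volume_um3 == 0.0

    def test_total_volume_additivity(self, lobe_day3_noiseless):
        _, truth, zones, _ = lobe_day3_noiseless
        comp = truth.infarct_components()
        records = measure_infarcts(comp, truth.voxel_size_um, zones)
        s = summarize_lobe(records, 1e9, zones)
        assert s.total_volume_um3 == pytest.approx(sum(r.V for r in records))
        assert s.total_volume_um3 == pytest.approx(
            truth.infarct_table.volume_um3.sum(), rel=1e-9)
        fracs = [s.per_zone[z]["count_fraction"] for z in (1, 2, 3)]
        assert sum(fracs) == pytest.approx(1.0)
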