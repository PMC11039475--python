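"""Generator contracts: determinism, label disjointness, preset calibration,
placement statistics, microchannel construction."""

import numpy as np
import pytest
from scipy import ndimage

from infarct3d.errors import CapacityError, PlacementError, ScaleError
from infarct3d.phantom import (LabelCodes, build_vessel_trees, generate_phantom,
                               lobe_preset, place_microchannels,
                               render_grayscale, submicron_preset)


def _expected_mean_unit_volume(params):
    """E[4/3 π r³] for r ~ U[a, b] — closed-form oracle for the presets."""
    a, b = params.infarct_radius_um_range
    er3 = (b ** 4 - a ** 4) / (4.0 * (b - a))
    return 4.0 / 3.0 * np.pi * er3


class TestVesselTrees:
    def test_portal_and_central_never_overlap_or_touch(self):
        truth = build_vessel_trees(lobe_preset("1", grid=64, seed=7))
        assert not (truth.portal_mask & truth.central_mask).any()
        halo = ndimage.binary_dilation(truth.portal_mask, np.ones((3, 3, 3)))
        assert not (halo & truth.central_mask).any()

    def test_same_seed_reproduces_identical_grid(self):
        a = build_vessel_trees(lobe_preset("1", grid=64, seed=7))
        b = build_vessel_trees(lobe_preset("1", grid=64, seed=7))
        assert np.array_equal(a.labels, b.labels)

    def test_every_parenchyma_voxel_near_some_vessel(self):
        # interdigitated lattice keeps the whole tissue within ~half a
        # lobule period of a vessel
        truth = build_vessel_trees(lobe_preset("7", grid=128, seed=3))
        vessels = truth.portal_mask | truth.central_mask
        d = ndimage.distance_transform_edt(~vessels)
        assert d[truth.parenchyma_mask].max() <= 40.0

    def test_tiny_grid_raises_placement_error(self):
        with pytest.raises(PlacementError):
            build_vessel_trees(lobe_preset("1", grid=8, seed=0))


class TestInfarctPlacement:
    def test_day1_lesions_mostly_originate_in_zone_one(self):
        fracs = []
        for seed in range(5):
            truth, _, _ = generate_phantom(lobe_preset("1", grid=96, seed=seed))
            ct = truth.component_table()
            fracs.append((ct.origin_zone == 1).mean())
        assert np.mean(fracs) > 0.5

    def test_zero_confluent_fraction_gives_unique_clusters(self):
        params = lobe_preset("3", grid=96, seed=2, confluent_fraction=0.0)
        truth, _, _ = generate_phantom(params)
        t = truth.infarct_table
        assert t.cluster_id.nunique() == len(t)

    def test_day7_truth_confluent_fraction_matches_preset(self):
        # Bernoulli(0.25) over 5 seeds x 40 units
        hits, n = 0, 0
        for seed in range(5):
            truth, _, _ = generate_phantom(lobe_preset("7", grid=128, seed=seed))
            ct = truth.component_table()
            hits += ct.confluent.sum()
            n += len(ct)
        frac = hits / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) <= 3 * se

    def test_overloaded_grid_raises_capacity_error(self):
        params = lobe_preset("7", grid=48, seed=0,
                             infarct_radius_um_range=(40.0, 60.0))
        with pytest.raises(CapacityError):
            generate_phantom(params)

    def test_labels_partition_pairwise_disjoint(self, submicron_small):
        _, truth, _, _ = submicron_small
        masks = [truth.portal_mask, truth.central_mask, truth.sinusoid_mask,
                 truth.infarct_mask, truth.channel_mask]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not (masks[i] & masks[j]).any()


class TestPresets:
    def test_preset_schedule_monotone_in_day(self):
        presets = [lobe_preset(d, grid=64) for d in ("1", "3", "5", "7")]
        for attr in ("n_infarcts", "confluent_fraction"):
            vals = [getattr(p, attr) for p in presets]
            assert vals == sorted(vals)
        chan = [submicron_preset(d).microchannel_count_mean
                for d in ("1", "3", "5", "7")]
        assert chan == sorted(chan)
        assert chan == [1.86, 2.47, 3.38, 5.47]

    def test_expected_total_volume_ratio_day7_day1_is_nine(self):
        # closed-form oracle for the preset calibration: a lesion *unit*
        # carries, beyond the mean sphere volume, the extra blobs of fused
        # clusters (mean 1.5 satellites of relative volume E[u^3],
        # u ~ U[0.85, 1], overlap negligible at the generator separations)
        # and the roughness inflation E[(1 + eps*clip(f, ±2))^3] for unit
        # normal f
        from scipy.stats import norm

        def unit_volume(p):
            e_u3 = (1 - 0.85 ** 4) / (4 * (1 - 0.85))
            cluster = 1.0 + p.confluent_fraction * 1.5 * e_u3
            e_fc2 = 1.0 + 6 * norm.sf(2.0) - 4 * norm.pdf(2.0)
            rough = 1.0 + 3 * p.sphericity_roughness ** 2 * e_fc2
            return _expected_mean_unit_volume(p) * cluster * rough

        p1, p7 = lobe_preset("1"), lobe_preset("7")
        ratio = (p7.n_infarcts * unit_volume(p7)) \
            / (p1.n_infarcts * unit_volume(p1))
        assert ratio == pytest.approx(9.0, rel=0.075)

    def test_truth_total_volume_strictly_increasing_across_days(self):
        totals = []
        for day in ("1", "3", "5", "7"):
            truth, _, _ = generate_phantom(lobe_preset(day, grid=128, seed=4))
            totals.append(truth.infarct_table.volume_um3.sum())
        assert all(a < b for a, b in zip(totals, totals[1:]))


class TestMicrochannels:
    def test_zero_mean_places_no_channels(self):
        params = submicron_preset("1", grid=96, seed=3, n_infarcts=2,
                                  microchannel_count_mean=0.0)
        truth, _, _ = generate_phantom(params)
        assert not truth.channel_mask.any()

    def test_forced_count_three_channels_touch_both_structures(self):
        params = submicron_preset("1", grid=96, seed=3, n_infarcts=1)
        truth, zones, _ = generate_phantom(
            params.replace(microchannel_count_mean=0.0))
        truth = place_microchannels(params, truth, counts=3)
        assert truth.channel_table.shape[0] == 3
        comp = truth.infarct_components() > 0
        comp_halo = ndimage.binary_dilation(comp, np.ones((3, 3, 3)))
        sin_halo = ndimage.binary_dilation(truth.sinusoid_mask, np.ones((3, 3, 3)))
        for cid in truth.channel_table.channel_id:
            ch = truth.labels == cid
            assert (ch & comp_halo).any(), "channel must touch its infarct"
            assert (ch & sin_halo).any(), "channel must reach a sinusoid"

    def test_channel_is_connected_path_between_structures(self, submicron_small):
        # brute-force: infarct and sinusoid must be in one 26-connected
        # component once the channel lumen is added
        _, truth, _, _ = submicron_small
        cid = int(truth.channel_table.channel_id.iloc[0])
        unit = int(truth.channel_table.cluster_id.iloc[0])
        bridge = (truth.labels == cid) | (truth.infarct_components() == unit) \
            | truth.sinusoid_mask
        lbl, _ = ndimage.label(bridge, structure=np.ones((3, 3, 3)))
        ch_label = np.unique(lbl[truth.labels == cid])
        assert len(ch_label) == 1
        assert (lbl[truth.sinusoid_mask] == ch_label[0]).any()
        assert (lbl[truth.infarct_components() == unit] == ch_label[0]).any()

    def test_poisson_counts_recover_preset_mean(self):
        counts = []
        for seed in range(3):
            params = submicron_preset("7", grid=144, seed=seed, n_infarcts=12)
            truth, _, _ = generate_phantom(params)
            counts.extend(truth.component_table().n_channels.tolist())
        counts = np.asarray(counts)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 5.47) <= 3 * se

    def test_lobe_scale_channels_raise_scale_error(self):
        params = lobe_preset("1", grid=64, seed=0)
        truth, zones, _ = generate_phantom(params)
        with pytest.raises(ScaleError):
            place_microchannels(params, truth, counts=1)


class TestRendering:
    def test_noiseless_render_is_piecewise_constant(self, lobe_day3_noiseless):
        params, truth, _, vol = lobe_day3_noiseless
        g = params.gray_levels
        assert np.array_equal(np.unique(vol.data[truth.infarct_mask]),
                              [np.float32(g["infarct"])])
        assert np.array_equal(np.unique(vol.data[truth.parenchyma_mask]),
                              [np.float32(g["parenchyma"])])

    def test_infarcts_darker_than_parenchyma(self, lobe_day3):
        params, truth, _, vol = lobe_day3
        assert vol.data[truth.infarct_mask].mean() \
            < vol.data[truth.parenchyma_mask].mean() - 2 * params.noise_sd

    def test_same_seed_renders_bit_identical(self, lobe_day3):
        params, truth, _, vol = lobe_day3
        again = render_grayscale(truth, params)
        assert np.array_equal(vol.data, again.data)

    def test_missing_gray_level_names_the_class(self, lobe_day3):
        from infarct3d.errors import ConfigurationError
        params, truth, _, _ = lobe_day3
        levels = {k: v for k, v in params.gray_levels.items() if k != "infarct"}
        with pytest.raises(ConfigurationError, match="infarct"):
            render_grayscale(truth, params.replace(gray_levels=levels))
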