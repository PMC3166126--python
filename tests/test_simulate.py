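import numpy as np
import pytest
from scipy import ndimage

from lenstomo.simulate import (GoldAttachment, GroundTruth, SceneParams,
                               build_scene, rasterize, scene_particle_table,
                               sphere_phantom)
from lenstomo.classify import classify_unlabeled
from lenstomo.network import build_connections


def straight_params(**overrides):
    base = dict(seed=5, n_filaments=1, box_size=160, filament_length=70,
                spacing_jitter_sd=0.0, curvature_sd_deg=0.0,
                gold_label_fraction=0.0, bead_fraction=0.0)
    base.update(overrides)
    return SceneParams(**base)


class TestBuildScene:
    def test_monomer_sites_arithmetic_sequence(self):
        truth = build_scene(straight_params())
        assert truth.n_sites == 11
        np.testing.assert_allclose(truth.site_arc, np.arange(0, 71, 7.0))
        d = np.linalg.norm(np.diff(truth.site_positions, axis=0), axis=1)
        np.testing.assert_allclose(d, 7.0, atol=1e-9)

    @pytest.mark.parametrize("mode,multiple", [("monomer", 1),
                                               ("dimer_skip1", 2),
                                               ("dimer_skip2", 3)])
    def test_dimers_double_or_triple_the_repeat(self, mode, multiple):
        truth = build_scene(straight_params(decoration_mode=mode))
        d = np.linalg.norm(np.diff(truth.site_positions, axis=0), axis=1)
        np.testing.assert_allclose(d, 7.0 * multiple, atol=1e-9)
        assert truth.true_spacing == pytest.approx(7.0 * multiple)

    def test_jittered_spacing_sample_mean(self):
        params = SceneParams(seed=9, n_filaments=40, box_size=220,
                             filament_length=200, curvature_sd_deg=2.0,
                             spacing_jitter_sd=0.5, gold_label_fraction=0.0,
                             bead_fraction=0.0)
        truth = build_scene(params)
        dists = []
        for f in range(params.n_filaments):
            pos = truth.site_positions[truth.site_filament == f]
            dists.extend(np.linalg.norm(np.diff(pos, axis=0), axis=1))
        assert len(dists) >= 1000
        assert abs(np.mean(dists) - 7.0) < 0.2

    def test_tether_length_law(self):
        # iid tether lengths: sample mean within 2 SE of the 14 nm mean
        params = SceneParams(seed=10, n_filaments=40, box_size=220,
                             filament_length=200, gold_label_fraction=1.0,
                             tether_length_within_sd=3.0, bead_fraction=0.0)
        truth = build_scene(params)
        lengths = np.array([g.tether_length for g in truth.gold_attachments])
        assert len(lengths) >= 1000
        assert abs(lengths.mean() - 14.0) < 2 * 3.0 / np.sqrt(len(lengths))

    def test_bead_clusters_have_15nm_envelope(self):
        # widely spaced sites so neighboring clusters cannot overlap
        truth = build_scene(straight_params(bead_fraction=1.0, base_spacing=21.0))
        assert len(truth.bead_centers) == 4
        assert truth.n_sites == 16
        for center in truth.bead_centers:
            members = truth.site_positions[
                np.linalg.norm(truth.site_positions - center, axis=1) < 7.6]
            assert len(members) == 4
            radii = np.linalg.norm(members - center, axis=1)
            np.testing.assert_allclose(radii, 7.5, atol=1e-9)

    def test_deterministic_under_seed(self):
        p = SceneParams(seed=3, box_size=60, n_filaments=2, noise_sd=5.0)
        v1 = rasterize(build_scene(p), p)
        v2 = rasterize(build_scene(p), p)
        np.testing.assert_array_equal(v1.grid, v2.grid)
        p_other = SceneParams(seed=4, box_size=60, n_filaments=2, noise_sd=5.0)
        v3 = rasterize(build_scene(p_other), p_other)
        assert not np.array_equal(v1.grid, v3.grid)

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            SceneParams(box_size=5.0, base_spacing=7.0)

    def test_gold_attachment_references_validated(self):
        with pytest.raises(ValueError, match="missing site"):
            GroundTruth(filaments=[], site_positions=np.zeros((1, 3)),
                        site_kinds=["monomer"], site_filament=np.array([0]),
                        gold_attachments=[GoldAttachment(5, np.ones(3), 3.0,
                                                         np.ones(3))],
                        box_size=50.0)


def single_gold_truth(diameter=7.0, box=60.0):
    center = np.full(3, box / 2)
    gold_c = center + np.array([10.0, 10.0, 10.0])
    return GroundTruth(
        filaments=[], site_positions=center[None, :], site_kinds=["monomer"],
        site_filament=np.array([0]),
        gold_attachments=[GoldAttachment(0, gold_c, diameter, gold_c - center)],
        box_size=box)


class TestRasterize:
    def test_empty_scene_is_pure_background(self):
        truth = GroundTruth(filaments=[], site_positions=np.empty((0, 3)),
                            site_kinds=[], site_filament=np.empty(0, int),
                            box_size=40.0)
        params = SceneParams(box_size=40.0, noise_sd=6.0, seed=2)
        vol = rasterize(truth, params)
        assert abs(vol.grid.mean() - params.background_level) < 1.0

    def test_gold_sphere_saturates_and_sizes_correctly(self):
        params = SceneParams(box_size=60.0, noise_sd=0.0, seed=1,
                             render_tethers=False)
        vol = rasterize(single_gold_truth(7.0), params)
        assert vol.grid.max() >= 240
        # equivalent diameter of the high-intensity blob within 15% of 7 nm
        blob = vol.grid >= 200
        count = int(blob.sum())
        d_eq = (6 * count * params.voxel_size ** 3 / np.pi) ** (1 / 3)
        assert abs(d_eq - 7.0) / 7.0 < 0.15

    def test_small_gold_still_saturates(self):
        params = SceneParams(box_size=60.0, noise_sd=0.0, seed=1,
                             render_tethers=False)
        vol = rasterize(single_gold_truth(3.0), params)
        assert vol.grid.max() >= 240

    def test_two_gold_spheres_disjoint_components(self):
        box = 60.0
        c = np.full(3, 20.0)
        g1, g2 = c + 14.0, c + np.array([14.0, 14.0, 34.0])
        truth = GroundTruth(
            filaments=[], site_positions=c[None, :], site_kinds=["monomer"],
            site_filament=np.array([0]),
            gold_attachments=[GoldAttachment(0, g1, 7.0, g1 - c),
                              GoldAttachment(0, g2, 7.0, g2 - c)],
            box_size=box)
        vol = rasterize(truth, SceneParams(box_size=box, noise_sd=0.0, seed=1,
                                           render_tethers=False))
        _, n = ndimage.label(vol.grid >= 230)
        assert n == 2


class TestSpherePhantom:
    def test_unblurred_sphere_matches_voxelization(self):
        vol = sphere_phantom([(20.0, 20.0, 20.0)], [7.0], box_size=40.0)
        count = int((vol.grid >= 100).sum())
        analytic = 4 / 3 * np.pi * 3.5 ** 3 / 0.8 ** 3
        assert abs(count - analytic) / analytic < 0.05


class TestSceneParticleTable:
    def test_counts_and_exact_coordinates(self):
        truth = build_scene(straight_params(gold_label_fraction=1.0,
                                            gold_small_fraction=1.0))
        table = scene_particle_table(truth)
        assert len(table) == truth.n_sites + len(truth.gold_attachments)
        np.testing.assert_allclose(
            table[["x_nm", "y_nm", "z_nm"]].to_numpy()[:truth.n_sites],
            truth.site_positions)

    def test_empty_truth_empty_table(self):
        truth = GroundTruth(filaments=[], site_positions=np.empty((0, 3)),
                            site_kinds=[], site_filament=np.empty(0, int),
                            box_size=40.0)
        assert len(scene_particle_table(truth)) == 0

    def test_ideal_monomer_spacings_are_exact(self):
        # no jitter: every blue-blue connection distance equals the repeat
        truth = build_scene(straight_params())
        table = classify_unlabeled(scene_particle_table(truth))
        conns = build_connections(table)
        bb = conns[conns["pair_type"] == "blue_blue"]
        assert len(bb) == 10
        np.testing.assert_allclose(bb["distance_nm"], 7.0, atol=1e-9)
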