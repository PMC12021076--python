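"""Nerve quantification scheme: projections, counts, lengths, tips, turns."""

import warnings

import numpy as np
import pytest

import axonquant as aq
from axonquant import nerve_metrics as nm
from axonquant.errors import InsufficientLengthError
from axonquant.trees import AxonTree

from conftest import brute_force_crossings


def straight_tree(length, y=0.0, step=10.0, radius=1.0):
    n = int(length / step) + 1
    nodes = np.stack([
        np.linspace(0, length, n), np.full(n, y), np.zeros(n)
    ], axis=1)
    return AxonTree(nodes=nodes, radius=np.full(n, radius),
                    parent=[-1] + list(range(n - 1)))


class TestProjectZ:
    def test_eight_slices_group4_gives_two_sections(self):
        stack = aq.ImageStack(np.arange(8 * 4 * 4).reshape(8, 4, 4),
                              pixel_size_xy=1.0, z_spacing=2.0)
        ps = nm.project_z(stack, group=4)
        assert len(ps) == 2
        assert ps.slice_ranges == [(0, 4), (4, 8)]
        np.testing.assert_array_equal(ps.projections[0],
                                      stack.data[:4].max(axis=0))

    def test_single_voxel_appears_in_exactly_one_projection(self):
        data = np.zeros((8, 4, 4))
        data[5, 2, 1] = 42.0
        ps = nm.project_z(aq.ImageStack(data, pixel_size_xy=1.0), group=4)
        hits = [int((p == 42.0).sum()) for p in ps.projections]
        assert hits == [0, 1]

    def test_group_one_is_identity(self):
        data = np.random.default_rng(0).poisson(5.0, (3, 5, 5)).astype(float)
        ps = nm.project_z(aq.ImageStack(data, pixel_size_xy=1.0), group=1)
        for k, proj in enumerate(ps.projections):
            np.testing.assert_array_equal(proj, data[k])

    def test_group_exceeding_slices_warns_full_mip(self):
        data = np.random.default_rng(1).poisson(5.0, (3, 4, 4)).astype(float)
        with pytest.warns(UserWarning, match="full MIP"):
            ps = nm.project_z(aq.ImageStack(data, pixel_size_xy=1.0), group=10)
        assert len(ps) == 1
        np.testing.assert_array_equal(ps.projections[0], data.max(axis=0))

    def test_group_all_reproduces_full_mip(self, straight3_stack):
        ps = nm.project_z(straight3_stack, group=straight3_stack.n_slices)
        assert len(ps) == 1
        np.testing.assert_array_equal(
            ps.projections[0], straight3_stack.data.max(axis=0)
        )


class TestCountFibers:
    def test_empty_stack_all_zero_stop_at_first_interval(self):
        stack = aq.ImageStack(np.zeros((4, 20, 600)), pixel_size_xy=1.0,
                              origin=(-10.0, 0.0, 0.0))
        ps = nm.project_z(stack, group=4)
        prof = nm.count_fibers(ps, aq.NerveGeometry(), threshold=5.0)
        assert (prof.counts == 0).all()
        assert prof.stop_distance == 250.0

    def test_three_axon_fixture_matches_crossing_oracle(
        self, straight3_truth, straight3_stack, noise_free_imaging
    ):
        ps = nm.project_z(straight3_stack, group=straight3_stack.n_slices)
        prof = nm.count_fibers(ps, straight3_truth.geometry,
                               threshold=noise_free_imaging.background + 1)
        assert prof.counts[:3].tolist() == [3, 2, 1]
        oracle = brute_force_crossings(
            straight3_truth.axons, straight3_truth.geometry, prof.distances
        )
        np.testing.assert_array_equal(prof.counts, oracle)

    def test_axon_spanning_two_sections_double_counted(self):
        # literal sum-over-projections: one axon visible in two optical
        # sections is counted once per section
        data = np.zeros((8, 30, 400))
        data[3, 10:13, 50:350] = 100.0    # section 0 (slices 0-3)
        data[4, 10:13, 50:350] = 100.0    # section 1 (slices 4-7)
        stack = aq.ImageStack(data, pixel_size_xy=1.0, origin=(-10.0, 0.0, 0.0))
        ps = nm.project_z(stack, group=4)
        prof = nm.count_fibers(ps, aq.NerveGeometry(), threshold=5.0)
        assert prof.counts[0] == 2

    def test_translation_invariance(self, straight3_truth, noise_free_imaging):
        gt = straight3_truth
        stack = aq.rasterize_stack(gt, noise_free_imaging)
        ps = nm.project_z(stack, group=stack.n_slices)
        prof = nm.count_fibers(ps, gt.geometry,
                               threshold=noise_free_imaging.background + 1)
        # translate stack and geometry together by whole voxels
        shift = np.array([17.0, -9.0, 4.0])
        stack2 = aq.ImageStack(stack.data, stack.pixel_size_xy,
                               stack.z_spacing,
                               origin=tuple(np.array(stack.origin) + shift))
        geo2 = gt.geometry.translated(shift)
        ps2 = nm.project_z(stack2, group=stack2.n_slices)
        prof2 = nm.count_fibers(ps2, geo2,
                                threshold=noise_free_imaging.background + 1)
        np.testing.assert_array_equal(prof.counts, prof2.counts)

    def test_crush_outside_image_raises(self, straight3_stack):
        geo = aq.NerveGeometry(crush_position=(1e6, 0.0, 0.0))
        ps = nm.project_z(straight3_stack, group=4)
        with pytest.raises(aq.nerve_metrics.GeometryError):
            nm.count_fibers(ps, geo, threshold=11.0)

    def test_adding_an_axon_never_decreases_counts(self, noise_free_imaging):
        base = aq.NerveSimConfig(
            n_axons=4, seed=13, tortuosity_sd=0.0, planar=True,
            lengths=(300.0, 420.0, 560.0, 700.0), nerve_length=900.0,
            nerve_radius=80.0, shaft_diameter=4.0, min_start_separation=18.0,
            gc_ratio_range=(1.0, 1.0),
        )
        more = aq.NerveSimConfig(
            n_axons=5, seed=13, tortuosity_sd=0.0, planar=True,
            lengths=(300.0, 420.0, 560.0, 700.0, 840.0), nerve_length=900.0,
            nerve_radius=80.0, shaft_diameter=4.0, min_start_separation=18.0,
            gc_ratio_range=(1.0, 1.0),
        )
        counts = {}
        for name, cfg in (("base", base), ("more", more)):
            gt = aq.simulate_nerve(cfg)
            stack = aq.rasterize_stack(gt, noise_free_imaging)
            ps = nm.project_z(stack, group=stack.n_slices)
            counts[name] = nm.count_fibers(
                ps, gt.geometry, threshold=noise_free_imaging.background + 1
            ).counts
        n = min(len(counts["base"]), len(counts["more"]))
        assert (counts["more"][:n] >= counts["base"][:n]).all()


class TestAxonLengths:
    def test_single_axon_fewer_than_k_warns(self):
        with pytest.warns(UserWarning, match="top-5"):
            lengths, mean = nm.axon_lengths([straight_tree(500.0)], k=5)
        assert mean == pytest.approx(500.0)

    def test_top5_of_seven_known_lengths(self):
        trees = [straight_tree(l) for l in (100, 200, 300, 400, 500, 600, 700)]
        _, mean = nm.axon_lengths(trees, k=5)
        assert mean == pytest.approx(500.0)   # mean of 300..700

    def test_tortuous_length_matches_generator_within_1pct(self):
        cfg = aq.NerveSimConfig(n_axons=8, seed=17, tortuosity_sd=8.0,
                                length_scale=400.0)
        gt = aq.simulate_nerve(cfg)
        lengths, _ = nm.axon_lengths(gt.axons)
        np.testing.assert_allclose(
            lengths, gt.labels.length_um.to_numpy(), rtol=0.01
        )

    def test_empty_input_distinguishes_no_axons(self):
        with pytest.raises(ValueError, match="no axons"):
            nm.axon_lengths([])

    def test_removing_longest_never_increases_topk_mean(self):
        trees = [straight_tree(l) for l in (100, 250, 380, 470, 520, 660)]
        _, full = nm.axon_lengths(trees, k=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, reduced = nm.axon_lengths(trees[:-1], k=5)
        assert reduced <= full


class TestTipMeasurement:
    def test_uniform_tube_ratio_one_growth_cone(self):
        tree = straight_tree(100.0, radius=1.5)
        m = nm.measure_tip(tree)
        assert m.ratio == pytest.approx(1.0)
        assert m.klass == "growth_cone"

    def test_simulated_bulb_ratio_within_20pct(self):
        cfg = aq.NerveSimConfig(
            n_axons=1, seed=5, tortuosity_sd=0.0, lengths=(200.0,),
            nerve_length=400.0, nerve_radius=40.0, shaft_diameter=2.0,
            planar=True, p_bulb=1.0, bulb_ratio_range=(5.0, 5.0),
        )
        gt = aq.simulate_nerve(cfg)
        img = aq.ImagingConfig(noise=False, psf_sigma=0.0, pixel_size_xy=0.5)
        stack = aq.rasterize_stack(gt, img)
        mask = aq.binarize(stack, "fixed", threshold=img.background + 1)
        res = aq.trace_axons(mask, gt.geometry)
        m = nm.measure_tip(res.trees[0], mask)
        assert m.ratio == pytest.approx(5.0, rel=0.2)
        assert m.klass == "retraction_bulb"

    def test_ratio_exactly_four_is_growth_cone(self):
        assert nm.classify_tip_ratio(4.0) == "growth_cone"
        assert nm.classify_tip_ratio(4.0 + 1e-9) == "retraction_bulb"
        m = nm.TipMeasurement(tip_width=8.0, shaft_diameter=2.0)
        assert m.ratio == pytest.approx(4.0)
        assert m.klass == "growth_cone"

    def test_short_axon_raises_insufficient_length(self):
        with pytest.raises(InsufficientLengthError):
            nm.measure_tip(straight_tree(30.0))


class TestDetectUturn:
    def test_straight_axon_zero_angle(self):
        angle, is_u = nm.detect_uturn(straight_tree(200.0))
        assert angle == pytest.approx(0.0)
        assert not is_u

    def test_reversed_terminal_180_degrees(self):
        nodes = [[0, 0, 0], [100, 0, 0], [200, 0, 0], [150, 0, 0], [100.0, 0, 0]]
        tree = AxonTree(nodes=nodes, radius=np.ones(5),
                        parent=[-1, 0, 1, 2, 3])
        angle, is_u = nm.detect_uturn(tree)
        assert angle == pytest.approx(180.0)
        assert is_u

    def test_flags_match_generator_on_ground_truth(self):
        cfg = aq.NerveSimConfig(n_axons=60, seed=23, p_uturn=0.4,
                                tortuosity_sd=8.0)
        gt = aq.simulate_nerve(cfg)
        flags = [nm.detect_uturn(t)[1] for t in gt.axons]
        np.testing.assert_array_equal(
            np.array(flags), gt.labels.uturn_flag.to_numpy()
        )


class TestTrajectoryMetrics:
    def test_twenty_straight_axons(self):
        trees = [straight_tree(100.0 + i, y=5.0 * i) for i in range(20)]
        tm = nm.trajectory_metrics(trees)
        assert tm.uturn_rate == 0.0
        assert tm.branching_index == 1.0
        assert tm.n_axons_analyzed == 20

    def test_branching_index_with_three_tip_tree(self):
        trees = [straight_tree(100.0 + i) for i in range(19)]
        # trunk 0-1-2-3 with side branches at nodes 1 and 2: 3 tips total
        three_tip = AxonTree(
            nodes=[[0, 0, 0], [50, 0, 0], [100, 0, 0], [150, 0, 0],
                   [80, 30, 0], [130, -30, 0]],
            radius=np.ones(6),
            parent=[-1, 0, 1, 2, 1, 2],
        )
        assert three_tip.n_tips() == 3
        tm = nm.trajectory_metrics(trees + [three_tip])
        assert tm.tip_count == 22
        assert tm.branching_index == pytest.approx(1.1)

    def test_fewer_than_twenty_warns_and_uses_all(self):
        trees = [straight_tree(100.0) for _ in range(7)]
        with pytest.warns(UserWarning, match="top-20"):
            tm = nm.trajectory_metrics(trees)
        assert tm.n_axons_analyzed == 7

    def test_recovered_rate_converges_to_p(self):
        rates = []
        for seed in range(25):
            gt = aq.simulate_nerve(
                aq.NerveSimConfig(n_axons=50, seed=seed, p_uturn=0.5)
            )
            tm = nm.trajectory_metrics(gt.axons, selection="all_in_region")
            rates.append(tm.uturn_rate)
        assert abs(np.mean(rates) - 0.5) < 0.05


class TestChiasmFates:
    def test_all_proximal_terminals_pre_chiasmic(self):
        geo = aq.NerveGeometry(chiasm=aq.ChiasmLandmarks())
        trees = [straight_tree(200.0, y=-100.0 + 5 * i) for i in range(5)]
        tab = nm.classify_chiasm_fates(trees, geo)
        assert tab.counts["pre_chiasmic"] == 5
        assert tab.fractions["pre_chiasmic"] == 1.0

    def test_simulated_fates_recovered_exactly(self):
        cfg = aq.NerveSimConfig(n_axons=120, seed=31)
        gt = aq.simulate_chiasm(cfg, fate_probs=(0.5, 0.3, 0.1, 0.1))
        tab = nm.classify_chiasm_fates(gt.axons, gt.geometry)
        truth = gt.labels.fate.value_counts().to_dict()
        for fate in aq.ChiasmLandmarks.FATES:
            assert tab.counts[fate] == truth.get(fate, 0)
        assert tab.counts["unassigned"] == 0

    def test_fractions_sum_to_one(self):
        cfg = aq.NerveSimConfig(n_axons=50, seed=8)
        gt = aq.simulate_chiasm(cfg)
        tab = nm.classify_chiasm_fates(gt.axons, gt.geometry)
        assert sum(tab.fractions.values()) == pytest.approx(1.0)


class TestSciatic:
    def test_fourteen_axons_fail_qc_no_summary(self):
        trees = [straight_tree(1000.0) for _ in range(14)]
        with pytest.warns(UserWarning, match="QC fail"):
            res = nm.sciatic_regeneration(trees)
        assert not res.qc_pass
        assert res.mean_length is None

    def test_fifteen_axons_pass_with_mean(self):
        trees = [straight_tree(1000.0) for _ in range(15)]
        res = nm.sciatic_regeneration(trees)
        assert res.qc_pass
        assert res.mean_length == pytest.approx(1000.0)

    def test_simulated_lengths_within_1pct_of_truth(self):
        cfg = aq.NerveSimConfig(n_axons=20, seed=41, tortuosity_sd=6.0,
                                length_scale=800.0, nerve_length=4000.0)
        gt = aq.simulate_nerve(cfg)
        res = nm.sciatic_regeneration(gt.axons)
        assert res.qc_pass
        np.testing.assert_allclose(
            np.sort(res.lengths), np.sort(gt.labels.length_um), rtol=0.01
        )
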