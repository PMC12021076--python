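"""Synthetic ground-truth generator: contracts, oracles, invariants."""

import numpy as np
import pytest
from scipy import stats as sps

import axonquant as aq
from axonquant.errors import ConfigurationError
from axonquant.simulate import TIP_RATIO_THRESHOLD

from conftest import brute_force_crossings


class TestNerveConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nerve_length": -1.0},
            {"step": 0.0},
            {"p_uturn": 1.5},
            {"branch_rate": -0.1},
            {"bulb_ratio_range": (3.0, 8.0)},   # straddles the threshold 4
            {"gc_ratio_range": (1.0, 4.5)},
            {"tortuosity_sd": float("nan")},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            aq.NerveSimConfig(**kwargs)

    def test_fixed_lengths_must_match_axon_count(self):
        with pytest.raises(ConfigurationError):
            aq.NerveSimConfig(n_axons=2, lengths=(100.0,))


class TestSimulateNerve:
    def test_degenerate_straight_growth(self):
        cfg = aq.NerveSimConfig(
            n_axons=6, seed=1, p_uturn=0.0, branch_rate=0.0, tortuosity_sd=0.0,
            length_scale=300.0, nerve_length=900.0,
        )
        gt = aq.simulate_nerve(cfg)
        assert not gt.labels.uturn_flag.any()
        assert gt.labels.n_tips.sum() == 6
        for tree in gt.axons:
            d = np.diff(tree.nodes, axis=0)
            # every step along +x only
            assert np.allclose(d[:, 1:], 0.0)
            assert (d[:, 0] > 0).all()

    def test_fixed_length_crossing_table(self, straight3_truth):
        tab = straight3_truth.crossing_table
        assert tab["count"].tolist()[:3] == [3, 2, 1]
        assert (tab["count"].tolist()[3:] == np.zeros(len(tab) - 3)).all()

    def test_crossing_table_matches_brute_force_on_tortuous_nerves(self):
        for seed in range(5):
            cfg = aq.NerveSimConfig(
                n_axons=20, seed=seed, p_uturn=0.3, branch_rate=1.0,
                tortuosity_sd=8.0, length_scale=400.0, nerve_length=1200.0,
            )
            gt = aq.simulate_nerve(cfg)
            oracle = brute_force_crossings(
                gt.axons, gt.geometry, gt.crossing_table.distance_um.to_numpy()
            )
            np.testing.assert_array_equal(
                gt.crossing_table["count"].to_numpy(), oracle
            )

    def test_same_seed_identical_different_seed_differs(self):
        cfg = aq.NerveSimConfig(n_axons=4, seed=7, tortuosity_sd=6.0)
        a, b = aq.simulate_nerve(cfg), aq.simulate_nerve(cfg)
        for ta, tb in zip(a.axons, b.axons):
            np.testing.assert_array_equal(ta.nodes, tb.nodes)
        c = aq.simulate_nerve(aq.NerveSimConfig(n_axons=4, seed=8, tortuosity_sd=6.0))
        assert any(
            ta.nodes.shape != tc.nodes.shape or not np.array_equal(ta.nodes, tc.nodes)
            for ta, tc in zip(a.axons, c.axons)
        )

    def test_adding_axons_preserves_earlier_trajectories(self):
        small = aq.simulate_nerve(aq.NerveSimConfig(n_axons=3, seed=5, tortuosity_sd=6.0))
        big = aq.simulate_nerve(aq.NerveSimConfig(n_axons=6, seed=5, tortuosity_sd=6.0))
        for ts, tb in zip(small.axons, big.axons[:3]):
            np.testing.assert_array_equal(ts.nodes, tb.nodes)

    def test_roots_on_crush_plane_and_uturn_geometry(self):
        cfg = aq.NerveSimConfig(n_axons=30, seed=3, p_uturn=0.5, tortuosity_sd=8.0)
        gt = aq.simulate_nerve(cfg)
        axis = np.array(gt.geometry.axis)
        for tree, flagged in zip(gt.axons, gt.labels.uturn_flag):
            assert abs(gt.geometry.axial_distance(tree.nodes[0])) < 1e-9
            ang = np.degrees(
                np.arccos(np.clip(tree.terminal_direction(20.0) @ axis, -1, 1))
            )
            assert (ang > 90.0) == flagged

    def test_tip_ratios_never_straddle_threshold(self):
        cfg = aq.NerveSimConfig(n_axons=40, seed=4, p_bulb=0.5)
        gt = aq.simulate_nerve(cfg)
        bulbs = gt.labels[gt.labels.tip_class == "bulb"].true_tip_ratio
        gcs = gt.labels[gt.labels.tip_class == "growth_cone"].true_tip_ratio
        assert (bulbs > TIP_RATIO_THRESHOLD).all()
        assert (gcs < TIP_RATIO_THRESHOLD).all()

    def test_uturn_fraction_converges_over_seeds(self):
        p = 0.3
        n, seeds = 40, 50
        flagged = sum(
            aq.simulate_nerve(
                aq.NerveSimConfig(n_axons=n, seed=s, p_uturn=p)
            ).labels.uturn_flag.sum()
            for s in range(seeds)
        )
        total = n * seeds
        lo, hi = sps.binom.interval(0.999, total, p)
        assert lo <= flagged <= hi

    def test_branch_events_scale_with_rate(self):
        no_branch = aq.simulate_nerve(
            aq.NerveSimConfig(n_axons=20, seed=6, branch_rate=0.0,
                              length_scale=500.0)
        )
        branched = aq.simulate_nerve(
            aq.NerveSimConfig(n_axons=20, seed=6, branch_rate=4.0,
                              length_scale=500.0)
        )
        assert no_branch.labels.n_tips.sum() == 20
        assert branched.labels.n_tips.sum() > 20


class TestSimulateChiasm:
    def test_all_mass_pre_chiasmic(self):
        cfg = aq.NerveSimConfig(n_axons=30, seed=1)
        gt = aq.simulate_chiasm(cfg, fate_probs=(1.0, 0.0, 0.0, 0.0))
        octz = gt.geometry.chiasm.octz_x
        for tree in gt.axons:
            assert tree.nodes[tree.longest_path()[-1]][0] < octz

    def test_fate_counts_within_binomial_bounds(self):
        probs = (0.6, 0.3, 0.05, 0.05)
        cfg = aq.NerveSimConfig(n_axons=200, seed=9)
        gt = aq.simulate_chiasm(cfg, fate_probs=probs)
        counts = gt.labels.fate.value_counts()
        for fate, p in zip(aq.ChiasmLandmarks.FATES, probs):
            lo, hi = sps.binom.interval(0.99, 200, p)
            assert lo <= counts.get(fate, 0) <= hi

    def test_contra_nerve_axons_cross_midline(self):
        cfg = aq.NerveSimConfig(n_axons=40, seed=2)
        gt = aq.simulate_chiasm(cfg, fate_probs=(0.0, 0.0, 0.0, 1.0))
        mid = gt.geometry.chiasm.midline_y
        for tree in gt.axons:
            y = tree.nodes[:, 1]
            side = y >= mid
            assert np.any(side[:-1] != side[1:])

    def test_bad_fate_probs_rejected(self):
        cfg = aq.NerveSimConfig(n_axons=5, seed=1)
        with pytest.raises(ConfigurationError, match="sum to 1"):
            aq.simulate_chiasm(cfg, fate_probs=(0.5, 0.5, 0.5, 0.5))


class TestRetinaPair:
    def test_equal_density_when_survival_one(self):
        cfg = aq.RetinaSimConfig(n_fields=10, survival_fraction=1.0, seed=3,
                                 cell_density=600.0, field_size=(300.0, 300.0))
        _, _, truth = aq.simulate_retina_pair(cfg, render=False)
        means = truth.groupby("arm").n_cells.mean()
        # both arms draw from the same Poisson law
        assert abs(means["injured"] - means["control"]) < 3 * np.sqrt(
            means["control"] / 10
        ) + 5

    def test_zero_cre_fraction_gives_zero_cre_cells(self):
        cfg = aq.RetinaSimConfig(n_fields=4, cre_fraction=0.0, seed=1,
                                 cell_density=500.0, field_size=(300.0, 300.0))
        _, _, truth = aq.simulate_retina_pair(cfg, render=False)
        assert truth.n_cre.sum() == 0

    def test_total_count_within_poisson_bounds(self):
        # 1000 cells/mm^2 over 0.25 mm^2 fields, 20 fields -> mean 5000
        cfg = aq.RetinaSimConfig(
            n_fields=20, cell_density=1000.0, field_size=(500.0, 500.0),
            survival_fraction=1.0, seed=11, cell_radius=4.0,
        )
        _, _, truth = aq.simulate_retina_pair(cfg, render=False)
        total = truth[truth.arm == "control"].n_cells.sum()
        lo, hi = sps.poisson.interval(0.99, 5000)
        assert lo <= total <= hi

    def test_saturating_density_raises(self):
        cfg = aq.RetinaSimConfig(
            n_fields=1, cell_density=20000.0, field_size=(200.0, 200.0),
            cell_radius=10.0, seed=0,
        )
        with pytest.raises(ConfigurationError, match="density"):
            aq.simulate_retina_pair(cfg, render=False)


class TestRasterize:
    def test_zero_axons_pure_background(self):
        cfg = aq.NerveSimConfig(n_axons=0, seed=0, nerve_length=100.0)
        gt = aq.simulate_nerve(cfg)
        img = aq.ImagingConfig(noise=False, psf_sigma=0.0, background=7.0)
        stack = aq.rasterize_stack(gt, img)
        assert np.all(stack.data == 7.0)

    def test_noise_free_mask_equals_analytic_tube(
        self, straight3_truth, straight3_stack, noise_free_imaging
    ):
        mask = straight3_stack.data > noise_free_imaging.background + 1
        # analytic oracle: voxel inside iff within radius of some segment
        coords = np.argwhere(mask)
        um = straight3_stack.voxel_to_um(coords)
        def dist_to_axons(p):
            best = np.inf
            for tree in straight3_truth.axons:
                a, b = tree.nodes[:-1], tree.nodes[1:]
                ab = b - a
                t = np.clip(
                    np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab),
                    0.0, 1.0,
                )
                proj = a + t[:, None] * ab
                best = min(best, float(np.linalg.norm(p - proj, axis=1).min()))
            return best
        rng = np.random.default_rng(0)
        sample = um[rng.choice(len(um), 200, replace=False)]
        r = straight3_truth.config.shaft_diameter / 2.0
        for p in sample:
            assert dist_to_axons(p[None, :]) <= r + 1e-6

    def test_bulb_tip_width_matches_distance_transform_oracle(self):
        cfg = aq.NerveSimConfig(
            n_axons=1, seed=5, tortuosity_sd=0.0, lengths=(200.0,),
            nerve_length=400.0, nerve_radius=40.0, shaft_diameter=2.0,
            planar=True, p_bulb=1.0, bulb_ratio_range=(5.0, 5.0),
        )
        gt = aq.simulate_nerve(cfg)
        img = aq.ImagingConfig(noise=False, psf_sigma=0.0, pixel_size_xy=0.5)
        stack = aq.rasterize_stack(gt, img)
        from scipy import ndimage
        mip = stack.data.max(axis=0) > img.background + 1
        edt = ndimage.distance_transform_edt(mip, sampling=0.5)
        assert 2 * edt.max() == pytest.approx(10.0, abs=2 * img.pixel_size_xy)

    def test_determinism_and_seed_sensitivity(self, straight3_truth):
        img = aq.ImagingConfig(noise=True, psf_sigma=0.5, seed=5)
        s1 = aq.rasterize_stack(straight3_truth, img)
        s2 = aq.rasterize_stack(straight3_truth, img)
        np.testing.assert_array_equal(s1.data, s2.data)
        s3 = aq.rasterize_stack(
            straight3_truth, aq.ImagingConfig(noise=True, psf_sigma=0.5, seed=6)
        )
        assert not np.array_equal(s1.data, s3.data)

    def test_voxel_cap_enforced(self, straight3_truth):
        img = aq.ImagingConfig(noise=False, pixel_size_xy=0.1, z_spacing=0.1)
        with pytest.raises(aq.simulate.ResourceError):
            aq.rasterize_stack(straight3_truth, img, max_voxels=10**6)
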