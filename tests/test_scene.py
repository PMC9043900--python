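"""Scene generator: allometry, rendering conventions, occlusion, growth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import canopymass as cm
from canopymass.scene import (
    CanopyScene,
    PlantSpec,
    StressSchedule,
    make_neighborhood_scene,
    occlusion_fraction,
    rosette_height,
    sample_mass,
    simulate_growth,
)

from conftest import SMALL_KW


class TestMakePlant:
    def test_zero_mass_plant_is_empty(self, rng):
        p = cm.make_plant(rng, 0.0)
        assert p.n_leaves == 0
        assert cm.true_mass(p) == 0.0

    def test_negative_mass_rejected(self, rng):
        with pytest.raises(ValueError):
            cm.make_plant(rng, -1.0)

    def test_target_mass_met_within_one_percent(self, rng):
        for target in (0.1, 1.0, 8.0, 35.0):
            p = cm.make_plant(rng, target)
            assert cm.true_mass(p) == pytest.approx(target, rel=1e-2)

    def test_eightfold_mass_doubles_linear_dimensions(self):
        # identical generator state -> identical shape draw, so only scale differs
        p1 = cm.make_plant(np.random.default_rng(7), 2.0)
        p8 = cm.make_plant(np.random.default_rng(7), 16.0)
        assert p8.max_radius == pytest.approx(2.0 * p1.max_radius, rel=1e-9)
        assert p8.max_height == pytest.approx(2.0 * p1.max_height, rel=1e-9)

    def test_deterministic_under_fixed_seed(self):
        a = cm.make_plant(np.random.default_rng(3), 5.0)
        b = cm.make_plant(np.random.default_rng(3), 5.0)
        assert a == b


class TestTrueMass:
    def test_zero_radius_gives_zero(self):
        p = PlantSpec("p", n_leaves=8, max_radius=0.0, max_height=10.0)
        assert cm.true_mass(p) == 0.0

    def test_voxel_integration_oracle(self, rng):
        """Absolute-resolution (0.1 mm) voxel sum over the rosette surface
        agrees with the plant-relative integral within 0.5%."""
        p = cm.make_plant(rng, 1.5)  # small plant keeps the fine grid tractable
        rb = 1.1 * p.max_radius
        step = 0.1
        axis = np.arange(-rb, rb + step, step)
        X, Y = np.meshgrid(axis, axis)
        h = rosette_height(p, X, Y)
        voxel_mass = cm.scene.LEAF_DENSITY_G_PER_MM3 * h.sum() * step * step
        assert voxel_mass == pytest.approx(cm.true_mass(p), rel=5e-3)

    def test_mass_invariant_to_context(self, rng):
        """Ground truth never changes with neighbors, exposure, or dropout."""
        center = cm.make_plant(rng, 4.0, plant_id="c")
        masses = []
        for k in range(5):
            neighbors = [
                cm.make_plant(rng, 20.0, plant_id=f"n{k}{i}", grid_row=r, grid_col=c)
                for i, (r, c) in enumerate([(-1, 0), (1, 0), (0, -1), (0, 1)][: k + 1])
            ]
            scene = CanopyScene(
                plants=[center] + neighbors,
                exposure_factor=0.6 + 0.2 * k,
                depth_dropout_base=0.05 * k,
                **SMALL_KW,
            )
            masses.append(cm.render_scene(scene, "c", rng).mass_g)
        assert np.ptp(masses) == 0.0


class TestRenderScene:
    def test_empty_scene_is_all_background(self, rng):
        scene = CanopyScene(plants=[PlantSpec("c")], **SMALL_KW)
        s = cm.render_scene(scene, "c", rng)
        assert np.all(s.depth == 3700)  # 37 cm in 0.1 mm units
        assert s.mass_g == 0.0
        assert not s.center_footprint.any()

    def test_single_plant_min_depth_matches_apex(self, rng):
        # apex height 50 mm -> nearest depth 3700 - 500 = 3200
        p = PlantSpec("c", n_leaves=8, max_radius=100.0, max_height=50.0, phase=0.0)
        scene = CanopyScene(
            plants=[p],
            image_size=(512, 512),
            mm_per_pixel=0.5,
            depth_dropout_base=0.0,
            depth_dropout_height=0.0,
        )
        s = cm.render_scene(scene, "c", rng)
        assert s.depth.min() == 3200
        assert s.depth.max() == 3700

    def test_zbuffer_takes_nearest_surface(self, rng):
        a = PlantSpec("a", grid_col=0, n_leaves=8, max_radius=60.0, max_height=25.0)
        b = PlantSpec("b", grid_col=1, n_leaves=8, max_radius=60.0, max_height=35.0, phase=0.4)
        scene = CanopyScene(
            plants=[a, b],
            grid_spacing=50.0,  # force overlap
            image_size=(128, 96),
            mm_per_pixel=2.0,
            depth_dropout_base=0.0,
            depth_dropout_height=0.0,
        )
        s = cm.render_scene(scene, "a", rng)
        W, Himg = scene.image_size
        xs = (np.arange(W) - (W - 1) / 2.0) * scene.mm_per_pixel
        ys = (np.arange(Himg) - (Himg - 1) / 2.0) * scene.mm_per_pixel
        X, Y = np.meshgrid(xs, ys)
        ax, ay = scene.plant_position(a)
        bx, by = scene.plant_position(b)
        ha = rosette_height(a, X - ax, Y - ay)
        hb = rosette_height(b, X - bx, Y - by)
        contested = (ha > 0) & (hb > 0)
        assert contested.any()
        expected = np.rint(3700 - 10 * np.maximum(ha, hb)).astype(np.int64)
        assert np.array_equal(s.depth[contested], expected[contested])

    def test_missing_center_plant_raises(self, rng):
        scene = CanopyScene(plants=[PlantSpec("a")], **SMALL_KW)
        with pytest.raises(KeyError):
            cm.render_scene(scene, "nope", rng)

    def test_depth_bounded_by_background(self, rng, small_sample):
        assert small_sample.depth.max() <= 3700
        assert small_sample.depth.min() >= 0


class TestDatasetGeneration:
    def test_manifest_contract(self, rng, tmp_path):
        manifest = cm.generate_dataset(10, tmp_path, rng, seed=9, **SMALL_KW)
        assert len(manifest) == 10
        assert manifest["mass_g"].between(0.1, 35.0).all()
        assert (tmp_path / "manifest.csv").exists()

    def test_mass_distribution_right_skewed(self):
        rng = np.random.default_rng(0)
        masses = np.array([sample_mass(rng) for _ in range(1000)])
        assert np.median(masses) < masses.mean()
        assert masses.min() >= 0.1 and masses.max() <= 35.0

    def test_same_seed_same_manifest(self, tmp_path):
        m1 = cm.generate_dataset(5, tmp_path / "a", np.random.default_rng(4), **SMALL_KW)
        m2 = cm.generate_dataset(5, tmp_path / "b", np.random.default_rng(4), **SMALL_KW)
        pd.testing.assert_frame_equal(
            m1.drop(columns=["rgb_path", "depth_path"]),
            m2.drop(columns=["rgb_path", "depth_path"]),
        )

    def test_missing_depth_increases_with_mass(self):
        """Spearman correlation between center mass and missing-pixel
        fraction is positive across the generated dataset."""
        rng = np.random.default_rng(21)
        masses, missing = [], []
        for _ in range(120):
            m = sample_mass(rng)
            scene, cid = make_neighborhood_scene(rng, m, **SMALL_KW)
            s = cm.render_scene(scene, cid, rng)
            masses.append(m)
            missing.append((s.depth == 0).mean())
        rho = stats.spearmanr(masses, missing).statistic
        assert rho > 0

    def test_occlusion_grows_with_plant_mass(self):
        """Bigger plants on the same grid occlude each other more."""
        occ = []
        for m in (1.0, 5.0, 15.0, 30.0):
            vals = [
                occlusion_fraction(*make_neighborhood_scene(np.random.default_rng(100 + i), m, **SMALL_KW))
                for i in range(8)
            ]
            occ.append(np.mean(vals))
        assert all(a <= b + 1e-9 for a, b in zip(occ, occ[1:]))
        assert occ[-1] > occ[0]


class TestStressSchedule:
    def test_validation_errors(self):
        with pytest.raises(ValueError):
            StressSchedule("x", ((6, "water"), (0, "nutrient")))  # unsorted
        with pytest.raises(ValueError):
            StressSchedule("x", ((1, "nutrient"),))  # no day-0 event
        with pytest.raises(ValueError):
            StressSchedule("x", ((0, "nutrient"), (6, "water"), (6, "nutrient")))  # conflict
        with pytest.raises(ValueError):
            StressSchedule("x", ((0, "juice"),))  # unknown solution

    def test_bundled_schedules_resolve_solutions(self):
        a, b, c, d = cm.table1_schedules()
        assert a.solution_at(7.0) == "water"
        assert a.solution_at(12.0) == "nutrient"
        assert c.solution_at(22.0) == "water"
        assert d.solution_at(30.0) == "nutrient"


class TestGrowthSimulation:
    def test_control_growth_monotone(self):
        df = simulate_growth(
            [StressSchedule("D", ((0, "nutrient"),), 5)], 30, rng=np.random.default_rng(1)
        )
        for _, g in df.groupby("plant_id"):
            assert np.all(np.diff(g.sort_values("timepoint")["mass_g"]) >= 0)

    def test_full_suppression_zero_lag_is_constant(self):
        df = simulate_growth(
            [StressSchedule("W", ((0, "water"),), 4)],
            20,
            rng=np.random.default_rng(2),
            lag_days=0.0,
            suppression=1.0,
        )
        for _, g in df.groupby("plant_id"):
            m = g.sort_values("timepoint")["mass_g"].to_numpy()
            assert np.allclose(m, m[0])

    def test_identical_schedules_differ_only_by_noise(self):
        """Two treatments with the same schedule: final masses are
        statistically indistinguishable in nearly all replicate runs."""
        ok = 0
        n_rep = 100
        for i in range(n_rep):
            rng = np.random.default_rng(500 + i)
            df = simulate_growth(
                [
                    StressSchedule("A", ((0, "nutrient"),), 10),
                    StressSchedule("B", ((0, "nutrient"),), 10),
                ],
                30,
                rng=rng,
            )
            final = df[df["timepoint"] == 29]
            a = final.loc[final["treatment"] == "A", "mass_g"]
            b = final.loc[final["treatment"] == "B", "mass_g"]
            if stats.ttest_ind(a, b).pvalue > 0.01:
                ok += 1
        assert ok >= 0.95 * n_rep

    def test_rendered_experiment_tracks_trajectories(self, tmp_path):
        rng = np.random.default_rng(6)
        scheds = [
            StressSchedule("S", ((0, "nutrient"), (1, "water")), 2),
            StressSchedule("C", ((0, "nutrient"),), 2),
        ]
        traj = cm.generate_growth_experiment(
            scheds, 4, rng=rng, render=True, out_dir=tmp_path,
            image_size=(96, 72), mm_per_pixel=4.25,
        )
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert len(manifest) == 4 * 4  # plants x timepoints
        merged = manifest.merge(
            traj, left_on=["plant_id", "timestamp"], right_on=["plant_id", "time_days"],
            suffixes=("_img", "_true"),
        )
        assert np.allclose(merged["mass_g_img"], merged["mass_g_true"], rtol=1e-6)
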