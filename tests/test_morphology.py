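"""3D morphometry, nucleus segmentation and partitioning."""

import numpy as np
import pandas as pd
import pytest

from condenskit import morphology as mo, simulate as sim
from condenskit.errors import GeometryError, ParameterError, SegmentationError
from condenskit.morphology import LabeledStack
from condenskit.simulate import _ellipsoid_mask

from conftest import ball_mask


class TestSphericity:
    def test_cube_closed_form_to_1e12(self):
        s = 3.7
        psi = mo.sphericity(volume=s**3, area=6 * s**2)
        assert psi == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-12)

    def test_sphere_is_one(self):
        r = 2.0
        psi = mo.sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2)
        assert psi == pytest.approx(1.0, abs=1e-12)

    def test_digital_ball_mesh_sphericity_high_and_monotone(self):
        psis = []
        for r in (5, 10, 15, 20):
            area, vol = mo._mesh_measures(ball_mask(r), (1.0, 1.0, 1.0))
            psis.append(mo.sphericity(vol, area))
        assert psis[1] >= 0.9
        assert all(a < b for a, b in zip(psis, psis[1:]))

    def test_mesh_area_matches_independent_mesh_oracle(self):
        import trimesh
        from skimage.measure import marching_cubes

        mask = ball_mask(10)
        area, _ = mo._mesh_measures(mask, (1.0, 1.0, 1.0))
        verts, faces, _, _ = marching_cubes(np.pad(mask.astype(float), 1), 0.5)
        oracle = trimesh.Trimesh(verts, faces, process=False).area
        assert area == pytest.approx(oracle, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            mo.sphericity(0.0, 1.0)


class TestNucleusSegmentation:
    def test_dice_against_generator_truth(self, default_stack):
        stack, truth = default_stack
        nucleus = mo.segment_nucleus(stack)
        ref = _ellipsoid_mask(
            stack.condensate.shape, stack.voxel_size_zyx,
            np.array(truth.truth["nucleus_center_um"]),
            truth.truth["nucleus_semiaxes_um"],
        )
        dice = 2 * (nucleus.mask & ref).sum() / (nucleus.mask.sum() + ref.sum())
        assert dice >= 0.98

    def test_empty_channel_raises(self):
        stack = LabeledStack(np.ones((8, 16, 16)), np.zeros((8, 16, 16)),
                             (0.3, 0.1, 0.1))
        with pytest.raises(SegmentationError):
            mo.segment_nucleus(stack)

    def test_two_nuclei_keep_largest_and_flag(self):
        nuclear = np.zeros((24, 48, 48))
        nuclear[4:12, 6:22, 6:22] = 100.0
        nuclear[14:20, 30:42, 30:42] = 100.0
        stack = LabeledStack(np.ones_like(nuclear), nuclear, (0.3, 0.1, 0.1))
        nucleus = mo.segment_nucleus(stack)
        assert "multiple_components" in nucleus.flags
        # largest block kept
        assert nucleus.mask[8, 14, 14] and not nucleus.mask[17, 36, 36]


class TestDetection:
    def test_count_matches_rendered_truth(self, default_stack):
        stack, truth = default_stack
        nucleus = mo.segment_nucleus(stack)
        table, _ = mo.detect_condensates(stack, nucleus)
        n_true = len({r["id"] for r in truth.truth["condensates"]})
        assert len(table) == n_true
        assert set(table["compartment"]) == {"nuclear"}

    def test_no_objects_returns_empty_table(self):
        stack, _ = sim.simulate_stack(sim.StackSimParams(n_condensates=0,
                                                         seed=3))
        nucleus = mo.segment_nucleus(stack)
        table, labels = mo.detect_condensates(stack, nucleus)
        assert table.empty and labels.max() == 0

    def test_merging_separations_reduce_count(self):
        # two blobs at controlled separation: resolved when well separated,
        # merged into one detection once they overlap within the spot scale
        shape, voxel = (16, 64, 64), (0.3, 0.1, 0.1)
        grids = [np.arange(n) * v for n, v in zip(shape, voxel)]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")

        def scene(separation):
            img = np.full(shape, 100.0)
            for sign in (+0.5, -0.5):
                d2 = ((zz - 2.4) ** 2 + (yy - 3.2) ** 2
                      + (xx - (3.2 + sign * separation)) ** 2)
                img += 400.0 * np.exp(-d2 / (2 * 0.1**2))
            return LabeledStack(img, np.full(shape, 50.0), voxel)

        counts = []
        for sep in (1.0, 0.15):
            table, _ = mo.detect_condensates(scene(sep))
            counts.append(len(table))
        assert counts[0] == 2 and counts[1] == 1

    def test_volumes_stable_under_voxel_refinement(self):
        common = dict(n_condensates=5, condensate_radius=0.3,
                      condensate_amplitude=600.0, seed=4)
        coarse_p = sim.StackSimParams(shape_zyx=(20, 80, 80),
                                      voxel_size_zyx=(0.3, 0.1, 0.1), **common)
        fine_p = sim.StackSimParams(shape_zyx=(40, 160, 160),
                                    voxel_size_zyx=(0.15, 0.05, 0.05), **common)
        vols = []
        for p in (coarse_p, fine_p):
            stack, _ = sim.simulate_stack(p)
            nucleus = mo.segment_nucleus(stack)
            table, _ = mo.detect_condensates(stack, nucleus)
            assert len(table) == 5
            vols.append(table["volume"].sum())
        assert abs(vols[1] - vols[0]) / vols[0] < 0.35


class TestZScores:
    def test_three_values_closed_form(self):
        tables = {"a": pd.DataFrame({"mean_intensity": [1.0, 2.0, 3.0]})}
        out, mu, sd = mo.zscore_intensities(tables)
        np.testing.assert_allclose(out["a"]["z_scored_intensity"],
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_all_equal_rejected(self):
        tables = {"a": pd.DataFrame({"mean_intensity": [2.0, 2.0, 2.0]})}
        with pytest.raises(ParameterError):
            mo.zscore_intensities(tables)

    def test_pooled_moments_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        tables = {
            "a": pd.DataFrame({"mean_intensity": rng.normal(5, 2, 40)}),
            "b": pd.DataFrame({"mean_intensity": rng.normal(7, 2, 60)}),
        }
        out, _, _ = mo.zscore_intensities(tables)
        pooled = np.concatenate([t["z_scored_intensity"] for t in out.values()])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-9)
        assert pooled.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_one_sd_offset_between_conditions(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1, 500)
        tables = {
            "lo": pd.DataFrame({"mean_intensity": base}),
            "hi": pd.DataFrame({"mean_intensity": base + base.std(ddof=0)}),
        }
        out, _, _ = mo.zscore_intensities(tables)
        delta = (out["hi"]["z_scored_intensity"].mean()
                 - out["lo"]["z_scored_intensity"].mean())
        assert delta == pytest.approx(1.0, abs=0.15)


class TestPartition:
    def test_all_signal_inside_nucleus(self):
        # PSF off: with blur, boundary bleed genuinely moves a few percent
        # of signal outside the segmented nucleus
        p = sim.StackSimParams(cytoplasm_level=0.0, background_level=2.0,
                               psf_sigma_zyx=(0.0, 0.0, 0.0), seed=6)
        stack, _ = sim.simulate_stack(p)
        nucleus = mo.segment_nucleus(stack)
        part = mo.partition_3d(stack, nucleus)
        assert part.nuclear_fraction >= 0.99

    def test_uniform_signal_proportional_to_volume(self):
        shape, voxel = (24, 64, 64), (0.3, 0.1, 0.1)
        center = np.array([s * v / 2 for s, v in zip(shape, voxel)])
        cell = _ellipsoid_mask(shape, voxel, center, (2.8, 2.6, 2.6))
        nucleus = _ellipsoid_mask(shape, voxel, center, (1.85, 1.75, 1.75))
        img = np.where(cell, 100.0, 0.0)
        stack = LabeledStack(img, np.where(nucleus, 50.0, 0.0), voxel)
        mask = mo.NucleusMask(nucleus, voxel, 0.0, 0.0)
        part = mo.partition_3d(stack, mask, cell_mask=cell)
        expected = nucleus.sum() / cell.sum()
        assert part.nuclear_fraction == pytest.approx(expected, abs=0.01)
        assert part.nuclear_fraction + part.cytoplasmic_fraction == 1.0

    def test_recovery_of_generator_truth_within_three_points(self,
                                                             default_stack):
        stack, truth = default_stack
        nucleus = mo.segment_nucleus(stack)
        part = mo.partition_3d(stack, nucleus)
        assert abs(part.nuclear_fraction
                   - truth.truth["nuclear_fraction"]) <= 0.03

    def test_nucleus_outside_cell_rejected(self):
        shape, voxel = (16, 32, 32), (0.3, 0.1, 0.1)
        img = np.zeros(shape)
        img[2:6, 2:10, 2:10] = 100.0
        nucleus = np.zeros(shape, bool)
        nucleus[10:14, 20:30, 20:30] = True
        stack = LabeledStack(img, img, voxel)
        cell = img > 10
        with pytest.raises(GeometryError):
            mo.partition_3d(stack, mo.NucleusMask(nucleus, voxel, 0, 0),
                            cell_mask=cell)


class TestPlotProfile:
    def _plane(self, nuclear_level, cyto_level, n=64):
        img = np.zeros((n, n))
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        c = n / 2
        cell = ((yy - c) ** 2 + (xx - c) ** 2) <= (0.45 * n) ** 2
        nuc = ((yy - c) ** 2 + (xx - c) ** 2) <= (0.22 * n) ** 2
        img[cell] = cyto_level
        img[nuc] = nuclear_level
        return img, nuc, cell

    def test_uniform_plane_ratio_one(self):
        img, nuc, cell = self._plane(100.0, 100.0)
        rec = mo.plot_profile(img, (32, 2), (32, 62), nuc, cell)
        assert rec.fmean_ratio == pytest.approx(1.0, abs=1e-9)
        assert rec.nuclear_fmin == rec.nuclear_fmax

    def test_nuclear_enrichment_ratio_recovered(self):
        img, nuc, cell = self._plane(67.0, 10.0)
        rec = mo.plot_profile(img, (32, 2), (32, 62), nuc, cell)
        assert rec.fmean_ratio == pytest.approx(6.7, rel=0.05)

    def test_cytoplasmic_enrichment_ratio_recovered(self):
        img, nuc, cell = self._plane(10.0, 30.0)
        rec = mo.plot_profile(img, (32, 2), (32, 62), nuc, cell)
        assert rec.fmean_ratio == pytest.approx(1 / 3, rel=0.05)

    def test_line_missing_nucleus_rejected(self):
        img, nuc, cell = self._plane(50.0, 10.0)
        with pytest.raises(GeometryError):
            mo.plot_profile(img, (2, 2), (2, 62), nuc, cell)


class TestDiffuseTotalRatio:
    def test_exactly_one_without_condensates(self):
        stack, _ = sim.simulate_stack(sim.StackSimParams(n_condensates=0,
                                                         seed=3))
        nucleus = mo.segment_nucleus(stack)
        table, labels = mo.detect_condensates(stack, nucleus)
        ratio, status = mo.diffuse_total_ratio(stack, nucleus, labels)
        assert status == "ok" and ratio == 1.0

    def test_analytic_construction_within_three_percent(self):
        shape, voxel = (16, 48, 48), (0.3, 0.1, 0.1)
        img = np.zeros(shape)
        nucleus = np.zeros(shape, bool)
        nucleus[2:14, 8:40, 8:40] = True
        img[nucleus] = 100.0
        labels = np.zeros(shape, int)
        labels[6:10, 20:28, 20:28] = 1
        img[labels > 0] = 900.0
        from scipy import ndimage
        guard = ndimage.binary_dilation(labels > 0, iterations=1)
        diffuse = nucleus & ~guard
        expected = img[diffuse].mean() / img[nucleus].mean()
        stack = LabeledStack(img, nucleus.astype(float) * 50, voxel)
        ratio, status = mo.diffuse_total_ratio(
            stack, mo.NucleusMask(nucleus, voxel, 0, 0), labels
        )
        assert status == "ok"
        assert ratio == pytest.approx(expected, rel=0.03)

    def test_ratio_decreases_with_brighter_condensates(self):
        ratios = []
        for amp in (300.0, 600.0, 1200.0):
            p = sim.StackSimParams(condensate_amplitude=amp, seed=2)
            stack, _ = sim.simulate_stack(p)
            nucleus = mo.segment_nucleus(stack)
            _, labels = mo.detect_condensates(stack, nucleus)
            ratios.append(mo.diffuse_total_ratio(stack, nucleus, labels)[0])
        assert ratios[0] > ratios[1] > ratios[2]

    def test_condensates_filling_nucleus_undefined(self):
        shape, voxel = (8, 16, 16), (0.3, 0.1, 0.1)
        nucleus = np.ones(shape, bool)
        labels = np.ones(shape, int)
        stack = LabeledStack(np.ones(shape), np.ones(shape), voxel)
        ratio, status = mo.diffuse_total_ratio(
            stack, mo.NucleusMask(nucleus, voxel, 0, 0), labels
        )
        assert status == "undefined" and np.isnan(ratio)


class TestRadialProfiles:
    def test_gaussian_core_not_flagged(self):
        p = sim.StackSimParams(n_condensates=1, condensate_radius=0.5,
                               min_separation=0.1, seed=7)
        stack, truth = sim.simulate_stack(p)
        rec = truth.truth["condensates"][0]
        profile = mo.radial_intensity_profile(
            stack, (rec["z"], rec["y"], rec["x"]), 0.5
        )
        assert profile is not None
        # peak at the innermost populated shell, decaying outward
        populated = profile[np.isfinite(profile)]
        assert populated[0] == np.nanmax(profile)
        assert populated[-1] < populated[0]
        assert not mo.classify_anisosome(profile)

    def test_shell_mode_flagged_as_anisosome(self):
        p = sim.StackSimParams(n_condensates=1, condensate_radius=0.5,
                               shell_mode=True, min_separation=0.1, seed=7)
        stack, truth = sim.simulate_stack(p)
        rec = truth.truth["condensates"][0]
        # shell radius is 2 * sigma = condensate radius; profile out to 1.5 R
        profile = mo.radial_intensity_profile(
            stack, (rec["z"], rec["y"], rec["x"]), 0.75
        )
        assert profile is not None
        assert mo.classify_anisosome(profile)

    def test_flat_profile_not_flagged(self):
        assert not mo.classify_anisosome(np.ones(10))

    def test_too_small_object_skipped(self):
        stack, _ = sim.simulate_stack(sim.StackSimParams(n_condensates=0,
                                                         seed=1))
        assert mo.radial_intensity_profile(stack, (3, 4, 4), 0.1) is None
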