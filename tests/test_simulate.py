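"""Synthetic field generator: axes, geometry, rendering, oracles, cohorts."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import CONTROL_DYS, NOISELESS, control_channels, roi_wall_fraction
from dysquant.model import MAX_12BIT
from dysquant.simulate import (
    ADIPOSE,
    CONNECTIVE,
    VESSEL,
    WALL,
    FluorophoreModel,
    GroupSpec,
    PlacementError,
    build_wavelength_axis,
    dystrophin_channel,
    generate_cohort,
    generate_geometry,
    group_intensity_params,
    oracle_rois,
    render_field,
    spectrin_channel,
)


class TestWavelengthAxisBuilder:
    def test_dystrophin_acquisition_axis(self):
        ax = build_wavelength_axis(485, 625, 5.21, 15)
        assert len(ax) == 27  # floor((625-485)/5.21) + 1
        assert ax.centers[0] == 485
        assert ax.centers[-1] <= 625

    def test_spectrin_acquisition_axis(self):
        ax = build_wavelength_axis(590, 780, 5.21, 15)
        assert ax.centers[0] == 590
        assert ax.centers[-1] <= 780

    def test_degenerate_single_window(self):
        ax = build_wavelength_axis(500, 500.1, 1, 1)
        assert ax.centers == (500.0,)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            build_wavelength_axis(485, 625, 0, 15)


class TestGeometry:
    def test_seeded_determinism(self):
        a = generate_geometry(128, 128, 8, 3, None, seed=1)
        b = generate_geometry(128, 128, 8, 3, None, seed=1)
        np.testing.assert_array_equal(a.label_image, b.label_image)

    def test_wall_disjoint_from_interiors(self, default_geometry):
        g = default_geometry
        assert g.wall_mask.sum() > 0
        assert not (g.wall_mask & g.fibre_interior_mask).any()

    def test_mean_equivalent_diameter(self, default_geometry):
        g = default_geometry
        labs = g.fibre_labels()
        areas = np.array([(g.label_image == l).sum() for l in labs])
        mean_eq_diam = np.mean(np.sqrt(4 * areas / np.pi))
        # oracle: diameter implied by total fibre area split over the count
        expected = np.sqrt(4 * areas.sum() / (np.pi * labs.size))
        assert abs(mean_eq_diam - expected) / expected < 0.15

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="too many fibres"):
            generate_geometry(32, 32, 500, 2, None, seed=0)

    def test_confounders_capped(self):
        g = generate_geometry(
            256, 256, 16, 4, {"vessel": 0.05, "adipose": 0.05, "connective": 0.05}, seed=3
        )
        for code in (VESSEL, ADIPOSE, CONNECTIVE):
            assert (g.label_image == code).any()
        assert g.fibre_count >= int(0.8 * 16)  # >= 80% of fibres survive


class TestRendering:
    def test_wall_mean_matches_truth(self, control_field):
        # oracle: direct average over the ground-truth wall mask
        tr = control_field.truth["NCL-Dys1"]
        wall = control_field.geometry.wall_mask
        rendered = control_field.dys_stack.cube[:, :, tr.peak_index][wall].mean()
        # expected: per-fibre wall values weighted by wall pixels + autofluorescence
        owner = control_field.geometry.wall_owner[wall]
        wall_vals = np.array([tr.per_fibre_wall[l] for l in owner])
        expected = wall_vals.mean() + tr.autofluorescence
        se = control_field.dys_stack.cube[:, :, tr.peak_index][wall].std() / np.sqrt(wall.sum())
        assert abs(rendered - expected) < max(2 * se, 1.0)

    def test_null_signal_indistinguishable_from_background(self, default_geometry):
        beta, _ = control_channels()
        dys_p = group_intensity_params("DMD", 0.0, 0.0)
        f = render_field(default_geometry, beta, dystrophin_channel("NCL-Dys1", dys_p), seed=5)
        tr = f.truth["NCL-Dys1"]
        img = f.dys_stack.cube[:, :, tr.peak_index].astype(float)
        wall = f.geometry.wall_mask
        bg = f.geometry.fibre_interior_mask
        se = np.hypot(img[wall].std() / np.sqrt(wall.sum()), img[bg].std() / np.sqrt(bg.sum()))
        assert abs(img[wall].mean() - img[bg].mean()) < 3 * se

    def test_noiseless_peak_window_is_nearest_to_fluorophore_peak(self, noiseless_field):
        for label, stack in {
            "NCL-Dys1": noiseless_field.dys_stack,
            "beta-spectrin": noiseless_field.beta_stack,
        }.items():
            tr = noiseless_field.truth[label]
            wall = noiseless_field.geometry.wall_mask
            spectrum = stack.cube[wall].mean(axis=0)
            peak_nm = 519.0 if label == "NCL-Dys1" else 670.0
            assert np.argmax(spectrum) == tr.peak_index
            assert abs(stack.axis.centers[tr.peak_index] - peak_nm) <= stack.axis.step

    def test_monotone_in_wall_mean(self):
        g = generate_geometry(128, 128, 6, 3, None, seed=7)
        beta = spectrin_channel(group_intensity_params("X", 1000, 0, noise=NOISELESS))
        means = []
        for wm in (200.0, 800.0, 2400.0):
            p = replace(group_intensity_params("X", wm, 0.0), noise=NOISELESS, wall_sd=0.0)
            f = render_field(g, beta, dystrophin_channel("d", p), seed=8)
            k = f.truth["d"].peak_index
            means.append(f.dys_stack.cube[:, :, k][g.wall_mask].mean())
        assert means[0] < means[1] < means[2]

    def test_twelve_bit_ceiling_and_clip_warning(self):
        g = generate_geometry(96, 96, 4, 3, None, seed=9)
        beta = spectrin_channel(group_intensity_params("X", 1000, 0))
        hot = group_intensity_params("X", 6000.0, 0.0)
        f = render_field(g, beta, dystrophin_channel("d", hot), seed=10)
        assert f.dys_stack.cube.max() <= MAX_12BIT
        assert f.truth["d"].clipping_warning

    def test_seeded_determinism(self, default_geometry):
        beta, dys = control_channels()
        f1 = render_field(default_geometry, beta, dys, seed=21)
        f2 = render_field(default_geometry, beta, dys, seed=21)
        np.testing.assert_array_equal(f1.dys_stack.cube, f2.dys_stack.cube)
        np.testing.assert_array_equal(f1.beta_stack.cube, f2.beta_stack.cube)

    def test_bleedthrough_raises_offpeak_signal(self):
        g = generate_geometry(96, 96, 4, 3, None, seed=9)
        beta_p = group_intensity_params("X", 2000, 0, noise=NOISELESS)
        dys_p = replace(group_intensity_params("X", 1500, 0, noise=NOISELESS), wall_sd=0.0)
        clean = render_field(g, spectrin_channel(beta_p), dystrophin_channel("d", dys_p), seed=1)
        leaky = render_field(
            g, spectrin_channel(beta_p), dystrophin_channel("d", dys_p), seed=1,
            bleed_dys_into_beta=0.2,
        )
        # dystrophin (peak 519 nm) leaks into the low end of the 590-780 nm axis
        k0 = 0
        assert (
            leaky.beta_stack.cube[:, :, k0][g.wall_mask].mean()
            > clean.beta_stack.cube[:, :, k0][g.wall_mask].mean()
        )

    def test_spectrin_level_recovered_over_oracle_rois(self):
        # beta-spectrin rendered at the dystrophic-muscle level is recovered
        # by membrane-only oracle ROIs within simulation error
        g = generate_geometry(320, 320, 14, 4, None, seed=31)
        beta_p = group_intensity_params("DMD", 2346.13, 65.88)
        dys_p = group_intensity_params("DMD", 500.8, 17.6)
        f = render_field(g, spectrin_channel(beta_p), dystrophin_channel("NCL-Dys1", dys_p), seed=32)
        rois = oracle_rois(g, n=26, ellipse_params=(4, 2), seed=33)
        k = f.truth["beta-spectrin"].peak_index
        img = f.beta_stack.cube[:, :, k].astype(float)
        vals = np.array([img[r.pixel_coords()].mean() for r in rois])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 2346.13) < 3 * se + f.truth["beta-spectrin"].autofluorescence


class TestOracleROIs:
    def test_requested_count_and_membrane_only(self, default_geometry):
        rois = oracle_rois(default_geometry, n=26, ellipse_params=(4, 2), seed=40)
        assert len(rois) == 26
        for r in rois:
            assert roi_wall_fraction(r, default_geometry.wall_mask) >= 0.9
        # pairwise non-overlap
        for i, a in enumerate(rois):
            for b in rois[i + 1 :]:
                assert not a.overlaps(b)

    def test_single_fibre_ring(self):
        g = generate_geometry(96, 96, 1, 3, None, seed=41)
        (roi,) = oracle_rois(g, n=1, ellipse_params=(3, 1.5), seed=42)
        assert roi_wall_fraction(roi, g.wall_mask) >= 0.9

    def test_placement_error_reports_achieved(self):
        g = generate_geometry(96, 96, 3, 4, None, seed=43)
        with pytest.raises(PlacementError) as ei:
            oracle_rois(g, n=500, ellipse_params=(4, 2), seed=44)
        assert 0 < ei.value.achieved < 500
        assert len(ei.value.rois) == ei.value.achieved


class TestCohort:
    @staticmethod
    def tiny_groups(between=0.05):
        p = lambda g, m, se: group_intensity_params(g, m, se)
        groups = []
        for g, nb in (("DMD", 10), ("BMD", 3), ("CONTROL", 6)):
            groups.append(
                GroupSpec(
                    group_label=g,
                    n_biopsies=nb,
                    channel_params={
                        "beta-spectrin": p(g, 1800, 60),
                        "NCL-Dys1": p(g, 800, 20),
                    },
                    between_biopsy_frac=between,
                )
            )
        return groups

    def test_reference_shape_yields_57_fields(self):
        cohort = generate_cohort(self.tiny_groups(), rows=96, cols=96, n_fibres=4, seed=50)
        assert len(cohort) == 19
        assert sum(len(b.fields) for b in cohort) == 57

    def test_zero_between_biopsy_sd_gives_equal_means(self):
        groups = [self.tiny_groups(between=0.0)[0]]
        cohort = generate_cohort(groups, rows=96, cols=96, n_fibres=4, seed=51)
        means = {b.true_means["NCL-Dys1"] for b in cohort}
        assert means == {800.0}

    def test_different_seeds_differ_but_match_statistically(self):
        groups = [replace(self.tiny_groups()[2], n_biopsies=1)]
        a = generate_cohort(groups, fields_per_biopsy=1, rows=128, cols=128, n_fibres=6, seed=52)
        b = generate_cohort(groups, fields_per_biopsy=1, rows=128, cols=128, n_fibres=6, seed=53)
        fa, fb = a[0].fields[0], b[0].fields[0]
        assert not np.array_equal(fa.dys_stack.cube, fb.dys_stack.cube)
        ka = fa.truth["NCL-Dys1"].peak_index
        ma = fa.dys_stack.cube[:, :, ka][fa.geometry.wall_mask].mean()
        mb = fb.dys_stack.cube[:, :, ka][fb.geometry.wall_mask].mean()
        assert abs(ma - mb) / ma < 0.25

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_cohort([])

    def test_guide_channel_required(self):
        with pytest.raises(ValueError, match="beta-spectrin"):
            GroupSpec("DMD", 2, {"NCL-Dys1": group_intensity_params("DMD", 500, 10)})
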