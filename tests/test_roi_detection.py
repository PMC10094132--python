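"""Sarcolemma localisation, ellipse proposal, scoring, and selection."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from conftest import control_channels, roi_wall_fraction, select_top_oracle
from dysquant.model import EllipticalROI
from dysquant.roi_detection import (
    ROIScore,
    SarcolemmaMask,
    detect_rois,
    locate_sarcolemma,
    propose_ellipses,
    score_rois,
    select_top,
    tangent_field,
)
from dysquant.segmentation import FibreRegion
from dysquant.simulate import generate_geometry, render_field


def region_from_mask(mask, label=1):
    rr, cc = np.nonzero(mask)
    return FibreRegion(
        label=label, pixel_mask=mask, area_px=int(mask.sum()),
        centroid=(float(rr.mean()), float(cc.mean())), circularity=1.0,
        mean_intensity=0.0,
    )


def band_mask(shape=(40, 60), rows=(18, 22)):
    m = np.zeros(shape, dtype=bool)
    m[rows[0] : rows[1], :] = True
    return m


class TestTangentField:
    def test_horizontal_band(self):
        theta = tangent_field(band_mask())
        assert np.allclose(theta[19, 20:40], 0.0, atol=0.05)

    def test_vertical_band(self):
        theta = tangent_field(band_mask().T)
        assert np.allclose(theta[20:40, 19], np.pi / 2, atol=0.05)

    def test_diagonal_band(self):
        m = np.zeros((60, 60), dtype=bool)
        for i in range(58):
            m[i, max(0, i - 2) : i + 2] = True
        theta = tangent_field(m)
        mid = theta[28:32, 28:32]
        # 45-degree wall: |cos(theta - pi/4)| near 1
        assert np.all(np.abs(np.cos(mid - np.pi / 4)) > 0.98)


class TestLocateSarcolemma:
    def test_gap_between_discs_is_covered(self):
        shape = (80, 80)
        m1 = np.zeros(shape, dtype=bool)
        m2 = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((40, 25), 12)
        m1[rr, cc] = True
        rr, cc = draw_disk((40, 55), 12)  # 6 px gap along the row
        m2[rr, cc] = True
        sarc = locate_sarcolemma([region_from_mask(m1), region_from_mask(m2)], shape, 4)
        assert sarc.mask[40, 40]  # centre of the gap band
        assert not sarc.mask[40, 25]  # interiors excluded

    def test_single_disc_gives_annulus(self):
        shape = (80, 80)
        m = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((40, 40), 15)
        m[rr, cc] = True
        sarc = locate_sarcolemma([region_from_mask(m)], shape, 4)
        d = np.hypot(*np.mgrid[0:80, 0:80] - np.array([40, 40])[:, None, None])
        assert not (sarc.mask & (d < 14.5)).any()
        assert sarc.mask[(d > 15.5) & (d < 18.5)].mean() > 0.9
        assert 2.0 <= sarc.thickness_px <= 6.0

    def test_zero_regions_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            locate_sarcolemma([], (32, 32), 4)

    def test_band_inside_true_wall(self, noiseless_field):
        from dysquant.segmentation import (
            binarize, denoise_median, extract_fibre_regions, select_reference_slice,
        )
        from skimage.morphology import dilation, disk

        _, ref = select_reference_slice(noiseless_field.beta_stack)
        den = denoise_median(ref, 1)
        regs = extract_fibre_regions(~binarize(den, "otsu"))
        sarc = locate_sarcolemma(regs, ref.shape, 4)
        truth = dilation(noiseless_field.geometry.wall_mask, disk(1))
        assert truth[sarc.mask].mean() >= 0.8


class TestProposeEllipses:
    def make_sarc(self, mask):
        return SarcolemmaMask(mask=mask, thickness_px=4.0, tangent_field=tangent_field(mask))

    def test_horizontal_band_candidates_aligned(self):
        sarc = self.make_sarc(band_mask())
        cands = propose_ellipses(sarc, 4, 2, 8)
        assert len(cands) >= 3
        for r in cands:
            assert min(r.theta, np.pi - r.theta) < 0.1

    def test_spacing_larger_than_extent_gives_one(self):
        sarc = self.make_sarc(band_mask((40, 60)))
        cands = propose_ellipses(sarc, 4, 2, 1000)
        assert len(cands) == 1

    def test_default_field_many_mostly_on_wall(self, noiseless_field):
        rs_mask = noiseless_field.geometry.wall_mask
        sarc = self.make_sarc(rs_mask)
        cands = propose_ellipses(sarc, 4, 2, 8)
        assert len(cands) >= 100
        on_wall = [roi_wall_fraction(r, rs_mask) for r in cands]
        frac_good = np.mean([2 * f - 1 > 0.5 for f in on_wall])
        assert frac_good >= 0.95

    def test_empty_mask_gives_empty_list(self):
        sarc = self.make_sarc(np.zeros((20, 20), dtype=bool))
        assert propose_ellipses(sarc, 4, 2, 8) == []


class TestScoreROIs:
    def test_hand_computed_three_candidate_case(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:14, :] = True  # horizontal wall band, rows 10..13
        sarc = SarcolemmaMask(mask=mask, thickness_px=4.0, tangent_field=tangent_field(mask))
        ref = np.full((30, 30), 100.0)
        cands = [
            EllipticalROI(11.5, 15, 4, 2, 0.0),        # fully in wall, aligned
            EllipticalROI(25.0, 15, 4, 2, np.pi / 2),  # fully outside, orthogonal
            EllipticalROI(13.5, 15, 4, 2, 0.0),        # half in, half out
        ]
        scores = score_rois(cands, ref, sarc, (1 / 3, 1 / 3, 1 / 3))
        # brightness = 1 everywhere (flat field); by hand:
        # c1: (1 + 1 + 1)/3 = 1;  c2: (1 + 0 + 0)/3;  c3: (1 + 1 + 0)/3
        assert scores[0].total == pytest.approx(1.0, abs=1e-9)
        assert scores[1].total == pytest.approx(1 / 3, abs=1e-9)
        assert scores[2].total == pytest.approx(2 / 3, abs=1e-9)
        assert scores[1].wall_overlap == 0.0

    def test_out_of_bounds_candidate_named(self):
        sarc = SarcolemmaMask(
            mask=np.ones((20, 20), dtype=bool), thickness_px=4.0,
            tangent_field=np.zeros((20, 20)),
        )
        with pytest.raises(ValueError, match="outside"):
            score_rois([EllipticalROI(1, 1, 4, 2, 0)], np.ones((20, 20)), sarc)

    def test_weights_validated(self):
        sarc = SarcolemmaMask(np.ones((20, 20), dtype=bool), 4.0, np.zeros((20, 20)))
        roi = [EllipticalROI(10, 10, 4, 2, 0)]
        with pytest.raises(ValueError, match="sum"):
            score_rois(roi, np.ones((20, 20)), sarc, (0.5, 0.5, 0.5))


def random_candidates(rng, n, shape=(100, 100)):
    cands, scores = [], []
    for _ in range(n):
        cands.append(
            EllipticalROI(
                rng.uniform(8, shape[0] - 8), rng.uniform(8, shape[1] - 8),
                4.0, 2.0, rng.uniform(0, np.pi),
            )
        )
        t = rng.random()
        scores.append(ROIScore(t, t, t, t))
    return cands, scores


class TestSelectTop:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(70)
        for trial in range(5):
            cands, scores = random_candidates(rng, 50)
            got = select_top(cands, scores, 26, image_shape=(100, 100))
            want = select_top_oracle(cands, scores, 26)
            assert got.rois == [cands[i] for i in want]

    def test_plenty_of_room_selects_exactly_n(self):
        # 40 non-overlapping candidates on a grid
        cands, scores = [], []
        rng = np.random.default_rng(71)
        for i in range(5):
            for j in range(8):
                cands.append(EllipticalROI(10 + 12 * i, 10 + 12 * j, 4, 2, 0))
                t = rng.random()
                scores.append(ROIScore(t, t, t, t))
        rs = select_top(cands, scores, 26, image_shape=(100, 110))
        assert len(rs.rois) == 26 and not rs.shortfall
        top = sorted(range(40), key=lambda i: -scores[i].total)[:26]
        assert sorted(s.total for s in rs.scores) == sorted(scores[i].total for i in top)

    def test_exhaustion_sets_shortfall(self):
        cands = [EllipticalROI(10, 10 + 12 * j, 4, 2, 0) for j in range(10)]
        scores = [ROIScore(0.5, 0.5, 0.5, 0.5)] * 10
        rs = select_top(cands, scores, 26, image_shape=(32, 140))
        assert len(rs.rois) == 10 and rs.shortfall

    def test_tie_break_prefers_smaller_row_col(self):
        a = EllipticalROI(10, 10, 4, 2, 0)
        b = EllipticalROI(10, 12, 4, 2, 0)  # overlaps a; identical score
        s = ROIScore(0.5, 0.5, 0.5, 0.5)
        rs = select_top([b, a], [s, s], 26, image_shape=(32, 32))
        assert rs.rois == [a]


class TestDetectROIs:
    def test_default_field_yields_26(self, control_field):
        rs = detect_rois(control_field.beta_stack)
        assert len(rs.rois) == 26 and not rs.shortfall

    def test_three_fields_yield_78(self):
        total = 0
        for seed in (80, 81, 82):
            g = generate_geometry(320, 320, 14, 4, None, seed=seed)
            beta, dys = control_channels()
            f = render_field(g, beta, dys, seed=seed + 100)
            total += len(detect_rois(f.beta_stack).rois)
        assert total == 78

    def test_deterministic(self, control_field):
        r1 = detect_rois(control_field.beta_stack)
        r2 = detect_rois(control_field.beta_stack)
        assert r1.rois == r2.rois
        assert [s.total for s in r1.scores] == [s.total for s in r2.scores]

    def test_selected_rois_on_true_wall(self, noiseless_field):
        rs = detect_rois(noiseless_field.beta_stack)
        fracs = [roi_wall_fraction(r, noiseless_field.geometry.wall_mask) for r in rs.rois]
        # pooled over ROIs: >= 90% of selected pixels on the ground-truth wall
        sizes = [r.pixel_coords()[0].size for r in rs.rois]
        pooled = np.average(fracs, weights=sizes)
        assert pooled >= 0.9

    def test_diagnosis_blind(self, default_geometry):
        # permuting the dystrophin cube must not change ROI selection
        beta, dys = control_channels()
        f = render_field(default_geometry, beta, dys, seed=90)
        rs1 = detect_rois(f.beta_stack)
        rng = np.random.default_rng(0)
        f.dys_stacks["NCL-Dys1"].cube = rng.permutation(
            f.dys_stack.cube.ravel()
        ).reshape(f.dys_stack.cube.shape)
        rs2 = detect_rois(f.beta_stack)
        assert rs1.rois == rs2.rois

    def test_placement_accuracy_across_seeds(self):
        """Mean ground-truth wall overlap >= 0.85 across 10 seeded fields."""
        overlaps = []
        for seed in range(10):
            g = generate_geometry(256, 256, 9, 4, None, seed=200 + seed)
            beta, dys = control_channels()
            f = render_field(g, beta, dys, seed=300 + seed)
            rs = detect_rois(f.beta_stack)
            overlaps.extend(roi_wall_fraction(r, g.wall_mask) for r in rs.rois)
        assert np.mean(overlaps) >= 0.85

    def test_stage_tagging_of_errors(self):
        from dysquant.model import SpectralStack, WavelengthAxis

        ax = WavelengthAxis([500.0, 505.0], 15.0, 5.0)
        flat = SpectralStack(
            cube=np.full((64, 64, 2), 7, dtype=np.uint16), axis=ax, excitation=470.0
        )
        with pytest.raises(RuntimeError, match="stage 'binarize'"):
            detect_rois(flat)
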