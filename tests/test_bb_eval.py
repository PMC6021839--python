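import numpy as np
import pytest

from touchsplit.bb_eval import (
    BBEvalConfig,
    RoI,
    UsefulBB,
    build_roi,
    cut_with_one_bb,
    cut_with_two_bbs,
    evaluate_bb,
    filter_candidates,
    perimeter_runs,
    quality_gate,
    select_useful_bbs,
)
from touchsplit.errors import EmptyMaskError, Fallback
from touchsplit.maskgeom import BBox, BoundaryLine, Mask, Point, split_by_line
from touchsplit.synthdata import ellipse_inside

from conftest import make_dumbbell, oracle_border_pixels

CFG = BBEvalConfig()


def brute_force_eval(bb, grid, roi, cfg=CFG):
    """Independent pixel-by-pixel evaluation of the box conditions."""
    pp_bb = 0
    for r in range(bb.top, bb.bottom + 1):
        for c in range(bb.left, bb.right + 1):
            if grid[r, c]:
                pp_bb += 1
    border = oracle_border_pixels(grid)
    bp_bb = 0
    for (r, c) in border:
        d_out = max(
            bb.top - r, r - bb.bottom, bb.left - c, c - bb.right, 0
        )
        if d_out > cfg.near_band:
            continue
        inside_depth = min(r - bb.top, bb.bottom - r, c - bb.left, bb.right - c)
        if d_out == 0 and inside_depth > cfg.near_band:
            continue
        bp_bb += 1
    size_ok = cfg.size_lo * roi.pp_roi <= pp_bb <= cfg.size_hi * roi.pp_roi
    boundary_ok = cfg.boundary_frac * roi.bp_roi <= bp_bb
    return pp_bb, bp_bb, size_ok, boundary_ok


class TestBuildRoi:
    def test_full_square(self):
        roi = build_roi(Mask(np.ones((10, 10), dtype=bool)))
        assert roi.pp_roi == 100
        assert (roi.box.top, roi.box.left, roi.box.bottom, roi.box.right) == (
            0,
            0,
            9,
            9,
        )

    def test_single_pixel(self):
        g = np.zeros((5, 5), dtype=bool)
        g[2, 2] = True
        roi = build_roi(Mask(g))
        assert roi.pp_roi == 1 and roi.bp_roi == 1

    def test_bp_roi_is_border_count(self, filled_ellipse):
        roi = build_roi(filled_ellipse)
        assert roi.bp_roi == len(oracle_border_pixels(filled_ellipse.grid))

    def test_empty_errors(self):
        with pytest.raises(EmptyMaskError):
            build_roi(Mask(np.zeros((3, 3), dtype=bool)))


class TestFilterCandidates:
    def setup_method(self):
        g = np.zeros((40, 40), dtype=bool)
        g[10:30, 10:30] = True
        self.mask = Mask(g)
        self.roi = build_roi(self.mask)

    def test_outside_removed(self):
        assert filter_candidates([BBox(0, 0, 5, 5)], self.roi) == []

    def test_roi_box_kept(self):
        out = filter_candidates([BBox(10, 10, 29, 29)], self.roi)
        assert len(out) == 1

    def test_overhang_within_tolerance_clipped(self):
        out = filter_candidates([BBox(9, 10, 29, 30)], self.roi)
        assert len(out) == 1
        b = out[0]
        assert (b.top, b.left, b.bottom, b.right) == (10, 10, 29, 29)

    def test_overhang_beyond_tolerance_removed(self):
        assert filter_candidates([BBox(6, 10, 29, 29)], self.roi) == []

    def test_probability_threshold_inclusive(self):
        cfg = BBEvalConfig(probability_th=0.9)
        keep = filter_candidates([BBox(10, 10, 29, 29, 0.9)], self.roi, cfg)
        drop = filter_candidates([BBox(10, 10, 29, 29, 0.89)], self.roi, cfg)
        assert len(keep) == 1 and drop == []


class TestEvaluateBB:
    def test_size_condition_printed_inequality(self):
        # pp_roi = 1000: pp_bb = 500 passes, 399 fails (0.4*1000 bound)
        g = np.zeros((10, 100), dtype=bool)
        g[:, :] = True  # 1000 pixels
        mask = Mask(g)
        roi = build_roi(mask)
        assert roi.pp_roi == 1000
        ok = evaluate_bb(BBox(0, 0, 9, 49), mask, roi)  # 500 px
        assert ok.pp_bb == 500 and ok.size_ok
        bad = evaluate_bb(BBox(0, 0, 9, 38), mask, roi)  # 390 px
        assert not bad.size_ok

    def test_confidence_hand_computed(self):
        # fabricate counts through a crafted RoI to check the formula
        g = np.ones((10, 100), dtype=bool)
        mask = Mask(g)
        roi = build_roi(mask)
        ub = evaluate_bb(BBox(0, 0, 9, 44), mask, roi)
        num = ub.bp_bb - CFG.boundary_frac * roi.bp_roi
        den = abs(ub.pp_bb - 0.5 * roi.pp_roi)
        if ub.passes:
            assert ub.confidence == pytest.approx(num / den)

    def test_zero_denominator_policy(self):
        g = np.ones((10, 100), dtype=bool)
        mask = Mask(g)
        roi = build_roi(mask)
        ub = evaluate_bb(BBox(0, 0, 9, 49), mask, roi)  # exactly half
        assert ub.pp_bb * 2 == roi.pp_roi
        if ub.passes:
            expected = (ub.bp_bb - 0.2 * roi.bp_roi) / 0.5
            assert ub.confidence == pytest.approx(expected)

    def test_flags_match_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(123)
        agree = 0
        for _ in range(100):
            a = rng.uniform(6, 14)
            b = rng.uniform(4, a)
            g = ellipse_inside((36, 36), (18, 18), (a, b), rng.uniform(0, np.pi))
            mask = Mask(g)
            roi = build_roi(mask)
            t = rng.integers(2, 18)
            l = rng.integers(2, 18)
            bb = BBox(int(t), int(l), int(t + rng.integers(4, 16)), int(l + rng.integers(4, 16))).clip(36, 36)
            got = evaluate_bb(bb, mask, roi)
            pp, bp, s_ok, b_ok = brute_force_eval(bb, g, roi)
            assert got.pp_bb == pp
            assert got.bp_bb == bp
            assert got.size_ok == s_ok
            assert got.boundary_ok == b_ok
            agree += 1
        assert agree == 100


class TestSelectUsefulBBs:
    def _mk(self, conf, pp, box):
        return UsefulBB(
            box=box, pp_bb=pp, bp_bb=30, size_ok=True, boundary_ok=True,
            confidence=conf,
        )

    def test_no_candidates(self):
        g = np.ones((10, 10), dtype=bool)
        roi = build_roi(Mask(g))
        fail = UsefulBB(BBox(0, 0, 4, 4), 25, 0, False, True)
        assert select_useful_bbs([fail], roi, Mask(g)) == []

    def test_single_candidate(self):
        g = np.ones((10, 10), dtype=bool)
        mask = Mask(g)
        roi = build_roi(mask)
        one = self._mk(1.0, 50, BBox(0, 0, 9, 4))
        assert select_useful_bbs([one], roi, mask) == [one]

    def test_two_disjoint_halves_selected_in_confidence_order(self):
        g = np.ones((10, 20), dtype=bool)
        mask = Mask(g)
        roi = build_roi(mask)
        left = self._mk(2.0, 100, BBox(0, 0, 9, 9))
        right = self._mk(3.0, 100, BBox(0, 10, 9, 19))
        out = select_useful_bbs([left, right], roi, mask)
        assert out == [right, left]
        assert out[0].confidence >= out[1].confidence

    def test_coverage_condition_rejects_nested_second(self):
        g = np.ones((10, 20), dtype=bool)
        mask = Mask(g)
        roi = build_roi(mask)
        big = self._mk(3.0, 100, BBox(0, 0, 9, 9))
        nested = self._mk(2.0, 60, BBox(2, 2, 7, 7))  # inside first box
        out = select_useful_bbs([big, nested], roi, mask)
        assert out == [big]

    def test_never_returns_failing_box(self, suite200):
        from touchsplit.bb_eval import filter_candidates

        for f in suite200[:40]:
            mask = f.mask
            roi = build_roi(mask)
            cands = filter_candidates(f.bbs, roi, BBEvalConfig(probability_th=0.8))
            evs = [evaluate_bb(b, mask, roi) for b in cands]
            out = select_useful_bbs(evs, roi, mask)
            assert all(u.passes for u in out)
            confs = [u.confidence for u in out]
            assert confs == sorted(confs, reverse=True)


class TestCutWithOneBB:
    def test_neck_crossing_gives_one_line(self):
        mask, (c1, c2) = make_dumbbell(neck_half_width=2, neck_len=10, r=8)
        rows, cols = mask.grid.shape
        # box over the left disc whose right edge crosses the bar once
        mid_c = (c1[1] + c2[1]) // 2
        bb = UsefulBB(BBox(0, 0, rows - 1, mid_c), 1, 1, True, True, 1.0)
        line = cut_with_one_bb(bb, mask)
        labels = split_by_line(mask, line)
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_interior_box_falls_back(self):
        g = ellipse_inside((30, 30), (15, 15), (12, 12), 0.0)
        bb = UsefulBB(BBox(10, 10, 20, 20), 1, 1, True, True, 1.0)
        with pytest.raises(Fallback):
            cut_with_one_bb(bb, Mask(g))

    def test_tangent_box_falls_back(self):
        g = np.zeros((30, 30), dtype=bool)
        g[10:20, 10:20] = True
        bb = UsefulBB(BBox(0, 0, 5, 5), 0, 0, True, True, 1.0)
        with pytest.raises(Fallback):
            cut_with_one_bb(bb, Mask(g))

    def test_two_crossings_fall_back(self):
        mask, (c1, c2) = make_dumbbell(neck_half_width=2, neck_len=14, r=8)
        rows, cols = mask.grid.shape
        # narrow vertical box straddling the bar: left and right edges cross
        mid = (c1[1] + c2[1]) // 2
        bb = UsefulBB(BBox(0, mid - 3, rows - 1, mid + 3), 1, 1, True, True, 1.0)
        with pytest.raises(Fallback):
            cut_with_one_bb(bb, mask)


class TestCutWithTwoBBs:
    def test_shared_edge_case2(self):
        g = np.ones((10, 20), dtype=bool)
        mask = Mask(g)
        a = UsefulBB(BBox(0, 0, 9, 10), 1, 1, True, True, 1.0)
        b = UsefulBB(BBox(0, 10, 9, 19), 1, 1, True, True, 1.0)
        line = cut_with_two_bbs(a, b, mask)
        labels = split_by_line(mask, line)
        assert labels.max() == 2

    def test_overlap_rectangle_cuts_dumbbell(self):
        mask, (c1, c2) = make_dumbbell(neck_half_width=2, neck_len=16, r=9)
        rows, cols = mask.grid.shape
        mid = (c1[1] + c2[1]) // 2
        a = UsefulBB(BBox(0, 0, rows - 1, mid + 2), 1, 1, True, True, 1.0)
        b = UsefulBB(BBox(0, mid - 2, rows - 1, cols - 1), 1, 1, True, True, 1.0)
        line = cut_with_two_bbs(a, b, mask)
        labels = split_by_line(mask, line)
        n1, n2 = (labels == 1).sum(), (labels == 2).sum()
        assert min(n1, n2) > 0

    def test_disjoint_boxes_cut_at_gap_midline(self):
        g = np.ones((10, 30), dtype=bool)
        mask = Mask(g)
        a = UsefulBB(BBox(0, 0, 9, 11), 1, 1, True, True, 1.0)
        b = UsefulBB(BBox(0, 18, 9, 29), 1, 1, True, True, 1.0)
        line = cut_with_two_bbs(a, b, mask)
        cols = {p.col for p in line.points}
        assert cols == {(11 + 18) // 2}


class TestQualityGate:
    def _labels(self, n1, n2):
        lab = np.zeros((1, n1 + n2), dtype=np.uint8)
        lab[0, :n1] = 1
        lab[0, n1:] = 2
        return lab

    def test_length_20_passes_21_fails(self):
        lab = self._labels(50, 50)
        mk = lambda n: BoundaryLine(points=[Point(0, c) for c in range(n)])
        assert quality_gate(mk(20), lab)
        assert not quality_gate(mk(21), lab)

    def test_size_ratio_printed_threshold(self):
        line = BoundaryLine(points=[Point(0, 0)])
        assert quality_gate(line, self._labels(60, 40))  # 1.5 exactly
        assert not quality_gate(line, self._labels(61, 39))  # ~1.564


class TestDeterminism:
    def test_same_inputs_same_outputs(self, suite200):
        from touchsplit.pipeline import separate_by_bbs

        f = suite200[3]
        cfg = BBEvalConfig(probability_th=0.8)
        r1 = separate_by_bbs(f.mask, f.bbs, cfg)
        r2 = separate_by_bbs(f.mask, f.bbs, cfg)
        assert (r1.labels == r2.labels).all()
        assert r1.boundary.points == r2.boundary.points
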