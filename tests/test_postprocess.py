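"""Gap bridging, distal relabeling, hole closing: the mask-cleanup rule table."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from peridermtk import measurement as ms
from peridermtk import postprocess as pp
from peridermtk import synthetic_data as sd
from peridermtk.io_formats import LabelMask

from .conftest import SMALL_PP


def straight_root_mask(
    periderm_spans: list[tuple[int, int]],
    total_rows: int = 1200,
    width: int = 31,
) -> LabelMask:
    """A vertical rectangular root; given row spans are periderm, rest endoderm."""
    labels = np.zeros((total_rows + 20, width + 20), dtype=np.uint8)
    labels[10 : 10 + total_rows, 10 : 10 + width] = 2
    for lo, hi in periderm_spans:
        labels[10 + lo : 10 + hi, 10 : 10 + width] = 1
    return LabelMask(labels)


def single_root(mask: LabelMask) -> pp.RootInstance:
    (root,) = pp.extract_root_instances(mask, pp.PostprocessConfig(min_root_area=100))
    return root


class TestExtractRootInstances:
    def test_six_roots_numbered_left_to_right(self):
        slide = sd.generate_slide(
            n_roots=6, seed=31, canvas=(2600, 3600),
            specs=[
                sd.SyntheticRootSpec(total_length=2000, width=45, curvature_amplitude=40,
                                     periderm_fraction=0.4, lateral_root_count=0, seed=s)
                for s in range(6)
            ],
            slide_id="six",
        )
        roots = pp.extract_root_instances(slide.truth_mask, SMALL_PP, "six")
        assert [r.root_id for r in roots] == [1, 2, 3, 4, 5, 6]
        hyp_cols = [r.centerline[0][1] for r in roots]
        assert hyp_cols == sorted(hyp_cols)

    def test_empty_mask_yields_empty_list(self):
        mask = LabelMask(np.zeros((100, 100), dtype=np.uint8))
        assert pp.extract_root_instances(mask, SMALL_PP) == []

    def test_debris_below_area_floor_discarded(self):
        mask = straight_root_mask([(0, 500)])
        mask.labels[5:8, 60:62] = 2  # a 6-px speck
        cfg = pp.PostprocessConfig(min_root_area=100)
        roots = pp.extract_root_instances(mask, cfg)
        assert len(roots) == 1

    def test_centerline_starts_at_hypocotyl_edge(self):
        root = single_root(straight_root_mask([(0, 100)]))
        assert root.centerline[0][0] < root.centerline[-1][0]


class TestProjectSegments:
    def test_fully_periderm_root_is_one_full_run(self):
        mask = straight_root_mask([(0, 1200)])
        root = single_root(mask)
        (seg,) = pp.project_segments(root, mask)
        assert seg.start_index == 0
        assert seg.end_index == len(root.centerline) - 1

    def test_two_planted_runs_and_gap_positions(self):
        mask = straight_root_mask([(0, 500), (600, 900)])
        root = single_root(mask)
        segs = pp.project_segments(root, mask)
        assert len(segs) == 2
        cum = ms.arc_positions(root.centerline)
        gap = cum[segs[1].start_index] - cum[segs[0].end_index]
        assert gap == pytest.approx(100, abs=6)

    def test_no_periderm_gives_no_segments(self):
        mask = straight_root_mask([])
        root = single_root(mask)
        assert pp.project_segments(root, mask) == []

    def test_empty_centerline_rejected(self):
        mask = straight_root_mask([])
        root = single_root(mask)
        broken = pp.RootInstance(1, "x", root.pixel_coords, np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError, match="centerline"):
            pp.project_segments(broken, mask)


class TestBridgeAndRelabel:
    def run_rule(self, spans, total_rows=1200):
        mask = straight_root_mask(spans, total_rows=total_rows)
        root = single_root(mask)
        segs = pp.project_segments(root, mask)
        cfg = pp.PostprocessConfig(min_root_area=100)
        merged, out = pp.bridge_and_relabel(root, segs, mask, cfg)
        return root, merged, out

    def test_small_gap_bridged_into_single_run(self):
        # 100 px gap < 150 -> connected
        root, merged, out = self.run_rule([(0, 500), (600, 900)])
        assert len(merged) == 1
        cum = ms.arc_positions(root.centerline)
        run_len = cum[merged[0].end_index] - cum[merged[0].start_index]
        assert run_len == pytest.approx(900, abs=10)
        # the gap rows are now periderm in the mask
        assert (out.labels[10 + 520 : 10 + 580, 25] == 1).all()

    def test_large_gap_relabels_distal_run_as_endoderm(self):
        # 300 px gap > 150 -> distal periderm becomes endoderm
        root, merged, out = self.run_rule([(0, 500), (800, 900)])
        cum = ms.arc_positions(root.centerline)
        run_len = cum[merged[0].end_index] - cum[merged[0].start_index]
        assert run_len == pytest.approx(500, abs=10)
        assert (out.labels[10 + 800 : 10 + 900, 25] == 2).all()
        assert not (out.labels[10 + 550 :, :] == 1).any()

    def test_gap_of_exactly_threshold_is_bridged(self):
        mask = straight_root_mask([(0, 400), (550, 700)])
        root = single_root(mask)
        segs = pp.project_segments(root, mask)
        cum = ms.arc_positions(root.centerline)
        gap = cum[segs[1].start_index] - cum[segs[0].end_index]
        cfg = pp.PostprocessConfig(min_root_area=100, bridge_max_gap=float(gap))
        merged, _ = pp.bridge_and_relabel(root, segs, mask, cfg)
        assert len(merged) == 1
        assert merged[0].end_index == segs[1].end_index

    def test_single_segment_unchanged(self):
        root, merged, out = self.run_rule([(100, 600)])
        assert len(merged) == 1
        cum = ms.arc_positions(root.centerline)
        assert cum[merged[0].end_index] - cum[merged[0].start_index] == pytest.approx(500, abs=10)

    def test_no_segments_passthrough(self):
        mask = straight_root_mask([])
        root = single_root(mask)
        merged, out = pp.bridge_and_relabel(root, [], mask, pp.PostprocessConfig(min_root_area=100))
        assert merged == []
        np.testing.assert_array_equal(out.labels, mask.labels)

    def test_idempotence(self):
        mask = straight_root_mask([(0, 300), (400, 700), (1000, 1100)])
        root = single_root(mask)
        cfg = pp.PostprocessConfig(min_root_area=100)
        m1, out1 = pp.bridge_and_relabel(root, pp.project_segments(root, mask), mask, cfg)
        m2, out2 = pp.bridge_and_relabel(root, pp.project_segments(root, out1), out1, cfg)
        np.testing.assert_array_equal(out1.labels, out2.labels)
        assert m1 == m2

    def test_non_background_pixel_count_conserved(self):
        mask = straight_root_mask([(0, 300), (400, 700), (1000, 1100)])
        root = single_root(mask)
        _, out = pp.bridge_and_relabel(
            root, pp.project_segments(root, mask), mask, pp.PostprocessConfig(min_root_area=100)
        )
        assert (out.labels != 0).sum() == (mask.labels != 0).sum()

    def test_run_anchored_at_proximal_most_periderm(self):
        # the surviving run contains the hypocotyl-proximal-most periderm position
        mask = straight_root_mask([(50, 300), (800, 1000)])
        root = single_root(mask)
        merged, out = pp.bridge_and_relabel(
            root, pp.project_segments(root, mask), mask, pp.PostprocessConfig(min_root_area=100)
        )
        cum = ms.arc_positions(root.centerline)
        assert cum[merged[0].start_index] == pytest.approx(50, abs=6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_interval_merge_oracle(self, seed):
        """Random planted runs vs an independent interval-scan oracle."""
        rng = np.random.default_rng(seed)
        total = 3000
        # random alternating run/gap layout, gaps 1..400 px, <= 20 segments
        spans, pos = [], 0
        while pos < total - 100 and len(spans) < 20:
            run = int(rng.integers(60, 300))
            spans.append((pos, min(pos + run, total)))
            pos += run + int(rng.integers(1, 400))
        # oracle: scan from the proximal end, merge while gap <= 150
        end = spans[0][1]
        for (lo, hi) in spans[1:]:
            if lo - end <= 150:
                end = hi
            else:
                break
        expected_len = end - spans[0][0]

        mask = straight_root_mask(spans, total_rows=total)
        root = single_root(mask)
        merged, _ = pp.bridge_and_relabel(
            root, pp.project_segments(root, mask), mask, pp.PostprocessConfig(min_root_area=100)
        )
        cum = ms.arc_positions(root.centerline)
        got = cum[merged[0].end_index] - cum[merged[0].start_index]
        assert got == pytest.approx(expected_len, abs=12)


class TestCloseSmallHoles:
    def punched_mask(self, hole_areas: list[int]):
        mask = straight_root_mask([(0, 1200)], width=41)
        root = single_root(mask)
        col = 10 + 20
        row = 200
        for area in hole_areas:
            radius = np.sqrt(area / np.pi)
            rr, cc = np.mgrid[0 : mask.height, 0 : mask.width]
            hole = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
            mask.labels[hole] = 0
            row += 300
        return mask, root

    def measured_hole_areas(self, mask: LabelMask) -> list[int]:
        interior = mask.labels == 0
        interior[:, :12] = interior[:, -12:] = False  # ignore outer background
        interior[:12, :] = interior[-12:, :] = False
        lab, n = ndimage.label(interior)
        areas = np.bincount(lab.ravel())[1:]
        return sorted(int(a) for a in areas if a > 0)

    def test_small_hole_filled_large_hole_kept(self):
        mask, root = self.punched_mask([10, 50])
        planted = self.measured_hole_areas(mask)
        assert planted[0] < 20 <= planted[1]
        out = pp.close_small_holes(mask, root, hole_max=20)
        remaining = self.measured_hole_areas(out)
        assert remaining == [planted[1]]

    def test_hole_of_exactly_threshold_not_filled(self):
        mask, root = self.punched_mask([10])
        area = self.measured_hole_areas(mask)[0]
        out = pp.close_small_holes(mask, root, hole_max=area)  # strict '<'
        assert self.measured_hole_areas(out) == [area]

    def test_hole_free_mask_unchanged(self):
        mask = straight_root_mask([(0, 1200)])
        root = single_root(mask)
        out = pp.close_small_holes(mask, root, hole_max=20)
        np.testing.assert_array_equal(out.labels, mask.labels)

    def test_periderm_count_never_decreases(self):
        mask, root = self.punched_mask([10, 15, 50])
        out = pp.close_small_holes(mask, root, hole_max=20)
        assert (out.labels == 1).sum() >= (mask.labels == 1).sum()


class TestPostprocessConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="bridge_max_gap > hole_max"):
            pp.PostprocessConfig(bridge_max_gap=10, hole_max=20)


class TestPostprocessSlide:
    def test_full_cleanup_on_corrupted_synthetic_slide(self, small_slide):
        corrupted = sd.corrupt_mask(
            small_slide,
            gap_spans=[(1, 400.0, 100.0), (2, 400.0, 300.0)],
            hole_specs=[(1, 800.0, 1.7)],
        )
        cleaned, roots = pp.postprocess_slide(corrupted, SMALL_PP, "fix1")
        assert len(roots) == 2
        for root in roots:
            segs = pp.project_segments(root, cleaned)
            assert len(segs) <= 1  # single anchored run per root
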