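"""Mask cleaning, region screening, backbones, inflections, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecount.counting import (
    Backbone,
    CountParams,
    accuracy,
    clean_mask,
    count_image,
    count_inflections,
    count_spikes,
    evaluate,
    extract_backbone,
    flag_overlap_candidates,
    region_statistics,
)
from spikecount.synthetic import _capsule_mask


def capsule(shape, center, angle, length, width):
    return _capsule_mask(shape, center, angle, length, width)


def chain(*segments, step=1.0):
    """Polyline chain through the given (length_px, angle_deg) segments."""
    pts = [np.array([100.0, 10.0])]
    for length, angle in segments:
        d = np.array([np.sin(np.deg2rad(angle)), np.cos(np.deg2rad(angle))])
        for _ in range(int(length / step)):
            pts.append(pts[-1] + d * step)
    return Backbone(pixels=np.array(np.round(pts), dtype=int), branch_count=0)


class TestCleanMask:
    def test_large_disk_survives_opening(self):
        mask = capsule((80, 80), (40, 40), 0.0, 24, 24)  # disk of radius 12
        out = clean_mask(mask, open_radius=4, min_area=10)
        assert out.sum() > 0.7 * mask.sum()
        assert region_statistics(out)[0].area == out.sum()

    def test_small_fragment_removed(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:8, 5:8] = True  # area 9
        assert not clean_mask(mask, open_radius=0, min_area=10).any()
        assert clean_mask(mask, open_radius=0, min_area=9).any()

    def test_thin_bridge_severed(self):
        shape = (60, 140)
        mask = capsule(shape, (30, 30), 0.0, 40, 16) | capsule(
            shape, (30, 110), 0.0, 40, 16
        )
        mask[30, :] = True  # 1-px bridge across
        out = clean_mask(mask, open_radius=2, min_area=20)
        assert len(region_statistics(out)) == 2

    def test_empty_in_empty_out(self):
        assert not clean_mask(np.zeros((5, 5), bool), 2, 10).any()

    def test_salt_noise_below_min_area_never_changes_count(self, rng):
        shape = (200, 200)
        mask = capsule(shape, (60, 100), 0.3, 80, 18) | capsule(
            shape, (150, 100), 1.2, 80, 18
        )
        params = CountParams(open_radius=2, min_area=60)
        base = count_image(mask, params)
        noisy = mask.copy()
        for _ in range(30):
            r, c = rng.integers(0, 198, 2)
            noisy[r : r + 2, c : c + 2] = True  # specks of area <= 4
        assert count_image(noisy, params).total == base.total


class TestRegionStatistics:
    def test_rectangle_elongation(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:12, 5:15] = True  # 10 x 2
        stats = region_statistics(mask)
        assert len(stats) == 1
        assert stats[0].area == 20
        assert stats[0].elongation == pytest.approx(5.0, rel=0.15)

    def test_disk_is_round(self):
        mask = capsule((60, 60), (30, 30), 0.0, 30, 30)
        stats = region_statistics(mask)
        assert stats[0].elongation == pytest.approx(1.0, abs=0.05)

    def test_empty_mask(self):
        assert region_statistics(np.zeros((5, 5), bool)) == []

    def test_axes_ordered_and_positive(self, rng):
        mask = rng.random((40, 40)) < 0.4
        for s in region_statistics(mask):
            assert s.major_axis >= s.minor_axis > 0
            assert s.elongation >= 1.0


class TestFlagOverlapCandidates:
    def _round_region(self, area):
        from spikecount.counting import RegionStats

        return RegionStats(1, area, (0.0, 0.0), 10.0, 9.0, 10.0 / 9.0)

    def test_identical_regions_no_candidates(self):
        stats = [self._round_region(100) for _ in range(5)]
        flagged = flag_overlap_candidates(stats)
        assert not any(s.is_overlap_candidate for s in flagged)

    def test_double_median_area_flagged(self):
        stats = [self._round_region(100) for _ in range(20)]
        stats.append(self._round_region(200))
        flagged = flag_overlap_candidates(stats)
        assert flagged[-1].is_overlap_candidate
        assert sum(s.is_overlap_candidate for s in flagged) == 1

    def test_single_region_only_elongation_rule(self):
        from spikecount.counting import RegionStats

        stout = RegionStats(1, 5000, (0.0, 0.0), 50.0, 40.0, 1.25)
        slim = RegionStats(1, 5000, (0.0, 0.0), 100.0, 10.0, 10.0)
        assert not flag_overlap_candidates([stout])[0].is_overlap_candidate
        assert flag_overlap_candidates([slim])[0].is_overlap_candidate

    def test_empty_list(self):
        assert flag_overlap_candidates([]) == []


class TestExtractBackbone:
    def test_bar_backbone_spans_length(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[8:12, 10:50] = True  # 40 x 4 bar
        bb = extract_backbone(mask)
        assert abs(len(bb.pixels) - 40) <= 4
        rows = bb.pixels[:, 0]
        assert rows.min() >= 8 and rows.max() < 12

    def test_plus_sign_takes_longest_opposing_arms(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[38:42, 10:70] = True  # long horizontal arms (60)
        mask[25:55, 38:42] = True  # shorter vertical arms (30)
        bb = extract_backbone(mask, spur_length=4)
        cols = bb.pixels[:, 1]
        assert cols.max() - cols.min() > 40  # follows the horizontal axis

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        bb = extract_backbone(mask)
        assert len(bb.pixels) == 1
        assert tuple(bb.pixels[0]) == (2, 2)

    def test_chain_is_simple_and_connected(self):
        mask = capsule((100, 100), (50, 50), 0.7, 70, 12)
        bb = extract_backbone(mask)
        pts = [tuple(p) for p in bb.pixels]
        assert len(pts) == len(set(pts))  # no repeated pixel
        diffs = np.abs(np.diff(bb.pixels, axis=0))
        assert diffs.max() <= 1  # 8-connected steps
        assert mask[bb.pixels[:, 0], bb.pixels[:, 1]].all()  # chain within region


class TestCountInflections:
    def test_straight_chain(self):
        assert count_inflections(chain((80, 90))) == 0

    def test_right_angle_v(self):
        bb = chain((30, 45), (30, 135))  # 90 degree turn
        assert count_inflections(bb) == 1

    @pytest.mark.parametrize("m", [0, 1, 2, 3])
    def test_zigzag_bend_recovery(self, m):
        """m alternating 60-degree bends spaced 25 px apart count as m."""
        segments = [(25, 0 if i % 2 == 0 else 60) for i in range(m + 1)]
        bb = chain(*segments)
        assert count_inflections(bb) == m

    def test_short_chain_counts_zero(self):
        assert count_inflections(chain((10, 0), (2, 80)), window=7) == 0


class TestCountSpikes:
    def test_three_disjoint_capsules(self):
        shape = (200, 200)
        mask = (
            capsule(shape, (40, 100), 0.2, 70, 16)
            | capsule(shape, (100, 60), 1.2, 70, 16)
            | capsule(shape, (160, 140), 2.0, 70, 16)
        )
        res = count_spikes(mask, CountParams(min_area=50))
        assert res.n_region == 3
        assert res.total == 3

    def test_fused_pair_counts_two_via_inflection(self):
        """Among ordinary capsules, a pair leaning at 60 degrees fuses into
        one double-area region; its single backbone bend restores the count
        to n_point + 1."""
        shape = (500, 500)
        mask = np.zeros(shape, dtype=bool)
        for c in ((60, 80), (60, 200), (60, 320), (120, 440), (250, 60)):
            mask |= capsule(shape, c, 0.0, 90, 16)
        a = np.deg2rad(60)
        c1 = (350.0, 150.0)
        contact = (350.0, 150.0 + 37.0)
        c2 = (contact[0] + np.sin(a) * 37, contact[1] + np.cos(a) * 37)
        mask |= capsule(shape, c1, 0.0, 90, 16) | capsule(shape, c2, a, 90, 16)
        res = count_spikes(mask, CountParams(min_area=50))
        assert res.n_region == 6
        fused = max(res.per_region, key=lambda s: s.area)
        assert fused.is_overlap_candidate and fused.n_inflections == 1
        assert res.n_point == 1
        assert res.total == 7  # five singles + the fused pair counted as two

    def test_empty_mask(self):
        res = count_spikes(np.zeros((10, 10), bool))
        assert res.total == 0 and res.n_region == 0

    def test_total_identity(self, small_scene):
        from spikecount.features import SPIKE

        _, _, truth = small_scene
        res = count_image(truth.class_map == SPIKE, CountParams(min_area=300))
        assert res.total == res.n_region + res.n_point
        assert res.n_point == sum(s.n_inflections for s in res.per_region)


class TestAccuracy:
    @pytest.mark.parametrize(
        "nc, na, expected",
        [(100, 100, 100.0), (90, 100, 90.0), (110, 100, 90.0)],
    )
    def test_worked_values(self, nc, na, expected):
        assert accuracy(nc, na) == expected

    @given(st.integers(1, 500), st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_reflection_invariance(self, na, nc):
        """A is symmetric around the benchmark: N_c and 2 N_a - N_c agree."""
        assert accuracy(nc, na) == pytest.approx(accuracy(2 * na - nc, na))
        assert accuracy(na, na) == 100.0

    def test_zero_benchmark_rejected(self):
        with pytest.raises(ValueError, match="benchmark"):
            accuracy(10, 0)


class TestEvaluate:
    def test_exact_line(self):
        pairs = [(10, 10), (20, 20), (35, 35)]
        res = evaluate(pairs)
        assert res.mean_accuracy == 100.0
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_r_squared_is_r_squared(self):
        res = evaluate([(10, 10), (20, 18), (30, 33)])
        assert res.r_squared == pytest.approx(res.pearson_r**2, abs=1e-9)

    def test_independent_counts_uncorrelated(self, rng):
        na = rng.integers(10, 60, size=200)
        nc = rng.permutation(na)
        res = evaluate(list(zip(nc, na)))
        assert abs(res.pearson_r) < 0.15

    def test_zero_variance_reports_nan_but_keeps_accuracy(self):
        res = evaluate([(10, 10), (10, 10), (10, 10)])
        assert np.isnan(res.pearson_r)
        assert res.mean_accuracy == 100.0

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError, match="3"):
            evaluate([(1, 1), (2, 2)])
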