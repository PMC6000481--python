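"""Extent, cluster, overlap metrics against exhaustive enumeration and
flood-fill oracles; pair analysis and cohort summaries."""

import numpy as np
import pytest

from bodymap.body_model import BodyView, Drawing, OutlineMask, SymptomMap, SymptomSpec, VIEWS
from bodymap.repro_metrics import (
    analyze_pair,
    cluster_count,
    cohort_summary,
    overlap_stats,
    pair_results_frame,
    symptom_extent,
)
from bodymap.synthetic_cohort import generate_outline_set

from conftest import SMALL_DIMS, make_map

DIMS = (20, 16)


# --- independent oracles ---------------------------------------------------


def extent_oracle(arr):
    return sum(1 for r in range(arr.shape[0]) for c in range(arr.shape[1]) if arr[r, c] > 0)


def flood_fill_count(arr, connectivity):
    """Component count by explicit BFS under the given neighbourhood."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros(arr.shape, dtype=bool)
    count = 0
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            if arr[r, c] > 0 and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < arr.shape[0]
                            and 0 <= nc < arr.shape[1]
                            and arr[nr, nc] > 0
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return count


def random_arr(rng, p=0.3):
    return (rng.random(DIMS) < p) * rng.integers(1, 11, size=DIMS)


# --- extent ----------------------------------------------------------------


class TestExtent:
    def test_all_zero(self):
        assert symptom_extent(make_map("front", DIMS, [])) == 0

    def test_filled_rectangle(self):
        pixels = [(r, c) for r in range(3, 8) for c in range(2, 6)]
        assert symptom_extent(make_map("front", DIMS, pixels)) == 20

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            arr = random_arr(rng)
            assert symptom_extent(arr) == extent_oracle(arr)


# --- clusters --------------------------------------------------------------


class TestClusterCount:
    def test_single_disk(self):
        pixels = [(r, c) for r in range(DIMS[0]) for c in range(DIMS[1])
                  if (r - 8) ** 2 + (c - 8) ** 2 <= 9]
        assert cluster_count(make_map("front", DIMS, pixels)) == 1

    def test_two_separated_blobs(self):
        m = make_map("front", DIMS, [(2, 2), (2, 3), (10, 10), (10, 11)])
        assert cluster_count(m) == 2

    def test_diagonal_touch_depends_on_connectivity(self):
        m = make_map("front", DIMS, [(5, 5), (6, 6)])
        assert cluster_count(m, connectivity=8) == 1
        assert cluster_count(m, connectivity=4) == 2

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            cluster_count(make_map("front", DIMS, []), connectivity=6)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(31)
        for _ in range(25):
            arr = random_arr(rng)
            assert cluster_count(arr, connectivity) == flood_fill_count(arr, connectivity)


# --- overlap ---------------------------------------------------------------


class TestOverlap:
    def test_identical_maps(self):
        m = make_map("front", DIMS, [(1, 1), (2, 2)])
        assert overlap_stats(m, m) == (2, 2, 1.0)

    def test_disjoint_maps(self):
        a = make_map("front", DIMS, [(1, 1)])
        b = make_map("front", DIMS, [(5, 5)])
        inter, union, jac = overlap_stats(a, b)
        assert (inter, union, jac) == (0, 2, 0.0)

    def test_shifted_square_half_overlap(self):
        sq = [(r, c) for r in range(5, 8) for c in range(5, 8)]
        shifted = [(r, c + 1) for r, c in sq]
        inter, union, jac = overlap_stats(make_map("front", DIMS, sq), make_map("front", DIMS, shifted))
        assert (inter, union) == (6, 12)
        assert jac == pytest.approx(0.5)

    def test_undefined_when_union_empty(self):
        blank = make_map("front", DIMS, [])
        assert overlap_stats(blank, blank)[2] is None

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = random_arr(rng), random_arr(rng)
            assert overlap_stats(a, b) == overlap_stats(b, a)


class TestMetricProperties:
    def test_merge_extent_subadditive(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a, b = random_arr(rng), random_arr(rng)
            both = symptom_extent(np.maximum(a, b))
            assert both <= symptom_extent(a) + symptom_extent(b)
            if not ((a > 0) & (b > 0)).any():
                assert both == symptom_extent(a) + symptom_extent(b)

    def test_cluster_count_bounded_by_extent_and_ink_monotone(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            arr = random_arr(rng, p=0.15)
            assert cluster_count(arr) <= symptom_extent(arr)
            more = arr.copy()
            blank = np.argwhere(more == 0)
            if len(blank):
                r, c = blank[rng.integers(len(blank))]
                more[r, c] = 5
            assert symptom_extent(more) >= symptom_extent(arr)


# --- pair analysis ---------------------------------------------------------


def _spec():
    return SymptomSpec(descriptors=("burning",), depths=("muscle",), vas_max=5)


def _drawing(outlines, patient, session, per_view_pixels):
    dims = next(iter(outlines.values())).dims
    maps = {
        BodyView(v): make_map(v, dims, px)
        for v, px in per_view_pixels.items() if px
    }
    return Drawing(patient, session, outlines, [(_spec(), maps)] if maps else [])


@pytest.fixture()
def pair_pixels(outlines_small):
    interiors = {v: np.argwhere(outlines_small[v].grid) for v in VIEWS}
    px = {v.value: [tuple(p) for p in interiors[v][:40]] for v in VIEWS}
    return px


class TestAnalyzePair:
    def test_identical_pair_perfect_metrics(self, outlines_small, pair_pixels):
        t = _drawing(outlines_small, "P1", "test", pair_pixels)
        r = _drawing(outlines_small, "P1", "retest", pair_pixels)
        res = analyze_pair(t, r)
        assert res.jaccard == pytest.approx(1.0)
        assert res.extent_1 == res.extent_2
        for v in VIEWS:
            assert res.views[v].jaccard == pytest.approx(1.0)

    def test_blank_in_both_view_excluded(self, outlines_small, pair_pixels):
        px = dict(pair_pixels)
        px["left"] = []
        t = _drawing(outlines_small, "P1", "test", px)
        r = _drawing(outlines_small, "P1", "retest", px)
        res = analyze_pair(t, r)
        assert not res.views[BodyView.LEFT].included
        assert res.extent_1 == sum(
            res.views[v].extent_1 for v in VIEWS if v != BodyView.LEFT
        )

    def test_view_drawn_once_counts_jaccard_zero(self, outlines_small, pair_pixels):
        px_retest = dict(pair_pixels)
        px_retest["back"] = []
        t = _drawing(outlines_small, "P1", "test", pair_pixels)
        r = _drawing(outlines_small, "P1", "retest", px_retest)
        res = analyze_pair(t, r, exclusion="both")
        assert res.views[BodyView.BACK].included
        assert res.views[BodyView.BACK].jaccard == 0.0
        res_either = analyze_pair(t, r, exclusion="either")
        assert not res_either.views[BodyView.BACK].included

    def test_hand_enumerated_view_metrics(self, outlines_small):
        interior = np.argwhere(outlines_small[BodyView.FRONT].grid)
        base = tuple(interior[len(interior) // 2])
        sq = [(base[0] + dr, base[1] + dc) for dr in range(3) for dc in range(3)]
        shifted = [(r, c + 1) for r, c in sq]
        t = _drawing(outlines_small, "P1", "test", {"front": sq})
        r = _drawing(outlines_small, "P1", "retest", {"front": shifted})
        m = analyze_pair(t, r).views[BodyView.FRONT]
        assert (m.extent_1, m.extent_2) == (9, 9)
        assert (m.intersection, m.union) == (6, 12)
        assert m.jaccard == pytest.approx(0.5)
        assert m.clusters_1 == 1 and m.clusters_2 == 1

    def test_mismatched_patient_rejected(self, outlines_small, pair_pixels):
        t = _drawing(outlines_small, "P1", "test", pair_pixels)
        r = _drawing(outlines_small, "P2", "retest", pair_pixels)
        with pytest.raises(ValueError, match="patient"):
            analyze_pair(t, r)

    def test_view_metric_invariants(self, outlines_small, pair_pixels):
        rng = np.random.default_rng(4)
        px2 = {
            v: [p for p in pts if rng.random() < 0.7]
            for v, pts in pair_pixels.items()
        }
        t = _drawing(outlines_small, "P1", "test", pair_pixels)
        r = _drawing(outlines_small, "P1", "retest", px2)
        res = analyze_pair(t, r)
        for v in VIEWS:
            m = res.views[v]
            assert m.intersection <= min(m.extent_1, m.extent_2)
            assert m.union >= max(m.extent_1, m.extent_2)
            if m.union > 0:
                assert m.jaccard == pytest.approx(m.intersection / m.union)


class TestCohortSummary:
    def _identical_pairs(self, outlines_small):
        interiors = np.argwhere(outlines_small[BodyView.FRONT].grid)
        pairs = []
        for i, n_px in enumerate([20, 45, 80]):
            px = {"front": [tuple(p) for p in interiors[:n_px]]}
            t = _drawing(outlines_small, f"P{i}", "test", px)
            r = _drawing(outlines_small, f"P{i}", "retest", px)
            pairs.append(analyze_pair(t, r))
        return pairs

    def test_identical_pairs_perfect_summary(self, outlines_small):
        s = cohort_summary(self._identical_pairs(outlines_small))
        assert s.jaccard_mean == pytest.approx(1.0)
        assert s.icc_extent.icc == pytest.approx(1.0)

    def test_icc_matches_anova_on_hand_set_extents(self, outlines_small):
        from bodymap.agreement_stats import icc31

        interiors = np.argwhere(outlines_small[BodyView.FRONT].grid)
        pairs = []
        extents = [(10, 20), (20, 40), (30, 60)]
        for i, (e1, e2) in enumerate(extents):
            t = _drawing(outlines_small, f"P{i}", "test",
                         {"front": [tuple(p) for p in interiors[:e1]]})
            r = _drawing(outlines_small, f"P{i}", "retest",
                         {"front": [tuple(p) for p in interiors[:e2]]})
            pairs.append(analyze_pair(t, r))
        s = cohort_summary(pairs)
        assert s.icc_extent.icc == pytest.approx(icc31(extents).icc)
        assert s.icc_extent.icc == pytest.approx(0.8)

    def test_too_few_patients_rejected(self, outlines_small):
        with pytest.raises(ValueError, match="at least 2"):
            cohort_summary(self._identical_pairs(outlines_small)[:1])

    def test_view_with_too_few_included_not_estimable(self, outlines_small):
        pairs = self._identical_pairs(outlines_small)
        s = cohort_summary(pairs)
        # only the front view was drawn; the others are not estimable
        assert s.icc_extent_by_view[BodyView.LEFT] is None

    def test_results_frame_has_one_row_per_patient(self, outlines_small):
        df = pair_results_frame(self._identical_pairs(outlines_small))
        assert len(df) == 3
        assert {"patient_id", "jaccard", "extent_test"} <= set(df.columns)
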