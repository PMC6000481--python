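"""Test-retest reproducibility metrics for drawing pairs.

For each body view of a test-retest pair the analysis extracts symptom
extent (number of drawn pixels inside the outline), cluster count
(connected components of the binarized drawing), and the intersection,
union and Jaccard index of the two binarized drawings.  A view blank in
both sessions is excluded; whole-drawing values sum extents/clusters
and pool pixels over the included views.  Cohort summaries report the
mean (SD) Jaccard index and ICC(3,1) of extent and cluster count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .agreement_stats import AgreementResult, icc31
from .body_model import BodyView, Drawing, OutlineMask, VIEWS
from .drawing_ops import MergedMap, binarize, merge_symptom_maps, restrict_to_outline

__all__ = [
    "ViewMetrics",
    "ReproPairResult",
    "CohortSummary",
    "symptom_extent",
    "cluster_count",
    "overlap_stats",
    "analyze_pair",
    "cohort_summary",
]

#: connected-component structuring elements
_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def symptom_extent(map_like, outline: OutlineMask | None = None, threshold: int = 0) -> int:
    """Number of drawn pixels (intensity > threshold), restricted to the
    outline interior when an outline is given."""
    if outline is not None:
        map_like = restrict_to_outline(map_like, outline)
    return int(binarize(map_like, threshold).sum())


def cluster_count(map_like, connectivity: int = 8, threshold: int = 0) -> int:
    """Number of connected components of the binarized map.

    ``connectivity`` 8 (default) joins diagonal neighbours; 4 joins only
    edge neighbours.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    _, n = ndimage.label(binarize(map_like, threshold), structure=_STRUCTURES[connectivity])
    return int(n)


def overlap_stats(
    map_a, map_b, outline: OutlineMask | None = None, threshold: int = 0
) -> tuple[int, int, float | None]:
    """(intersection, union, jaccard) of two binarized maps.

    Jaccard is ``None`` (undefined) when the union is empty; it is never
    coerced to 0 or 1.
    """
    a = binarize(map_a, threshold)
    b = binarize(map_b, threshold)
    if a.shape != b.shape:
        raise ValueError(f"map dims differ: {a.shape} vs {b.shape}")
    if outline is not None:
        if outline.grid.shape != a.shape:
            raise ValueError("outline dims do not match maps")
        a = a & outline.grid
        b = b & outline.grid
    inter = int((a & b).sum())
    union = int((a | b).sum())
    return inter, union, (inter / union if union > 0 else None)


# ---------------------------------------------------------------------------
# Pair analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViewMetrics:
    view: BodyView
    extent_1: int
    extent_2: int
    clusters_1: int
    clusters_2: int
    intersection: int
    union: int
    jaccard: float | None
    included: bool


@dataclass(frozen=True)
class ReproPairResult:
    patient_id: str
    views: dict[BodyView, ViewMetrics]
    extent_1: int  # whole-drawing totals over included views
    extent_2: int
    clusters_1: int
    clusters_2: int
    intersection: int
    union: int
    jaccard: float | None  # pooled over included views
    jaccard_view_max: float | None  # aggregates of per-view jaccards
    jaccard_view_mean: float | None

    @property
    def included_views(self) -> list[BodyView]:
        return [v for v in VIEWS if self.views[v].included]


def _merged_views(d: Drawing) -> dict[BodyView, MergedMap]:
    out = {}
    for view in VIEWS:
        merged = merge_symptom_maps(d.maps_for_view(view), view, dims=d.dims)
        out[view] = restrict_to_outline(merged, d.outlines[view])
    return out


def analyze_pair(
    test: Drawing,
    retest: Drawing,
    connectivity: int = 8,
    threshold: int = 0,
    exclusion: str = "both",
) -> ReproPairResult:
    """Full reproducibility metrics for one test-retest pair.

    Symptoms are merged per drawing (max VAS per pixel), metrics are
    computed independently per body view, then the view-exclusion rule
    is applied: with ``exclusion="both"`` (default) a view is excluded
    only when blank in *both* sessions, so a view drawn in exactly one
    session contributes Jaccard 0; ``exclusion="either"`` drops views
    blank in at least one session.
    """
    if test.patient_id != retest.patient_id:
        raise ValueError(f"patient ids differ: {test.patient_id!r} vs {retest.patient_id!r}")
    if test.dims != retest.dims:
        raise ValueError(f"outline dims differ: {test.dims} vs {retest.dims}")
    for v in VIEWS:
        if not np.array_equal(test.outlines[v].grid, retest.outlines[v].grid):
            raise ValueError(f"outline grids differ on view {v.value}")
    if exclusion not in ("both", "either"):
        raise ValueError("exclusion must be 'both' or 'either'")

    m1 = _merged_views(test)
    m2 = _merged_views(retest)
    views: dict[BodyView, ViewMetrics] = {}
    for v in VIEWS:
        e1 = symptom_extent(m1[v], threshold=threshold)
        e2 = symptom_extent(m2[v], threshold=threshold)
        inter, union, jac = overlap_stats(m1[v], m2[v], threshold=threshold)
        if exclusion == "both":
            included = (e1 > 0) or (e2 > 0)
        else:
            included = (e1 > 0) and (e2 > 0)
        views[v] = ViewMetrics(
            view=v,
            extent_1=e1,
            extent_2=e2,
            clusters_1=cluster_count(m1[v], connectivity, threshold),
            clusters_2=cluster_count(m2[v], connectivity, threshold),
            intersection=inter,
            union=union,
            jaccard=jac,
            included=included,
        )

    inc = [v for v in VIEWS if views[v].included]
    inter = sum(views[v].intersection for v in inc)
    union = sum(views[v].union for v in inc)
    per_view_jacs = [views[v].jaccard for v in inc if views[v].jaccard is not None]
    return ReproPairResult(
        patient_id=test.patient_id,
        views=views,
        extent_1=sum(views[v].extent_1 for v in inc),
        extent_2=sum(views[v].extent_2 for v in inc),
        clusters_1=sum(views[v].clusters_1 for v in inc),
        clusters_2=sum(views[v].clusters_2 for v in inc),
        intersection=inter,
        union=union,
        jaccard=(inter / union if union > 0 else None),
        jaccard_view_max=(max(per_view_jacs) if per_view_jacs else None),
        jaccard_view_mean=(float(np.mean(per_view_jacs)) if per_view_jacs else None),
    )


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    """Mean (SD) Jaccard plus ICC(3,1) of extent and cluster count, for
    the whole drawing and each single view (per-view ICCs over the
    patients whose view is included)."""

    n_patients: int
    jaccard_mean: float | None
    jaccard_sd: float | None
    jaccard_view_mean_mean: float | None
    icc_extent: AgreementResult | None
    icc_clusters: AgreementResult | None
    icc_extent_by_view: dict[BodyView, AgreementResult | None]
    icc_clusters_by_view: dict[BodyView, AgreementResult | None]

    def to_frame(self) -> pd.DataFrame:
        """Table-style summary: one row per reported quantity."""

        def _icc_cells(r: AgreementResult | None):
            if r is None:
                return (math.nan, "not estimable")
            return (r.icc, f"({r.ci_low:.2f}-{r.ci_high:.2f})")

        rows = [
            ("jaccard_mean", self.jaccard_mean, f"(SD {self.jaccard_sd:.2f})" if self.jaccard_sd is not None else ""),
            ("icc_extent_whole", *_icc_cells(self.icc_extent)),
            *[
                (f"icc_extent_{v.value}", *_icc_cells(self.icc_extent_by_view[v]))
                for v in VIEWS
            ],
            ("icc_clusters_whole", *_icc_cells(self.icc_clusters)),
            *[
                (f"icc_clusters_{v.value}", *_icc_cells(self.icc_clusters_by_view[v]))
                for v in VIEWS
            ],
        ]
        return pd.DataFrame(rows, columns=["quantity", "value", "detail"])


def _safe_icc(pairs: Sequence[tuple[float, float]]) -> AgreementResult | None:
    if len(pairs) < 2:
        return None
    try:
        return icc31(np.asarray(pairs, dtype=float))
    except ValueError:
        return None


def cohort_summary(results: Iterable[ReproPairResult]) -> CohortSummary:
    """Aggregate per-pair metrics over a cohort (>= 2 patients)."""
    res = list(results)
    if len(res) < 2:
        raise ValueError("cohort summary needs at least 2 patients")

    jacs = [r.jaccard for r in res if r.jaccard is not None]
    view_means = [r.jaccard_view_mean for r in res if r.jaccard_view_mean is not None]
    icc_extent = _safe_icc([(r.extent_1, r.extent_2) for r in res])
    icc_clusters = _safe_icc([(r.clusters_1, r.clusters_2) for r in res])
    icc_extent_by_view: dict[BodyView, AgreementResult | None] = {}
    icc_clusters_by_view: dict[BodyView, AgreementResult | None] = {}
    for v in VIEWS:
        inc = [r.views[v] for r in res if r.views[v].included]
        icc_extent_by_view[v] = _safe_icc([(m.extent_1, m.extent_2) for m in inc])
        icc_clusters_by_view[v] = _safe_icc([(m.clusters_1, m.clusters_2) for m in inc])

    return CohortSummary(
        n_patients=len(res),
        jaccard_mean=(float(np.mean(jacs)) if jacs else None),
        jaccard_sd=(float(np.std(jacs, ddof=1)) if len(jacs) > 1 else None),
        jaccard_view_mean_mean=(float(np.mean(view_means)) if view_means else None),
        icc_extent=icc_extent,
        icc_clusters=icc_clusters,
        icc_extent_by_view=icc_extent_by_view,
        icc_clusters_by_view=icc_clusters_by_view,
    )


def pair_results_frame(results: Iterable[ReproPairResult]) -> pd.DataFrame:
    """One row per patient with whole-drawing and per-view metrics."""
    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "extent_test": r.extent_1,
            "extent_retest": r.extent_2,
            "clusters_test": r.clusters_1,
            "clusters_retest": r.clusters_2,
            "intersection": r.intersection,
            "union": r.union,
            "jaccard": r.jaccard,
            "jaccard_view_max": r.jaccard_view_max,
            "jaccard_view_mean": r.jaccard_view_mean,
        }
        for v in VIEWS:
            m = r.views[v]
            row[f"{v.value}_extent_test"] = m.extent_1
            row[f"{v.value}_extent_retest"] = m.extent_2
            row[f"{v.value}_clusters_test"] = m.clusters_1
            row[f"{v.value}_clusters_retest"] = m.clusters_2
            row[f"{v.value}_jaccard"] = m.jaccard
            row[f"{v.value}_included"] = m.included
        rows.append(row)
    return pd.DataFrame(rows)
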