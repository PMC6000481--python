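"""Synthetic test-retest cohorts of body-map drawings.

No clinical drawings ship with this package, so every downstream stage
is exercised on simulated cohorts with known ground truth.  The
generator emulates the salient features of real tablet drawings:

* four body views on procedurally generated silhouette outlines;
* per-view symptom-cluster counts drawn from an over-dispersed count
  distribution (clinical cluster counts have SD larger than the mean);
* clusters rasterized as unions of 1-3 filled disks with one VAS level
  per cluster, rejection-placed inside the outline, free to merge by
  overlap (so drawn-cluster count >= connected-component count);
* a retest perturbation model producing partial overlap between the
  two sessions of one patient: random cluster translation, signed
  morphological grow/shrink of the cluster boundary, cluster dropout
  ("forgot a symptom") and cluster addition ("remembered a new one").

One master seed drives the cohort; per-patient substreams are derived
by counter-based seed splitting, so adding patients never perturbs
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .body_model import (
    BodyView,
    DAY_INTERVALS,
    DEPTH_CATEGORIES,
    Drawing,
    OutlineMask,
    SymptomMap,
    SymptomSpec,
    VIEWS,
    sensation_descriptors,
)

__all__ = [
    "PerturbParams",
    "SimParams",
    "generate_outline",
    "generate_outline_set",
    "generate_pair",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbParams:
    """Retest perturbation model.

    translation_sigma : SD (pixels) of the random shift applied to each
        surviving cluster at retest.
    boundary_noise_sigma : SD (pixels) of the signed morphological
        grow/shrink applied to each cluster's disk radii.
    cluster_dropout_p : probability a test cluster is omitted at retest.
    cluster_addition_p : per-cluster probability that an extra new
        cluster appears at retest (balances dropout in expectation).
    """

    translation_sigma: float = 10.0
    boundary_noise_sigma: float = 2.0
    cluster_dropout_p: float = 0.15
    cluster_addition_p: float = 0.15

    def __post_init__(self) -> None:
        if self.translation_sigma < 0 or self.boundary_noise_sigma < 0:
            raise ValueError("perturbation sigmas must be non-negative")
        for p in (self.cluster_dropout_p, self.cluster_addition_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("perturbation probabilities must be in [0, 1]")

    @classmethod
    def none(cls) -> "PerturbParams":
        """The zero-perturbation setting: retest identical to test."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of a synthetic cohort.

    Defaults emulate a pain-clinic reproducibility cohort: 25 patients,
    the tablet's 800x1280 portrait canvas, over-dispersed per-view
    cluster counts (mean 4.8, SD 6.0, negative-binomial — the range of
    clinical per-view means/SDs), lognormal disk radii (median 18 px on
    the full-resolution canvas) and a retest perturbation calibrated to
    the moderate-overlap regime seen in clinical test-retest drawings.
    """

    n_patients: int = 25
    outline_dims: tuple[int, int] = (1280, 800)
    clusters_per_view_mean: float = 4.8
    clusters_per_view_sd: float = 6.0
    blob_radius_median: float = 18.0
    blob_radius_sigma: float = 0.5
    vas_level_weights: tuple[float, ...] | None = None  # over levels 1..10; None = uniform
    perturb: PerturbParams = field(default_factory=PerturbParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        rows, cols = self.outline_dims
        if rows < 64 or cols < 64:
            raise ValueError("outline dims must be at least 64x64")
        if self.clusters_per_view_mean < 0 or self.clusters_per_view_sd < 0:
            raise ValueError("cluster-count parameters must be non-negative")
        if self.blob_radius_median <= 0 or self.blob_radius_sigma < 0:
            raise ValueError("blob radius parameters must be positive")
        if self.vas_level_weights is not None and len(self.vas_level_weights) != 10:
            raise ValueError("vas_level_weights must cover levels 1..10")


# ---------------------------------------------------------------------------
# Procedural outlines
# ---------------------------------------------------------------------------


def _silhouette(dims: tuple[int, int], parts: list[tuple[str, tuple[float, ...]]]) -> np.ndarray:
    rows, cols = dims
    u = (np.arange(rows, dtype=float)[:, None] + 0.5) / rows
    v = (np.arange(cols, dtype=float)[None, :] + 0.5) / cols
    mask = np.zeros(dims, dtype=bool)
    for kind, p in parts:
        if kind == "ellipse":
            cu, cv, ru, rv = p
            mask |= ((u - cu) / ru) ** 2 + ((v - cv) / rv) ** 2 <= 1.0
        else:  # rect
            u0, u1, v0, v1 = p
            mask |= (u >= u0) & (u < u1) & (v >= v0) & (v < v1)
    return mask


@lru_cache(maxsize=32)
def generate_outline(view: BodyView, dims: tuple[int, int] = (1280, 800)) -> OutlineMask:
    """Deterministic schematic silhouette (head/torso/limbs) for one view.

    Front and back use a two-arm, two-leg silhouette; the side views a
    narrower profile.  The interior occupies 20-60% of the canvas and
    forms a single connected component.
    """
    view = BodyView(view)
    rows, cols = dims
    if rows < 64 or cols < 64:
        raise ValueError("outline dims must be at least 64x64")
    if view in (BodyView.FRONT, BodyView.BACK):
        parts = [
            ("ellipse", (0.085, 0.5, 0.065, 0.055)),  # head
            ("rect", (0.13, 0.19, 0.46, 0.54)),       # neck
            ("rect", (0.17, 0.56, 0.33, 0.67)),       # torso
            ("rect", (0.18, 0.60, 0.23, 0.345)),      # arms (overlap torso at shoulder)
            ("rect", (0.18, 0.60, 0.655, 0.77)),
            ("rect", (0.55, 0.96, 0.355, 0.49)),      # legs
            ("rect", (0.55, 0.96, 0.51, 0.645)),
        ]
    else:
        off = 0.01 if view is BodyView.LEFT else -0.01
        parts = [
            ("ellipse", (0.085, 0.5 + off, 0.065, 0.05)),
            ("rect", (0.13, 0.19, 0.45 + off, 0.55 + off)),  # neck
            ("rect", (0.17, 0.56, 0.36 + off, 0.66 + off)),  # trunk
            ("rect", (0.55, 0.96, 0.39 + off, 0.61 + off)),  # leg
        ]
    return OutlineMask(view, _silhouette(dims, parts))


def generate_outline_set(dims: tuple[int, int] = (1280, 800)) -> dict[BodyView, OutlineMask]:
    return {v: generate_outline(v, dims) for v in VIEWS}


# ---------------------------------------------------------------------------
# Cluster geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Cluster:
    """Ground-truth cluster: filled disks (row, col, radius) + one VAS level."""

    view: BodyView
    disks: tuple[tuple[float, float, float], ...]
    vas: int
    symptom: int  # index of the symptom this cluster belongs to

    def shifted(self, dr: float, dc: float, drad: float) -> "_Cluster":
        disks = tuple(
            (r + dr, c + dc, max(1.0, rad + drad)) for r, c, rad in self.disks
        )
        return replace(self, disks=disks)


def _paint_disks(canvas: np.ndarray, cluster: _Cluster, outline: OutlineMask) -> None:
    rows, cols = canvas.shape
    for r0, c0, rad in cluster.disks:
        rlo = max(0, int(np.floor(r0 - rad)))
        rhi = min(rows, int(np.ceil(r0 + rad)) + 1)
        clo = max(0, int(np.floor(c0 - rad)))
        chi = min(cols, int(np.ceil(c0 + rad)) + 1)
        if rlo >= rhi or clo >= chi:
            continue
        yy = np.arange(rlo, rhi, dtype=float)[:, None] - r0
        xx = np.arange(clo, chi, dtype=float)[None, :] - c0
        disk = (yy**2 + xx**2 <= rad**2) & outline.grid[rlo:rhi, clo:chi]
        sub = canvas[rlo:rhi, clo:chi]
        np.maximum(sub, np.where(disk, cluster.vas, 0), out=sub)


def _sample_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Over-dispersed count: negative binomial when var > mean, else Poisson."""
    if mean == 0:
        return 0
    var = sd**2
    if var <= mean:
        return int(rng.poisson(mean))
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _sample_vas(rng: np.random.Generator, params: SimParams) -> int:
    if params.vas_level_weights is None:
        return int(rng.integers(1, 11))
    w = np.asarray(params.vas_level_weights, dtype=float)
    return int(rng.choice(np.arange(1, 11), p=w / w.sum()))


def _sample_cluster(
    rng: np.random.Generator,
    params: SimParams,
    outline: OutlineMask,
    interior: np.ndarray,
    symptom: int,
) -> _Cluster:
    """Rejection-place one cluster (1-3 disks) inside the outline."""
    idx = int(rng.integers(interior.shape[0]))
    r0, c0 = float(interior[idx, 0]), float(interior[idx, 1])
    rad = float(rng.lognormal(np.log(params.blob_radius_median), params.blob_radius_sigma))
    rad = max(2.0, rad)
    disks = [(r0, c0, rad)]
    for _ in range(int(rng.integers(0, 3))):  # 0-2 satellite disks
        satrad = max(2.0, rad * float(rng.uniform(0.4, 0.9)))
        for _try in range(20):
            # satellite center within the overlap range so the drawn
            # cluster stays a single connected blob
            ang = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(0.0, 0.9 * (rad + satrad))
            rr = int(round(r0 + dist * np.sin(ang)))
            cc = int(round(c0 + dist * np.cos(ang)))
            if 0 <= rr < outline.grid.shape[0] and 0 <= cc < outline.grid.shape[1] and outline.grid[rr, cc]:
                disks.append((float(rr), float(cc), satrad))
                break
    return _Cluster(outline.view, tuple(disks), _sample_vas(rng, params), symptom)


# ---------------------------------------------------------------------------
# Pair and cohort generation
# ---------------------------------------------------------------------------


def _rasterize(
    clusters: list[_Cluster],
    specs: list[SymptomSpec],
    outlines: dict[BodyView, OutlineMask],
    patient_id: str,
    session: str,
) -> Drawing:
    dims = next(iter(outlines.values())).dims
    symptoms: list[tuple[SymptomSpec, dict[BodyView, SymptomMap]]] = []
    for si, spec in enumerate(specs):
        maps: dict[BodyView, SymptomMap] = {}
        for view in VIEWS:
            mine = [c for c in clusters if c.symptom == si and c.view == view]
            if not mine:
                continue
            canvas = np.zeros(dims, dtype=np.int16)
            for c in mine:
                _paint_disks(canvas, c, outlines[view])
            maps[view] = SymptomMap(view, canvas)
        symptoms.append((spec, maps))
    return Drawing(patient_id=patient_id, session=session, outlines=outlines, symptoms=symptoms)


def _sample_spec(rng: np.random.Generator, vocab: tuple[str, ...], vas_levels: list[int]) -> SymptomSpec:
    n_desc = int(rng.integers(1, 4))
    descriptors = tuple(rng.choice(vocab, size=n_desc, replace=False))
    n_depth = int(rng.integers(1, 3))
    depths = tuple(rng.choice(DEPTH_CATEGORIES, size=n_depth, replace=False))
    vmax = max(vas_levels) if vas_levels else int(rng.integers(1, 11))
    return SymptomSpec(
        descriptors=descriptors,
        depths=depths,
        vas_max=vmax,
        vas_min=int(rng.integers(0, vmax + 1)),
        currently_present=bool(rng.random() < 0.7),
        worst_interval=str(rng.choice(DAY_INTERVALS)),
        burden=int(rng.integers(0, 11)),
    )


@dataclass(frozen=True)
class PairTruth:
    """Ground-truth bookkeeping of one generated pair: drawn-cluster
    counts per view (connected components can only be fewer, when
    clusters merge by overlap)."""

    clusters_test: dict[BodyView, int]
    clusters_retest: dict[BodyView, int]


def generate_pair(
    params: SimParams,
    patient_id: str,
    rng: np.random.Generator | int,
    return_truth: bool = False,
):
    """One synthetic test-retest pair, fully reproducible given the rng state.

    The test drawing is sampled from the cluster model; the retest
    re-rasterizes the same ground-truth clusters after applying the
    perturbation model (dropout, translation, grow/shrink, additions),
    clipped to the outline so both drawings validate.  With
    ``return_truth`` the drawn-cluster counts are returned as a third
    element.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    outlines = generate_outline_set(params.outline_dims)
    interiors = {v: np.argwhere(outlines[v].grid) for v in VIEWS}
    vocab = sensation_descriptors()
    pp = params.perturb

    n_symptoms = int(rng.integers(1, 4))
    clusters: list[_Cluster] = []
    for view in VIEWS:
        n = _sample_count(rng, params.clusters_per_view_mean, params.clusters_per_view_sd)
        for _ in range(n):
            clusters.append(
                _sample_cluster(rng, params, outlines[view], interiors[view], int(rng.integers(n_symptoms)))
            )

    specs = [
        _sample_spec(rng, vocab, [c.vas for c in clusters if c.symptom == si])
        for si in range(n_symptoms)
    ]
    test = _rasterize(clusters, specs, outlines, patient_id, "test")

    retest_clusters: list[_Cluster] = []
    for c in clusters:
        if rng.random() < pp.cluster_dropout_p:
            continue
        dr, dc = rng.normal(0.0, pp.translation_sigma, size=2)
        drad = rng.normal(0.0, pp.boundary_noise_sigma)
        retest_clusters.append(c.shifted(float(dr), float(dc), float(drad)))
    for view in VIEWS:
        n_view = sum(1 for c in clusters if c.view == view)
        n_new = int(rng.binomial(n_view, pp.cluster_addition_p)) if n_view else 0
        for _ in range(n_new):
            retest_clusters.append(
                _sample_cluster(rng, params, outlines[view], interiors[view], int(rng.integers(n_symptoms)))
            )
    retest = _rasterize(retest_clusters, specs, outlines, patient_id, "retest")
    if return_truth:
        truth = PairTruth(
            clusters_test={v: sum(1 for c in clusters if c.view == v) for v in VIEWS},
            clusters_retest={v: sum(1 for c in retest_clusters if c.view == v) for v in VIEWS},
        )
        return test, retest, truth
    return test, retest


def generate_cohort(params: SimParams) -> list[tuple[Drawing, Drawing]]:
    """``n_patients`` independent pairs; patient ``i`` uses the substream
    ``SeedSequence(seed, spawn_key=(i,))`` of the master seed."""
    pairs = []
    for i in range(params.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(i,)))
        pairs.append(generate_pair(params, f"P{i + 1:03d}", rng))
    return pairs
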