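"""Domain types for body-map symptom drawings.

A *drawing* is one acquisition session on a tablet: a patient (or doctor)
shades symptomatic regions on four views of a body outline (front, back,
left, right) and attaches a textual specification to each symptom
(sensation descriptors, perceived depth, VAS intensity ratings).  Pixel
intensities encode a 0-10 visual analog scale (VAS); ink is only valid
inside the interior of the body outline.

Validation is report-based: domain objects can be constructed from
imperfect external data and :func:`validate_drawing` enumerates every
rule violation instead of raising on the first one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BodyView",
    "VIEWS",
    "DEFAULT_CANVAS",
    "VAS_MIN",
    "VAS_MAX",
    "DEPTH_CATEGORIES",
    "DAY_INTERVALS",
    "SESSIONS",
    "OutlineMask",
    "SymptomSpec",
    "FindingSpec",
    "SymptomMap",
    "Drawing",
    "Violation",
    "sensation_descriptors",
    "finding_vocabulary",
    "validate_outline_set",
    "make_blank_drawing",
    "validate_drawing",
]


class BodyView(str, Enum):
    """One of the four views of the body outline."""

    FRONT = "front"
    BACK = "back"
    LEFT = "left"
    RIGHT = "right"


VIEWS: tuple[BodyView, ...] = tuple(BodyView)

#: Default per-view canvas in (rows, cols); the acquisition tablet's
#: 800x1280 screen used in portrait orientation.
DEFAULT_CANVAS: tuple[int, int] = (1280, 800)

VAS_MIN, VAS_MAX = 0, 10

#: Perceived symptom depth categories (multi-select).
DEPTH_CATEGORIES: tuple[str, ...] = (
    "on_skin",
    "beneath_skin",
    "muscle",
    "organ",
    "bone",
)

#: Six-hour intervals of the day in which a symptom can be worst.
DAY_INTERVALS: tuple[str, ...] = ("night", "morning", "afternoon", "evening")

SESSIONS: tuple[str, ...] = ("test", "retest")

OUTLINE_GENDERS: tuple[str, ...] = ("female", "male", "not_specified")


def _load_data(name: str):
    with resources.files("bodymap.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def sensation_descriptors() -> tuple[str, ...]:
    """Vocabulary of sensation descriptors offered to patients."""
    return tuple(_load_data("sensation_descriptors.json"))


def finding_vocabulary() -> dict[str, tuple[str, ...]]:
    """Per-category vocabulary of diagnostic findings offered to doctors."""
    return {k: tuple(v) for k, v in _load_data("finding_vocabulary.json").items()}


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlineMask:
    """Binary raster marking the interior of a body outline for one view.

    Drawings are only defined on interior (``True``) pixels.
    """

    view: BodyView
    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError("outline grid must be a 2-D raster")
        if not grid.any():
            raise ValueError("outline must contain at least one interior pixel")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "view", BodyView(self.view))

    @property
    def dims(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def interior_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class SymptomMap:
    """Per-view raster of VAS intensities (0-10) for one symptom."""

    view: BodyView
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ValueError("symptom map must be a 2-D raster")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("symptom map intensities must be integer VAS levels")
            arr = np.round(arr).astype(np.int16)
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "view", BodyView(self.view))

    @property
    def dims(self) -> tuple[int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def is_blank(self) -> bool:
        return not (self.intensities > 0).any()


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


def round_vas(value: float) -> int:
    """Round a sub-unit VAS slider value to an integer level, half-up."""
    return int(np.floor(value + 0.5))


@dataclass(frozen=True)
class SymptomSpec:
    """Textual specification a patient attaches to one symptom."""

    descriptors: tuple[str, ...]
    depths: tuple[str, ...]
    vas_max: int
    vas_min: int = 0
    currently_present: bool = True
    worst_interval: str = "morning"
    burden: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        object.__setattr__(self, "depths", tuple(self.depths))


@dataclass(frozen=True)
class FindingSpec:
    """Diagnostic finding entered by a doctor: a category, terms from the
    category's vocabulary (free text allowed but flagged), depths, and a
    single VAS rating."""

    category: str
    terms: tuple[str, ...]
    depths: tuple[str, ...]
    vas: int
    free_text: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "depths", tuple(self.depths))
        object.__setattr__(self, "free_text", tuple(self.free_text))


# ---------------------------------------------------------------------------
# Drawings
# ---------------------------------------------------------------------------


def validate_outline_set(outlines: Mapping[BodyView, OutlineMask]) -> dict[BodyView, OutlineMask]:
    """Check an outline set covers all four views with equal dims; raise otherwise."""
    out = {BodyView(v): m for v, m in outlines.items()}
    missing = [v.value for v in VIEWS if v not in out]
    if missing:
        raise ValueError(f"outline set is missing views: {', '.join(missing)}")
    dims = {m.dims for m in out.values()}
    if len(dims) != 1:
        raise ValueError(f"outline views have mismatched dims: {sorted(dims)}")
    return out


@dataclass
class Drawing:
    """One acquisition session: all symptoms drawn by one patient.

    ``symptoms`` pairs each :class:`SymptomSpec` with its per-view maps; a
    view absent from a symptom's map dict is blank for that symptom.
    """

    patient_id: str
    session: str
    outlines: Mapping[BodyView, OutlineMask]
    symptoms: list[tuple[SymptomSpec, dict[BodyView, SymptomMap]]] = field(default_factory=list)
    outline_gender: str = "not_specified"

    @property
    def dims(self) -> tuple[int, int]:
        return next(iter(self.outlines.values())).dims

    def maps_for_view(self, view: BodyView) -> list[SymptomMap]:
        view = BodyView(view)
        return [maps[view] for _, maps in self.symptoms if view in maps]

    def view_is_blank(self, view: BodyView) -> bool:
        return all(m.is_blank() for m in self.maps_for_view(view)) if self.maps_for_view(view) else True


def make_blank_drawing(
    outlines: Mapping[BodyView, OutlineMask],
    patient_id: str,
    session: str,
    outline_gender: str = "not_specified",
) -> Drawing:
    """A drawing with zero symptoms on a validated outline set."""
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}, got {session!r}")
    return Drawing(
        patient_id=patient_id,
        session=session,
        outlines=validate_outline_set(outlines),
        symptoms=[],
        outline_gender=outline_gender,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def _check_spec(i: int, spec: SymptomSpec, out: list[Violation]) -> None:
    if not spec.descriptors:
        out.append(Violation("empty_descriptors", f"symptom {i}: descriptor list is empty"))
    if not spec.depths:
        out.append(Violation("empty_depths", f"symptom {i}: depth list is empty"))
    bad_depths = [d for d in spec.depths if d not in DEPTH_CATEGORIES]
    if bad_depths:
        out.append(Violation("unknown_depth", f"symptom {i}: unknown depth categories {bad_depths}"))
    if not (VAS_MIN <= spec.vas_min <= spec.vas_max <= VAS_MAX):
        out.append(
            Violation(
                "vas_order",
                f"symptom {i}: need 0 <= vas_min <= vas_max <= 10, "
                f"got vas_min={spec.vas_min}, vas_max={spec.vas_max}",
            )
        )
    if not (VAS_MIN <= spec.burden <= VAS_MAX):
        out.append(Violation("burden_range", f"symptom {i}: burden {spec.burden} outside 0-10"))
    if spec.worst_interval not in DAY_INTERVALS:
        out.append(
            Violation("bad_interval", f"symptom {i}: worst_interval {spec.worst_interval!r} unknown")
        )


def validate_drawing(d: Drawing) -> list[Violation]:
    """Enumerate every rule violation in a drawing; empty list means valid.

    Checked rules: complete and consistent outline set, valid session
    label, per-symptom specification ranges, intensity levels in 0-10,
    and no ink outside the outline interior (the app restricted drawing
    to within the outline borders, but files from other sources may not).
    """
    violations: list[Violation] = []
    try:
        outlines = validate_outline_set(d.outlines)
    except ValueError as exc:
        return [Violation("outline_set", str(exc))]
    dims = next(iter(outlines.values())).dims
    if d.session not in SESSIONS:
        violations.append(Violation("bad_session", f"session {d.session!r} not in {SESSIONS}"))
    for i, (spec, maps) in enumerate(d.symptoms):
        _check_spec(i, spec, violations)
        for view, smap in maps.items():
            view = BodyView(view)
            if smap.view != view:
                violations.append(
                    Violation("view_mismatch", f"symptom {i}: map keyed {view.value} has view {smap.view.value}")
                )
            if smap.dims != dims:
                violations.append(
                    Violation("dim_mismatch", f"symptom {i}/{view.value}: map dims {smap.dims} != outline {dims}")
                )
                continue
            arr = smap.intensities
            if (arr < VAS_MIN).any() or (arr > VAS_MAX).any():
                violations.append(
                    Violation("vas_range", f"symptom {i}/{view.value}: intensities outside 0-10")
                )
            outside = (arr > 0) & ~outlines[view].grid
            if outside.any():
                violations.append(
                    Violation(
                        "outside_outline",
                        f"symptom {i}/{view.value}: {int(outside.sum())} nonzero pixel(s) outside the outline",
                    )
                )
    return violations


def validate_finding(f: FindingSpec) -> list[Violation]:
    """Check a finding's terms against the per-category vocabulary."""
    vocab = finding_vocabulary()
    violations: list[Violation] = []
    if f.category not in vocab:
        return [Violation("unknown_category", f"unknown finding category {f.category!r}")]
    allowed = set(vocab[f.category])
    bad = [t for t in f.terms if t not in allowed and t not in f.free_text]
    if bad:
        violations.append(
            Violation("unknown_terms", f"terms {bad} not in category {f.category!r} and not flagged free-text")
        )
    if not (VAS_MIN <= f.vas <= VAS_MAX):
        violations.append(Violation("vas_range", f"finding VAS {f.vas} outside 0-10"))
    return violations
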