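"""Pixel-level operations on symptom maps prior to metric extraction.

When a patient draws several symptoms they are merged for the
reproducibility analysis by taking the maximum VAS value at each pixel.
Overlap and cluster metrics then operate on the binarized merged map
(any nonzero ink counts by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import BodyView, OutlineMask, SymptomMap, VAS_MAX

__all__ = ["MergedMap", "merge_symptom_maps", "binarize", "restrict_to_outline"]


@dataclass(frozen=True)
class MergedMap:
    """Pixelwise-max merge of the symptom maps of one view; ``n_sources``
    counts the contributing symptoms."""

    view: BodyView
    intensities: np.ndarray
    n_sources: int

    @property
    def dims(self) -> tuple[int, int]:
        return self.intensities.shape  # type: ignore[return-value]


def merge_symptom_maps(
    maps: list[SymptomMap], view: BodyView, dims: tuple[int, int] | None = None
) -> MergedMap:
    """Merge symptom maps of one view by the per-pixel maximum VAS.

    An empty list yields an all-zero map; ``dims`` is then required to
    size the blank canvas.
    """
    view = BodyView(view)
    if not maps:
        if dims is None:
            raise ValueError("dims required to merge an empty map list")
        return MergedMap(view, np.zeros(dims, dtype=np.int16), 0)
    for m in maps:
        if m.view != view:
            raise ValueError(f"map for view {m.view.value} passed to merge of {view.value}")
        if m.dims != maps[0].dims:
            raise ValueError(f"mixed dims in merge: {m.dims} vs {maps[0].dims}")
    merged = np.maximum.reduce([m.intensities for m in maps]).astype(np.int16)
    return MergedMap(view, merged, len(maps))


def _intensities(map_like) -> np.ndarray:
    if isinstance(map_like, (SymptomMap, MergedMap)):
        return map_like.intensities
    return np.asarray(map_like)


def binarize(map_like, threshold: int = 0) -> np.ndarray:
    """Presence mask: pixel True iff intensity > threshold (default: any ink)."""
    if not (0 <= threshold <= VAS_MAX):
        raise ValueError("threshold must be in [0, 10]")
    return _intensities(map_like) > threshold


def restrict_to_outline(map_like, outline: OutlineMask):
    """Zero out all intensity outside the outline interior."""
    arr = _intensities(map_like)
    if arr.shape != outline.grid.shape:
        raise ValueError(f"map dims {arr.shape} do not match outline dims {outline.grid.shape}")
    restricted = np.where(outline.grid, arr, 0)
    if isinstance(map_like, SymptomMap):
        return SymptomMap(map_like.view, restricted)
    if isinstance(map_like, MergedMap):
        return MergedMap(map_like.view, restricted.astype(np.int16), map_like.n_sources)
    return restricted
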