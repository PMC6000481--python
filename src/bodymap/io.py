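"""File formats: PNG drawing sets, CSV/JSON symptom specs, NIfTI export.

Drawings are stored as one directory per session::

    <dir>/manifest.json          patient_id, session, outline_gender, dims
    <dir>/outlines/<view>.png    binary outline interior (255 = interior)
    <dir>/symptoms.json          list of symptom specifications
    <dir>/symptoms.csv           same, one row per symptom
    <dir>/symptom_00/<view>.png  per-view VAS raster of each symptom

PNG encoding is single-channel 8-bit with level = round(255 * VAS / 10);
decoding inverts by nearest VAS level, so the round trip is lossless.
App-exported color drawings that encode intensity as color saturation
can be ingested with :func:`decode_saturation_image` (configurable
transfer curve).  NIfTI export wraps a raster as a single-slice volume
with an identity affine — a carrier format for neuroimaging cluster
tools, not a spatial claim.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from PIL import Image

from .body_model import (
    BodyView,
    Drawing,
    OutlineMask,
    SymptomMap,
    SymptomSpec,
    VIEWS,
    validate_outline_set,
)
from .drawing_ops import MergedMap

__all__ = [
    "DrawingFileSet",
    "vas_to_level",
    "level_to_vas",
    "write_drawing",
    "read_drawing",
    "write_cohort",
    "read_cohort",
    "export_nifti",
    "decode_saturation_image",
]

_LIST_SEP = ";"


def vas_to_level(vas: np.ndarray | int) -> np.ndarray | int:
    """VAS 0-10 -> 8-bit PNG level (0, 26, 51, ... 255)."""
    return np.round(np.asarray(vas) * 255.0 / 10.0).astype(np.uint8)


def level_to_vas(level: np.ndarray | int) -> np.ndarray | int:
    """8-bit PNG level -> nearest VAS 0-10 (inverse of :func:`vas_to_level`)."""
    return np.round(np.asarray(level) * 10.0 / 255.0).astype(np.int16)


@dataclass(frozen=True)
class DrawingFileSet:
    """Paths of one serialized drawing session."""

    root: Path
    manifest: Path
    outline_pngs: dict[BodyView, Path]
    symptom_pngs: list[dict[BodyView, Path]]
    spec_json: Path
    spec_csv: Path


def _spec_to_dict(s: SymptomSpec) -> dict:
    return {
        "descriptors": list(s.descriptors),
        "depths": list(s.depths),
        "vas_max": s.vas_max,
        "vas_min": s.vas_min,
        "currently_present": s.currently_present,
        "worst_interval": s.worst_interval,
        "burden": s.burden,
    }


def _spec_from_dict(d: Mapping) -> SymptomSpec:
    return SymptomSpec(
        descriptors=tuple(d["descriptors"]),
        depths=tuple(d["depths"]),
        vas_max=int(d["vas_max"]),
        vas_min=int(d["vas_min"]),
        currently_present=bool(d["currently_present"]),
        worst_interval=str(d["worst_interval"]),
        burden=int(d["burden"]),
    )


def write_drawing(d: Drawing, directory) -> DrawingFileSet:
    """Serialize a drawing to PNG rasters plus JSON/CSV specs."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    outlines = validate_outline_set(d.outlines)
    rows, cols = d.dims

    out_dir = root / "outlines"
    out_dir.mkdir(exist_ok=True)
    outline_pngs = {}
    for v in VIEWS:
        p = out_dir / f"{v.value}.png"
        Image.fromarray(np.where(outlines[v].grid, 255, 0).astype(np.uint8), mode="L").save(p)
        outline_pngs[v] = p

    symptom_pngs: list[dict[BodyView, Path]] = []
    specs = []
    for i, (spec, maps) in enumerate(d.symptoms):
        sdir = root / f"symptom_{i:02d}"
        sdir.mkdir(exist_ok=True)
        paths = {}
        for v, smap in maps.items():
            v = BodyView(v)
            p = sdir / f"{v.value}.png"
            Image.fromarray(vas_to_level(smap.intensities), mode="L").save(p)
            paths[v] = p
        symptom_pngs.append(paths)
        specs.append(_spec_to_dict(spec))

    spec_json = root / "symptoms.json"
    spec_json.write_text(json.dumps(specs, indent=1), encoding="utf-8")
    spec_csv = root / "symptoms.csv"
    with spec_csv.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["symptom", "descriptors", "depths", "vas_max", "vas_min",
                    "currently_present", "worst_interval", "burden"])
        for i, s in enumerate(specs):
            w.writerow([
                i, _LIST_SEP.join(s["descriptors"]), _LIST_SEP.join(s["depths"]),
                s["vas_max"], s["vas_min"], s["currently_present"],
                s["worst_interval"], s["burden"],
            ])

    manifest = root / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "patient_id": d.patient_id,
                "session": d.session,
                "outline_gender": d.outline_gender,
                "dims": [rows, cols],
                "n_symptoms": len(d.symptoms),
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    return DrawingFileSet(root, manifest, outline_pngs, symptom_pngs, spec_json, spec_csv)


def _read_png(path: Path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def read_drawing(source) -> Drawing:
    """Read a drawing from a directory (or :class:`DrawingFileSet`);
    inverse of :func:`write_drawing`."""
    root = source.root if isinstance(source, DrawingFileSet) else Path(source)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    dims = tuple(manifest["dims"])

    outlines = {}
    for v in VIEWS:
        p = root / "outlines" / f"{v.value}.png"
        if not p.exists():
            raise FileNotFoundError(f"missing outline PNG: {p}")
        grid = _read_png(p) > 127
        if grid.shape != dims:
            raise ValueError(f"outline {p} dims {grid.shape} do not match manifest {dims}")
        outlines[v] = OutlineMask(v, grid)

    specs = [_spec_from_dict(s) for s in json.loads((root / "symptoms.json").read_text(encoding="utf-8"))]
    symptoms = []
    for i, spec in enumerate(specs):
        maps: dict[BodyView, SymptomMap] = {}
        sdir = root / f"symptom_{i:02d}"
        for v in VIEWS:
            p = sdir / f"{v.value}.png"
            if p.exists():
                arr = level_to_vas(_read_png(p))
                if arr.shape != dims:
                    raise ValueError(f"symptom PNG {p} dims {arr.shape} do not match manifest {dims}")
                maps[v] = SymptomMap(v, arr)
        symptoms.append((spec, maps))
    return Drawing(
        patient_id=manifest["patient_id"],
        session=manifest["session"],
        outlines=outlines,
        symptoms=symptoms,
        outline_gender=manifest.get("outline_gender", "not_specified"),
    )


def write_cohort(pairs, directory) -> Path:
    """Serialize test-retest pairs to <dir>/<patient>/<session>/..."""
    root = Path(directory)
    for test, retest in pairs:
        write_drawing(test, root / test.patient_id / "test")
        write_drawing(retest, root / retest.patient_id / "retest")
    return root


def read_cohort(directory) -> list[tuple[Drawing, Drawing]]:
    root = Path(directory)
    patients = sorted(p for p in root.iterdir() if (p / "test" / "manifest.json").exists()) if root.is_dir() else []
    if not patients:
        raise FileNotFoundError(f"no cohort found under {root}")
    return [(read_drawing(p / "test"), read_drawing(p / "retest")) for p in patients]


def export_nifti(map_like, path) -> Path:
    """Write a raster (symptom map, merged map, or mask) as a single-slice
    NIfTI volume; nonzero voxel count equals the symptom extent."""
    import nibabel as nib

    if isinstance(map_like, (SymptomMap, MergedMap)):
        arr = map_like.intensities
    elif isinstance(map_like, OutlineMask):
        arr = map_like.grid.astype(np.int16)
    else:
        arr = np.asarray(map_like)
    vol = np.asarray(arr, dtype=np.int16)[:, :, None]
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_nifti_raster(path) -> np.ndarray:
    """Read back a single-slice volume written by :func:`export_nifti`."""
    import nibabel as nib

    vol = np.asarray(nib.load(str(path)).get_fdata())
    return vol[:, :, 0].astype(np.int16)


def decode_saturation_image(
    source, curve: Callable[[np.ndarray], np.ndarray] | None = None
) -> np.ndarray:
    """Decode an RGB drawing whose intensity is color saturation into a
    VAS raster.  ``curve`` maps HSV saturation in [0, 1] to VAS units
    in [0, 10]; the default is linear (VAS = 10 * S, rounded)."""
    if isinstance(source, (str, Path)):
        with Image.open(source) as img:
            rgb = np.asarray(img.convert("RGB"), dtype=float) / 255.0
    else:
        rgb = np.asarray(source, dtype=float)
        if rgb.max() > 1.0:
            rgb = rgb / 255.0
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    vas = curve(sat) if curve is not None else 10.0 * sat
    return np.clip(np.round(vas), 0, 10).astype(np.int16)
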