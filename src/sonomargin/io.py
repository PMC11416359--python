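"""Readers and writers for volumes, slide stacks, landmarks and tables.

File formats
------------
* Label volumes: NRRD (built-in minimal codec) or NIfTI (via nibabel).
* Slide masks: single-channel 8-bit TIFF or PNG, one file per slide,
  listed by a JSON sidecar that carries pixel spacing, slice thickness,
  orientation and the per-slide mucosal-edge landmarks (mm).
* Per-elevation mucosal landmarks for the US volume: JSON mapping
  elevation index -> [[x, y], [x, y]] in mm.
* Measurement tables: long-format CSV with columns
  ``specimen,modality,slide,measure,value_mm`` (slide empty for the
  anterior/posterior end margins).

Sidecar schema (``stack.json``)::

    {
      "pixel_spacing": [px, py],
      "slice_thickness": 4.0,
      "orientation": "cranial_right",        # or [cx, cy]
      "slides": [
        {"file": "slide_000.png", "index": 0,
         "mucosal_edges": [[x1, y1], [x2, y2]]},   # mm; null if absent
        ...
      ]
    }
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nrrd
from .model import (
    END_MEASURES,
    PER_SLICE_MEASURES,
    LabelVolume,
    MeasurementRecord,
    Slide,
    SliceMeasurements,
    SlideStack,
)

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "read_slide_stack",
    "write_slide_stack",
    "read_landmarks",
    "write_landmarks",
    "records_to_frame",
    "frame_to_records",
    "read_measurements",
    "write_measurements",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_label_volume(path) -> LabelVolume:
    """Read a segmented label volume from NRRD or NIfTI.

    Spacing is taken from the file header; a missing or degenerate
    spacing raises rather than silently assuming isotropy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            if np.allclose(data, np.round(data)):
                data = np.round(data).astype(np.int16)
            else:
                raise ValueError(f"{path}: label volume has non-integer data")
        zooms = img.header.get_zooms()[:3]
        if any(not np.isfinite(z) or z <= 0 for z in zooms):
            raise ValueError(f"{path}: missing or invalid spacing {zooms}")
        origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
        return LabelVolume(voxels=data, spacing=tuple(float(z) for z in zooms),
                           origin=origin)
    if path.suffix.lower() == ".nrrd":
        data, header = _nrrd.read(path)
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"{path}: label volume has non-integer data")
        if "spacing" not in header:
            raise ValueError(f"{path}: NRRD header carries no spacing information")
        spacing = header["spacing"]
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"{path}: invalid spacing {spacing}")
        origin = tuple(header.get("origin", (0.0, 0.0, 0.0)))
        return LabelVolume(voxels=data, spacing=tuple(spacing), origin=origin)
    raise ValueError(f"{path}: unsupported volume format (expect .nrrd or .nii[.gz])")


def write_label_volume(path, volume: LabelVolume) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.voxels.astype(np.int16), affine), str(path))
        return
    if path.suffix.lower() == ".nrrd":
        _nrrd.write(path, volume.voxels.astype(np.uint8), volume.spacing,
                    volume.origin)
        return
    raise ValueError(f"{path}: unsupported volume format (expect .nrrd or .nii[.gz])")


# ---------------------------------------------------------------------------
# slide stacks


def _read_mask(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(str(path)))
    if suffix == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(str(path)))
    raise ValueError(f"{path}: unsupported slide format (expect TIFF or PNG)")


def _write_mask(path: Path, mask: np.ndarray) -> None:
    mask8 = np.ascontiguousarray(mask.astype(np.uint8))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), mask8)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(str(path), mask8)
    else:
        raise ValueError(f"{path}: unsupported slide format (expect TIFF or PNG)")


def read_slide_stack(directory, sidecar=None) -> SlideStack:
    """Read an ordered slide stack from ``directory``.

    ``sidecar`` defaults to ``<directory>/stack.json``. Slide order, the
    physical metadata and the mucosal-edge landmarks all come from the
    sidecar; mask files only carry pixels.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such slide directory: {directory}")
    sidecar = Path(sidecar) if sidecar is not None else directory / "stack.json"
    if not sidecar.exists():
        raise FileNotFoundError(
            f"no slides: missing sidecar JSON {sidecar} (empty or non-stack "
            "directory?)"
        )
    meta = json.loads(sidecar.read_text())

    for key in ("pixel_spacing", "slice_thickness", "orientation", "slides"):
        if key not in meta:
            raise ValueError(f"{sidecar}: sidecar missing required key {key!r}")
    entries = meta["slides"]
    if not entries:
        raise ValueError(f"{sidecar}: no slides listed")
    indices = [e["index"] for e in entries]
    if sorted(indices) != list(range(min(indices), min(indices) + len(indices))):
        raise ValueError(f"{sidecar}: slide indices have gaps or duplicates: {indices}")

    px, py = (float(v) for v in meta["pixel_spacing"])
    slides = []
    for entry in sorted(entries, key=lambda e: e["index"]):
        mask = _read_mask(directory / entry["file"])
        edges = entry.get("mucosal_edges")
        if edges is not None:
            edges = np.asarray(edges, dtype=float)
            h, w = mask.shape
            bounds = np.array([(w - 1) * px, (h - 1) * py])
            if (edges < -max(px, py)).any() or (edges > bounds + max(px, py)).any():
                raise ValueError(
                    f"slide {entry['index']}: mucosal edge landmark outside "
                    f"image bounds {bounds} mm: {edges.tolist()}"
                )
        slides.append(Slide(mask=mask, index=int(entry["index"]),
                            mucosal_edges=edges))
    stack = SlideStack(
        slides=slides,
        pixel_spacing=(px, py),
        slice_thickness=float(meta["slice_thickness"]),
        orientation=meta["orientation"],
    )
    missing = [s.index for s in stack if s.has_tumor() and s.mucosal_edges is None]
    if missing:
        raise ValueError(
            f"tumor-bearing slides without mucosal-edge landmarks: {missing}"
        )
    return stack


def write_slide_stack(directory, stack: SlideStack, fmt: str = "tif") -> Path:
    """Write masks + sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for slide in stack:
        fname = f"slide_{slide.index:03d}.{fmt}"
        _write_mask(directory / fname, slide.mask)
        entries.append(
            {
                "file": fname,
                "index": slide.index,
                "mucosal_edges": None
                if slide.mucosal_edges is None
                else np.asarray(slide.mucosal_edges, dtype=float).tolist(),
            }
        )
    orientation = stack.orientation
    if isinstance(orientation, np.ndarray):
        orientation = orientation.tolist()
    sidecar = directory / "stack.json"
    sidecar.write_text(
        json.dumps(
            {
                "pixel_spacing": list(stack.pixel_spacing),
                "slice_thickness": stack.slice_thickness,
                "orientation": orientation,
                "slides": entries,
            },
            indent=2,
        )
    )
    return sidecar


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path) -> dict[int, np.ndarray]:
    """Read per-elevation mucosal-edge landmarks (mm) from JSON."""
    data = json.loads(Path(path).read_text())
    out = {}
    for key, value in data.items():
        pts = np.asarray(value, dtype=float)
        if pts.shape != (2, 2):
            raise ValueError(f"landmark entry {key!r} must be two 2D points")
        out[int(key)] = pts
    return out


def write_landmarks(path, landmarks: dict[int, np.ndarray]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {str(k): np.asarray(v, dtype=float).tolist()
             for k, v in sorted(landmarks.items())},
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# measurement tables


def records_to_frame(records) -> pd.DataFrame:
    """Flatten MeasurementRecords into the long-format table."""
    if isinstance(records, MeasurementRecord):
        records = [records]
    rows = []
    for rec in records:
        for entry in rec.slices:
            for measure in PER_SLICE_MEASURES:
                value = getattr(entry, measure)
                if value is not None:
                    rows.append((rec.specimen, rec.modality, entry.slide,
                                 measure, float(value)))
        for measure in END_MEASURES:
            value = getattr(rec, measure)
            if value is not None:
                rows.append((rec.specimen, rec.modality, pd.NA, measure,
                             float(value)))
    return pd.DataFrame(
        rows, columns=["specimen", "modality", "slide", "measure", "value_mm"]
    )


def frame_to_records(frame: pd.DataFrame) -> list[MeasurementRecord]:
    records = []
    for (specimen, modality), group in frame.groupby(
        ["specimen", "modality"], sort=True
    ):
        rec = MeasurementRecord(specimen=str(specimen), modality=str(modality))
        per_slice = group[group["measure"].isin(PER_SLICE_MEASURES)]
        for slide, sgroup in per_slice.groupby("slide", sort=True):
            entry = SliceMeasurements(slide=int(slide))
            for _, row in sgroup.iterrows():
                setattr(entry, str(row["measure"]), float(row["value_mm"]))
            rec.slices.append(entry)
        for _, row in group[group["measure"].isin(END_MEASURES)].iterrows():
            setattr(rec, str(row["measure"]), float(row["value_mm"]))
        records.append(rec)
    return records


def write_measurements(path, records) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)


def read_measurements(path) -> list[MeasurementRecord]:
    frame = pd.read_csv(path)
    expected = ["specimen", "modality", "slide", "measure", "value_mm"]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return frame_to_records(frame)
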