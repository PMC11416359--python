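"""Core domain types for specimen margin assessment.

Coordinate conventions
----------------------
* Volumes are indexed ``voxels[i, j, k]`` with axes (x, y, z):
  x = in-plane lateral, y = in-plane depth, z = elevation
  (anterior -> posterior; the motorized sweep / sectioning axis).
* 2D slide masks are indexed ``mask[row, col]`` with row = y, col = x.
* All indices are 0-based; a voxel/pixel index ``i`` sits at world
  position ``origin + i * spacing`` (voxel centers).
* Every distance in the public API is physical (mm), never pixels.

Labels
------
0 = background, 1 = specimen tissue, 2 = tumor, 3 = fiducial channel
(volume) / fiducial hole (slide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_TISSUE",
    "LABEL_TUMOR",
    "LABEL_FIDUCIAL",
    "VALID_LABELS",
    "PER_SLICE_MEASURES",
    "END_MEASURES",
    "ALL_MEASURES",
    "LabelVolume",
    "Slide",
    "SlideStack",
    "SliceMeasurements",
    "MeasurementRecord",
    "MarginStatus",
    "classify_margin",
    "resolve_cranial_direction",
]

LABEL_BACKGROUND = 0
LABEL_TISSUE = 1
LABEL_TUMOR = 2
LABEL_FIDUCIAL = 3
VALID_LABELS = frozenset({0, 1, 2, 3})

#: per-slice measures: tumor thickness and the three region margins
PER_SLICE_MEASURES = ("TT", "cranial", "deep", "caudal")
#: per-specimen end-cap measures along the sectioning axis
END_MEASURES = ("anterior", "posterior")
ALL_MEASURES = PER_SLICE_MEASURES + END_MEASURES

#: named presets mapping an orientation tag to the cranial direction
#: expressed in image coordinates (x to the right, y downward, mm space)
_ORIENTATION_PRESETS = {
    "cranial_right": (1.0, 0.0),
    "cranial_left": (-1.0, 0.0),
}


def resolve_cranial_direction(orientation) -> np.ndarray:
    """Return the unit cranial direction for an orientation tag.

    ``orientation`` is either a preset name (``"cranial_right"`` /
    ``"cranial_left"``) or an explicit 2-vector in image (x, y) mm space.
    """
    if isinstance(orientation, str):
        try:
            vec = _ORIENTATION_PRESETS[orientation]
        except KeyError:
            raise ValueError(
                f"unknown orientation tag {orientation!r}; expected one of "
                f"{sorted(_ORIENTATION_PRESETS)} or an explicit (x, y) vector"
            ) from None
    else:
        vec = tuple(float(v) for v in orientation)
        if len(vec) != 2:
            raise ValueError("orientation vector must have length 2")
    arr = np.asarray(vec, dtype=float)
    norm = float(np.linalg.norm(arr))
    if norm == 0.0:
        raise ValueError("orientation vector must be non-zero")
    return arr / norm


def _validate_labels(arr: np.ndarray, what: str) -> None:
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{what} must have an integer dtype, got {arr.dtype}")
    present = set(np.unique(arr).tolist())
    bad = sorted(present - VALID_LABELS)
    if bad:
        raise ValueError(f"{what} contains invalid labels {bad}; allowed: 0,1,2,3")


@dataclass
class LabelVolume:
    """A segmented 3D label volume with physical spacing.

    Parameters
    ----------
    voxels:
        3D integer array indexed (x, y, z).
    spacing:
        (dx, dy, dz) voxel pitch in mm. dz defaults to the 0.5 mm
        elevation spacing of the reconstructed US sweep.
    origin:
        World position (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        _validate_labels(self.voxels, "volume")

    # -- convenience -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def z_world(self, k: int | np.ndarray) -> np.ndarray | float:
        """World z coordinate (mm) of elevation index ``k``."""
        return self.origin[2] + np.asarray(k) * self.spacing[2]

    def z_index(self, z: float) -> int:
        """Nearest elevation index to world coordinate ``z`` (clipped;
        half-way ties round toward the higher index)."""
        k = int(np.floor((z - self.origin[2]) / self.spacing[2] + 0.5))
        return int(np.clip(k, 0, self.shape[2] - 1))

    def plane(self, k: int) -> np.ndarray:
        """2D label image at elevation index ``k``, indexed [row=y, col=x]."""
        return self.voxels[:, :, k].T

    def foreground(self) -> np.ndarray:
        return self.voxels > 0

    def specimen_z_extent(self) -> tuple[float, float]:
        """World z range (mm, voxel centers) spanned by non-background voxels."""
        ks = np.flatnonzero(self.foreground().any(axis=(0, 1)))
        if ks.size == 0:
            raise ValueError("volume contains no specimen voxels")
        return float(self.z_world(ks[0])), float(self.z_world(ks[-1]))


@dataclass
class Slide:
    """One histology slide: a 2D label mask plus its landmarks.

    ``mucosal_edges`` holds the two points (mm, image coordinates) where
    the mucosal surface meets the resection surface, or ``None`` when not
    annotated.
    """

    mask: np.ndarray
    index: int
    mucosal_edges: Optional[np.ndarray] = None  # shape (2, 2), mm (x, y)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError(f"slide mask must be 2D, got shape {self.mask.shape}")
        _validate_labels(self.mask, f"slide {self.index}")
        if self.mucosal_edges is not None:
            self.mucosal_edges = np.asarray(self.mucosal_edges, dtype=float)
            if self.mucosal_edges.shape != (2, 2):
                raise ValueError("mucosal_edges must have shape (2, 2)")

    def has_tumor(self) -> bool:
        return bool((self.mask == LABEL_TUMOR).any())


@dataclass
class SlideStack:
    """Ordered anterior -> posterior stack of histology slide masks."""

    slides: list[Slide]
    pixel_spacing: tuple[float, float] = (0.25, 0.25)  # (px, py) mm
    slice_thickness: float = 4.0  # mm, standard gross sectioning
    orientation: object = "cranial_right"

    def __post_init__(self) -> None:
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be > 0, got {self.pixel_spacing}")
        self.slice_thickness = float(self.slice_thickness)
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        indices = [s.index for s in self.slides]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError("slides must be ordered with unique increasing indices")
        resolve_cranial_direction(self.orientation)  # validate eagerly

    def __len__(self) -> int:
        return len(self.slides)

    def __iter__(self):
        return iter(self.slides)

    def cranial_direction(self) -> np.ndarray:
        return resolve_cranial_direction(self.orientation)

    def tumor_flags(self) -> list[bool]:
        return [s.has_tumor() for s in self.slides]


@dataclass
class SliceMeasurements:
    """The four per-slice measurements for one tumor-bearing slide (mm)."""

    slide: int
    TT: Optional[float] = None
    cranial: Optional[float] = None
    deep: Optional[float] = None
    caudal: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {m: getattr(self, m) for m in PER_SLICE_MEASURES}


@dataclass
class MeasurementRecord:
    """All measurements of one specimen in one modality."""

    specimen: str
    modality: str  # "us-manual" | "us-auto" | "histology"
    slices: list[SliceMeasurements] = field(default_factory=list)
    anterior: Optional[float] = None
    posterior: Optional[float] = None

    def __post_init__(self) -> None:
        for entry in self.slices:
            for m in PER_SLICE_MEASURES:
                v = getattr(entry, m)
                if v is not None and v < 0:
                    raise ValueError(
                        f"negative {m} = {v} mm on slide {entry.slide}"
                    )
        for m in END_MEASURES:
            v = getattr(self, m)
            if v is not None and v < 0:
                raise ValueError(f"negative {m} margin = {v} mm")

    def slide_indices(self) -> list[int]:
        return [s.slide for s in self.slices]

    def scaled(self, factor: float) -> "MeasurementRecord":
        """Return a copy with every distance multiplied by ``factor``."""

        def f(v):
            return None if v is None else v * factor

        return MeasurementRecord(
            specimen=self.specimen,
            modality=self.modality,
            slices=[
                SliceMeasurements(
                    slide=s.slide,
                    **{m: f(getattr(s, m)) for m in PER_SLICE_MEASURES},
                )
                for s in self.slices
            ],
            anterior=f(self.anterior),
            posterior=f(self.posterior),
        )


@dataclass(frozen=True)
class MarginStatus:
    """Margin classification thresholds (mm).

    ``clear`` iff margin >= threshold_close (default 5 mm, the common
    "close margin" cut-off); ``involved`` iff margin <= threshold_involved
    (default 0: tumor at the resection surface); ``close`` otherwise.
    """

    threshold_close: float = 5.0
    threshold_involved: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_involved < 0:
            raise ValueError("threshold_involved must be >= 0")
        if self.threshold_close <= self.threshold_involved:
            raise ValueError("threshold_close must exceed threshold_involved")


def classify_margin(margin_mm: float, status: MarginStatus = MarginStatus()) -> str:
    """Classify a margin distance as ``clear``, ``close`` or ``involved``."""
    margin_mm = float(margin_mm)
    if not np.isfinite(margin_mm):
        raise ValueError(f"margin must be finite, got {margin_mm}")
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0 mm, got {margin_mm}")
    if margin_mm >= status.threshold_close:
        return "clear"
    if margin_mm <= status.threshold_involved:
        return "involved"
    return "close"
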