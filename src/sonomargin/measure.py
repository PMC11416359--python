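"""Resection-surface partitioning and distance measurements.

Per-slice geometry: a chord is drawn between the two mucosal-edge
landmarks; from its midpoint two rays at +/-45 degrees to the chord
(measured in physical mm space) divide the non-mucosal boundary — the
resection surface — into cranial, deep and caudal regions. Four
measurements are taken per tumor-bearing slice: the minimum tumor-to-
surface distance in each region and the tumor thickness (extent along
the chord normal). Anterior/posterior end margins are per-specimen:
counted tumor-free slides on the histology side, a 3D closest-surface
distance on the ultrasound side.

All distances are physical (mm) and computed between pixel/voxel
centers, so they agree exactly with a brute-force pairwise computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .correspondence import SliceCorrespondence
from .model import (
    LABEL_TUMOR,
    LabelVolume,
    MeasurementRecord,
    SliceMeasurements,
    SlideStack,
    resolve_cranial_direction,
)

__all__ = [
    "RegionPartition",
    "REGION_NAMES",
    "assign_regions",
    "partition_resection_surface",
    "region_margin",
    "tumor_thickness",
    "end_margins_histology",
    "end_margins_us",
    "measure_histology",
    "measure_us",
    "measure_specimen",
]

REGION_NAMES = ("cranial", "deep", "caudal")
_QUARTER = np.pi / 4.0


def assign_regions(points, edge1, edge2, interior_point, cranial_direction,
                   chord_tolerance: float = 0.0):
    """Assign boundary points to mucosa / cranial / deep / caudal.

    Works on any point set in mm coordinates (rasterized boundary pixels
    or analytically sampled contour points), so the phantom ground truth
    and the pixel pipeline share one partition rule.

    ``chord_tolerance`` widens the mucosal band: points within that
    distance on the tissue side of the chord, and between the edges,
    still count as mucosa. Rasterized callers pass half a pixel diagonal
    so a staircase mucosal edge hugging the chord is not misread as
    resection surface.

    Returns an array of strings from {"mucosa", "cranial", "deep",
    "caudal"}, one per point.
    """
    points = np.asarray(points, dtype=float)
    e1 = np.asarray(edge1, dtype=float)
    e2 = np.asarray(edge2, dtype=float)
    chord = e2 - e1
    chord_len = float(np.linalg.norm(chord))
    if chord_len <= 1e-9:
        raise ValueError("mucosal edge points coincide; chord is degenerate")
    t = chord / chord_len
    mid = 0.5 * (e1 + e2)
    normal = np.array([-t[1], t[0]])
    inward_sign = float(np.dot(np.asarray(interior_point, dtype=float) - mid, normal))
    if inward_sign < 0:
        normal = -normal

    cdir = resolve_cranial_direction(cranial_direction)
    side = float(np.dot(cdir, t))
    if abs(side) < 1e-9:
        raise ValueError(
            "cranial direction is perpendicular to the mucosal chord; "
            "cannot resolve cranial vs caudal"
        )
    pos_t_region = "cranial" if side > 0 else "caudal"
    neg_t_region = "caudal" if side > 0 else "cranial"

    v = points - mid
    vn = v @ normal
    vt = v @ t
    angles = np.arctan2(vn, vt)  # in [-pi, pi]; resection side has vn > 0

    out = np.empty(len(points), dtype=object)
    out[:] = "mucosa"
    mucosal = (vn <= 0) | (
        (vn <= chord_tolerance) & (np.abs(vt) <= 0.5 * chord_len)
    )
    resection = ~mucosal
    a = angles[resection]
    labels = np.where(
        (a >= _QUARTER) & (a <= 3 * _QUARTER),
        "deep",
        np.where(a < _QUARTER, pos_t_region, neg_t_region),
    )
    out[resection] = labels
    return out


def _tissue_mask(mask: np.ndarray) -> np.ndarray:
    """Outer tissue silhouette: labels 1 and 2 with interior holes filled
    (fiducial channels/holes must not contribute boundary pixels)."""
    tissue = (mask == 1) | (mask == 2)
    return ndimage.binary_fill_holes(tissue)


def _boundary(mask2d: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask2d, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask2d & ~eroded


@dataclass
class RegionPartition:
    """Partition of one slice's tissue boundary into named regions.

    ``indices`` are (row, col) pixel indices of boundary pixels,
    ``points`` their physical (x, y) positions in mm, ``labels`` the
    region of each boundary pixel ("mucosa"/"cranial"/"deep"/"caudal").
    """

    indices: np.ndarray  # (N, 2) int, (row, col)
    points: np.ndarray  # (N, 2) float, mm (x, y)
    labels: np.ndarray  # (N,) object
    edges: np.ndarray  # (2, 2) mm, the mucosal edge landmarks
    midpoint: np.ndarray  # (2,) mm
    chord_tangent: np.ndarray  # (2,) unit
    chord_normal: np.ndarray  # (2,) unit, pointing into the tissue
    shape: tuple[int, int]

    def region_pixels(self, region: str) -> np.ndarray:
        if region not in REGION_NAMES + ("mucosa",):
            raise ValueError(f"unknown region {region!r}")
        return self.indices[self.labels == region]


def partition_resection_surface(
    mask: np.ndarray,
    edges,
    orientation,
    spacing: tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
) -> RegionPartition:
    """Partition a slice's tissue boundary into mucosa + three regions.

    Parameters
    ----------
    mask:
        2D label image [row=y, col=x].
    edges:
        the two mucosal-edge landmarks, shape (2, 2), mm (x, y).
    orientation:
        stack orientation tag resolving cranial vs caudal.
    spacing:
        (px, py) mm.
    origin:
        world position of pixel (0, 0), mm (x, y).
    """
    mask = np.asarray(mask)
    px, py = (float(s) for s in spacing)
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (2, 2):
        raise ValueError("edges must be two 2D points")
    if np.linalg.norm(edges[0] - edges[1]) <= 1e-9:
        raise ValueError("mucosal edge points coincide")

    tissue = _tissue_mask(mask)
    if not tissue.any():
        raise ValueError("slice contains no tissue")
    boundary = _boundary(tissue)
    rows, cols = np.nonzero(boundary)
    indices = np.column_stack([rows, cols])
    points = np.column_stack(
        [origin[0] + cols * px, origin[1] + rows * py]
    )

    # landmarks must sit on (or within ~2 px of) the tissue boundary
    tol = 3.0 * max(px, py)
    for edge in edges:
        d = np.min(np.linalg.norm(points - edge, axis=1))
        if d > tol:
            raise ValueError(
                f"mucosal edge {edge.tolist()} is {d:.2f} mm from the tissue "
                f"boundary (tolerance {tol:.2f} mm)"
            )

    com = ndimage.center_of_mass(tissue)  # (row, col)
    interior = np.array([origin[0] + com[1] * px, origin[1] + com[0] * py])
    labels = assign_regions(
        points, edges[0], edges[1], interior, orientation,
        chord_tolerance=0.5 * float(np.hypot(px, py)),
    )

    t = (edges[1] - edges[0]) / np.linalg.norm(edges[1] - edges[0])
    normal = np.array([-t[1], t[0]])
    if np.dot(interior - 0.5 * (edges[0] + edges[1]), normal) < 0:
        normal = -normal
    return RegionPartition(
        indices=indices,
        points=points,
        labels=labels,
        edges=edges,
        midpoint=0.5 * (edges[0] + edges[1]),
        chord_tangent=t,
        chord_normal=normal,
        shape=mask.shape,
    )


def region_margin(
    mask: np.ndarray,
    partition: RegionPartition,
    region: str,
    spacing: tuple[float, float],
) -> Optional[float]:
    """Minimum tumor-to-resection-surface distance within one region (mm).

    Computed with an exact Euclidean distance transform on the physical
    (anisotropic) grid seeded at the region's surface pixels; equals the
    brute-force minimum over all tumor x surface pixel pairs.

    Returns ``None`` when the region has no surface pixels.
    """
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region {region!r}; expected one of {REGION_NAMES}")
    tumor = np.asarray(mask) == LABEL_TUMOR
    if not tumor.any():
        raise ValueError("slice contains no tumor pixels")
    surf = partition.region_pixels(region)
    if len(surf) == 0:
        return None
    feature = np.ones(partition.shape, dtype=bool)
    feature[surf[:, 0], surf[:, 1]] = False
    px, py = (float(s) for s in spacing)
    dist = ndimage.distance_transform_edt(feature, sampling=(py, px))
    return float(dist[tumor].min())


def tumor_thickness(
    mask: np.ndarray,
    partition: RegionPartition,
    spacing: tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Tumor extent along the chord normal (max - min projection), mm."""
    tumor = np.asarray(mask) == LABEL_TUMOR
    if not tumor.any():
        raise ValueError("slice contains no tumor pixels")
    rows, cols = np.nonzero(tumor)
    px, py = (float(s) for s in spacing)
    pts = np.column_stack([origin[0] + cols * px, origin[1] + rows * py])
    proj = pts @ partition.chord_normal
    tt = float(proj.max() - proj.min())
    if tt == 0.0:
        warnings.warn(
            "tumor spans a single pixel row along the thickness axis; "
            "TT reported as 0 mm",
            stacklevel=2,
        )
    return tt


def end_margins_histology(stack: SlideStack) -> tuple[float, float]:
    """Anterior/posterior margins from counted tumor-free slides (mm).

    anterior = (# consecutive tumor-free slides before the first
    tumor-bearing slide) x slice_thickness; posterior symmetric.
    """
    flags = stack.tumor_flags()
    if not any(flags):
        raise ValueError("no tumor in any slide of the specimen")
    first = flags.index(True)
    last = len(flags) - 1 - flags[::-1].index(True)
    return (
        first * stack.slice_thickness,
        (len(flags) - 1 - last) * stack.slice_thickness,
    )


def _cap_surface(volume: LabelVolume, cap_depth: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of anterior / posterior end-cap surface voxels.

    The cap surface is the set of specimen boundary voxels (foreground
    adjacent to background, 6-connectivity) whose z lies within
    ``cap_depth`` mm of the respective z-extreme of the specimen.
    """
    fg = volume.foreground()
    eroded = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surface = fg & ~eroded
    z_min, z_max = volume.specimen_z_extent()
    z = volume.z_world(np.arange(volume.shape[2]))
    ant = surface & (z[np.newaxis, np.newaxis, :] <= z_min + cap_depth)
    post = surface & (z[np.newaxis, np.newaxis, :] >= z_max - cap_depth)
    return ant, post


def end_margins_us(volume: LabelVolume, cap_depth: float = 0.5) -> tuple[float, float]:
    """Anterior/posterior margins in the US volume (mm).

    Minimum 3D physical distance from any tumor voxel to the anterior
    (min-z) and posterior (max-z) end-cap surfaces. The cap defaults to
    the surface within one US slice spacing (0.5 mm) of the z-extreme —
    the last annotated slice region; wider slabs let the distance cut
    laterally through the specimen flank and systematically undershoot
    the axial gap the histology counting rule measures.
    """
    tumor = volume.voxels == LABEL_TUMOR
    if not tumor.any():
        raise ValueError("no tumor in the volume")
    ant, post = _cap_surface(volume, cap_depth)
    out = []
    for cap in (ant, post):
        dist = ndimage.distance_transform_edt(~cap, sampling=volume.spacing)
        out.append(float(dist[tumor].min()))
    return out[0], out[1]


def _measure_slice(mask, edges, orientation, spacing, origin=(0.0, 0.0)):
    part = partition_resection_surface(mask, edges, orientation, spacing, origin)
    values = {"TT": tumor_thickness(mask, part, spacing, origin)}
    for region in REGION_NAMES:
        values[region] = region_margin(mask, part, region, spacing)
    return values


def measure_histology(
    stack: SlideStack, specimen: str = "specimen", modality: str = "histology"
) -> MeasurementRecord:
    """Measure every tumor-bearing slide of a histology stack."""
    record = MeasurementRecord(specimen=specimen, modality=modality)
    any_tumor = False
    for slide in stack:
        if not slide.has_tumor():
            continue
        any_tumor = True
        if slide.mucosal_edges is None:
            raise ValueError(
                f"slide {slide.index} contains tumor but has no mucosal-edge "
                "landmarks"
            )
        values = _measure_slice(
            slide.mask, slide.mucosal_edges, stack.orientation, stack.pixel_spacing
        )
        record.slices.append(SliceMeasurements(slide=slide.index, **values))
    if not any_tumor:
        raise ValueError("no tumor in any slide of the specimen")
    record.anterior, record.posterior = end_margins_histology(stack)
    return record


def measure_us(
    volume: LabelVolume,
    correspondence: SliceCorrespondence,
    landmarks: dict[int, np.ndarray],
    orientation,
    specimen: str = "specimen",
    modality: str = "us-manual",
    cap_depth: float = 0.5,
) -> MeasurementRecord:
    """Measure the US volume at the slices matched to the histology slides.

    Slices where the matched US image shows no tumor are simply absent
    from the record (they surface as discordant detections at pairing
    time); landmarks are required only for slices that are measured.
    """
    if (volume.voxels == LABEL_TUMOR).sum() == 0:
        raise ValueError("no tumor in the volume")
    spacing2d = (volume.spacing[0], volume.spacing[1])
    origin2d = (volume.origin[0], volume.origin[1])
    record = MeasurementRecord(specimen=specimen, modality=modality)
    for match in correspondence.matches:
        k = match.us_index
        plane = volume.plane(k)
        if not (plane == LABEL_TUMOR).any():
            continue
        if k not in landmarks:
            raise ValueError(f"no mucosal-edge landmarks for US elevation index {k}")
        values = _measure_slice(
            plane, np.asarray(landmarks[k], dtype=float), orientation,
            spacing2d, origin2d,
        )
        record.slices.append(SliceMeasurements(slide=match.slide, **values))
    record.anterior, record.posterior = end_margins_us(volume, cap_depth)
    return record


def measure_specimen(source, **kwargs) -> MeasurementRecord:
    """Dispatch to :func:`measure_us` or :func:`measure_histology`."""
    if isinstance(source, LabelVolume):
        return measure_us(source, **kwargs)
    if isinstance(source, SlideStack):
        return measure_histology(source, **kwargs)
    raise TypeError(f"cannot measure object of type {type(source).__name__}")
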