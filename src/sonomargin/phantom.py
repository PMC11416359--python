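"""Digital specimen phantoms with analytic ground truth.

A phantom specimen is a superellipsoid of tissue with a designated
mucosal sector on its boundary, an embedded ellipsoidal tumor, and up to
three ~1.7 mm fiducial channels running roughly along the long (z) axis,
each independently tilted so that inter-fiducial distances vary linearly
with elevation. The US side is a rasterized :class:`LabelVolume`; the
histology side applies a configurable transform — uniform linear
shrinkage, an optional volume-preserving z-stretch (emulating a specimen
pinned out before fixation) and an optional smooth in-plane deformation
— then sections the result into 4 mm slices, rasterizing each section's
central plane.

Ground-truth measurements are computed from the continuous analytic
geometry (densely sampled contours), independent of any rasterization,
so every downstream stage can be validated against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .measure import REGION_NAMES, assign_regions
from .model import (
    LabelVolume,
    MeasurementRecord,
    Slide,
    SliceMeasurements,
    SlideStack,
)

__all__ = [
    "PhantomConfig",
    "SpecimenGeometry",
    "SlideTruth",
    "GroundTruth",
    "PhantomSpecimen",
    "generate_specimen",
    "apply_histology_transform",
    "true_measurements",
    "us_landmarks",
    "generate_phantom",
    "sample_config",
    "generate_cohort",
    "generate_outlier_cohort",
]

_CONTOUR_SAMPLES = 2048
_TUMOR_SAMPLES = 1024


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of one synthetic specimen; fully determines the phantom
    together with nothing else (pure function of the config)."""

    seed: int = 0
    half_axes: tuple[float, float, float] = (12.0, 10.0, 20.0)  # (a, b, c) mm
    exponent: float = 2.5  # superellipse exponent (2 = ellipsoid)
    mucosa_half_angle_deg: float = 50.0  # sector half-angle around "up" (-y)
    tumor_center: tuple[float, float, float] = (0.0, -2.0, 0.0)
    tumor_half_axes: tuple[float, float, float] = (4.5, 3.5, 11.0)
    tumor_z_exponent: float = 2.0  # >2 blunts the tumor's z tips
    n_fiducials: int = 3
    fiducial_diameter: float = 1.7  # ~16 gauge cannula
    fiducial_tilt_deg: float = 6.0  # maximum tilt off the z axis
    shrinkage: float = 0.0  # linear fraction s in [0, 0.5]
    deformation_amplitude: float = 0.0  # mm, smooth in-plane warp
    stretch_factor: float = 1.0  # volume-preserving z elongation
    us_spacing: tuple[float, float, float] = (0.4, 0.4, 0.5)
    histo_pixel_spacing: tuple[float, float] = (0.25, 0.25)
    slice_thickness: float = 4.0
    orientation: str = "cranial_right"

    def __post_init__(self) -> None:
        a, b, c = self.half_axes
        if min(a, b, c) <= 0:
            raise ValueError("specimen half-axes must be positive")
        if not (0.0 <= self.shrinkage < 1.0):
            raise ValueError("shrinkage must lie in [0, 1)")
        if not (0 <= self.n_fiducials <= 3):
            raise ValueError("n_fiducials must be 0..3")
        if self.stretch_factor <= 0:
            raise ValueError("stretch_factor must be positive")
        if self.exponent < 2:
            raise ValueError("superellipse exponent must be >= 2")

    @property
    def has_tumor(self) -> bool:
        return all(h > 0 for h in self.tumor_half_axes)


@dataclass
class SpecimenGeometry:
    """Continuous analytic geometry of one phantom (US / material frame)."""

    config: PhantomConfig
    fiducial_points: np.ndarray  # (n, 2): axis position (x, y) at z = 0
    fiducial_tilts: np.ndarray  # (n, 2): d(x, y)/dz of each axis
    deformation_phases: np.ndarray  # (4,)
    volume_origin: Optional[tuple[float, float, float]] = None

    # -- implicit shapes -------------------------------------------------
    def specimen_implicit(self, pts: np.ndarray) -> np.ndarray:
        a, b, c = self.config.half_axes
        p = self.config.exponent
        pts = np.atleast_2d(pts)
        return (
            np.abs(pts[:, 0] / a) ** p
            + np.abs(pts[:, 1] / b) ** p
            + np.abs(pts[:, 2] / c) ** p
        )

    def inside_specimen(self, pts: np.ndarray) -> np.ndarray:
        return self.specimen_implicit(pts) <= 1.0

    def inside_tumor(self, pts: np.ndarray) -> np.ndarray:
        if not self.config.has_tumor:
            return np.zeros(len(np.atleast_2d(pts)), dtype=bool)
        cx, cy, cz = self.config.tumor_center
        ra, rb, rc = self.config.tumor_half_axes
        pz = self.config.tumor_z_exponent
        pts = np.atleast_2d(pts)
        return (
            ((pts[:, 0] - cx) / ra) ** 2
            + ((pts[:, 1] - cy) / rb) ** 2
            + np.abs((pts[:, 2] - cz) / rc) ** pz
        ) <= 1.0

    def inside_fiducial(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        hit = np.zeros(len(pts), dtype=bool)
        r = self.config.fiducial_diameter / 2.0
        for p0, tilt in zip(self.fiducial_points, self.fiducial_tilts):
            ax = p0[0] + tilt[0] * pts[:, 2]
            ay = p0[1] + tilt[1] * pts[:, 2]
            hit |= (pts[:, 0] - ax) ** 2 + (pts[:, 1] - ay) ** 2 <= r * r
        return hit

    # -- cross-sections --------------------------------------------------
    def section_half_axes(self, z: float) -> Optional[tuple[float, float]]:
        a, b, c = self.config.half_axes
        p = self.config.exponent
        rest = 1.0 - abs(z / c) ** p
        if rest <= 0:
            return None
        k = rest ** (1.0 / p)
        return a * k, b * k

    def _boundary_radius(self, u: np.ndarray, az: float, bz: float) -> np.ndarray:
        p = self.config.exponent
        denom = np.abs(u[:, 0] / az) ** p + np.abs(u[:, 1] / bz) ** p
        return denom ** (-1.0 / p)

    def section_contour(self, z: float, n: int = _CONTOUR_SAMPLES) -> Optional[np.ndarray]:
        """Specimen boundary contour at elevation ``z`` (mm, (x, y))."""
        half = self.section_half_axes(z)
        if half is None:
            return None
        phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        # phi measured from the mucosal "up" direction (-y), turning toward +x
        u = np.column_stack([np.sin(phi), -np.cos(phi)])
        r = self._boundary_radius(u, *half)
        return u * r[:, None]

    def mucosal_edges(self, z: float) -> Optional[np.ndarray]:
        """Sector boundary ∩ slice plane: the two mucosal-edge landmarks."""
        half = self.section_half_axes(z)
        if half is None:
            return None
        phi = math.radians(self.config.mucosa_half_angle_deg)
        u = np.array(
            [[math.sin(-phi), -math.cos(-phi)], [math.sin(phi), -math.cos(phi)]]
        )
        r = self._boundary_radius(u, *half)
        return u * r[:, None]

    def tumor_contour(self, z: float, n: int = _TUMOR_SAMPLES) -> Optional[np.ndarray]:
        if not self.config.has_tumor:
            return None
        cx, cy, cz = self.config.tumor_center
        ra, rb, rc = self.config.tumor_half_axes
        rest = 1.0 - abs((z - cz) / rc) ** self.config.tumor_z_exponent
        if rest <= 0:
            return None
        k = math.sqrt(rest)
        phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack(
            [cx + ra * k * np.cos(phi), cy + rb * k * np.sin(phi)]
        )

    # -- histology transform --------------------------------------------
    @property
    def inplane_scale(self) -> float:
        cfg = self.config
        return (1.0 - cfg.shrinkage) / math.sqrt(cfg.stretch_factor)

    @property
    def z_scale(self) -> float:
        cfg = self.config
        return (1.0 - cfg.shrinkage) * cfg.stretch_factor

    def _displacement(self, xy: np.ndarray, z: float) -> np.ndarray:
        amp = self.config.deformation_amplitude
        if amp == 0.0:
            return np.zeros_like(xy)
        a, b, c = self.config.half_axes
        p1, p2, p3, p4 = self.deformation_phases
        dx = amp * np.sin(0.5 * np.pi * z / c + p1) * np.cos(
            0.5 * np.pi * xy[:, 1] / b + p2
        )
        dy = amp * np.sin(0.5 * np.pi * z / c + p3) * np.cos(
            0.5 * np.pi * xy[:, 0] / a + p4
        )
        return np.column_stack([dx, dy])

    def transform_inplane(self, xy: np.ndarray, z: float) -> np.ndarray:
        """Material (US) in-plane coordinates -> histology coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return self.inplane_scale * xy + self._displacement(xy, z)

    def invert_inplane(self, xy_h: np.ndarray, z: float, iters: int = 8) -> np.ndarray:
        """Histology in-plane coordinates -> material coordinates
        (fixed-point iteration; the warp is smooth and sub-millimetre)."""
        xy_h = np.atleast_2d(np.asarray(xy_h, dtype=float))
        xy = xy_h / self.inplane_scale
        for _ in range(iters):
            xy = (xy_h - self._displacement(xy, z)) / self.inplane_scale
        return xy

    def transform_z(self, z: float) -> float:
        return self.z_scale * z

    def invert_z(self, z_h: float) -> float:
        return z_h / self.z_scale


# ---------------------------------------------------------------------------
# generation



def _tumor_surface_points(config: PhantomConfig, n_theta: int, n_phi: int) -> np.ndarray:
    """Sample the tumor surface (handles the z-bluntness exponent)."""
    cx, cy, cz = config.tumor_center
    ra, rb, rc = config.tumor_half_axes
    pz = config.tumor_z_exponent
    w = np.cos(np.linspace(0, np.pi, n_theta))
    zf = np.sign(w) * np.abs(w) ** (2.0 / pz)
    k = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    kk, pp = np.meshgrid(k, phi, indexing="ij")
    zz = np.broadcast_to((cz + rc * zf)[:, None], kk.shape)
    return np.column_stack(
        [
            (cx + ra * kk * np.cos(pp)).ravel(),
            (cy + rb * kk * np.sin(pp)).ravel(),
            zz.ravel(),
        ]
    )


def _place_fiducials(config: PhantomConfig, rng: np.random.Generator):
    """Random fiducial axes that stay inside the specimen over most of
    its length; tilts are independent so inter-fiducial distances carry
    a usable linear-in-z signal."""
    a, b, c = config.half_axes
    n = config.n_fiducials
    if n == 0:
        return np.zeros((0, 2)), np.zeros((0, 2))
    tilt_max = math.tan(math.radians(config.fiducial_tilt_deg))
    base_angles = rng.uniform(0, 2 * np.pi) + np.arange(n) * 2 * np.pi / max(n, 1)
    for attempt in range(300):
        shrink = 1.0 - 0.1 * min(attempt // 50, 3)
        radius = 0.38 * min(a, b) * shrink
        angles = base_angles + rng.normal(0, 0.25, size=n)
        pts = radius * np.column_stack([np.cos(angles), np.sin(angles)])
        pts += rng.normal(0, 0.35, size=(n, 2))
        mags = rng.uniform(0.5, 1.0, size=n) * tilt_max * shrink
        dirs = rng.uniform(0, 2 * np.pi, size=n)
        tilts = mags[:, None] * np.column_stack([np.cos(dirs), np.sin(dirs)])
        ok = True
        for zc in (-0.82 * c, 0.0, 0.82 * c):
            half = SpecimenGeometry(
                config, pts, tilts, np.zeros(4)
            ).section_half_axes(zc)
            if half is None:
                ok = False
                break
            az, bz = half
            xy = pts + tilts * zc
            margin = config.fiducial_diameter
            if (
                (np.abs(xy[:, 0]) / max(az - margin, 0.1)) ** config.exponent
                + (np.abs(xy[:, 1]) / max(bz - margin, 0.1)) ** config.exponent
                > 1.0
            ).any():
                ok = False
                break
        # keep the channels apart so cross-sections never merge, and keep
        # each pair's closest approach outside the specimen so the
        # inter-fiducial distances vary monotonically (about linearly)
        # over the whole length
        if ok and n > 1:
            for i in range(n):
                for j in range(i + 1, n):
                    dp = pts[i] - pts[j]
                    dt = tilts[i] - tilts[j]
                    if np.linalg.norm(dp) < 2.5 * config.fiducial_diameter:
                        ok = False
                    nt = float(dt @ dt)
                    if nt > 1e-12 and abs(-(dp @ dt) / nt) < 2.0 * c:
                        ok = False
        if ok:
            return pts, tilts
    raise ValueError(
        "could not place fiducials inside the specimen; reduce tilt or count"
    )


def generate_specimen(config: PhantomConfig) -> tuple[LabelVolume, SpecimenGeometry]:
    """Rasterize one phantom into a US-side label volume.

    Deterministic: identical configs (including seed) yield identical
    voxel grids.
    """
    rng = np.random.default_rng(config.seed)
    a, b, c = config.half_axes

    if config.has_tumor:
        _check_tumor_inside(config)

    fid_pts, fid_tilts = _place_fiducials(config, rng)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    geom = SpecimenGeometry(config, fid_pts, fid_tilts, phases)

    pad = 1.0
    dx, dy, dz = config.us_spacing
    origin = (-(a + pad), -(b + pad), -(c + pad))
    nx = int(math.floor(2 * (a + pad) / dx)) + 1
    ny = int(math.floor(2 * (b + pad) / dy)) + 1
    nz = int(math.floor(2 * (c + pad) / dz)) + 1
    xs = origin[0] + np.arange(nx) * dx
    ys = origin[1] + np.arange(ny) * dy
    zs = origin[2] + np.arange(nz) * dz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    labels = np.zeros(len(pts), dtype=np.uint8)
    spec = geom.inside_specimen(pts)
    labels[spec] = 1
    if config.has_tumor:
        labels[spec & geom.inside_tumor(pts)] = 2
    if config.n_fiducials:
        labels[spec & geom.inside_fiducial(pts)] = 3

    volume = LabelVolume(
        voxels=labels.reshape(nx, ny, nz),
        spacing=config.us_spacing,
        origin=origin,
    )
    geom.volume_origin = origin
    return volume, geom


# ---------------------------------------------------------------------------
# analytic measurement of one cross-section


def _cross_section_truth(geom: SpecimenGeometry, z: float, transformed: bool):
    """Analytic {TT, cranial, deep, caudal} at elevation z, either on the
    material (US) geometry or after the histology transform."""
    contour = geom.section_contour(z)
    tumor = geom.tumor_contour(z)
    edges = geom.mucosal_edges(z)
    if contour is None or tumor is None or edges is None:
        return None
    if transformed:
        contour = geom.transform_inplane(contour, z)
        tumor = geom.transform_inplane(tumor, z)
        edges = geom.transform_inplane(edges, z)
    interior = contour.mean(axis=0)
    labels = assign_regions(contour, edges[0], edges[1], interior,
                            geom.config.orientation)
    t = edges[1] - edges[0]
    t = t / np.linalg.norm(t)
    normal = np.array([-t[1], t[0]])
    if np.dot(interior - edges.mean(axis=0), normal) < 0:
        normal = -normal
    proj = tumor @ normal
    values = {"TT": float(proj.max() - proj.min())}
    tree = cKDTree(tumor)
    for region in REGION_NAMES:
        pts = contour[labels == region]
        if len(pts) == 0:
            values[region] = None
            continue
        d, _ = tree.query(pts)
        values[region] = float(d.min())
    return values


def _us_end_margins_truth(geom: SpecimenGeometry, cap_depth: float = 0.5):
    """Analytic 3D tumor-to-end-cap distances on the material geometry."""
    cfg = geom.config
    a, b, c = cfg.half_axes
    tumor_surf = _tumor_surface_points(cfg, 80, 160)
    out = []
    for sign in (-1, 1):
        z_lo = sign * c
        zs = np.linspace(z_lo, z_lo - sign * cap_depth, 60)
        cap_pts = []
        for z in zs:
            contour = geom.section_contour(z, n=180)
            if contour is None:
                cap_pts.append(np.array([[0.0, 0.0, z if abs(z) <= c else sign * c]]))
                continue
            cap_pts.append(
                np.column_stack([contour, np.full(len(contour), z)])
            )
        cap = np.vstack(cap_pts)
        d, _ = cKDTree(cap).query(tumor_surf)
        out.append(float(d.min()))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# histology transform + ground truth


@dataclass
class SlideTruth:
    slide: int
    z_histology: float  # slide central plane, histology frame, mm
    z_us: float  # pre-image elevation in the US/material frame, mm
    us_index: int  # nearest US elevation index
    us: Optional[dict] = None  # {TT, cranial, deep, caudal} or None
    histology: Optional[dict] = None


@dataclass
class GroundTruth:
    """Analytic truth for every downstream stage of the pipeline."""

    slides: list[SlideTruth]
    us_anterior: float
    us_posterior: float
    histo_anterior: float
    histo_posterior: float

    def correspondence_indices(self) -> dict[int, int]:
        return {s.slide: s.us_index for s in self.slides}


def apply_histology_transform(
    geom: SpecimenGeometry, config: Optional[PhantomConfig] = None
) -> tuple[SlideStack, GroundTruth]:
    """Shrink/stretch/deform the specimen, section it, rasterize slides.

    Sections are ``slice_thickness`` mm thick along z; the number of
    slides is ``ceil(extent / thickness)`` and each slide rasterizes its
    section's central plane (a 4 um microtome slide samples one plane of
    the 4 mm block). Returns the slide stack plus analytic ground truth
    on both the material (US) and transformed (histology) geometry.
    """
    config = config or geom.config
    if config is not geom.config:
        geom = replace(geom, config=config)
    a, b, c = config.half_axes
    t = config.slice_thickness
    beta = geom.z_scale
    alpha = geom.inplane_scale
    amp = config.deformation_amplitude

    z_lo, z_hi = -beta * c, beta * c
    extent = z_hi - z_lo
    n_slides = max(1, int(math.ceil(extent / t - 1e-9)))

    # "equally cut": n_slides sections of identical thickness
    # extent / n_slides (<= the nominal slice thickness)
    t_eff = extent / n_slides
    centers = [z_lo + (m + 0.5) * t_eff for m in range(n_slides)]

    px, py = config.histo_pixel_spacing
    half_x = alpha * a + amp + 2.0
    half_y = alpha * b + amp + 2.0
    w = int(math.floor(2 * half_x / px)) + 1
    h = int(math.floor(2 * half_y / py)) + 1
    img_origin = np.array([-half_x, -half_y])
    cols = img_origin[0] + np.arange(w) * px
    rows = img_origin[1] + np.arange(h) * py
    CX, CY = np.meshgrid(cols, rows)  # [row, col]
    grid = np.column_stack([CX.ravel(), CY.ravel()])

    dz = config.us_spacing[2]
    z_origin = (
        geom.volume_origin[2] if geom.volume_origin is not None else -(c + 1.0)
    )

    slides: list[Slide] = []
    truths: list[SlideTruth] = []
    for m, z_h in enumerate(centers):
        z_us = geom.invert_z(z_h)
        material = geom.invert_inplane(grid, z_us)
        pts3 = np.column_stack([material, np.full(len(material), z_us)])
        labels = np.zeros(len(grid), dtype=np.uint8)
        spec = geom.inside_specimen(pts3)
        labels[spec] = 1
        if config.has_tumor:
            labels[spec & geom.inside_tumor(pts3)] = 2
        if config.n_fiducials:
            labels[spec & geom.inside_fiducial(pts3)] = 3
        mask = labels.reshape(h, w)

        edges_mat = geom.mucosal_edges(z_us)
        edges_img = None
        if edges_mat is not None:
            edges_img = geom.transform_inplane(edges_mat, z_us) - img_origin
        slides.append(Slide(mask=mask, index=m, mucosal_edges=edges_img))

        us_index = int(math.floor((z_us - z_origin) / dz + 0.5))
        truths.append(
            SlideTruth(
                slide=m,
                z_histology=float(z_h),
                z_us=float(z_us),
                us_index=us_index,
                us=_cross_section_truth(geom, z_us, transformed=False),
                histology=_cross_section_truth(geom, z_us, transformed=True),
            )
        )

    stack = SlideStack(
        slides=slides,
        pixel_spacing=(px, py),
        slice_thickness=t,
        orientation=config.orientation,
    )

    if config.has_tumor:
        us_ant, us_post = _us_end_margins_truth(geom)
        cz, rc_half = config.tumor_center[2], config.tumor_half_axes[2]
        histo_ant = beta * (cz - rc_half + c)
        histo_post = beta * (c - (cz + rc_half))
    else:
        us_ant = us_post = histo_ant = histo_post = float("nan")
    truth = GroundTruth(
        slides=truths,
        us_anterior=us_ant,
        us_posterior=us_post,
        histo_anterior=histo_ant,
        histo_posterior=histo_post,
    )
    return stack, truth


def true_measurements(
    truth: GroundTruth, side: str, specimen: str = "specimen"
) -> MeasurementRecord:
    """Analytic ground-truth measurements in the pipeline's record schema.

    ``side`` is ``"us"`` or ``"histology"``.
    """
    if side not in ("us", "histology"):
        raise ValueError(f"side must be 'us' or 'histology', got {side!r}")
    modality = "us-manual" if side == "us" else "histology"
    record = MeasurementRecord(specimen=specimen, modality=modality)
    for st in truth.slides:
        values = st.us if side == "us" else st.histology
        if values is None:
            continue
        record.slices.append(SliceMeasurements(slide=st.slide, **values))
    if side == "us":
        record.anterior, record.posterior = truth.us_anterior, truth.us_posterior
    else:
        record.anterior, record.posterior = (
            truth.histo_anterior,
            truth.histo_posterior,
        )
    return record


def us_landmarks(geom: SpecimenGeometry, volume: LabelVolume) -> dict[int, np.ndarray]:
    """Analytic mucosal-edge landmarks for every US elevation (world mm)."""
    out = {}
    for k in range(volume.shape[2]):
        z = float(volume.z_world(k))
        edges = geom.mucosal_edges(z)
        if edges is not None:
            out[k] = edges
    return out


# ---------------------------------------------------------------------------
# cohort helpers


@dataclass
class PhantomSpecimen:
    specimen: str
    config: PhantomConfig
    volume: LabelVolume
    geometry: SpecimenGeometry
    stack: SlideStack
    truth: GroundTruth
    landmarks: dict[int, np.ndarray]


def generate_phantom(config: PhantomConfig, specimen: str = "specimen") -> PhantomSpecimen:
    """Generate a complete phantom: volume, slides, truth, landmarks."""
    volume, geom = generate_specimen(config)
    stack, truth = apply_histology_transform(geom)
    return PhantomSpecimen(
        specimen=specimen,
        config=config,
        volume=volume,
        geometry=geom,
        stack=stack,
        truth=truth,
        landmarks=us_landmarks(geom, volume),
    )


def sample_config(seed: int, **overrides) -> PhantomConfig:
    """Draw a random but valid specimen configuration.

    Specimen long axes default to ~32-44 mm (an assumption; no size
    statistics are published for the cohort the design emulates).
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(10.5, 13.0)
    b = rng.uniform(9.0, 11.5)
    c = float(2 * rng.integers(8, 12))  # whole slide counts at s = 0
    ra = rng.uniform(3.0, 6.0)
    rb = rng.uniform(2.5, 5.0)
    rc = rng.uniform(0.55, 0.75) * c
    cx = rng.uniform(-2.0, 2.0)
    cy = rng.uniform(-3.5, -0.5)
    cz = rng.uniform(-0.10, 0.10) * c
    params = dict(
        seed=seed,
        half_axes=(a, b, c),
        exponent=rng.uniform(2.2, 3.0),
        mucosa_half_angle_deg=rng.uniform(42.0, 58.0),
        tumor_center=(cx, cy, cz),
        tumor_half_axes=(ra, rb, rc),
        tumor_z_exponent=rng.uniform(2.5, 4.0),
        fiducial_tilt_deg=rng.uniform(4.0, 7.0),
    )
    params.update(overrides)
    config = PhantomConfig(**params)
    # shrink the tumor until it fits strictly inside the specimen
    for _ in range(20):
        try:
            _check_tumor_inside(config)
            return config
        except ValueError:
            ra, rb, rc = config.tumor_half_axes
            config = replace(config, tumor_half_axes=(0.93 * ra, 0.93 * rb, 0.93 * rc))
    raise ValueError(f"could not fit a tumor for seed {seed}")


def _check_tumor_inside(config: PhantomConfig) -> None:
    if not config.has_tumor:
        return
    geom = SpecimenGeometry(config, np.zeros((0, 2)), np.zeros((0, 2)), np.zeros(4))
    surf = _tumor_surface_points(config, 24, 48)
    if (geom.specimen_implicit(surf) > 0.995).any():
        raise ValueError("tumor is not strictly inside the specimen")


def generate_cohort(
    n_specimens: int, seed: int, **overrides
) -> list[PhantomSpecimen]:
    """Generate a deterministic cohort of phantoms (ids P1, P2, ...)."""
    root = np.random.default_rng(seed)
    out = []
    for i in range(n_specimens):
        sub_seed = int(root.integers(0, 2**31 - 1))
        config = sample_config(sub_seed, **overrides)
        out.append(generate_phantom(config, specimen=f"P{i + 1}"))
    return out


def generate_outlier_cohort(
    seed: int,
    n_specimens: int = 5,
    shrinkage: float = 0.2,
    stretch_factor: float = 1.3,
    **overrides,
) -> tuple[list[PhantomSpecimen], str]:
    """A cohort in which the last specimen was pinned out before fixation.

    All specimens share the same uniform shrinkage; the last additionally
    gets a volume-preserving z-stretch, emulating a specimen delivered to
    pathology stretched and pinned. Returns (cohort, outlier specimen id).
    """
    root = np.random.default_rng(seed)
    out = []
    for i in range(n_specimens):
        sub_seed = int(root.integers(0, 2**31 - 1))
        f = stretch_factor if i == n_specimens - 1 else 1.0
        config = sample_config(sub_seed, shrinkage=shrinkage,
                               stretch_factor=f, **overrides)
        out.append(generate_phantom(config, specimen=f"P{i + 1}"))
    return out, f"P{n_specimens}"
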