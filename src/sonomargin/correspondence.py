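"""Slide-to-ultrasound slice correspondence.

Two-step matching: (1) the annotated specimen length along the sweep
axis is divided by the number of histology slices, giving a nominal
elevation for each slide; (2) within a +/-window around each nominal
position, the elevation whose inter-fiducial distance profile best
matches the slide's fiducial-hole profile is chosen. Histology profiles
are rescaled by a global factor first, compensating bulk fixation
shrinkage. A strict anterior->posterior monotonicity constraint is
enforced by dynamic programming over the candidate windows; per-slide
residuals are reported (never thresholded) as the automated stand-in
for the manual visual check.

Specimens without at least two visible fiducials fall back to the
nominal positions alone.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .model import LABEL_FIDUCIAL, LabelVolume, Slide, SlideStack

__all__ = [
    "SlideMatch",
    "SliceCorrespondence",
    "nominal_positions",
    "fiducial_profile",
    "match_slides",
    "write_correspondence",
    "read_correspondence",
]

#: cost (mm of residual) charged per mm of deviation from the nominal
#: position when a slide has no usable fiducial profile
_NOMINAL_WEIGHT = 0.01
#: residual penalty (mm) per missing/extra fiducial pair
_COUNT_PENALTY = 0.75
#: cost (mm of residual) per mm of deviation of consecutive matches from
#: the nominal slide spacing — the equal-thickness sectioning prior
_SPACING_WEIGHT = 0.08
#: cost (mm of residual) per mm of deviation from the reconstructed
#: section centers; breaks the global-offset degeneracy of the rescaled
#: fiducial residual
_CALIB_WEIGHT = 0.08
_MIN_COMPONENT_PIXELS = 2


@dataclass
class SlideMatch:
    slide: int
    nominal_z: float  # mm, world coordinates
    us_index: int
    residual: Optional[float]  # RMS profile mismatch, mm; None = fallback
    window: float  # mm search half-width actually used


@dataclass
class SliceCorrespondence:
    """Mapping from each histology slide to a US elevation index."""

    specimen: str
    length: float  # annotated specimen length along z in US, mm
    n_slides: int
    matches: list[SlideMatch] = field(default_factory=list)
    scale_ratio: float = 1.0  # US / histology inter-fiducial distance ratio

    def __post_init__(self) -> None:
        indices = [m.us_index for m in self.matches]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(
                f"matched US indices must be strictly increasing, got {indices}"
            )

    def index_for(self, slide: int) -> int:
        for m in self.matches:
            if m.slide == slide:
                return m.us_index
        raise KeyError(f"no match recorded for slide {slide}")


def nominal_positions(volume: LabelVolume, n_slides: int) -> np.ndarray:
    """Nominal slide-center elevations (mm, world coordinates).

    The specimen's z-extent [z_min, z_max] of length L is divided into
    ``n_slides`` equal sections; centers sit at z_min + (i - 0.5) L / M.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    z_min, z_max = volume.specimen_z_extent()  # raises on empty specimen
    length = z_max - z_min
    i = np.arange(1, n_slides + 1)
    return z_min + (i - 0.5) * length / n_slides


# ---------------------------------------------------------------------------
# fiducial profiles


def _plane_profile(plane: np.ndarray, spacing_xy) -> Optional[np.ndarray]:
    """Sorted (descending) pairwise centroid distances of fiducial
    cross-sections in one 2D label image [row=y, col=x]; None if < 2."""
    fid = plane == LABEL_FIDUCIAL
    labeled, n = ndimage.label(fid)
    if n < 2:
        return None
    sizes = ndimage.sum_labels(fid, labeled, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= _MIN_COMPONENT_PIXELS) + 1
    if len(keep) < 2:
        return None
    coms = ndimage.center_of_mass(fid, labeled, keep)  # (row, col)
    px, py = (float(s) for s in spacing_xy)
    pts = np.array([(c[1] * px, c[0] * py) for c in coms])
    dists = [
        float(np.linalg.norm(pts[a] - pts[b]))
        for a, b in itertools.combinations(range(len(pts)), 2)
    ]
    return np.sort(np.asarray(dists))[::-1]


def fiducial_profile(obj, spacing=None):
    """Inter-fiducial distance profile(s), ordering-invariant (sorted).

    * For a :class:`LabelVolume`: dict {z index -> sorted distances or
      None} over all elevations.
    * For a :class:`Slide` (``spacing`` = (px, py) mm required): sorted
      distances of the fiducial holes, or None if fewer than two.
    """
    if isinstance(obj, LabelVolume):
        px, py = obj.spacing[0], obj.spacing[1]
        return {
            k: _plane_profile(obj.plane(k), (px, py)) for k in range(obj.shape[2])
        }
    if isinstance(obj, Slide):
        if spacing is None:
            raise ValueError("pixel spacing required for a slide profile")
        return _plane_profile(np.asarray(obj.mask), spacing)
    raise TypeError(f"cannot profile object of type {type(obj).__name__}")


def _smoothed_profiles(profiles: dict[int, Optional[np.ndarray]]):
    """Average each elevation's profile with its immediate neighbors.

    Fiducial axes are straight, so inter-fiducial distances vary linearly
    with z and a +/-1-slice moving average reduces centroid noise without
    biasing the profile."""
    out: dict[int, Optional[np.ndarray]] = {}
    for k, prof in profiles.items():
        if prof is None:
            out[k] = None
            continue
        stackable = [prof]
        for kk in (k - 1, k + 1):
            other = profiles.get(kk)
            if other is not None and len(other) == len(prof):
                stackable.append(other)
        out[k] = np.mean(stackable, axis=0)
    return out


def _profile_residual(us_d: np.ndarray, slide_d: np.ndarray) -> float:
    m = min(len(us_d), len(slide_d))
    rms = float(np.sqrt(np.mean((us_d[:m] - slide_d[:m]) ** 2)))
    return rms + _COUNT_PENALTY * abs(len(us_d) - len(slide_d))


# ---------------------------------------------------------------------------
# matching


def match_slides(
    volume: LabelVolume,
    stack: SlideStack,
    window: float = 4.0,
    specimen: str = "specimen",
) -> SliceCorrespondence:
    """Match every histology slide to a US elevation index.

    ``window`` is the search half-width (mm) around each slide's nominal
    position; the default of one slice thickness covers the sectioning
    uncertainty.
    """
    if len(stack) == 0:
        raise ValueError("empty slide stack")
    if window <= 0:
        raise ValueError("window must be > 0")

    n = len(stack)
    nominal = nominal_positions(volume, n)
    z_min, z_max = volume.specimen_z_extent()

    us_profiles = _smoothed_profiles(fiducial_profile(volume))
    slide_profiles = [
        fiducial_profile(s, spacing=stack.pixel_spacing) for s in stack
    ]

    # candidate elevations per slide
    z_of = volume.z_world(np.arange(volume.shape[2]))
    candidates: list[np.ndarray] = []
    for i in range(n):
        ks = np.flatnonzero(
            (np.abs(z_of - nominal[i]) <= window) & (z_of >= z_min) & (z_of <= z_max)
        )
        if ks.size == 0:
            ks = np.array([volume.z_index(nominal[i])])
        candidates.append(ks)

    def estimate_scale(positions: list[int]) -> float:
        """Bulk shrinkage compensation: US / histology ratio of the mean
        inter-fiducial distance, sampled at the current match positions
        so both means weight the material identically."""
        us_vals: list[np.ndarray] = []
        slide_vals: list[np.ndarray] = []
        for i in range(n):
            prof = slide_profiles[i]
            us_prof = us_profiles.get(positions[i])
            if prof is None or us_prof is None:
                continue
            m = min(len(prof), len(us_prof))
            us_vals.append(us_prof[:m])
            slide_vals.append(prof[:m])
        if us_vals and np.concatenate(slide_vals).mean() > 0:
            return float(np.concatenate(us_vals).mean()
                         / np.concatenate(slide_vals).mean())
        return 1.0

    # Iterate scale estimation and matching: the scale fixes the expected
    # inter-slide spacing in US space (slice_thickness x scale) and the
    # profile rescaling; matched positions in turn refine the scale.
    positions = [volume.z_index(nominal[i]) for i in range(n)]
    scale = 1.0
    chosen = None
    costs: list[np.ndarray] = []
    fallback: list[bool] = []
    for _ in range(3):
        scale = estimate_scale(positions)
        # Reconstructed section centers: the specimen is cut into n equal
        # sections, so slide i is centered at (i + 0.5)/n of the extent.
        # The voxelized extent clips the specimen tips by about half a
        # slice spacing on each end; correct for that here.
        dz_half = 0.5 * volume.spacing[2]
        z_lo, z_hi = z_min - dz_half, z_max + dz_half
        calib = z_lo + (np.arange(n) + 0.5) * (z_hi - z_lo) / n
        costs = []
        fallback = []
        for i in range(n):
            ks = candidates[i]
            prof = slide_profiles[i]
            use_fallback = prof is None or all(
                us_profiles[k] is None for k in ks
            )
            if use_fallback:
                # tiny bias toward the higher index so half-way ties agree
                # with LabelVolume.z_index
                cost = _NOMINAL_WEIGHT * np.abs(z_of[ks] - nominal[i]) - 1e-9 * ks
            else:
                scaled = prof * scale
                cost = np.array(
                    [
                        _profile_residual(us_profiles[k], scaled)
                        if us_profiles[k] is not None
                        else np.inf
                        for k in ks
                    ]
                ) + _CALIB_WEIGHT * np.abs(z_of[ks] - calib[i])
            costs.append(cost)
            fallback.append(use_fallback)
        expected = (z_hi - z_lo) / n
        # without any fiducial signal the match is the nominal rule alone
        weight = 0.0 if all(fallback) else _SPACING_WEIGHT
        chosen = _monotone_assignment(candidates, costs, z_of, expected,
                                      spacing_weight=weight)
        if chosen is None:
            raise ValueError(
                "no strictly increasing assignment of US slices exists within "
                f"the search windows for slides {list(range(n))}; widen the window"
            )
        new_positions = [int(candidates[i][chosen[i]]) for i in range(n)]
        if new_positions == positions:
            break
        positions = new_positions

    matches = []
    for i, j in enumerate(chosen):
        k = int(candidates[i][j])
        residual = None if fallback[i] else float(costs[i][j])
        matches.append(
            SlideMatch(
                slide=stack.slides[i].index,
                nominal_z=float(nominal[i]),
                us_index=k,
                residual=residual,
                window=float(window),
            )
        )
    return SliceCorrespondence(
        specimen=specimen,
        length=float(z_max - z_min),
        n_slides=n,
        matches=matches,
        scale_ratio=scale,
    )


def _monotone_assignment(candidates, costs, z_of, spacing_mm,
                         spacing_weight=_SPACING_WEIGHT):
    """Choose one candidate per slide minimizing the total cost subject
    to strictly increasing US indices.

    The cost is the per-slide profile residual plus a mild prior that
    consecutive matches should be about one nominal slide spacing apart
    (slices are cut to equal thickness). Returns per-slide candidate
    positions, or None when no increasing assignment exists.
    """
    n = len(candidates)
    dp: list[np.ndarray] = [np.asarray(costs[0], dtype=float).copy()]
    back: list[np.ndarray] = [np.full(len(candidates[0]), -1, dtype=int)]
    for i in range(1, n):
        ks = candidates[i]
        cost = np.asarray(costs[i], dtype=float)
        prev_ks = candidates[i - 1]
        prev_dp = dp[i - 1]
        cur = np.full(len(ks), np.inf)
        bk = np.full(len(ks), -1, dtype=int)
        for j, k in enumerate(ks):
            gaps = z_of[k] - z_of[prev_ks]
            trans = np.where(
                prev_ks < k,
                prev_dp + spacing_weight * np.abs(gaps - spacing_mm),
                np.inf,
            )
            jj = int(np.argmin(trans))
            if np.isfinite(trans[jj]):
                cur[j] = trans[jj] + cost[j]
                bk[j] = jj
        dp.append(cur)
        back.append(bk)
    if not np.isfinite(dp[-1]).any():
        return None
    chosen = [0] * n
    j = int(np.argmin(dp[-1]))
    for i in range(n - 1, -1, -1):
        chosen[i] = j
        j = int(back[i][j])
    return chosen


# ---------------------------------------------------------------------------
# serialization


def write_correspondence(path, corr: SliceCorrespondence) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "specimen": corr.specimen,
        "length_mm": corr.length,
        "n_slides": corr.n_slides,
        "scale_ratio": corr.scale_ratio,
        "matches": [asdict(m) for m in corr.matches],
    }
    path.write_text(json.dumps(payload, indent=2))


def read_correspondence(path) -> SliceCorrespondence:
    data = json.loads(Path(path).read_text())
    return SliceCorrespondence(
        specimen=data["specimen"],
        length=float(data["length_mm"]),
        n_slides=int(data["n_slides"]),
        matches=[SlideMatch(**m) for m in data["matches"]],
        scale_ratio=float(data.get("scale_ratio", 1.0)),
    )
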