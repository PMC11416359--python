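import numpy as np
import pytest
from scipy import ndimage

from sonomargin import measure
from sonomargin.correspondence import match_slides
from sonomargin.model import LABEL_TUMOR, LabelVolume, Slide, SlideStack
from sonomargin.measure import (
    REGION_NAMES,
    end_margins_histology,
    end_margins_us,
    measure_histology,
    measure_specimen,
    measure_us,
    partition_resection_surface,
    region_margin,
    tumor_thickness,
)

from conftest import make_phantom


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the EDT implementation paths)


def brute_min_distance(pts_a, pts_b):
    """O(n*m) minimum pairwise Euclidean distance."""
    best = np.inf
    for a in pts_a:
        d = np.sqrt(((pts_b - a) ** 2).sum(axis=1))
        best = min(best, float(d.min()))
    return best


def brute_region_margin(mask, partition, region, spacing):
    px, py = spacing
    rows, cols = np.nonzero(np.asarray(mask) == LABEL_TUMOR)
    tumor = np.column_stack([cols * px, rows * py])
    surf_idx = partition.region_pixels(region)
    if len(surf_idx) == 0:
        return None
    surf = np.column_stack([surf_idx[:, 1] * px, surf_idx[:, 0] * py])
    return brute_min_distance(tumor, surf)


def brute_tumor_thickness(mask, partition, spacing):
    px, py = spacing
    rows, cols = np.nonzero(np.asarray(mask) == LABEL_TUMOR)
    proj = [
        float(np.dot((c * px, r * py), partition.chord_normal))
        for r, c in zip(rows, cols)
    ]
    return max(proj) - min(proj)


def brute_end_margins(volume, cap_depth=0.5):
    from sonomargin.measure import _cap_surface

    dx, dy, dz = volume.spacing
    ti, tj, tk = np.nonzero(volume.voxels == LABEL_TUMOR)
    tumor = np.column_stack([ti * dx, tj * dy, tk * dz])
    out = []
    for cap in _cap_surface(volume, cap_depth):
        ci, cj, ck = np.nonzero(cap)
        pts = np.column_stack([ci * dx, cj * dy, ck * dz])
        out.append(brute_min_distance(tumor, pts))
    return tuple(out)


# ---------------------------------------------------------------------------
# constructed geometries


def square_slice(spacing=0.5):
    """Rectangular tissue (width = 2 x height), mucosa along the top edge,
    edges at the top corners: the +/-45-degree rays from the chord
    midpoint then exit exactly through the bottom corners, so the bottom
    edge is deep and the lateral edges are cranial/caudal."""
    h, w = 21, 41
    mask = np.zeros((h + 10, w + 10), dtype=np.uint8)
    mask[5 : 5 + h, 5 : 5 + w] = 1
    mask[12:17, 22:28] = LABEL_TUMOR
    edges = np.array(
        [[5 * spacing, 5 * spacing], [(4 + w) * spacing, 5 * spacing]]
    )
    return mask, edges, (spacing, spacing)


class TestPartition:
    def test_rectangle_regions(self):
        mask, edges, spacing = square_slice()
        part = partition_resection_surface(mask, edges, "cranial_right", spacing)
        rows, cols = part.indices[:, 0], part.indices[:, 1]
        top, bottom = rows.min(), rows.max()
        left, right = cols.min(), cols.max()
        labels = part.labels
        # top edge (interior of it) is mucosa
        top_interior = (rows == top) & (cols > left + 1) & (cols < right - 1)
        assert set(labels[top_interior]) == {"mucosa"}
        # bottom edge is deep (up to the 45-degree corner pixels)
        bot_interior = (rows == bottom) & (cols > left + 2) & (cols < right - 2)
        assert set(labels[bot_interior]) == {"deep"}
        # lateral edges are cranial (right, +x) / caudal, corners excluded
        lateral = (rows > top) & (rows < bottom - 1)
        assert set(labels[(cols == right) & lateral]) == {"cranial"}
        assert set(labels[(cols == left) & lateral]) == {"caudal"}

    def test_mirror_swaps_cranial_caudal(self):
        mask, edges, spacing = square_slice()
        part = partition_resection_surface(mask, edges, "cranial_right", spacing)
        w = mask.shape[1]
        mirrored = mask[:, ::-1].copy()
        px = spacing[0]
        mirrored_edges = edges.copy()
        mirrored_edges[:, 0] = (w - 1) * px - edges[:, 0]
        part_m = partition_resection_surface(
            mirrored, mirrored_edges, "cranial_left", spacing
        )
        for region, mirror_region in (("cranial", "cranial"), ("caudal", "caudal"),
                                      ("deep", "deep"), ("mucosa", "mucosa")):
            a = {tuple(i) for i in part.region_pixels(region)} if region != "mucosa" \
                else {tuple(i) for i in part.indices[part.labels == "mucosa"]}
            b_idx = part_m.indices[part_m.labels == mirror_region]
            b = {(r, w - 1 - c) for r, c in b_idx}
            assert a == b

    @pytest.mark.parametrize("seed", [6, 8])
    def test_union_disjoint_invariant_on_phantom_slices(self, seed):
        spec = make_phantom(seed)
        stack = spec.stack
        audited = 0
        for slide in stack:
            if not slide.has_tumor() or slide.mucosal_edges is None:
                continue
            part = partition_resection_surface(
                slide.mask, slide.mucosal_edges, stack.orientation,
                stack.pixel_spacing,
            )
            counts = sum(
                len(part.indices[part.labels == name])
                for name in ("mucosa",) + REGION_NAMES
            )
            assert counts == len(part.indices)  # disjoint + exhaustive
            audited += 1
        assert audited >= 3

    def test_coincident_edges_rejected(self):
        mask, edges, spacing = square_slice()
        edges[1] = edges[0]
        with pytest.raises(ValueError, match="coincide"):
            partition_resection_surface(mask, edges, "cranial_right", spacing)

    def test_edge_far_from_boundary_rejected(self):
        mask, edges, spacing = square_slice()
        edges[0] = [50.0, 50.0]
        with pytest.raises(ValueError, match="boundary"):
            partition_resection_surface(mask, edges, "cranial_right", spacing)

    def test_rotation_invariance(self):
        mask, edges, spacing = square_slice()
        part = partition_resection_surface(mask, edges, "cranial_right", spacing)
        base = {
            region: region_margin(mask, part, region, spacing)
            for region in REGION_NAMES
        }
        base["TT"] = tumor_thickness(mask, part, spacing)

        angle = 30.0
        rot = ndimage.rotate(mask, angle, order=0, reshape=True, cval=0)
        theta = np.deg2rad(-angle)  # image rotation is clockwise in xy
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        px = spacing[0]
        center_old = (np.array(mask.shape[::-1]) - 1) / 2 * px
        center_new = (np.array(rot.shape[::-1]) - 1) / 2 * px
        edges_rot = (edges - center_old) @ R.T + center_new
        cranial_rot = R @ np.array([1.0, 0.0])
        part_rot = partition_resection_surface(rot, edges_rot, cranial_rot, spacing)
        tol = float(np.hypot(*spacing))
        for region in REGION_NAMES:
            got = region_margin(rot, part_rot, region, spacing)
            assert got == pytest.approx(base[region], abs=tol)
        assert tumor_thickness(rot, part_rot, spacing) == pytest.approx(
            base["TT"], abs=tol
        )


class TestRegionMargin:
    def test_adjacent_tumor_one_pixel_pitch(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:18, 2:18] = 1
        mask[16, 8:12] = LABEL_TUMOR  # one row above the bottom boundary row
        edges = np.array([[2 * 0.5, 2 * 0.5], [17 * 0.5, 2 * 0.5]])
        part = partition_resection_surface(mask, edges, "cranial_right",
                                           (0.5, 0.5))
        assert region_margin(mask, part, "deep", (0.5, 0.5)) == pytest.approx(0.5)

    def test_disk_in_disk_margins_equal(self):
        size, spacing = 101, 0.25
        yy, xx = np.mgrid[0:size, 0:size]
        center = (size - 1) / 2
        rr = np.hypot(yy - center, xx - center)
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[rr <= 45] = 1
        mask[rr <= 20] = LABEL_TUMOR
        # mucosal edges at the top, symmetric about the vertical axis
        phi = np.deg2rad(50)
        e = np.array(
            [
                [center - 45 * np.sin(phi), center - 45 * np.cos(phi)],
                [center + 45 * np.sin(phi), center - 45 * np.cos(phi)],
            ]
        ) * spacing
        part = partition_resection_surface(mask, e, "cranial_right",
                                           (spacing, spacing))
        margins = [
            region_margin(mask, part, region, (spacing, spacing))
            for region in REGION_NAMES
        ]
        tol = float(np.hypot(spacing, spacing))
        assert max(margins) - min(margins) <= tol

    def test_unknown_region(self):
        mask, edges, spacing = square_slice()
        part = partition_resection_surface(mask, edges, "cranial_right", spacing)
        with pytest.raises(ValueError, match="region"):
            region_margin(mask, part, "medial", spacing)

    def test_equals_brute_force_on_phantom_slices(self):
        checked = 0
        for seed in (6, 8):
            spec = make_phantom(seed)
            stack = spec.stack
            for slide in stack:
                if not slide.has_tumor() or slide.mucosal_edges is None:
                    continue
                part = partition_resection_surface(
                    slide.mask, slide.mucosal_edges, stack.orientation,
                    stack.pixel_spacing,
                )
                for region in REGION_NAMES:
                    got = region_margin(slide.mask, part, region,
                                        stack.pixel_spacing)
                    expected = brute_region_margin(slide.mask, part, region,
                                                   stack.pixel_spacing)
                    if expected is None:
                        assert got is None
                    else:
                        assert got == pytest.approx(expected, abs=1e-9)
                        checked += 1
        assert checked >= 20

    def test_monotone_under_tumor_dilation(self):
        spec = make_phantom(6)
        stack = spec.stack
        slide = next(s for s in stack if s.has_tumor())
        part = partition_resection_surface(
            slide.mask, slide.mucosal_edges, stack.orientation,
            stack.pixel_spacing,
        )
        base = {
            r: region_margin(slide.mask, part, r, stack.pixel_spacing)
            for r in REGION_NAMES
        }
        tissue = (slide.mask == 1) | (slide.mask == LABEL_TUMOR)
        grown = slide.mask.copy()
        dilated = ndimage.binary_dilation(slide.mask == LABEL_TUMOR,
                                          iterations=3) & tissue
        grown[dilated] = LABEL_TUMOR
        for r in REGION_NAMES:
            after = region_margin(grown, part, r, stack.pixel_spacing)
            if base[r] is not None:
                assert after <= base[r] + 1e-9

    def test_region_margin_bounds_unconstrained_minimum(self):
        spec = make_phantom(8)
        stack = spec.stack
        for slide in stack:
            if not slide.has_tumor():
                continue
            part = partition_resection_surface(
                slide.mask, slide.mucosal_edges, stack.orientation,
                stack.pixel_spacing,
            )
            px, py = stack.pixel_spacing
            rows, cols = np.nonzero(slide.mask == LABEL_TUMOR)
            tumor = np.column_stack([cols * px, rows * py])
            non_mucosa = part.points[part.labels != "mucosa"]
            unconstrained = brute_min_distance(tumor, non_mucosa)
            margins = [
                region_margin(slide.mask, part, r, stack.pixel_spacing)
                for r in REGION_NAMES
            ]
            margins = [m for m in margins if m is not None]
            assert all(m >= unconstrained - 1e-9 for m in margins)
            assert min(margins) == pytest.approx(unconstrained, abs=1e-9)


class TestTumorThickness:
    def test_single_pixel_is_zero_with_warning(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:18, 2:18] = 1
        mask[10, 10] = LABEL_TUMOR
        edges = np.array([[1.0, 1.0], [8.5, 1.0]])
        part = partition_resection_surface(mask, edges, "cranial_right",
                                           (0.5, 0.5))
        with pytest.warns(UserWarning, match="single pixel"):
            assert tumor_thickness(mask, part, (0.5, 0.5)) == 0.0

    def test_rectangle_thickness(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[2:38, 2:38] = 1
        mask[10:21, 8:30] = LABEL_TUMOR  # rows 10..20 -> 10 px * 0.5 = 5 mm
        edges = np.array([[1.0, 1.0], [18.5, 1.0]])  # horizontal chord
        part = partition_resection_surface(mask, edges, "cranial_right",
                                           (0.5, 0.5))
        assert tumor_thickness(mask, part, (0.5, 0.5)) == pytest.approx(5.0)

    def test_equals_brute_force_on_phantom_slices(self):
        spec = make_phantom(6)
        stack = spec.stack
        for slide in stack:
            if not slide.has_tumor():
                continue
            part = partition_resection_surface(
                slide.mask, slide.mucosal_edges, stack.orientation,
                stack.pixel_spacing,
            )
            got = tumor_thickness(slide.mask, part, stack.pixel_spacing)
            expected = brute_tumor_thickness(slide.mask, part,
                                             stack.pixel_spacing)
            assert got == pytest.approx(expected, abs=1e-9)


def _stack_with_flags(flags, thickness=4.0):
    slides = []
    for i, has_tumor in enumerate(flags):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[4:16, 4:16] = 1
        if has_tumor:
            mask[8:12, 8:12] = LABEL_TUMOR
        slides.append(Slide(mask=mask, index=i))
    return SlideStack(slides=slides, pixel_spacing=(0.5, 0.5),
                      slice_thickness=thickness)


class TestEndMarginsHistology:
    @pytest.mark.parametrize(
        "free,expected", [(0, 0.0), (1, 4.0), (3, 12.0)]
    )
    def test_counting_formula(self, free, expected):
        flags = [False] * free + [True, True] + [False]
        anterior, posterior = end_margins_histology(_stack_with_flags(flags))
        assert anterior == pytest.approx(expected)
        assert posterior == pytest.approx(4.0)

    def test_tumor_in_first_slide(self):
        anterior, _ = end_margins_histology(_stack_with_flags([True, False]))
        assert anterior == 0.0

    def test_no_tumor_errors(self):
        with pytest.raises(ValueError, match="no tumor"):
            end_margins_histology(_stack_with_flags([False, False]))

    def test_phantom_within_one_slice_of_truth(self):
        spec = make_phantom(6)
        anterior, posterior = end_margins_histology(spec.stack)
        assert anterior == pytest.approx(spec.truth.histo_anterior, abs=4.0)
        assert posterior == pytest.approx(spec.truth.histo_posterior, abs=4.0)


class TestEndMarginsUS:
    def test_tumor_touching_cap_is_zero(self):
        vox = np.zeros((20, 20, 30), dtype=np.uint8)
        vox[4:16, 4:16, 2:28] = 1
        vox[8:12, 8:12, 2:10] = LABEL_TUMOR  # touches the anterior surface
        volume = LabelVolume(vox, spacing=(0.5, 0.5, 0.5))
        anterior, posterior = end_margins_us(volume)
        assert anterior == 0.0
        assert posterior > 0

    def test_no_tumor_errors(self):
        vox = np.zeros((10, 10, 10), dtype=np.uint8)
        vox[2:8, 2:8, 2:8] = 1
        with pytest.raises(ValueError, match="no tumor"):
            end_margins_us(LabelVolume(vox))

    def test_equals_brute_force(self):
        spec = make_phantom(6, us_spacing=(0.8, 0.8, 1.0))
        got = end_margins_us(spec.volume)
        expected = brute_end_margins(spec.volume)
        assert got[0] == pytest.approx(expected[0], abs=1e-9)
        assert got[1] == pytest.approx(expected[1], abs=1e-9)

    def test_identity_phantom_ends_agree_within_one_slice(self):
        spec = make_phantom(6)
        us = end_margins_us(spec.volume)
        histo = end_margins_histology(spec.stack)
        assert abs(us[0] - histo[0]) <= 4.0
        assert abs(us[1] - histo[1]) <= 4.0


class TestMeasureSpecimen:
    def test_identity_records_agree(self, random_phantom):
        spec = random_phantom
        corr = match_slides(spec.volume, spec.stack, specimen=spec.specimen)
        us = measure_us(spec.volume, corr, spec.landmarks,
                        spec.stack.orientation, specimen=spec.specimen)
        histo = measure_histology(spec.stack, specimen=spec.specimen)
        histo_by_slide = {s.slide: s for s in histo.slices}
        dx, dy, _ = spec.volume.spacing
        tol = 3.0 * float(np.hypot(dx, dy)) + 0.5  # matched-slice offset slack
        compared = 0
        for entry in us.slices:
            other = histo_by_slide.get(entry.slide)
            if other is None:
                continue
            for m in ("TT", "cranial", "deep", "caudal"):
                a, b = getattr(entry, m), getattr(other, m)
                if a is not None and b is not None:
                    assert a == pytest.approx(b, abs=tol), (entry.slide, m)
                    compared += 1
        assert compared >= 12

    def test_dispatch(self, random_phantom):
        spec = random_phantom
        rec = measure_specimen(spec.stack, specimen=spec.specimen)
        assert rec.modality == "histology"
        with pytest.raises(TypeError):
            measure_specimen(42)

    def test_no_tumor_specimen_errors(self):
        config_kwargs = dict(tumor_half_axes=(0.0, 0.0, 0.0))
        spec = make_phantom(9, **config_kwargs)
        with pytest.raises(ValueError, match="no tumor"):
            measure_histology(spec.stack)
        corr = match_slides(spec.volume, spec.stack)
        with pytest.raises(ValueError, match="no tumor"):
            measure_us(spec.volume, corr, spec.landmarks,
                       spec.stack.orientation)

    def test_missing_landmarks_error(self, random_phantom):
        spec = random_phantom
        corr = match_slides(spec.volume, spec.stack)
        with pytest.raises(ValueError, match="landmarks"):
            measure_us(spec.volume, corr, {}, spec.stack.orientation)
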