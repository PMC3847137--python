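import numpy as np
import nibabel as nib
import pytest
from shapely.geometry import Point, Polygon

from thoravol.imaging_core import (
    BinaryMask,
    CircularROI,
    PlanarContour,
    VoxelGrid,
    contours_from_json,
    contours_to_json,
    rasterize_contour,
    read_volume,
    roi_pixels,
    rois_from_json,
    rois_to_json,
    write_volume,
)

from conftest import star_polygon


def make_grid(values, spacing=(1.6, 1.6), thickness=8.0, gap=2.0, modality="MR"):
    return VoxelGrid(np.asarray(values, float), spacing, thickness, gap, modality)


class TestVoxelGrid:
    def test_effective_slice_spacing_is_thickness_plus_gap(self):
        g = make_grid(np.ones((2, 4, 4)))
        assert g.effective_slice_spacing_mm == 10.0
        assert g.voxel_volume_mm3 == pytest.approx(1.6 * 1.6 * 10.0)

    @pytest.mark.parametrize("bad", [
        dict(values=np.ones((4, 4))),                      # non-3-D
        dict(values=np.ones((0, 4, 4))),                   # empty
        dict(values=np.ones((2, 4, 4)), spacing=(0, 1.6)),  # zero spacing
        dict(values=-np.ones((2, 4, 4))),                  # negative MR
        dict(values=np.full((2, 4, 4), np.nan)),           # non-finite
    ])
    def test_invariant_violations_rejected(self, bad):
        values = bad.pop("values")
        with pytest.raises(ValueError):
            make_grid(values, **bad)

    def test_ct_may_be_negative(self):
        g = make_grid(np.full((2, 4, 4), -1000.0), modality="CT")
        assert g.values.min() == -1000.0


class TestNiftiRoundTrip:
    def test_values_spacings_and_modality_survive(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 4000, (3, 10, 12)).astype(np.int16)
        grid = VoxelGrid(data, (1.6, 1.6), 8.0, 2.0, "MR")
        path = tmp_path / "vol.nii.gz"
        write_volume(grid, path)
        back = read_volume(path)
        assert np.array_equal(back.values, data)
        assert back.pixel_spacing_mm == (1.6, 1.6)
        assert back.slice_thickness_mm == 8.0
        assert back.slice_gap_mm == 2.0
        assert back.modality == "MR"

    def test_written_zooms_encode_effective_spacing(self, tmp_path):
        grid = make_grid(np.ones((2, 6, 6)))
        path = tmp_path / "vol.nii"
        write_volume(grid, path)
        zooms = nib.load(str(path)).header.get_zooms()[:3]  # independent reader
        assert zooms == pytest.approx((10.0, 1.6, 1.6))

    def test_foreign_nifti_zooms_become_spacings(self, tmp_path):
        img = nib.Nifti1Image(np.ones((4, 8, 8), np.float32), np.eye(4))
        img.header.set_zooms((10.0, 1.6, 1.6))
        path = tmp_path / "foreign.nii"
        nib.save(img, str(path))
        grid = read_volume(path, modality="MR")
        assert grid.effective_slice_spacing_mm == pytest.approx(10.0)
        assert grid.pixel_spacing_mm == pytest.approx((1.6, 1.6))

    def test_non_3d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.ones((5, 5), np.float32), np.eye(4))
        path = tmp_path / "flat.nii"
        nib.save(img, str(path))
        with pytest.raises(ValueError, match="non-3-D"):
            read_volume(path)


class TestContour:
    def test_needs_three_vertices_and_area(self):
        with pytest.raises(ValueError):
            PlanarContour(0, [[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            PlanarContour(0, [[0, 0], [1, 1], [2, 2]])  # collinear, zero area

    def test_self_intersection_rejected(self):
        bowtie = [[0, 0], [4, 4], [0, 4], [4, 0]]
        with pytest.raises(ValueError, match="self-intersect"):
            PlanarContour(0, bowtie)


class TestRasterization:
    def test_axis_aligned_square_counts_interior_centers(self):
        ct = PlanarContour(0, [[0.5, 0.5], [0.5, 4.5], [4.5, 4.5], [4.5, 0.5]])
        mask = rasterize_contour(ct, (1, 10, 10))
        assert mask.count() == 16  # centers 1..4 x 1..4
        assert mask.values[0, 1:5, 1:5].all()

    def test_only_named_slice_is_marked(self):
        ct = PlanarContour(2, [[0.5, 0.5], [0.5, 4.5], [4.5, 4.5], [4.5, 0.5]])
        mask = rasterize_contour(ct, (4, 10, 10))
        assert mask.values[2].sum() == 16
        assert mask.values[[0, 1, 3]].sum() == 0

    def test_full_frame_rectangle_saturates_slice(self):
        ct = PlanarContour(0, [[-0.5, -0.5], [-0.5, 9.5], [9.5, 9.5], [9.5, -0.5]])
        mask = rasterize_contour(ct, (1, 10, 10))
        assert mask.values[0].all()

    def test_out_of_bounds_vertices_rejected(self):
        ct = PlanarContour(0, [[20, 20], [25, 20], [22, 25]])
        with pytest.raises(ValueError, match="outside"):
            rasterize_contour(ct, (1, 10, 10))

    def test_matches_point_in_polygon_oracle_on_random_polygons(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            verts = star_polygon(rng, rng.integers(3, 12), (20.0, 20.0), 3.0, 17.0)
            ct = PlanarContour(0, verts)
            mask = rasterize_contour(ct, (1, 40, 40)).values[0]
            poly = Polygon([(c, r) for r, c in verts])
            for r in range(40):
                for c in range(40):
                    assert mask[r, c] == poly.contains(Point(c, r)), (r, c)

    def test_reversed_vertex_order_gives_identical_mask(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            verts = star_polygon(rng, 8, (16.0, 16.0), 3.0, 13.0)
            ct = PlanarContour(0, verts)
            fwd = rasterize_contour(ct, (1, 32, 32)).values
            rev = rasterize_contour(ct.reversed(), (1, 32, 32)).values
            assert np.array_equal(fwd, rev)


class TestRoiPixels:
    def test_subpixel_disc_returns_single_pixel(self):
        vals = np.arange(32.0).reshape(2, 4, 4)
        grid = make_grid(vals, spacing=(8.0, 8.0))
        roi = CircularROI(1, (2.0, 1.0), 5.0)
        out = roi_pixels(roi, grid)
        assert out.tolist() == [vals[1, 2, 1]]

    def test_constant_field_returns_constant(self):
        grid = make_grid(np.full((1, 20, 20), 100.0))
        out = roi_pixels(CircularROI(0, (10.0, 10.0), 8.0), grid)
        assert np.all(out == 100.0)

    def test_membership_matches_brute_force_distance(self):
        rng = np.random.default_rng(1)
        grid = make_grid(rng.normal(100, 5, (1, 30, 30)))
        roi = CircularROI(0, (14.3, 16.7), 8.0)
        got = np.sort(roi_pixels(roi, grid))
        expect = []
        for r in range(30):
            for c in range(30):
                d2 = ((r - 14.3) * 1.6) ** 2 + ((c - 16.7) * 1.6) ** 2
                if d2 <= 4.0 ** 2:
                    expect.append(grid.values[0, r, c])
        assert np.array_equal(got, np.sort(expect))

    def test_disc_beyond_image_rejected(self):
        grid = make_grid(np.ones((1, 10, 10)))
        with pytest.raises(ValueError, match="beyond"):
            roi_pixels(CircularROI(0, (0.0, 5.0), 8.0), grid)

    def test_diameter_bounds_enforced(self):
        with pytest.raises(ValueError, match="diameter"):
            CircularROI(0, (5.0, 5.0), 12.0)


class TestJsonInterfaces:
    def test_contour_and_roi_round_trip(self, tmp_path):
        cts = [PlanarContour(1, [[0.5, 0.5], [0.5, 4.5], [4.5, 2.0]])]
        rois = [CircularROI(0, (3.0, 4.0), 6.0)]
        contours_to_json(cts, tmp_path / "c.json")
        rois_to_json(rois, tmp_path / "r.json")
        cts2 = contours_from_json(tmp_path / "c.json")
        rois2 = rois_from_json(tmp_path / "r.json")
        assert np.array_equal(cts2[0].vertices, cts[0].vertices)
        assert cts2[0].slice_index == 1
        assert rois2[0].center == (3.0, 4.0)
        assert rois2[0].diameter_mm == 6.0


class TestBinaryMask:
    def test_set_algebra_and_shape_check(self):
        a = BinaryMask(np.zeros((1, 2, 2), bool))
        b = BinaryMask(np.ones((1, 2, 2), bool))
        assert (a | b).count() == 4
        assert (b - b).count() == 0
        with pytest.raises(ValueError, match="shape"):
            a & BinaryMask(np.ones((2, 2, 2), bool))
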