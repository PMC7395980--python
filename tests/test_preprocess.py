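"""Resampling, consensus fusion, and cube extraction."""

import numpy as np
import pytest

from mvsir.errors import ConfigurationError
from mvsir.labeling import SliceAnnotation, rasterize_polygon
from mvsir.preprocess import (VolumeImage, consensus_mask, extract_cube,
                              load_cube, load_volume, resample_isotropic,
                              save_cube, save_volume)


def square(y0, x0, side):
    return np.array([[y0, x0], [y0 + side, x0], [y0 + side, x0 + side],
                     [y0, x0 + side]], dtype=float)


class TestResample:
    def test_identity_when_spacing_already_matches(self):
        vol = VolumeImage(np.random.default_rng(0).normal(size=(4, 5, 6)))
        out = resample_isotropic(vol, (1, 1, 1))
        assert out.shape == vol.shape
        assert np.array_equal(out.data, vol.data)

    def test_2mm_axis_doubles_and_preserves_extent(self):
        vol = VolumeImage(np.zeros((10, 10, 10)), spacing=(2.0, 1.0, 1.0))
        out = resample_isotropic(vol)
        assert out.shape == (20, 10, 10)
        # physical extent preserved within one voxel per axis
        assert abs(out.shape[0] * 1.0 - vol.shape[0] * 2.0) <= 1.0

    def test_ramp_matches_independent_resampler(self):
        """Cross-check trilinear resampling against SimpleITK on a ramp."""
        sitk = pytest.importorskip("SimpleITK")
        data = np.arange(10, dtype=float)[:, None, None] * np.ones((10, 8, 8))
        vol = VolumeImage(data, spacing=(2.0, 1.0, 1.0))
        ours = resample_isotropic(vol)

        img = sitk.GetImageFromArray(data)
        img.SetSpacing((1.0, 1.0, 2.0))  # sitk order (x, y, z)
        rs = sitk.ResampleImageFilter()
        rs.SetOutputSpacing((1.0, 1.0, 1.0))
        rs.SetSize((8, 8, 20))
        rs.SetInterpolator(sitk.sitkLinear)
        theirs = sitk.GetArrayFromImage(rs.Execute(img))
        # sitk returns its default value past the last voxel centre (z=19 is
        # 19 mm > the 18 mm input extent, where we clamp); compare within it
        assert np.allclose(ours.data[:19], theirs[:19], atol=1e-6)

    def test_constant_volume_stays_constant(self):
        vol = VolumeImage(np.full((6, 6, 6), 3.5), spacing=(1.7, 0.9, 1.3))
        out = resample_isotropic(vol)
        assert np.allclose(out.data, 3.5)

    def test_round_trip_recovers_constant_exactly(self):
        vol = VolumeImage(np.full((6, 6, 6), -2.0), spacing=(2.0, 2.0, 2.0))
        back = resample_isotropic(resample_isotropic(vol), (2.0, 2.0, 2.0))
        assert back.shape == vol.shape
        assert np.array_equal(back.data, vol.data)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ConfigurationError):
            resample_isotropic(VolumeImage(np.zeros((2, 2, 2))), (1, 0, 1))


class TestConsensus:
    GRID = (3, 20, 20)

    def test_four_identical_readers_equal_single_rasterization(self):
        poly = square(4, 4, 8)
        anns = [SliceAnnotation(r, 1, poly) for r in range(4)]
        cons = consensus_mask(anns, self.GRID)
        expected = rasterize_polygon(poly, self.GRID[1:])
        assert np.array_equal(cons[1], expected)
        assert not cons[0].any() and not cons[2].any()

    def test_single_reader_is_its_own_consensus(self):
        poly = square(2, 2, 6)
        cons = consensus_mask([SliceAnnotation(0, 0, poly)], self.GRID)
        assert np.array_equal(cons[0], rasterize_polygon(poly, self.GRID[1:]))

    def test_nested_squares_majority_vote_matches_per_voxel_oracle(self):
        inner, outer = square(6, 6, 6), square(3, 3, 12)
        anns = ([SliceAnnotation(r, 0, inner) for r in (0, 1)] +
                [SliceAnnotation(r, 0, outer) for r in (2, 3)])
        cons = consensus_mask(anns, self.GRID)
        # oracle: per-voxel vote over the four rasterized masks
        votes = (2 * rasterize_polygon(inner, self.GRID[1:]).astype(int) +
                 2 * rasterize_polygon(outer, self.GRID[1:]).astype(int))
        assert np.array_equal(cons[0], votes >= 2)
        # the small square (4/4 votes) is always in; the ring has 2/4 = tie -> in
        assert np.array_equal(cons[0], rasterize_polygon(outer, self.GRID[1:]))

    def test_superset_reader_never_shrinks_consensus(self):
        inner, outer = square(6, 6, 6), square(3, 3, 12)
        anns = [SliceAnnotation(r, 0, inner) for r in range(3)]
        before = consensus_mask(anns, self.GRID, n_readers=3)
        after = consensus_mask(anns + [SliceAnnotation(3, 0, outer)],
                               self.GRID, n_readers=4)
        assert not (before & ~after).any()

    def test_empty_annotations_rejected(self):
        with pytest.raises(ConfigurationError):
            consensus_mask([], self.GRID)

    def test_self_intersecting_polygon_names_reader_and_slice(self):
        bowtie = np.array([[0, 0], [10, 10], [0, 10], [10, 0]], dtype=float)
        with pytest.raises(ConfigurationError, match="reader 2.*slice 1"):
            consensus_mask([SliceAnnotation(2, 1, bowtie)], self.GRID)


class TestExtractCube:
    def test_ten_voxel_pad_gives_thirty_voxel_extent(self):
        vol = VolumeImage(np.zeros((40, 40, 40)))
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[15:25, 15:25, 15:25] = True  # bbox spans 10 voxels per axis
        cube = extract_cube(vol, mask, pad=10)
        assert cube.shape == (30, 30, 30)
        assert cube.offset == (5, 5, 5)
        assert cube.pad_faces == ((10, 10),) * 3

    def test_zero_pad_is_tight_bbox(self):
        vol = VolumeImage(np.arange(27.0).reshape(3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1:3, 0:2] = True
        cube = extract_cube(vol, mask, pad=0)
        assert cube.shape == (1, 2, 2)
        assert np.array_equal(cube.data, vol.data[1:2, 1:3, 0:2])

    def test_edge_clipping_records_effective_pad(self):
        vol = VolumeImage(np.random.default_rng(1).normal(size=(12, 12, 12)))
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[0:3, 4:7, 9:12] = True
        cube = extract_cube(vol, mask, pad=4)
        # brute-force crop: clip the padded box to the volume
        assert cube.offset == (0, 0, 5)
        assert cube.shape == (7, 11, 7)
        assert cube.pad_faces == ((0, 4), (4, 4), (4, 0))
        assert np.array_equal(cube.data, vol.data[0:7, 0:11, 5:12])

    def test_consensus_mask_zero_in_unclipped_pad_band(self, clean_cube):
        for axis in range(3):
            lo, hi = clean_cube.pad_faces[axis]
            sl = [slice(None)] * 3
            if lo:
                sl[axis] = slice(0, lo)
                assert not clean_cube.consensus_mask[tuple(sl)].any()
            if hi:
                sl[axis] = slice(-hi, None)
                assert not clean_cube.consensus_mask[tuple(sl)].any()

    def test_offset_addresses_valid_source_subbox(self, clean_case, clean_cube):
        src = clean_case.volume.data
        sl = tuple(slice(o, o + n) for o, n in zip(clean_cube.offset,
                                                   clean_cube.shape))
        assert np.array_equal(src[sl], clean_cube.data)

    def test_empty_mask_rejected(self):
        vol = VolumeImage(np.zeros((4, 4, 4)))
        with pytest.raises(ConfigurationError):
            extract_cube(vol, np.zeros((4, 4, 4), dtype=bool))


def test_volume_and_cube_io_round_trip(tmp_path, clean_cube):
    vol = VolumeImage(np.random.default_rng(0).normal(size=(4, 5, 6)).astype(np.float32),
                      spacing=(1.0, 0.7, 0.7), origin=(1, 2, 3))
    save_volume(vol, tmp_path / "v.nii.gz")
    back = load_volume(tmp_path / "v.nii.gz")
    assert np.allclose(back.data, vol.data)
    assert np.allclose(back.spacing, vol.spacing)

    save_cube(clean_cube, tmp_path / "cube")
    cube2 = load_cube(tmp_path / "cube")
    assert np.array_equal(cube2.consensus_mask, clean_cube.consensus_mask)
    assert cube2.offset == clean_cube.offset
    assert cube2.pad_faces == clean_cube.pad_faces
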