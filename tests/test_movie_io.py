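"""Movie loading, temporal downsampling, patch extraction, regions JSON."""

import json

import numpy as np
import pytest
import tifffile

from hnccorr.movie_io import (
    Footprint,
    Movie,
    downsample_temporal,
    extract_patch,
    load_movie,
    read_regions_json,
    write_regions_json,
)


class TestLoadMovie:
    def test_tiff_dir_preserves_frame_count_and_order(self, tmp_path, rng):
        frames = rng.integers(0, 1000, size=(12, 16, 16)).astype(np.uint16)
        for t in range(12):
            tifffile.imwrite(tmp_path / f"image{t:05d}.tif", frames[t])
        movie = load_movie(tmp_path, "tiff-dir")
        assert movie.data.shape == (12, 16, 16)
        np.testing.assert_array_equal(movie.data, frames.astype(float))

    def test_tiff_stack_identical_frames(self, tmp_path):
        frame = np.full((8, 8), 7, dtype=np.uint16)
        tifffile.imwrite(tmp_path / "stack.tif", np.stack([frame] * 5))
        movie = load_movie(tmp_path / "stack.tif", "tiff-stack")
        assert movie.num_frames == 5
        for t in range(5):
            np.testing.assert_array_equal(movie.data[t], movie.data[0])

    def test_raw_array(self, tmp_path, rng):
        arr = rng.normal(size=(4, 5, 6))
        np.save(tmp_path / "movie.npy", arr)
        movie = load_movie(tmp_path / "movie.npy", "raw-array")
        np.testing.assert_allclose(movie.data, arr)

    def test_empty_directory_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="no frames found"):
            load_movie(tmp_path, "tiff-dir")

    def test_inconsistent_shapes_is_an_error(self, tmp_path):
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((4, 4), dtype=np.uint16))
        tifffile.imwrite(tmp_path / "b.tif", np.zeros((5, 5), dtype=np.uint16))
        with pytest.raises(ValueError, match="inconsistent"):
            load_movie(tmp_path, "tiff-dir")

    def test_intensities_promoted_to_float(self, tmp_path):
        tifffile.imwrite(
            tmp_path / "s.tif", np.ones((3, 4, 4), dtype=np.uint16)
        )
        movie = load_movie(tmp_path / "s.tif", "tiff-stack")
        assert np.issubdtype(movie.data.dtype, np.floating)


class TestMovieInvariants:
    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            Movie(data=np.zeros((1, 4, 4)))

    def test_rejects_nonfinite(self):
        data = np.zeros((3, 4, 4))
        data[1, 2, 2] = np.nan
        with pytest.raises(ValueError):
            Movie(data=data)


class TestDownsample:
    def test_frame_count_and_remainder_drop(self, rng):
        movie = Movie(data=rng.normal(size=(25, 4, 4)))
        out = downsample_temporal(movie, 10)
        assert out.num_frames == 2

    def test_output_is_group_mean(self, rng):
        movie = Movie(data=rng.normal(size=(20, 3, 3)))
        out = downsample_temporal(movie, 10)
        np.testing.assert_allclose(out.data[0], movie.data[:10].mean(axis=0))
        np.testing.assert_allclose(out.data[1], movie.data[10:20].mean(axis=0))

    def test_constant_movie_stays_constant(self):
        movie = Movie(data=np.full((30, 2, 2), 3.5))
        out = downsample_temporal(movie, 7)
        np.testing.assert_allclose(out.data, 3.5)

    def test_total_intensity_conserved_up_to_remainder(self, rng):
        movie = Movie(data=rng.uniform(size=(23, 5, 5)))
        factor = 4
        out = downsample_temporal(movie, factor)
        kept = movie.num_frames - movie.num_frames % factor
        np.testing.assert_allclose(
            out.data.sum() * factor, movie.data[:kept].sum()
        )

    def test_factor_one_identity(self, rng):
        movie = Movie(data=rng.normal(size=(5, 3, 3)))
        np.testing.assert_array_equal(downsample_temporal(movie, 1).data, movie.data)

    def test_factor_exceeding_length_is_an_error(self):
        movie = Movie(data=np.zeros((5, 2, 2)))
        with pytest.raises(ValueError):
            downsample_temporal(movie, 6)


class TestExtractPatch:
    @pytest.fixture
    def big_movie(self):
        return Movie(data=np.zeros((2, 512, 512)))

    def test_interior_center(self, big_movie):
        patch = extract_patch(big_movie, (100, 100), 31)
        assert patch.origin == (85, 85)
        assert patch.data.shape == (2, 31, 31)

    def test_boundary_center_shifts_inward(self, big_movie):
        patch = extract_patch(big_movie, (2, 2), 31)
        assert patch.origin == (0, 0)

    @pytest.mark.parametrize("center", [(0, 0), (511, 511), (0, 256), (300, 511)])
    def test_shape_independent_of_center(self, big_movie, center):
        patch = extract_patch(big_movie, center, 31)
        assert patch.data.shape == (2, 31, 31)
        # center always inside the patch
        r, c = patch.to_patch_coords(center)
        assert 0 <= r < 31 and 0 <= c < 31

    def test_even_size_is_an_error(self, big_movie):
        with pytest.raises(ValueError, match="odd"):
            extract_patch(big_movie, (100, 100), 32)

    def test_coordinate_round_trip(self, big_movie):
        patch = extract_patch(big_movie, (10, 500), 31)
        for pix in [(10, 500), (0, 490)]:
            assert patch.to_movie_coords(patch.to_patch_coords(pix)) == pix


class TestRegionsJson:
    def test_read_basic(self, tmp_path):
        path = tmp_path / "regions.json"
        path.write_text(json.dumps([{"coordinates": [[0, 0], [0, 1]]}]))
        fps = read_regions_json(path)
        assert len(fps) == 1
        assert fps[0].pixels == {(0, 0), (0, 1)}

    def test_round_trip_identity(self, tmp_path, rng):
        fps = [
            Footprint(
                pixels=frozenset(
                    (int(r), int(c))
                    for r, c in rng.integers(0, 50, size=(20, 2))
                )
            )
            for _ in range(5)
        ]
        path = tmp_path / "out.json"
        write_regions_json(fps, path)
        back = read_regions_json(path)
        assert [f.pixels for f in back] == [f.pixels for f in fps]

    def test_empty_list(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("[]")
        assert read_regions_json(path) == []

    def test_duplicates_deduplicated(self, tmp_path):
        path = tmp_path / "dup.json"
        path.write_text(json.dumps([{"coordinates": [[1, 1], [1, 1], [2, 2]]}]))
        assert read_regions_json(path)[0].pixels == {(1, 1), (2, 2)}

    def test_out_of_bounds_warns(self, tmp_path):
        path = tmp_path / "oob.json"
        path.write_text(json.dumps([{"coordinates": [[99, 99]]}]))
        with pytest.warns(UserWarning, match="outside"):
            read_regions_json(path, frame_shape=(10, 10))
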