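"""Movie and annotation I/O.

A calcium-imaging movie is a stack of fluorescence frames, indexed
``(t, row, col)`` with 0-based coordinates and rows increasing downward.
All downstream modules share this convention.  Footprints (the per-cell
pixel sets the algorithm outputs) are exchanged as Neurofinder-style
regions JSON: a list of objects each holding a ``"coordinates"`` list of
``[row, col]`` pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Movie",
    "Patch",
    "Footprint",
    "load_movie",
    "downsample_temporal",
    "extract_patch",
    "read_regions_json",
    "write_regions_json",
]


@dataclass(frozen=True)
class Movie:
    """A motion-corrected fluorescence movie.

    Parameters
    ----------
    data:
        Array of shape ``(T, H, W)``; promoted to floating point.
    frame_rate:
        Optional acquisition rate in Hz.  Metadata only; no computation
        depends on it.
    """

    data: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"movie must be 3-D (T, H, W), got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValueError("movie intensities must be finite")
        object.__setattr__(self, "data", arr)

    @property
    def num_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass(frozen=True)
class Patch:
    """An ``m x m`` spatial window of a movie around a seed.

    ``origin`` is the (row, col) of the patch's top-left pixel in movie
    coordinates, so patch pixel ``(r, c)`` is movie pixel
    ``(origin[0] + r, origin[1] + c)``.
    """

    data: np.ndarray
    origin: tuple[int, int]
    m: int

    def __post_init__(self) -> None:
        if self.m % 2 == 0:
            raise ValueError("patch size must be odd")
        if self.data.ndim != 3 or self.data.shape[1:] != (self.m, self.m):
            raise ValueError("patch data must have shape (T, m, m)")

    @property
    def num_pixels(self) -> int:
        return self.m * self.m

    def to_movie_coords(self, pixel: tuple[int, int]) -> tuple[int, int]:
        return pixel[0] + self.origin[0], pixel[1] + self.origin[1]

    def to_patch_coords(self, pixel: tuple[int, int]) -> tuple[int, int]:
        r, c = pixel[0] - self.origin[0], pixel[1] - self.origin[1]
        if not (0 <= r < self.m and 0 <= c < self.m):
            raise ValueError(f"movie pixel {pixel} lies outside the patch")
        return r, c


@dataclass(frozen=True)
class Footprint:
    """The set of (row, col) movie pixels a detected cell occupies."""

    pixels: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        pix = frozenset((int(r), int(c)) for r, c in self.pixels)
        if not pix:
            raise ValueError("footprint must be nonempty")
        object.__setattr__(self, "pixels", pix)

    def __len__(self) -> int:
        return len(self.pixels)

    def __contains__(self, pixel: tuple[int, int]) -> bool:
        return pixel in self.pixels


_TIFF_SUFFIXES = (".tif", ".tiff")


def load_movie(path: str | Path, format: str, frame_rate: float | None = None) -> Movie:
    """Read a movie from disk.

    Supported formats: ``"tiff-stack"`` (one multi-page TIFF),
    ``"tiff-dir"`` (a directory of single-frame TIFFs whose lexicographic
    filename order is the temporal order, the Neurofinder layout) and
    ``"raw-array"`` (a ``.npy`` file holding a (T, H, W) array).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tiff-stack":
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
    elif format == "tiff-dir":
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
        )
        if not files:
            raise ValueError(f"no frames found in {path}")
        frames = [np.asarray(tifffile.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        data = np.stack(frames)
    elif format == "raw-array":
        data = np.load(path)
    else:
        raise ValueError(f"unknown movie format {format!r}")
    return Movie(data=data.astype(np.float64), frame_rate=frame_rate)


def downsample_temporal(movie: Movie, factor: int) -> Movie:
    """Average every ``factor`` consecutive frames into one.

    Trailing frames that do not fill a complete group (``T mod factor``)
    are dropped, so every output frame is the mean of exactly ``factor``
    inputs.  ``factor=1`` returns an identical movie.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    T = movie.num_frames
    if factor > T:
        raise ValueError(f"factor {factor} exceeds movie length {T}")
    if factor == 1:
        return Movie(data=movie.data.copy(), frame_rate=movie.frame_rate)
    T_out = T // factor
    data = movie.data[: T_out * factor].reshape(
        T_out, factor, *movie.frame_shape
    ).mean(axis=1)
    rate = movie.frame_rate / factor if movie.frame_rate else None
    return Movie(data=data, frame_rate=rate)


def extract_patch(movie: Movie, center: tuple[int, int], m: int) -> Patch:
    """Cut the ``m x m`` window centered at ``center`` out of the movie.

    Near the frame border the window is translated by the minimal offset
    that keeps it fully inside (the seed is then off-center but still
    inside the patch); no padding is ever fabricated.
    """
    if m % 2 == 0:
        raise ValueError("patch size must be odd")
    H, W = movie.frame_shape
    if m > min(H, W):
        raise ValueError(f"patch size {m} exceeds frame {H}x{W}")
    r, c = center
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"center {center} outside frame")
    half = m // 2
    top = min(max(r - half, 0), H - m)
    left = min(max(c - half, 0), W - m)
    data = movie.data[:, top : top + m, left : left + m]
    return Patch(data=data, origin=(top, left), m=m)


def read_regions_json(path: str | Path, frame_shape: tuple[int, int] | None = None) -> list[Footprint]:
    """Read Neurofinder-style regions JSON into footprints.

    Duplicate pixels within a region are silently deduplicated; if
    ``frame_shape`` is given, out-of-bounds coordinates trigger a warning
    (they are kept, so the round trip stays lossless).
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError("regions JSON must be a list of region objects")
    footprints = []
    for idx, region in enumerate(raw):
        if "coordinates" not in region:
            raise ValueError(f"region {idx} lacks a 'coordinates' key")
        pixels = frozenset((int(r), int(c)) for r, c in region["coordinates"])
        if frame_shape is not None:
            H, W = frame_shape
            bad = [p for p in pixels if not (0 <= p[0] < H and 0 <= p[1] < W)]
            if bad:
                warnings.warn(
                    f"region {idx}: {len(bad)} coordinate(s) outside {H}x{W} frame"
                )
        footprints.append(Footprint(pixels=pixels))
    return footprints


def write_regions_json(footprints: list[Footprint], path: str | Path) -> None:
    """Write footprints as Neurofinder-style regions JSON (sorted pixels)."""
    payload = [
        {"coordinates": [[int(r), int(c)] for r, c in sorted(fp.pixels)]}
        for fp in footprints
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)
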