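"""Grayscale image I/O: PGM (P2 ASCII / P5 binary) and delimited text
grids, plus intensity-scale handling.

Two scales are supported: ``raw-8bit`` (integral values in [0, 255]) and
``unit`` (reals in [0, 1]).  The gradient threshold is interpreted on
whichever scale is active, so the detection pipeline normalizes 8-bit
input to the unit scale by default.

PGM decoding goes through Pillow, which accepts both dialects and
rescales files with maxval < 255 to 8-bit.  Written PGM always uses
maxval 255 (P5 via Pillow; P2 via a small ASCII formatter, which Pillow
does not provide).  Coordinates in user-facing messages are 1-based
(i = row, j = column), top-left origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import FormatError

__all__ = [
    "RAW_8BIT",
    "UNIT",
    "GrayImage",
    "read_gray",
    "write_gray",
    "write_edges",
    "normalize",
]

RAW_8BIT = "raw-8bit"
UNIT = "unit"
_SCALES = (RAW_8BIT, UNIT)


@dataclass(frozen=True)
class GrayImage:
    """An h x w grid of pixel intensities with an explicit scale."""

    pixels: np.ndarray
    scale: str = RAW_8BIT

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FormatError(f"image must be a non-empty 2-D grid, got {arr.shape}")
        if self.scale not in _SCALES:
            raise FormatError(f"unknown intensity scale {self.scale!r}")
        if self.scale == RAW_8BIT:
            if arr.min() < 0 or arr.max() > 255 or not np.all(arr == np.round(arr)):
                raise FormatError(
                    "raw-8bit image requires integral intensities in [0, 255]"
                )
        else:
            if arr.min() < 0 or arr.max() > 1:
                raise FormatError("unit-scale image requires intensities in [0, 1]")
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.scale == other.scale and np.array_equal(self.pixels, other.pixels)


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("pgm", "csv"):
            raise FormatError(f"unknown image format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix == ".pgm":
        return "pgm"
    if suffix in (".csv", ".txt", ".tsv", ".dat"):
        return "csv"
    raise FormatError(f"cannot infer format from suffix of {path}")


def _read_pgm(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            if im.format != "PPM":
                raise FormatError(f"{path}: not a PGM file (decoded as {im.format})")
            if im.mode == "L":
                return np.asarray(im, dtype=np.float64)
            # 16-bit PGM (maxval > 255): rescale to 8-bit using the header maxval
            arr = np.asarray(im, dtype=np.float64)
            header = path.read_bytes()[:256]
            fields = re.findall(rb"(?:^|\s)#[^\n]*|\S+", header)
            tokens = [f for f in fields if not f.lstrip().startswith(b"#")]
            maxval = int(tokens[3])
            return np.round(arr * (255.0 / maxval))
    except FileNotFoundError:
        raise
    except (UnidentifiedImageError, OSError, SyntaxError, ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed PGM file: {exc}") from exc


def _read_csv(path: Path) -> np.ndarray:
    text = path.read_text()
    first = next((line for line in text.splitlines() if line.strip()), "")
    delimiter = "," if "," in first else None
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed numeric grid: {exc}") from exc
    return arr


def read_gray(
    path: Union[str, Path],
    format: Optional[str] = None,
    scale: Optional[str] = None,
) -> GrayImage:
    """Read a grayscale image.

    ``format`` defaults to the file suffix (``.pgm`` vs ``.csv/.txt``).
    PGM is always raw-8bit.  For delimited text the scale is inferred
    unless given: raw-8bit when any value exceeds 1, otherwise unit.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pgm":
        arr = _read_pgm(path)
        if scale not in (None, RAW_8BIT):
            raise FormatError("PGM files are read on the raw-8bit scale")
        return GrayImage(arr, RAW_8BIT)
    arr = _read_csv(path)
    if scale is None:
        scale = RAW_8BIT if arr.size and arr.max() > 1 else UNIT
    return GrayImage(arr, scale)


def _write_p2(arr: np.ndarray, path: Path) -> None:
    lines = [f"P2", f"{arr.shape[1]} {arr.shape[0]}", "255"]
    lines += [" ".join(str(int(v)) for v in row) for row in arr]
    path.write_text("\n".join(lines) + "\n")


def write_gray(
    image: GrayImage,
    path: Union[str, Path],
    format: Optional[str] = None,
    pgm_dialect: str = "P5",
) -> Path:
    """Write an image; PGM output always uses maxval 255 (unit-scale
    images are converted to raw-8bit first).  Round-trips losslessly at
    matching scale."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pgm":
        raw = normalize(image, RAW_8BIT)
        arr = raw.pixels.astype(np.uint8)
        if pgm_dialect == "P2":
            _write_p2(arr, path)
        elif pgm_dialect == "P5":
            Image.fromarray(arr, mode="L").save(path, format="PPM")
        else:
            raise FormatError(f"unknown PGM dialect {pgm_dialect!r}")
    else:
        fmt_str = "%d" if image.scale == RAW_8BIT else "%.17g"
        np.savetxt(path, image.pixels, fmt=fmt_str, delimiter=",")
    return path


def write_edges(
    edge_map: np.ndarray,
    path: Union[str, Path],
    format: Optional[str] = None,
    pgm_dialect: str = "P5",
) -> Path:
    """Write a binary edge map: {0, 255} as PGM or {0, 1} as text."""
    edge_map = np.asarray(edge_map)
    if not np.isin(edge_map, (0, 1)).all():
        raise FormatError("edge map values must be 0 or 1")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pgm":
        img = GrayImage(edge_map.astype(np.float64) * 255.0, RAW_8BIT)
        return write_gray(img, path, format="pgm", pgm_dialect=pgm_dialect)
    np.savetxt(path, edge_map.astype(int), fmt="%d", delimiter=",")
    return path


def normalize(image: GrayImage, target_scale: str) -> GrayImage:
    """Convert between scales: raw -> unit divides by 255; unit -> raw
    multiplies by 255 and rounds half-up.  Idempotent at the target."""
    if target_scale not in _SCALES:
        raise FormatError(f"unknown intensity scale {target_scale!r}")
    if image.scale == target_scale:
        return image
    if target_scale == UNIT:
        return GrayImage(image.pixels / 255.0, UNIT)
    return GrayImage(np.floor(image.pixels * 255.0 + 0.5), RAW_8BIT)
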