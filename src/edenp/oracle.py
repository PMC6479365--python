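"""Serial gradient-based edge detection (GBED).

The classical pipeline: correlate a mask pair with the image to estimate
directional gradients gx, gy on the interior pixels (borders are 0),
take the magnitude g = sqrt(gx^2 + gy^2), and declare pixel (i,j) an
edge when d = g - theta >= 0.  The boundary case d = 0 counts as an
edge.  Non-maximum suppression is deliberately out of scope.

This module is the independent serial reference that the membrane-based
engine is verified against.  The masks slide without flipping
(correlation, not convolution); term accumulation follows the row-major
order of the non-zero mask coefficients, which :func:`mask_terms` fixes
for both this module and the rule compiler so the two pipelines agree
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "MaskPair",
    "GradientFields",
    "MASKS",
    "get_mask_pair",
    "mask_terms",
    "directional_gradients",
    "gradient_magnitude",
    "threshold_edges",
    "gbed",
    "gradient_fields",
]


@dataclass(frozen=True)
class MaskPair:
    """A horizontal/vertical mask pair.

    ``anchor`` is the (row, col) offset of the window's top-left cell
    relative to the output pixel: (-1, -1) centers a 3x3 window; (0, 0)
    anchors a 2x2 window at its top-left pixel (Roberts convention).
    """

    name: str
    mx: np.ndarray
    my: np.ndarray
    anchor: Tuple[int, int]

    def __post_init__(self):
        if self.mx.shape != self.my.shape:
            raise ValueError("mask pair shapes differ")


def _m(rows) -> np.ndarray:
    a = np.array(rows, dtype=float)
    a.setflags(write=False)
    return a


MASKS = {
    "sobel": MaskPair(
        "sobel",
        mx=_m([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]),
        my=_m([[1, 2, 1], [0, 0, 0], [-1, -2, -1]]),
        anchor=(-1, -1),
    ),
    "prewitt": MaskPair(
        "prewitt",
        mx=_m([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]]),
        my=_m([[1, 1, 1], [0, 0, 0], [-1, -1, -1]]),
        anchor=(-1, -1),
    ),
    "roberts": MaskPair(
        "roberts",
        mx=_m([[-1, 0], [0, 1]]),
        my=_m([[0, -1], [1, 0]]),
        anchor=(0, 0),
    ),
}


def get_mask_pair(name: str) -> MaskPair:
    try:
        return MASKS[name]
    except KeyError:
        raise KeyError(
            f"unknown mask {name!r}; valid masks: {', '.join(sorted(MASKS))}"
        ) from None


def mask_terms(mask: np.ndarray) -> List[Tuple[int, int, float]]:
    """Non-zero mask coefficients as (row_offset, col_offset, coefficient)
    in row-major order.  This order is the contract shared with the rule
    compiler: accumulating terms in it makes the serial and membrane
    pipelines bitwise identical."""
    return [
        (a, b, float(mask[a, b]))
        for a in range(mask.shape[0])
        for b in range(mask.shape[1])
        if mask[a, b] != 0.0
    ]


@dataclass(frozen=True)
class GradientFields:
    """gx, gy directional gradients, magnitude g, difference d = g - theta."""

    gx: np.ndarray
    gy: np.ndarray
    g: np.ndarray
    d: np.ndarray


def _correlate_interior(image: np.ndarray, mask: np.ndarray, anchor) -> np.ndarray:
    """Correlate ``mask`` over the interior pixels (rows/cols 2..n-1,
    1-based); border pixels are 0.  Terms accumulate in mask_terms order."""
    h, w = image.shape
    out = np.zeros((h, w), dtype=np.float64)
    if h < 3 or w < 3:
        return out
    ar, ac = anchor
    acc = None
    for a, b, coeff in mask_terms(mask):
        block = image[1 + ar + a : h - 1 + ar + a, 1 + ac + b : w - 1 + ac + b]
        term = coeff * block
        acc = term if acc is None else acc + term
    out[1 : h - 1, 1 : w - 1] = acc
    return out


def directional_gradients(
    image: np.ndarray, masks: MaskPair
) -> Tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical derivative estimates; borders are 0."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D grid")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(
            f"image {image.shape} is smaller than the 3x3 interior window"
        )
    gx = _correlate_interior(image, masks.mx, masks.anchor)
    gy = _correlate_interior(image, masks.my, masks.anchor)
    return gx, gy


def gradient_magnitude(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Elementwise sqrt(gx^2 + gy^2)."""
    gx = np.asarray(gx, dtype=np.float64)
    gy = np.asarray(gy, dtype=np.float64)
    if gx.shape != gy.shape:
        raise ValueError("gx and gy shapes differ")
    return np.sqrt(gx * gx + gy * gy)


def threshold_edges(g: np.ndarray, theta: float) -> np.ndarray:
    """Binary edge map: 1 where g - theta >= 0 (d = 0 is an edge)."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return (np.asarray(g, dtype=np.float64) - theta >= 0.0).astype(np.uint8)


def gradient_fields(image: np.ndarray, mask_name: str, theta: float) -> GradientFields:
    masks = get_mask_pair(mask_name)
    gx, gy = directional_gradients(image, masks)
    g = gradient_magnitude(gx, gy)
    return GradientFields(gx=gx, gy=gy, g=g, d=g - theta)


def gbed(image: np.ndarray, mask_name: str, theta: float) -> np.ndarray:
    """Full serial pipeline: gradients -> magnitude -> threshold."""
    fields = gradient_fields(image, mask_name, theta)
    return threshold_edges(fields.g, theta)
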