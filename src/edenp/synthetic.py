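"""Seeded synthetic test images with known edge structure.

Every generator is deterministic given its seed, and the noiseless
geometric kinds return an annotation describing the true discontinuity
locus (the rows/columns adjacent to the intensity step), so detection
results can be checked against analytically known edges without any
external image assets.

Intensities are specified on the unit scale [0, 1] (``foreground`` /
``background``); set ``scale="raw-8bit"`` to emit an 8-bit image
instead.  Additive Gaussian noise and salt-and-pepper corruption are
applied after the geometry and truncated to the valid intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .errors import FormatError
from .image_io import RAW_8BIT, UNIT, GrayImage, normalize

__all__ = ["KINDS", "PatternSpec", "generate"]

KINDS = ("constant", "vstep", "hstep", "square", "disk", "ramp", "checker", "noise")


@dataclass(frozen=True)
class PatternSpec:
    """Description of a synthetic image.

    size:
        (rows, cols) or a single integer for a square image.
    background / foreground:
        intensities on the unit scale.
    noise_sd:
        standard deviation of additive Gaussian noise (unit scale).
    salt_pepper_fraction:
        fraction of pixels replaced by 0 or 1 (half each, in expectation).
    """

    kind: str
    size: Union[int, Tuple[int, int]] = 32
    background: float = 0.0
    foreground: float = 1.0
    noise_sd: float = 0.0
    salt_pepper_fraction: float = 0.0
    seed: int = 0
    scale: str = UNIT

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}; valid: {KINDS}")
        size = self.size
        if isinstance(size, int):
            size = (size, size)
        size = (int(size[0]), int(size[1]))
        if size[0] < 1 or size[1] < 1:
            raise ValueError(f"image size must be positive, got {size}")
        object.__setattr__(self, "size", size)
        for name in ("background", "foreground"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside the unit intensity range")
        if self.noise_sd < 0 or not 0.0 <= self.salt_pepper_fraction <= 1.0:
            raise ValueError("noise parameters must be non-negative")


def _geometry(spec: PatternSpec) -> Tuple[np.ndarray, Optional[Dict]]:
    rows, cols = spec.size
    bg, fg = spec.background, spec.foreground
    grid = np.full((rows, cols), bg, dtype=np.float64)
    annotation: Optional[Dict] = None

    if spec.kind == "constant":
        pass
    elif spec.kind == "vstep":
        c = cols // 2  # columns 1..c are background (1-based)
        grid[:, c:] = fg
        annotation = {"kind": "vstep", "columns": (c, c + 1)}
    elif spec.kind == "hstep":
        r = rows // 2
        grid[r:, :] = fg
        annotation = {"kind": "hstep", "rows": (r, r + 1)}
    elif spec.kind == "square":
        r0, r1 = rows // 4, rows - rows // 4  # half-open 0-based block
        c0, c1 = cols // 4, cols - cols // 4
        grid[r0:r1, c0:c1] = fg
        annotation = {
            "kind": "square",
            "rows": (r0 + 1, r1),  # 1-based inclusive foreground bounds
            "cols": (c0 + 1, c1),
        }
    elif spec.kind == "disk":
        cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
        radius = min(rows, cols) / 4.0
        rr, cc_idx = np.mgrid[0:rows, 0:cols]
        inside = (rr - cr) ** 2 + (cc_idx - cc) ** 2 <= radius**2
        grid[inside] = fg
        annotation = {"kind": "disk", "center": (cr + 1, cc + 1), "radius": radius}
    elif spec.kind == "ramp":
        if cols > 1:
            ramp = np.linspace(bg, fg, cols)
            grid[:] = ramp[np.newaxis, :]
    elif spec.kind == "checker":
        block = max(1, min(rows, cols) // 4)
        rr, cc_idx = np.mgrid[0:rows, 0:cols]
        grid[((rr // block) + (cc_idx // block)) % 2 == 1] = fg
        annotation = {"kind": "checker", "block": block}
    elif spec.kind == "noise":
        rng = np.random.default_rng(spec.seed)
        grid = rng.uniform(min(bg, fg), max(bg, fg), size=(rows, cols))
    return grid, annotation


def generate(spec: PatternSpec) -> Tuple[GrayImage, Optional[Dict]]:
    """Generate the image described by ``spec``.

    Returns the image and, for noiseless geometric kinds, an annotation
    of the true discontinuity locus (1-based coordinates); ``None`` for
    textureless or stochastic kinds.
    """
    grid, annotation = _geometry(spec)
    noisy = spec.noise_sd > 0 or spec.salt_pepper_fraction > 0
    if noisy:
        # independent stream from the geometry RNG of the "noise" kind
        rng = np.random.default_rng((int(spec.seed), 1))
        if spec.noise_sd > 0:
            grid = grid + rng.normal(0.0, spec.noise_sd, size=grid.shape)
        if spec.salt_pepper_fraction > 0:
            mask = rng.random(grid.shape) < spec.salt_pepper_fraction
            values = rng.random(grid.shape) < 0.5
            grid = np.where(mask, values.astype(np.float64), grid)
        grid = np.clip(grid, 0.0, 1.0)
        annotation = None
    image = GrayImage(grid, UNIT)
    if spec.scale == RAW_8BIT:
        image = normalize(image, RAW_8BIT)
    elif spec.scale != UNIT:
        raise FormatError(f"unknown intensity scale {spec.scale!r}")
    return image, annotation
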