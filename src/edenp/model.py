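"""EDENP: gradient-based edge detection as a four-membrane ENPS.

The compiler maps an h x w grayscale image onto the nested membrane
structure [[[[ ]1]2]3]4 (membrane 4 is the skin):

* membrane 1 holds gx/gy and the directional-gradient rules — one mask
  rule per interior pixel and per direction, plus zero-production rules
  that pin the border gradients to 0, all gated by the seed enzyme
  e1_1 (initially 256, above any admissible intensity);
* membrane 2 holds g and the magnitude rules g = sqrt(gx^2 + gy^2);
* membrane 3 holds the helper constants ed1=0, ed2=1, ed3=-256, the
  per-pixel enzymes E and ED, the difference rules 2*(g - theta) split
  evenly onto g and E (so both end up holding d = g - theta), the edge
  decision pair (ed1 + 2*ed2 gated by E >= min(ed1, ed2), so it fires
  exactly when d >= 0 and writes edg = 1; its zero-production partner
  gated by E >= min(ed1, ed3) always fires and writes edg = 0
  otherwise), and three constant-refresh rules that keep ed1..ed3 alive
  (identities under the non-consuming policy; they restore the constants
  under the consuming one and complete the 6n^2 + 4 rule count);
* membrane 4 (skin) holds the image x, the output edg, theta, the seed
  enzyme and the halting variable ED, set to 1 by the main rule.

Execution is staged: five scheduled steps (gradients, magnitude,
difference, edge decision, halt) regardless of image size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .core import (
    Configuration,
    ENPSystem,
    ExecutionPolicy,
    Membrane,
    Program,
    RunResult,
    ScheduleEntry,
    run_to_halt,
)
from .errors import BuildError, StateError
from .image_io import RAW_8BIT, UNIT, GrayImage, normalize
from .oracle import get_mask_pair, mask_terms

__all__ = [
    "EDENPConfig",
    "EDENPInstance",
    "ResourceReport",
    "build_edenp",
    "detect_edges",
    "extract_edge_map",
    "count_resources",
    "instance_resources",
]


@dataclass(frozen=True)
class EDENPConfig:
    """Parameters of the compiled system.

    theta:
        edge threshold, on the active intensity scale (with
        ``normalize=True`` the scale is [0, 1] and the conventional
        default is 0.2).
    mask_name:
        sobel | prewitt | roberts.
    enzyme_seed_value:
        initial value of the seed enzyme e1_1; must exceed every pixel
        intensity or the gradient rules silently stall (256 covers both
        scales).
    ed1, ed2, ed3:
        helper constants of the edge decision (background value, edge
        value, sentinel below any reachable difference).
    normalize:
        rescale raw 8-bit input to the unit scale before compiling.
    """

    theta: float = 0.2
    mask_name: str = "sobel"
    normalize: bool = True
    enzyme_seed_value: float = 256.0
    ed1: float = 0.0
    ed2: float = 1.0
    ed3: float = -256.0
    n_rows: Optional[int] = None
    n_cols: Optional[int] = None

    def __post_init__(self):
        if self.theta < 0:
            raise BuildError("theta must be non-negative")
        get_mask_pair(self.mask_name)  # raises on unknown mask
        if not self.ed3 < self.ed1 < self.ed2:
            raise BuildError(
                f"helper constants must satisfy ed3 < ed1 < ed2, got "
                f"{self.ed3}, {self.ed1}, {self.ed2}"
            )


@dataclass(frozen=True)
class ResourceReport:
    """Resource accounting of a compiled system."""

    cells: int
    enzymatic_variables: int
    numerical_variables: int
    rules: int
    execution_steps: int
    molecules: int

    @property
    def variables(self) -> int:
        return self.enzymatic_variables + self.numerical_variables

    def as_dict(self) -> Dict[str, int]:
        return {
            "cells": self.cells,
            "enzymatic_variables": self.enzymatic_variables,
            "numerical_variables": self.numerical_variables,
            "rules": self.rules,
            "execution_steps": self.execution_steps,
            "molecules": self.molecules,
        }


def count_resources(n: int) -> ResourceReport:
    """Closed-form resource counts for a square n x n image: 2n^2 + 2
    enzymatic and 5n^2 + 4 numerical variables, 6n^2 + 4 rules, 5
    execution steps, one cell with 13n^2 + 10 molecules in total."""
    if not (isinstance(n, int) and n >= 3):
        raise ValueError(f"image side must be an integer >= 3, got {n!r}")
    n2 = n * n
    return ResourceReport(
        cells=1,
        enzymatic_variables=2 * n2 + 2,
        numerical_variables=5 * n2 + 4,
        rules=6 * n2 + 4,
        execution_steps=5,
        molecules=13 * n2 + 10,
    )


@dataclass
class EDENPInstance:
    """A compiled EDENP system with its staged schedule and policy."""

    system: ENPSystem
    schedule: List[ScheduleEntry]
    policy: ExecutionPolicy
    config: EDENPConfig
    n_rows: int
    n_cols: int
    pixels: np.ndarray  # working-scale intensities fed into the skin

    def run(
        self, theta: Optional[float] = None, record_trace: bool = False
    ) -> RunResult:
        """Run the five-step schedule to the halting configuration.

        ``theta`` overrides the threshold in the initial configuration
        (it is an ordinary initial value, so no rebuild is needed)."""
        initial = self.system.initial_configuration()
        if theta is not None:
            if theta < 0:
                raise BuildError("theta must be non-negative")
            initial.values["theta"] = float(theta)
        return run_to_halt(
            self.system,
            self.policy,
            schedule=self.schedule,
            config=initial,
            record_trace=record_trace,
        )

    def detect(
        self, theta: Optional[float] = None, record_trace: bool = False
    ) -> Tuple[np.ndarray, RunResult]:
        result = self.run(theta=theta, record_trace=record_trace)
        return extract_edge_map(result.configuration, self.n_rows, self.n_cols), result


def _term_string(coeff: float, var: str, first: bool) -> str:
    mag = abs(coeff)
    mag_str = str(int(mag)) if mag == int(mag) else repr(mag)
    body = var if mag == 1 else f"{mag_str}*{var}"
    if first:
        return body if coeff >= 0 else f"-{body}"
    return (" + " if coeff >= 0 else " - ") + body


def _mask_production(
    terms: List[Tuple[int, int, float]], i: int, j: int, anchor: Tuple[int, int]
) -> str:
    """Production for the gradient at 1-based pixel (i, j): the mask's
    non-zero coefficients in row-major order (the same order the serial
    reference accumulates in)."""
    parts = []
    for a, b, coeff in terms:
        var = f"x_{i + anchor[0] + a}_{j + anchor[1] + b}"
        parts.append(_term_string(coeff, var, first=not parts))
    return "".join(parts)


def _working_pixels(
    image: Union[GrayImage, np.ndarray], config: EDENPConfig
) -> np.ndarray:
    if isinstance(image, np.ndarray):
        scale = RAW_8BIT if image.size and image.max() > 1 else UNIT
        image = GrayImage(np.asarray(image, dtype=np.float64), scale)
    if config.normalize:
        image = normalize(image, UNIT)
    return image.pixels


def build_edenp(
    image: Union[GrayImage, np.ndarray], config: EDENPConfig = EDENPConfig()
) -> EDENPInstance:
    """Compile an image and a threshold into the four-membrane system."""
    pixels = _working_pixels(image, config)
    h, w = pixels.shape
    if h < 3 or w < 3:
        raise BuildError(f"image {h}x{w} is smaller than the 3x3 mask window")
    for dim, expected in (("n_rows", h), ("n_cols", w)):
        declared = getattr(config, dim)
        if declared is not None and declared != expected:
            raise BuildError(
                f"config.{dim}={declared} does not match the image ({expected})"
            )
    if pixels.max() >= config.enzyme_seed_value:
        raise BuildError(
            f"pixel intensity {pixels.max()} >= enzyme seed value "
            f"{config.enzyme_seed_value}; gradient rules would not fire"
        )

    masks = get_mask_pair(config.mask_name)
    tx, ty = mask_terms(masks.mx), mask_terms(masks.my)
    # The magnitude rule is gated by e1_1 >= min(gx, gy); if both
    # directional gradients can reach the seed value the gate may block
    # and the system no longer matches the serial detector.  The unit
    # scale keeps gradients <= 4, the raw scale does not.
    one_sided = max(
        m[m > 0].sum() if (m > 0).any() else 0.0 for m in (masks.mx, masks.my)
    )
    gradient_bound = one_sided * pixels.max()
    if gradient_bound >= config.enzyme_seed_value:
        warnings.warn(
            f"worst-case gradient magnitude {gradient_bound} reaches the "
            f"enzyme seed value {config.enzyme_seed_value}: the magnitude "
            "rules may stall on high-contrast pixels; raise "
            "enzyme_seed_value or enable normalization",
            RuntimeWarning,
            stacklevel=2,
        )
    seed_enzyme = "e1_1"

    # membrane 1: directional gradients ---------------------------------
    m1_vars: Dict[str, float] = {}
    m1_programs: List[Program] = []
    for i in range(1, h + 1):
        for j in range(1, w + 1):
            m1_vars[f"gx_{i}_{j}"] = 0.0
            m1_vars[f"gy_{i}_{j}"] = 0.0
    for i in range(2, h):
        for j in range(2, w):
            m1_programs.append(
                Program(
                    name=f"Pr1_{i}_{j}",
                    production=_mask_production(tx, i, j, masks.anchor),
                    repartition=((1.0, f"gx_{i}_{j}"),),
                    enzyme=seed_enzyme,
                )
            )
            m1_programs.append(
                Program(
                    name=f"Pr2_{i}_{j}",
                    production=_mask_production(ty, i, j, masks.anchor),
                    repartition=((1.0, f"gy_{i}_{j}"),),
                    enzyme=seed_enzyme,
                )
            )
    # border zeroing (rows 1 and h over all columns, then the remaining
    # first/last columns), for gx (Pr3-Pr6) and gy (Pr7-Pr10)
    border: List[Tuple[int, int]] = []
    border += [(1, j) for j in range(1, w + 1)]
    border += [(h, j) for j in range(1, w + 1)]
    border += [(i, 1) for i in range(2, h)]
    border += [(i, w) for i in range(2, h)]
    for family, grid in (("Pr3", "gx"), ("Pr7", "gy")):
        for i, j in border:
            m1_programs.append(
                Program(
                    name=f"{family}_{i}_{j}",
                    production="0",
                    repartition=((1.0, f"{grid}_{i}_{j}"),),
                    enzyme=seed_enzyme,
                )
            )
    membrane1 = Membrane("1", parent="2", variables=m1_vars, programs=m1_programs)

    # membrane 2: gradient magnitude -------------------------------------
    m2_vars = {f"g_{i}_{j}": 0.0 for i in range(1, h + 1) for j in range(1, w + 1)}
    m2_programs = [
        Program(
            name=f"Pr21_{i}_{j}",
            production=(
                f"sqrt(gx_{i}_{j}*gx_{i}_{j} + gy_{i}_{j}*gy_{i}_{j})"
            ),
            repartition=((1.0, f"g_{i}_{j}"),),
            enzyme=seed_enzyme,
        )
        for i in range(1, h + 1)
        for j in range(1, w + 1)
    ]
    membrane2 = Membrane("2", parent="3", variables=m2_vars, programs=m2_programs)

    # membrane 3: difference and edge decision ---------------------------
    m3_vars: Dict[str, float] = {
        "ed1": config.ed1,
        "ed2": config.ed2,
        "ed3": config.ed3,
    }
    m3_enzymes: List[str] = []
    m3_programs: List[Program] = []
    pr31_names: List[str] = []
    pr3x_names: List[str] = []
    for i in range(1, h + 1):
        for j in range(1, w + 1):
            m3_vars[f"E_{i}_{j}"] = 0.0
            m3_vars[f"ED_{i}_{j}"] = 0.0
            m3_enzymes += [f"E_{i}_{j}", f"ED_{i}_{j}"]
            pr31 = Program(
                name=f"Pr31_{i}_{j}",
                production=f"2*(g_{i}_{j} - theta)",
                repartition=((1.0, f"g_{i}_{j}"), (1.0, f"E_{i}_{j}")),
            )
            pr32 = Program(
                name=f"Pr32_{i}_{j}",
                production="ed1 + 2*ed2",
                repartition=((1.0, f"edg_{i}_{j}"), (1.0, f"ED_{i}_{j}")),
                enzyme=f"E_{i}_{j}",
            )
            pr33 = Program(
                name=f"Pr33_{i}_{j}",
                production="0*ed1 + 0*ed3",
                repartition=((1.0, f"edg_{i}_{j}"), (1.0, f"ED_{i}_{j}")),
                enzyme=f"E_{i}_{j}",
            )
            m3_programs += [pr31, pr32, pr33]
            pr31_names.append(pr31.name)
            pr3x_names += [pr32.name, pr33.name]
    for const in ("ed1", "ed2", "ed3"):
        refresh = Program(
            name=f"PrK_{const}", production=const, repartition=((1.0, const),)
        )
        m3_programs.append(refresh)
        pr3x_names.append(refresh.name)
    membrane3 = Membrane(
        "3",
        parent="4",
        variables=m3_vars,
        enzymes=tuple(m3_enzymes),
        programs=m3_programs,
    )

    # membrane 4 (skin): image, output, threshold, control ---------------
    m4_vars: Dict[str, float] = {}
    for i in range(1, h + 1):
        for j in range(1, w + 1):
            m4_vars[f"x_{i}_{j}"] = float(pixels[i - 1, j - 1])
    for i in range(1, h + 1):
        for j in range(1, w + 1):
            m4_vars[f"edg_{i}_{j}"] = 0.0
    m4_vars["theta"] = float(config.theta)
    m4_vars[seed_enzyme] = float(config.enzyme_seed_value)
    m4_vars["ED"] = 0.0
    main_terms = "".join(
        _term_string(0.0, f"ED_{i}_{j}", first=False)
        for i in range(1, h + 1)
        for j in range(1, w + 1)
    )
    # zero-coefficient terms format as "+ 0*EDij"; lead with them, end "+ 1"
    main_production = main_terms.lstrip(" +") + " + 1"
    prmain = Program(
        name="Prmain", production=main_production, repartition=((1.0, "ED"),)
    )
    membrane4 = Membrane(
        "4",
        parent=None,
        variables=m4_vars,
        enzymes=(seed_enzyme, "ED"),
        programs=[prmain],
    )

    system = ENPSystem([membrane1, membrane2, membrane3, membrane4])
    schedule = [
        ScheduleEntry(("1",), label="step1:gradients"),
        ScheduleEntry(("2",), label="step2:magnitude"),
        ScheduleEntry(("3",), frozenset(pr31_names), label="step3:difference"),
        ScheduleEntry(("3",), frozenset(pr3x_names), label="step4:edges"),
        ScheduleEntry(("4",), label="step5:halt"),
    ]
    policy = ExecutionPolicy(
        mode="staged",
        consumption="non-consuming",
        max_steps=10,
        halt_variable="ED",
        halt_threshold=1.0,
    )
    cfg = replace(config, n_rows=h, n_cols=w)
    return EDENPInstance(
        system=system,
        schedule=schedule,
        policy=policy,
        config=cfg,
        n_rows=h,
        n_cols=w,
        pixels=pixels,
    )


def extract_edge_map(final: Configuration, n_rows: int, n_cols: int) -> np.ndarray:
    """Read the edg grid out of a halted configuration as a {0,1} array."""
    if final.values.get("ED", 0.0) < 1.0:
        raise StateError(
            "system has not halted (ED < 1); run the schedule before "
            "extracting the edge map"
        )
    out = np.empty((n_rows, n_cols), dtype=np.uint8)
    for i in range(1, n_rows + 1):
        for j in range(1, n_cols + 1):
            v = final.values[f"edg_{i}_{j}"]
            if v not in (0.0, 1.0):
                raise StateError(f"edg_{i}_{j} = {v} is not a binary edge value")
            out[i - 1, j - 1] = int(v)
    return out


def detect_edges(
    image: Union[GrayImage, np.ndarray], config: EDENPConfig = EDENPConfig()
) -> np.ndarray:
    """Build the system, run the five-step schedule to halting, and
    return the binary edge map."""
    edge_map, _ = build_edenp(image, config).detect()
    return edge_map


def instance_resources(instance: EDENPInstance) -> ResourceReport:
    """Resource counts measured on an actual compiled instance (the
    cross-check for :func:`count_resources`)."""
    total_vars = sum(len(mb.variables) for mb in instance.system.membranes)
    enzymatic = sum(len(mb.enzymes) for mb in instance.system.membranes)
    rules = sum(len(mb.programs) for mb in instance.system.membranes)
    return ResourceReport(
        cells=1,
        enzymatic_variables=enzymatic,
        numerical_variables=total_vars - enzymatic,
        rules=rules,
        execution_steps=len(instance.schedule),
        molecules=total_vars + rules,
    )
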