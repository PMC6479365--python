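# edenp — image edge detection with enzymatic numerical P systems

`edenp` is a simulator for **enzymatic numerical P systems** (ENPS) — a
membrane-computing model in which numerical variables, placed in a nested
hierarchy of membranes, evolve under *programs* of the form

```
F(y1, …, yk) | e  →  c1|v1 + c2|v2 + … + cm|vm
```

A program evaluates its **production function** `F` over the current variable
values and splits the result among its **repartition targets** `v` in
proportion to the coefficients `c` (each target receives `F · cᵢ / Σc`).  An
optional **enzyme** variable `e` gates execution: the program fires only when
`e ≥ min(y1, …, yk)` (a strict `>` variant is also supported).  All applicable
programs of a step fire synchronously against the pre-step values, which makes
execution deterministic and massively parallel.

On top of the engine, the package compiles **gradient-based edge detection**
(EDENP) into a four-membrane system.  For an `n × n` grayscale image `I`, with
a mask pair such as Sobel:

```
gx = Sobelx ∗ I        gy = Sobely ∗ I           (directional gradients)
g(i,j)   = √(gx² + gy²)                          (gradient magnitude)
d(i,j)   = g(i,j) − θ                            (difference to threshold θ)
edg(i,j) = 1 if d(i,j) ≥ 0 else 0                (edge decision)
```

Each pipeline stage becomes one family of per-pixel rules inside the nest
`[[[[ ]₁]₂]₃]₄` (membrane 4 — the skin — holds the image, θ, and the control
variables; membranes 1–3 compute gradients, magnitudes, and the edge
decision).  A staged schedule runs the whole computation in **exactly five
steps regardless of image size**; the space cost is `Θ(n²)` (one cell,
`2n²+2` enzymatic variables, `5n²+4` numerical variables, `6n²+4` rules).
An independent serial detector (`edenp.oracle`) implements the same pipeline
with plain array arithmetic; the membrane run reproduces it **bit-for-bit**,
which the test suite and the `--verify` flag check continuously.  Sobel,
Prewitt and Roberts mask pairs are built in, and arbitrary ENPS models can be
described in a small JSON dialect and simulated directly.

The package is aimed at researchers in membrane computing / natural computing
who want an executable, testable reference for ENPS semantics, and at anyone
studying how classical image operators map onto rule-based parallel models.

## Worked example

```sh
$ edenp synth --kind square --size 16 --seed 1 --output square.pgm
synth: square 16x16 (seed=1) -> square.pgm [locus: {'kind': 'square', 'rows': (5, 12), 'cols': (5, 12)}]

$ edenp detect --input square.pgm --threshold 0.2 --mask sobel \
        --output edges.pgm --verify --report report.json
verify: membrane and serial edge maps are identical
enps: 64 edge pixels (16x16, mask=sobel, theta=0.2) -> edges.pgm
```

The synthetic image is a bright 8×8 square (rows/columns 5–12) on a dark
background.  `detect` compiles it into the membrane system, runs the staged
schedule, and — because of `--verify` — also runs the serial detector and
compares the two maps pixel-for-pixel.  The JSON report shows the run
structure:

```json
"steps_executed": 5,
"rules_fired_per_step": [512, 256, 256, 323, 1],
"maps_identical": true,
"edge_pixels": 64
```

Step 1 fires the `2·16² = 512` gradient rules, steps 2 and 3 the 256
magnitude and 256 difference rules, step 4 the edge-decision rules (256
always-firing background rules, 64 edge rules — one per pixel with `d ≥ 0` —
and 3 constant refreshes), and step 5 the single halting rule that sets
`ED = 1`.  The 64 edge pixels are exactly the one-pixel ring around the
square's boundary.  The same counts for any image size come from:

```sh
$ edenp resources --size 64
EDENP resources for a 64x64 image:
  cells:                1
  enzymatic variables:  8194
  numerical variables:  20484
  rules:                24580
  execution steps:      5
  molecules:            53258
```

The same pipeline is available as a library:

```python
from edenp import EDENPConfig, PatternSpec, build_edenp, gbed, generate

image, locus = generate(PatternSpec(kind="vstep", size=32, seed=7))
instance = build_edenp(image, EDENPConfig(theta=0.2, mask_name="sobel"))
edge_map, result = instance.detect()       # runs the 5-step schedule
assert result.steps_executed == 5
assert (edge_map == gbed(image.pixels, "sobel", 0.2)).all()
```

Arbitrary models can be exported, inspected and re-run:

```sh
edenp export-model --input square.pgm --output model.json
edenp simulate --model model.json --trace trace.csv --final final.json
```

## Layout

| module              | contents                                              |
|---------------------|-------------------------------------------------------|
| `edenp.core`        | ENPS engine: programs, membranes, stepping, halting    |
| `edenp.expressions` | production-function grammar and evaluation             |
| `edenp.serialize`   | JSON model files (round-trip, validation)              |
| `edenp.model`       | the EDENP compiler, staged schedule, resource counts   |
| `edenp.oracle`      | independent serial gradient-based edge detection       |
| `edenp.image_io`    | PGM (P2/P5) and delimited-text images, scale handling  |
| `edenp.synthetic`   | seeded test-image generator with known edge loci       |
| `edenp.cli`         | `edenp detect / simulate / resources / synth`          |

See `docs/methods.md` for the model semantics, the design choices behind
them, and known limitations.
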