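# Methods

## The model

An enzymatic numerical P system (ENPS) is a cell-like P system
`Π = (m, H, μ, Var₁, E₁, Pr₁, Var₁(0), …)`: a rooted tree of `m` membranes
(the root is the *skin*), each owning a set of named numerical variables with
initial values, a subset flagged as *enzymes*, and an ordered list of
programs.  A program

```
F(y₁, …, y_k) | e  →  c₁|v₁ + … + c_m|v_m
```

is **applicable** when it has no enzyme, or when the enzyme's value compares
against `min(y₁, …, y_k)`; the production value `F` is then split among the
targets `vᵢ` in proportion to the non-negative coefficients `cᵢ`
(`vᵢ` receives `F · cᵢ / Σc`).  Enzymes make otherwise nondeterministic
numerical P systems deterministic: a membrane can hold many programs and fire
all applicable ones in the same step.

Four semantic points are deliberately configurable because the literature is
not uniform about them; the defaults are the ones the edge-detection system
needs:

1. **Enzyme comparison** (`strict` / `non-strict`, default non-strict).
   The classical definition uses `e > min(...)`, but the edge-decision rules
   only work with `e ≥ min(...)`: the boundary case `d = 0` must count as an
   edge.  The comparison is a per-program setting.
2. **Operand-free productions with an enzyme.**  The border rules have the
   form `0 | e → 1|gx`.  With no operands the minimum is taken to be 0, so a
   positive enzyme makes constant rules applicable.
3. **Assignment vs. accumulation.**  Repartition targets of fired programs
   are reset to 0 at the start of the step and then receive the *summed*
   increments of all rules that target them, in program declaration order.
   A single rule therefore overwrites its target (the reading the difference
   rule `2(g−θ) → 1|g + 1|E` requires — both targets *become* `d`), while
   several rules writing one variable accumulate (the two edge-decision rules
   jointly produce `edg = 1 + 0`).  Variables not targeted by any fired rule
   are untouched.
4. **Operand consumption** (`consuming` / `non-consuming`, default
   non-consuming).  Classical numerical P systems zero the production
   operands of fired rules; the edge-detection system needs the image
   variables to survive being read by twelve overlapping window rules per
   pixel, so it runs non-consuming.  The classical behaviour remains
   available as a policy flag.

All values are double-precision reals.  Two runs of the same system, policy
and schedule produce bit-identical traces: program order is fixed, increments
are summed in declaration order, and no randomness enters the engine.

### Scheduling and halting

In **all-parallel** mode every membrane is active every step; the run stops
when a designated halt variable reaches its threshold, when no program fires,
or (optionally) at a fixed point; exhausting `max_steps` raises an explicit
non-halting error rather than truncating silently.  In **staged** mode an
explicit schedule — a list of (membrane set, optional program subset)
entries — drives one step per entry.  Staged mode exists because a
pipeline-shaped computation is only meaningful if its stages fire in order:
in true all-parallel mode the magnitude rules would fire in step 1 on
zero-initialized gradients (their gate `e₁,₁ ≥ min(gx, gy)` holds trivially),
destroying the five-step structure.  The schedule is the explicit form of the
stage ordering that the membrane nesting implies.

## The edge-detection system (EDENP)

Gradient-based edge detection with mask pair `(Mx, My)` and threshold `θ`:

```
gx = Mx ∗ I,  gy = My ∗ I          (correlation, borders 0)
g  = √(gx² + gy²)
edg = 1  iff  g − θ ≥ 0
```

The compiler maps an `h × w` image onto the nest `[[[[ ]₁]₂]₃]₄`:

| membrane | variables | rules (per pixel) |
|----------|-----------|-------------------|
| 1 | `gx`, `gy` | mask rule per direction on the interior; zero-production border rules; all gated by `e1_1` |
| 2 | `g` | `sqrt(gx² + gy²) | e1_1 → 1|g` |
| 3 | `ed1=0`, `ed2=1`, `ed3=−256`, `E`, `ED_{i,j}` | `2(g−θ) → 1|g + 1|E`; `ed1+2·ed2 | E → 1|edg + 1|ED_{i,j}`; `0·ed1+0·ed3 | E → 1|edg + 1|ED_{i,j}`; three constant refreshes |
| 4 (skin) | `x`, `edg`, `θ`, `e1_1=256`, `ED` | the halting rule `0·ED_{1,1}+…+1 → 1|ED` |

The decision pair implements the threshold exactly: after the difference
step, `E = d`.  The edge rule's gate is `E ≥ min(ed1, ed2) = 0`, so it fires
iff `d ≥ 0` and contributes `ed1 + 2·ed2 = 2`, split as `1` to `edg` and `1`
to `ED_{i,j}`.  The background rule's gate is `E ≥ min(ed1, ed3) = −256`,
which always holds (d ≥ −θ), and contributes 0 — so `edg` is overwritten with
1 exactly on edge pixels and 0 elsewhere.  The five-entry schedule is
gradients → magnitude → difference → decision → halt; the run sets `ED = 1`
after exactly five steps for every image size.

Index convention: the gradient at pixel `(i,j)` (1-based) is computed from
the 3×3 window centered there, for `2 ≤ i ≤ h−1`, `2 ≤ j ≤ w−1`; borders are
pinned to 0 by the border rules.  The printed rule tables in the membrane
computing literature sometimes anchor the window at the pixel instead and
leave the second-to-last row uncovered; the centered reading is the
self-consistent one and is what the serial pipeline implements.  Roberts'
2×2 masks are anchored at the pixel itself (window `(i..i+1, j..j+1)`), again
restricted to the interior.  Rectangular images are supported throughout; the
closed-form resource counts are stated for square inputs.

### Resource accounting

For an `n × n` image the compiled system has exactly `2n² + 2` enzymatic
variables (`E`, `ED_{i,j}`, `e1_1`, `ED`), `5n² + 4` numerical variables
(`x`, `gx`, `gy`, `g`, `edg`, `ed1..3`, `θ`) and `6n² + 4` rules: `2n²`
gradient rules (interior mask rules plus border zeroing sum to exactly `n²`
per direction), `n²` magnitude, `n²` difference, `2n²` decision rules, the
halting rule, and the three constant-refresh rules `edᵢ → 1|edᵢ`.  The
refreshes are the standard numerical-P-system idiom for keeping helper
constants alive: under consuming semantics the decision rules would zero
`ed1..ed3` each step, and the refreshes restore them in the same step.  Under
the default non-consuming policy they are exact identities.  They complete
the `6n² + 4` count that the per-membrane tally otherwise misses by three.
`count_resources(n)` returns the closed forms; `instance_resources(...)`
counts a compiled system, and the test suite asserts they agree for
`n ∈ {4, 8, 16, 32}`.

### Intensity scale

The decision constants mix two conventions: `e1_1 = 256` speaks 8-bit, while
a threshold like `θ = 0.2` only makes sense on magnitudes of order 1.  The
default therefore normalizes 8-bit input to `[0, 1]` (divide by 255); `θ` is
interpreted on whichever scale is active.  On the unit scale Sobel gradients
are bounded by 4, so the seed enzyme 256 dominates every gate.  With
`normalize=False` and 8-bit data that is no longer automatic: `|gx|` can
reach 4·255 = 1020, and where *both* directional gradients reach 256 the
magnitude rule's gate blocks and the membrane result diverges from the serial
one.  `build_edenp` computes the worst-case one-sided mask response and warns
when it reaches `enzyme_seed_value`; raising the seed (e.g. to 1021 for Sobel
on 8-bit data) restores exact agreement, which the tests check.

### Exact equivalence with the serial detector

Equality is asserted bit-for-bit, not approximately.  This is achievable
because both pipelines perform the same floating-point operations in the same
order: `mask_terms` fixes the row-major order of non-zero mask coefficients,
the rule compiler emits production terms in that order (evaluated
left-to-right), and the serial detector accumulates its slice products in the
same order.  Coefficient multiplications (±1, ±2) are exact; `a − b` and
`a + (−b)` round identically; `x*x` and the correctly rounded `sqrt` agree
between `math` and numpy; and the difference rule's `2(g−θ)/2` is exact
because the factor is a power of two.  The two implementations still take
disjoint code paths (string expressions through the engine vs. vectorized
array arithmetic), so the comparison remains a genuine cross-check of the
engine semantics, not a tautology.

## Synthetic data

The generator produces seeded images with analytically known edge structure:
`constant`, `vstep`/`hstep` (intensity step at the midline; the annotation
names the two adjacent columns/rows), `square` (centered bright block),
`disk`, `ramp`, `checker`, and `noise` (uniform texture), with optional
additive Gaussian noise and salt-and-pepper corruption (both truncated to the
valid range; corruption removes the locus annotation, since it invalidates
it).  Identical spec + seed ⇒ identical image.

What these images exercise: every mask/threshold decision path, including
ties (`d = 0`), dense sign changes (noise kinds), and known loci (for a unit
step, Sobel responds with `|gx| = 4` on the two step columns, Prewitt with 3,
Roberts with `√2` on the last background column — the tests recover exactly
these sets).  What they do not show: behaviour on natural images
(anti-aliased edges, texture statistics, sensor noise correlations) — the
bit-exactness argument is scale- and content-independent, but detection
*quality* on such data is outside what passing tests demonstrate.

## Problem sizes and numerical choices

The randomized equivalence battery uses 9 base images with sides 8–64
crossed with the three masks and four thresholds (108 configurations), which
keeps the full suite under a minute while covering the size range the
resource formulas are asserted on (`n ≤ 64`, about 24.6k rules and 28.7k
variables at the top end).  Production expressions are parsed once per rule
and compiled to Python bytecode; the halting rule's production lists every
`ED_{i,j}` with a zero coefficient, so the parser temporarily raises the
interpreter recursion limit proportionally to the expression's operator count
(capped at 10⁵, enough for n = 128).  Repartition conservation holds to
1e−9 relative tolerance by construction (`Σ increments = F` up to one
rounding per term); the engine tests assert it on randomized rules.

## Known limitations

* Staged scheduling is part of the artifact, not of the formal ENPS
  definition; the five-step claim is meaningful only under it.
* The halting rule is not genuinely enzyme-gated (there is no enforceable
  "all `ED_{i,j}` assigned" condition); in staged mode it simply occupies the
  final schedule entry, and `ED ≥ 1` is the halt condition.
* One-parallel/stochastic NPS modes, membrane creation/dissolution and
  P-Lingua compatibility are out of scope; so are non-maximum suppression,
  hysteresis, and color images.
* The simulator is a faithful sequential emulation of a parallel model: its
  wall-clock time grows with `n²` even though the simulated step count does
  not.
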