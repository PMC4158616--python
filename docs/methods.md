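# Methods

## The cubic glyph model

`glyphscape` renders each tabular case record as a *cubic glyph*: a small
2.5D object whose visual properties encode up to 16 data variables.  The
glyph is organised in three levels of detail so that the same dataset can
be read at any zoom:

* **pixel** (footprint < 2 px): a single filled cell carrying one
  variable, the *primary color* (slot 1);
* **iconic** (2–64 px): the main cube is added — cube height, cap color,
  base color, cap size, cap height, cap shape (slots 2–7);
* **detail** (> 64 px): three quarter-size sub-elements on the west, east
  and south faces of the plinth, each with a height, a base color and a
  cap color (slots 8–16).

The switching thresholds (2 px and 64 px, strict inequalities on both
sides; both boundary values render iconic) live in `LodPolicy` and are
compared against the glyph footprint edge, `min(cell_w, cell_h) × zoom`.
Levels nest by the *dominant-variable continuity* principle: the slot-1
color that fills the whole glyph at pixel level is the main-cube body
color at the higher levels, so zooming never changes what the strongest
channel means.

Each slot carries a Bertin-style characterisation: a *scale capability*
(`nominal-only`, `ordinal-capable`, `nominal-or-ordinal`) and a *length
class* (`short`/`medium`/`long` — how many states a viewer can reliably
tell apart on that channel).  One deliberate quirk is preserved from the
slot table this implementation follows: row 5 ("size cap") is typed
`geometry-shape` while row 7 ("shape cap") is typed `geometry-size` and
ordinal-capable, although shape as a retinal variable is purely nominal.
We keep the table as the operative definition — slot 7 is treated as a
discrete size-step of the cap silhouette (flat / bevel / pyramid), which
is an ordered 3-step family — and note the tension here.  Texture and
orientation are recognised by the scale rules (both ordinal-capable,
texture short, orientation very short) but no cubic-glyph slot uses them.

## Mapping validation

`validate_mapping` compares each assigned variable's metadata against its
slot and returns a traffic-light verdict:

* **red** — scale mismatch: nominal data on a pure-order channel (size,
  height), or ordered data on a purely nominal channel (shape);
* **yellow** — scale fits but `distinct_count > capacity(length_class)`,
  or ordered data sits on a hue slot without a sequential gradient
  colormap (hue alone carries no order; a gradient restores it);
* **green** — otherwise.

The overall verdict is the maximum severity over slots.  A mapped
variable without metadata is a programming error (`MappingError`), never
a red verdict.  Numeric capacities for the qualitative length classes are
configuration, defaulting to short = 10 (the "roughly ten distinguishable
values" rule for hue/value), medium = 25, long = 256.  Continuous and
interval variables are admitted on ordinal-capable slots via quantization;
the length check then counts quantization steps (default 10, settable per
slot), not raw distinct values.

Ordinal scales are never inferred from data — only declared (in code or a
metadata sidecar).  Lexical orders are exactly the misinterpretation this
validator exists to prevent, so silent inference would be
self-defeating.

## Placement and projection

Glyphs sit on an integer grid projected with a parallel 2:1 dimetric
projection: `sx = (gx − gy)·w/2`, `sy = (gx + gy)·h/2 − gz·z`, with
`w = 32 px`, `h = w/2`, `z = h/2` by default.  The projection is affine,
so a translated glyph keeps its exact screen size — the property that
makes sprite caching and dense small multiples work.  A cavalier/military
variant (`h = w`) changes only the grid constants, not the contract.
Painter's order sorts ascending by depth `gx + gy` (ties by `gx`, then
record index); under this camera a glyph is never overdrawn by one behind
it.

**Age pyramid** — males at `gx ≤ −1`, females at `gx ≥ +1`, row
`gy = floor(age / bin_years)` (5-year bins by default; rows are flipped at
render time so age 0 sits at the base).  The column magnitude is the
1-based stage rank plus one; records with *missing* stage take column 1,
directly against the axis, because absent staging is a finding the
analyst must see, not noise to push outward.  Cell collisions stack
outward to the next free column.  The per-stage column rule is one
consistent reading of the pyramid figure type; offsetting and stacking
variants would be equally defensible.

**Grouped small multiples** — partition by a grouping variable
(optionally binned into fixed-width periods such as `1995-1999`), apply
an inner layout per group, and shift groups along the screen-horizontal
direction (`gx + d, gy − d`, which preserves depth) until bounding boxes
are disjoint with a 2-cell gap.

**Discretized scatter** — bin x and y, then resolve collisions with a
deterministic square-spiral search in record order (a fixed offset
ordering, never randomness): reproducible figures beat faithful
emulation of random jitter.  A saturated neighbourhood (no free cell
within `max_jitter_radius`, default 10) is an error that reports the
overflow count.

## Geometry and rendering

Proportions are fixed in a geometry table (glyph-local units, the cell is
the unit square): plinth 1.0 × 1.0 × 0.1 in neutral gray — the border that
prevents spurious grid patterns in dense views; main cube 0.5 × 0.5
footprint, the lower 25 % of its height tinted in the base color; cap
inset on the cube top (size 0.3–0.9 of the top, height 0.08–0.5, flat /
bevel / pyramid silhouette); sub-elements 0.25 × 0.25 on the west/east/
south plinth edges.  Cube height spans 0.3–1.8 units and total glyph
height is clamped to 3.0 units: information-bearing caps sit on top and
may never be buried behind a tall neighbour, which the cap-visibility
test verifies by rasterizing a dense 8 × 8 grid and counting cap pixels.

A record whose primary value is missing renders as an all-white glyph at
every level (plinth excepted), the white-glyph convention for absent
staging.  Default palettes are colorblind-safe; body, cap and base
palettes occupy disjoint hue ranges (blues / warm / greens) so stacked
primitives cannot produce misleading secondary-color reads.

SVG is the reference output: polygons are emitted with fixed two-decimal
formatting in painter's order, so identical inputs give byte-identical
files.  The PNG path (pillow, no antialiasing) rounds every vertex to
integer device pixels relative to a rounded per-glyph anchor; a cached
sprite composited at an integer offset is therefore pixel-identical to
direct polygon drawing, and the cache key is the exact integer polygon
list, so a sprite is only ever reused for an identical rasterization.
Selection highlighting is a black outline on selected glyphs; unselected
glyphs are dimmed by mixing their fills 60 % toward the background (solid
colors, not alpha, to keep raster compositing order-free).

## Filtering and histograms

Filters are conjunctive per-variable conditions: numeric `[lo, hi]`
ranges (inclusive; ordinal variables filter in rank units) or category
subsets.  Missing values fail a filter unless `include_missing` is set
for that variable.  Range filters on unordered nominal variables are
rejected.  Histograms use half-open bins `[lo, hi)`; a maximum exactly on
the final edge gets its own bin.  Overall counts ignore the selection
mask, selected counts apply it, and a dedicated missing bin (on by
default) keeps the white-glyph population visible in the panels.

## Synthetic registry generator

The generator emulates a cancer-registry schema (organ, sex, age,
examination year, T/N/M staging, grading, receptor state, disease-free
and overall survival, mortality flag).  Forms are the simplest producing
the figure phenomenology, not epidemiological estimates:

* age ~ truncated normal on [0, 100], rounded to years;
* T stage ~ configured categorical probabilities; N, M conditioned on T
  through fixed tables (nodal involvement and metastasis rise with T);
* death ~ Bernoulli per T class; disease-free survival ~ exponential with
  a per-T mean, truncated at a 120-month follow-up horizon;
* missing T staging at a per-sex rate — the colon preset uses male 0.15 /
  female 0.05 to reproduce the male-biased missing-staging anomaly
  qualitatively (in the motivating registry the effect was traced to
  colon tissue arriving as a secondary finding of prostate biopsies);
* a small `outlier_rate` of records get their age forced to exactly 0 or
  100, emulating data-entry errors that pyramids expose instantly.

Presets: **thyroid** (n = 2109, 25 % male, low mortality with a
no-death-event T1 subgroup, visible age outliers), **lung** (n = 1782,
68 % male, high mortality), **colon** (n = 11 000, 1984–2004 with a
linearly increasing caseload, per-sex missing-T rates), and **mixed**
(thyroid + lung concatenated — the two-cohort comparison).  The fixed
cohort sizes 2109/1782 define the standard comparison figure.  All
sampling flows through one seeded `numpy` Generator; a seed determines
the dataset byte for byte, independent of platform, locale or time.

What the generator does *not* emulate: real incidence rates, registry
coding systems (ICD codes are reduced to an organ token), informative
censoring, or correlations beyond the staging→outcome chain.  Passing
tests therefore demonstrate the mechanics of the visualization pipeline
on data with the right qualitative structure, not clinical validity.

## Problem sizes and numerical choices

The default test and reproduction runs use the preset sizes (3891-case
mixed comparison at iconic level, 11 000-case colon cohort at pixel
level) — the scale at which these figure types are legible on one
screen.  Monte-Carlo checks on generator marginals use n = 20 000 with
4-standard-deviation binomial bounds.  Quantization ties round half to
even via Python's `round`; validation capacities, geometry proportions
and palette choices are module-level constants intended to be read as
configuration.  Degenerate inputs are defined rather than special-cased:
empty datasets render a background-only image, a single-value domain
quantizes to step 0, and an empty group still appears in the group key
list.

## Known limitations

* No interactivity: filtering, highlighting and re-layout are batch
  operations; coordinated-views event wiring is out of scope.
* LoD switching is discrete; no smooth geometric transition between
  levels is attempted.
* The grouped layout only nests age pyramids as the inner strategy via
  the CLI (the library composes arbitrary inner layouts).
* Sprite caching benefits drop when a continuous variable drives glyph
  geometry (most glyphs become unique); rendering then degrades to the
  direct path's cost.
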