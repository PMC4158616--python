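# glyphscape

Multilevel **cubic data glyphs** for visual exploration of large
biomedical record sets.

Analysts working with big tabular case collections — the motivating
domain is cancer-registry data with hundreds of thousands to millions of
records — need to see the whole cohort at once *and* read individual
cases in detail.  `glyphscape` implements the glyph-based approach to
this problem: every record becomes a small 2.5D cubic glyph whose visual
channels (colors, heights, cap geometry) encode up to 16 data variables,
drawn on a parallel dimetric grid where a glyph keeps its screen size
wherever it is placed.

The core pieces:

* **Three levels of detail** (semantic zoom).  A glyph smaller than
  2×2 px renders as a single colored pixel (1 variable); between 2 and
  64 px as an iconic cube (7 variables: primary color, cube height, cap
  and base colors, cap size/height/shape); above 64 px with three extra
  sub-elements (16 variables).  The dominant channel — the slot-1 color —
  carries through every level.
* **Traffic-light mapping validation.**  Each of the 16 slots has, per
  Bertin's retinal variables, a *scale capability* (nominal/ordinal) and
  a *length* (how many states a viewer can distinguish; hue ≈ 10).
  Assigning a variable to a slot is checked automatically: **red** for a
  scale mismatch (e.g. unordered categories on a height), **yellow**
  when the channel is too short for the variable's distinct values,
  **green** otherwise.
* **Dimetric placement strategies**: back-to-back age pyramids (males
  left, females right, rows by age class, columns by stage rank, missing
  staging pinned at the axis), grouped small multiples (e.g. one pyramid
  per examination year), and discretized scatter with deterministic
  spiral jittering — all drawn in painter's (back-to-front) order.
* **Linked-histogram filtering**: conjunctive per-variable range/subset
  filters; panels show the overall distribution in blue, the selected
  subgroup in green, and active filter ranges as red markers.
* **A seeded synthetic registry generator** (age, sex, examination year,
  organ, T/N/M staging, grading, receptor state, survival, mortality)
  with the conditional structure that makes these views interesting:
  sex-skewed organs, staging-dependent mortality, male-biased missing
  staging, and age-entry errors pinned at 0 and 100 years.

Output is deterministic by construction: the same config and seed yield
byte-identical SVG (and pixel-identical PNG, with or without the sprite
cache).

## Worked example

Generate the standard two-cohort comparison (2109 thyroid + 1782 lung
cases), select the 50–70 age band, and render organ-wise age pyramids at
the iconic level:

```yaml
# run.yaml
data: {preset: mixed, seed: 1}
layout: {kind: grouped, group_var: organ, inner: age_pyramid}
filters: {age: [50, 70]}
render: {lod: iconic, zoom: 0.6}
```

```sh
glyphscape run -c run.yaml -o out/
```

The manifest it prints (abridged):

```json
{
  "n_records": 3891,
  "n_placed": 3891,
  "n_selected": 1923,
  "n_groups": 2,
  "lod": "iconic",
  "validation": {"overall": "green", "per_slot": {"1": "green", "2": "green", "...": "..."}}
}
```

3891 records were generated and every one was placed (two pyramid
groups, lung and thyroid, side by side); 1923 fall in the 50–70 age band
and are outlined in `out/scene.svg` while the rest are dimmed;
`out/panel.svg` shows the per-variable histograms with the selection
overlaid in green and red markers at ages 50 and 70.  The default
mapping validated green on all twelve assigned slots — T staging on the
primary color, age on the cube height, the mortality flag on the cap
(black cap = deceased), organ on the base color.

In the rendered scene the two cohorts differ visibly: the lung pyramid
leans male (left-heavy) with mostly black caps; the thyroid pyramid
leans female with few black caps, plus a handful of glyphs at exactly
age 0 and 100 — injected data-entry errors that the pyramid exposes
immediately.

Other commands: `glyphscape generate` (synthetic cohorts to CSV + a
metadata sidecar), `glyphscape validate` (traffic-light table, exit 1 on
red), `glyphscape render`, `glyphscape hist`.  See `docs/methods.md` for
the model, geometry table and design choices.

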