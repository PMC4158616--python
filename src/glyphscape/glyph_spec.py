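"""The cubic glyph's visual-variable slot table and the mapping validator.

A cubic glyph exposes 16 mappable visual slots organised in three levels of
detail: one slot at level 1 (the primary color, the only channel visible
when a glyph shrinks to a pixel), six more at level 2 (the iconic cube:
heights, cap and base colors, cap geometry), and nine at level 3 (west,
east and south sub-elements, each with a height and two colors).

Each slot is characterised, following Bertin's retinal variables, by its
scale capability (which scales of measurement it can encode without lying)
and its length class (how many states a viewer can reliably distinguish).
``validate_mapping`` compares a variable's scale and distinct-value count
against those capabilities and issues a traffic-light verdict per slot:

* green  — scale fits and the channel has room for every distinct value,
* yellow — scale fits but the channel is shorter than the value count
           (or hue is asked to carry order without a sequential gradient),
* red    — the scale itself is incompatible (e.g. nominal data on a
           size channel, or ordered data on a purely nominal shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .data_model import VariableMeta

__all__ = [
    "VisualSlot",
    "GlyphSpec",
    "LodPolicy",
    "ColorMap",
    "GlyphMapping",
    "SlotVerdict",
    "ValidationReport",
    "MappingError",
    "cubic_glyph_spec",
    "capacity",
    "scale_compatible",
    "validate_mapping",
    "DEFAULT_CAPACITIES",
]

# How many states each Bertin length class is assumed to hold.  "short"
# follows the roughly-ten-distinguishable-values rule for hue/value;
# medium and long are package defaults (the classes are qualitative).
DEFAULT_CAPACITIES = {"short": 10, "medium": 25, "long": 256}

SCALE_CAPABILITIES = ("nominal-only", "ordinal-capable", "nominal-or-ordinal")
VTYPES = ("color", "geometry-size", "geometry-shape")
ORDERED_SCALES = ("ordinal", "interval", "continuous")

#: Default quantization step count used for continuous/interval variables
#: when a mapping does not state one; the length check then counts these
#: steps, not the raw distinct values.
DEFAULT_QUANT_STEPS = 10


class MappingError(ValueError):
    """Structurally invalid mapping (distinct from a red verdict)."""


@dataclass(frozen=True)
class VisualSlot:
    id: int
    name: str
    level: int
    vtype: str
    scale_capability: str
    length_class: str


@dataclass(frozen=True)
class LodPolicy:
    """Footprint thresholds (px) for switching level of detail."""

    pixel_max_px: float = 2.0
    detail_min_px: float = 64.0

    def __post_init__(self):
        if not (0 < self.pixel_max_px < self.detail_min_px):
            raise ValueError("need 0 < pixel_max_px < detail_min_px")


@dataclass(frozen=True)
class GlyphSpec:
    slots: tuple
    lod_policy: LodPolicy = LodPolicy()

    def slot(self, slot_id: int) -> VisualSlot:
        for s in self.slots:
            if s.id == slot_id:
                return s
        raise KeyError(slot_id)

    def slot_by_name(self, name: str) -> VisualSlot:
        for s in self.slots:
            if s.name == name:
                return s
        raise KeyError(name)

    def slots_at_level(self, level: int):
        return [s for s in self.slots if s.level <= level]


@dataclass
class ColorMap:
    """How a color slot turns a data value into a hue.

    ``direct`` indexes a categorical palette by domain position, ``gradient``
    interpolates between two endpoint colors by rank fraction (restoring
    order on the hue channel), ``custom`` uses an explicit value->color
    table that must cover the variable's domain.  A missing value always
    renders in ``missing_color`` (white by default — the white-glyph
    convention for absent staging).
    """

    kind: str = "direct"
    colors: Sequence[str] | None = None      # direct palette
    endpoints: tuple | None = None           # gradient (lo, hi)
    table: Mapping | None = None             # custom value -> color
    missing_color: str = "#ffffff"

    def __post_init__(self):
        if self.kind not in ("direct", "gradient", "custom"):
            raise MappingError(f"unknown colormap kind {self.kind!r}")
        if self.kind == "gradient":
            lo, hi = self.endpoints or ("#f7fbff", "#08306b")
            if lo == hi:
                raise MappingError("gradient endpoints must differ")
            self.endpoints = (lo, hi)


@dataclass
class GlyphMapping:
    """Assignment of data variables to glyph slots.

    ``assignments`` maps slot id -> variable name (one variable may fill
    several slots).  ``color_maps`` optionally overrides the colormap per
    color slot; ``quant_steps`` optionally fixes the quantization step
    count per slot for continuous/interval variables.
    """

    assignments: dict
    color_maps: dict = field(default_factory=dict)
    quant_steps: dict = field(default_factory=dict)

    def check_against(self, spec: GlyphSpec) -> None:
        for sid in self.assignments:
            spec.slot(sid)  # KeyError on unknown slot id

    def steps_for(self, slot_id: int) -> int:
        return int(self.quant_steps.get(slot_id, DEFAULT_QUANT_STEPS))


@dataclass(frozen=True)
class SlotVerdict:
    status: str  # green | yellow | red
    reason: str


_SEVERITY = {"green": 0, "yellow": 1, "red": 2}


@dataclass
class ValidationReport:
    per_slot: dict  # slot id -> SlotVerdict

    @property
    def overall(self) -> str:
        worst = max(
            (_SEVERITY[v.status] for v in self.per_slot.values()), default=0
        )
        return {0: "green", 1: "yellow", 2: "red"}[worst]

    @property
    def is_red(self) -> bool:
        return self.overall == "red"

    def format_table(self) -> str:
        lines = []
        for sid in sorted(self.per_slot):
            v = self.per_slot[sid]
            lines.append(f"  slot {sid:>2}  {v.status.upper():<6}  {v.reason}")
        lines.append(f"overall: {self.overall.upper()}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the cubic glyph slot table

_CUBIC_SLOTS = (
    # id, name, level, vtype, scale capability, length class
    (1, "primary color", 1, "color", "nominal-or-ordinal", "short"),
    (2, "height main cube", 2, "geometry-size", "ordinal-capable", "long"),
    (3, "color cap", 2, "color", "nominal-or-ordinal", "short"),
    (4, "color base", 2, "color", "nominal-or-ordinal", "short"),
    (5, "size cap", 2, "geometry-shape", "ordinal-capable", "medium"),
    (6, "height cap", 2, "geometry-size", "ordinal-capable", "long"),
    (7, "shape cap", 2, "geometry-size", "ordinal-capable", "short"),
    (8, "height west-element", 3, "geometry-size", "ordinal-capable", "long"),
    (9, "color west-element base", 3, "color", "nominal-or-ordinal", "short"),
    (10, "color west-element cap", 3, "color", "nominal-or-ordinal", "short"),
    (11, "height east-element", 3, "geometry-size", "ordinal-capable", "long"),
    (12, "color east-element base", 3, "color", "nominal-or-ordinal", "short"),
    (13, "color east-element cap", 3, "color", "nominal-or-ordinal", "short"),
    (14, "height south-element", 3, "geometry-size", "ordinal-capable", "long"),
    (15, "color south-element base", 3, "color", "nominal-or-ordinal", "short"),
    (16, "color south-element cap", 3, "color", "nominal-or-ordinal", "short"),
)


def cubic_glyph_spec(lod_policy: LodPolicy | None = None) -> GlyphSpec:
    """The 16-slot cubic glyph: 1 pixel-level slot, 6 iconic, 9 detail."""
    slots = tuple(VisualSlot(*row) for row in _CUBIC_SLOTS)
    return GlyphSpec(slots=slots, lod_policy=lod_policy or LodPolicy())


def capacity(length_class: str, capacities: Mapping[str, int] | None = None) -> int:
    """Number of distinguishable states for a Bertin length class."""
    table = capacities or DEFAULT_CAPACITIES
    try:
        return int(table[length_class])
    except KeyError:
        raise MappingError(
            f"unknown length class {length_class!r}; expected one of "
            f"{sorted(table)}"
        ) from None


def scale_compatible(data_scale: str, slot: VisualSlot) -> bool:
    """Can ``data_scale`` be honestly encoded on ``slot``?

    Nominal data needs a slot that accepts nominal; ordered data (ordinal,
    and interval/continuous after quantization) needs an ordinal-capable
    slot.  A purely nominal channel such as shape must never carry ordered
    data, and an order-encoding channel such as size must never carry
    unordered categories.  Texture and orientation, were they present,
    would be ordinal-capable (texture short, orientation very short).
    """
    cap = slot.scale_capability
    if cap not in SCALE_CAPABILITIES:
        raise MappingError(f"unknown scale capability {cap!r}")
    if data_scale == "nominal":
        return cap in ("nominal-only", "nominal-or-ordinal")
    if data_scale in ORDERED_SCALES:
        return cap in ("ordinal-capable", "nominal-or-ordinal")
    raise MappingError(f"unknown data scale {data_scale!r}")


def effective_distinct_count(
    meta: VariableMeta, mapping: GlyphMapping, slot_id: int
) -> int:
    """Distinct values the slot must hold: quantization steps for
    continuous/interval variables, raw distinct count otherwise."""
    if meta.scale in ("continuous", "interval"):
        return min(mapping.steps_for(slot_id), meta.distinct_count)
    return meta.distinct_count


def validate_mapping(
    mapping: GlyphMapping,
    metas: Mapping[str, VariableMeta],
    spec: GlyphSpec,
    capacities: Mapping[str, int] | None = None,
) -> ValidationReport:
    """Traffic-light verdict per assigned slot.

    Red when the variable's scale is incompatible with the slot; yellow
    when compatible but the channel is too short for the distinct values,
    or when ordered data sits on a hue slot without a sequential gradient;
    green otherwise.  A mapped variable without metadata raises
    :class:`MappingError` — that is a broken call, not a data mismatch.
    """
    mapping.check_against(spec)
    per_slot = {}
    for sid, var in mapping.assignments.items():
        slot = spec.slot(sid)
        if var not in metas:
            raise MappingError(f"variable {var!r} (slot {sid}) has no metadata")
        meta = metas[var]
        if not scale_compatible(meta.scale, slot):
            per_slot[sid] = SlotVerdict(
                "red",
                f"{meta.scale} variable {var!r} cannot be encoded on "
                f"{slot.scale_capability} slot {slot.name!r}",
            )
            continue
        cap = capacity(slot.length_class, capacities)
        count = effective_distinct_count(meta, mapping, sid)
        if count > cap:
            per_slot[sid] = SlotVerdict(
                "yellow",
                f"{var!r} has {count} distinct values but {slot.length_class} "
                f"slot {slot.name!r} distinguishes only {cap}",
            )
            continue
        if (
            slot.vtype == "color"
            and meta.scale in ORDERED_SCALES
            and mapping.color_maps.get(sid, ColorMap(kind="gradient")).kind
            != "gradient"
        ):
            per_slot[sid] = SlotVerdict(
                "yellow",
                f"ordered variable {var!r} on hue slot {slot.name!r} needs a "
                f"sequential gradient colormap to preserve order",
            )
            continue
        per_slot[sid] = SlotVerdict(
            "green", f"{var!r} fits {slot.name!r} ({count} of {cap} states)"
        )
    return ValidationReport(per_slot=per_slot)
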