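"""Cubic-glyph geometry and deterministic SVG/PNG scene rendering.

Geometry
--------
A glyph occupies one grid cell.  Its primitives are polygons in a local
coordinate frame obtained from the dimetric projection of the unit cell:
``lp(u, v, w) = (u - v, (u + v)/2 - w/2)``, so local x spans [-1, 1] and
one local y unit equals one cell height.  The renderer only translates
and scales these polygons — a glyph therefore has the same screen size
wherever it is placed, and identical records share cached sprites.

The proportions are fixed in a geometry table below: a full-cell plinth
(the neutral border that prevents moiré-like grid patterns in dense
views), a centred main cube split into a base band and a body, a cap on
top (the occlusion rule: the most informative elements sit on top of the
geometry, and total height is capped), and three quarter-size
sub-elements on the west, east and south faces for the detail level.
The cap silhouette has a 3-step family: flat, bevel, pyramid.

A record whose primary (level-1) variable is missing renders as an
all-white glyph at every level — absent staging must be conspicuous, not
invisible.

Rendering
---------
SVG is the reference output: identical inputs produce byte-identical
files.  PNG rasterization (pillow) rounds every vertex to integer device
pixels, which makes sprite caching exact: a cached glyph tile composited
at an integer offset is pixel-identical to drawing the polygons directly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from PIL import Image, ImageDraw

from .data_model import MISSING, CaseRecord, VariableMeta
from .filtering import FilterState, Histogram
from .glyph_spec import ColorMap, GlyphMapping, GlyphSpec, MappingError
from .layout import DimetricGrid, Placement, paint_order, project

__all__ = [
    "GlyphGeometry",
    "Primitive",
    "RenderError",
    "WarningLog",
    "quantize",
    "resolve_color",
    "build_geometry",
    "render_scene",
    "render_histogram_panel",
    "MAX_HEIGHT_UNITS",
    "CAP_SHAPES",
    "DEFAULT_CATEGORICAL",
]


class RenderError(ValueError):
    """Unrenderable request (canvas too small, malformed geometry)."""


class WarningLog:
    """Counter for non-fatal data issues (clamped values, skipped rows)."""

    def __init__(self):
        self.counts: dict = {}

    def count(self, key: str, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n

    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# geometry table (glyph-local grid units; the cell is the unit square)

PLINTH_HEIGHT = 0.1
PLINTH_COLOR = "#c8c8c8"
CUBE_FOOT = (0.25, 0.25, 0.75, 0.75)   # main cube footprint
BASE_BAND_FRAC = 0.25                  # lower fraction of cube in base color
CUBE_H_MIN, CUBE_H_MAX = 0.3, 1.8
CAP_H_MIN, CAP_H_MAX = 0.08, 0.5
CAP_SIZE_MIN, CAP_SIZE_MAX = 0.3, 0.9  # cap footprint as fraction of cube top
ELEM_H_MIN, ELEM_H_MAX = 0.15, 0.8
ELEM_CAP_FRAC = 0.6
ELEM_CAP_H = 0.08
#: hard cap on total glyph height (plinth + cube + cap), in height units
MAX_HEIGHT_UNITS = 3.0
CAP_SHAPES = ("flat", "bevel", "pyramid")

# element footprints on the plinth, back-to-front around the main cube
ELEMENT_FOOT = {
    "west": (0.0, 0.375, 0.25, 0.625),
    "east": (0.75, 0.375, 1.0, 0.625),
    "south": (0.375, 0.75, 0.625, 1.0),
}

# defaults for unmapped slots
DEFAULT_BODY_COLOR = "#888888"
DEFAULT_CAP_COLOR = "#b0b0b0"
DEFAULT_CUBE_H = 0.8
DEFAULT_CAP_SIZE = 0.6
DEFAULT_CAP_H = 0.15
DEFAULT_ELEM_H = 0.3

# colorblind-safe palettes; body / cap / base draw from disjoint hue
# ranges so stacked primitives cannot blend into misleading secondaries
DEFAULT_CATEGORICAL = (
    "#0072b2", "#d55e00", "#009e73", "#cc79a7",
    "#f0e442", "#56b4e9", "#e69f00", "#999999",
)
CAP_CATEGORICAL = ("#1a1a1a", "#fdae61", "#d7191c", "#ffffbf", "#a6611a")
BASE_CATEGORICAL = ("#018571", "#80cdc1", "#dfc27d", "#a6611a", "#5ab4ac")
BODY_GRADIENT = ("#deebf7", "#08306b")
CAP_GRADIENT = ("#fee0d2", "#67000d")
BASE_GRADIENT = ("#e5f5e0", "#00441b")

_SEVERITY_LEVELS = {"pixel": 1, "iconic": 2, "detail": 3}


@dataclass(frozen=True)
class Primitive:
    points: tuple          # ((x, y), ...) in glyph-local units
    fill: str
    outline: str | None = None


@dataclass
class GlyphGeometry:
    level: str
    primitives: tuple
    height_units: float

    def content_key(self) -> str:
        h = hashlib.sha256()
        for p in self.primitives:
            h.update(repr((p.points, p.fill, p.outline)).encode())
        h.update(self.level.encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# quantization and color resolution


def quantize(value, meta: VariableMeta, steps: int, warnings: WarningLog | None = None):
    """Map a value to a step index in ``0..steps-1`` (order preserving).

    Ordinal (and nominal) values use their domain rank spread evenly over
    the steps, so the first rank maps to step 0 and the last to
    ``steps-1``.  Continuous/interval values use equal-width bins over the
    declared range.  :data:`MISSING` passes through; out-of-domain values
    clamp to the nearest step and are counted in ``warnings``.
    """
    if value is MISSING:
        return MISSING
    if steps < 1:
        raise RenderError("steps must be >= 1")
    if steps == 1:
        return 0
    if meta.is_numeric:
        lo, hi = float(meta.domain[0]), float(meta.domain[1])
        v = float(value)
        if v < lo or v > hi:
            if warnings is not None:
                warnings.count(f"clamped:{meta.name}")
            v = min(max(v, lo), hi)
        if hi <= lo:
            return 0
        idx = int((v - lo) / (hi - lo) * steps)
        return min(idx, steps - 1)
    domain = list(meta.domain)
    try:
        r = domain.index(value)
    except ValueError:
        if warnings is not None:
            warnings.count(f"clamped:{meta.name}")
        return steps - 1
    n = len(domain)
    if n <= 1:
        return 0
    return round(r * (steps - 1) / (n - 1))


def _hex_to_rgb(color: str) -> tuple:
    c = color.lstrip("#")
    return tuple(int(c[i:i + 2], 16) for i in (0, 2, 4))


def _rgb_to_hex(rgb) -> str:
    return "#%02x%02x%02x" % tuple(max(0, min(255, int(round(v)))) for v in rgb)


def _lerp_color(a: str, b: str, t: float) -> str:
    ra, rb = _hex_to_rgb(a), _hex_to_rgb(b)
    return _rgb_to_hex(tuple(x + (y - x) * t for x, y in zip(ra, rb)))


def _shade(color: str, factor: float) -> str:
    return _rgb_to_hex(tuple(v * factor for v in _hex_to_rgb(color)))


def _mix(a: str, b: str, t: float) -> str:
    return _lerp_color(a, b, t)


def default_colormap(meta: VariableMeta, role: str = "body") -> ColorMap:
    """Role-appropriate default: sequential gradient for ordered data,
    categorical palette otherwise; hue ranges disjoint per role."""
    gradients = {"body": BODY_GRADIENT, "cap": CAP_GRADIENT, "base": BASE_GRADIENT}
    palettes = {
        "body": DEFAULT_CATEGORICAL,
        "cap": CAP_CATEGORICAL,
        "base": BASE_CATEGORICAL,
    }
    if meta.scale == "nominal":
        return ColorMap(kind="direct", colors=palettes.get(role, DEFAULT_CATEGORICAL))
    return ColorMap(kind="gradient", endpoints=gradients.get(role, BODY_GRADIENT))


def resolve_color(
    value,
    meta: VariableMeta,
    cmap: ColorMap,
    steps: int = 10,
    warnings: WarningLog | None = None,
) -> str:
    """Value -> hex color under a colormap; MISSING -> missing_color."""
    if value is MISSING:
        return cmap.missing_color
    if cmap.kind == "custom":
        table = cmap.table or {}
        key = str(value)
        if key not in table:
            raise MappingError(
                f"custom colormap for {meta.name!r} lacks value {key!r}"
            )
        return table[key]
    if cmap.kind == "direct":
        palette = tuple(cmap.colors or DEFAULT_CATEGORICAL)
        if meta.is_numeric:
            idx = quantize(value, meta, min(steps, len(palette)), warnings)
        else:
            try:
                idx = meta.rank(value)
            except ValueError:
                if warnings is not None:
                    warnings.count(f"clamped:{meta.name}")
                idx = 0
        return palette[idx % len(palette)]
    # gradient
    lo, hi = cmap.endpoints or BODY_GRADIENT
    idx = quantize(value, meta, steps, warnings)
    t = idx / (steps - 1) if steps > 1 else 0.0
    return _lerp_color(lo, hi, t)


# ---------------------------------------------------------------------------
# geometry construction


def _lp(u: float, v: float, w: float) -> tuple:
    """Glyph-local dimetric projection of the unit cell."""
    return (u - v, (u + v) / 2.0 - w / 2.0)


def _frustum(bottom, top, z0: float, z1: float, fill: str):
    """Visible faces of a (possibly tapered) box: +u face, +v face, top.

    ``bottom``/``top`` are (u0, v0, u1, v1) rectangles; a degenerate top
    (zero area) yields a pyramid with two triangular faces and no top.
    """
    bu0, bv0, bu1, bv1 = bottom
    tu0, tv0, tu1, tv1 = top
    prims = []
    degenerate = abs(tu1 - tu0) < 1e-12 and abs(tv1 - tv0) < 1e-12
    if z1 > z0:
        if degenerate:
            apex = _lp(tu0, tv0, z1)
            prims.append(Primitive(
                (_lp(bu1, bv0, z0), _lp(bu1, bv1, z0), apex),
                _shade(fill, 0.80),
            ))
            prims.append(Primitive(
                (_lp(bu0, bv1, z0), _lp(bu1, bv1, z0), apex),
                _shade(fill, 0.62),
            ))
            return prims
        prims.append(Primitive(
            (_lp(bu1, bv0, z0), _lp(bu1, bv1, z0), _lp(tu1, tv1, z1), _lp(tu1, tv0, z1)),
            _shade(fill, 0.80),
        ))
        prims.append(Primitive(
            (_lp(bu0, bv1, z0), _lp(bu1, bv1, z0), _lp(tu1, tv1, z1), _lp(tu0, tv1, z1)),
            _shade(fill, 0.62),
        ))
    if not degenerate:
        prims.append(Primitive(
            (_lp(tu0, tv0, z1), _lp(tu1, tv0, z1), _lp(tu1, tv1, z1), _lp(tu0, tv1, z1)),
            fill,
        ))
    return prims


def _box(foot, z0: float, z1: float, fill: str):
    return _frustum(foot, foot, z0, z1, fill)


def _inset(foot, frac: float):
    u0, v0, u1, v1 = foot
    cu, cv = (u0 + u1) / 2.0, (v0 + v1) / 2.0
    hw, hh = (u1 - u0) / 2.0 * frac, (v1 - v0) / 2.0 * frac
    return (cu - hw, cv - hh, cu + hw, cv + hh)


def _cap_prims(foot, z0: float, height: float, fill: str, shape: str):
    if shape == "flat":
        return _box(foot, z0, z0 + height, fill)
    if shape == "bevel":
        return _frustum(foot, _inset(foot, 0.5), z0, z0 + height, fill)
    if shape == "pyramid":
        u0, v0, u1, v1 = foot
        cu, cv = (u0 + u1) / 2.0, (v0 + v1) / 2.0
        return _frustum(foot, (cu, cv, cu, cv), z0, z0 + height, fill)
    raise RenderError(f"unknown cap shape {shape!r}; expected one of {CAP_SHAPES}")


class _SlotReader:
    """Resolves a record's value/color/height per slot of one mapping."""

    def __init__(self, record, mapping, spec, metas, warnings):
        self.record = record
        self.mapping = mapping
        self.spec = spec
        self.metas = metas
        self.warnings = warnings

    def value(self, sid: int):
        var = self.mapping.assignments.get(sid)
        if var is None:
            return None  # unmapped
        if var not in self.record.values:
            raise MappingError(
                f"slot {sid} maps variable {var!r} but the record lacks it"
            )
        return self.record.values[var]

    def meta(self, sid: int) -> VariableMeta:
        return self.metas[self.mapping.assignments[sid]]

    def color(self, sid: int, role: str, default: str) -> str:
        v = self.value(sid)
        if v is None:
            return default
        meta = self.meta(sid)
        cmap = self.mapping.color_maps.get(sid) or default_colormap(meta, role)
        return resolve_color(
            v, meta, cmap, self.mapping.steps_for(sid), self.warnings
        )

    def fraction(self, sid: int, default: float) -> float:
        """Quantized value as a 0..1 fraction (MISSING/unmapped -> default/0)."""
        v = self.value(sid)
        if v is None:
            return default
        if v is MISSING:
            return 0.0
        steps = self.mapping.steps_for(sid)
        idx = quantize(v, self.meta(sid), steps, self.warnings)
        return idx / (steps - 1) if steps > 1 else 0.0


def build_geometry(
    record: CaseRecord,
    mapping: GlyphMapping,
    level: str,
    spec: GlyphSpec,
    metas: Mapping[str, VariableMeta],
    warnings: WarningLog | None = None,
) -> GlyphGeometry:
    """Construct the glyph geometry for one record at one level of detail.

    The level-1 primary color is the dominant color at every level: it
    fills the whole glyph at pixel level and the main-cube body at iconic
    and detail levels.  A missing primary value yields an all-white glyph
    (the plinth keeps its neutral color).  Slots assigned to variables a
    record does not carry raise :class:`MappingError`.
    """
    if level not in _SEVERITY_LEVELS:
        raise RenderError(f"unknown level {level!r}")
    reader = _SlotReader(record, mapping, spec, metas, warnings)

    primary_value = reader.value(1)
    white = primary_value is MISSING
    if white:
        cmap1 = mapping.color_maps.get(1) or ColorMap()
        body_color = cmap1.missing_color
    else:
        body_color = reader.color(1, "body", DEFAULT_BODY_COLOR)

    if level == "pixel":
        cell = (_lp(0, 0, 0), _lp(1, 0, 0), _lp(1, 1, 0), _lp(0, 1, 0))
        return GlyphGeometry(
            level="pixel",
            primitives=(Primitive(cell, body_color),),
            height_units=0.0,
        )

    def col(sid, role, default):
        return body_color if white else reader.color(sid, role, default)

    cube_h = CUBE_H_MIN + reader.fraction(2, (DEFAULT_CUBE_H - CUBE_H_MIN) / (CUBE_H_MAX - CUBE_H_MIN)) * (CUBE_H_MAX - CUBE_H_MIN)
    cap_color = col(3, "cap", DEFAULT_CAP_COLOR)
    base_color = col(4, "base", body_color)
    cap_size = CAP_SIZE_MIN + reader.fraction(5, (DEFAULT_CAP_SIZE - CAP_SIZE_MIN) / (CAP_SIZE_MAX - CAP_SIZE_MIN)) * (CAP_SIZE_MAX - CAP_SIZE_MIN)
    cap_h = CAP_H_MIN + reader.fraction(6, (DEFAULT_CAP_H - CAP_H_MIN) / (CAP_H_MAX - CAP_H_MIN)) * (CAP_H_MAX - CAP_H_MIN)
    shape_frac = reader.fraction(7, 0.0)
    cap_shape = CAP_SHAPES[min(int(shape_frac * len(CAP_SHAPES)), len(CAP_SHAPES) - 1)]

    # enforce the height cap
    total = PLINTH_HEIGHT + cube_h + cap_h
    if total > MAX_HEIGHT_UNITS:
        cube_h -= total - MAX_HEIGHT_UNITS
        total = MAX_HEIGHT_UNITS

    prims = []
    prims += _box((0.0, 0.0, 1.0, 1.0), 0.0, PLINTH_HEIGHT, PLINTH_COLOR)

    element_slots = {"west": (8, 9, 10), "east": (11, 12, 13), "south": (14, 15, 16)}

    def element(name):
        h_sid, base_sid, cap_sid = element_slots[name]
        foot = ELEMENT_FOOT[name]
        h = ELEM_H_MIN + reader.fraction(h_sid, (DEFAULT_ELEM_H - ELEM_H_MIN) / (ELEM_H_MAX - ELEM_H_MIN)) * (ELEM_H_MAX - ELEM_H_MIN)
        e_base = col(base_sid, "base", body_color)
        e_cap = col(cap_sid, "cap", DEFAULT_CAP_COLOR)
        out = _box(foot, PLINTH_HEIGHT, PLINTH_HEIGHT + h, e_base)
        out += _box(_inset(foot, ELEM_CAP_FRAC),
                    PLINTH_HEIGHT + h, PLINTH_HEIGHT + h + ELEM_CAP_H, e_cap)
        return out

    if level == "detail":
        prims += element("west")

    z_cube0 = PLINTH_HEIGHT
    z_band = z_cube0 + cube_h * BASE_BAND_FRAC
    z_cube1 = z_cube0 + cube_h
    prims += _box(CUBE_FOOT, z_cube0, z_band, base_color)
    prims += _box(CUBE_FOOT, z_band, z_cube1, body_color)
    prims += _cap_prims(_inset(CUBE_FOOT, cap_size), z_cube1, cap_h, cap_color, cap_shape)

    if level == "detail":
        prims += element("east")
        prims += element("south")

    return GlyphGeometry(
        level=level, primitives=tuple(prims), height_units=total
    )


# ---------------------------------------------------------------------------
# scene rendering


def _transform_factory(grid: DimetricGrid, zoom: float):
    cw = grid.cell_w_px * zoom
    ch = grid.cell_h_px * zoom
    zs = grid.z_scale_px * zoom
    ox, oy = grid.origin_px

    def anchor(p: Placement):
        return (
            ox + (p.gx - p.gy) * cw / 2.0,
            oy + (p.gx + p.gy) * ch / 2.0 - p.gz * zs,
        )

    def local(pt):
        return (pt[0] * cw / 2.0, pt[1] * ch)

    return anchor, local


def _scene_polygons(placements, geometries, grid, zoom, highlight, dim_unselected,
                    background):
    """Per-glyph display lists: (placement, [(points, fill, outline), ...])."""
    if len(placements) != len(geometries):
        raise RenderError("placements and geometries must be aligned")
    anchor, local = _transform_factory(grid, zoom)
    selected_set = set(highlight) if highlight is not None else None
    any_selected = (
        bool(selected_set)
        if selected_set is not None
        else any(p.selected for p in placements)
    )
    order = paint_order(placements)
    out = []
    for k in order:
        p, g = placements[k], geometries[k]
        ax, ay = anchor(p)
        is_sel = (
            p.record_index in selected_set
            if selected_set is not None
            else p.selected
        )
        polys = []
        for prim in g.primitives:
            fill = prim.fill
            if any_selected and not is_sel and dim_unselected:
                fill = _mix(fill, background, 0.6)
            outline = "#000000" if is_sel else prim.outline
            pts = [(ax + local(pt)[0], ay + local(pt)[1]) for pt in prim.points]
            polys.append((pts, fill, outline))
        out.append((p, g, is_sel, polys))
    return out


def _scene_bounds(display):
    xs = [x for _, _, _, polys in display for pts, _, _ in polys for x, _ in pts]
    ys = [y for _, _, _, polys in display for pts, _, _ in polys for _, y in pts]
    if not xs:
        return (0.0, 0.0, 0.0, 0.0)
    return (min(xs), min(ys), max(xs), max(ys))


def render_scene(
    placements: Sequence[Placement],
    geometries: Sequence[GlyphGeometry],
    grid: DimetricGrid,
    canvas: tuple | None = None,
    background: str = "#ffffff",
    out=None,
    zoom: float = 1.0,
    highlight: Sequence[int] | None = None,
    dim_unselected: bool = True,
    fmt: str | None = None,
    margin_px: float = 8.0,
    use_sprite_cache: bool = True,
):
    """Draw glyphs in painter's order to SVG text or a PNG image.

    ``canvas=None`` auto-sizes (and shifts the origin so everything fits
    with a margin); an explicit canvas that cannot hold the layout raises
    :class:`RenderError` naming the required size.  ``highlight`` is a set
    of record indices to outline; the rest are dimmed toward the
    background.  Identical inputs give byte-identical SVG; the PNG path
    may reuse cached glyph sprites with pixel-identical results.
    """
    fmt = fmt or (str(out).rsplit(".", 1)[-1].lower() if out else "svg")
    display = _scene_polygons(
        placements, geometries, grid, zoom, highlight, dim_unselected, background
    )
    x0, y0, x1, y1 = _scene_bounds(display)
    need_w = int(x1 - x0 + 2 * margin_px) + 1
    need_h = int(y1 - y0 + 2 * margin_px) + 1
    if canvas is None:
        canvas = (need_w, need_h)
        dx, dy = margin_px - x0, margin_px - y0
    else:
        if display and (canvas[0] < need_w or canvas[1] < need_h):
            raise RenderError(
                f"canvas {canvas[0]}x{canvas[1]} too small; layout needs at "
                f"least {need_w}x{need_h}"
            )
        dx, dy = margin_px - x0, margin_px - y0

    if fmt == "svg":
        text = _emit_svg(display, canvas, background, dx, dy)
        if out is not None:
            with open(out, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text
    if fmt == "png":
        img = _emit_png(display, canvas, background, dx, dy, use_sprite_cache)
        if out is not None:
            img.save(out, format="PNG")
        return img
    raise RenderError(f"unknown output format {fmt!r}")


def _emit_svg(display, canvas, background, dx, dy) -> str:
    w, h = int(canvas[0]), int(canvas[1])
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{h}" viewBox="0 0 {w} {h}">',
        f'<rect x="0" y="0" width="{w}" height="{h}" fill="{background}"/>',
    ]
    for _, _, is_sel, polys in display:
        for pts, fill, outline in polys:
            pstr = " ".join(f"{x + dx:.2f},{y + dy:.2f}" for x, y in pts)
            if outline:
                lines.append(
                    f'<polygon points="{pstr}" fill="{fill}" '
                    f'stroke="{outline}" stroke-width="1"/>'
                )
            else:
                lines.append(f'<polygon points="{pstr}" fill="{fill}"/>')
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def _emit_png(display, canvas, background, dx, dy, use_sprite_cache):
    w, h = int(canvas[0]), int(canvas[1])
    img = Image.new("RGBA", (w, h), _hex_to_rgb(background) + (255,))
    cache: dict = {}
    draw = ImageDraw.Draw(img)
    for _, g, is_sel, polys in display:
        # integer-pixel polygons relative to a rounded anchor make the
        # sprite path exactly equal to direct drawing
        if not polys:
            continue
        ax, ay = polys[0][0][0]  # first vertex as reference
        axi, ayi = round(ax + dx), round(ay + dy)
        int_polys = []
        for pts, fill, outline in polys:
            ipts = [
                (round(x + dx) - axi, round(y + dy) - ayi) for x, y in pts
            ]
            int_polys.append((tuple(ipts), fill, outline))
        if use_sprite_cache:
            # key on the exact integer polygons: sub-pixel anchor phase can
            # alter rounding, and a sprite must only be reused when the
            # rasterized shape is identical
            key = tuple(int_polys)
            tile_info = cache.get(key)
            if tile_info is None:
                tile_info = _make_sprite(int_polys)
                cache[key] = tile_info
            tile, (mx, my) = tile_info
            px, py = axi + mx, ayi + my
            _composite(img, tile, px, py)
        else:
            for ipts, fill, outline in int_polys:
                shifted = [(x + axi, y + ayi) for x, y in ipts]
                draw.polygon(
                    shifted,
                    fill=_hex_to_rgb(fill) + (255,),
                    outline=_hex_to_rgb(outline) + (255,) if outline else None,
                )
    return img


def _make_sprite(int_polys):
    xs = [x for ipts, _, _ in int_polys for x, _ in ipts]
    ys = [y for ipts, _, _ in int_polys for _, y in ipts]
    mx, my = min(xs), min(ys)
    tw, th = max(xs) - mx + 2, max(ys) - my + 2
    tile = Image.new("RGBA", (tw, th), (0, 0, 0, 0))
    tdraw = ImageDraw.Draw(tile)
    for ipts, fill, outline in int_polys:
        tdraw.polygon(
            [(x - mx, y - my) for x, y in ipts],
            fill=_hex_to_rgb(fill) + (255,),
            outline=_hex_to_rgb(outline) + (255,) if outline else None,
        )
    return tile, (mx, my)


def _composite(img, tile, px, py):
    """Alpha-composite ``tile`` onto ``img`` at (px, py), clipping edges."""
    tw, th = tile.size
    sx = max(0, -px)
    sy = max(0, -py)
    ex = min(tw, img.size[0] - px)
    ey = min(th, img.size[1] - py)
    if ex <= sx or ey <= sy:
        return
    region = tile if (sx, sy, ex, ey) == (0, 0, tw, th) else tile.crop((sx, sy, ex, ey))
    img.alpha_composite(region, dest=(px + sx, py + sy))


# ---------------------------------------------------------------------------
# histogram panel

_PANEL_BLUE = "#9ecae1"
_PANEL_GREEN = "#31a354"
_PANEL_RED = "#e31a1c"
_PANEL_MISSING = "#d9d9d9"


def render_histogram_panel(
    histograms: Sequence[Histogram],
    filter_state: FilterState | None = None,
    out=None,
    panel_w: int = 240,
    panel_h: int = 110,
    per_row: int = 4,
) -> str:
    """One bar sub-panel per variable: overall counts in blue, the selected
    subset overlaid in green, active filter ranges as red markers, and an
    optional gray missing-value bar.  Returns deterministic SVG text."""
    filter_state = filter_state or FilterState()
    n = len(histograms)
    rows = (n + per_row - 1) // per_row if n else 1
    cols = min(n, per_row) if n else 1
    W, H = cols * panel_w, rows * panel_h
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{W}" height="{H}" viewBox="0 0 {W} {H}">',
        f'<rect x="0" y="0" width="{W}" height="{H}" fill="#ffffff"/>',
    ]
    for i, hist in enumerate(histograms):
        px = (i % per_row) * panel_w
        py = (i // per_row) * panel_h
        lines += _panel_svg(hist, filter_state, px, py, panel_w, panel_h)
    lines.append("</svg>")
    text = "\n".join(lines) + "\n"
    if out is not None:
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def _panel_svg(hist, filter_state, px, py, pw, ph):
    pad, title_h = 8.0, 14.0
    plot_x, plot_y = px + pad, py + title_h + 2
    plot_w, plot_h = pw - 2 * pad, ph - title_h - 2 * pad
    counts = list(hist.overall_counts)
    sel = list(hist.selected_counts)
    has_missing = hist.overall_missing > 0
    nbars = len(counts) + (1 if has_missing else 0)
    peak = max(
        [*counts, hist.overall_missing if has_missing else 0, 1]
    )
    bw = plot_w / max(nbars, 1)
    out = [
        f'<text x="{plot_x:.2f}" y="{py + title_h - 3:.2f}" '
        f'font-family="sans-serif" font-size="10">{hist.variable}</text>'
    ]
    base = plot_y + plot_h

    def bar(j, value, color, width_frac=1.0):
        bh = plot_h * value / peak
        x = plot_x + j * bw + bw * (1 - width_frac) / 2
        return (
            f'<rect x="{x:.2f}" y="{base - bh:.2f}" '
            f'width="{bw * width_frac:.2f}" height="{bh:.2f}" fill="{color}"/>'
        )

    for j, c in enumerate(counts):
        if c:
            out.append(bar(j, c, _PANEL_BLUE))
    for j, c in enumerate(sel):
        if c:
            out.append(bar(j, c, _PANEL_GREEN, width_frac=0.6))
    if has_missing:
        out.append(bar(len(counts), hist.overall_missing, _PANEL_MISSING))
        if hist.selected_missing:
            out.append(bar(len(counts), hist.selected_missing, _PANEL_GREEN, 0.6))
    out.append(
        f'<line x1="{plot_x:.2f}" y1="{base:.2f}" x2="{plot_x + plot_w:.2f}" '
        f'y2="{base:.2f}" stroke="#555555" stroke-width="1"/>'
    )
    # red range markers for the active filter on this variable
    if filter_state.is_active(hist.variable):
        cond = filter_state.ranges[hist.variable]
        if hist.edges is not None and isinstance(cond, (tuple, list)) \
                and len(cond) == 2 and not isinstance(cond[0], str):
            lo, hi = float(cond[0]), float(cond[1])
            e0, e1 = float(hist.edges[0]), float(hist.edges[-1])
            span = (e1 - e0) or 1.0
            for v in (lo, hi):
                x = plot_x + (min(max(v, e0), e1) - e0) / span * plot_w * (len(counts) / max(nbars, 1))
                out.append(
                    f'<line x1="{x:.2f}" y1="{plot_y:.2f}" x2="{x:.2f}" '
                    f'y2="{base:.2f}" stroke="{_PANEL_RED}" stroke-width="2"/>'
                )
        elif hist.categories is not None:
            subset = {str(c) for c in (cond if not isinstance(cond, str) else [cond])}
            for j, c in enumerate(hist.categories):
                if str(c) in subset:
                    x = plot_x + j * bw
                    out.append(
                        f'<line x1="{x + 1:.2f}" y1="{base + 3:.2f}" '
                        f'x2="{x + bw - 1:.2f}" y2="{base + 3:.2f}" '
                        f'stroke="{_PANEL_RED}" stroke-width="3"/>'
                    )
    return out
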