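"""Level-of-detail selection, dimetric projection, and glyph placement.

Glyphs live on an integer grid ``(gx, gy)`` with a non-negative height
``gz`` and are projected to the screen with a parallel (dimetric, 2:1)
projection — the three-quarter view of classic simulation games.  Because
the projection is parallel, a glyph keeps its exact screen size wherever it
is moved, which is what makes sprite caching and dense grids workable.

Three placement strategies are provided:

* :func:`layout_age_pyramid` — demographic back-to-back pyramid: males on
  the left, females on the right, rows by age class, column by stage rank.
* :func:`layout_grouped` — small multiples: partition by a grouping
  variable (optionally binned into periods), lay each group out with an
  inner strategy, and offset groups side by side.
* :func:`layout_scatter_discrete` — discretized scatter with deterministic
  spiral jittering to keep one glyph per cell.

:func:`paint_order` yields the painter's (back-to-front) drawing order for
the standard dimetric camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .data_model import MISSING, Dataset
from .glyph_spec import LodPolicy

__all__ = [
    "DimetricGrid",
    "CAVALIER_GRID_KW",
    "Placement",
    "LayoutResult",
    "LayoutError",
    "select_lod",
    "project",
    "layout_age_pyramid",
    "layout_grouped",
    "layout_scatter_discrete",
    "paint_order",
]

LOD_LEVELS = ("pixel", "iconic", "detail")


class LayoutError(ValueError):
    """Unsatisfiable placement request (e.g. saturated grid)."""


@dataclass(frozen=True)
class DimetricGrid:
    """Screen geometry of the 2:1 dimetric grid (pure parallel projection)."""

    cell_w_px: int = 32
    cell_h_px: int | None = None
    z_scale_px: float | None = None
    origin_px: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.cell_w_px <= 0 or self.cell_w_px % 2:
            raise ValueError("cell_w_px must be an even positive integer")
        if self.cell_h_px is None:
            object.__setattr__(self, "cell_h_px", self.cell_w_px // 2)
        if self.cell_h_px <= 0:
            raise ValueError("cell_h_px must be positive")
        if self.z_scale_px is None:
            object.__setattr__(self, "z_scale_px", self.cell_h_px / 2)


#: Cavalier/military projection: full-height cells, as if seen from higher
#: up; same affine contract, different constants.
CAVALIER_GRID_KW = dict(cell_w_px=32, cell_h_px=32)


@dataclass
class Placement:
    record_index: int
    gx: int
    gy: int
    gz: float = 0.0
    group_key: object = None
    selected: bool = False


@dataclass
class LayoutResult:
    """Placements plus bookkeeping (skipped records, group keys in order)."""

    placements: list
    skipped: int = 0
    group_keys: list = field(default_factory=list)


def select_lod(footprint_px: float, policy: LodPolicy | None = None) -> str:
    """Pick the level of detail from the glyph's on-screen footprint edge.

    Below ``pixel_max_px`` (2 px) the glyph is a bare pixel; above
    ``detail_min_px`` (64 px) the full detail geometry is shown; between
    the two (inclusive at both boundaries) the iconic cube is used.
    """
    policy = policy or LodPolicy()
    if footprint_px <= 0:
        raise ValueError("footprint must be positive")
    if footprint_px < policy.pixel_max_px:
        return "pixel"
    if footprint_px > policy.detail_min_px:
        return "detail"
    return "iconic"


def project(gx: float, gy: float, gz: float, grid: DimetricGrid) -> tuple:
    """Grid cell (+height) -> screen point, pure parallel projection.

    ``sx = ox + (gx - gy) * cell_w/2``; ``sy = oy + (gx + gy) * cell_h/2
    - gz * z_scale``.  Screen y grows downward; larger ``gx + gy`` is
    nearer the camera.
    """
    ox, oy = grid.origin_px
    sx = ox + (gx - gy) * grid.cell_w_px / 2
    sy = oy + (gx + gy) * grid.cell_h_px / 2 - gz * grid.z_scale_px
    return (sx, sy)


# ---------------------------------------------------------------------------
# age pyramid


def layout_age_pyramid(
    dataset: Dataset,
    sex_var: str = "sex",
    age_var: str = "age",
    stage_var: str = "t_stage",
    bin_years: int = 5,
    male_token: str = "M",
    female_token: str = "F",
    indices: Sequence[int] | None = None,
) -> LayoutResult:
    """Back-to-back age pyramid: males left (gx <= -1), females right.

    Row ``gy = floor(age / bin_years)`` (age 0 at row 0; the renderer
    flips rows so the youngest sit at the base of the picture).  The
    column magnitude is the 1-based stage rank plus one; records with
    missing stage take column 1, right against the axis, where they stay
    visible — absent staging is a finding, not noise.  Cell collisions
    stack outward to the next free column.  Records with an unknown sex
    token are skipped and counted.
    """
    if bin_years <= 0:
        raise ValueError("bin_years must be positive")
    stage_meta = dataset.meta(stage_var)
    if indices is None:
        indices = range(len(dataset))

    occupied = set()
    placements = []
    skipped = 0
    for i in indices:
        rec = dataset.records[i]
        sex = rec.values.get(sex_var, MISSING)
        age = rec.values.get(age_var, MISSING)
        if sex == male_token:
            side = -1
        elif sex == female_token:
            side = +1
        else:
            skipped += 1
            continue
        if age is MISSING:
            skipped += 1
            continue
        row = int(math.floor(float(age) / bin_years))
        stage = rec.values.get(stage_var, MISSING)
        if stage is MISSING:
            col = 1
        else:
            col = stage_meta.rank(stage) + 2  # 1-based rank, then +1
        while (side * col, row) in occupied:
            col += 1  # stack outward on collision
        occupied.add((side * col, row))
        placements.append(Placement(record_index=i, gx=side * col, gy=row))
    return LayoutResult(placements=placements, skipped=skipped)


# ---------------------------------------------------------------------------
# grouped small multiples


def _period_key(value: float, base: int, width: int) -> tuple:
    start = base + int(math.floor((float(value) - base) / width)) * width
    return (start, f"{start}-{start + width - 1}")


def layout_grouped(
    dataset: Dataset,
    group_var: str,
    inner: Callable[..., LayoutResult],
    group_bin: int | None = None,
    gap_cells: int = 2,
    indices: Sequence[int] | None = None,
    **inner_kwargs,
) -> LayoutResult:
    """Partition records by ``group_var`` and lay out each group with
    ``inner``, offsetting groups left-to-right in ascending key order.

    ``group_bin`` bins a numeric grouping variable into fixed-width
    periods labelled ``"start-end"`` (e.g. five-year periods).  Groups are
    shifted along the screen-horizontal direction (``gx + d, gy - d``),
    which preserves depth and keeps bounding boxes disjoint.  Every record
    with a non-missing group value lands in exactly one group; an empty
    group still appears in ``group_keys``.
    """
    if indices is None:
        indices = range(len(dataset))
    values = dataset.column(group_var)

    groups: dict = {}
    skipped = 0
    if group_bin is not None:
        numeric = [float(values[i]) for i in indices if values[i] is not MISSING]
        base = int(min(numeric)) if numeric else 0
    for i in indices:
        v = values[i]
        if v is MISSING:
            skipped += 1
            continue
        if group_bin is not None:
            sort_key, label = _period_key(v, base, group_bin)
        else:
            sort_key, label = v, v
        groups.setdefault((sort_key, label), []).append(i)

    placements = []
    group_keys = []
    next_min_sx = None  # running bound on (gx - gy), screen-horizontal units
    for (sort_key, label) in sorted(groups):
        sub = inner(dataset, indices=groups[(sort_key, label)], **inner_kwargs)
        skipped += sub.skipped
        group_keys.append(label)
        if not sub.placements:
            continue
        lo = min(p.gx - p.gy for p in sub.placements)
        hi = max(p.gx - p.gy for p in sub.placements)
        if next_min_sx is None:
            shift = 0
        else:
            # gx+d, gy-d moves (gx-gy) by 2d and keeps depth gx+gy
            shift = math.ceil((next_min_sx - lo) / 2)
        for p in sub.placements:
            placements.append(
                Placement(
                    record_index=p.record_index,
                    gx=p.gx + shift,
                    gy=p.gy - shift,
                    gz=p.gz,
                    group_key=label,
                    selected=p.selected,
                )
            )
        next_min_sx = (hi + 2 * shift) + gap_cells * 2
    return LayoutResult(placements=placements, skipped=skipped, group_keys=group_keys)


# ---------------------------------------------------------------------------
# discretized scatter


# ring offsets for the deterministic spiral search, precomputed lazily
def _ring_offsets(radius: int):
    out = []
    for r in range(1, radius + 1):
        ring = []
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                if max(abs(dx), abs(dy)) == r:
                    ring.append((dx, dy))
        ring.sort()  # fixed, platform-independent order
        out.extend(ring)
    return out


def _discretize(value, meta, bins: int):
    if value is MISSING:
        return None
    if meta.is_numeric:
        lo, hi = float(meta.domain[0]), float(meta.domain[1])
        if hi <= lo:
            return 0
        idx = int((float(value) - lo) / (hi - lo) * bins)
        return min(max(idx, 0), bins - 1)
    return meta.rank(value)


def layout_scatter_discrete(
    dataset: Dataset,
    x_var: str,
    y_var: str,
    x_bins: int = 20,
    y_bins: int = 20,
    max_jitter_radius: int = 10,
    indices: Sequence[int] | None = None,
) -> LayoutResult:
    """Discretized scatter plot on the grid with deterministic jittering.

    Each record lands at the cell of its binned (x, y) values; when the
    cell is taken, a square-spiral search (processed in record order, with
    a fixed offset ordering — never random) finds the nearest free cell,
    so the same dataset always yields the same picture.  If no free cell
    exists within ``max_jitter_radius``, a :class:`LayoutError` reports
    how many records overflowed.
    """
    if indices is None:
        indices = range(len(dataset))
    mx, my = dataset.meta(x_var), dataset.meta(y_var)
    offsets = _ring_offsets(max_jitter_radius)

    occupied = set()
    placements = []
    skipped = 0
    overflow = 0
    for i in indices:
        rec = dataset.records[i]
        bx = _discretize(rec.values.get(x_var, MISSING), mx, x_bins)
        by = _discretize(rec.values.get(y_var, MISSING), my, y_bins)
        if bx is None or by is None:
            skipped += 1
            continue
        cell = (bx, by)
        if cell in occupied:
            for dx, dy in offsets:
                cand = (bx + dx, by + dy)
                if cand not in occupied:
                    cell = cand
                    break
            else:
                overflow += 1
                continue
        occupied.add(cell)
        placements.append(Placement(record_index=i, gx=cell[0], gy=cell[1]))
    if overflow:
        raise LayoutError(
            f"grid saturated: {overflow} record(s) found no free cell within "
            f"radius {max_jitter_radius}"
        )
    return LayoutResult(placements=placements, skipped=skipped)


# ---------------------------------------------------------------------------
# painter's order


def paint_order(placements: Sequence[Placement]) -> list:
    """Indices into ``placements`` in back-to-front drawing order.

    Ascending by depth ``gx + gy`` (farther first), ties by ``gx``, then
    by record index — under the standard dimetric camera a glyph is then
    never overdrawn by one behind it.
    """
    return sorted(
        range(len(placements)),
        key=lambda k: (
            placements[k].gx + placements[k].gy,
            placements[k].gx,
            placements[k].record_index,
        ),
    )
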