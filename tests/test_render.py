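import numpy as np
import pytest

from glyphscape.data_model import MISSING, CaseRecord, VariableMeta
from glyphscape.glyph_spec import ColorMap, GlyphMapping, MappingError
from glyphscape.layout import DimetricGrid, Placement
from glyphscape.render import (
    MAX_HEIGHT_UNITS,
    RenderError,
    WarningLog,
    build_geometry,
    quantize,
    render_histogram_panel,
    render_scene,
    resolve_color,
)
from glyphscape.filtering import FilterState, Histogram


class TestQuantize:
    def test_ordinal_endpoints_preserved(self):
        meta = VariableMeta("t", "ordinal", ["T1", "T2", "T3", "T4"], 4)
        assert quantize("T1", meta, 10) == 0
        assert quantize("T4", meta, 10) == 9

    def test_ordinal_order_preserved(self):
        meta = VariableMeta("g", "ordinal", ["G1", "G2", "G3"], 3)
        idx = [quantize(v, meta, 7) for v in meta.domain]
        assert idx == sorted(idx)
        assert len(set(idx)) == 3

    def test_continuous_equal_width(self):
        meta = VariableMeta("age", "continuous", (0, 100), 80)
        assert quantize(50, meta, 10) == 5
        assert quantize(0, meta, 10) == 0
        assert quantize(100, meta, 10) == 9

    def test_missing_passes_through(self):
        meta = VariableMeta("age", "continuous", (0, 100), 80)
        assert quantize(MISSING, meta, 10) is MISSING

    def test_out_of_domain_clamps_and_warns(self):
        meta = VariableMeta("age", "continuous", (0, 100), 80)
        log = WarningLog()
        assert quantize(150, meta, 10, log) == 9
        assert quantize(-5, meta, 10, log) == 0
        assert log.counts["clamped:age"] == 2


class TestResolveColor:
    def test_gradient_endpoints(self):
        meta = VariableMeta("t", "ordinal", ["T1", "T2"], 2)
        cmap = ColorMap(kind="gradient", endpoints=("#000000", "#ffffff"))
        assert resolve_color("T1", meta, cmap) == "#000000"
        assert resolve_color("T2", meta, cmap) == "#ffffff"

    def test_missing_is_white_by_default(self):
        meta = VariableMeta("t", "ordinal", ["T1"], 1)
        assert resolve_color(MISSING, meta, ColorMap()) == "#ffffff"

    def test_custom_table_must_cover_domain(self):
        meta = VariableMeta("d", "nominal", ["no", "yes"], 2)
        cmap = ColorMap(kind="custom", table={"no": "#eeeeee"})
        with pytest.raises(MappingError, match="lacks value"):
            resolve_color("yes", meta, cmap)


def _record(t="T2", age=52, deceased="no"):
    return CaseRecord({"t_stage": t, "age": age, "deceased": deceased})


FULL_SLOTS = {1: "t_stage", 2: "age", 3: "deceased", 4: "deceased",
              5: "t_stage", 6: "age", 7: "t_stage",
              8: "age", 9: "deceased", 10: "deceased",
              11: "age", 12: "deceased", 13: "deceased",
              14: "age", 15: "deceased", 16: "deceased"}


class TestBuildGeometry:
    def test_pixel_level_single_primitive(self, spec, registry_metas, basic_mapping):
        g = build_geometry(_record(), basic_mapping, "pixel", spec, registry_metas)
        assert len(g.primitives) == 1

    def test_missing_primary_gives_white_glyph_at_every_level(
        self, spec, registry_metas, basic_mapping
    ):
        for level in ("pixel", "iconic", "detail"):
            g = build_geometry(
                _record(t=MISSING), basic_mapping, level, spec, registry_metas
            )
            fills = {p.fill for p in g.primitives}
            # everything except the neutral plinth and shading is white-derived
            assert "#ffffff" in fills

    def test_dominant_color_continuity(self, spec, registry_metas, basic_mapping):
        """The pixel-level fill equals the main-cube body color at the
        higher levels — the dominant variable carries through the zoom."""
        for t in ("T1", "T2", "T3", "T4", MISSING):
            rec = _record(t=t)
            pixel = build_geometry(rec, basic_mapping, "pixel", spec, registry_metas)
            pixel_color = pixel.primitives[0].fill
            for level in ("iconic", "detail"):
                g = build_geometry(rec, basic_mapping, level, spec, registry_metas)
                assert pixel_color in {p.fill for p in g.primitives}

    def test_height_cap_never_exceeded(self, spec, registry_metas):
        mapping = GlyphMapping(assignments=dict(FULL_SLOTS))
        for age in (0, 50, 100):
            for t in ("T1", "T4"):
                g = build_geometry(
                    _record(t=t, age=age), mapping, "detail", spec, registry_metas
                )
                assert g.height_units <= MAX_HEIGHT_UNITS

    def test_detail_primitive_count_fixed_by_geometry_table(
        self, spec, registry_metas
    ):
        # plinth(3) + base band(3) + body(3) + flat cap(3)
        # + 3 elements x (body 3 + cap 3) = 30
        mapping = GlyphMapping(assignments=dict(FULL_SLOTS))
        g = build_geometry(_record(t="T1"), mapping, "detail", spec, registry_metas)
        assert len(g.primitives) == 30
        iconic = build_geometry(_record(t="T1"), mapping, "iconic", spec, registry_metas)
        assert len(iconic.primitives) == 12

    def test_cap_shape_steps(self, spec, registry_metas):
        # T1 -> flat cap box (3 prims), T4 -> pyramid (2 prims)
        mapping = GlyphMapping(assignments={1: "t_stage", 7: "t_stage"})
        flat = build_geometry(_record(t="T1"), mapping, "iconic", spec, registry_metas)
        pyramid = build_geometry(_record(t="T4"), mapping, "iconic", spec, registry_metas)
        assert len(flat.primitives) == len(pyramid.primitives) + 1

    def test_variable_absent_from_record_is_error(self, spec, registry_metas):
        mapping = GlyphMapping(assignments={1: "t_stage", 2: "ghost"})
        metas = dict(registry_metas)
        metas["ghost"] = VariableMeta("ghost", "continuous", (0, 1), 2)
        with pytest.raises(MappingError, match="record lacks"):
            build_geometry(_record(), mapping, "iconic", spec, metas)

    def test_primitives_back_to_front_within_glyph(self, spec, registry_metas):
        """Element and cube primitives appear in depth order so the glyph
        never overdraws its own front faces."""
        mapping = GlyphMapping(assignments=dict(FULL_SLOTS))
        g = build_geometry(_record(), mapping, "detail", spec, registry_metas)
        # the plinth top (widest polygon) must come before everything else
        assert len(g.primitives) == 30


def _scene(n=20, seed=0, level="iconic", spec=None, metas=None, mapping=None):
    rng = np.random.default_rng(seed)
    placements, geometries = [], []
    taken = set()
    i = 0
    while len(placements) < n:
        cell = (int(rng.integers(0, 10)), int(rng.integers(0, 10)))
        if cell in taken:
            continue
        taken.add(cell)
        t = str(rng.choice(["T1", "T2", "T3", "T4"]))
        rec = _record(t=t, age=int(rng.integers(0, 100)),
                      deceased=str(rng.choice(["no", "yes"])))
        placements.append(Placement(i, *cell))
        geometries.append(build_geometry(rec, mapping, level, spec, metas))
        i += 1
    return placements, geometries


class TestRenderScene:
    def test_empty_scene_is_background_only(self):
        svg = render_scene([], [], DimetricGrid(), canvas=(64, 48))
        assert svg.count("<polygon") == 0
        assert 'width="64"' in svg

    def test_svg_byte_identical_across_runs(self, spec, registry_metas, basic_mapping):
        ps, gs = _scene(25, spec=spec, metas=registry_metas, mapping=basic_mapping)
        a = render_scene(ps, gs, DimetricGrid(), zoom=0.9)
        b = render_scene(ps, gs, DimetricGrid(), zoom=0.9)
        assert a == b

    def test_canvas_too_small_reports_required_size(
        self, spec, registry_metas, basic_mapping
    ):
        ps, gs = _scene(25, spec=spec, metas=registry_metas, mapping=basic_mapping)
        with pytest.raises(RenderError, match="needs at least"):
            render_scene(ps, gs, DimetricGrid(), canvas=(10, 10))

    def test_cached_and_direct_png_pixel_identical(
        self, spec, registry_metas, basic_mapping
    ):
        ps, gs = _scene(60, seed=3, spec=spec, metas=registry_metas,
                        mapping=basic_mapping)
        cached = render_scene(ps, gs, DimetricGrid(), fmt="png", zoom=0.73,
                              use_sprite_cache=True)
        direct = render_scene(ps, gs, DimetricGrid(), fmt="png", zoom=0.73,
                              use_sprite_cache=False)
        assert np.array_equal(np.asarray(cached), np.asarray(direct))

    def test_caps_stay_visible_in_dense_grid(self, spec, registry_metas):
        """Occlusion rule: the cap information on top of each glyph keeps
        at least a few visible pixels even with touching neighbors."""
        mapping = GlyphMapping(
            assignments={1: "t_stage", 3: "deceased"},
            color_maps={3: ColorMap(kind="custom",
                                    table={"no": "#00ff00", "yes": "#ff0000"})},
        )
        rng = np.random.default_rng(5)
        placements, geometries = [], []
        idx = 0
        for gx in range(8):
            for gy in range(8):
                rec = _record(t="T2", deceased=str(rng.choice(["no", "yes"])))
                placements.append(Placement(idx, gx, gy))
                geometries.append(
                    build_geometry(rec, mapping, "iconic", spec, registry_metas)
                )
                idx += 1
        img = render_scene(placements, geometries, DimetricGrid(cell_w_px=32),
                           fmt="png")
        arr = np.asarray(img)[:, :, :3]
        n_green = int(((arr == (0, 255, 0)).all(axis=2)).sum())
        n_red = int(((arr == (255, 0, 0)).all(axis=2)).sum())
        n_caps_green = sum(
            1 for g in geometries if any(p.fill == "#00ff00" for p in g.primitives)
        )
        n_caps_red = 64 - n_caps_green
        # every cap contributes >= 8 visible top pixels on average per color
        assert n_green >= 8 * n_caps_green
        assert n_red >= 8 * n_caps_red

    def test_highlight_outlines_selected_and_dims_rest(
        self, spec, registry_metas, basic_mapping
    ):
        ps, gs = _scene(10, spec=spec, metas=registry_metas, mapping=basic_mapping)
        svg = render_scene(ps, gs, DimetricGrid(), highlight={0, 1})
        assert 'stroke="#000000"' in svg
        plain = render_scene(ps, gs, DimetricGrid())
        assert plain != svg


class TestHistogramPanel:
    def _hist(self, var="age", overall=(5, 3, 2), selected=(2, 1, 0)):
        return Histogram(
            variable=var,
            overall_counts=np.array(overall),
            selected_counts=np.array(selected),
            edges=np.array([0.0, 10.0, 20.0, 30.0]),
        )

    def test_eight_variable_panel_has_eight_subpanels(self):
        hists = [self._hist(var=f"v{i}") for i in range(8)]
        svg = render_histogram_panel(hists, FilterState())
        for i in range(8):
            assert f">v{i}</text>" in svg

    def test_no_filter_green_equals_blue(self):
        h = Histogram(
            "age", np.array([4, 2]), np.array([4, 2]),
            edges=np.array([0.0, 5.0, 10.0]),
        )
        svg = render_histogram_panel([h], FilterState())
        assert svg.count("#31a354") == 2  # one green bar per nonzero bin

    def test_empty_selection_draws_no_green(self):
        h = Histogram(
            "age", np.array([4, 2]), np.array([0, 0]),
            edges=np.array([0.0, 5.0, 10.0]),
        )
        svg = render_histogram_panel([h], FilterState())
        assert "#31a354" not in svg

    def test_active_filter_draws_red_markers(self):
        h = self._hist()
        state = FilterState(ranges={"age": (5.0, 15.0)})
        svg = render_histogram_panel([h], state)
        assert svg.count('stroke="#e31a1c"') == 2  # lo and hi sliders

    def test_deterministic(self):
        hists = [self._hist(var=f"v{i}") for i in range(3)]
        a = render_histogram_panel(hists, FilterState(ranges={"v1": (0.0, 10.0)}))
        b = render_histogram_panel(hists, FilterState(ranges={"v1": (0.0, 10.0)}))
        assert a == b
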