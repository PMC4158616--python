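"""Conjunctive range filters, histograms, and subgroup comparison.

The linked-histogram view divides a cohort into subgroups: each variable
carries at most one filter (a numeric ``[lo, hi]`` range or a category
subset), and a record is selected when it satisfies *all* of them.  A
:class:`Histogram` holds both the overall bin counts (the blue area of the
panel) and the counts of the currently selected subset (the green area),
so selected counts can never exceed overall counts bin-wise.

Numeric bins are half-open ``[lo, hi)`` with the last bin closed, the
``numpy.histogram`` convention.  Missing values get an optional dedicated
bin (on by default) so that a white-glyph population — records without
staging — stays visible in the panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import MISSING, Dataset

__all__ = [
    "FilterState",
    "Histogram",
    "FilterError",
    "apply_filter",
    "compute_histogram",
    "subgroup_summary",
    "SubgroupSummary",
]


class FilterError(ValueError):
    """Ill-formed filter: bad range, unknown variable or category."""


@dataclass
class FilterState:
    """Per-variable filters, combined conjunctively.

    ``ranges`` maps a variable either to a numeric ``(lo, hi)`` pair
    (inclusive both ends — the red sliders of the histogram panel) or to a
    collection of category tokens.  ``include_missing`` controls, per
    variable, whether records missing that variable pass its filter
    (default: they do not).
    """

    ranges: dict = field(default_factory=dict)
    include_missing: dict = field(default_factory=dict)

    def is_active(self, variable: str) -> bool:
        return variable in self.ranges

    def merged_with(self, other: "FilterState") -> "FilterState":
        overlap = set(self.ranges) & set(other.ranges)
        if overlap:
            raise FilterError(f"filters overlap on variables {sorted(overlap)}")
        return FilterState(
            ranges={**self.ranges, **other.ranges},
            include_missing={**self.include_missing, **other.include_missing},
        )


def apply_filter(dataset: Dataset, state: FilterState) -> np.ndarray:
    """Boolean selection mask: AND over all active per-variable filters.

    An empty filter state selects everything.  A numeric range demands a
    numeric (interval/continuous) or ordinal variable — a range over an
    unordered nominal domain is meaningless and raises
    :class:`FilterError`; nominal variables take category subsets.
    """
    mask = np.ones(len(dataset), dtype=bool)
    for var, cond in state.ranges.items():
        meta = dataset.meta(var)  # KeyError for unknown variables
        include_missing = bool(state.include_missing.get(var, False))
        values = dataset.column(var)
        missing = np.array([v is MISSING for v in values])

        if _is_numeric_range(cond):
            lo, hi = float(cond[0]), float(cond[1])
            if lo > hi:
                raise FilterError(f"range for {var!r} has lo > hi: {cond}")
            if meta.scale == "nominal":
                raise FilterError(
                    f"range filter on nominal variable {var!r} without a "
                    f"declared order; use a category subset"
                )
            if meta.scale == "ordinal":
                # range over ordinal ranks, endpoints in rank units
                ranks = np.array(
                    [meta.rank(v) if v is not MISSING else -1 for v in values],
                    dtype=float,
                )
                ok = (ranks >= lo) & (ranks <= hi)
            else:
                arr = np.array(
                    [float(v) if v is not MISSING else np.nan for v in values]
                )
                with np.errstate(invalid="ignore"):
                    ok = (arr >= lo) & (arr <= hi)
        else:
            subset = set(cond) if not isinstance(cond, str) else {cond}
            domain = set(map(str, meta.domain)) if not meta.is_numeric else None
            if domain is not None:
                unknown = subset - domain
                if unknown:
                    raise FilterError(
                        f"categories {sorted(unknown)} not in the domain of {var!r}"
                    )
            ok = np.array(
                [v is not MISSING and str(v) in subset for v in values]
            )
        ok = np.where(missing, include_missing, ok)
        mask &= ok
    return mask


def _is_numeric_range(cond) -> bool:
    return (
        isinstance(cond, (tuple, list))
        and len(cond) == 2
        and all(isinstance(c, (int, float)) and not isinstance(c, bool) for c in cond)
    )


@dataclass
class Histogram:
    """Overall vs selected bin counts for one variable.

    ``edges`` is set for numeric bins (half-open, last closed),
    ``categories`` for categorical ones.  ``overall_missing`` /
    ``selected_missing`` hold the optional missing-value bin.
    """

    variable: str
    overall_counts: np.ndarray
    selected_counts: np.ndarray
    edges: np.ndarray | None = None
    categories: list | None = None
    overall_missing: int = 0
    selected_missing: int = 0

    def labels(self) -> list:
        if self.categories is not None:
            return [str(c) for c in self.categories]
        return [
            f"[{self.edges[i]:g},{self.edges[i + 1]:g})"
            for i in range(len(self.edges) - 1)
        ]


def compute_histogram(
    dataset: Dataset,
    variable: str,
    bin_width: float | None = None,
    edges: Sequence[float] | None = None,
    categories: Sequence | None = None,
    mask: np.ndarray | None = None,
    missing_bin: bool = True,
) -> Histogram:
    """Histogram of one variable; overall counts ignore ``mask``, selected
    counts apply it.

    Exactly one binning may be forced (``bin_width``, explicit ``edges``,
    or ``categories``); by default numeric variables get width-based bins
    covering the observed range and categorical variables use their
    domain.  Explicit edges must be strictly increasing.
    """
    meta = dataset.meta(variable)
    values = dataset.column(variable)
    if mask is None:
        mask = np.ones(len(dataset), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(dataset):
        raise FilterError("mask length does not match dataset")

    present = [(v, m) for v, m in zip(values, mask) if v is not MISSING]
    overall_missing = len(values) - len(present) if missing_bin else 0
    selected_missing = (
        sum(1 for v, m in zip(values, mask) if v is MISSING and m)
        if missing_bin
        else 0
    )

    if categories is not None or (meta.scale in ("nominal", "ordinal") and edges is None and bin_width is None):
        cats = list(categories) if categories is not None else list(meta.domain)
        index = {str(c): i for i, c in enumerate(cats)}
        overall = np.zeros(len(cats), dtype=int)
        selected = np.zeros(len(cats), dtype=int)
        for v, m in present:
            i = index.get(str(v))
            if i is None:
                raise FilterError(
                    f"value {v!r} of {variable!r} outside the binning categories"
                )
            overall[i] += 1
            if m:
                selected[i] += 1
        return Histogram(
            variable, overall, selected, categories=cats,
            overall_missing=overall_missing, selected_missing=selected_missing,
        )

    vals = np.array([float(v) for v, _ in present]) if present else np.array([])
    sel_vals = np.array([float(v) for v, m in present if m]) if present else np.array([])
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise FilterError(
                f"explicit bin edges must be strictly increasing, got {list(edges)}"
            )
        if len(vals) and (vals.min() < edges[0] or vals.max() > edges[-1]):
            raise FilterError(
                f"bin edges do not cover the observed range of {variable!r}"
            )
    else:
        width = float(bin_width) if bin_width else _default_width(meta)
        lo = np.floor(vals.min() / width) * width if len(vals) else 0.0
        hi = vals.max() if len(vals) else width
        nbins = max(1, int(np.ceil((hi - lo) / width)))
        if lo + nbins * width <= hi:  # max exactly on the edge
            nbins += 1
        edges = lo + width * np.arange(nbins + 1)
    overall, _ = np.histogram(vals, bins=edges)
    selected, _ = np.histogram(sel_vals, bins=edges)
    return Histogram(
        variable, overall, selected, edges=np.asarray(edges, dtype=float),
        overall_missing=overall_missing, selected_missing=selected_missing,
    )


def _default_width(meta) -> float:
    lo, hi = float(meta.domain[0]), float(meta.domain[1])
    span = hi - lo
    if span <= 0:
        return 1.0
    return max(span / 20.0, 1e-9)


@dataclass
class SubgroupSummary:
    """Parallel per-variable count tables for two subgroups."""

    tables: dict  # variable -> DataFrame with columns A, B
    total_a: int
    total_b: int


def subgroup_summary(
    dataset: Dataset,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    variables: Sequence[str],
    **hist_kwargs,
) -> SubgroupSummary:
    """Side-by-side bin counts for two subgroups over the given variables.

    Feeds the two-cohort comparisons (e.g. thyroid vs lung age pyramids):
    each variable yields a table of parallel counts for subgroup A and B
    on a shared binning.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if len(mask_a) != len(dataset) or len(mask_b) != len(dataset):
        raise FilterError("mask length does not match dataset")
    tables = {}
    for var in variables:
        ha = compute_histogram(dataset, var, mask=mask_a, **hist_kwargs)
        hb = compute_histogram(
            dataset, var,
            mask=mask_b,
            edges=None if ha.edges is None else ha.edges,
            categories=ha.categories,
            **{k: v for k, v in hist_kwargs.items() if k not in ("edges", "categories")},
        )
        labels = ha.labels() + ["missing"]
        a_counts = list(ha.selected_counts) + [ha.selected_missing]
        b_counts = list(hb.selected_counts) + [hb.selected_missing]
        tables[var] = pd.DataFrame({"A": a_counts, "B": b_counts}, index=labels)
    return SubgroupSummary(
        tables=tables, total_a=int(mask_a.sum()), total_b=int(mask_b.sum())
    )
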