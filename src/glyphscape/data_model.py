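"""Record/table model, variable metadata, and delimited-text I/O.

A :class:`Dataset` is an ordered list of case records plus per-variable
metadata (:class:`VariableMeta`).  Record order is significant and preserved:
the default mass view places glyphs in database order, so a round trip through
CSV must reproduce records, their order, and every missing cell exactly.

Missingness is modelled with a dedicated singleton, :data:`MISSING`, distinct
from every legal value including the empty string.  On disk a missing cell is
written as the empty string; on read both the empty string and a configurable
sentinel (default ``"NA"``) map to :data:`MISSING`, because registry exports
use either convention.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "CaseRecord",
    "VariableMeta",
    "Dataset",
    "DataModelError",
    "read_cases",
    "write_cases",
    "infer_variable_meta",
]


class _Missing:
    """Singleton marker for a missing value; falsy, distinct from ''."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False

    def __reduce__(self):
        return (_Missing, ())


MISSING = _Missing()

#: Scales of measurement a variable may carry.
SCALES = ("nominal", "ordinal", "interval", "continuous")


class DataModelError(ValueError):
    """Malformed input table or inconsistent variable metadata."""


@dataclass
class CaseRecord:
    """One case: a mapping variable-name -> value (or :data:`MISSING`)."""

    values: dict

    def __getitem__(self, name):
        return self.values[name]

    def get(self, name, default=None):
        return self.values.get(name, default)


@dataclass
class VariableMeta:
    """Measurement scale, ordered domain and distinct-value count.

    ``domain`` is an ordered list of category tokens for nominal/ordinal
    variables, or a ``(lo, hi)`` numeric range for interval/continuous ones.
    For ordinal variables the domain order is explicit and total — ordinal
    order is never inferred from lexical sorting, only declared, because a
    silently invented order is exactly the misinterpretation the mapping
    validator exists to catch.
    """

    name: str
    scale: str
    domain: Sequence
    distinct_count: int
    missing_count: int = 0

    def __post_init__(self):
        if self.scale not in SCALES:
            raise DataModelError(
                f"unknown scale {self.scale!r} for variable {self.name!r}; "
                f"expected one of {SCALES}"
            )

    @property
    def is_numeric(self) -> bool:
        return self.scale in ("interval", "continuous")

    def rank(self, value) -> int:
        """0-based position of ``value`` in an ordinal/nominal domain."""
        return list(self.domain).index(value)


@dataclass
class Dataset:
    """Ordered records plus variable metadata and a provenance tag."""

    records: list
    variables: list
    provenance: str = ""

    def __post_init__(self):
        if not self.variables:
            return  # metadata still being inferred
        known = {v.name for v in self.variables}
        for i, rec in enumerate(self.records):
            extra = set(rec.values) - known
            if extra:
                raise DataModelError(
                    f"record {i} carries unknown variables {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variable_names(self) -> list:
        return [v.name for v in self.variables]

    def meta(self, name: str) -> VariableMeta:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def column(self, name: str) -> list:
        """All values of one variable, in record order (MISSING included)."""
        if name not in self.variable_names:
            raise KeyError(name)
        return [rec.values.get(name, MISSING) for rec in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        """Copy into a DataFrame; MISSING becomes NaN/None."""
        cols = {}
        for v in self.variables:
            vals = self.column(v.name)
            cols[v.name] = [None if val is MISSING else val for val in vals]
        df = pd.DataFrame(cols)
        for v in self.variables:
            if v.is_numeric:
                df[v.name] = pd.to_numeric(df[v.name])
        return df


# ---------------------------------------------------------------------------
# value parsing


def _parse_cell(text: str, na_sentinel: str):
    if text == "" or text == na_sentinel:
        return MISSING
    return text


def _coerce_numeric(value):
    """str -> int/float where the token is numeric, else unchanged."""
    if isinstance(value, str):
        try:
            f = float(value)
        except ValueError:
            return value
        if f.is_integer() and "." not in value and "e" not in value.lower():
            return int(value)
        return f
    return value


# ---------------------------------------------------------------------------
# metadata inference


def infer_variable_meta(
    dataset: Dataset,
    name: str,
    declared_scale: str | None = None,
    declared_order: Sequence | None = None,
) -> VariableMeta:
    """Infer (or apply declared) metadata for one variable.

    Inference rule: all non-missing values numeric -> ``continuous``;
    otherwise ``nominal``.  Ordinal and interval scales are only ever
    declared.  ``declared_order`` fixes the ordinal domain order and must
    cover every observed value.
    """
    values = dataset.column(name)
    non_missing = [v for v in values if v is not MISSING]
    missing_count = len(values) - len(non_missing)
    distinct = sorted(set(map(str, non_missing)))

    numeric = []
    all_numeric = len(non_missing) > 0
    for v in non_missing:
        c = _coerce_numeric(v)
        if isinstance(c, (int, float)):
            numeric.append(c)
        else:
            all_numeric = False
            break

    scale = declared_scale
    if scale is None:
        scale = "continuous" if all_numeric else "nominal"
    if scale not in SCALES:
        raise DataModelError(f"unknown declared scale {scale!r} for {name!r}")

    if scale in ("interval", "continuous"):
        if not all_numeric:
            raise DataModelError(
                f"variable {name!r} declared {scale} but holds non-numeric values"
            )
        domain = (min(numeric), max(numeric)) if numeric else (0.0, 0.0)
        distinct_count = len(set(numeric))
    elif scale == "ordinal":
        if declared_order is None:
            raise DataModelError(
                f"ordinal variable {name!r} needs an explicit declared_order"
            )
        observed = set(str(v) for v in non_missing)
        missing_from_order = observed - set(map(str, declared_order))
        if missing_from_order:
            raise DataModelError(
                f"declared_order for {name!r} lacks observed values "
                f"{sorted(missing_from_order)}"
            )
        domain = list(declared_order)
        distinct_count = len(observed)
    else:  # nominal
        domain = list(declared_order) if declared_order is not None else distinct
        distinct_count = len(distinct)

    return VariableMeta(
        name=name,
        scale=scale,
        domain=domain,
        distinct_count=distinct_count,
        missing_count=missing_count,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_cases(
    path,
    delimiter: str = ",",
    declared_scales: Mapping[str, str] | None = None,
    declared_orders: Mapping[str, Sequence] | None = None,
    na_sentinel: str = "NA",
    sidecar: str | Path | None = "auto",
) -> Dataset:
    """Read a delimited table with a header row into a :class:`Dataset`.

    Empty cells (and ``na_sentinel``) become :data:`MISSING`.  A sidecar
    metadata file ``<path>.meta.yaml`` / ``.meta.json`` — declaring scales
    and ordinal orders — is picked up automatically unless ``sidecar`` is
    ``None`` or an explicit path.

    Raises :class:`DataModelError` on duplicate header names and on rows
    whose arity differs from the header (naming the offending line).
    """
    path = Path(path)
    declared_scales = dict(declared_scales or {})
    declared_orders = dict(declared_orders or {})

    side = _resolve_sidecar(path, sidecar)
    if side is not None:
        meta_doc = _load_sidecar(side)
        for var, spec in meta_doc.get("variables", {}).items():
            declared_scales.setdefault(var, spec.get("scale"))
            if "order" in spec:
                declared_orders.setdefault(var, spec["order"])
        declared_scales = {k: v for k, v in declared_scales.items() if v}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DataModelError(f"{path}: empty file, expected a header row")
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise DataModelError(f"{path}: duplicate header names {dups}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise DataModelError(
                    f"{path}: line {lineno} has {len(row)} fields, "
                    f"header has {len(header)}"
                )
            records.append(
                CaseRecord(
                    {h: _parse_cell(cell, na_sentinel) for h, cell in zip(header, row)}
                )
            )

    ds = Dataset(records=records, variables=[], provenance=str(path))
    # temporary metas so column() works during inference
    ds.variables = [
        VariableMeta(h, "nominal", [], 0) for h in header
    ]
    metas = []
    for h in header:
        meta = infer_variable_meta(
            ds, h,
            declared_scale=declared_scales.get(h),
            declared_order=declared_orders.get(h),
        )
        metas.append(meta)
    ds.variables = metas

    # coerce numeric columns to numbers in-place
    for meta in metas:
        if meta.is_numeric:
            for rec in ds.records:
                v = rec.values.get(meta.name, MISSING)
                if v is not MISSING:
                    rec.values[meta.name] = _coerce_numeric(v)
    return ds


def write_cases(dataset: Dataset, path, delimiter: str = ",") -> None:
    """Write a Dataset as UTF-8 delimited text; MISSING cells become ''."""
    path = Path(path)
    names = dataset.variable_names
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(names)
        for rec in dataset.records:
            row = []
            for n in names:
                v = rec.values.get(n, MISSING)
                row.append("" if v is MISSING else _format_cell(v))
            writer.writerow(row)


def write_sidecar(dataset: Dataset, path) -> None:
    """Write a YAML sidecar declaring scales and ordinal orders."""
    doc = {"variables": {}}
    for meta in dataset.variables:
        entry = {"scale": meta.scale}
        if meta.scale == "ordinal":
            entry["order"] = list(meta.domain)
        doc["variables"][meta.name] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _format_cell(v) -> str:
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def _resolve_sidecar(path: Path, sidecar):
    if sidecar is None:
        return None
    if sidecar != "auto":
        return Path(sidecar)
    for suffix in (".meta.yaml", ".meta.yml", ".meta.json"):
        cand = Path(str(path) + suffix)
        if cand.exists():
            return cand
    return None


def _load_sidecar(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
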