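"""Typed geometry spreadsheet: descriptors, selections, filtering, grouping,
topological-symmetry pooling and CSV/TSV round-trip.

A :class:`GeometryTable` holds one row per substructure hit — identified by a
structure id (refcode-like string) and a 1-based fragment index — and one
typed column per geometric descriptor.  Descriptor kinds distinguish ordinary
real-valued parameters (``linear``: distances, non-periodic angles) from
periodic ones (``circular``: torsions on −180°…+180°), integer labels used
for grouping, and free-text categories.

Rows can be *hidden*: hidden rows are retained in the table but excluded from
every selection, grouping, pooling and downstream statistic, which is the
batch analogue of narrowing a spreadsheet view to rows of interest.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Descriptor",
    "GeometryTable",
    "Selection",
    "PooledColumn",
    "FormatError",
    "read_table",
    "write_table",
    "filter_rows",
    "group_rows",
    "pool_equivalent",
    "parse_criteria",
]

KINDS = ("linear", "circular", "integer", "categorical")
RESERVED = ("_id", "_frag", "_hidden")

_COMPARATORS = ("<", "<=", ">", ">=", "==", "!=", "in-range")


class FormatError(ValueError):
    """Malformed input table (ragged rows, duplicate headers, bad values)."""


@dataclass(frozen=True)
class Descriptor:
    """Column metadata for one geometric parameter.

    Parameters
    ----------
    name : str
        Unique, non-empty column name.
    kind : {"linear", "circular", "integer", "categorical"}
        Statistical type of the column.  ``circular`` marks periodic
        quantities such as torsion angles.
    units : str
        Display units, e.g. ``"Å"`` or ``"deg"``; empty for unitless.
    period : float
        Period in the column's units; only meaningful for circular
        descriptors (default 360, the torsion convention).
    """

    name: str
    kind: str = "linear"
    units: str = ""
    period: float = 360.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("descriptor name must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.kind == "circular" and not self.period > 0:
            raise ValueError("circular descriptor requires period > 0")


@dataclass
class Selection:
    """Boolean row mask aligned to a table; selected rows are never hidden."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def complement(self, table: "GeometryTable") -> "Selection":
        """Non-hidden rows outside this selection."""
        return Selection(~self.mask & ~table.hidden)


@dataclass
class PooledColumn:
    """Topologically equivalent columns merged into a single distribution.

    ``values[i]`` came from cell ``(provenance[i][0], provenance[i][1])`` of
    the source table; order is column-major (all of the first source column,
    then the second, …) with missing cells dropped.
    """

    values: np.ndarray
    provenance: list[tuple[int, str]]
    kind: str = "linear"
    units: str = ""
    name: str = "pooled"

    def __len__(self) -> int:
        return len(self.values)


class GeometryTable:
    """Spreadsheet of fragment-geometry observations.

    Parameters
    ----------
    structure_id : sequence of str
        Refcode-like identifier per row.
    fragment_index : sequence of int
        1-based index of the hit within its structure; the pair
        ``(structure_id, fragment_index)`` must be unique per row.
    data : pandas.DataFrame
        One column per descriptor.  Numeric columns use NaN for missing
        cells; categorical columns use None/NaN.
    descriptors : mapping name -> Descriptor, optional
        Kinds are inferred for columns not listed (see :func:`infer_kind`).
    hidden : boolean array, optional
        Per-row hidden mask (default: nothing hidden).
    """

    def __init__(
        self,
        structure_id: Sequence[str],
        fragment_index: Sequence[int],
        data: pd.DataFrame,
        descriptors: Mapping[str, Descriptor] | None = None,
        hidden: np.ndarray | None = None,
    ) -> None:
        self.structure_id = np.asarray(structure_id, dtype=object)
        self.fragment_index = np.asarray(fragment_index, dtype=int)
        self.data = data.reset_index(drop=True)
        n = len(self.data)
        if len(self.structure_id) != n or len(self.fragment_index) != n:
            raise ValueError("id/index vectors must match the row count")
        if np.any(self.fragment_index < 1):
            raise ValueError("fragment_index is 1-based and must be >= 1")
        pairs = list(zip(self.structure_id, self.fragment_index))
        if len(set(pairs)) != n:
            raise ValueError("(structure_id, fragment_index) pairs must be unique")
        for col in self.data.columns:
            if col in RESERVED:
                raise ValueError(f"column name {col!r} is reserved")
        seen: set[str] = set()
        for col in self.data.columns:
            if col in seen:
                raise FormatError(f"duplicate column name {col!r}")
            seen.add(col)
        self.descriptors: dict[str, Descriptor] = {}
        descriptors = dict(descriptors or {})
        for col in self.data.columns:
            d = descriptors.get(col) or Descriptor(col, infer_kind(self.data[col]))
            if d.name != col:
                d = replace(d, name=col)
            self.descriptors[col] = d
        self.hidden = (
            np.zeros(n, dtype=bool) if hidden is None else np.asarray(hidden, dtype=bool)
        )
        if len(self.hidden) != n:
            raise ValueError("hidden mask length must equal the row count")

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def descriptor(self, name: str) -> Descriptor:
        try:
            return self.descriptors[name]
        except KeyError:
            raise KeyError(f"no such descriptor: {name!r}") from None

    def values(self, name: str, *, include_hidden: bool = False) -> np.ndarray:
        """Numeric values of a column with NaN as the missing marker.

        Hidden rows are replaced by NaN unless ``include_hidden`` is set, so
        they never leak into statistics.
        """
        d = self.descriptor(name)
        if d.kind == "categorical":
            raise TypeError(f"column {name!r} is categorical, not numeric")
        v = pd.to_numeric(self.data[name], errors="coerce").to_numpy(dtype=float)
        if not include_hidden:
            v = np.where(self.hidden, np.nan, v)
        return v

    def nonmissing(self, name: str) -> np.ndarray:
        """Non-missing, non-hidden values of a numeric column."""
        v = self.values(name)
        return v[~np.isnan(v)]

    def add_column(
        self, name: str, values, descriptor: Descriptor | None = None
    ) -> None:
        """Append a derived descriptor column (e.g. 180° − θ)."""
        if name in self.data.columns or name in RESERVED:
            raise ValueError(f"column {name!r} already exists or is reserved")
        vals = pd.Series(list(values))
        if len(vals) != self.n_rows:
            raise ValueError("column length must equal the row count")
        self.data[name] = vals
        self.descriptors[name] = descriptor or Descriptor(name, infer_kind(vals))

    def hide(self, selection: Selection) -> None:
        self.hidden |= selection.mask

    def unhide_all(self) -> None:
        self.hidden[:] = False

    def copy(self) -> "GeometryTable":
        return GeometryTable(
            self.structure_id.copy(),
            self.fragment_index.copy(),
            self.data.copy(),
            dict(self.descriptors),
            self.hidden.copy(),
        )


def infer_kind(column: pd.Series) -> str:
    """Infer a descriptor kind from raw column values.

    All-integer numeric → ``integer``; otherwise numeric → ``linear``;
    otherwise ``categorical``.  Missing cells are ignored for the decision.
    """
    numeric = pd.to_numeric(column, errors="coerce")
    nonmissing = column.notna() & (column.astype(str).str.strip() != "")
    if nonmissing.any() and numeric[nonmissing].notna().all():
        vals = numeric[nonmissing]
        if np.allclose(vals, np.round(vals), atol=0, rtol=0) and (
            vals == np.floor(vals)
        ).all():
            return "integer"
        return "linear"
    if not nonmissing.any():
        return "linear"
    return "categorical"


# -- I/O -------------------------------------------------------------------


def _kinds_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".kinds.json")


def read_kinds_config(path: str | Path) -> dict[str, Descriptor]:
    """Load a JSON column-kind config: name -> {kind, units, period}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    out = {}
    for name, entry in raw.items():
        out[name] = Descriptor(
            name,
            entry.get("kind", "linear"),
            entry.get("units", ""),
            float(entry.get("period", 360.0)),
        )
    return out


def read_table(
    path: str | Path,
    dialect: str = "csv",
    kinds: Mapping[str, "Descriptor | str"] | None = None,
) -> GeometryTable:
    """Read a delimited geometry table.

    The header row is mandatory; the first two columns carry the structure
    id and the 1-based fragment index (conventionally ``_id`` and ``_frag``).
    An optional ``_hidden`` column (0/1) restores the hidden-row mask.  Blank
    cells are missing values, never zeros.  ``kinds`` maps column names to
    :class:`Descriptor` objects or bare kind strings and overrides inference;
    when absent, a ``<name>.kinds.json`` sidecar written by
    :func:`write_table` is honoured automatically.
    """
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise FormatError(f"{path}: empty file (header row required)")
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: need at least id and fragment-index columns")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate header names: {', '.join(dupes)}")
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: line {lineno}: expected {width} fields, got {len(row)}"
            )
    body = rows[1:]
    frame = pd.DataFrame(body, columns=header, dtype=object)
    frame = frame.apply(lambda s: s.str.strip()).replace("", np.nan)

    ids = frame.iloc[:, 0].astype(str).to_numpy()
    try:
        frags = frame.iloc[:, 1].astype(float).astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: fragment-index column must be integer") from exc

    hidden = None
    datacols = list(header[2:])
    if "_hidden" in datacols:
        hidden = frame["_hidden"].fillna(0).astype(float).astype(bool).to_numpy()
        datacols.remove("_hidden")

    data = frame[datacols].copy()
    # coerce numeric-looking columns so the DataFrame carries floats, not str;
    # python float() is used (not a fast parser) so values round-trip exactly
    for col in datacols:
        try:
            data[col] = data[col].map(
                lambda x: np.nan if x is np.nan or x is None else float(x)
            )
        except (TypeError, ValueError):
            pass

    kind_map: dict[str, Descriptor] = {}
    if kinds is None:
        sidecar = _kinds_sidecar(path)
        if sidecar.exists():
            kind_map = read_kinds_config(sidecar)
    else:
        for name, spec in kinds.items():
            kind_map[name] = (
                spec if isinstance(spec, Descriptor) else Descriptor(name, str(spec))
            )
    return GeometryTable(ids, frags, data, kind_map, hidden)


def write_table(
    table: GeometryTable,
    path: str | Path,
    dialect: str = "csv",
    *,
    write_kinds: bool = True,
) -> Path:
    """Write a table so that :func:`read_table` round-trips it exactly.

    Values are serialised with ``repr`` so floats survive bit-identically;
    the hidden mask goes into a reserved ``_hidden`` column and descriptor
    kinds into a ``<name>.kinds.json`` sidecar (suppress with
    ``write_kinds=False``).
    """
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    header = ["_id", "_frag", *table.columns, "_hidden"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(header)
        for i in range(table.n_rows):
            row: list[str] = [str(table.structure_id[i]), str(table.fragment_index[i])]
            for col in table.columns:
                cell = table.data[col].iloc[i]
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    row.append("")
                elif isinstance(cell, float):
                    row.append(repr(float(cell)))  # shortest repr round-trips bit-identically
                else:
                    row.append(str(cell))
            row.append("1" if table.hidden[i] else "0")
            writer.writerow(row)
    if write_kinds:
        sidecar = _kinds_sidecar(path)
        payload = {
            d.name: {"kind": d.kind, "units": d.units, "period": d.period}
            for d in table.descriptors.values()
        }
        sidecar.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return path


# -- selection algebra -----------------------------------------------------


def filter_rows(
    table: GeometryTable,
    criteria: Iterable[tuple] = (),
) -> Selection:
    """Select non-hidden rows satisfying every criterion (conjunction).

    Each criterion is ``(descriptor, comparator, value)`` with comparator one
    of ``< <= > >= == != in-range``; ``in-range`` takes a ``(lo, hi)`` pair
    and is inclusive on both ends.  Rows missing a tested descriptor are
    excluded.  An empty criteria list selects all non-hidden rows.
    """
    mask = ~table.hidden.copy()
    for crit in criteria:
        try:
            name, op, value = crit
        except ValueError:
            raise ValueError(f"criterion must be (name, comparator, value): {crit!r}")
        if op not in _COMPARATORS:
            raise ValueError(f"unknown comparator {op!r}")
        d = table.descriptor(name)
        if d.kind == "categorical":
            if op not in ("==", "!="):
                raise TypeError(
                    f"comparator {op!r} not valid for categorical column {name!r}"
                )
            col = table.data[name]
            present = col.notna().to_numpy()
            eq = (col.astype(str) == str(value)).to_numpy()
            this = eq if op == "==" else (~eq & present)
            this &= present
        else:
            v = table.values(name, include_hidden=True)
            present = ~np.isnan(v)
            if op == "in-range":
                lo, hi = value
                this = (v >= float(lo)) & (v <= float(hi))
            elif op == "<":
                this = v < float(value)
            elif op == "<=":
                this = v <= float(value)
            elif op == ">":
                this = v > float(value)
            elif op == ">=":
                this = v >= float(value)
            elif op == "==":
                this = v == float(value)
            else:  # !=
                this = v != float(value)
            this = np.where(present, this, False)
        mask &= this
    return Selection(mask)


_CRIT_RE = re.compile(
    r"^\s*(?P<name>\w+)\s*(?P<op><=|>=|!=|==|=|<|>|\bin\b)\s*(?P<val>.+?)\s*$"
)


def parse_criteria(expression: str) -> list[tuple]:
    """Parse a filter expression like ``"D <= 2.5 and HAL == 1"``.

    Clauses are joined with ``and`` (or ``;``); each clause is
    ``NAME OP VALUE`` or ``NAME in LO..HI`` (inclusive range).
    """
    criteria: list[tuple] = []
    for clause in re.split(r"\s+and\s+|;", expression.strip()):
        if not clause.strip():
            continue
        m = _CRIT_RE.match(clause)
        if not m:
            raise ValueError(f"cannot parse filter clause {clause!r}")
        name, op, val = m.group("name"), m.group("op"), m.group("val")
        if op == "=":
            op = "=="
        if op == "in":
            lo, hi = re.split(r"\.\.|,", val)
            criteria.append((name, "in-range", (float(lo), float(hi))))
        else:
            criteria.append((name, op, val))
    return criteria


def group_rows(table: GeometryTable, descriptor: str) -> dict[int, Selection]:
    """Partition the non-hidden, non-missing rows by an integer descriptor."""
    d = table.descriptor(descriptor)
    if d.kind != "integer":
        raise TypeError(
            f"grouping requires an integer descriptor; {descriptor!r} is {d.kind}"
        )
    v = table.values(descriptor)
    groups: dict[int, Selection] = {}
    present = ~np.isnan(v)
    for key in sorted(np.unique(v[present]).astype(int)):
        groups[key] = Selection((v == key) & present)
    return groups


def pool_equivalent(
    table: GeometryTable, column_names: Sequence[str]
) -> PooledColumn:
    """Merge topologically equivalent columns into one distribution.

    A search fragment with internal symmetry (six C—C—C angles of a phenyl
    ring, six Fe—C bonds of an octahedral cyanide) yields several chemically
    equivalent but crystallographically independent columns; statistics must
    treat them as a single distribution.  Values are concatenated
    column-major with per-value provenance; missing cells and hidden rows
    are dropped.  All source columns must share kind and units.
    """
    if not column_names:
        raise ValueError("need at least one column to pool")
    descs = [table.descriptor(c) for c in column_names]
    kinds = {d.kind for d in descs}
    units = {d.units for d in descs}
    if len(kinds) > 1:
        raise TypeError(f"cannot pool mixed kinds: {sorted(kinds)}")
    if len(units) > 1:
        raise TypeError(f"cannot pool mixed units: {sorted(units)}")
    vals: list[float] = []
    prov: list[tuple[int, str]] = []
    for name in column_names:
        v = table.values(name)
        for i in np.flatnonzero(~np.isnan(v)):
            vals.append(v[i])
            prov.append((int(i), name))
    return PooledColumn(
        np.asarray(vals, dtype=float),
        prov,
        kind=descs[0].kind,
        units=descs[0].units,
        name="+".join(column_names),
    )
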