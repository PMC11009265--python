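"""Assembly of per-edge-type identifier-pair lists from tabular sources.

Each edge type (e.g. ``chemical-disease``) is described by an
:class:`EdgeSpec`: where the table lives, which columns carry the
subject/object identifiers, the relation IRI, optional inverse/symmetric
information, filter clauses (evidence criteria), and identifier maps.
The pipeline is fixed:

    parse -> filter -> map subject -> map object -> project -> deduplicate

with provenance counts recorded at every stage. Row counts may only
shrink except at identifier mapping, where one-to-many maps unnest a row
into several. The result serializes to a versioned JSON document and
the whole pipeline is byte-deterministic under fixed inputs.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .ontology import ConfigurationError
from .rdf import is_absolute_iri

logger = logging.getLogger(__name__)

EDGE_LIST_SCHEMA_VERSION = 1

_OPERATORS = {"==", "!=", "<", "<=", ">", ">=", "in", "not-in"}
_ORDERING_OPERATORS = {"<", "<=", ">", ">="}


class SchemaError(ValueError):
    """A declared column is missing from the source table."""


@dataclass(frozen=True)
class FilterClause:
    """One conjunct of an edge type's evidence criteria.

    ``value_type`` decides comparison space: ``"number"`` coerces the
    cell with float semantics (unparseable cells drop the row),
    ``"text"`` compares lexically. Ordering operators require numbers.
    """

    column: str
    operator: str
    value: object
    value_type: str = "text"

    def __post_init__(self) -> None:
        if self.operator not in _OPERATORS:
            raise ConfigurationError(f"unknown operator {self.operator!r}")
        if self.value_type not in ("text", "number"):
            raise ConfigurationError(f"unknown value_type {self.value_type!r}")
        if self.operator in _ORDERING_OPERATORS and self.value_type != "number":
            raise ConfigurationError(
                f"operator {self.operator!r} requires value_type 'number'")
        if self.operator in ("in", "not-in"):
            if not isinstance(self.value, (list, tuple, set, frozenset)):
                raise ConfigurationError(
                    f"operator {self.operator!r} requires a value set")


@dataclass
class EdgeSpec:
    """Assembly instructions for one edge type."""

    edge_type: str
    source_path: str
    subject_column: str
    object_column: str
    relation: str
    inverse_relation: Optional[str] = None
    symmetric: bool = False
    filters: Sequence[FilterClause] = field(default_factory=tuple)
    subject_map: Optional[str] = None
    object_map: Optional[str] = None
    delimiter: Optional[str] = None

    def __post_init__(self) -> None:
        if self.symmetric and self.inverse_relation:
            raise ConfigurationError(
                f"edge type {self.edge_type!r}: symmetric and "
                "inverse_relation are mutually exclusive")
        if not is_absolute_iri(self.relation):
            raise ConfigurationError(
                f"edge type {self.edge_type!r}: relation must be an "
                f"absolute IRI, got {self.relation!r}")
        if self.inverse_relation and not is_absolute_iri(self.inverse_relation):
            raise ConfigurationError(
                f"edge type {self.edge_type!r}: inverse_relation must be "
                f"an absolute IRI, got {self.inverse_relation!r}")


@dataclass
class EdgeList:
    """Deduplicated (subject, object) identifier pairs for one edge type."""

    edge_type: str
    relation: str
    inverse_relation: Optional[str]
    symmetric: bool
    pairs: list[tuple[str, str]]
    provenance: dict

    def to_json(self) -> str:
        doc = {
            "schema_version": EDGE_LIST_SCHEMA_VERSION,
            "edge_type": self.edge_type,
            "relation": self.relation,
            "inverse_relation": self.inverse_relation,
            "symmetric": self.symmetric,
            "pairs": [list(p) for p in self.pairs],
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "EdgeList":
        doc = json.loads(text)
        return cls(
            edge_type=doc["edge_type"],
            relation=doc["relation"],
            inverse_relation=doc.get("inverse_relation"),
            symmetric=bool(doc.get("symmetric", False)),
            pairs=[tuple(p) for p in doc["pairs"]],
            provenance=doc.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def parse_table(source: Union[str, Path], spec: EdgeSpec) -> pd.DataFrame:
    """Read a delimited source (gzip transparent) into an all-string table.

    The delimiter comes from the spec or is sniffed from {tab, comma}.
    Declared subject/object/filter columns must exist. A header-only
    file yields zero rows.
    """
    path = Path(source)
    delimiter = spec.delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str,
                     keep_default_na=False, compression="infer")
    required = {spec.subject_column, spec.object_column}
    required.update(c.column for c in spec.filters)
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(
            f"source {path.name} is missing declared column(s): "
            f"{', '.join(missing)}")
    return df


def _clause_mask(df: pd.DataFrame, clause: FilterClause):
    """Boolean keep-mask and count of rows dropped for unparseable cells."""
    col = df[clause.column]
    unparseable = 0
    if clause.value_type == "number":
        values = pd.to_numeric(col, errors="coerce")
        parseable = values.notna()
        unparseable = int((~parseable).sum())
        if clause.operator in ("in", "not-in"):
            wanted = {float(v) for v in clause.value}
            mask = values.isin(wanted)
            if clause.operator == "not-in":
                mask = ~mask
        else:
            rhs = float(clause.value)  # type: ignore[arg-type]
            ops = {"==": values.eq, "!=": values.ne, "<": values.lt,
                   "<=": values.le, ">": values.gt, ">=": values.ge}
            mask = ops[clause.operator](rhs)
        mask &= parseable
    else:
        if clause.operator == "==":
            mask = col == str(clause.value)
        elif clause.operator == "!=":
            mask = col != str(clause.value)
        elif clause.operator == "in":
            mask = col.isin({str(v) for v in clause.value})
        elif clause.operator == "not-in":
            mask = ~col.isin({str(v) for v in clause.value})
        else:  # pragma: no cover - blocked by FilterClause validation
            raise ConfigurationError(
                f"operator {clause.operator!r} requires numbers")
    return mask, unparseable


def apply_filters(df: pd.DataFrame, clauses: Sequence[FilterClause]
                  ) -> tuple[pd.DataFrame, int]:
    """Keep rows satisfying ALL clauses (conjunction).

    Returns the surviving table and the number of rows dropped because a
    numeric clause met an unparseable cell.
    """
    if not clauses:
        return df, 0
    unknown = sorted({c.column for c in clauses} - set(df.columns))
    if unknown:
        raise SchemaError(f"filter references missing column(s): "
                          f"{', '.join(unknown)}")
    keep = pd.Series(True, index=df.index)
    bad = pd.Series(False, index=df.index)
    for clause in clauses:
        mask, _ = _clause_mask(df, clause)
        if clause.value_type == "number":
            bad |= pd.to_numeric(df[clause.column], errors="coerce").isna()
        keep &= mask
    # _clause_mask already excludes unparseable rows from keep; bad counts
    # every row dropped because a numeric clause met an unparseable cell.
    return df[keep].copy(), int(bad.sum())


def map_identifiers(df: pd.DataFrame, column: str,
                    idmap: dict[str, Sequence[str]]
                    ) -> tuple[pd.DataFrame, int]:
    """Replace *column* values through a one-to-many identifier map.

    Each row becomes one row per mapped target (unnesting); rows whose
    identifier has no mapping are dropped and counted.
    """
    if column not in df.columns:
        raise SchemaError(f"mapping references missing column {column!r}")
    targets = df[column].map(lambda v: list(idmap.get(v, ())))
    mapped = targets.map(len) > 0
    dropped = int((~mapped).sum())
    out = df[mapped].copy()
    out[column] = targets[mapped]
    out = out.explode(column, ignore_index=True)
    return out, dropped


def read_identifier_map(path: Union[str, Path]) -> dict[str, tuple[str, ...]]:
    """Two-column headerless TSV source→target; repeated sources collect
    into sorted multi-target tuples."""
    mapping: dict[str, set[str]] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(
                    f"{path}: line {lineno} is not two tab-separated fields")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return {k: tuple(sorted(v)) for k, v in mapping.items()}


def assemble_edge_list(spec: EdgeSpec,
                       idmaps: Optional[dict[str, dict]] = None,
                       base_dir: Optional[Union[str, Path]] = None
                       ) -> EdgeList:
    """Run the full assembly pipeline for one edge type.

    ``idmaps`` is a registry name→map consulted for ``spec.subject_map``
    / ``spec.object_map``; a name not in the registry is treated as a
    path to a two-column TSV. Provenance records the row count after
    every stage. An all-rows-filtered outcome is a warning, not an
    error.
    """
    idmaps = idmaps or {}
    source = Path(spec.source_path)
    if base_dir is not None and not source.is_absolute():
        source = Path(base_dir) / source

    df = parse_table(source, spec)
    provenance: dict = {
        "source_path": str(spec.source_path),
        "rows_parsed": int(len(df)),
    }

    df, unparseable = apply_filters(df, list(spec.filters))
    provenance["rows_after_filters"] = int(len(df))
    provenance["rows_dropped_unparseable"] = unparseable

    def resolve_map(name: Optional[str]) -> Optional[dict]:
        if name is None:
            return None
        if name in idmaps:
            return idmaps[name]
        path = Path(name)
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        return read_identifier_map(path)

    for role, column, map_name in (
            ("subject", spec.subject_column, spec.subject_map),
            ("object", spec.object_column, spec.object_map)):
        idmap = resolve_map(map_name)
        if idmap is not None:
            df, dropped = map_identifiers(df, column, idmap)
            provenance[f"rows_after_{role}_map"] = int(len(df))
            provenance[f"rows_dropped_unmapped_{role}"] = dropped

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for s, o in zip(df[spec.subject_column], df[spec.object_column]):
        pair = (str(s), str(o))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    provenance["pairs_unique"] = len(pairs)

    if not pairs:
        logger.warning("edge type %s: no pairs survived assembly",
                       spec.edge_type)
    return EdgeList(
        edge_type=spec.edge_type,
        relation=spec.relation,
        inverse_relation=spec.inverse_relation,
        symmetric=spec.symmetric,
        pairs=pairs,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Instruction documents
# ---------------------------------------------------------------------------

def _clause_from_doc(doc: dict) -> FilterClause:
    return FilterClause(
        column=doc["column"],
        operator=doc["operator"],
        value=doc["value"],
        value_type=doc.get("value_type", "text"),
    )


def edge_spec_from_doc(doc: dict) -> EdgeSpec:
    return EdgeSpec(
        edge_type=doc["edge_type"],
        source_path=doc["source_path"],
        subject_column=doc["subject_column"],
        object_column=doc["object_column"],
        relation=doc["relation"],
        inverse_relation=doc.get("inverse_relation"),
        symmetric=bool(doc.get("symmetric", False)),
        filters=tuple(_clause_from_doc(c) for c in doc.get("filters", [])),
        subject_map=doc.get("subject_map"),
        object_map=doc.get("object_map"),
        delimiter=doc.get("delimiter"),
    )


def load_edge_specs(path: Union[str, Path]) -> list[EdgeSpec]:
    """Load an edge-assembly instruction document (YAML or JSON)."""
    import yaml

    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if isinstance(doc, dict):
        entries = doc.get("edges", [])
    else:
        entries = doc or []
    return [edge_spec_from_doc(e) for e in entries]
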