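"""Readers and writers for the plain-text carrier formats.

* GMT (Broad dialect) for annotation collections: one tab-delimited line per
  set -- id, description, then member ids.  Trailing empty fields are
  ignored; duplicate members within a line are collapsed.
* Feature tables as TSV with a header: required column ``feature``;
  optional ``statistic``, ``p_value`` and boolean ``selected``.  The table's
  rows define the universe; ``selected`` (when present) defines the feature
  list, otherwise every row is selected.
* Ontology DAGs as a (child, parent, relation) TSV edge table.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .types import AnnotationCollection, FeatureList, OntologyDag

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_feature_table",
    "read_dag_table",
    "write_dag_table",
]

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


class GmtParseError(ValueError):
    """Raised when a GMT file is malformed."""


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT gene-set file into an :class:`AnnotationCollection`.

    Raises :class:`GmtParseError` naming the offending line when a line has
    fewer than three fields or an annotation id repeats.
    """
    members: dict[str, frozenset[str]] = {}
    description: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            # Broad-compatible: trailing empty member fields are padding.
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            aid, desc, *mems = fields
            if aid in members:
                raise GmtParseError(
                    f"{path}: line {lineno}: duplicate annotation id {aid!r}"
                )
            mem_set = frozenset(m for m in mems if m != "")
            if not mem_set:
                raise GmtParseError(
                    f"{path}: line {lineno}: annotation {aid!r} has no members"
                )
            members[aid] = mem_set
            description[aid] = desc
    return AnnotationCollection(members=members, description=description)


def write_gmt(coll: AnnotationCollection, path: str | Path) -> None:
    """Write a collection as GMT; members sorted for reproducibility."""
    with open(path, "w", encoding="utf-8") as handle:
        for aid in sorted(coll.members):
            desc = coll.description.get(aid, "")
            mems = "\t".join(sorted(coll.members[aid]))
            handle.write(f"{aid}\t{desc}\t{mems}\n")


def _parse_bool(value: str, lineno: int) -> bool:
    lowered = str(value).strip().lower()
    if lowered in _TRUE:
        return True
    if lowered in _FALSE:
        return False
    raise ValueError(f"row {lineno}: unrecognised boolean {value!r} in 'selected'")


def read_feature_table(path: str | Path, list_id: str) -> FeatureList:
    """Read a TSV feature table into a :class:`FeatureList`.

    The universe is all rows; the feature set is the rows flagged by a
    boolean ``selected`` column, or all rows if that column is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "feature" not in df.columns:
        raise ValueError(f"{path}: required column 'feature' is missing")
    universe = [str(f) for f in df["feature"]]
    if len(set(universe)) != len(universe):
        raise ValueError(f"{path}: duplicate feature ids in table")

    if "selected" in df.columns:
        selected_mask = [
            _parse_bool(v, i) for i, v in enumerate(df["selected"], start=2)
        ]
    else:
        selected_mask = [True] * len(universe)
    features = [f for f, keep in zip(universe, selected_mask) if keep]

    statistic = None
    if "statistic" in df.columns:
        statistic = {
            f: float(v)
            for f, v, keep in zip(universe, df["statistic"], selected_mask)
            if keep and not pd.isna(v)
        }
    p_value = None
    if "p_value" in df.columns:
        p_value = {}
        for f, v, keep in zip(universe, df["p_value"], selected_mask):
            if pd.isna(v):
                continue
            p = float(v)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{path}: p_value {p} for {f!r} outside [0, 1]")
            if keep:
                p_value[f] = p
        if not p_value:
            p_value = None

    return FeatureList(
        list_id=list_id,
        features=frozenset(features),
        universe=frozenset(universe),
        statistic=statistic,
        p_value=p_value,
    )


def read_dag_table(path: str | Path) -> OntologyDag:
    """Read a (child, parent, relation) TSV edge table.

    A header line is detected by the literal column names and skipped; the
    relation column may be omitted (defaults to ``is_a``).
    """
    edges: set[tuple[str, str, str]] = set()
    with open(path, "r", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or not "".join(row).strip():
                continue
            if i == 0 and row[0].strip().lower() == "child":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: edge line {i + 1} needs child and parent")
            child, parent = row[0].strip(), row[1].strip()
            relation = row[2].strip() if len(row) > 2 and row[2].strip() else "is_a"
            edges.add((child, parent, relation))
    return OntologyDag(edges=frozenset(edges))


def write_dag_table(dag: OntologyDag, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("child\tparent\trelation\n")
        for child, parent, rel in sorted(dag.edges):
            handle.write(f"{child}\t{parent}\t{rel}\n")
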