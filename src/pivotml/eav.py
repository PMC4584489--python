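"""Entity-Attribute-Value (EAV) to wide-table pivoting.

Clinical repositories commonly store facts tall-and-skinny: one row per
(entity, attribute, value) triple, where the entity identifies a clinical
event (typically a patient-id/timestamp pair), the attribute names a
clinical parameter, and the value carries its payload.  Predictive
modelling needs the wide layout with one column per parameter.

The pivot here follows a map/reduce contract: a map step turns each EAV
tuple whose attribute is wanted into a (entity, (attribute, value)) pair —
tuples for unneeded parameters are filtered out as early as possible — and
a reduce step combines all pairs sharing an entity, possibly drawn from
several source tables, into one relational row.  Several pivot queries over
the same sources can share a single scan (multi-query optimization), and a
partition-based external grouping mode handles sources larger than memory.

Values pass through as text; numeric coercion is deferred to modelling so
extraction stays lossless.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EAVRecord",
    "EAVSource",
    "PivotQuery",
    "PivotBatch",
    "DataError",
    "DuplicateMeasurementError",
    "map_eav",
    "reduce_entity",
    "pivot",
    "pivot_batch",
    "melt",
    "import_relational",
    "write_wide",
    "EAVPivoter",
]


class DataError(ValueError):
    """Malformed source data (missing role column, unparseable file...)."""


class DuplicateMeasurementError(DataError):
    """Repeated (entity, attribute) under duplicate_policy='error'."""


class EAVRecord(NamedTuple):
    entity: str
    attribute: str
    value: str


@dataclass
class EAVSource:
    """One EAV table plus its column-role assignment.

    ``table`` is either a path to a CSV file (optionally gzipped) or an
    in-memory DataFrame.  Roles may name columns or give integer positions.
    """

    table: str | os.PathLike | pd.DataFrame
    entity_col: str | int = "entity"
    attribute_col: str | int = "attribute"
    value_col: str | int = "value"

    def _resolve(self, columns: Sequence[str], role: str, spec: str | int) -> str:
        if isinstance(spec, int):
            if not 0 <= spec < len(columns):
                raise DataError(f"{role} column index {spec} out of range")
            return columns[spec]
        if spec not in columns:
            raise DataError(f"{role} column {spec!r} absent from source")
        return str(spec)

    def chunks(self, chunksize: int | None) -> Iterator[pd.DataFrame]:
        """Yield DataFrames with canonical columns entity/attribute/value."""
        if isinstance(self.table, pd.DataFrame):
            frames: Iterable[pd.DataFrame] = [self.table]
        else:
            frames = pd.read_csv(
                self.table, dtype=str, keep_default_na=False,
                chunksize=chunksize or None, iterator=chunksize is not None,
            )
            if chunksize is None:
                frames = [frames]  # type: ignore[list-item]
        for frame in frames:
            cols = list(frame.columns)
            e = self._resolve(cols, "entity", self.entity_col)
            a = self._resolve(cols, "attribute", self.attribute_col)
            v = self._resolve(cols, "value", self.value_col)
            out = frame[[e, a, v]].copy()
            out.columns = ["entity", "attribute", "value"]
            out = out.astype(str).mask(frame[[e, a, v]].isna().values, "")
            yield out


@dataclass
class PivotQuery:
    """One pivot: which sources, which parameters, how to resolve clashes."""

    sources: list[EAVSource]
    wanted: list[str]
    duplicate_policy: str = "last"  # first | last | error
    roster: list[str] | None = None  # None = observed-only entity scope

    def __post_init__(self) -> None:
        if not self.wanted:
            raise ValueError("wanted attribute list must be non-empty")
        if len(set(self.wanted)) != len(self.wanted):
            raise ValueError("wanted attribute list contains duplicates")
        if self.duplicate_policy not in ("first", "last", "error"):
            raise ValueError(f"unknown duplicate_policy {self.duplicate_policy!r}")
        if not self.sources:
            raise ValueError("at least one source is required")


@dataclass
class PivotBatch:
    """Several pivot queries sharing the identical source list."""

    queries: list[PivotQuery] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.queries:
            raise ValueError("batch must contain at least one query")
        first = self.queries[0].sources
        for q in self.queries[1:]:
            if q.sources is not first and q.sources != first:
                raise ValueError("all queries in a batch must share one source set")


def map_eav(record: EAVRecord, wanted: frozenset[str] | set[str]):
    """Map step: emit (entity, (attribute, value)) iff the attribute is wanted.

    Tuples for unneeded clinical parameters are dropped here, before any
    grouping work — the early-filtering optimization.
    """
    if not record.entity or not record.attribute:
        raise DataError(f"malformed EAV record {record!r}: empty entity or attribute")
    if record.attribute in wanted:
        return record.entity, (record.attribute, record.value)
    return None


def reduce_entity(
    entity: str,
    pairs: Iterable[tuple[str, str]],
    wanted: Sequence[str],
    duplicate_policy: str = "last",
) -> list:
    """Reduce step: combine one entity's (attribute, value) pairs into a row.

    Pairs must arrive in the declared ordering (source index, row index);
    under policy 'first'/'last' that ordering decides which duplicate wins.
    Attributes never observed come out as None.
    """
    cells: dict[str, str] = {}
    for attribute, value in pairs:
        if attribute in cells:
            if duplicate_policy == "error":
                raise DuplicateMeasurementError(
                    f"duplicate measurement of {attribute!r} for entity {entity!r}"
                )
            if duplicate_policy == "first":
                continue
        cells[attribute] = value
    return [entity] + [cells.get(a) for a in wanted]


def _scan_pairs(
    sources: Sequence[EAVSource], wanted: frozenset[str], chunksize: int | None
) -> Iterator[tuple[str, str, str]]:
    """Stream (entity, attribute, value) for wanted attributes, in declared order."""
    for source in sources:
        for chunk in source.chunks(chunksize):
            bad = (chunk["entity"] == "") | (chunk["attribute"] == "")
            if bad.any():
                row = chunk.index[bad][0]
                raise DataError(f"malformed EAV row {row}: empty entity or attribute")
            hit = chunk[chunk["attribute"].isin(wanted)]
            yield from hit.itertuples(index=False, name=None)


def _rows_to_frame(rows: list[list], wanted: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["entity", *wanted], dtype=object)


def _pivot_grouped(
    groups: dict[str, list[tuple[str, str]]], query: PivotQuery
) -> pd.DataFrame:
    if query.roster is not None:
        entities: Iterable[str] = query.roster
    else:
        entities = sorted(groups)
    rows = [
        reduce_entity(e, groups.get(e, []), query.wanted, query.duplicate_policy)
        for e in entities
    ]
    return _rows_to_frame(rows, query.wanted)


def pivot(
    query: PivotQuery,
    chunksize: int | None = None,
    n_partitions: int | None = None,
    spill_dir: str | None = None,
) -> pd.DataFrame:
    """Pivot EAV source(s) into a wide table, one column per wanted attribute.

    Covers pivoting a single table, pivoting across several tables (an
    attribute may live in any source; clashes across sources are ordinary
    duplicates under ``duplicate_policy``), and — via :func:`pivot_batch` —
    many pivots in one scan.  Under observed-only scope the output has one
    row per entity with at least one wanted tuple; under roster scope,
    exactly the roster's rows.  With ``n_partitions`` set, filtered pairs
    are spilled to hash partitions on disk and reduced partition by
    partition, so sources need never fit in memory.
    """
    [result] = pivot_batch(
        PivotBatch([query]), chunksize=chunksize,
        n_partitions=n_partitions, spill_dir=spill_dir,
    )
    return result


def pivot_batch(
    batch: PivotBatch,
    chunksize: int | None = None,
    n_partitions: int | None = None,
    spill_dir: str | None = None,
) -> list[pd.DataFrame]:
    """Run every query of a batch in a single scan over the shared sources.

    Each output equals the table its query would produce standalone.
    """
    queries = batch.queries
    union_wanted = frozenset().union(*(q.wanted for q in queries))
    sources = queries[0].sources

    if n_partitions is None:
        groups: dict[str, list[tuple[str, str]]] = {}
        for entity, attribute, value in _scan_pairs(sources, union_wanted, chunksize):
            groups.setdefault(entity, []).append((attribute, value))
        return [_pivot_grouped(_restrict(groups, q), q) for q in queries]

    # External mode: spill pairs to hash partitions, then reduce per partition.
    with tempfile.TemporaryDirectory(dir=spill_dir) as tmp:
        paths = [os.path.join(tmp, f"part{i}.csv") for i in range(n_partitions)]
        handles = [open(p, "w", encoding="utf-8") for p in paths]
        try:
            for entity, attribute, value in _scan_pairs(sources, union_wanted, chunksize):
                h = int(hashlib.md5(entity.encode()).hexdigest(), 16) % n_partitions
                row = pd.DataFrame([[entity, attribute, value]])
                row.to_csv(handles[h], header=False, index=False)
        finally:
            for fh in handles:
                fh.close()
        pieces: list[list[pd.DataFrame]] = [[] for _ in queries]
        roster_sets = [
            None if q.roster is None else set(q.roster) for q in queries
        ]
        for i, path in enumerate(paths):
            part: dict[str, list[tuple[str, str]]] = {}
            if os.path.getsize(path):
                frame = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
                for entity, attribute, value in frame.itertuples(index=False, name=None):
                    part.setdefault(entity, []).append((attribute, value))
            for qi, q in enumerate(queries):
                sub = _restrict(part, q)
                if roster_sets[qi] is not None:
                    scoped = PivotQuery(
                        q.sources, q.wanted, q.duplicate_policy,
                        [e for e in q.roster  # roster rows living in this partition
                         if int(hashlib.md5(e.encode()).hexdigest(), 16)
                         % n_partitions == i],
                    )
                    pieces[qi].append(_pivot_grouped(sub, scoped))
                else:
                    pieces[qi].append(_pivot_grouped(sub, q))
        out = []
        for qi, q in enumerate(queries):
            frame = pd.concat(pieces[qi], ignore_index=True)
            if q.roster is not None:
                frame = frame.set_index("entity").loc[q.roster].reset_index()
            else:
                frame = frame.sort_values("entity", kind="stable").reset_index(drop=True)
            out.append(frame.astype(object).where(frame.notna(), None))
        return out


def _restrict(
    groups: dict[str, list[tuple[str, str]]], query: PivotQuery
) -> dict[str, list[tuple[str, str]]]:
    wanted = set(query.wanted)
    out: dict[str, list[tuple[str, str]]] = {}
    for entity, pairs in groups.items():
        hit = [p for p in pairs if p[0] in wanted]
        if hit:
            out[entity] = hit
    return out


def melt(table: pd.DataFrame, entity_col: str = "entity") -> list[EAVRecord]:
    """Inverse transform: one EAV record per non-null cell of a wide table.

    Round trip: pivoting the melted records (observed-only scope, wanted =
    the table's columns) reproduces the table up to row order.
    """
    attributes = [c for c in table.columns if c != entity_col]
    records: list[EAVRecord] = []
    for _, row in table.iterrows():
        entity = str(row[entity_col])
        for attribute in attributes:
            value = row[attribute]
            if value is None or pd.isna(value):
                continue
            records.append(EAVRecord(entity, attribute, str(value)))
    return records


def import_relational(path: str | os.PathLike, format: str = "csv") -> pd.DataFrame:
    """Import an already-relational table (RFC 4180 CSV, optionally gzipped)."""
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty or header-less file") from exc
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: {exc}") from exc
    return frame


def write_wide(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a wide table as UTF-8 RFC 4180 CSV, empty string for null."""
    table.to_csv(path, index=False, na_rep="", encoding="utf-8")


class EAVPivoter(TransformerMixin, BaseEstimator):
    """Transformer facade over :func:`pivot` for pipeline composition.

    Parameters
    ----------
    wanted : list of str
        Clinical parameters (attribute names) to extract, in output order.
    entity_col, attribute_col, value_col : str or int
        Column roles in the EAV input.
    duplicate_policy : {'first', 'last', 'error'}
        Resolution for repeated (entity, attribute) measurements under the
        declared (source index, row index) ordering; 'last' matches the
        usual latest-measurement-wins EMR convention.
    roster : list of str, optional
        Entity scope; None keeps only entities observed with wanted tuples.
    """

    def __init__(
        self,
        wanted: list[str] | None = None,
        entity_col: str | int = "entity",
        attribute_col: str | int = "attribute",
        value_col: str | int = "value",
        duplicate_policy: str = "last",
        roster: list[str] | None = None,
    ):
        self.wanted = wanted
        self.entity_col = entity_col
        self.attribute_col = attribute_col
        self.value_col = value_col
        self.duplicate_policy = duplicate_policy
        self.roster = roster

    def fit(self, X, y=None):  # noqa: D102 — stateless transformer
        if not self.wanted:
            raise ValueError("wanted attribute list must be non-empty")
        self.n_features_in_ = len(self.wanted)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Pivot one EAV DataFrame (or a list of them) into a wide table."""
        self.fit(X)
        tables = X if isinstance(X, (list, tuple)) else [X]
        sources = [
            EAVSource(t, self.entity_col, self.attribute_col, self.value_col)
            for t in tables
        ]
        return pivot(
            PivotQuery(sources, list(self.wanted), self.duplicate_policy, self.roster)
        )
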