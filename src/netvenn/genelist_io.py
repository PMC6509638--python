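"""Parsing and validation of two-column gene-list files.

Each input file has one gene per line: ``<gene_id>\\t<code>`` where the code
is ``1`` (upregulated) or ``2`` (downregulated). Lines starting with ``#``
and blank lines are skipped; a single leading header line is tolerated when
its second field is not a valid code.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .errors import (
    CollectionSizeError,
    DirectionConflictError,
    EmptyInputError,
    GeneListParseError,
    NameCollisionError,
)

logger = logging.getLogger(__name__)

MIN_LISTS = 2
MAX_LISTS = 8

UP = 1
DOWN = 2
_VALID_CODES = {"1": UP, "2": DOWN}


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its regulation direction (1 = up, 2 = down)."""

    gene_id: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be 1 or 2, got {self.direction!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if "\t" in self.gene_id or "\n" in self.gene_id or "\r" in self.gene_id:
            raise ValueError(f"gene_id contains tab/newline: {self.gene_id!r}")


@dataclass
class ExperimentList:
    """A named, deduplicated, ordered list of gene records."""

    name: str
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("experiment name must be non-empty")

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def direction_of(self, gene_id: str) -> int | None:
        for r in self.records:
            if r.gene_id == gene_id:
                return r.direction
        return None

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentList):
            return NotImplemented
        return self.name == other.name and self.records == other.records


def parse_gene_list(
    stream: TextIO | str,
    name: str,
    *,
    case_insensitive: bool = False,
) -> ExperimentList:
    """Parse a two-column tab-separated stream into an :class:`ExperimentList`.

    Parameters
    ----------
    stream
        Text stream or string with one ``gene\\tcode`` pair per line.
    name
        Experiment name (non-empty, unique within a run).
    case_insensitive
        Fold gene IDs to upper case before deduplication.
    """
    if not name:
        raise ValueError("experiment name must be non-empty")
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    seen: dict[str, int] = {}
    order: list[str] = []
    n_dups = 0
    first_data_line = True
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise GeneListParseError(
                f"expected 2 tab-separated fields, found {len(fields)}", lineno
            )
        gene_raw, code_raw = fields[0].strip(), fields[1].strip()
        if code_raw not in _VALID_CODES:
            # tolerate one header line at the top of the file
            if first_data_line:
                first_data_line = False
                logger.info("%s: treating line %d as header", name, lineno)
                continue
            raise GeneListParseError(
                f"second field must be \"1\" or \"2\", got {code_raw!r}", lineno
            )
        first_data_line = False
        if not gene_raw:
            raise GeneListParseError("empty gene ID", lineno)
        gene_id = gene_raw.upper() if case_insensitive else gene_raw
        direction = _VALID_CODES[code_raw]
        if gene_id in seen:
            if seen[gene_id] != direction:
                raise DirectionConflictError(
                    f"{name}: gene {gene_id!r} listed with both direction codes"
                )
            n_dups += 1
            continue
        seen[gene_id] = direction
        order.append(gene_id)

    if not order:
        raise EmptyInputError(f"{name}: no gene records found")
    if n_dups:
        logger.warning("%s: %d duplicate line(s) deduplicated", name, n_dups)
    return ExperimentList(name, [GeneRecord(g, seen[g]) for g in order])


def serialize_gene_list(exp: ExperimentList) -> str:
    """Render an experiment list back to two-column TSV (round-trip safe)."""
    return "".join(f"{r.gene_id}\t{r.direction}\n" for r in exp.records)


def load_collection(
    paths_and_names: Sequence[tuple[str | os.PathLike, str]],
    *,
    case_insensitive: bool = False,
) -> list[ExperimentList]:
    """Load 2-8 gene-list files, preserving order.

    Order defines experiment display order and palette assignment downstream.
    """
    n = len(paths_and_names)
    if n < MIN_LISTS:
        raise CollectionSizeError(f"need at least two gene lists, got {n}")
    if n > MAX_LISTS:
        raise CollectionSizeError(f"at most eight gene lists are supported, got {n}")
    names = [name for _, name in paths_and_names]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise NameCollisionError(f"duplicate experiment name(s): {', '.join(dupes)}")
    lists = []
    for path, name in paths_and_names:
        with open(path, encoding="utf-8") as fh:
            lists.append(parse_gene_list(fh, name, case_insensitive=case_insensitive))
    return lists


def collection_from_streams(
    streams_and_names: Iterable[tuple[TextIO | str, str]],
    *,
    case_insensitive: bool = False,
) -> list[ExperimentList]:
    """In-memory variant of :func:`load_collection` with the same size checks."""
    pairs = list(streams_and_names)
    n = len(pairs)
    if n < MIN_LISTS:
        raise CollectionSizeError(f"need at least two gene lists, got {n}")
    if n > MAX_LISTS:
        raise CollectionSizeError(f"at most eight gene lists are supported, got {n}")
    names = [name for _, name in pairs]
    if len(set(names)) != len(names):
        raise NameCollisionError("duplicate experiment names")
    return [
        parse_gene_list(s, name, case_insensitive=case_insensitive)
        for s, name in pairs
    ]
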