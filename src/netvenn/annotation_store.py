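"""Local gene<->term annotation store (pathways, GO terms, descriptions).

Replaces a live pathway/GO backend with plain files. Two formats are read:

* **long TSV** — four columns per line: ``gene_id  term_id  term_name  category``
* **GMT** — one gene set per line: ``term_id  term_name|CATEGORY  gene1 gene2 ...``
  (a missing ``|CATEGORY`` suffix defaults to ``PATHWAY``)

Categories are ``PATHWAY``, ``GO_BP``, ``GO_MF``, ``GO_CC``.
"""

from __future__ import annotations

import enum
import logging
import os
import re
from dataclasses import dataclass, field

from .errors import AnnotationFormatError, TermNotFoundError

logger = logging.getLogger(__name__)


class Category(enum.Enum):
    PATHWAY = "PATHWAY"
    GO_BP = "GO_BP"
    GO_MF = "GO_MF"
    GO_CC = "GO_CC"

    @property
    def is_go(self) -> bool:
        return self is not Category.PATHWAY


@dataclass(frozen=True)
class Term:
    term_id: str
    term_name: str
    category: Category

    def __post_init__(self) -> None:
        if not self.term_name:
            raise ValueError(f"{self.term_id}: term_name must be non-empty")


@dataclass
class AnnotationTable:
    """Cross-indexed term<->gene mappings plus free-text gene descriptions."""

    terms: dict[str, Term] = field(default_factory=dict)
    term_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add_membership(self, gene_id: str, term: Term) -> None:
        existing = self.terms.get(term.term_id)
        if existing is not None and existing.term_name != term.term_name:
            raise AnnotationFormatError(
                f"term {term.term_id} has conflicting names: "
                f"{existing.term_name!r} vs {term.term_name!r}"
            )
        self.terms.setdefault(term.term_id, term)
        self.term_genes.setdefault(term.term_id, set()).add(gene_id)
        self.gene_terms.setdefault(gene_id, set()).add(term.term_id)

    def merge(self, other: "AnnotationTable") -> None:
        for term_id, genes in other.term_genes.items():
            for g in genes:
                self.add_membership(g, other.terms[term_id])
        self.descriptions.update(other.descriptions)

    @property
    def universe(self) -> set[str]:
        """All annotated genes in the table."""
        return set(self.gene_terms)

    def check_inverse_maps(self) -> None:
        for t, genes in self.term_genes.items():
            if t not in self.terms:
                raise AnnotationFormatError(f"term {t} has genes but no metadata")
            for g in genes:
                if t not in self.gene_terms.get(g, ()):
                    raise AnnotationFormatError(f"inverse map broken at ({g}, {t})")
        for g, ts in self.gene_terms.items():
            for t in ts:
                if g not in self.term_genes.get(t, ()):
                    raise AnnotationFormatError(f"inverse map broken at ({g}, {t})")

    def __len__(self) -> int:
        return len(self.terms)


def _parse_category(token: str, context: str) -> Category:
    try:
        return Category(token.strip())
    except ValueError:
        valid = ", ".join(c.value for c in Category)
        raise AnnotationFormatError(
            f"{context}: unknown category {token!r} (expected one of {valid})"
        ) from None


def load_annotations(path: str | os.PathLike, format: str = "auto") -> AnnotationTable:
    """Load an annotation file into a fully cross-indexed table.

    ``format`` is ``"long_tsv"``, ``"gmt"`` or ``"auto"`` (by extension, GMT
    for ``.gmt`` else long TSV). Duplicate (gene, term) pairs deduplicate.
    """
    path = os.fspath(path)
    if format == "auto":
        format = "gmt" if path.lower().endswith(".gmt") else "long_tsv"
    if format not in ("gmt", "long_tsv"):
        raise ValueError(f"unknown annotation format {format!r}")
    table = AnnotationTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            ctx = f"{os.path.basename(path)}:{lineno}"
            if format == "gmt":
                _read_gmt_line(table, line, ctx)
            else:
                _read_long_line(table, line, ctx)
    if not table.terms:
        logger.warning("%s: empty annotation table (unusable for enrichment)", path)
    table.check_inverse_maps()
    return table


def _read_gmt_line(table: AnnotationTable, line: str, ctx: str) -> None:
    fields = line.split("\t")
    if len(fields) < 2:
        raise AnnotationFormatError(f"{ctx}: GMT line needs id and name fields")
    term_id = fields[0].strip()
    name_field = fields[1].strip()
    if "|" in name_field:
        name, _, cat_token = name_field.rpartition("|")
        category = _parse_category(cat_token, ctx)
    else:
        name, category = name_field, Category.PATHWAY
    term = Term(term_id, name, category)
    genes = [g.strip() for g in fields[2:] if g.strip()]
    if not genes:
        # term present with zero genes is legal (degenerate)
        table.terms.setdefault(term_id, term)
        table.term_genes.setdefault(term_id, set())
        return
    for g in genes:
        table.add_membership(g, term)


def _read_long_line(table: AnnotationTable, line: str, ctx: str) -> None:
    fields = line.split("\t")
    if len(fields) != 4:
        raise AnnotationFormatError(
            f"{ctx}: long TSV needs 4 columns (gene, term_id, term_name, category)"
        )
    gene_id, term_id, term_name, cat_token = (f.strip() for f in fields)
    category = _parse_category(cat_token, ctx)
    table.add_membership(gene_id, Term(term_id, term_name, category))


def load_descriptions(path: str | os.PathLike, table: AnnotationTable | None = None) -> dict[str, str]:
    """Read a two-column ``gene_id<TAB>description`` file."""
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            gene_id, _, desc = line.partition("\t")
            descriptions[gene_id.strip()] = desc.strip()
    if table is not None:
        table.descriptions.update(descriptions)
    return descriptions


def search_terms(
    table: AnnotationTable,
    keyword: str,
    category_filter: Category | None = None,
    *,
    regex: bool = False,
) -> list[Term]:
    """Case-insensitive substring (or regex) match on term name and ID.

    Results come back in stable term_id order; no match yields an empty list.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    if regex:
        pat = re.compile(keyword, re.IGNORECASE)
        match = lambda t: pat.search(t.term_name) or pat.search(t.term_id)
    else:
        kw = keyword.lower()
        match = lambda t: kw in t.term_name.lower() or kw in t.term_id.lower()
    hits = [
        t
        for t in table.terms.values()
        if (category_filter is None or t.category is category_filter) and match(t)
    ]
    return sorted(hits, key=lambda t: t.term_id)


def genes_for_term(table: AnnotationTable, term_id: str) -> set[str]:
    """The gene set of one term; a defensive copy, safe for callers to mutate."""
    if term_id not in table.terms:
        raise TermNotFoundError(f"term {term_id!r} not in annotation table")
    return set(table.term_genes.get(term_id, set()))


def annotate_gene(table: AnnotationTable, gene_id: str) -> tuple[str, list[Term]]:
    """Description and sorted term list for one gene; missing genes are legal."""
    desc = table.descriptions.get(gene_id, "")
    terms = sorted(
        (table.terms[t] for t in table.gene_terms.get(gene_id, ())),
        key=lambda t: t.term_id,
    )
    return desc, terms
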