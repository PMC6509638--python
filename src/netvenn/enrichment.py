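"""One-sided over-representation testing of gene selections against terms.

For each term a 2x2 table is formed from the selection, the term's genes and
a background universe; the upper hypergeometric tail ``P[X >= k]`` gives the
standard one-sided Fisher exact p-value. The ``ease`` variant recomputes the
tail after discounting one overlapping gene (``k -> max(k-1, 0)``), the
conservative score popularized by DAVID. Benjamini-Hochberg adjustment is
available but off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from scipy.stats import hypergeom

from .annotation_store import AnnotationTable, Category, Term
from .errors import EnrichmentInputError

logger = logging.getLogger(__name__)

Variant = Literal["standard", "ease"]
AdjustMethod = Literal["none", "bh"]


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts behind one term's 2x2 table.

    k: selected genes annotated to the term; K: background genes annotated to
    the term; n: selected genes in the background; N: background size.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid counts: k={self.k} must be in [0, min(n, K)]")
        if self.n > self.N or self.K > self.N:
            raise ValueError(f"invalid counts: n={self.n}, K={self.K} exceed N={self.N}")
        if self.N <= 0:
            raise ValueError("background size N must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    term: Term
    counts: ContingencyCounts
    p_raw: float
    p_adj: float
    odds_ratio: float


def make_counts(
    selected: Iterable[str],
    term_genes: Iterable[str],
    background: Iterable[str],
) -> ContingencyCounts:
    """Intersect everything down to the background and count the 2x2 table.

    Selected genes outside the background are dropped (with a logged count);
    an empty background or an empty post-intersection selection is an error.
    """
    background = set(background)
    if not background:
        raise EnrichmentInputError("background universe is empty")
    selected = set(selected)
    sel_bg = selected & background
    dropped = len(selected) - len(sel_bg)
    if dropped:
        logger.warning("%d selected gene(s) outside the background dropped", dropped)
    if not sel_bg:
        raise EnrichmentInputError(
            "no selected genes remain after intersecting with the background"
        )
    term_bg = set(term_genes) & background
    return ContingencyCounts(
        k=len(sel_bg & term_bg), K=len(term_bg), n=len(sel_bg), N=len(background)
    )


def fisher_p(counts: ContingencyCounts, variant: Variant = "standard") -> float:
    """Upper-tail ``P[X >= k]`` for ``X ~ Hypergeometric(N, K, n)``.

    ``variant="ease"`` computes the tail at ``max(k-1, 0)`` on the same
    margins, which can only weaken the evidence.
    """
    k = counts.k
    if variant == "ease":
        k = max(k - 1, 0)
    elif variant != "standard":
        raise ValueError(f"unknown variant {variant!r}")
    if k == 0:
        return 1.0
    # sf(k-1) = P[X >= k]; exact for these integer margins
    p = float(hypergeom.sf(k - 1, counts.N, counts.K, counts.n))
    return min(max(p, 0.0), 1.0)


def odds_ratio(counts: ContingencyCounts) -> float:
    """Sample odds ratio of the 2x2 table; +inf when a null cell zeroes it."""
    a = counts.k
    b = counts.n - counts.k
    c = counts.K - counts.k
    d = counts.N - counts.K - b
    if a * d == 0 and b * c == 0:
        return math.nan
    if b * c == 0:
        return math.inf
    return (a * d) / (b * c)


def adjust_pvalues(p_list: Sequence[float], method: AdjustMethod = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bh`` is the Benjamini-Hochberg step-up with monotonicity enforcement,
    capped at 1; ``none`` is the identity.
    """
    for p in p_list:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    if method == "none":
        return list(p_list)
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    m = len(p_list)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_list[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_list[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def enrich(
    selected: Iterable[str],
    table: AnnotationTable,
    background: Iterable[str] | Literal["annotated_genome"] = "annotated_genome",
    variant: Variant = "standard",
    adjust: AdjustMethod = "none",
    categories: Iterable[Category] | None = None,
) -> list[EnrichmentResult]:
    """Test every term with at least one background gene against the selection.

    Results are sorted by raw p ascending with ties broken by term_id; the
    adjustment is computed within each category separately.
    """
    selected = set(selected)
    if not selected:
        raise EnrichmentInputError("selection is empty")
    if not table.terms:
        raise EnrichmentInputError("annotation table is empty")
    if isinstance(background, str) and background == "annotated_genome":
        bg = table.universe
    else:
        bg = set(background)
    if not bg:
        raise EnrichmentInputError("background universe is empty")
    wanted = set(categories) if categories is not None else None

    rows: list[tuple[Term, ContingencyCounts, float]] = []
    for term_id in sorted(table.terms):
        term = table.terms[term_id]
        if wanted is not None and term.category not in wanted:
            continue
        counts = make_counts(selected, table.term_genes.get(term_id, set()), bg)
        if counts.K < 1:
            continue
        rows.append((term, counts, fisher_p(counts, variant)))

    # BH within each category, mapped back to row order
    p_adj = {id(r): r[2] for r in rows}
    if adjust == "bh":
        by_cat: dict[Category, list[tuple[int, float]]] = {}
        for idx, (term, _, p) in enumerate(rows):
            by_cat.setdefault(term.category, []).append((idx, p))
        adj_by_idx: dict[int, float] = {}
        for members in by_cat.values():
            adj = adjust_pvalues([p for _, p in members], "bh")
            for (idx, _), a in zip(members, adj):
                adj_by_idx[idx] = a
        results = [
            EnrichmentResult(term, counts, p, adj_by_idx[idx], odds_ratio(counts))
            for idx, (term, counts, p) in enumerate(rows)
        ]
    elif adjust == "none":
        results = [
            EnrichmentResult(term, counts, p, p, odds_ratio(counts))
            for term, counts, p in rows
        ]
    else:
        raise ValueError(f"unknown adjustment method {adjust!r}")

    results.sort(key=lambda r: (r.p_raw, r.term.term_id))
    return results


def results_tsv(results: Sequence[EnrichmentResult]) -> str:
    """Render enrichment results as a stable, re-parsable TSV document."""
    lines = ["category\tterm_id\tterm_name\tk\tK\tn\tN\todds_ratio\tp_raw\tp_adj"]
    for r in results:
        orv = "inf" if math.isinf(r.odds_ratio) else (
            "NA" if math.isnan(r.odds_ratio) else f"{r.odds_ratio:.6g}"
        )
        lines.append(
            "\t".join(
                [
                    r.term.category.value,
                    r.term.term_id,
                    r.term.term_name,
                    str(r.counts.k),
                    str(r.counts.K),
                    str(r.counts.n),
                    str(r.counts.N),
                    orv,
                    f"{r.p_raw:.6g}",
                    f"{r.p_adj:.6g}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
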