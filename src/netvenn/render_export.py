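"""SVG/PNG figure rendering and TSV table export.

The SVG is the source of truth: a deterministic document with edges drawn
beneath nodes, circle/square gene shapes and static edge coloring by
direction (1 red, 2 blue). PNG output rasterizes the same scene at a
requested dpi with Pillow. The gene-information table is emitted as plain
TSV so it is diffable and bit-exactly testable.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence
from xml.sax.saxutils import escape

from PIL import Image, ImageDraw

from .annotation_store import AnnotationTable, annotate_gene
from .enrichment import EnrichmentResult
from .errors import NetVennError
from .graph import EDGE_COLORS, GraphModel, Layout
from .set_model import DirectionClass

#: fixed info-table column order (before the per-experiment code columns,
#: which are inserted after gene_id in experiment display order)
INFO_TABLE_FIXED_COLUMNS = (
    "direction_class",
    "description",
    "pathway_terms",
    "go_terms",
    "pathway_p",
    "go_p",
)


@dataclass(frozen=True)
class StyleConfig:
    experiment_radius: float = 14.0
    gene_radius: float = 5.0
    edge_width: float = 1.2
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 10.0
    canvas_width: int = 800
    canvas_height: int = 600
    margin: float = 40.0
    background: str = "#ffffff"

    def __post_init__(self) -> None:
        for name in ("experiment_radius", "gene_radius", "edge_width",
                     "font_size", "canvas_width", "canvas_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_STYLE = StyleConfig()


def _fit(layout: Layout, style: StyleConfig) -> dict[str, tuple[float, float]]:
    """Map layout coordinates into the canvas, preserving aspect ratio."""
    xmin, ymin, xmax, ymax = layout.bounds
    spanx = xmax - xmin
    spany = ymax - ymin
    availw = style.canvas_width - 2 * style.margin
    availh = style.canvas_height - 2 * style.margin
    scale = min(
        availw / spanx if spanx > 0 else math.inf,
        availh / spany if spany > 0 else math.inf,
    )
    if not math.isfinite(scale):  # degenerate: all nodes coincident
        scale = 1.0
    cx = (xmin + xmax) / 2.0
    cy = (ymin + ymax) / 2.0
    return {
        nid: (
            style.canvas_width / 2.0 + (x - cx) * scale,
            style.canvas_height / 2.0 - (y - cy) * scale,
        )
        for nid, (x, y) in layout.positions.items()
    }


def _check_layout(model: GraphModel, layout: Layout) -> None:
    missing = [n.node_id for n in model.nodes if n.node_id not in layout.positions]
    if missing:
        raise NetVennError(f"layout missing node(s): {', '.join(sorted(missing))}")


def render_svg(model: GraphModel, layout: Layout, style: StyleConfig = DEFAULT_STYLE) -> str:
    """Render a standalone SVG document (deterministic for fixed inputs)."""
    _check_layout(model, layout)
    pos = _fit(layout, style)
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{style.canvas_width}" '
        f'height="{style.canvas_height}" viewBox="0 0 {style.canvas_width} '
        f'{style.canvas_height}">',
        f'<rect class="background" width="{style.canvas_width}" '
        f'height="{style.canvas_height}" fill="{style.background}"/>',
        '<g class="edges">',
    ]
    for e in model.edges:
        x1, y1 = pos[e.experiment]
        x2, y2 = pos[e.gene]
        out.append(
            f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" y2="{y2:.2f}" '
            f'stroke="{EDGE_COLORS[e.direction]}" stroke-width="{style.edge_width}" '
            f'stroke-opacity="0.6"/>'
        )
    out.append("</g>")
    out.append('<g class="nodes">')
    labels: list[str] = []
    for n in model.nodes:
        x, y = pos[n.node_id]
        r = style.experiment_radius if n.kind == "EXPERIMENT" else style.gene_radius
        if n.shape == "square":
            side = 2 * r
            out.append(
                f'<rect x="{x - r:.2f}" y="{y - r:.2f}" width="{side:.2f}" '
                f'height="{side:.2f}" fill="{n.color}" stroke="#333333"/>'
            )
        else:
            out.append(
                f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{r}" fill="{n.color}" '
                f'stroke="#333333"/>'
            )
        if n.label_visible and n.label:
            size = style.font_size * (1.2 if n.kind == "EXPERIMENT" else 1.0)
            labels.append(
                f'<text x="{x:.2f}" y="{y - r - 2:.2f}" text-anchor="middle" '
                f'font-family="{style.font_family}" font-size="{size:g}">'
                f"{escape(n.label)}</text>"
            )
    out.append("</g>")
    out.append('<g class="labels">')
    out.extend(labels)
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def render_png(
    model: GraphModel,
    layout: Layout,
    style: StyleConfig = DEFAULT_STYLE,
    dpi: int = 300,
) -> bytes:
    """Rasterize the SVG scene; pixel dims = canvas x dpi/72 (rounded)."""
    if dpi < 72:
        raise ValueError(f"dpi must be >= 72, got {dpi}")
    _check_layout(model, layout)
    scale = dpi / 72.0
    w = round(style.canvas_width * scale)
    h = round(style.canvas_height * scale)
    img = Image.new("RGB", (w, h), style.background)
    draw = ImageDraw.Draw(img, "RGBA")
    pos = {nid: (x * scale, y * scale) for nid, (x, y) in _fit(layout, style).items()}

    ew = max(1, round(style.edge_width * scale))
    for e in model.edges:
        draw.line(
            [pos[e.experiment], pos[e.gene]],
            fill=EDGE_COLORS[e.direction] + "99",
            width=ew,
        )
    for n in model.nodes:
        x, y = pos[n.node_id]
        r = (style.experiment_radius if n.kind == "EXPERIMENT" else style.gene_radius) * scale
        box = (x - r, y - r, x + r, y + r)
        if n.shape == "square":
            draw.rectangle(box, fill=n.color, outline="#333333")
        else:
            draw.ellipse(box, fill=n.color, outline="#333333")
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def _gene_term_pvalues(
    gene_terms: set[str], results_by_term: Mapping[str, EnrichmentResult], go: bool
) -> str:
    parts = []
    for tid in sorted(gene_terms):
        r = results_by_term.get(tid)
        if r is None or r.term.category.is_go != go:
            continue
        parts.append(f"{tid}={r.p_raw:.4g}")
    return ";".join(parts)


def export_info_table(
    model: GraphModel,
    table: AnnotationTable | None = None,
    enrichment: Sequence[EnrichmentResult] | None = None,
) -> str:
    """One TSV row per gene node: codes per experiment, class, annotation.

    Columns: ``gene_id``, one column per experiment (direction code printed
    as "1"/"2", blank where absent), then ``direction_class``,
    ``description``, ``pathway_terms``, ``go_terms``, ``pathway_p``,
    ``go_p``. Rows are sorted by gene_id.
    """
    experiments = [n.node_id for n in model.experiment_nodes]
    memberships = model.memberships()
    results_by_term = {r.term.term_id: r for r in enrichment or ()}

    header = ["gene_id", *experiments, *INFO_TABLE_FIXED_COLUMNS]
    lines = ["\t".join(header)]
    for n in sorted(model.gene_nodes, key=lambda n: n.node_id):
        codes = memberships.get(n.node_id, {})
        cls = n.direction_class
        if table is not None:
            desc, terms = annotate_gene(table, n.node_id)
            pathway_terms = ";".join(t.term_id for t in terms if not t.category.is_go)
            go_terms = ";".join(t.term_id for t in terms if t.category.is_go)
            tids = {t.term_id for t in terms}
            pathway_p = _gene_term_pvalues(tids, results_by_term, go=False)
            go_p = _gene_term_pvalues(tids, results_by_term, go=True)
        else:
            desc = pathway_terms = go_terms = pathway_p = go_p = ""
        row = [
            n.node_id,
            *[str(codes[e]) if e in codes else "" for e in experiments],
            cls.value if cls is not None else "",
            desc,
            pathway_terms,
            go_terms,
            pathway_p,
            go_p,
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_info_table(text: str) -> tuple[list[str], list[dict[str, str]]]:
    """Re-parse an info table; returns (experiment columns, row dicts).

    Recovers gene_id, per-experiment codes and direction_class losslessly.
    """
    lines = [ln for ln in text.splitlines() if ln]
    if not lines:
        raise NetVennError("empty info table")
    header = lines[0].split("\t")
    if header[0] != "gene_id" or header[-len(INFO_TABLE_FIXED_COLUMNS):] != list(
        INFO_TABLE_FIXED_COLUMNS
    ):
        raise NetVennError("unrecognized info-table header")
    experiments = header[1 : len(header) - len(INFO_TABLE_FIXED_COLUMNS)]
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise NetVennError("ragged info-table row")
        rows.append(dict(zip(header, fields)))
    return experiments, rows
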