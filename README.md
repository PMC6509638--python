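# netvenn

Compare 2–8 differential-gene lists as one force-directed experiment–gene
graph instead of a Venn diagram. Each list becomes a hub node; each gene is a
node connected to every list containing it, colored red (upregulated
everywhere), blue (downregulated everywhere) or yellow (discordant). Any gene
selection can be enriched against local pathway/GO annotation tables with a
one-sided Fisher exact test (standard or the conservative EASE variant), the
graph can be subset or highlighted by functional terms, and everything
exports to SVG/PNG figures plus sortable TSV tables.

## Input formats

* **Gene list** — two tab-separated columns per line: gene ID, then `1`
  (upregulated) or `2` (downregulated) under your own fold-change cutoff.
  Blank lines and `#` comments are ignored; one header line is tolerated.
  Duplicate lines deduplicate; a gene listed with *both* codes in one file is
  an error.
* **Annotations** — GMT (`term_id<TAB>term_name|CATEGORY<TAB>gene...`, one
  set per line; category one of `PATHWAY`, `GO_BP`, `GO_MF`, `GO_CC`,
  defaulting to `PATHWAY`) or long TSV
  (`gene_id<TAB>term_id<TAB>term_name<TAB>category`).
* **Descriptions** — optional two-column `gene_id<TAB>description` TSV.

## CLI

Stages compose through a JSON graph document:

```sh
# parse lists, build the graph + gene information table
netvenn build --list WT=wt.tsv --list OX=ox.tsv \
    --pathways kegg.gmt --go go.gmt --out run/

# Venn-region report (signature, size, up/down/discordant breakdown)
netvenn regions --list WT=wt.tsv --list OX=ox.tsv

# over-representation test (all genes, one region, or a gene file)
netvenn enrich --graph run/graph.json --pathways kegg.gmt --go go.gmt \
    --select region:OX+WT --background annotated_genome --adjust bh

# induced subgraph for a term of interest, re-enriched and rendered
netvenn subset --graph run/graph.json --go go.gmt \
    --keyword "oxidative stress" --out run/subset/

# redraw with genes of interest as square nodes
netvenn highlight --graph run/graph.json --go go.gmt \
    --term-id GO:0006979 --out run/highlight.svg

# figures at publication resolution
netvenn render --graph run/graph.json --svg run/graph.svg \
    --png run/graph.png --dpi 300

# synthetic fixture with known ground truth (see FixtureSpec JSON)
netvenn simulate --spec spec.json --out fixture/
```

Layouts are seeded Fruchterman–Reingold spring embeddings: identical inputs
and `--seed` give byte-identical `graph.json` and SVG output. Gene labels
are hidden automatically above 200 gene nodes (`--labels on|off|auto`).
`--ease` switches enrichment to the EASE score (tail recomputed at `k-1`);
Benjamini–Hochberg adjustment is available via `--adjust bh` and is applied
within each annotation category separately.

The info table (`info_table.tsv`) has one row per gene node: `gene_id`, one
direction-code column per experiment (blank where absent), then
`direction_class`, `description`, `pathway_terms`, `go_terms`, `pathway_p`,
`go_p`.

## Library

Every CLI stage is a plain function:

```python
from netvenn import (
    load_collection, build_membership, venn_regions, build_graph,
    layout_graph, load_annotations, enrich, render_svg, export_info_table,
)
```

`netvenn.synthetic_fixtures` generates reproducible gene-list collections
with exact region sizes, controlled up/down proportions and one planted
over-represented term — the basis of the property-based test suite.

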