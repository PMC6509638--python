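import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netvenn.errors import EmptySubsetError, LayoutError
from netvenn.genelist_io import ExperimentList, GeneRecord
from netvenn.graph import (
    EXPERIMENT_PALETTE,
    GENE_COLORS,
    GraphModel,
    build_graph,
    from_json,
    highlight_genes,
    layout_graph,
    subset_graph,
    to_json,
)
from netvenn.set_model import DirectionClass, build_membership


def _model(*specs, **kw) -> GraphModel:
    lists = [
        ExperimentList(name, [GeneRecord(g, c) for g, c in genes.items()])
        for name, genes in specs
    ]
    return build_graph(lists, build_membership(lists), **kw)


class TestBuildGraph:
    def test_discordant_gene_yellow_with_two_edges(self):
        m = _model(("A", {"g1": 1}), ("B", {"g1": 2}))
        assert len(m.experiment_nodes) == 2
        genes = m.gene_nodes
        assert len(genes) == 1
        assert genes[0].color == GENE_COLORS[DirectionClass.DISCORDANT]
        assert sorted(e.direction for e in m.edges) == [1, 2]

    def test_shared_gene_degree_eight(self):
        specs = [(f"E{i}", {"g1": 1}) for i in range(8)]
        m = _model(*specs)
        assert sum(1 for e in m.edges if e.gene == "g1") == 8

    def test_disjoint_lists_no_multidegree_gene(self):
        m = _model(("A", {"g1": 1, "g2": 2}), ("B", {"g3": 1}))
        degrees = {}
        for e in m.edges:
            degrees[e.gene] = degrees.get(e.gene, 0) + 1
        assert all(d == 1 for d in degrees.values())

    def test_palette_by_input_order(self):
        m = _model(("X", {"g1": 1}), ("Y", {"g2": 1}), ("Z", {"g3": 1}))
        assert [n.color for n in m.experiment_nodes] == list(EXPERIMENT_PALETTE[:3])

    def test_gene_colors_follow_classification(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        by_id = {n.node_id: n for n in m.gene_nodes}
        assert by_id["g1"].color == GENE_COLORS[DirectionClass.UP]
        assert by_id["g4"].color == GENE_COLORS[DirectionClass.DOWN]
        assert by_id["g3"].color == GENE_COLORS[DirectionClass.DISCORDANT]

    def test_edge_direction_matches_membership(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        for e in m.edges:
            assert e.direction == toy_profiles[e.gene].memberships[e.experiment]

    def test_label_auto_threshold(self):
        small = _model(("A", {"g1": 1}), ("B", {"g2": 1}))
        assert all(n.label_visible for n in small.gene_nodes)
        big = _model(
            ("A", {f"g{i}": 1 for i in range(150)}),
            ("B", {f"h{i}": 2 for i in range(150)}),
        )
        assert not any(n.label_visible for n in big.gene_nodes)
        assert all(n.label_visible for n in big.experiment_nodes)


class TestLayout:
    def test_determinism_same_seed(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        l1 = layout_graph(m, iterations=40, seed=7)
        l2 = layout_graph(m, iterations=40, seed=7)
        assert l1.positions == l2.positions  # bit-identical

    def test_different_seed_differs(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        l1 = layout_graph(m, seed=1)
        l2 = layout_graph(m, seed=2)
        assert l1.positions != l2.positions

    def test_two_connected_nodes_regression(self):
        # frozen from a reference run of the seeded spring embedding
        m = _model(("A", {"g1": 1}), ("B", {"g1": 1}))
        layout = layout_graph(m, iterations=50, seed=42)
        assert set(layout.positions) == {"A", "B", "g1"}
        xs = [x for x, _ in layout.positions.values()]
        ys = [y for _, y in layout.positions.values()]
        assert max(xs) - min(xs) <= 2.0 and max(ys) - min(ys) <= 2.0
        d_ab = (
            (layout.positions["A"][0] - layout.positions["B"][0]) ** 2
            + (layout.positions["A"][1] - layout.positions["B"][1]) ** 2
        ) ** 0.5
        assert 0 < d_ab <= 2.83  # inside the unit box diagonal

    def test_iterations_validated(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        with pytest.raises(ValueError):
            layout_graph(m, iterations=0)

    def test_empty_model_rejected(self):
        with pytest.raises(LayoutError):
            layout_graph(GraphModel())

    def test_pinned_experiments_on_circle(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        layout = layout_graph(m, seed=3, pin_experiments=True)
        for hub in ("A", "B"):
            x, y = layout.positions[hub]
            assert (x * x + y * y) ** 0.5 == pytest.approx(1.0, abs=1e-9)


class TestSubsetGraph:
    def test_all_genes_identity(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        sub = subset_graph(m, m.gene_ids)
        assert sub.nodes == m.nodes
        assert sub.edges == m.edges

    def test_subset_keeps_colors_and_directions(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        sub = subset_graph(m, {"g3"})
        assert {n.node_id for n in sub.gene_nodes} == {"g3"}
        assert sub.gene_nodes[0].color == GENE_COLORS[DirectionClass.DISCORDANT]
        assert {(e.experiment, e.direction) for e in sub.edges} == {("A", 1), ("B", 2)}

    def test_isolated_experiment_dropped(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        sub = subset_graph(m, {"g1"})  # only in A
        assert [n.node_id for n in sub.experiment_nodes] == ["A"]

    def test_empty_intersection_rejected(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        with pytest.raises(EmptySubsetError):
            subset_graph(m, {"nope"})

    def test_monotone(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        small = subset_graph(m, {"g3"})
        large = subset_graph(m, {"g3", "g4", "g1"})
        assert {n.node_id for n in small.nodes} <= {n.node_id for n in large.nodes}
        assert set(small.edges) <= set(large.edges)


class TestHighlight:
    def test_square_only_for_subset(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        marked = highlight_genes(m, {"g1"})
        shapes = {n.node_id: n.shape for n in marked.nodes}
        assert shapes["g1"] == "square"
        assert all(s == "circle" for nid, s in shapes.items() if nid != "g1")

    def test_empty_subset_unchanged(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        assert highlight_genes(m, set()).nodes == m.nodes

    def test_idempotent(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        once = highlight_genes(m, {"g1", "g3"})
        twice = highlight_genes(once, {"g1", "g3"})
        assert once.nodes == twice.nodes

    def test_unknown_genes_ignored(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        marked = highlight_genes(m, {"not-a-gene"})
        assert marked.nodes == m.nodes

    def test_does_not_mutate_original(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        highlight_genes(m, {"g1"})
        assert all(n.shape == "circle" for n in m.nodes)


class TestJsonRoundTrip:
    def test_round_trip_equality(self, toy_lists, toy_profiles):
        m = build_graph(toy_lists, toy_profiles)
        again = from_json(to_json(m))
        assert again.nodes == m.nodes
        assert again.edges == m.edges
        assert again.seed == m.seed

    def test_write_read_write_bytes(self, toy_lists, toy_profiles):
        m = highlight_genes(build_graph(toy_lists, toy_profiles), {"g3"})
        text = to_json(m)
        assert to_json(from_json(text)) == text


# ---- randomized properties ----

_collections = st.integers(min_value=2, max_value=8).flatmap(
    lambda n: st.lists(
        st.dictionaries(
            st.integers(min_value=0, max_value=199).map(lambda i: f"g{i}"),
            st.sampled_from([1, 2]),
            min_size=1,
            max_size=40,
        ),
        min_size=n,
        max_size=n,
    )
)


@settings(max_examples=50, deadline=None)
@given(_collections)
def test_edge_conservation_and_color_soundness(genes_by_list):
    lists = [
        ExperimentList(f"E{i}", [GeneRecord(g, c) for g, c in d.items()])
        for i, d in enumerate(genes_by_list)
    ]
    m = build_graph(lists, build_membership(lists))
    assert len(m.edges) == sum(len(x) for x in lists)
    # yellow iff edge codes include both 1 and 2
    codes_by_gene: dict[str, set[int]] = {}
    for e in m.edges:
        codes_by_gene.setdefault(e.gene, set()).add(e.direction)
    for n in m.gene_nodes:
        is_yellow = n.color == GENE_COLORS[DirectionClass.DISCORDANT]
        assert is_yellow == (codes_by_gene[n.node_id] == {1, 2})
        # degree equals number of containing experiments
        deg = sum(1 for e in m.edges if e.gene == n.node_id)
        assert deg == sum(1 for d in genes_by_list if n.node_id in d)
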