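import pytest

from netvenn.annotation_store import load_annotations, load_descriptions
from netvenn.genelist_io import ExperimentList, GeneRecord
from netvenn.set_model import build_membership


@pytest.fixture
def toy_lists():
    """Two overlapping experiments with one discordant shared gene.

    A = {g1:1, g2:1, g3:1, g4:2}; B = {g3:2, g4:2, g5:2}.
    g3 is discordant, g4 concordant-down, rest single-experiment.
    """
    a = ExperimentList(
        "A",
        [GeneRecord("g1", 1), GeneRecord("g2", 1), GeneRecord("g3", 1), GeneRecord("g4", 2)],
    )
    b = ExperimentList("B", [GeneRecord("g3", 2), GeneRecord("g4", 2), GeneRecord("g5", 2)])
    return [a, b]


@pytest.fixture
def toy_profiles(toy_lists):
    return build_membership(toy_lists)


@pytest.fixture
def toy_list_files(tmp_path, toy_lists):
    """The toy collection written to disk as two-column TSVs."""
    paths = []
    for exp in toy_lists:
        p = tmp_path / f"{exp.name}.tsv"
        p.write_text("".join(f"{r.gene_id}\t{r.direction}\n" for r in exp.records))
        paths.append((str(p), exp.name))
    return paths


@pytest.fixture
def toy_annotations(tmp_path):
    """Small GMT with GO + pathway terms covering the toy genes."""
    gmt = (
        "GO:0006979\tresponse to oxidative stress|GO_BP\tg1\tg3\tg5\n"
        "GO:0008150\tbiological process|GO_BP\tg1\tg2\tg3\tg4\tg5\tg6\n"
        "ath00920\tsulfur metabolism|PATHWAY\tg2\tg4\n"
        "ath99999\tunrelated pathway|PATHWAY\tg6\tg7\tg8\n"
    )
    p = tmp_path / "annotations.gmt"
    p.write_text(gmt)
    table = load_annotations(p)
    desc = tmp_path / "descriptions.tsv"
    desc.write_text("g1\talpha subunit\ng3\tstress kinase\n")
    load_descriptions(desc, table)
    return table
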