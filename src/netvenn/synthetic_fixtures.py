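"""Synthetic gene-list collections and annotation tables with known truth.

Generators emit the same plain-text formats the parsers read (two-column
TSV lists, GMT annotation sets) so every module is testable offline:
region sizes are exact by construction, direction codes are Bernoulli per
(gene, experiment), and the annotation table optionally contains one
planted over-represented term against a configurable null background.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FixtureSpecError
from .genelist_io import ExperimentList, GeneRecord, serialize_gene_list

PLANTED_TERM_ID = "PLANTED:0001"


@dataclass(frozen=True)
class PlantedTermSpec:
    """One over-represented term planted against a given Venn region."""

    target_signature: tuple[str, ...]
    term_size: int          # K: total genes annotated to the planted term
    overlap: int            # k*: planted genes inside the target region
    n_null_terms: int = 100
    null_term_size: int = 40

    def __post_init__(self) -> None:
        if self.overlap > self.term_size:
            raise FixtureSpecError("planted overlap k* exceeds term size K")
        if self.overlap < 0 or self.term_size < 1:
            raise FixtureSpecError("planted term sizes must be positive")
        if self.n_null_terms < 0 or self.null_term_size < 1:
            raise FixtureSpecError("null term configuration invalid")


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for one reproducible synthetic data set."""

    experiments: tuple[str, ...]
    region_sizes: Mapping[tuple[str, ...], int]
    p_up: float = 0.5
    universe_size: int = 2000
    planted: PlantedTermSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.experiments)
        if not (2 <= n <= 8):
            raise FixtureSpecError(f"need 2-8 experiments, got {n}")
        if len(set(self.experiments)) != n:
            raise FixtureSpecError("experiment names must be distinct")
        if not (0.0 <= self.p_up <= 1.0):
            raise FixtureSpecError(f"p_up must be in [0, 1], got {self.p_up}")
        total = 0
        exp_set = set(self.experiments)
        for sig, count in self.region_sizes.items():
            if not sig or not set(sig) <= exp_set:
                raise FixtureSpecError(f"bad region signature {sig!r}")
            if len(set(sig)) != len(sig):
                raise FixtureSpecError(f"repeated name in signature {sig!r}")
            if count < 0:
                raise FixtureSpecError(f"negative region size for {sig!r}")
            total += count
        if total < 1:
            raise FixtureSpecError("region sizes must sum to at least 1")
        if self.universe_size < total:
            raise FixtureSpecError(
                f"universe_size {self.universe_size} smaller than collection ({total})"
            )
        if self.planted is not None:
            tsig = tuple(sorted(self.planted.target_signature))
            realized = {tuple(sorted(s)): c for s, c in self.region_sizes.items()}
            if tsig not in realized:
                raise FixtureSpecError(f"planted target region {tsig!r} not in spec")
            if self.planted.overlap > realized[tsig]:
                raise FixtureSpecError("planted overlap k* exceeds target region size")
            if self.planted.term_size > self.universe_size:
                raise FixtureSpecError("planted term size exceeds universe")

    @property
    def total_genes(self) -> int:
        return sum(self.region_sizes.values())


@dataclass
class FixtureTruth:
    """Realized ground truth for one generated fixture."""

    regions: dict[str, list[str]] = field(default_factory=dict)  # "A+B" -> genes
    gene_codes: dict[str, dict[str, int]] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)
    planted_term_id: str | None = None
    planted_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _gene_id(i: int) -> str:
    return f"SG{i + 1:06d}"


def _sig_key(sig: Sequence[str]) -> str:
    return "+".join(sorted(sig))


def _ordered_signatures(spec: FixtureSpec) -> list[tuple[str, ...]]:
    return sorted(
        (tuple(sorted(s)) for s in spec.region_sizes),
        key=lambda s: (-len(s), s),
    )


def generate_collection(spec: FixtureSpec) -> tuple[list[ExperimentList], FixtureTruth]:
    """Distribute synthetic genes exactly per region and draw direction codes.

    Codes are independent Bernoulli(p_up) per (gene, experiment): 1 with
    probability ``p_up``, else 2. Fully reproducible from the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = {tuple(sorted(s)): c for s, c in spec.region_sizes.items()}
    truth = FixtureTruth(universe=[_gene_id(i) for i in range(spec.universe_size)])

    next_gene = 0
    per_experiment: dict[str, list[GeneRecord]] = {e: [] for e in spec.experiments}
    for sig in _ordered_signatures(spec):
        genes = [_gene_id(next_gene + j) for j in range(sizes[sig])]
        next_gene += sizes[sig]
        truth.regions[_sig_key(sig)] = genes
        for g in genes:
            codes = {}
            for exp in spec.experiments:
                if exp in sig:
                    codes[exp] = 1 if rng.random() < spec.p_up else 2
            truth.gene_codes[g] = codes
            for exp, code in codes.items():
                per_experiment[exp].append(GeneRecord(g, code))

    lists = []
    for exp in spec.experiments:
        if not per_experiment[exp]:
            raise FixtureSpecError(f"experiment {exp!r} receives no genes")
        lists.append(ExperimentList(exp, per_experiment[exp]))
    return lists, truth


def generate_annotations(spec: FixtureSpec, truth: FixtureTruth) -> tuple[str, FixtureTruth]:
    """Write a GMT document with optional planted term plus uniform null terms.

    The planted term takes ``k*`` genes from the target region and ``K - k*``
    genes from the rest of the universe; null terms sample uniformly from the
    whole universe. Returns (GMT text, updated truth).
    """
    rng = np.random.default_rng(spec.seed + 1)
    universe = np.array(truth.universe)
    lines = []
    if spec.planted is not None:
        p = spec.planted
        region = truth.regions[_sig_key(p.target_signature)]
        if p.overlap > len(region):
            raise FixtureSpecError("planted overlap exceeds realized region size")
        inside = list(rng.choice(np.array(region), size=p.overlap, replace=False))
        outside_pool = np.array(sorted(set(truth.universe) - set(region)))
        n_out = p.term_size - p.overlap
        if n_out > len(outside_pool):
            raise FixtureSpecError("universe too small for planted term filler genes")
        outside = list(rng.choice(outside_pool, size=n_out, replace=False))
        genes = sorted(str(g) for g in inside + outside)
        truth.planted_term_id = PLANTED_TERM_ID
        truth.planted_genes = genes
        lines.append(
            "\t".join([PLANTED_TERM_ID, "planted signal|PATHWAY", *genes])
        )
        n_null = p.n_null_terms
        null_size = p.null_term_size
    else:
        n_null = 100
        null_size = 40
    for i in range(n_null):
        genes = sorted(
            str(g) for g in rng.choice(universe, size=null_size, replace=False)
        )
        lines.append("\t".join([f"NULL:{i + 1:04d}", f"null term {i + 1}|PATHWAY", *genes]))
    return "\n".join(lines) + "\n", truth


def default_spec(seed: int = 0) -> FixtureSpec:
    """Planted-signal recipe used by the recovery properties.

    Universe 2000 genes; two experiments sharing a region of 100 genes;
    planted term of 40 genes overlapping that region in 25; 100 null terms
    of 40 genes each.
    """
    return FixtureSpec(
        experiments=("A", "B"),
        region_sizes={("A",): 200, ("B",): 200, ("A", "B"): 100},
        p_up=0.5,
        universe_size=2000,
        planted=PlantedTermSpec(
            target_signature=("A", "B"),
            term_size=40,
            overlap=25,
            n_null_terms=100,
            null_term_size=40,
        ),
        seed=seed,
    )


def null_spec(seed: int = 0, n_terms: int = 2000, term_size: int = 300) -> FixtureSpec:
    """Null-only recipe (no planted signal) used for type-I calibration."""
    return FixtureSpec(
        experiments=("A", "B"),
        region_sizes={("A",): 200, ("B",): 200, ("A", "B"): 100},
        p_up=0.5,
        universe_size=2000,
        planted=PlantedTermSpec(
            target_signature=("A", "B"),
            term_size=1,
            overlap=0,
            n_null_terms=n_terms,
            null_term_size=term_size,
        ),
        seed=seed,
    )


def _strip_planted(gmt_text: str) -> str:
    return "".join(
        ln + "\n"
        for ln in gmt_text.splitlines()
        if not ln.startswith(PLANTED_TERM_ID)
    )


def generate_null_annotations(spec: FixtureSpec, truth: FixtureTruth) -> str:
    """Null terms only — the planted line is omitted for calibration runs."""
    gmt, _ = generate_annotations(spec, truth)
    return _strip_planted(gmt)


def write_fixture(spec: FixtureSpec, outdir: str | os.PathLike) -> dict[str, str]:
    """Write list TSVs, annotations GMT and truth JSON; returns path map.

    Same spec (including seed) produces byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    lists, truth = generate_collection(spec)
    gmt, truth = generate_annotations(spec, truth)
    paths: dict[str, str] = {}
    for exp in lists:
        path = os.path.join(outdir, f"list_{exp.name}.tsv")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(serialize_gene_list(exp))
        paths[exp.name] = path
    gmt_path = os.path.join(outdir, "annotations.gmt")
    with open(gmt_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(gmt)
    paths["annotations"] = gmt_path
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(truth.to_json())
    paths["truth"] = truth_path
    return paths


def spec_from_json(text: str) -> FixtureSpec:
    """Parse a JSON fixture spec (signatures written as "A+B" strings)."""
    doc = json.loads(text)
    try:
        planted = None
        if doc.get("planted"):
            p = doc["planted"]
            planted = PlantedTermSpec(
                target_signature=tuple(p["target_signature"].split("+")),
                term_size=int(p["term_size"]),
                overlap=int(p["overlap"]),
                n_null_terms=int(p.get("n_null_terms", 100)),
                null_term_size=int(p.get("null_term_size", 40)),
            )
        return FixtureSpec(
            experiments=tuple(doc["experiments"]),
            region_sizes={
                tuple(k.split("+")): int(v) for k, v in doc["region_sizes"].items()
            },
            p_up=float(doc.get("p_up", 0.5)),
            universe_size=int(doc.get("universe_size", 2000)),
            planted=planted,
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FixtureSpecError(f"malformed fixture spec: {exc}") from exc
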