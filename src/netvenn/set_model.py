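"""Venn-region membership and cross-experiment regulation classes.

A gene's *membership profile* maps each experiment containing it to that
experiment's direction code. A *Venn region* is the set of genes whose
containing-experiment signature is exactly a given subset of the inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .genelist_io import DOWN, UP, ExperimentList


class DirectionClass(enum.Enum):
    """Cross-experiment regulation state of one gene."""

    UP = "UP"            # code 1 in every containing experiment -> red node
    DOWN = "DOWN"        # code 2 in every containing experiment -> blue node
    DISCORDANT = "DISCORDANT"  # both codes occur -> yellow node


@dataclass
class MembershipProfile:
    gene_id: str
    memberships: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.memberships:
            raise ValueError(f"{self.gene_id}: profile must be non-empty")

    @property
    def signature(self) -> frozenset[str]:
        return frozenset(self.memberships)


@dataclass
class VennRegion:
    signature: frozenset[str]
    genes: set[str]


def build_membership(lists: list[ExperimentList]) -> dict[str, MembershipProfile]:
    """Union the collection into one profile per distinct gene."""
    profiles: dict[str, MembershipProfile] = {}
    for exp in lists:
        for rec in exp.records:
            prof = profiles.get(rec.gene_id)
            if prof is None:
                profiles[rec.gene_id] = MembershipProfile(
                    rec.gene_id, {exp.name: rec.direction}
                )
            else:
                prof.memberships[exp.name] = rec.direction
    return profiles


def venn_regions(profiles: Mapping[str, MembershipProfile]) -> list[VennRegion]:
    """Partition the gene universe into realized Venn regions.

    Regions are ordered by signature cardinality descending, then by the
    lexicographic order of the sorted experiment names. Empty (unrealized)
    signatures are omitted.
    """
    if not profiles:
        raise ValueError("profile map must be non-empty")
    by_sig: dict[frozenset[str], set[str]] = {}
    for gene_id, prof in profiles.items():
        by_sig.setdefault(prof.signature, set()).add(gene_id)
    ordered = sorted(by_sig, key=lambda s: (-len(s), tuple(sorted(s))))
    return [VennRegion(sig, by_sig[sig]) for sig in ordered]


def classify_direction(profile: MembershipProfile) -> DirectionClass:
    """UP iff all codes are 1; DOWN iff all are 2; DISCORDANT iff both occur."""
    codes = set(profile.memberships.values())
    if codes == {UP}:
        return DirectionClass.UP
    if codes == {DOWN}:
        return DirectionClass.DOWN
    return DirectionClass.DISCORDANT


def signature_label(signature: frozenset[str]) -> str:
    return "+".join(sorted(signature))


def region_table(
    profiles: Mapping[str, MembershipProfile], regions: list[VennRegion] | None = None
) -> str:
    """TSV report: signature, size, direction breakdown, member genes."""
    if regions is None:
        regions = venn_regions(profiles)
    lines = ["signature\tsize\tn_up\tn_down\tn_discordant\tgenes"]
    for reg in regions:
        classes = [classify_direction(profiles[g]) for g in sorted(reg.genes)]
        lines.append(
            "\t".join(
                [
                    signature_label(reg.signature),
                    str(len(reg.genes)),
                    str(sum(c is DirectionClass.UP for c in classes)),
                    str(sum(c is DirectionClass.DOWN for c in classes)),
                    str(sum(c is DirectionClass.DISCORDANT for c in classes)),
                    ",".join(sorted(reg.genes)),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def genes_in_region(
    profiles: Mapping[str, MembershipProfile], signature: frozenset[str] | set[str]
) -> set[str]:
    """Genes whose signature equals ``signature`` exactly."""
    sig = frozenset(signature)
    return {g for g, p in profiles.items() if p.signature == sig}
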