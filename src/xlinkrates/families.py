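"""Relatedness graphs, informative-family extraction and female phasing.

Two family kinds carry recombination information:

* type I  — a mother phased through her own genotyped father (the children's
  maternal grandfather) plus at least one child with an observable maternal
  haplotype;
* type II — a mother of unknown phase with at least two such children.

Children's maternal haplotypes are read directly from sons (hemizygous) and
recovered from daughters by subtracting the father's haplotype when he is
genotyped.  Inconsistencies are logged and the offending unit is skipped or
downgraded, never silently patched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .pedigree_io import Haplotype, Individual, PedDataError

__all__ = [
    "PhasedMother",
    "UnphasedMother",
    "InformativeFamily",
    "PhasingConflict",
    "build_family_graphs",
    "phase_daughter",
    "phase_mother_by_grandfather",
    "extract_families",
]

logger = logging.getLogger("xlinkrates")


class PhasingConflict(Exception):
    """A parent allele incompatible with a female's genotype at some marker."""

    def __init__(self, message: str, individual_id: str = "", marker: int = -1):
        super().__init__(message)
        self.individual_id = individual_id
        self.marker = marker


@dataclass
class PhasedMother:
    """Mother as two ordered haplotypes (hap1, hap2)."""

    hap1: Haplotype
    hap2: Haplotype
    source: str = "grandfather-phased"

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise PedDataError("phased mother haplotypes differ in length")

    def genotype(self) -> list:
        """Recover the unordered genotype (involution check helper)."""
        out = []
        for a, b in zip(self.hap1, self.hap2):
            out.append(None if a is None or b is None else tuple(sorted((a, b))))
        return out


@dataclass
class UnphasedMother:
    """Mother as an unordered genotype; phase is summed over in the likelihood."""

    genotype: list

    @property
    def het_mask(self) -> tuple:
        return tuple(g is not None and g[0] != g[1] for g in self.genotype)

    @property
    def n_phasings(self) -> int:
        h = sum(self.het_mask)
        return 2 ** max(h - 1, 0)


@dataclass
class InformativeFamily:
    kind: str  # "typeI" or "typeII"
    mother: object  # PhasedMother or UnphasedMother
    children: list  # list of Haplotype (maternal haplotypes)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("typeI", "typeII"):
            raise PedDataError(f"unknown family kind {self.kind!r}")
        minimum = 1 if self.kind == "typeI" else 2
        if len(self.children) < minimum:
            raise PedDataError(
                f"{self.kind} family needs at least {minimum} children, "
                f"got {len(self.children)}"
            )


def build_family_graphs(individuals) -> list:
    """One directed parent-to-child graph per connected group of relatives."""
    by_key = {(ind.family_id, ind.id): ind for ind in individuals}
    g = nx.DiGraph()
    for ind in individuals:
        key = (ind.family_id, ind.id)
        g.add_node(key, individual=ind)
    for ind in individuals:
        key = (ind.family_id, ind.id)
        for parent_id, want_sex, label in (
            (ind.father_id, "male", "father"),
            (ind.mother_id, "female", "mother"),
        ):
            if parent_id is None:
                continue
            pkey = (ind.family_id, parent_id)
            parent = by_key.get(pkey)
            if parent is None:
                logger.warning(
                    "individual %s:%s names %s %r who is not in the file; treated as absent",
                    ind.family_id, ind.id, label, parent_id,
                )
                continue
            if parent.sex != want_sex:
                raise PedDataError(
                    f"individual {ind.family_id}:{ind.id} names {parent_id!r} as "
                    f"{label}, but that individual is {parent.sex}"
                )
            g.add_edge(pkey, key)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise PedDataError(f"parent-child cycle detected: {cycle}")
    components = sorted(nx.weakly_connected_components(g), key=lambda c: min(c))
    return [g.subgraph(c).copy() for c in components]


def phase_daughter(daughter: Individual, father: Individual) -> Haplotype:
    """Recover a daughter's maternal haplotype by subtracting the father's.

    Raises :class:`PhasingConflict` when the father's allele is absent from
    the daughter's pair at some marker; markers missing on either side stay
    missing in the result.
    """
    alleles = []
    for i, (pair, pat) in enumerate(zip(daughter.genotype, father.genotype)):
        if pair is None or pat is None:
            alleles.append(None)
        elif pat == pair[0]:
            alleles.append(pair[1])
        elif pat == pair[1]:
            alleles.append(pair[0])
        else:
            raise PhasingConflict(
                f"daughter {daughter.family_id}:{daughter.id} lacks the father's "
                f"allele at marker index {i}",
                individual_id=daughter.id,
                marker=i,
            )
    return Haplotype(tuple(alleles))


def phase_mother_by_grandfather(mother: Individual, grandfather: Individual) -> PhasedMother:
    """Phase a mother using her father's haplotype (hap1 = grandfather's).

    Raises :class:`PhasingConflict` on an incompatible or missing grandfather
    allele at a marker where the mother is genotyped.
    """
    hap1, hap2 = [], []
    for i, (pair, gpa) in enumerate(zip(mother.genotype, grandfather.genotype)):
        if pair is None:
            hap1.append(None)
            hap2.append(None)
            continue
        if gpa is None:
            raise PhasingConflict(
                f"grandfather {grandfather.family_id}:{grandfather.id} is missing "
                f"marker index {i}, cannot phase {mother.id}",
                individual_id=mother.id,
                marker=i,
            )
        if gpa == pair[0]:
            hap1.append(pair[0])
            hap2.append(pair[1])
        elif gpa == pair[1]:
            hap1.append(pair[1])
            hap2.append(pair[0])
        else:
            raise PhasingConflict(
                f"mother {mother.family_id}:{mother.id} lacks the grandfather's "
                f"allele at marker index {i}",
                individual_id=mother.id,
                marker=i,
            )
    return PhasedMother(Haplotype(tuple(hap1)), Haplotype(tuple(hap2)))


def _maternal_haplotype(child: Individual, by_key: dict) -> Optional[Haplotype]:
    """Observable maternal haplotype of a child, or None if unusable."""
    if child.is_male:
        hap = Haplotype(tuple(child.genotype))
    else:
        if child.father_id is None:
            logger.warning(
                "daughter %s:%s has no genotyped father; cannot recover her "
                "maternal haplotype", child.family_id, child.id,
            )
            return None
        father = by_key.get((child.family_id, child.father_id))
        if father is None or not father.is_genotyped:
            logger.warning(
                "daughter %s:%s has no genotyped father; cannot recover her "
                "maternal haplotype", child.family_id, child.id,
            )
            return None
        try:
            hap = phase_daughter(child, father)
        except PhasingConflict as exc:
            logger.warning(
                "dropping daughter %s:%s from informative children: %s",
                child.family_id, child.id, exc,
            )
            return None
    if all(a is None for a in hap):
        logger.warning(
            "child %s:%s has no genotype data; skipped", child.family_id, child.id
        )
        return None
    return hap


def extract_families(graphs) -> list:
    """Extract every informative type I / type II family from relatedness graphs.

    Each genotyped mother is examined independently, so one pedigree can
    yield several families.  The result is deterministic and independent of
    the individual ordering in the source file.
    """
    families = []
    for graph in graphs:
        by_key = {key: graph.nodes[key]["individual"] for key in graph.nodes}
        mother_keys = sorted(
            key
            for key in graph.nodes
            if by_key[key].sex == "female" and graph.out_degree(key) > 0
        )
        for mkey in mother_keys:
            mother = by_key[mkey]
            if not mother.fully_genotyped:
                logger.warning(
                    "mother %s:%s has missing genotypes; skipped from family "
                    "extraction", mother.family_id, mother.id,
                )
                continue
            child_haps, child_ids = [], []
            for ckey in sorted(graph.successors(mkey)):
                child = by_key[ckey]
                if child.mother_id != mother.id:
                    continue
                hap = _maternal_haplotype(child, by_key)
                if hap is not None:
                    child_haps.append(hap)
                    child_ids.append(child.id)

            phased = None
            if mother.father_id is not None:
                grandfather = by_key.get((mother.family_id, mother.father_id))
                if grandfather is not None and grandfather.is_genotyped:
                    try:
                        phased = phase_mother_by_grandfather(mother, grandfather)
                    except PhasingConflict as exc:
                        logger.warning(
                            "mother %s:%s downgraded to unphased: %s",
                            mother.family_id, mother.id, exc,
                        )
            provenance = {
                "family_id": mother.family_id,
                "mother_id": mother.id,
                "children_ids": child_ids,
            }
            if phased is not None and child_haps:
                provenance["grandfather_id"] = mother.father_id
                families.append(
                    InformativeFamily("typeI", phased, child_haps, provenance)
                )
            elif len(child_haps) >= 2:
                families.append(
                    InformativeFamily(
                        "typeII",
                        UnphasedMother(list(mother.genotype)),
                        child_haps,
                        provenance,
                    )
                )
            else:
                logger.warning(
                    "mother %s:%s is not informative (%d observable children, "
                    "phased=%s); skipped",
                    mother.family_id, mother.id, len(child_haps), phased is not None,
                )
    return families
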