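"""Pedigree simulator with known recombination and mutation rates.

Generates type I families (maternal grandfather, mother, children) and
type II families (mother plus two or more children).  Mother haplotypes get
independent random alleles; each child draws an inheritance vector (uniform
initial state, switch between adjacent markers with probability theta_i),
copies the inherited alleles and mutates them marker-wise: an STR allele
steps one repeat up or down each with probability mu_i (reflected inward at
the edge of the allele pool) and a non-STR allele mutates to an alternative
with the 9:1 transition weighting of the likelihood kernel (with a 2-allele
pool the single alternative receives the whole mutation mass).  Daughters
receive a random genotyped father so their maternal haplotype can be
recovered by phasing; female allele pairs are sorted, erasing phase.

The returned truth record keeps the simulated phases, inheritance vectors
and mutation events so tests can assert against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .pedigree_io import MarkerPanel, POLY, STR, build_dataset

__all__ = [
    "SimConfig",
    "SimTruth",
    "FamilyTruth",
    "ChildTruth",
    "simulate_pedigrees",
    "write_truth_tsv",
]


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_markers: int
    theta: Union[float, Sequence[float]] = 0.1
    mu: Union[float, Sequence[float]] = 0.001
    n_type_i: int = 0
    n_type_ii: int = 0
    children_per_family: int = 2
    marker_types: Optional[Sequence[str]] = None  # default: all STR
    str_allele_range: tuple = (8, 20)
    poly_alleles: tuple = ("A", "G")
    include_fathers: bool = True
    daughter_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise SimConfigError("n_markers must be >= 1")
        if self.n_type_i < 0 or self.n_type_ii < 0:
            raise SimConfigError("family counts must be non-negative")
        if self.children_per_family < 1:
            raise SimConfigError("children_per_family must be >= 1")
        if self.marker_types is None:
            self.marker_types = (STR,) * self.n_markers
        self.marker_types = tuple(self.marker_types)
        if len(self.marker_types) != self.n_markers:
            raise SimConfigError("marker_types length must equal n_markers")
        for t in self.marker_types:
            if t not in (STR, POLY):
                raise SimConfigError(f"unknown marker type {t!r}")
        if POLY in self.marker_types and len(set(self.poly_alleles)) < 2:
            raise SimConfigError("POLY markers need at least 2 alleles in the pool")
        lo, hi = self.str_allele_range
        if hi <= lo:
            raise SimConfigError("str_allele_range must span at least 2 repeat counts")
        self.theta_true = _broadcast(self.theta, max(self.n_markers - 1, 0), "theta")
        self.mu_true = _broadcast(self.mu, self.n_markers, "mu")
        for name, vec in (("theta", self.theta_true), ("mu", self.mu_true)):
            if np.any(vec < 0) or np.any(vec > 0.5):
                raise SimConfigError(f"{name} entries must lie in [0, 0.5]")


def _broadcast(value, length, name) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if len(arr) == 1:
        arr = np.full(length, arr[0])
    if len(arr) != length:
        raise SimConfigError(f"{name} has length {len(arr)}, expected {length}")
    return arr


@dataclass
class ChildTruth:
    id: str
    sex: str
    inheritance_vector: tuple  # entries in {1, 2}
    maternal_hap: tuple        # encoded alleles (post-mutation)
    mutated_markers: tuple     # marker indices where a mutation happened


@dataclass
class FamilyTruth:
    family_id: str
    kind: str
    mother_id: str
    hap1: tuple
    hap2: tuple
    children: list


@dataclass
class SimTruth:
    theta: np.ndarray
    mu: np.ndarray
    families: list = field(default_factory=list)

    @property
    def n_type_i(self) -> int:
        return sum(f.kind == "typeI" for f in self.families)

    @property
    def n_type_ii(self) -> int:
        return sum(f.kind == "typeII" for f in self.families)


def _random_haplotype(rng, config) -> list:
    lo, hi = config.str_allele_range
    out = []
    for t in config.marker_types:
        if t == STR:
            out.append(str(int(rng.integers(lo, hi + 1))))
        else:
            out.append(config.poly_alleles[rng.integers(len(config.poly_alleles))])
    return out


def _mutate(rng, allele: str, i: int, config) -> tuple:
    """Return (possibly mutated allele string, mutated flag) for marker i."""
    mu = config.mu_true[i]
    if mu == 0.0:
        return allele, False
    if config.marker_types[i] == STR:
        lo, hi = config.str_allele_range
        u = rng.random()
        if u >= 2.0 * mu:
            return allele, False
        step = 1 if u < mu else -1
        value = int(allele) + step
        if value > hi or value < lo:
            value = int(allele) - step  # reflect inward at the pool edge
        return str(value), True
    from .likelihood import is_transition

    alternatives = [a for a in config.poly_alleles if a != allele]
    if len(alternatives) == 1:
        weights = [mu]  # whole mutation mass on the single alternative
    else:
        weights = [mu * (0.9 if is_transition(allele, b) else 0.1) for b in alternatives]
    total = sum(weights)
    u = rng.random()
    if u >= total:
        return allele, False
    acc = 0.0
    for b, w in zip(alternatives, weights):
        acc += w
        if u < acc:
            return b, True
    return alternatives[-1], True


def _simulate_child_hap(rng, hap1, hap2, config) -> tuple:
    n = config.n_markers
    state = int(rng.integers(2))  # 0 -> hap1, 1 -> hap2
    vector, alleles, mutated = [], [], []
    for i in range(n):
        if i > 0 and rng.random() < config.theta_true[i - 1]:
            state = 1 - state
        vector.append(state + 1)
        allele = hap1[i] if state == 0 else hap2[i]
        allele, did_mutate = _mutate(rng, allele, i, config)
        alleles.append(allele)
        if did_mutate:
            mutated.append(i)
    return tuple(vector), alleles, tuple(mutated)


def simulate_pedigrees(config: SimConfig) -> tuple:
    """Simulate pedigrees; returns ``(panel, individuals, truth)``.

    Identical configs (including the seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    rows: list = []            # (lineno, tokens) consumed by build_dataset
    raw_families: list = []    # string-level truth, encoded after the panel exists

    def add_row(fid, iid, father, mother, sex, alleles_pairs):
        tokens = [fid, iid, father, mother, sex, "0"]
        for a, b in alleles_pairs:
            tokens += [a, b]
        rows.append((len(rows) + 1, tokens))

    def simulate_family(fid: str, kind: str) -> None:
        hap1 = _random_haplotype(rng, config)
        hap2 = _random_haplotype(rng, config)
        children = []
        for k in range(config.children_per_family):
            sex = "female" if rng.random() < config.daughter_fraction else "male"
            vector, alleles, mutated = _simulate_child_hap(rng, hap1, hap2, config)
            children.append({
                "id": f"C{k + 1}", "sex": sex, "vector": vector,
                "alleles": alleles, "mutated": mutated,
            })
        has_daughter = any(c["sex"] == "female" for c in children)
        # daughters always carry a paternal allele; the father's own row is
        # only emitted when fathers are genotyped
        father_hap = _random_haplotype(rng, config) if has_daughter else None
        emit_father = father_hap is not None and config.include_fathers

        if kind == "typeI":
            gf_hap = hap1 if rng.integers(2) == 0 else hap2
            add_row(fid, "GF", "0", "0", "1", [(a, a) for a in gf_hap])
        if emit_father:
            add_row(fid, "FA", "0", "0", "1", [(a, a) for a in father_hap])
        mother_father = "GF" if kind == "typeI" else "0"
        add_row(fid, "MO", mother_father, "0", "2",
                [tuple(sorted(p)) for p in zip(hap1, hap2)])
        child_father = "FA" if emit_father else "0"
        for c in children:
            if c["sex"] == "male":
                add_row(fid, c["id"], child_father, "MO", "1",
                        [(a, a) for a in c["alleles"]])
            else:
                add_row(fid, c["id"], child_father, "MO", "2",
                        [tuple(sorted(p)) for p in zip(c["alleles"], father_hap)])
        raw_families.append((fid, kind, hap1, hap2, children))

    for k in range(config.n_type_i):
        simulate_family(f"FI{k + 1:04d}", "typeI")
    for k in range(config.n_type_ii):
        simulate_family(f"FII{k + 1:04d}", "typeII")

    if not rows:
        raise SimConfigError("nothing to simulate: both family counts are zero")

    names = [f"M{i + 1}" for i in range(config.n_markers)]
    forced = dict(zip(names, config.marker_types))
    panel, individuals = build_dataset(rows, marker_names=names, forced_types=forced)

    def encode(alleles) -> tuple:
        return tuple(panel.encode_allele(i, a) for i, a in enumerate(alleles))

    truth = SimTruth(theta=config.theta_true.copy(), mu=config.mu_true.copy())
    for fid, kind, hap1, hap2, children in raw_families:
        truth.families.append(FamilyTruth(
            family_id=fid,
            kind=kind,
            mother_id="MO",
            hap1=encode(hap1),
            hap2=encode(hap2),
            children=[
                ChildTruth(
                    id=c["id"],
                    sex=c["sex"],
                    inheritance_vector=c["vector"],
                    maternal_hap=encode(c["alleles"]),
                    mutated_markers=c["mutated"],
                )
                for c in children
            ],
        ))
    return panel, individuals, truth


def write_truth_tsv(truth: SimTruth, panel: MarkerPanel, path) -> None:
    """Emit the truth record as a tab-separated sidecar for tests and audits."""
    def decode(hap) -> str:
        return ",".join(panel.decode_allele(i, a) for i, a in enumerate(hap))

    lines = [
        "# theta_true=" + ",".join(f"{t:g}" for t in truth.theta),
        "# mu_true=" + ",".join(f"{m:g}" for m in truth.mu),
        "family_id\tkind\trecord\tindividual_id\thaplotype\tinheritance_vector\tmutated_markers",
    ]
    for fam in truth.families:
        for label, hap in (("mother_hap1", fam.hap1), ("mother_hap2", fam.hap2)):
            lines.append(
                f"{fam.family_id}\t{fam.kind}\t{label}\t{fam.mother_id}\t{decode(hap)}\t.\t."
            )
        for c in fam.children:
            vec = ",".join(str(v) for v in c.inheritance_vector)
            muts = ",".join(str(m) for m in c.mutated_markers) or "."
            lines.append(
                f"{fam.family_id}\t{fam.kind}\tchild\t{c.id}\t{decode(c.maternal_hap)}\t{vec}\t{muts}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
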