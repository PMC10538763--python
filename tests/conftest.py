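import numpy as np
import pytest

from xlinkrates.families import InformativeFamily, PhasedMother, UnphasedMother
from xlinkrates.likelihood import RateParams
from xlinkrates.pedigree_io import Haplotype, MarkerPanel, POLY, STR


def make_str_panel(n):
    return MarkerPanel(tuple(f"M{i + 1}" for i in range(n)), (STR,) * n, {})


def make_mixed_panel(types, poly_alleles=("A", "G", "C", "T")):
    """Panel for explicit type sequences; every POLY marker shares the pool."""
    maps = {
        i: {s: -(k + 1) for k, s in enumerate(poly_alleles)}
        for i, t in enumerate(types)
        if t == POLY
    }
    return MarkerPanel(tuple(f"M{i + 1}" for i in range(len(types))), tuple(types), maps)


@pytest.fixture
def panel2():
    return make_str_panel(2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_allele(rng, panel, i, lo=8, hi=13):
    if panel.is_str(i):
        return int(rng.integers(lo, hi + 1))
    codes = sorted(panel.allele_maps[i].values(), reverse=True)
    return int(codes[rng.integers(len(codes))])


def random_haplotype(rng, panel):
    return tuple(random_allele(rng, panel, i) for i in range(panel.n_markers))


def random_child(rng, panel, hap1, hap2, p_mut=0.1, p_missing=0.0):
    """Recombine the two haplotypes and occasionally perturb/blank alleles."""
    n = panel.n_markers
    state = int(rng.integers(2))
    out = []
    for i in range(n):
        if i > 0 and rng.random() < 0.3:
            state = 1 - state
        allele = (hap1, hap2)[state][i]
        if rng.random() < p_mut:
            if panel.is_str(i):
                allele = allele + (1 if rng.random() < 0.5 else -1)
            else:
                allele = random_allele(rng, panel, i)
        if p_missing and rng.random() < p_missing:
            allele = None
        out.append(allele)
    return tuple(out)


def random_rates(rng, n):
    return RateParams(
        rng.uniform(0.01, 0.5, size=max(n - 1, 0)), rng.uniform(0.001, 0.5, size=n)
    )


def random_type_i(rng, panel, n_children=None, p_missing=0.0):
    hap1 = random_haplotype(rng, panel)
    hap2 = random_haplotype(rng, panel)
    if n_children is None:
        n_children = int(rng.integers(1, 4))
    children = [
        Haplotype(random_child(rng, panel, hap1, hap2, p_missing=p_missing))
        for _ in range(n_children)
    ]
    mother = PhasedMother(Haplotype(hap1), Haplotype(hap2))
    return InformativeFamily("typeI", mother, children, {"family_id": "R", "mother_id": "MO"})


def random_type_ii(rng, panel, n_children=None):
    hap1 = random_haplotype(rng, panel)
    hap2 = random_haplotype(rng, panel)
    if n_children is None:
        n_children = int(rng.integers(2, 5))
    children = [
        Haplotype(random_child(rng, panel, hap1, hap2)) for _ in range(n_children)
    ]
    genotype = [tuple(sorted((a, b))) for a, b in zip(hap1, hap2)]
    mother = UnphasedMother(genotype)
    return InformativeFamily("typeII", mother, children, {"family_id": "R", "mother_id": "MO"})


def to_oracle_space(panel, alleles):
    """Map encoded alleles to the oracle's plain representation."""
    out = []
    for i, a in enumerate(alleles):
        if a is None:
            out.append(None)
        elif panel.is_str(i):
            out.append(a)
        else:
            out.append(panel.decode_allele(i, a))
    return tuple(out)
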