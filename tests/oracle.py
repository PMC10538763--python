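"""Independent brute-force reference implementations used only by the tests.

Everything here is written from the model definition with plain Python
loops and no imports from the package, so it can serve as an oracle for the
optimized engines.  Alleles are plain values: numbers for STR markers,
strings for non-STR markers; ``None`` marks a missing allele (factor 1).
"""

from itertools import product

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def oracle_mut_prob(marker_type, a, b, mu):
    if a is None or b is None:
        return 1.0
    if a == b:
        return 1.0 - mu
    if marker_type == "STR":
        return mu if abs(a - b) == 1 else 0.0
    a, b = str(a).upper(), str(b).upper()
    transition = (
        len(a) == 1
        and len(b) == 1
        and ((a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES))
    )
    return 0.9 * mu if transition else 0.1 * mu


def oracle_child_likelihood(child, hap1, hap2, theta, mu, types):
    """Sum over all 2^n inheritance vectors, straight from the definition."""
    n = len(child)
    haps = (hap1, hap2)
    total = 0.0
    for v in product((0, 1), repeat=n):
        term = 1.0
        for i in range(n - 1):
            term *= (1.0 - theta[i]) if v[i] == v[i + 1] else theta[i]
        for i in range(n):
            term *= oracle_mut_prob(types[i], haps[v[i]][i], child[i], mu[i])
        total += term
    return total


def oracle_family_likelihood_type_i(children, hap1, hap2, theta, mu, types):
    out = 1.0
    for child in children:
        out *= oracle_child_likelihood(child, hap1, hap2, theta, mu, types)
    return out


def oracle_family_likelihood_type_ii(children, genotype, theta, mu, types):
    """Enumerate all ordered phasings, deduplicate to unordered, and sum."""
    n = len(genotype)
    total = 0.0
    seen = set()
    for bits in product((0, 1), repeat=n):
        hap1 = tuple(genotype[i][bits[i]] for i in range(n))
        hap2 = tuple(genotype[i][1 - bits[i]] for i in range(n))
        key = tuple(sorted((hap1, hap2)))
        if key in seen:
            continue
        seen.add(key)
        total += oracle_family_likelihood_type_i(children, hap1, hap2, theta, mu, types)
    return total
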