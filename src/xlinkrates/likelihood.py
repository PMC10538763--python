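"""Exact family likelihoods for X-linked recombination/mutation inference.

The probability of observing a child's maternal haplotype ``c`` given the
mother's ordered haplotypes ``(m^1, m^2)`` sums, over every inheritance
vector ``v`` in {1,2}^n, the product of recombination factors
``theta_i + (1 - 2 theta_i) * delta(v_i, v_{i+1})`` for adjacent markers and
per-marker mutation kernels ``p*(m_i^{v_i}, c_i)``.

Two engines compute the same value:

* ``direct``  — literal enumeration of all 2^n inheritance vectors
  (exponential; kept as the simple reference and refused for large n);
* ``dynamic`` — a forward recurrence over the two inheritance states,
  linear in n, with per-marker rescaling so that chromosomes with tens of
  thousands of markers neither underflow nor overflow.

An unphased mother's likelihood additionally sums over her compatible
phasings (anchored at the first heterozygous marker, so each unordered
phasing is counted once), implemented by depth-first branching with shared
partial forward states and early pruning of zero-likelihood branches.

Kernel conventions: STR mutations move by exactly one repeat unit (any other
change has probability zero); non-STR mutations weight transitions
(purine-purine / pyrimidine-pyrimidine single-base changes) 9/10 of the
mutation rate and everything else 1/10.  The STR kernel is used exactly as
defined, without renormalizing its rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .families import InformativeFamily, PhasedMother, UnphasedMother
from .pedigree_io import Haplotype, MarkerPanel, POLY, STR

__all__ = [
    "MAX_DIRECT_MARKERS",
    "RateParams",
    "LikelihoodZeroError",
    "mut_prob_str",
    "mut_prob_poly",
    "is_transition",
    "child_likelihood_direct",
    "child_likelihood_dynamic",
    "child_loglik_dynamic",
    "family_likelihood_typeI",
    "family_loglik_typeI",
    "family_likelihood_typeII",
    "family_loglik_typeII",
    "family_loglik",
    "dataset_negloglik",
]

#: the direct engine enumerates 2^n inheritance vectors and is refused beyond this
MAX_DIRECT_MARKERS = 20

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class LikelihoodZeroError(ValueError):
    """Data incompatible with the single-step mutation model (likelihood 0)."""

    def __init__(self, provenances):
        self.provenances = list(provenances)
        ids = ", ".join(
            f"{p.get('family_id', '?')}:{p.get('mother_id', '?')}"
            for p in self.provenances
        )
        super().__init__(
            f"zero likelihood at interior parameters for families [{ids}]; the "
            "genotypes are incompatible with single-step mutations"
        )


@dataclass
class RateParams:
    """Recombination rates ``theta`` (length n-1) and mutation rates ``mu`` (length n).

    Estimation constrains rates to (0, 0.5]; the likelihood itself also
    accepts the boundary value 0 so degenerate cases can be evaluated.
    """

    theta: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if len(self.mu) != len(self.theta) + 1:
            raise ValueError(
                f"mu has length {len(self.mu)}, expected {len(self.theta) + 1} "
                "(one more than theta)"
            )
        for name, vec in (("theta", self.theta), ("mu", self.mu)):
            if np.any(vec < 0) or np.any(vec > 0.5):
                raise ValueError(f"{name} entries must lie in [0, 0.5]")

    @property
    def n_markers(self) -> int:
        return len(self.mu)

    @classmethod
    def filled(cls, n_markers: int, theta: float = 0.1, mu: float = 0.001) -> "RateParams":
        return cls(np.full(max(n_markers - 1, 0), theta), np.full(n_markers, mu))


# ---------------------------------------------------------------------------
# mutation kernels
# ---------------------------------------------------------------------------

def mut_prob_str(a, b, mu_i: float) -> float:
    """Single-step STR kernel: 1-mu on match, mu on a one-repeat step, else 0."""
    if a == b:
        return 1.0 - mu_i
    return mu_i if abs(a - b) == 1 else 0.0


def is_transition(a: str, b: str) -> bool:
    """True when ``a -> b`` is a purine-purine or pyrimidine-pyrimidine SNP."""
    a, b = a.upper(), b.upper()
    if a == b or len(a) != 1 or len(b) != 1:
        return False
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def mut_prob_poly(a: str, b: str, mu_i: float) -> float:
    """Non-STR kernel on original allele strings: 9:1 transition weighting."""
    if a == b:
        return 1.0 - mu_i
    return 0.9 * mu_i if is_transition(a, b) else 0.1 * mu_i


def _weight(panel: MarkerPanel, i: int, mother_allele, child_allele) -> tuple:
    """Coefficients (w0, w1) with p = w0*(1-mu_i) + w1*mu_i for one marker.

    A missing child (or mother) allele contributes factor 1: (w0, w1) = (1, 1).
    """
    if child_allele is None or mother_allele is None:
        return (1.0, 1.0)
    if mother_allele == child_allele:
        return (1.0, 0.0)
    if panel.is_str(i):
        return (0.0, 1.0) if abs(mother_allele - child_allele) == 1 else (0.0, 0.0)
    sa = panel.decode_allele(i, mother_allele)
    sb = panel.decode_allele(i, child_allele)
    return (0.0, 0.9) if is_transition(sa, sb) else (0.0, 0.1)


def _alleles(x) -> tuple:
    return tuple(x.alleles) if isinstance(x, Haplotype) else tuple(x)


def _child_weights(child, mother: PhasedMother, panel: MarkerPanel) -> tuple:
    """(W0, W1) arrays of shape (2, n): rows are the two maternal haplotypes."""
    c = _alleles(child)
    n = panel.n_markers
    if len(c) != n or len(mother.hap1) != n:
        raise ValueError(
            f"length mismatch: child has {len(c)} markers, mother "
            f"{len(mother.hap1)}, panel {n}"
        )
    w0 = np.empty((2, n))
    w1 = np.empty((2, n))
    for s, hap in enumerate((mother.hap1, mother.hap2)):
        for i in range(n):
            w0[s, i], w1[s, i] = _weight(panel, i, hap[i], c[i])
    return w0, w1


def _mutation_probs(child, mother, panel, mu) -> np.ndarray:
    w0, w1 = _child_weights(child, mother, panel)
    return w0 * (1.0 - mu) + w1 * mu


# ---------------------------------------------------------------------------
# per-child engines
# ---------------------------------------------------------------------------

def child_likelihood_direct(child, mother: PhasedMother, params: RateParams,
                            panel: MarkerPanel) -> float:
    """Literal sum over all 2^n inheritance vectors (exponential reference)."""
    n = panel.n_markers
    if n > MAX_DIRECT_MARKERS:
        raise ValueError(
            f"direct engine refused for n={n} markers (limit {MAX_DIRECT_MARKERS}); "
            "use the dynamic engine"
        )
    theta = params.theta
    probs = _mutation_probs(child, mother, panel, params.mu)
    total = 0.0
    for v in product((0, 1), repeat=n):
        term = 1.0
        for i in range(n - 1):
            term *= (1.0 - theta[i]) if v[i] == v[i + 1] else theta[i]
        for i in range(n):
            term *= probs[v[i], i]
        total += term
    return total


def child_loglik_dynamic(child, mother: PhasedMother, params: RateParams,
                         panel: MarkerPanel) -> float:
    """Log of the child likelihood via the linear-time forward recurrence.

    Returns ``-inf`` when the likelihood is exactly zero.
    """
    probs = _mutation_probs(child, mother, panel, params.mu)
    theta = params.theta
    f = probs[:, 0].copy()
    log_scale = 0.0
    for i in range(panel.n_markers - 1):
        s = f[0] + f[1]
        if s == 0.0:
            return -np.inf
        log_scale += np.log(s)
        f /= s
        t = theta[i]
        f = probs[:, i + 1] * ((1.0 - t) * f + t * f[::-1])
    s = f[0] + f[1]
    if s == 0.0:
        return -np.inf
    return log_scale + np.log(s)


def child_likelihood_dynamic(child, mother: PhasedMother, params: RateParams,
                             panel: MarkerPanel) -> float:
    """Same value as :func:`child_likelihood_direct`, computed in linear time."""
    return float(np.exp(child_loglik_dynamic(child, mother, params, panel)))


# ---------------------------------------------------------------------------
# family likelihoods
# ---------------------------------------------------------------------------

def family_loglik_typeI(fam: InformativeFamily, params: RateParams,
                        panel: MarkerPanel, engine: str = "dynamic") -> float:
    """Children are independent meioses: sum of per-child log-likelihoods."""
    if not fam.children:
        raise ValueError("type I family with no children")
    if engine == "dynamic":
        return float(
            sum(child_loglik_dynamic(c, fam.mother, params, panel) for c in fam.children)
        )
    if engine == "direct":
        total = 0.0
        for c in fam.children:
            value = child_likelihood_direct(c, fam.mother, params, panel)
            if value == 0.0:
                return -np.inf
            total += np.log(value)
        return float(total)
    raise ValueError(f"unknown engine {engine!r}")


def family_likelihood_typeI(fam: InformativeFamily, params: RateParams,
                            panel: MarkerPanel, engine: str = "dynamic") -> float:
    return float(np.exp(family_loglik_typeI(fam, params, panel, engine)))


def enumerate_phasings(mother: UnphasedMother) -> list:
    """All compatible phasings, anchored at the first heterozygous marker.

    The anchor fixes hap1 to the first listed allele there, so each unordered
    phasing appears exactly once: 2^(h-1) phasings for h heterozygous markers
    (one when h = 0).
    """
    het = [i for i, is_het in enumerate(mother.het_mask) if is_het]
    free = het[1:]
    out = []
    for bits in product((0, 1), repeat=len(free)):
        swap = dict(zip(free, bits))
        hap1, hap2 = [], []
        for i, pair in enumerate(mother.genotype):
            if pair is None:
                hap1.append(None)
                hap2.append(None)
                continue
            j = swap.get(i, 0)
            hap1.append(pair[j])
            hap2.append(pair[1 - j])
        out.append(PhasedMother(Haplotype(tuple(hap1)), Haplotype(tuple(hap2)),
                                source="enumerated"))
    return out


def _typeII_pm(fam: InformativeFamily, panel: MarkerPanel, mu) -> np.ndarray:
    """probs[i, j, c]: P(child c's allele at marker i | mother passed pair[j])."""
    n = panel.n_markers
    children = [_alleles(c) for c in fam.children]
    n_children = len(children)
    probs = np.empty((n, 2, n_children))
    for i, pair in enumerate(fam.mother.genotype):
        alleles = (None, None) if pair is None else pair
        for j in (0, 1):
            for c, child in enumerate(children):
                w0, w1 = _weight(panel, i, alleles[j], child[i])
                probs[i, j, c] = w0 * (1.0 - mu[i]) + w1 * mu[i]
    return probs


def family_loglik_typeII(fam: InformativeFamily, params: RateParams,
                         panel: MarkerPanel) -> float:
    """Sum over maternal phasings by depth-first branching with pruning.

    Partial forward states up to the current marker are shared between the
    two branches at each heterozygous marker; a branch whose partial
    likelihood is zero for any child is discarded immediately.  The result is
    identical to exhaustively enumerating the phasings.
    """
    if len(fam.children) < 2:
        raise ValueError("type II family needs at least 2 children")
    n = panel.n_markers
    theta = params.theta
    probs = _typeII_pm(fam, panel, params.mu)
    het = list(fam.mother.het_mask)
    first_het = het.index(True) if any(het) else None
    branch_logs: list = []

    def recurse(i: int, forward: np.ndarray, acc: float) -> None:
        # forward: (n_children, 2) partial states; prune on any zero child
        sums = forward.sum(axis=1)
        if np.any(sums == 0.0):
            return
        acc += float(np.log(sums).sum())
        forward = forward / sums[:, None]
        if i == n:
            branch_logs.append(acc)
            return
        t = theta[i - 1]
        base = (1.0 - t) * forward + t * forward[:, ::-1]
        choices = (0, 1) if het[i] and i != first_het else (0,)
        for j in choices:
            step = np.stack((probs[i, j], probs[i, 1 - j]), axis=1)
            recurse(i + 1, base * step, acc)

    recurse(1, np.stack((probs[0, 0], probs[0, 1]), axis=1), 0.0)
    if not branch_logs:
        return -np.inf
    return float(logsumexp(branch_logs))


def _family_loglik_typeII_direct(fam: InformativeFamily, params: RateParams,
                                 panel: MarkerPanel) -> float:
    """Exhaustive phasing enumeration on top of the direct child engine."""
    total = 0.0
    for phased in enumerate_phasings(fam.mother):
        term = 1.0
        for c in fam.children:
            term *= child_likelihood_direct(c, phased, params, panel)
        total += term
    return -np.inf if total == 0.0 else float(np.log(total))


def family_likelihood_typeII(fam: InformativeFamily, params: RateParams,
                             panel: MarkerPanel, engine: str = "dynamic") -> float:
    if engine == "dynamic":
        return float(np.exp(family_loglik_typeII(fam, params, panel)))
    if engine == "direct":
        return float(np.exp(_family_loglik_typeII_direct(fam, params, panel)))
    raise ValueError(f"unknown engine {engine!r}")


def family_loglik(fam: InformativeFamily, params: RateParams, panel: MarkerPanel,
                  engine: str = "dynamic") -> float:
    if fam.kind == "typeI":
        return family_loglik_typeI(fam, params, panel, engine)
    if engine == "direct":
        return _family_loglik_typeII_direct(fam, params, panel)
    return family_loglik_typeII(fam, params, panel)


def dataset_negloglik(families, params: RateParams, panel: MarkerPanel,
                      engine: str = "dynamic") -> float:
    """Negative log of the product of family likelihoods.

    A family with likelihood zero signals data incompatible with the
    single-step mutation model and raises :class:`LikelihoodZeroError`
    naming the offending families.
    """
    if not families:
        raise ValueError("empty family list")
    total = 0.0
    dead = []
    for fam in families:
        value = family_loglik(fam, params, panel, engine)
        if value == -np.inf:
            dead.append(fam.provenance)
        else:
            total += value
    if dead:
        raise LikelihoodZeroError(dead)
    return -total


# ---------------------------------------------------------------------------
# batched evaluators used by the optimizer (same math, vectorized)
# ---------------------------------------------------------------------------

class TypeIBatch:
    """All children of all type I families stacked for fast re-evaluation.

    The mutation-weight structure is parameter independent, so each
    likelihood evaluation reduces to one weight combination and n-1
    vectorized forward steps over every child at once.
    """

    def __init__(self, fams: Sequence[InformativeFamily], panel: MarkerPanel):
        w0_rows, w1_rows, prov = [], [], []
        for fam in fams:
            for child in fam.children:
                w0, w1 = _child_weights(child, fam.mother, panel)
                w0_rows.append(w0)
                w1_rows.append(w1)
                prov.append(fam.provenance)
        self.n_children = len(w0_rows)
        self.provenances = prov
        if self.n_children:
            self._w0 = np.stack(w0_rows)              # (C, 2, n)
            self._dw = np.stack(w1_rows) - self._w0   # (C, 2, n)

    def negloglik(self, theta: np.ndarray, mu: np.ndarray) -> float:
        if not self.n_children:
            return 0.0
        probs = self._w0 + self._dw * mu              # broadcast over markers
        f = probs[:, :, 0].copy()
        acc = 0.0
        n = probs.shape[2]
        for i in range(n - 1):
            s = f.sum(axis=1)
            if np.any(s == 0.0):
                raise LikelihoodZeroError(
                    [self.provenances[c] for c in np.nonzero(s == 0.0)[0]]
                )
            acc += float(np.log(s).sum())
            f /= s[:, None]
            t = theta[i]
            f = probs[:, :, i + 1] * ((1.0 - t) * f + t * f[:, ::-1])
        s = f.sum(axis=1)
        if np.any(s == 0.0):
            raise LikelihoodZeroError(
                [self.provenances[c] for c in np.nonzero(s == 0.0)[0]]
            )
        acc += float(np.log(s).sum())
        return -acc


class TypeIIEvaluator:
    """One type II family with its phasings enumerated as a dense batch.

    For h heterozygous markers the 2^(h-1) anchored phasings become the
    leading axis of a weight tensor; when that would be too large the
    evaluator falls back to the branch-and-prune recursion.
    """

    def __init__(self, fam: InformativeFamily, panel: MarkerPanel,
                 max_dense_phasings: int = 1024):
        self.fam = fam
        self.panel = panel
        self.provenance = fam.provenance
        het = [i for i, is_het in enumerate(fam.mother.het_mask) if is_het]
        n_free = max(len(het) - 1, 0)
        self._dense = 2 ** n_free <= max_dense_phasings
        if not self._dense:
            return
        n = panel.n_markers
        n_children = len(fam.children)
        n_ph = 2 ** n_free
        assign = np.zeros((n_ph, n), dtype=np.intp)
        for k, i in enumerate(het[1:]):
            assign[:, i] = (np.arange(n_ph) >> k) & 1
        w0m = np.empty((n, 2, n_children))
        w1m = np.empty((n, 2, n_children))
        children = [_alleles(c) for c in fam.children]
        for i, pair in enumerate(fam.mother.genotype):
            alleles = (None, None) if pair is None else pair
            for j in (0, 1):
                for c, child in enumerate(children):
                    w0m[i, j, c], w1m[i, j, c] = _weight(
                        panel, i, alleles[j], child[i]
                    )
        w0 = np.empty((n_ph, n_children, 2, n))
        w1 = np.empty((n_ph, n_children, 2, n))
        for i in range(n):
            w0[:, :, 0, i] = w0m[i, assign[:, i]]
            w0[:, :, 1, i] = w0m[i, 1 - assign[:, i]]
            w1[:, :, 0, i] = w1m[i, assign[:, i]]
            w1[:, :, 1, i] = w1m[i, 1 - assign[:, i]]
        self._w0 = w0
        self._dw = w1 - w0

    def loglik(self, params: RateParams) -> float:
        if not self._dense:
            return family_loglik_typeII(self.fam, params, self.panel)
        probs = self._w0 + self._dw * params.mu
        theta = params.theta
        f = probs[..., 0].copy()
        n = probs.shape[3]
        for i in range(n - 1):
            t = theta[i]
            f = probs[..., i + 1] * ((1.0 - t) * f + t * f[..., ::-1])
        per_child = f.sum(axis=2)                     # (n_ph, n_children)
        with np.errstate(divide="ignore"):
            branch = np.log(per_child).sum(axis=1)    # -inf where pruned
        if np.all(np.isneginf(branch)):
            return -np.inf
        return float(logsumexp(branch))
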