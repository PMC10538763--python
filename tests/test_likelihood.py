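import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    make_mixed_panel,
    make_str_panel,
    random_rates,
    random_type_i,
    random_type_ii,
    to_oracle_space,
)
from oracle import (
    oracle_child_likelihood,
    oracle_family_likelihood_type_ii,
)
from xlinkrates.families import InformativeFamily, PhasedMother, UnphasedMother
from xlinkrates.likelihood import (
    MAX_DIRECT_MARKERS,
    LikelihoodZeroError,
    RateParams,
    TypeIBatch,
    TypeIIEvaluator,
    child_likelihood_direct,
    child_likelihood_dynamic,
    child_loglik_dynamic,
    dataset_negloglik,
    enumerate_phasings,
    family_likelihood_typeI,
    family_likelihood_typeII,
    family_loglik_typeI,
    family_loglik_typeII,
    mut_prob_poly,
    mut_prob_str,
)
from xlinkrates.pedigree_io import Haplotype


def phased(hap1, hap2):
    return PhasedMother(Haplotype(hap1), Haplotype(hap2))


def type_i(hap1, hap2, children):
    return InformativeFamily(
        "typeI", phased(hap1, hap2), [Haplotype(c) for c in children],
        {"family_id": "T", "mother_id": "MO"},
    )


def type_ii(genotype, children):
    return InformativeFamily(
        "typeII", UnphasedMother([tuple(sorted(p)) for p in genotype]),
        [Haplotype(c) for c in children], {"family_id": "T", "mother_id": "MO"},
    )


class TestRateParams:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            RateParams([0.1], [0.1])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            RateParams([0.6], [0.1, 0.1])
        with pytest.raises(ValueError):
            RateParams([0.1], [-0.1, 0.1])

    def test_boundary_zero_accepted(self):
        RateParams([0.0], [0.0, 0.0])


class TestStrKernel:
    def test_match(self):
        assert mut_prob_str(10, 10, 0.01) == pytest.approx(0.99)

    def test_single_step(self):
        assert mut_prob_str(10, 11, 0.01) == pytest.approx(0.01)
        assert mut_prob_str(11, 10, 0.01) == pytest.approx(0.01)

    def test_non_unit_step_is_zero(self):
        assert mut_prob_str(10, 12.5, 0.01) == 0.0
        assert mut_prob_str(10, 12, 0.01) == 0.0

    def test_fractional_repeat_step(self):
        from fractions import Fraction
        assert mut_prob_str(Fraction("9.3"), Fraction("10.3"), 0.02) == pytest.approx(0.02)
        assert mut_prob_str(Fraction("9.3"), Fraction(10), 0.02) == 0.0


class TestPolyKernel:
    def test_transition(self):
        assert mut_prob_poly("A", "G", 0.001) == pytest.approx(0.0009)
        assert mut_prob_poly("C", "T", 0.001) == pytest.approx(0.0009)

    def test_transversion(self):
        assert mut_prob_poly("A", "C", 0.001) == pytest.approx(0.0001)

    def test_match(self):
        assert mut_prob_poly("A", "A", 0.001) == pytest.approx(0.999)

    def test_indel_like_strings_are_otherwise(self):
        assert mut_prob_poly("A", "AT", 0.001) == pytest.approx(0.0001)


class TestChildDirect:
    def test_single_marker(self):
        panel = make_str_panel(1)
        value = child_likelihood_direct(
            Haplotype((10,)), phased((10,), (12,)), RateParams([], [0.01]), panel
        )
        assert value == pytest.approx(0.99, abs=1e-15)

    def test_two_markers_single_vector(self, panel2):
        value = child_likelihood_direct(
            Haplotype((10, 20)), phased((10, 20), (12, 22)),
            RateParams([0.1], [0.0, 0.0]), panel2,
        )
        assert value == pytest.approx(0.9, abs=1e-15)

    def test_two_markers_half_theta(self, panel2):
        value = child_likelihood_direct(
            Haplotype((10, 22)), phased((10, 20), (12, 22)),
            RateParams([0.5], [0.0, 0.0]), panel2,
        )
        # hand enumeration of the 4 inheritance vectors: only (1,2) survives
        assert value == pytest.approx(0.5, abs=1e-15)

    def test_refused_beyond_limit(self):
        n = MAX_DIRECT_MARKERS + 10
        panel = make_str_panel(n)
        fam = type_i((10,) * n, (12,) * n, [(10,) * n])
        with pytest.raises(ValueError, match="refused"):
            child_likelihood_direct(
                fam.children[0], fam.mother, RateParams.filled(n), panel
            )

    def test_length_mismatch(self, panel2):
        with pytest.raises(ValueError, match="mismatch"):
            child_likelihood_direct(
                Haplotype((10,)), phased((10, 20), (12, 22)),
                RateParams([0.1], [0.0, 0.0]), panel2,
            )

    def test_missing_child_marker_contributes_factor_one(self, panel2):
        params = RateParams([0.2], [0.01, 0.01])
        mother = phased((10, 20), (12, 22))
        got = child_likelihood_direct(Haplotype((10, None)), mother, params, panel2)
        want = oracle_child_likelihood(
            (10, None), (10, 20), (12, 22), [0.2], [0.01, 0.01], ["STR", "STR"]
        )
        assert got == pytest.approx(want, rel=1e-14)


class TestDynamicEqualsDirect:
    def test_examples(self, panel2):
        cases = [
            (make_str_panel(1), (10,), (10,), (12,), RateParams([], [0.01])),
            (panel2, (10, 20), (10, 20), (12, 22), RateParams([0.1], [0.0, 0.0])),
            (panel2, (10, 22), (10, 20), (12, 22), RateParams([0.5], [0.0, 0.0])),
        ]
        for panel, c, m1, m2, params in cases:
            direct = child_likelihood_direct(Haplotype(c), phased(m1, m2), params, panel)
            dynamic = child_likelihood_dynamic(Haplotype(c), phased(m1, m2), params, panel)
            assert dynamic == pytest.approx(direct, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_random_instances_match_direct_and_oracle(self, rng, n):
        panel = make_str_panel(n)
        for _ in range(12):
            fam = random_type_i(rng, panel, n_children=1, p_missing=0.1)
            params = random_rates(rng, n)
            child = fam.children[0]
            direct = child_likelihood_direct(child, fam.mother, params, panel)
            dynamic = child_likelihood_dynamic(child, fam.mother, params, panel)
            ora = oracle_child_likelihood(
                child.alleles, fam.mother.hap1.alleles, fam.mother.hap2.alleles,
                params.theta, params.mu, panel.types,
            )
            assert dynamic == pytest.approx(direct, rel=1e-12, abs=1e-300)
            assert direct == pytest.approx(ora, rel=1e-12, abs=1e-300)

    def test_mixed_panel_against_oracle(self, rng):
        panel = make_mixed_panel(["STR", "POLY", "STR", "POLY", "POLY"])
        for _ in range(25):
            fam = random_type_i(rng, panel, n_children=1)
            params = random_rates(rng, 5)
            child = fam.children[0]
            direct = child_likelihood_direct(child, fam.mother, params, panel)
            dynamic = child_likelihood_dynamic(child, fam.mother, params, panel)
            ora = oracle_child_likelihood(
                to_oracle_space(panel, child.alleles),
                to_oracle_space(panel, fam.mother.hap1.alleles),
                to_oracle_space(panel, fam.mother.hap2.alleles),
                params.theta, params.mu, panel.types,
            )
            assert dynamic == pytest.approx(direct, rel=1e-12, abs=1e-300)
            assert direct == pytest.approx(ora, rel=1e-12, abs=1e-300)

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(1, 6),
        theta=st.floats(0.0, 0.5),
        mu=st.floats(0.0, 0.5),
        seed=st.integers(0, 2**31),
    )
    def test_property_equivalence(self, n, theta, mu, seed):
        local = np.random.default_rng(seed)
        panel = make_str_panel(n)
        fam = random_type_i(local, panel, n_children=1)
        params = RateParams([theta] * (n - 1), [mu] * n)
        child = fam.children[0]
        direct = child_likelihood_direct(child, fam.mother, params, panel)
        dynamic = child_likelihood_dynamic(child, fam.mother, params, panel)
        assert dynamic == pytest.approx(direct, rel=1e-12, abs=1e-300)

    def test_ten_thousand_markers_log_space(self, rng):
        n = 10_000
        alleles1 = rng.integers(8, 21, size=n)
        alleles2 = rng.integers(8, 21, size=n)
        mother = phased(tuple(int(a) for a in alleles1), tuple(int(a) for a in alleles2))
        child = Haplotype(mother.hap1.alleles)
        params = RateParams.filled(n, theta=0.1, mu=0.001)
        panel = make_str_panel(n)
        value = child_loglik_dynamic(child, mother, params, panel)
        assert math.isfinite(value)
        assert value < 0


class TestClosedForms:
    def test_half_theta_factorizes(self, rng):
        n = 7
        panel = make_str_panel(n)
        fam = random_type_i(rng, panel, n_children=1)
        mu = rng.uniform(0.001, 0.4, size=n)
        params = RateParams([0.5] * (n - 1), mu)
        child = fam.children[0]
        want = 0.5 ** (n - 1)
        for i in range(n):
            want *= mut_prob_str(fam.mother.hap1[i], child[i], mu[i]) + mut_prob_str(
                fam.mother.hap2[i], child[i], mu[i]
            )
        got = child_likelihood_dynamic(child, fam.mother, params, panel)
        assert got == pytest.approx(want, rel=1e-12)

    def test_no_mutation_chain(self):
        n = 6
        panel = make_str_panel(n)
        hap1 = tuple(range(10, 10 + n))
        hap2 = tuple(range(30, 30 + n))  # heterozygous everywhere
        theta = [0.05, 0.1, 0.2, 0.3, 0.4]
        params = RateParams(theta, [0.0] * n)
        value = child_likelihood_dynamic(Haplotype(hap1), phased(hap1, hap2), params, panel)
        assert value == pytest.approx(np.prod(1 - np.array(theta)), rel=1e-12)

    def test_monotone_decreasing_in_each_theta(self):
        n = 4
        panel = make_str_panel(n)
        hap1 = (10, 11, 12, 13)
        hap2 = (20, 21, 22, 23)
        child = Haplotype(hap1)
        mother = phased(hap1, hap2)
        for i in range(n - 1):
            values = []
            for t in (0.1, 0.2, 0.3, 0.4, 0.5):
                theta = [0.25] * (n - 1)
                theta[i] = t
                values.append(
                    child_likelihood_dynamic(child, mother, RateParams(theta, [0.0] * n), panel)
                )
            assert all(a > b for a, b in zip(values, values[1:]))


class TestTypeI:
    def test_product_of_one(self, panel2):
        fam = type_i((10, 20), (12, 22), [(10, 20)])
        params = RateParams([0.1], [0.01, 0.01])
        one = family_likelihood_typeI(fam, params, panel2)
        single = child_likelihood_dynamic(fam.children[0], fam.mother, params, panel2)
        assert one == pytest.approx(single, rel=1e-12)

    def test_two_identical_children_square(self, panel2):
        fam1 = type_i((10, 20), (12, 22), [(10, 20)])
        fam2 = type_i((10, 20), (12, 22), [(10, 20), (10, 20)])
        params = RateParams([0.1], [0.01, 0.01])
        assert family_likelihood_typeI(fam2, params, panel2) == pytest.approx(
            family_likelihood_typeI(fam1, params, panel2) ** 2, rel=1e-12
        )

    def test_haplotype_swap_invariance(self, rng):
        panel = make_str_panel(5)
        for _ in range(20):
            fam = random_type_i(rng, panel)
            params = random_rates(rng, 5)
            swapped = InformativeFamily(
                "typeI", PhasedMother(fam.mother.hap2, fam.mother.hap1),
                fam.children, fam.provenance,
            )
            a = family_loglik_typeI(fam, params, panel)
            b = family_loglik_typeI(swapped, params, panel)
            assert b == pytest.approx(a, rel=1e-12) or (a == -np.inf and b == -np.inf)

    def test_empty_children_error(self, panel2):
        fam = type_i((10, 20), (12, 22), [(10, 20)])
        fam.children = []
        with pytest.raises(ValueError, match="children"):
            family_loglik_typeI(fam, RateParams([0.1], [0.0, 0.0]), panel2)

    def test_batch_matches_per_family(self, rng):
        panel = make_str_panel(6)
        fams = [random_type_i(rng, panel) for _ in range(10)]
        params = random_rates(rng, 6)
        batch = TypeIBatch(fams, panel)
        want = -sum(family_loglik_typeI(f, params, panel) for f in fams)
        assert batch.negloglik(params.theta, params.mu) == pytest.approx(want, rel=1e-10)


class TestTypeII:
    def test_two_phasings_hand_value(self, panel2):
        fam = type_ii([(10, 12), (20, 22)], [(10, 20), (12, 22)])
        params = RateParams([0.1], [0.0, 0.0])
        # phasing 1: both sons non-recombinant (0.9 * 0.9); phasing 2: both
        # recombinant (0.1 * 0.1)
        assert family_likelihood_typeII(fam, params, panel2) == pytest.approx(0.82, rel=1e-12)

    def test_homozygous_mother_single_phasing(self, panel2):
        fam = type_ii([(10, 10), (20, 20)], [(10, 20), (10, 20)])
        params = RateParams([0.1], [0.01, 0.01])
        assert fam.mother.n_phasings == 1
        as_type_i = type_i((10, 20), (10, 20), [(10, 20), (10, 20)])
        assert family_likelihood_typeII(fam, params, panel2) == pytest.approx(
            family_likelihood_typeI(as_type_i, params, panel2), rel=1e-12
        )

    def test_phasing_count(self):
        fam = type_ii([(10, 12), (20, 20), (30, 32), (40, 42)],
                      [(10, 20, 30, 40), (12, 20, 32, 42)])
        assert fam.mother.n_phasings == 4
        assert len(enumerate_phasings(fam.mother)) == 4

    @pytest.mark.parametrize("n", range(1, 9))
    def test_pruned_equals_exhaustive_oracle(self, rng, n):
        panel = make_str_panel(n)
        for _ in range(8):
            fam = random_type_ii(rng, panel)
            params = random_rates(rng, n)
            got = family_likelihood_typeII(fam, params, panel)
            ora = oracle_family_likelihood_type_ii(
                [c.alleles for c in fam.children], fam.mother.genotype,
                params.theta, params.mu, panel.types,
            )
            assert got == pytest.approx(ora, rel=1e-12, abs=1e-300)

    def test_direct_engine_matches_dynamic(self, rng):
        panel = make_str_panel(5)
        for _ in range(10):
            fam = random_type_ii(rng, panel)
            params = random_rates(rng, 5)
            a = family_likelihood_typeII(fam, params, panel, engine="direct")
            b = family_likelihood_typeII(fam, params, panel, engine="dynamic")
            assert b == pytest.approx(a, rel=1e-12, abs=1e-300)

    def test_dense_evaluator_matches_recursion(self, rng):
        panel = make_str_panel(6)
        for _ in range(10):
            fam = random_type_ii(rng, panel)
            params = random_rates(rng, 6)
            ev = TypeIIEvaluator(fam, panel)
            want = family_loglik_typeII(fam, params, panel)
            got = ev.loglik(params)
            if want == -np.inf:
                assert got == -np.inf
            else:
                assert got == pytest.approx(want, rel=1e-10)

    def test_fallback_evaluator_used_when_too_many_phasings(self, rng):
        panel = make_str_panel(6)
        fam = random_type_ii(rng, panel)
        ev = TypeIIEvaluator(fam, panel, max_dense_phasings=1)
        params = random_rates(rng, 6)
        assert ev.loglik(params) == pytest.approx(
            family_loglik_typeII(fam, params, panel), rel=1e-12
        )

    def test_too_few_children_error(self, panel2):
        fam = type_ii([(10, 12), (20, 22)], [(10, 20), (12, 22)])
        fam.children = fam.children[:1]
        with pytest.raises(ValueError, match="2 children"):
            family_loglik_typeII(fam, RateParams([0.1], [0.0, 0.0]), panel2)


class TestDatasetNegloglik:
    def test_single_family_value(self, panel2):
        fam = type_i((10, 20), (12, 22), [(10, 20)])
        params = RateParams([0.1], [0.0, 0.0])
        assert dataset_negloglik([fam], params, panel2) == pytest.approx(
            -math.log(0.9), rel=1e-12
        )

    def test_duplicated_families_double(self, panel2):
        fam = type_i((10, 20), (12, 22), [(10, 20), (12, 20)])
        params = RateParams([0.1], [0.01, 0.01])
        one = dataset_negloglik([fam], params, panel2)
        two = dataset_negloglik([fam, fam], params, panel2)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_engines_agree(self, rng):
        panel = make_str_panel(5)
        fams = [random_type_i(rng, panel) for _ in range(5)]
        fams += [random_type_ii(rng, panel) for _ in range(5)]
        params = random_rates(rng, 5)
        a = dataset_negloglik(fams, params, panel, engine="direct")
        b = dataset_negloglik(fams, params, panel, engine="dynamic")
        assert b == pytest.approx(a, abs=1e-10)

    def test_zero_likelihood_reports_provenance(self, panel2):
        # child allele 2 repeats away from both maternal alleles: impossible
        # under single-step mutation
        fam = type_i((10, 20), (12, 22), [(16, 20)])
        fam.provenance = {"family_id": "BAD", "mother_id": "MO"}
        params = RateParams([0.1], [0.01, 0.01])
        with pytest.raises(LikelihoodZeroError, match="BAD"):
            dataset_negloglik([fam], params, panel2)

    def test_empty_list_error(self, panel2):
        with pytest.raises(ValueError, match="empty"):
            dataset_negloglik([], RateParams([0.1], [0.0, 0.0]), panel2)
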