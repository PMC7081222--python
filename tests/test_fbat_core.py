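"""Unit and property tests for the conditional-distribution machinery and
the score tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import oracle_distribution, oracle_moments, random_theta
from fbatscan.fbat_core import (
    Coding,
    ConditioningLevel,
    MendelianImpossibilityError,
    code_traits,
    compatible_matings,
    conditional_distribution,
    family_contribution,
    fbat_gee_test,
    fbat_z_test,
    offspring_probs,
)


class TestCompatibleMatings:
    def test_opposite_homozygote_sibs_force_het_cross(self):
        assert compatible_matings(None, None, [0, 2]) == frozenset({(1, 1)})

    def test_observed_hom_ref_parent_with_het_offspring(self):
        assert compatible_matings(0, None, [1]) == frozenset({(0, 1), (0, 2)})

    def test_hom_alt_parent_with_hom_ref_offspring_impossible(self):
        assert compatible_matings(2, None, [0]) == frozenset()

    def test_all_three_offspring_genotypes_force_double_het(self):
        assert compatible_matings(None, None, [0, 1, 2]) == frozenset({(1, 1)})


class TestConditionalDistribution:
    def test_het_cross_single_offspring_mendelian_table(self):
        cd = conditional_distribution(1, 1, [1])
        assert cd.level is ConditioningLevel.PARENTAL
        probs = dict(cd.configurations)
        assert probs[(0,)] == pytest.approx(0.25)
        assert probs[(1,)] == pytest.approx(0.5)
        assert probs[(2,)] == pytest.approx(0.25)
        assert cd.expected[0] == pytest.approx(1.0)
        assert cd.covariance[0, 0] == pytest.approx(0.5)

    def test_homalt_by_het_single_offspring(self):
        cd = conditional_distribution(2, 1, [2])
        assert cd.expected[0] == pytest.approx(1.5)
        assert cd.covariance[0, 0] == pytest.approx(0.25)

    def test_two_sib_distinct_set_example(self):
        # no parents, sibs (2, 1): both het x het and het x hom-alt are
        # compatible and induce the same law on {(2,1), (1,2)}
        cd = conditional_distribution(None, None, [2, 1])
        assert cd.level is ConditioningLevel.DISTINCT_SET
        probs = dict(cd.configurations)
        assert probs == {(1, 2): pytest.approx(0.5), (2, 1): pytest.approx(0.5)}
        np.testing.assert_allclose(cd.expected, [1.5, 1.5])
        np.testing.assert_allclose(
            cd.covariance, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-15
        )

    def test_identical_offspring_without_parents_degenerate(self):
        cd = conditional_distribution(None, None, [1, 1, 1])
        assert cd.level is ConditioningLevel.DEGENERATE
        assert cd.is_degenerate
        np.testing.assert_array_equal(cd.covariance, 0.0)

    def test_identified_mating_conditions_on_identification(self):
        # sibs (2, 1, 0) identify het x het, but conditioning keeps only
        # configurations that themselves identify it (contain both
        # homozygotes), not the full i.i.d. law
        cd = conditional_distribution(None, None, [2, 1, 0])
        assert cd.level is ConditioningLevel.FORCED_MATING
        for cfg, _ in cd.configurations:
            assert {0, 2} <= set(cfg)
        assert abs(sum(p for _, p in cd.configurations) - 1.0) < 1e-12

    def test_mendelian_impossibility_raises(self):
        with pytest.raises(MendelianImpossibilityError):
            conditional_distribution(2, None, [0])

    def test_probabilities_and_moments_are_consistent(self):
        cd = conditional_distribution(None, 1, [0, 1, 2])
        total = sum(p for _, p in cd.configurations)
        assert abs(total - 1.0) < 1e-12
        e = sum(p * np.asarray(c, float) for c, p in cd.configurations)
        np.testing.assert_allclose(e, cd.expected, atol=1e-12)


def _all_parent_patterns():
    yield (None, None)
    for g in (0, 1, 2):
        yield (g, None)
        yield (None, g)
    for f, m in itertools.product((0, 1, 2), repeat=2):
        yield (f, m)


@pytest.mark.parametrize("parents", list(_all_parent_patterns()))
def test_oracle_equivalence_small_sibships(parents):
    """Implementation moments match the independent brute-force
    conditioning oracle, and the conditional law is free of the
    parental-genotype nuisance, for every configuration up to 3 sibs."""
    rng = np.random.default_rng(11)
    thetas = [random_theta(rng) for _ in range(3)]
    father, mother = parents
    for k in (1, 2, 3):
        for cfg in itertools.product((0, 1, 2), repeat=k):
            try:
                cd = conditional_distribution(father, mother, cfg)
            except MendelianImpossibilityError:
                with pytest.raises(ValueError):
                    oracle_distribution(father, mother, cfg, thetas[0])
                continue
            dists = [oracle_distribution(father, mother, cfg, t) for t in thetas]
            for other in dists[1:]:  # nuisance-freeness
                assert set(other) == set(dists[0])
                for c in other:
                    assert other[c] == pytest.approx(dists[0][c], abs=1e-12)
            e, cov = oracle_moments(dists[0], k)
            np.testing.assert_allclose(cd.expected, e, atol=1e-12)
            np.testing.assert_allclose(cd.covariance, cov, atol=1e-12)


class TestCodeTraits:
    def test_sex_interaction_weights(self):
        tv = code_traits(["male", "female"], ["affected", "affected"], Coding.SEX_INTER)
        np.testing.assert_allclose(tv.values, [-0.425, 0.425])

    def test_unaffected_sibling_zero_under_every_coding(self):
        for coding in Coding:
            tv = code_traits(["male"], ["unaffected"], coding)
            assert tv.values[0] == 0.0
            tv = code_traits(["female"], ["missing"], coding)
            assert tv.values[0] == 0.0

    def test_unknown_sex_excluded_from_interaction(self):
        tv = code_traits(["unknown"], ["affected"], Coding.SEX_INTER)
        assert tv.values[0] == 0.0

    def test_stratified_codings_select_one_sex(self):
        sexes = ["male", "female"]
        affs = ["affected", "affected"]
        np.testing.assert_allclose(
            code_traits(sexes, affs, Coding.MALE_ONLY).values, [0.85, 0.0]
        )
        np.testing.assert_allclose(
            code_traits(sexes, affs, Coding.FEMALE_ONLY).values, [0.0, 0.85]
        )

    def test_custom_offset(self):
        tv = code_traits(["male"], ["affected"], Coding.MAIN, mu=0.1)
        assert tv.values[0] == pytest.approx(0.9)


class TestFamilyContribution:
    def _worked_family(self, coding):
        cd = conditional_distribution(None, None, [2, 1])
        tv = code_traits(["male", "female"], ["affected", "affected"], coding)
        return family_contribution(cd, [2, 1], [tv])

    def test_worked_family_sex_interaction(self):
        fc = self._worked_family(Coding.SEX_INTER)
        assert fc.u[0] == pytest.approx(-0.425)
        assert fc.cov[0, 0] == pytest.approx(0.180625)
        assert fc.informative

    def test_worked_family_main_coding_non_informative(self):
        # both configurations have dosage sum 3, so the main-effect score
        # is constant: u = 0 and zero variance
        fc = self._worked_family(Coding.MAIN)
        assert fc.u[0] == pytest.approx(0.0)
        assert fc.cov[0, 0] == pytest.approx(0.0)
        assert not fc.informative

    def test_all_zero_traits_non_informative(self):
        cd = conditional_distribution(1, 1, [1, 0])
        tv = code_traits(["male", "male"], ["unaffected", "unaffected"], Coding.MAIN)
        fc = family_contribution(cd, [1, 0], [tv])
        assert fc.u[0] == 0.0 and not fc.informative

    def test_dimension_mismatch_raises(self):
        cd = conditional_distribution(1, 1, [1])
        tv = code_traits(["male", "female"], ["affected", "affected"], Coding.MAIN)
        with pytest.raises(ValueError):
            family_contribution(cd, [1], [tv])


class TestZTest:
    def _contrib(self):
        cd = conditional_distribution(None, None, [2, 1])
        tv = code_traits(["male", "female"], ["affected", "affected"], Coding.SEX_INTER)
        return family_contribution(cd, [2, 1], [tv])

    def test_single_worked_family(self):
        res = fbat_z_test([self._contrib()], min_informative=1)
        assert res.statistic == pytest.approx(-1.0)
        assert res.p == pytest.approx(0.3173, abs=1e-4)
        assert res.n_informative == 1
        assert res.direction == -1

    def test_sqrt_n_scaling(self):
        res = fbat_z_test([self._contrib()] * 100, min_informative=1)
        assert res.statistic == pytest.approx(-10.0)

    def test_min_informative_gate(self):
        assert fbat_z_test([self._contrib()], min_informative=2) is None

    def test_no_informative_families_skipped(self):
        cd = conditional_distribution(None, None, [1, 1])
        tv = code_traits(["male", "female"], ["affected", "affected"], Coding.SEX_INTER)
        fc = family_contribution(cd, [1, 1], [tv])
        assert fbat_z_test([fc], min_informative=0) is None


class TestGeeTest:
    def test_identity_covariance_closed_form(self):
        from fbatscan.fbat_core import FamilyContribution

        contribs = [
            FamilyContribution(
                u=np.array([1.0, 1.0]), cov=np.eye(2), informative=True
            )
        ]
        res = fbat_gee_test(contribs, min_informative=1)
        assert res.statistic == pytest.approx(2.0)
        assert res.df == 2
        assert res.p == pytest.approx(math.exp(-1.0), abs=1e-10)

    def test_one_sex_reduces_to_main_effect_z_squared(self):
        # all-male affected sibship: the interaction coding is -0.5x the
        # main coding, so V is rank 1 and the chi-square equals Z^2
        cd = conditional_distribution(1, 1, [2, 1])
        sexes, affs = ["male", "male"], ["affected", "affected"]
        tmain = code_traits(sexes, affs, Coding.MAIN)
        tint = code_traits(sexes, affs, Coding.SEX_INTER)
        fc2 = family_contribution(cd, [2, 1], [tmain, tint])
        fc1 = family_contribution(cd, [2, 1], [tmain])
        gee = fbat_gee_test([fc2], min_informative=1)
        z = fbat_z_test([fc1], test="main", min_informative=1)
        assert gee.df == 1
        assert gee.statistic == pytest.approx(z.statistic**2, abs=1e-12)
        assert gee.p == pytest.approx(z.p, abs=1e-12)

    def test_rank_zero_skipped(self):
        from fbatscan.fbat_core import FamilyContribution

        contribs = [
            FamilyContribution(
                u=np.array([0.0, 0.0]), cov=np.zeros((2, 2)), informative=True
            )
        ]
        assert fbat_gee_test(contribs, min_informative=1) is None


# ---------------------------------------------------------------------------
# property tests

sibship = st.lists(st.integers(0, 2), min_size=1, max_size=4)
parent_slot = st.one_of(st.none(), st.integers(0, 2))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(father=parent_slot, mother=parent_slot, doses=sibship)
def test_score_is_conditionally_mean_zero(father, mother, doses):
    """E(u) = 0 exactly under the conditional law, for every coding."""
    try:
        cd = conditional_distribution(father, mother, doses)
    except MendelianImpossibilityError:
        return
    rng = np.random.default_rng(abs(hash((father, mother, tuple(doses)))) % 2**31)
    sexes = [rng.choice(["male", "female"]) for _ in doses]
    affs = [rng.choice(["affected", "unaffected"]) for _ in doses]
    for coding in Coding:
        tv = code_traits(sexes, affs, coding)
        eu = sum(
            p * float(tv.values @ (np.asarray(cfg, float) - cd.expected))
            for cfg, p in cd.configurations
        )
        assert abs(eu) < 1e-12


@settings(max_examples=200, deadline=None, derandomize=True)
@given(father=parent_slot, mother=parent_slot, doses=sibship, data=st.data())
def test_sibling_permutation_invariance(father, mother, doses, data):
    """Reordering siblings together with their traits leaves u and cov
    unchanged."""
    try:
        cd = conditional_distribution(father, mother, doses)
    except MendelianImpossibilityError:
        return
    k = len(doses)
    perm = data.draw(st.permutations(range(k)))
    sexes = ["male" if i % 2 else "female" for i in range(k)]
    affs = ["affected"] * k
    tv = code_traits(sexes, affs, Coding.SEX_INTER)
    fc = family_contribution(cd, doses, [tv])
    doses_p = [doses[i] for i in perm]
    cd_p = conditional_distribution(father, mother, doses_p)
    tv_p = code_traits([sexes[i] for i in perm], affs, Coding.SEX_INTER)
    fc_p = family_contribution(cd_p, doses_p, [tv_p])
    assert fc.u[0] == pytest.approx(fc_p.u[0], abs=1e-12)
    assert fc.cov[0, 0] == pytest.approx(fc_p.cov[0, 0], abs=1e-12)
    assert fc.informative == fc_p.informative


@settings(max_examples=200, deadline=None, derandomize=True)
@given(father=parent_slot, mother=parent_slot, doses=sibship)
def test_allele_relabel_antisymmetry(father, mother, doses):
    """Swapping ref/alt (x -> 2 - x everywhere) flips the sign of u and
    leaves the conditional variance unchanged."""
    try:
        cd = conditional_distribution(father, mother, doses)
    except MendelianImpossibilityError:
        return
    k = len(doses)
    sexes = ["male" if i % 2 else "female" for i in range(k)]
    tv = code_traits(sexes, ["affected"] * k, Coding.SEX_INTER)
    fc = family_contribution(cd, doses, [tv])
    flip = lambda g: None if g is None else 2 - g
    cd_f = conditional_distribution(flip(father), flip(mother), [2 - d for d in doses])
    fc_f = family_contribution(cd_f, [2 - d for d in doses], [tv])
    assert fc_f.u[0] == pytest.approx(-fc.u[0], abs=1e-12)
    assert fc_f.cov[0, 0] == pytest.approx(fc.cov[0, 0], abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(father=parent_slot, mother=parent_slot, doses=sibship)
def test_degenerate_iff_single_configuration_iff_zero_covariance(
    father, mother, doses
):
    try:
        cd = conditional_distribution(father, mother, doses)
    except MendelianImpossibilityError:
        return
    single = len(cd.configurations) == 1
    zero_cov = bool(np.all(np.abs(cd.covariance) < 1e-15))
    assert (cd.level is ConditioningLevel.DEGENERATE) == single
    assert single == zero_cov
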