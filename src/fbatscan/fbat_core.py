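"""Conditional-on-sufficient-statistic family-based association score tests.

The FBAT score statistic is

    U = sum_i sum_j  T_ij * (X_ij - E[X_ij | S_i])

where ``X_ij`` is the additive genotype coding (count of the alternate
allele) of offspring ``j`` in nuclear family ``i``, ``T_ij`` a coded trait,
and ``S_i`` the family's sufficient statistic for the unobserved parental
genotypes.  Conditioning on ``S_i`` makes the null distribution of the
offspring genotypes depend only on Mendelian transmission, so the test is
valid under arbitrary population structure.

This module implements the conditioning hierarchy (both parents observed;
a single compatible mating forced by the data; conditioning on the set of
distinct offspring genotypes when that removes the mating-type nuisance;
and the always-valid permutation distribution of the observed offspring
multiset), exact moment computation by enumeration, the sex-interaction
trait coding T = (Y - mu)(Z - 0.5), the one-dimensional normal score test,
and the multivariate FBAT-GEE chi-square for the joint main + interaction
test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

GENOTYPES = (0, 1, 2)

#: probability tolerance used for normalisation checks and for the
#: cross-mating identity test at the distinct-set conditioning level
PROB_TOL = 1e-12


class MendelianImpossibilityError(ValueError):
    """No parental mating can produce the observed family genotypes."""


class ConditioningLevel(Enum):
    """Coarsest-first hierarchy of valid conditioning strategies."""

    PARENTAL = "parental"
    FORCED_MATING = "forced_mating"
    DISTINCT_SET = "distinct_set"
    PERMUTATION = "permutation"
    DEGENERATE = "degenerate"


class Coding(Enum):
    """Trait codings for the affected-only sex-specific design."""

    MAIN = "main"
    SEX_INTER = "sex_inter"
    MALE_ONLY = "male_only"
    FEMALE_ONLY = "female_only"


def offspring_probs(g1: int, g2: int) -> tuple[float, float, float]:
    """Mendelian transmission table: P(offspring dosage | mating g1 x g2).

    Each parent transmits the alternate allele with probability g/2; the
    offspring dosage is the sum of the two transmitted alleles.  All values
    are dyadic rationals, hence exact in binary floating point.
    """
    p1, p2 = g1 / 2.0, g2 / 2.0
    return (
        (1.0 - p1) * (1.0 - p2),
        p1 * (1.0 - p2) + (1.0 - p1) * p2,
        p1 * p2,
    )


def compatible_matings(
    father_gt: Optional[int],
    mother_gt: Optional[int],
    offspring_dosages: Sequence[int],
) -> frozenset[tuple[int, int]]:
    """All unordered parental genotype pairs consistent with the family.

    A mating is compatible when it matches every observed parent slot and
    assigns positive transmission probability to every observed offspring
    dosage.  Returns the empty set on Mendelian impossibility (the caller
    decides whether that is an error or a skip).
    """
    if not offspring_dosages:
        raise ValueError("at least one observed offspring dosage required")
    fathers = GENOTYPES if father_gt is None else (father_gt,)
    mothers = GENOTYPES if mother_gt is None else (mother_gt,)
    out = set()
    for f, m in itertools.product(fathers, mothers):
        probs = offspring_probs(f, m)
        if all(probs[d] > 0.0 for d in offspring_dosages):
            out.add((f, m) if f <= m else (m, f))
    return frozenset(out)


@dataclass(frozen=True)
class ConditionalDistribution:
    """Offspring-genotype distribution given the family sufficient statistic.

    ``configurations`` lists (dosage vector, probability) pairs over the
    observed offspring; ``expected`` and ``covariance`` are the exact first
    and second central moments of that list.
    """

    configurations: tuple[tuple[tuple[int, ...], float], ...]
    level: ConditioningLevel
    expected: np.ndarray
    covariance: np.ndarray

    @property
    def n_offspring(self) -> int:
        return len(self.expected)

    @property
    def is_degenerate(self) -> bool:
        return len(self.configurations) == 1


def _moments(
    configs: Sequence[tuple[tuple[int, ...], float]], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean vector and covariance matrix of a configuration list."""
    e = np.zeros(k)
    exx = np.zeros((k, k))
    for cfg, p in configs:
        x = np.asarray(cfg, dtype=float)
        e += p * x
        exx += p * np.outer(x, x)
    return e, exx - np.outer(e, e)


def _iid_configs(
    mating: tuple[int, int], k: int
) -> list[tuple[tuple[int, ...], float]]:
    """i.i.d. Mendelian configurations of k offspring for a known mating."""
    probs = offspring_probs(*mating)
    support = [g for g in GENOTYPES if probs[g] > 0.0]
    out = []
    for cfg in itertools.product(support, repeat=k):
        p = math.prod(probs[g] for g in cfg)
        out.append((cfg, p))
    return out


def _identified_mating_configs(
    father_gt: Optional[int],
    mother_gt: Optional[int],
    mating: tuple[int, int],
    k: int,
) -> list[tuple[tuple[int, ...], float]]:
    """Conditioning event when the offspring data identify the mating.

    With unobserved parents the mating type is only known *because* the
    observed genotypes admit no alternative, so the conditioning event is
    "the offspring configuration identifies this mating", not "the mating
    is this one": the i.i.d. Mendelian measure must be restricted to
    configurations whose own compatible-mating set is the same singleton,
    then renormalised.  Only those configurations receive zero probability
    under every other mating, which is what makes the conditional law free
    of the parental-genotype nuisance.  (With both parents observed the
    restriction is vacuous and this reduces to the plain i.i.d. table.)
    """
    probs = offspring_probs(*mating)
    support = [g for g in GENOTYPES if probs[g] > 0.0]
    target = frozenset((mating,))
    out = []
    total = 0.0
    for cfg in itertools.product(support, repeat=k):
        if compatible_matings(father_gt, mother_gt, cfg) != target:
            continue
        p = math.prod(probs[g] for g in cfg)
        out.append((cfg, p))
        total += p
    return [(cfg, p / total) for cfg, p in out]


def _distinct_set_configs(
    mating: tuple[int, int], k: int, target: frozenset[int]
) -> list[tuple[tuple[int, ...], float]]:
    """Configurations whose distinct-genotype set equals ``target``,
    renormalised within the mating's transmission measure."""
    probs = offspring_probs(*mating)
    out = []
    total = 0.0
    for cfg in itertools.product(GENOTYPES, repeat=k):
        if frozenset(cfg) != target:
            continue
        p = math.prod(probs[g] for g in cfg)
        if p > 0.0:
            out.append((cfg, p))
            total += p
    return [(cfg, p / total) for cfg, p in out]


def _same_distribution(
    a: Sequence[tuple[tuple[int, ...], float]],
    b: Sequence[tuple[tuple[int, ...], float]],
    tol: float = PROB_TOL,
) -> bool:
    da, db = dict(a), dict(b)
    if set(da) != set(db):
        return False
    return all(abs(da[c] - db[c]) <= tol for c in da)


def _permutation_configs(
    dosages: Sequence[int],
) -> list[tuple[tuple[int, ...], float]]:
    perms = sorted(set(itertools.permutations(dosages)))
    p = 1.0 / len(perms)
    return [(cfg, p) for cfg in perms]


@lru_cache(maxsize=65536)
def _conditional_cached(
    father_gt: Optional[int],
    mother_gt: Optional[int],
    dosages: tuple[int, ...],
) -> ConditionalDistribution:
    matings = compatible_matings(father_gt, mother_gt, dosages)
    if not matings:
        raise MendelianImpossibilityError(
            f"no mating compatible with parents ({father_gt}, {mother_gt}) "
            f"and offspring {dosages}"
        )
    k = len(dosages)

    if father_gt is not None and mother_gt is not None:
        configs = _iid_configs((father_gt, mother_gt), k)
        level = ConditioningLevel.PARENTAL
    elif len(matings) == 1:
        (mating,) = matings
        configs = _identified_mating_configs(father_gt, mother_gt, mating, k)
        level = ConditioningLevel.FORCED_MATING
    else:
        # Distinct-set conditioning removes the mating nuisance only when
        # the induced distribution coincides across every compatible
        # mating; that identity is checked explicitly, with fallback to
        # the exchangeability (permutation) distribution.
        target = frozenset(dosages)
        per_mating = [_distinct_set_configs(m, k, target) for m in sorted(matings)]
        first = per_mating[0]
        if all(_same_distribution(first, other) for other in per_mating[1:]):
            configs = first
            level = ConditioningLevel.DISTINCT_SET
        else:
            configs = _permutation_configs(dosages)
            level = ConditioningLevel.PERMUTATION

    total = sum(p for _, p in configs)
    assert abs(total - 1.0) <= 1e-9, "configuration probabilities must sum to 1"
    configs = [(cfg, p / total) for cfg, p in configs]
    if len(configs) == 1:
        level = ConditioningLevel.DEGENERATE
    expected, covariance = _moments(configs, k)
    if level is ConditioningLevel.DEGENERATE:
        covariance = np.zeros((k, k))
    expected.setflags(write=False)
    covariance.setflags(write=False)
    return ConditionalDistribution(tuple(configs), level, expected, covariance)


def conditional_distribution(
    father_gt: Optional[int],
    mother_gt: Optional[int],
    offspring_dosages: Sequence[int],
) -> ConditionalDistribution:
    """Distribution of observed offspring dosages given the sufficient statistic.

    Offspring with missing genotype must be excluded by the caller; the
    observed members define the sufficient statistic.  Raises
    :class:`MendelianImpossibilityError` when no mating is compatible.
    """
    return _conditional_cached(father_gt, mother_gt, tuple(int(d) for d in offspring_dosages))


# ---------------------------------------------------------------------------
# trait coding


@dataclass(frozen=True)
class TraitVector:
    """Coded traits T_ij for the observed offspring of one family."""

    values: np.ndarray
    coding: Coding
    mu: float


def code_traits(
    sexes: Sequence[str],
    affections: Sequence[str],
    coding: Coding,
    mu: float = 0.15,
) -> TraitVector:
    """Affected-only trait coding with offset ``mu``.

    Affected offspring carry Y = 1; unaffected and phenotype-missing
    offspring get T = 0 so their genotypes still inform the sufficient
    statistic without contributing to the score.  Under the
    sex-interaction coding T = (Y - mu)(Z - 0.5) with Z = 0 for males and
    1 for females; offspring of unknown sex are zeroed with a warning.
    Sex-stratified codings keep T = Y - mu for one sex only.
    """
    t = np.zeros(len(sexes))
    for j, (sex, aff) in enumerate(zip(sexes, affections)):
        if aff != "affected":
            continue
        w = 1.0 - mu
        if coding is Coding.MAIN:
            t[j] = w
        elif coding is Coding.SEX_INTER:
            if sex == "male":
                t[j] = -0.5 * w
            elif sex == "female":
                t[j] = 0.5 * w
            else:
                logger.warning(
                    "offspring %d has unknown sex; excluded from the "
                    "sex-interaction coding (genotype still conditions S)",
                    j,
                )
        elif coding is Coding.MALE_ONLY:
            t[j] = w if sex == "male" else 0.0
        elif coding is Coding.FEMALE_ONLY:
            t[j] = w if sex == "female" else 0.0
    return TraitVector(values=t, coding=coding, mu=mu)


# ---------------------------------------------------------------------------
# per-family score contribution and tests


@dataclass(frozen=True)
class FamilyContribution:
    """Score vector u_i and conditional covariance block for one family."""

    u: np.ndarray
    cov: np.ndarray
    informative: bool


def family_contribution(
    cond: ConditionalDistribution,
    dosages: Sequence[int],
    traits: Sequence[TraitVector],
) -> FamilyContribution:
    """u_k = T_k . (x - E[X|S]);  cov_kl = T_k' Cov(X|S) T_l."""
    x = np.asarray(dosages, dtype=float)
    if len(x) != cond.n_offspring:
        raise ValueError("dosage vector does not match conditional distribution")
    tmat = np.vstack([tv.values for tv in traits])
    if tmat.shape[1] != cond.n_offspring:
        raise ValueError("trait vectors do not match conditional distribution")
    u = tmat @ (x - cond.expected)
    cov = tmat @ cond.covariance @ tmat.T
    informative = bool(np.any(np.diag(cov) > PROB_TOL))
    return FamilyContribution(u=u, cov=cov, informative=informative)


@dataclass(frozen=True)
class TestResult:
    """Per-variant test outcome."""

    __test__ = False  # not a pytest class despite the name

    test: str
    statistic: float
    df: int
    p: float
    n_informative: int
    direction: Optional[int] = None


def fbat_z_test(
    contributions: Sequence[FamilyContribution],
    test: str = "sex_inter",
    min_informative: int = 10,
) -> Optional[TestResult]:
    """Normal score test: Z = sum u_i / sqrt(sum var_i), two-sided p.

    Returns ``None`` when fewer than ``min_informative`` families are
    informative or the total conditional variance vanishes.
    """
    informative = [c for c in contributions if c.informative]
    n_inf = len(informative)
    if n_inf < min_informative:
        return None
    u = sum(float(c.u[0]) for c in informative)
    v = sum(float(c.cov[0, 0]) for c in informative)
    if v <= 0.0:
        return None
    z = u / math.sqrt(v)
    p = 2.0 * stats.norm.sf(abs(z))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return TestResult(
        test=test,
        statistic=z,
        df=1,
        p=p,
        n_informative=n_inf,
        direction=int(np.sign(z)) if z != 0 else 0,
    )


def fbat_gee_test(
    contributions: Sequence[FamilyContribution],
    test: str = "joint",
    min_informative: int = 10,
) -> Optional[TestResult]:
    """Multivariate FBAT-GEE: chi-square = U' V^- U with df = rank(V).

    ``V^-`` is the Moore-Penrose generalized inverse; the rank tolerance
    scales with the largest eigenvalue so a coding that is identically
    zero (e.g. one sex absent) collapses exactly to the remaining
    1-df score test.
    """
    informative = [c for c in contributions if c.informative]
    n_inf = len(informative)
    if n_inf < min_informative:
        return None
    dim = contributions[0].u.shape[0] if contributions else 0
    u = np.sum([c.u for c in informative], axis=0)
    v = np.sum([c.cov for c in informative], axis=0)
    eigval, eigvec = np.linalg.eigh(v)
    tol = np.finfo(float).eps * dim * max(eigval.max(initial=0.0), 0.0)
    keep = eigval > tol
    rank = int(np.count_nonzero(keep))
    if rank == 0:
        return None
    inv = (eigvec[:, keep] / eigval[keep]) @ eigvec[:, keep].T
    chi2 = float(u @ inv @ u)
    p = float(stats.chi2.sf(chi2, df=rank))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return TestResult(test=test, statistic=chi2, df=rank, p=p, n_informative=n_inf)
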