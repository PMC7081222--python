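"""Vectorised score-test engine for Monte-Carlo experiments.

The conditional offspring-genotype distribution of a nuclear family at a
biallelic marker depends only on the observed parent slots and the
multiset of observed offspring dosages, and at every non-degenerate
conditioning level the offspring are exchangeable, so the per-offspring
conditional mean is a single scalar E and the covariance has compound
symmetry (variance v, common off-diagonal c).  This module precomputes a
lookup table of (E, v, c) over all such patterns — using the exact
enumeration in :mod:`fbatscan.fbat_core` — and evaluates the score tests
for thousands of simulated replicates with numpy array arithmetic.

For a family with trait vector T and observed dosages x:

    u   = sum_j T_j x_j  -  E * sum_j T_j
    var = v * sum_j T_j^2  +  c * ((sum_j T_j)^2 - sum_j T_j^2)

and the two-coding FBAT-GEE block follows the same pattern with cross
products.  Agreement with the object-level pipeline is exact and covered
by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .fbat_core import (
    ConditioningLevel,
    MendelianImpossibilityError,
    conditional_distribution,
)

MISS = 3  # parent-slot code for an unobserved parent
MAX_SIB = 8


@dataclass(frozen=True)
class PatternTable:
    """(E, v, c, valid) indexed by parent codes and offspring dosage counts."""

    max_sib: int
    e: np.ndarray
    var: np.ndarray
    cov: np.ndarray
    valid: np.ndarray

    def index(
        self, fcode: np.ndarray, mcode: np.ndarray, c0: np.ndarray, c1: np.ndarray, c2: np.ndarray
    ) -> np.ndarray:
        m = self.max_sib + 1
        return (((fcode * 4 + mcode) * m + c0) * m + c1) * m + c2


@lru_cache(maxsize=4)
def pattern_table(max_sib: int = 4) -> PatternTable:
    """Enumerate every (parent slots, offspring multiset) pattern up to
    sibship size ``max_sib`` and store the exact conditional moments."""
    m = max_sib + 1
    size = 4 * 4 * m * m * m
    e = np.zeros(size)
    var = np.zeros(size)
    cov = np.zeros(size)
    valid = np.zeros(size, dtype=bool)
    for f in range(4):
        for mo in range(4):
            for c0 in range(m):
                for c1 in range(m - c0):
                    for c2 in range(m - c0 - c1):
                        k = c0 + c1 + c2
                        if k == 0:
                            continue
                        idx = (((f * 4 + mo) * m + c0) * m + c1) * m + c2
                        doses = (0,) * c0 + (1,) * c1 + (2,) * c2
                        try:
                            cond = conditional_distribution(
                                None if f == MISS else f,
                                None if mo == MISS else mo,
                                doses,
                            )
                        except MendelianImpossibilityError:
                            continue
                        valid[idx] = True
                        if cond.level is ConditioningLevel.DEGENERATE:
                            # single configuration: x - E == 0 for every
                            # offspring, zero variance; E stored as the
                            # common (necessarily identical) dosage
                            e[idx] = doses[0]
                            continue
                        ev = cond.expected
                        assert np.allclose(ev, ev[0], atol=1e-12), "exchangeability"
                        e[idx] = ev[0]
                        var[idx] = cond.covariance[0, 0]
                        cov[idx] = cond.covariance[0, 1] if k > 1 else 0.0
    return PatternTable(max_sib=max_sib, e=e, var=var, cov=cov, valid=valid)


@dataclass
class FamilyArrays:
    """One replicate of simulated families in rectangular array form.

    Offspring axes are padded to the maximum sibship; ``present`` masks
    real offspring slots.  Dosages use -1 for missing.
    """

    father: np.ndarray  # (n,) int, -1 = missing
    mother: np.ndarray  # (n,) int
    dose: np.ndarray  # (n, smax) int
    present: np.ndarray  # (n, smax) bool
    female: np.ndarray  # (n, smax) bool
    affected: np.ndarray  # (n, smax) bool

    @property
    def n_families(self) -> int:
        return self.father.shape[0]


def _trait_matrix(fam: FamilyArrays, coding: str, mu: float) -> np.ndarray:
    base = (1.0 - mu) * (fam.affected & fam.present)
    if coding == "main":
        return base
    if coding == "sex_inter":
        return base * np.where(fam.female, 0.5, -0.5)
    if coding == "male_only":
        return base * ~fam.female
    if coding == "female_only":
        return base * fam.female
    raise ValueError(f"unknown coding {coding!r}")


def _moment_lookup(fam: FamilyArrays, table: PatternTable):
    obs = fam.present & (fam.dose >= 0)
    c0 = ((fam.dose == 0) & obs).sum(axis=1)
    c1 = ((fam.dose == 1) & obs).sum(axis=1)
    c2 = ((fam.dose == 2) & obs).sum(axis=1)
    fcode = np.where(fam.father < 0, MISS, fam.father)
    mcode = np.where(fam.mother < 0, MISS, fam.mother)
    idx = table.index(fcode, mcode, c0, c1, c2)
    nobs = c0 + c1 + c2
    ok = nobs > 0
    valid = np.zeros(fam.n_families, dtype=bool)
    e = np.zeros(fam.n_families)
    v = np.zeros(fam.n_families)
    c = np.zeros(fam.n_families)
    valid[ok] = table.valid[idx[ok]]
    e[ok] = table.e[idx[ok]]
    v[ok] = table.var[idx[ok]]
    c[ok] = table.cov[idx[ok]]
    return obs, valid, e, v, c


def score_tests(
    fam: FamilyArrays,
    mu: float = 0.15,
    min_informative: int = 10,
    tests: tuple[str, ...] = ("sex_inter",),
) -> dict[str, tuple[float, float, int]]:
    """Evaluate the requested tests on one replicate.

    Returns ``{test: (statistic, p, n_informative)}``; a skipped test
    (too few informative families or zero variance / rank) maps to
    ``(nan, nan, n_informative)``.  ``joint`` is the 2-coding FBAT-GEE
    chi-square; the others are 1-df Z tests.
    """
    table = pattern_table(max(2, fam.dose.shape[1]))
    obs, valid, e, v, c = _moment_lookup(fam, table)
    x = np.where(obs, fam.dose, 0).astype(float)

    def zero_invalid(a: np.ndarray) -> np.ndarray:
        return np.where(valid, a, 0.0)

    def u_and_var(t: np.ndarray):
        t = np.where(obs, t, 0.0)
        st = t.sum(axis=1)
        st2 = (t * t).sum(axis=1)
        stx = (t * x).sum(axis=1)
        u = zero_invalid(stx - e * st)
        vv = zero_invalid(v * st2 + c * (st * st - st2))
        return t, st, st2, u, vv

    out: dict[str, tuple[float, float, int]] = {}
    cache: dict[str, tuple] = {}

    def coding_terms(coding: str):
        if coding not in cache:
            cache[coding] = u_and_var(_trait_matrix(fam, coding, mu))
        return cache[coding]

    for test in tests:
        if test == "joint":
            t1, s1, s12, u1, v1 = coding_terms("main")
            t2, s2, s22, u2, v2 = coding_terms("sex_inter")
            s12x = (t1 * t2).sum(axis=1)
            v12 = zero_invalid(v * s12x + c * (s1 * s2 - s12x))
            informative = (v1 > 1e-12) | (v2 > 1e-12)
            n_inf = int(informative.sum())
            if n_inf < min_informative:
                out[test] = (np.nan, np.nan, n_inf)
                continue
            uvec = np.array([u1[informative].sum(), u2[informative].sum()])
            vmat = np.array(
                [
                    [v1[informative].sum(), v12[informative].sum()],
                    [v12[informative].sum(), v2[informative].sum()],
                ]
            )
            eigval, eigvec = np.linalg.eigh(vmat)
            tol = np.finfo(float).eps * 2 * max(eigval.max(initial=0.0), 0.0)
            keep = eigval > tol
            rank = int(keep.sum())
            if rank == 0:
                out[test] = (np.nan, np.nan, n_inf)
                continue
            inv = (eigvec[:, keep] / eigval[keep]) @ eigvec[:, keep].T
            chi2 = float(uvec @ inv @ uvec)
            out[test] = (chi2, float(stats.chi2.sf(chi2, df=rank)), n_inf)
        else:
            _, _, _, u, vv = coding_terms(test)
            informative = vv > 1e-12
            n_inf = int(informative.sum())
            vtot = float(vv[informative].sum())
            if n_inf < min_informative or vtot <= 0.0:
                out[test] = (np.nan, np.nan, n_inf)
                continue
            z = float(u[informative].sum()) / np.sqrt(vtot)
            out[test] = (z, float(2.0 * stats.norm.sf(abs(z))), n_inf)
    return out
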