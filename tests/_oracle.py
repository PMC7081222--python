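"""Independent brute-force oracle for the conditional offspring-genotype law.

Re-derives, from the generative model alone, the distribution of a
nuclear family's offspring genotype configuration conditional on the
sufficient statistic: enumerate every configuration, classify each by the
conditioning statistic (observed parents; identified mating; distinct
genotype set when the induced law is mating-invariant; otherwise the
multiset), then condition the full mixture law P_theta(c) =
sum_m theta(m) P(c | m) on the event that the statistic equals its
observed value.  Nuisance-freeness is checked by evaluating the result
under several random mating priors theta.

Shares no code with fbatscan.fbat_core beyond the Mendelian transmission
table, which it re-implements.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

GEN = (0, 1, 2)


def trans_probs(g1: int, g2: int) -> tuple[float, float, float]:
    p1, p2 = g1 / 2.0, g2 / 2.0
    return (
        (1 - p1) * (1 - p2),
        p1 * (1 - p2) + (1 - p1) * p2,
        p1 * p2,
    )


def config_prob(mating: tuple[int, int], cfg: tuple[int, ...]) -> float:
    t = trans_probs(*mating)
    return math.prod(t[d] for d in cfg)


@lru_cache(maxsize=None)
def matings_for(father, mother, cfg) -> frozenset[tuple[int, int]]:
    fs = GEN if father is None else (father,)
    ms = GEN if mother is None else (mother,)
    out = set()
    for f, m in itertools.product(fs, ms):
        if config_prob((f, m), cfg) > 0:
            out.add((f, m) if f <= m else (m, f))
    return frozenset(out)


@lru_cache(maxsize=None)
def _set_law_invariant(father, mother, s: frozenset, k: int) -> bool:
    """Is the law restricted to {set(c) = s} identical for every compatible
    mating?"""
    matings = matings_for(father, mother, tuple(sorted(s)))
    laws = []
    for m in sorted(matings):
        probs = {}
        tot = 0.0
        for cfg in itertools.product(GEN, repeat=k):
            if frozenset(cfg) != s:
                continue
            p = config_prob(m, cfg)
            if p > 0:
                probs[cfg] = p
                tot += p
        laws.append({c: p / tot for c, p in probs.items()})
    first = laws[0]
    for other in laws[1:]:
        if set(other) != set(first):
            return False
        if any(abs(other[c] - first[c]) > 1e-12 for c in first):
            return False
    return True


@lru_cache(maxsize=None)
def statistic(father, mother, cfg: tuple[int, ...]):
    """Oracle's conditioning statistic for one observed configuration."""
    m = matings_for(father, mother, cfg)
    if not m:
        return ("impossible",)
    if father is not None and mother is not None:
        return ("parental",)
    if len(m) == 1:
        return ("mating", next(iter(m)))
    s = frozenset(cfg)
    if _set_law_invariant(father, mother, s, len(cfg)):
        return ("set", tuple(sorted(s)))
    return ("multiset", tuple(sorted(cfg)))


def oracle_distribution(
    father, mother, cfg_obs: tuple[int, ...], theta: np.ndarray
) -> dict[tuple[int, ...], float]:
    """P_theta(c | statistic = statistic(cfg_obs)) by direct summation.

    ``theta`` is a 3x3 (father genotype x mother genotype) prior with
    positive mass everywhere; rows/columns are restricted automatically
    by observed parent slots.
    """
    k = len(cfg_obs)
    target = statistic(father, mother, cfg_obs)
    if target == ("impossible",):
        raise ValueError("Mendelian impossibility")
    fs = GEN if father is None else (father,)
    ms = GEN if mother is None else (mother,)
    out: dict[tuple[int, ...], float] = {}
    total = 0.0
    for cfg in itertools.product(GEN, repeat=k):
        if statistic(father, mother, cfg) != target:
            continue
        p = 0.0
        for f in fs:
            for m in ms:
                p += theta[f, m] * config_prob((f, m), cfg)
        if p > 0:
            out[cfg] = p
            total += p
    return {c: p / total for c, p in out.items()}


def oracle_moments(dist: dict[tuple[int, ...], float], k: int):
    e = np.zeros(k)
    exx = np.zeros((k, k))
    for cfg, p in dist.items():
        x = np.asarray(cfg, dtype=float)
        e += p * x
        exx += p * np.outer(x, x)
    return e, exx - np.outer(e, e)


def random_theta(rng: np.random.Generator) -> np.ndarray:
    """Strictly positive random prior over ordered parental genotype pairs."""
    t = rng.dirichlet(np.ones(9)).reshape(3, 3) + 1e-3
    return t / t.sum()
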