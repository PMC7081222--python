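"""Genome-scan orchestration.

Runs the requested score tests per variant across all nuclear families:
the joint two-phenotype FBAT-GEE chi-square on (T1, T2) = (Y - mu,
(Y - mu)(Z - 0.5)), the 1-df sex-interaction Z test, and sex-stratified
male-only / female-only runs (one sex's phenotypes set to missing to read
off the effect direction per sex).  Adds allele frequencies by affected
sex, fixed-threshold significance tiers, and a +/- window lookup around
known susceptibility loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import fbat_core, pedio
from .fbat_core import Coding, MendelianImpossibilityError, TestResult
from .pedio import MISSING, GenotypeMatrix, Individual, NuclearFamily

logger = logging.getLogger(__name__)

TESTS = ("joint", "sex_inter", "male_only", "female_only")

_CODING_FOR_TEST = {
    "sex_inter": Coding.SEX_INTER,
    "male_only": Coding.MALE_ONLY,
    "female_only": Coding.FEMALE_ONLY,
}


@dataclass
class ScanConfig:
    mu: float = 0.15
    tests: tuple[str, ...] = TESTS
    min_informative: int = 10
    genomewide_alpha: float = 5e-8
    suggestive_alpha: float = 5e-6
    lookup_window: int = 500_000
    lookup_alpha: float = 0.05

    def __post_init__(self) -> None:
        for a in (self.genomewide_alpha, self.suggestive_alpha, self.lookup_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("significance levels must lie in (0, 1)")
        if self.lookup_window < 0:
            raise ValueError("lookup window must be >= 0")
        unknown = set(self.tests) - set(TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (99, c)


def allele_freq(dosages: np.ndarray) -> Optional[float]:
    called = dosages[dosages != MISSING]
    if called.size == 0:
        return None
    return float(called.sum()) / (2.0 * called.size)


def allele_freq_by_sex(
    dosages: np.ndarray,
    individuals: Sequence[Individual],
    gm: GenotypeMatrix,
) -> tuple[Optional[float], Optional[float]]:
    """Alt-allele frequency among affected males and affected females.

    Undefined (None) rather than zero when no affected individual of a
    sex has a called genotype.
    """
    out = []
    for sex in ("male", "female"):
        cols = [
            gm.sample_column(ind.person_id)
            for ind in individuals
            if ind.sex == sex and ind.affection == "affected"
        ]
        cols = [c for c in cols if c is not None]
        out.append(allele_freq(dosages[cols]) if cols else None)
    return out[0], out[1]


@dataclass
class VariantResult:
    variant: pedio.VariantRecord
    result: TestResult
    af_all: Optional[float]
    af_affected_male: Optional[float]
    af_affected_female: Optional[float]
    tier: str = "none"


def _family_members_at(
    fam: NuclearFamily, gm: GenotypeMatrix, vi: int
) -> tuple[Optional[int], Optional[int], list[Individual], list[int]]:
    f = gm.dosage_of(vi, fam.father_id)
    m = gm.dosage_of(vi, fam.mother_id)
    kids, doses = [], []
    for child in fam.offspring:
        d = gm.dosage_of(vi, child.person_id)
        if d != MISSING:
            kids.append(child)
            doses.append(d)
    return (None if f == MISSING else f, None if m == MISSING else m, kids, doses)


def run_scan(
    gm: GenotypeMatrix,
    families: Sequence[NuclearFamily],
    individuals: Sequence[Individual],
    config: ScanConfig = ScanConfig(),
) -> tuple[list[VariantResult], list[dict]]:
    """Per-variant score tests over all nuclear families.

    Offspring with missing genotype are dropped from the family for that
    variant (the observed members define the sufficient statistic);
    families whose genotypes admit no Mendelian mating are skipped for
    the variant and logged.  Output order is deterministic:
    (chrom, pos, test-order as configured).
    """
    order = sorted(
        range(len(gm.variants)),
        key=lambda vi: (_chrom_sort_key(gm.variants[vi].chrom), gm.variants[vi].pos),
    )
    results: list[VariantResult] = []
    skip_log: list[dict] = []
    for vi in order:
        variant = gm.variants[vi]
        dosages = gm.dosage[vi]
        per_fam = []
        for fam in families:
            f, m, kids, doses = _family_members_at(fam, gm, vi)
            if not kids:
                continue
            try:
                cond = fbat_core.conditional_distribution(f, m, doses)
            except MendelianImpossibilityError:
                skip_log.append(
                    {
                        "chrom": variant.chrom,
                        "pos": variant.pos,
                        "unit": fam.family_id,
                        "reason": "mendelian_impossibility",
                    }
                )
                continue
            per_fam.append((fam, cond, kids, doses))

        af_all = allele_freq(dosages)
        af_m, af_f = allele_freq_by_sex(dosages, individuals, gm)

        for test in config.tests:
            codings = (
                (Coding.MAIN, Coding.SEX_INTER)
                if test == "joint"
                else (_CODING_FOR_TEST[test],)
            )
            contribs = []
            for fam, cond, kids, doses in per_fam:
                sexes = [k.sex for k in kids]
                affs = [k.affection for k in kids]
                traits = [
                    fbat_core.code_traits(sexes, affs, coding, config.mu)
                    for coding in codings
                ]
                contribs.append(fbat_core.family_contribution(cond, doses, traits))
            if test == "joint":
                res = fbat_core.fbat_gee_test(
                    contribs, test=test, min_informative=config.min_informative
                )
            else:
                res = fbat_core.fbat_z_test(
                    contribs, test=test, min_informative=config.min_informative
                )
            if res is None:
                skip_log.append(
                    {
                        "chrom": variant.chrom,
                        "pos": variant.pos,
                        "unit": test,
                        "reason": "non_informative",
                    }
                )
                continue
            results.append(
                VariantResult(
                    variant=variant,
                    result=res,
                    af_all=af_all,
                    af_affected_male=af_m,
                    af_affected_female=af_f,
                )
            )
    annotate_significance(results, config)
    return results, skip_log


def annotate_significance(
    results: Sequence[VariantResult], config: ScanConfig = ScanConfig()
) -> Sequence[VariantResult]:
    """Tier each result by fixed thresholds (genome-wide 5e-8, suggestive 5e-6)."""
    for r in results:
        if r.result.p < config.genomewide_alpha:
            r.tier = "genomewide"
        elif r.result.p < config.suggestive_alpha:
            r.tier = "suggestive"
        else:
            r.tier = "none"
    return results


def results_to_rows(results: Sequence[VariantResult]) -> list[dict]:
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "rsid": r.variant.var_id,
                "A1": r.variant.alt,
                "A2": r.variant.ref,
                "af_all": r.af_all,
                "af_affected_male": r.af_affected_male,
                "af_affected_female": r.af_affected_female,
                "test": r.result.test,
                "statistic": r.result.statistic,
                "df": r.result.df,
                "n_informative_families": r.result.n_informative,
                "p": r.result.p,
            }
        )
    return rows


def region_lookup(
    results: pd.DataFrame,
    anchors: Sequence[tuple[str, int]],
    window: int = 500_000,
    alpha: float = 0.05,
    test: str = "sex_inter",
) -> pd.DataFrame:
    """Nominally significant variants within +/- ``window`` bp of an anchor.

    A variant qualifies when it lies on an anchor's chromosome with
    |pos - anchor| <= window and its p-value for ``test`` is <= alpha.
    The nearest anchor (smallest distance, ties to the lowest anchor
    position) is annotated.
    """
    df = results[results["test"] == test].copy() if "test" in results else results.copy()
    keep_rows = []
    for _, row in df.iterrows():
        if row["p"] > alpha:
            continue
        best = None
        for chrom, pos in anchors:
            if str(chrom) != str(row["chrom"]):
                continue
            dist = abs(int(row["pos"]) - int(pos))
            if dist <= window and (best is None or (dist, pos) < best):
                best = (dist, pos)
        if best is not None:
            r = row.to_dict()
            r["anchor_pos"] = best[1]
            r["anchor_distance"] = best[0]
            keep_rows.append(r)
    cols = list(df.columns) + ["anchor_pos", "anchor_distance"]
    return pd.DataFrame(keep_rows, columns=cols)


def write_skip_log(skip_log: Sequence[dict], path: str) -> None:
    pd.DataFrame(skip_log, columns=["chrom", "pos", "unit", "reason"]).to_csv(
        path, sep="\t", index=False
    )
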