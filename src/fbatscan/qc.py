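"""Variant-level quality control cascade.

Filters mirror a stringent family-WGS workflow: FILTER=PASS only,
biallelic SNVs, no monomorphic sites or singletons, no sites with
half-called genotypes, per-variant genotyping rate >= 95%, zero Mendelian
inconsistencies in trios (optionally parent-offspring duos), and
list-based exclusions (an external call-set whitelist and regions of
genes with known X/Y pseudogenes, where mismapped sex-chromosome reads
create sex-differential genotype errors).

Every filter is a pure predicate on the variant and its dosage vector, so
the kept set is independent of filter ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .fbat_core import offspring_probs
from .pedio import MISSING, GenotypeMatrix, NuclearFamily, VariantRecord

VariantKey = tuple[str, int, str, str]

REASONS = (
    "not_pass",
    "multiallelic",
    "monomorphic",
    "singleton",
    "indel",
    "half_call",
    "low_call_rate",
    "mendel_error",
    "not_in_siteslist",
    "pseudogene_region",
)


@dataclass
class QCDecision:
    key: VariantKey
    reasons: list[str] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return not self.reasons

    def merge(self, other: "QCDecision") -> "QCDecision":
        assert self.key == other.key
        return QCDecision(self.key, self.reasons + [r for r in other.reasons if r not in self.reasons])


def filter_variant_basic(variant: VariantRecord, dosages: np.ndarray) -> QCDecision:
    """Basic per-variant exclusions: FILTER, allele structure, informativeness.

    A singleton is a site with exactly one alternate allele observed across
    the whole dataset; a half call (one missing allele of two in any
    individual) excludes the entire variant rather than masking the
    genotype.
    """
    d = QCDecision(variant.key)
    if not variant.filter_pass:
        d.reasons.append("not_pass")
    if variant.is_multiallelic:
        d.reasons.append("multiallelic")
    dosages = np.asarray(dosages)
    called = dosages[dosages != MISSING]
    if called.size and np.all(called == called[0]):
        d.reasons.append("monomorphic")
    if called.size and int(called.sum()) == 1:
        d.reasons.append("singleton")
    if len(variant.ref) > 1 or len(variant.alt) > 1:
        d.reasons.append("indel")
    if variant.has_half_call:
        d.reasons.append("half_call")
    return d


def genotyping_rate_filter(
    variant: VariantRecord, dosages: np.ndarray, threshold: float = 0.95
) -> QCDecision:
    """Drop the variant when the fraction of called genotypes falls below
    ``threshold`` (call rate strictly less than the threshold fails)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    dosages = np.asarray(dosages)
    if dosages.size == 0:
        raise ValueError("empty sample set")
    d = QCDecision(variant.key)
    rate = float(np.count_nonzero(dosages != MISSING)) / dosages.size
    if rate < threshold:
        d.reasons.append("low_call_rate")
    return d


def mendel_check_duo(parent_dosage: int, offspring_dosage: int) -> bool:
    """A duo is inconsistent only for discordant homozygotes (0 vs 2);
    a missing genotype on either side means no check."""
    if parent_dosage == MISSING or offspring_dosage == MISSING:
        return True
    return {parent_dosage, offspring_dosage} != {0, 2}


def mendel_check_trio(
    father_dosage: int, mother_dosage: int, offspring_dosage: int
) -> bool:
    """Offspring must be producible from both parents by Mendelian
    transmission; with a missing member only the duo check applies."""
    if MISSING in (father_dosage, mother_dosage):
        return mendel_check_duo(
            mother_dosage if father_dosage == MISSING else father_dosage,
            offspring_dosage,
        )
    if offspring_dosage == MISSING:
        return True
    return offspring_probs(father_dosage, mother_dosage)[offspring_dosage] > 0.0


def mendel_error_scan(
    families: Sequence[NuclearFamily],
    gm: GenotypeMatrix,
    mode: str = "trio_only",
    max_errors: int = 0,
) -> tuple[np.ndarray, list[QCDecision], list[tuple[VariantKey, str, str]]]:
    """Count Mendelian inconsistencies per variant across nuclear families.

    In ``trio_only`` mode only families with both parents genotyped are
    checked (the classical Mendel QC); ``include_duos`` additionally
    screens one-parent families for discordant homozygotes.  A variant is
    dropped when its error count exceeds ``max_errors``.  Returns the
    per-variant counts, decisions, and a detail list of
    (variant key, family id, offspring id) for auditing.
    """
    if mode not in ("trio_only", "include_duos"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = np.zeros(len(gm.variants), dtype=int)
    details: list[tuple[VariantKey, str, str]] = []
    for vi, variant in enumerate(gm.variants):
        for fam in families:
            f = gm.dosage_of(vi, fam.father_id)
            m = gm.dosage_of(vi, fam.mother_id)
            both = f != MISSING and m != MISSING
            one = (f != MISSING) != (m != MISSING)
            for child in fam.offspring:
                o = gm.dosage_of(vi, child.person_id)
                if o == MISSING:
                    continue
                if both:
                    ok = mendel_check_trio(f, m, o)
                elif one and mode == "include_duos":
                    ok = mendel_check_duo(f if f != MISSING else m, o)
                else:
                    continue
                if not ok:
                    counts[vi] += 1
                    details.append((variant.key, fam.family_id, child.person_id))
    decisions = []
    for vi, variant in enumerate(gm.variants):
        d = QCDecision(variant.key)
        if counts[vi] > max_errors:
            d.reasons.append("mendel_error")
        decisions.append(d)
    return counts, decisions, details


def read_site_list(path: str) -> set[VariantKey]:
    """One ``chrom:pos:ref:alt`` key per line."""
    keys: set[VariantKey] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(":")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected chrom:pos:ref:alt")
            keys.add((parts[0], int(parts[1]), parts[2], parts[3]))
    return keys


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read BED regions as 0-based half-open intervals."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            regions.append((parts[0], start, end))
    return regions


def exclusion_list_filter(
    variants: Sequence[VariantRecord],
    site_list: Optional[set[VariantKey]] = None,
    region_list: Optional[Sequence[tuple[str, int, int]]] = None,
) -> list[QCDecision]:
    """Whitelist/blacklist filters.

    ``site_list`` is a whitelist: when given, variants absent from it are
    dropped.  ``region_list`` holds 0-based half-open intervals; a variant
    at 1-based position p overlaps [start, end) iff start < p <= end.
    """
    decisions = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in region_list or []:
        by_chrom.setdefault(chrom, []).append((s, e))
    for v in variants:
        d = QCDecision(v.key)
        if site_list is not None and v.key not in site_list:
            d.reasons.append("not_in_siteslist")
        for s, e in by_chrom.get(v.chrom, []):
            if s <= v.pos - 1 < e:  # convert 1-based position to 0-based
                d.reasons.append("pseudogene_region")
                break
        decisions.append(d)
    return decisions


def run_qc(
    gm: GenotypeMatrix,
    families: Sequence[NuclearFamily],
    call_rate_threshold: float = 0.95,
    mendel_mode: str = "trio_only",
    site_list: Optional[set[VariantKey]] = None,
    region_list: Optional[Sequence[tuple[str, int, int]]] = None,
) -> list[QCDecision]:
    """Full cascade; one merged decision per variant, in matrix order."""
    _, mendel_decisions, _ = mendel_error_scan(families, gm, mode=mendel_mode)
    listed = exclusion_list_filter(gm.variants, site_list, region_list)
    out = []
    for vi, variant in enumerate(gm.variants):
        dosages = gm.dosage[vi]
        d = filter_variant_basic(variant, dosages)
        d = d.merge(genotyping_rate_filter(variant, dosages, call_rate_threshold))
        d = d.merge(mendel_decisions[vi])
        d = d.merge(listed[vi])
        out.append(d)
    return out


def qc_report(decisions: Iterable[QCDecision]) -> "pd.DataFrame":
    import pandas as pd

    rows = [
        {
            "chrom": d.key[0],
            "pos": d.key[1],
            "ref": d.key[2],
            "alt": d.key[3],
            "kept": d.kept,
            "reasons": ";".join(d.reasons),
        }
        for d in decisions
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "kept", "reasons"])
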