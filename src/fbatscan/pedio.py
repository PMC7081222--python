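"""Pedigree and genotype ingestion and the shared data model.

Reads 6-column PED/FAM pedigrees and multi-sample VCFs into plain
containers (a list of :class:`Individual` and a :class:`GenotypeMatrix`
of alternate-allele dosages), decomposes arbitrary pedigrees into
nuclear families — the unit of conditioning for the score tests — and
writes the per-variant results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a fully missing genotype

#: default PED dialect: sex 1=male/2=female/0=unknown,
#: affection 2=affected/1=unaffected/0=missing
SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
AFFECTION_CODES = {"2": "affected", "1": "unaffected", "0": "missing", "-9": "missing"}

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    person_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # male / female / unknown
    affection: str  # affected / unaffected / missing


@dataclass
class NuclearFamily:
    """One (father, mother) pair and their common offspring.

    Parent ids may be ``None`` (unobserved parent slot); genotypes are
    looked up per variant in the :class:`GenotypeMatrix` at analysis time.
    """

    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    offspring: list[Individual]

    def __post_init__(self) -> None:
        if not self.offspring:
            raise PedigreeError("nuclear family requires at least one offspring")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    var_id: str
    ref: str
    alt: str
    filter_pass: bool
    is_multiallelic: bool = False
    has_half_call: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix: variants x samples, missing = -1."""

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray  # int8, shape (n_variants, n_samples)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage shape does not match variants x samples")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def sample_column(self, person_id: str) -> Optional[int]:
        return self._sample_index.get(person_id)

    def dosage_of(self, variant_idx: int, person_id: Optional[str]) -> int:
        """Dosage for one person at one variant; missing if the person is
        absent from the matrix (e.g. an ungenotyped parent)."""
        if person_id is None:
            return MISSING
        col = self._sample_index.get(person_id)
        if col is None:
            return MISSING
        return int(self.dosage[variant_idx, col])


def read_pedigree(
    path: str,
    sex_codes: dict[str, str] = SEX_CODES,
    affection_codes: dict[str, str] = AFFECTION_CODES,
) -> list[Individual]:
    """Parse a whitespace-delimited 6+ column PED/FAM file.

    Columns: family id, person id, father id, mother id, sex, affection.
    A parent id of "0" means unknown.  Duplicate (family, person) keys and
    unrecognised sex/affection codes are hard errors naming the line.
    """
    individuals: list[Individual] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected >=6 columns, got {len(fields)}")
            fam, pid, fid, mid, sex, aff = fields[:6]
            if (fam, pid) in seen:
                raise PedigreeError(f"{path}:{lineno}: duplicate individual ({fam}, {pid})")
            seen.add((fam, pid))
            if sex not in sex_codes:
                raise PedigreeError(f"{path}:{lineno}: unknown sex code {sex!r}")
            if aff not in affection_codes:
                raise PedigreeError(f"{path}:{lineno}: unknown affection code {aff!r}")
            individuals.append(
                Individual(
                    person_id=pid,
                    family_id=fam,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=sex_codes[sex],
                    affection=affection_codes[aff],
                )
            )
    _check_acyclic(individuals)
    return individuals


def _check_acyclic(individuals: Sequence[Individual]) -> None:
    parents = {ind.person_id: (ind.father_id, ind.mother_id) for ind in individuals}

    for start in parents:
        seen = {start}
        stack = [p for p in parents.get(start, ()) if p is not None]
        while stack:
            node = stack.pop()
            if node == start:
                raise PedigreeError(f"individual {start!r} is its own ancestor")
            if node in seen:
                continue
            seen.add(node)
            stack.extend(p for p in parents.get(node, ()) if p is not None)


def decompose_nuclear(individuals: Sequence[Individual]) -> list[NuclearFamily]:
    """Split a pedigree into nuclear units keyed by (father_id, mother_id).

    Each distinct parent pair with at least one offspring yields one
    family; individuals with no named parents become singleton sibships
    with both parent slots empty (non-informative downstream but retained
    so allele frequencies and QC see them).  An individual may appear as
    offspring in one unit and as parent in another.
    """
    groups: dict[tuple[str, Optional[str], Optional[str]], list[Individual]] = {}
    for ind in individuals:
        key = (ind.family_id, ind.father_id, ind.mother_id)
        groups.setdefault(key, []).append(ind)
    out = []
    for (fam, fid, mid), offspring in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or "", kv[0][2] or "")
    ):
        out.append(
            NuclearFamily(family_id=fam, father_id=fid, mother_id=mid, offspring=offspring)
        )
    return out


def read_genotypes(
    path: str,
    keep_samples: Optional[Sequence[str]] = None,
    drop_non_autosomal: bool = True,
) -> GenotypeMatrix:
    """Load a VCF into an alt-allele dosage matrix.

    Dosage counts the first ALT allele; "./." becomes missing.  Variant
    flags needed by QC (FILTER not PASS, multiallelic ALT, any half-called
    genotype at the site) are recorded on each :class:`VariantRecord`.
    Non-autosomal rows are dropped with a logged count, as the score tests
    assume autosomal transmission.
    """
    vcf = VCF(path, gts012=True)
    if keep_samples is not None:
        missing = [s for s in keep_samples if s not in set(vcf.samples)]
        if missing:
            raise KeyError(f"samples absent from VCF header: {', '.join(missing)}")
        vcf.set_samples(list(keep_samples))
    samples = list(vcf.samples)

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for v in vcf:
        chrom = v.CHROM
        if drop_non_autosomal and chrom not in AUTOSOMES:
            n_dropped += 1
            continue
        gts = v.genotype.array()  # (n_samples, ploidy+1); last col = phased
        alleles = gts[:, :-1]
        known = alleles >= 0
        half = known.sum(axis=1) == 1
        dos = np.where(known.all(axis=1), (alleles == 1).sum(axis=1), MISSING)
        # only first-ALT copies count; any other ALT allele in a
        # multiallelic row is not ref, handled by the multiallelic flag
        alt_list = v.ALT or ["."]
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=v.POS,
                var_id=v.ID or ".",
                ref=v.REF,
                alt=alt_list[0],
                filter_pass=v.FILTER is None,  # cyvcf2: None == PASS
                is_multiallelic=len(alt_list) > 1,
                has_half_call=bool(half.any()),
            )
        )
        rows.append(dos.astype(np.int8))
    if n_dropped:
        logger.info("dropped %d non-autosomal variant rows", n_dropped)
    dosage = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(variants=variants, samples=samples, dosage=dosage)


RESULT_COLUMNS = [
    "chrom",
    "pos",
    "rsid",
    "A1",
    "A2",
    "af_all",
    "af_affected_male",
    "af_affected_female",
    "test",
    "statistic",
    "df",
    "n_informative_families",
    "p",
]


def _fmt_af(x: Optional[float]) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.4f}"


def write_results(rows: Iterable[dict], path: str) -> None:
    """Write per-variant test results as a TSV with a fixed column schema.

    ``rows`` are dicts with the RESULT_COLUMNS keys (allele frequencies
    may be None for an undefined frequency).  p-values are printed in
    scientific notation with three significant digits.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        str(r["chrom"]),
                        str(r["pos"]),
                        str(r["rsid"]),
                        str(r["A1"]),
                        str(r["A2"]),
                        _fmt_af(r["af_all"]),
                        _fmt_af(r["af_affected_male"]),
                        _fmt_af(r["af_affected_female"]),
                        str(r["test"]),
                        f"{r['statistic']:.3f}",
                        str(r["df"]),
                        str(r["n_informative_families"]),
                        f"{r['p']:.2e}",
                    ]
                )
                + "\n"
            )


def read_results(path: str) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
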