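"""Synthetic ascertained-family data generator and simulation experiments.

Emulates the structure of multiplex late-onset disease cohorts used for
family-based association testing: nuclear families with mixed sibship
sizes ascertained for at least one affected offspring, parental genotypes
mostly missing, balanced sex ratio, optional subpopulation structure
(different allele frequencies and prevalences), and optional
sex-differential genotype error — the failure mode that motivates the
X/Y-pseudogene QC filter.

Disease model: affection is Bernoulli with
logit P(affected) = logit(prevalence) + beta_sex * dosage, a logistic
model with sex-specific per-allele log-odds, the minimal generative model
in which the two sexes can carry effects in opposite directions.

Defaults describe a common-variant study: minor allele frequency 0.3
(typical of reported top loci in family AD scans), prevalence 0.15
(matching the score-test offset), sibships of 2-4, 90% of parental
genotypes missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from ._engine import FamilyArrays, score_tests
from .pedio import MISSING, GenotypeMatrix, Individual, NuclearFamily, VariantRecord


class AscertainmentError(RuntimeError):
    """Raised when virtually no simulated family meets the ascertainment rule."""


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 500
    sibship_sizes: tuple[int, ...] = (2, 3, 4)
    sibship_probs: Optional[tuple[float, ...]] = None  # uniform when None
    maf: tuple[float, ...] = (0.3,)
    prevalence: tuple[float, ...] = (0.15,)
    subpop_weights: tuple[float, ...] = (1.0,)
    beta_male: float = 0.0
    beta_female: float = 0.0
    ascertainment_min_affected: int = 1
    parent_missing_prob: float = 0.9
    error_rate_male: float = 0.0
    error_rate_female: float = 0.0
    n_null_variants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not (len(self.maf) == len(self.prevalence) == len(self.subpop_weights)):
            raise ValueError("maf, prevalence and subpop_weights must align")
        for p in self.maf:
            if not 0.0 < p <= 0.5:
                raise ValueError("maf must lie in (0, 0.5]")
        for p in self.prevalence:
            if not 0.0 < p < 1.0:
                raise ValueError("prevalence must lie in (0, 1)")
        for p in (self.parent_missing_prob, self.error_rate_male, self.error_rate_female):
            if not 0.0 <= p < 1.0 + 1e-12:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.sibship_sizes) < 1:
            raise ValueError("sibship sizes must be >= 1")


@dataclass
class SimTruth:
    """Generative ground truth kept alongside the observable data."""

    subpop: np.ndarray  # (n_families,)
    father_true: np.ndarray  # causal-variant parental dosages before masking
    mother_true: np.ndarray
    father_observed: np.ndarray  # masks (True = genotype released)
    mother_observed: np.ndarray
    n_error_flips: int = 0


def _transmit(parent_dose: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per entry: Bernoulli(g/2)."""
    return (rng.random(parent_dose.shape) < parent_dose / 2.0).astype(np.int8)


def _draw_replicate(
    config: SimConfig, rng: np.random.Generator
) -> tuple[FamilyArrays, SimTruth]:
    """Vectorised rejection sampling of ascertained families (causal variant)."""
    smax = max(config.sibship_sizes)
    sizes = np.asarray(config.sibship_sizes)
    size_probs = (
        np.full(len(sizes), 1.0 / len(sizes))
        if config.sibship_probs is None
        else np.asarray(config.sibship_probs, dtype=float) / sum(config.sibship_probs)
    )
    maf = np.asarray(config.maf)
    prev = np.asarray(config.prevalence)
    weights = np.asarray(config.subpop_weights, dtype=float)
    weights = weights / weights.sum()
    beta = np.array([config.beta_male, config.beta_female])

    need = config.n_families
    chunks: list[tuple] = []
    drawn = accepted = 0
    while need > 0:
        m = max(4 * need, 512)
        sib = rng.choice(sizes, size=m, p=size_probs)
        sub = rng.choice(len(weights), size=m, p=weights)
        fd = rng.binomial(2, maf[sub]).astype(np.int8)
        md = rng.binomial(2, maf[sub]).astype(np.int8)
        present = np.arange(smax)[None, :] < sib[:, None]
        dose = _transmit(np.repeat(fd[:, None], smax, axis=1), rng) + _transmit(
            np.repeat(md[:, None], smax, axis=1), rng
        )
        female = rng.random((m, smax)) < 0.5
        eta = logit(prev[sub])[:, None] + beta[female.astype(int)] * dose
        affected = (rng.random((m, smax)) < expit(eta)) & present
        ok = affected.sum(axis=1) >= config.ascertainment_min_affected
        drawn += m
        accepted += int(ok.sum())
        take = np.flatnonzero(ok)[:need]
        chunks.append((fd[take], md[take], dose[take], present[take], female[take], affected[take], sub[take]))
        need -= len(take)
        if drawn >= 20_000 and accepted / drawn < 1e-4:
            raise AscertainmentError(
                "ascertainment acceptance probability below 1e-4; relax "
                "ascertainment_min_affected or raise prevalence/sibship size"
            )

    fd, md, dose, present, female, affected, sub = (
        np.concatenate([c[i] for c in chunks]) for i in range(7)
    )
    obs_f = rng.random(config.n_families) >= config.parent_missing_prob
    obs_m = rng.random(config.n_families) >= config.parent_missing_prob
    fam = FamilyArrays(
        father=np.where(obs_f, fd, -1).astype(np.int8),
        mother=np.where(obs_m, md, -1).astype(np.int8),
        dose=np.where(present, dose, -1).astype(np.int8),
        present=present,
        female=female,
        affected=affected,
    )
    truth = SimTruth(
        subpop=sub,
        father_true=fd,
        mother_true=md,
        father_observed=obs_f,
        mother_observed=obs_m,
    )
    return fam, truth


def _flip_genotypes(
    dose: np.ndarray, flip_mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric genotype-error move: het -> random homozygote,
    homozygote -> het; missing entries untouched."""
    out = dose.copy()
    flip = flip_mask & (dose >= 0)
    het = flip & (dose == 1)
    hom = flip & (dose != 1)
    out[hom] = 1
    out[het] = np.where(rng.random(int(het.sum())) < 0.5, 0, 2).astype(out.dtype)
    return out


def _inject_errors_arrays(
    fam: FamilyArrays, e_m: float, e_f: float, rng: np.random.Generator
) -> tuple[FamilyArrays, int]:
    """Per-genotype sex-differential errors on offspring and parents."""
    if e_m == 0.0 and e_f == 0.0:
        return fam, 0
    rate = np.where(fam.female, e_f, e_m)
    flip_off = (rng.random(fam.dose.shape) < rate) & fam.present
    dose = _flip_genotypes(fam.dose, flip_off, rng)
    father = _flip_genotypes(fam.father, rng.random(fam.father.shape) < e_m, rng)
    mother = _flip_genotypes(fam.mother, rng.random(fam.mother.shape) < e_f, rng)
    n_flips = int(
        (dose != fam.dose).sum() + (father != fam.father).sum() + (mother != fam.mother).sum()
    )
    return (
        FamilyArrays(
            father=father,
            mother=mother,
            dose=dose,
            present=fam.present,
            female=fam.female,
            affected=fam.affected,
        ),
        n_flips,
    )


# ---------------------------------------------------------------------------
# object-level dataset (pedigree + genotype matrix + writers)


@dataclass
class SimulatedDataset:
    individuals: list[Individual]
    gm: GenotypeMatrix
    truth: SimTruth
    arrays: FamilyArrays


def _null_variant_doses(
    config: SimConfig, truth: SimTruth, present: np.ndarray, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Extra markers independent of affection: fresh parental genotypes at
    the family's subpopulation frequency, Mendelian transmission."""
    out = []
    n, smax = present.shape
    maf = np.asarray(config.maf)
    for _ in range(config.n_null_variants):
        fd = rng.binomial(2, maf[truth.subpop]).astype(np.int8)
        md = rng.binomial(2, maf[truth.subpop]).astype(np.int8)
        dose = _transmit(np.repeat(fd[:, None], smax, axis=1), rng) + _transmit(
            np.repeat(md[:, None], smax, axis=1), rng
        )
        out.append((fd, md, np.where(present, dose, -1).astype(np.int8)))
    return out


def simulate_families(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedDataset:
    """Simulate one ascertained cohort.

    Returns the pedigree (parents carry unknown phenotype), the dosage
    matrix over one causal variant plus ``n_null_variants`` independent
    null markers, and the generative truth.  Masked parents appear in the
    pedigree but with missing genotypes, as in the cohorts this emulates.
    Deterministic for a fixed ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fam, truth = _draw_replicate(config, rng)
    extra = _null_variant_doses(config, truth, fam.present, rng)
    fam, n_flips = _inject_errors_arrays(
        fam, config.error_rate_male, config.error_rate_female, rng
    )
    truth.n_error_flips = n_flips

    individuals: list[Individual] = []
    samples: list[str] = []
    variant_rows: list[list[int]] = [[] for _ in range(1 + len(extra))]
    for i in range(config.n_families):
        famid = f"F{i + 1:04d}"
        dad, mom = f"{famid}_dad", f"{famid}_mom"
        for pid, sex, observed, causal_d in (
            (dad, "male", truth.father_observed[i], int(fam.father[i])),
            (mom, "female", truth.mother_observed[i], int(fam.mother[i])),
        ):
            individuals.append(
                Individual(
                    person_id=pid,
                    family_id=famid,
                    father_id=None,
                    mother_id=None,
                    sex=sex,
                    affection="missing",
                )
            )
            # an unsequenced parent exists in the pedigree but is not a
            # genotype sample, as in the cohorts this emulates
            if observed:
                samples.append(pid)
                variant_rows[0].append(causal_d)
                for vj, (fd, md, _) in enumerate(extra, start=1):
                    variant_rows[vj].append(int((fd if pid == dad else md)[i]))
        for j in range(int(fam.present[i].sum())):
            pid = f"{famid}_kid{j + 1}"
            individuals.append(
                Individual(
                    person_id=pid,
                    family_id=famid,
                    father_id=dad,
                    mother_id=mom,
                    sex="female" if fam.female[i, j] else "male",
                    affection="affected" if fam.affected[i, j] else "unaffected",
                )
            )
            samples.append(pid)
            variant_rows[0].append(int(fam.dose[i, j]))
            for vj, (_, _, dd) in enumerate(extra, start=1):
                variant_rows[vj].append(int(dd[i, j]))

    variants = [
        VariantRecord(
            chrom="1",
            pos=100_000 + 10_000 * vj,
            var_id=f"sim{vj}",
            ref="A",
            alt="G",
            filter_pass=True,
        )
        for vj in range(1 + len(extra))
    ]
    gm = GenotypeMatrix(
        variants=variants,
        samples=samples,
        dosage=np.array(variant_rows, dtype=np.int8),
    )
    return SimulatedDataset(individuals=individuals, gm=gm, truth=truth, arrays=fam)


def inject_sex_differential_errors(
    gm: GenotypeMatrix,
    individuals: Sequence[Individual],
    e_m: float,
    e_f: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, int]:
    """Perturb each genotype independently at a sex-specific rate.

    Hets become a random homozygote, homozygotes become het; missing
    genotypes are untouched.  Returns the perturbed matrix and the
    realised number of flips.
    """
    rng = np.random.default_rng(seed)
    sex_by_id = {ind.person_id: ind.sex for ind in individuals}
    rate = np.array(
        [
            {"male": e_m, "female": e_f}.get(sex_by_id.get(s, "unknown"), 0.0)
            for s in gm.samples
        ]
    )
    flip = rng.random(gm.dosage.shape) < rate[None, :]
    dose = _flip_genotypes(gm.dosage, flip, rng)
    n_flips = int((dose != gm.dosage).sum())
    return GenotypeMatrix(variants=gm.variants, samples=gm.samples, dosage=dose), n_flips


# ---------------------------------------------------------------------------
# standard-format writers (round-trip tested against pedio readers)

PED_SEX = {"male": "1", "female": "2", "unknown": "0"}
PED_AFF = {"affected": "2", "unaffected": "1", "missing": "0"}
_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_ped(individuals: Sequence[Individual], path: str) -> None:
    with open(path, "w") as fh:
        for ind in individuals:
            fh.write(
                " ".join(
                    [
                        ind.family_id,
                        ind.person_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        PED_SEX[ind.sex],
                        PED_AFF[ind.affection],
                    ]
                )
                + "\n"
            )


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    contigs = sorted({v.chrom for v in gm.variants}, key=lambda c: (len(c), c))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fbatscan-simdata\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for vi, v in enumerate(gm.variants):
            gts = "\t".join(_GT[int(d)] for d in gm.dosage[vi])
            filt = "PASS" if v.filter_pass else "q10"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.var_id}\t{v.ref}\t{v.alt}\t.\t{filt}\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Monte-Carlo experiment drivers


@dataclass
class ExperimentResult:
    alpha: float
    n_reps: int
    rejection_rate: dict[str, float]
    mc_se: dict[str, float]
    n_valid: dict[str, int]
    pvalues: dict[str, np.ndarray]


def _run_replicates(
    config: SimConfig,
    n_reps: int,
    seed: int,
    tests: tuple[str, ...],
    mu: float = 0.15,
    min_informative: int = 10,
) -> dict[str, np.ndarray]:
    pvals = {t: np.full(n_reps, np.nan) for t in tests}
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        fam, _ = _draw_replicate(config, rng)
        fam, _ = _inject_errors_arrays(
            fam, config.error_rate_male, config.error_rate_female, rng
        )
        res = score_tests(fam, mu=mu, min_informative=min_informative, tests=tests)
        for t in tests:
            pvals[t][r] = res[t][1]
    return pvals


def type1_error_experiment(
    config: SimConfig,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    tests: tuple[str, ...] = ("sex_inter", "joint", "male_only", "female_only"),
    mu: float = 0.15,
    min_informative: int = 10,
) -> ExperimentResult:
    """Empirical rejection rate of each test under repeated simulation.

    With null effects this estimates the type-I error; the Monte-Carlo
    standard error is sqrt(alpha (1 - alpha) / n_valid).
    """
    pvals = _run_replicates(config, n_reps, seed, tests, mu, min_informative)
    rates, ses, nval = {}, {}, {}
    for t in tests:
        ok = ~np.isnan(pvals[t])
        n = int(ok.sum())
        nval[t] = n
        rates[t] = float((pvals[t][ok] < alpha).mean()) if n else math.nan
        ses[t] = math.sqrt(alpha * (1 - alpha) / n) if n else math.nan
    return ExperimentResult(
        alpha=alpha, n_reps=n_reps, rejection_rate=rates, mc_se=ses, n_valid=nval, pvalues=pvals
    )


def power_experiment(
    configs: dict[str, SimConfig],
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    tests: tuple[str, ...] = ("sex_inter", "main"),
    mu: float = 0.15,
    min_informative: int = 10,
) -> dict[str, ExperimentResult]:
    """Rejection rates per (scenario, test) on non-null configurations.

    The ``main`` test here is the 1-df score test under the main-effect
    coding T = Y - mu, the natural comparator for the interaction coding.
    """
    out = {}
    for i, (name, cfg) in enumerate(configs.items()):
        out[name] = type1_error_experiment(
            cfg, n_reps=n_reps, alpha=alpha, seed=seed + i, tests=tests,
            mu=mu, min_informative=min_informative,
        )
    return out
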