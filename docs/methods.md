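# Methods

## The testing problem

`fbatscan` implements sex-specific family-based association tests (FBATs)
for a dichotomous, late-onset disease studied in multiplex nuclear
families — sibships ascertained for at least one affected member, with
most parental genotypes unobserved. The score statistic is

    U = Σ_i Σ_j  T_ij ( X_ij − E[X_ij | S_i] )

over families *i* and offspring *j*, where `X_ij ∈ {0,1,2}` counts copies
of the alternate allele and `S_i` is the family's sufficient statistic
for the unobserved parental genotypes. Because the offspring-genotype
distribution conditional on `S_i` is determined by Mendelian transmission
alone, the test is valid under arbitrary population structure and
phenotype-model misspecification; those only affect power.

### Trait codings

All codings are affected-only: unaffected or phenotype-missing siblings
get `T = 0` but their genotypes still enter `S_i`. With offset `μ`
(default 0.15, chosen near the disease prevalence so affected offspring
carry weight `1 − μ`):

| coding       | T for an affected offspring        | use |
|--------------|------------------------------------|-----|
| `main`       | `Y − μ`                            | main genetic effect (T1) |
| `sex_inter`  | `(Y − μ)(Z − 0.5)`, Z = 0 male / 1 female | sex × genotype interaction (T2) |
| `male_only` / `female_only` | `Y − μ` for that sex, else 0 | effect direction per sex |

The interaction coding gives males weight `−0.425` and females `+0.425`
(at μ = 0.15), so it is maximally sensitive when the allele's effect has
opposite directions in the two sexes, and nearly blind to a shared main
effect. The joint test applies the multivariate FBAT-GEE chi-square to
the bivariate score over (`main`, `sex_inter`): `χ² = Uᵀ V⁻ U` with
`V = Σ_i cov_i`, a Moore–Penrose inverse, and df equal to the numerical
rank of `V` (tolerance: machine epsilon × dimension × largest
eigenvalue). When one coding is degenerate — e.g. a single-sex cohort —
the statistic collapses exactly to the 1-df squared Z of the other
coding.

## Conditioning on the sufficient statistic

For each nuclear family and variant, offspring with missing genotype are
dropped (the observed members define `S_i`) and the conditional law of
the observed configuration is built at the coarsest level that provably
removes the parental-genotype nuisance:

1. **Parental** — both parents genotyped: offspring are i.i.d. Mendelian
   given the parents.
2. **Identified mating** — exactly one parental mating is compatible with
   the observed data. The mating is known only because the data exclude
   every alternative, so the conditioning event is "the configuration
   identifies this mating": the i.i.d. Mendelian measure restricted to
   configurations whose own compatible-mating set is the same singleton,
   renormalised. (Using the unrestricted i.i.d. law here understates the
   conditional variance — for opposite-homozygote sibs the true
   conditional variance per sib is 1, the i.i.d. table says 0.5 — and
   measurably inflates type-I error.)
3. **Distinct set** — several matings compatible: condition on the set of
   distinct offspring genotypes, accepted only if the induced law is
   identical (within 1e-12) under every compatible mating; this identity
   is asserted at run time.
4. **Permutation** — otherwise condition on the observed multiset:
   uniform over its distinct orderings, valid under any mating by
   exchangeability.
5. **Degenerate** — a single admissible configuration: zero variance,
   the family is non-informative.

Moments are computed exactly by enumeration (all probabilities are dyadic
rationals, so the arithmetic is exact in floating point up to
normalisation). A family is informative when its conditional variance
under the chosen coding is positive; variants report results only when at
least `min_informative` (default 10) families are informative. A family
whose genotypes admit no Mendelian mating at a variant is skipped for
that variant and logged.

The test suite verifies the whole construction against an independent
brute-force oracle: for every parent pattern and every offspring
configuration up to sibship 4, the conditional law is recomputed by
direct summation of the mixture over matings under several random
parental-genotype priors, checking both nuisance-freeness and agreement
of all moments to 1e-12.

## Quality control

The variant QC cascade consists of pure per-variant predicates, so the
kept set is order-independent: FILTER must be PASS; multiallelic,
monomorphic, singleton (exactly one alternate allele in the dataset) and
indel sites are dropped; any half-called genotype (one missing allele of
two) excludes the variant rather than masking the genotype; call rate
must be ≥ 95% of the retained samples; Mendelian inconsistencies drop the
variant at the first error (configurable), checked in trios and
optionally in single-parent duos (discordant homozygotes); and two
list-based exclusions — a site whitelist (e.g. an external call-set) and
BED regions (e.g. genes with X/Y pseudogenes, where mismapped
sex-chromosome reads cause sex-differential genotype errors). BED
intervals are 0-based half-open and converted to VCF 1-based positions
once, at the filter boundary.

## Synthetic cohorts

The generator emulates the structure of ascertained family cohorts, not
any particular dataset:

| parameter | default | rationale |
|-----------|---------|-----------|
| sibship size | uniform on {2, 3, 4} | mixed multiplex sibships |
| causal MAF | 0.30 | a common variant, typical of reportable family-study loci |
| prevalence | 0.15 | matches the trait offset μ |
| disease model | logit P(aff) = logit(prev) + β_sex·dosage | minimal model allowing opposite-direction sex effects |
| ascertainment | ≥ 1 affected offspring (rejection sampling) | multiplex ascertainment |
| parental genotypes | 90% unsequenced (absent from the VCF, present in the PED) | late-onset disease cohorts |
| sex | Bernoulli(1/2) | balanced sex ratio |
| subpopulations | 1 (optionally several with own MAF/prevalence) | stratification experiments |
| genotype error | sex-specific rate; het→random homozygote, homozygote→het | X/Y-homology mismapping artefact, without modelling reads |

Families are drawn by vectorised rejection sampling; an acceptance
probability below 1e-4 raises an error rather than looping. Parents'
genotypes are Hardy–Weinberg at their subpopulation frequency and
offspring follow Mendelian transmission, so generated data are
Mendel-consistent before error injection (tested). Additional null
markers are simulated independently of affection (no linkage
disequilibrium between markers is modelled). A single master seed drives
per-replicate substreams (`numpy` SeedSequence spawning), so experiments
are reproducible and order-independent.

What the generator does not emulate: age-at-onset and censoring,
relatedness beyond nuclear units, LD, genotype-calling error modes other
than the symmetric flip model, and real ascertainment subtleties (e.g.
excluding carriers of known strong risk alleles). Calibration and power
results on these cohorts therefore demonstrate the statistical properties
of the tests under the stated generative model, not performance on any
real dataset.

## Monte-Carlo experiments

Replicated experiments run on a vectorised engine that tabulates the
exact conditional moments for every (parent slots × offspring multiset)
pattern up to the maximum sibship — valid because at every
non-degenerate level the offspring are exchangeable, so the mean is a
scalar and the covariance compound-symmetric. The engine is asserted to
reproduce the object-level scan exactly (statistics, p-values,
informative counts), including after error injection creates Mendelian
impossibilities.

Problem sizes: null calibration uses 10,000 replicates of 500-family
cohorts; the FBAT-GEE null comparison 5,000 replicates; power orderings
1,000 replicates per scenario. The genotype-error inflation experiment
uses 5,000-family cohorts: the male-only error rate e_m = 0.02 induces a
per-family score bias of order 0.01 SD, which accumulates as √n, so a
larger cohort makes the inflation unambiguous at 5,000 replicates while
the equal-error control stays at the nominal level.

## Numerical and design notes

- Probabilities are normalised and cross-checked to 1e-12; conditional
  moments are enumerated, never sampled.
- Two-sided p-values for Z tests; the sign of Z refers to the alternate
  allele of the tested variant (the output table also reports both
  alleles so the minor-allele direction can be read off).
- p-values are floored at the smallest positive double and capped at 1.
- Extended pedigrees are decomposed into all nuclear (two-parent-slot)
  units; each unit contributes independently to U. An individual may be
  offspring in one unit and parent in another; each role is treated
  independently.
- Genotyping-rate denominators use the retained-sample set.
- Significance tiers use fixed thresholds (5e-8 genome-wide, 5e-6
  suggestive) and the known-locus lookup uses ±500 kb with nominal
  p ≤ 0.05; no multiplicity correction beyond these fixed thresholds.
- Nearest-anchor ties in the lookup break to the smaller distance, then
  the lower anchor position.

## Known limitations

- Autosomal biallelic SNVs only; chrX/Y/M rows are dropped on load.
- No haplotype or multi-marker tests; variants are tested marginally.
- The offset μ is a global scalar; no covariate model for the trait.
- Whether the identified-mating/distinct-set/permutation hierarchy
  coincides with the conditioning tables of other FBAT implementations in
  every one-observed-parent corner case has not been established here;
  validity (conditional mean zero, correct variance) is guaranteed at
  every level by construction and verified by the oracle suite, but power
  may differ slightly from other tools in those cases.
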