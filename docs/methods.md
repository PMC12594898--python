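# Methods

## Score computation and harmonization

The raw score is the weighted effect-allele count `PRS_i = Σ_j d_ij w_j`
with weights on the natural-log odds scale; weight files that carry an `OR`
column are converted by `w = ln(OR)` at load time. Genotypes enter either
as hard GT calls from a VCF (dosage = count of the first ALT allele;
`./.` and multi-allelic calls become missing) or as a TSV dosage matrix
with a companion variant-info table.

Harmonization classifies each score variant against the panel by comparing
allele labels under the four possible orientations. Two conventions matter:

- **Palindromic (A/T, C/G) score variants are dropped.** For these pairs a
  strand flip is indistinguishable from an allele swap without population
  frequencies, and frequency-based resolution is deliberately out of scope.
- **Irreconcilable allele labels are also filed under `ambiguous_dropped`**
  rather than a separate status: in both situations the orientation cannot
  be resolved, and keeping one bucket keeps the status set a partition of
  the score file.

Variants classified `matched`, `allele_swapped` (dosage complemented as
`2 − d`) or `strand_flipped` contribute to scores. The default missing-data
policy is **skip**: a sample's sum simply omits variants with missing
dosage and `n_variants_used` records how many contributed. This mirrors
scoring on the markers actually available in a panel (e.g. 307 of 313)
instead of imputing the absent ones; `mean_dosage` substitution is
available when equal `n_variants_used` across samples matters more.
Standardization is `(raw − mean)/sd` with the n−1 denominator over a
reference set, by default all scored samples; a controls-only reference is
a caller choice.

## Kinship, degree, and pair groups

Kinship uses the classical recursion with outbred founders:
φ(a,a) = ½(1 + φ(father, mother)), φ(a,b) = ½[φ(f_a,b) + φ(m_a,b)]
recursing on the later-generation member, founders pairwise unrelated.
Relationship **degree is classified by path type, not by the kinship
value** — parent/offspring and full siblings are first degree;
grandparent/grandchild, half-siblings and (full-sibling-of-parent)
aunt–niece pairs are second; any other pair with positive kinship is
third-plus — so inbreeding can never promote a pair into a closer class.
A parent's half-sibling therefore classifies as third-plus, not as an
aunt.

Pair enumeration pairs every affected female with each eligible unaffected
female relative of the requested group, so a case recurs once per
relative and a relative may serve several cases. "Total relatives" means
any positive-kinship female relative; spouses and other marriage links
have zero kinship and never pair. Individuals of unknown affection are
excluded from both sides. Pairs lacking a PRS z-score are dropped and
counted. A `deduplicate_relatives` flag restricts each relative to one
case for sensitivity analysis of relative re-use.

## Signed-rank inference

Zero differences are dropped before ranking and |differences| receive
midranks. W is the **smaller** of the two rank sums, so Z = (W − n(n+1)/4)
/ √(n(n+1)(2n+1)/24) is always ≤ 0 and p = 2Φ(Z); the `direction` field
records which side dominated. No tie correction is applied to sd(W) by
default — PRS differences are continuous, so exact ties have measure zero,
and the uncorrected variance matches the arithmetic of the common online
calculators this module is designed to audit — but a flag enables the
standard Σ(t³−t)/48 correction. The α-level critical interval for W is
`mean ± z_{1−α/2}·sd` rounded half-away-from-zero to integers. The normal
approximation is used at every n; an exact sign-flip enumeration (dynamic
programming over doubled midranks, n ≤ 20) is exposed purely as a testing
oracle. `wilcoxon_from_summary(n, W)` recomputes Z, p and the interval
from a published (N, W) pair for auditing printed tables.

Published tables of this kind can disagree with the nearest-integer
convention by one unit in one row while matching it exactly in another;
this implementation fixes the convention above and does not special-case
individual rows.

## Cohort arm

Selection applies the exclusion cascade in its stated order (males;
incomplete genetic or phenotypic records; controls with personal or family
history; one control per family) and tallies removals per criterion. The
one-per-family tie-break keeps the **oldest** eligible member —
an older unaffected woman has survived more risk-years unaffected, making
her the most informative control — with a seeded random alternative. Note
an interaction worth knowing when reading outputs: under age-dependent
risk this rule makes the selected controls systematically old, so the age
AUC of the *selected* sample can fall below 0.5 even though risk rises
with age in the full cohort.

The logistic fit is plain maximum likelihood (IRLS); non-convergence,
infinite estimates and (quasi-)perfect separation raise a dedicated
`SeparationError`. Confidence intervals are Wald on the log-odds scale.
AUC is the Mann–Whitney pair statistic with half-credit ties, computed
from ranks. The joint model enters age linearly on the liability of the
logit; rank-deficient designs are rejected.

## Monogenic arm

`build_pathogenic_set` intersects (default, `shared`) or unions
candidate-gene loss-of-function evidence with clinical pathogenic
assertions. The LOF consequence set is fixed to {stop_gained, frameshift,
splice_donor, splice_acceptor, start_lost}. Carrier status uses hard
calls only: dosage 1 = heterozygous, 2 = homozygous; allele frequency is
recomputed as (het + 2·hom)/(2·n_called). Flagged variants absent from the
panel are reported, never fatal.

## The simulator: what it emulates, and what it does not

`simdata` generates three-generation families — founder couple, their
children (each founding a branch with a married-in spouse with probability
0.8), grandchildren — with generation-band ages (70±8, 47±6, 25±5 years)
and at least one daughter per sibship so all female relative classes are
populated. Unlinked biallelic variants are dropped from Hardy–Weinberg
founders, one uniformly chosen allele per parent per child. Disease is
assigned to females by the liability threshold `L > Φ⁻¹(1 − K)` with
`Var(L) = 1`.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_families` | 200 | a desk-scale family cohort (~1,900 individuals) |
| `target_prevalence` | 0.0122 | female breast-cancer prevalence of the emulated cohort (1.22%) |
| `or_per_sd` | 1.24 | the reported per-SD odds ratio; converted to the liability slope b₁ ≈ 0.087 by `liability_slope_for_or` (root search against logistic fits on one large common-random-number sample) |
| `beta_age` | 0.3 | risk accrues with age; produces older cases, echoing the case/control age gap of the emulated cohort |
| `weight_sd` | 0.05 | centered-normal weights with magnitudes typical of GWAS per-allele log-ORs; a real weight file can be supplied instead |
| `n_prs_variants` | 313 | the size of the score the pipeline is built around |
| `n_lof_variants`, `lof_freq_range` | 21, (0.00037, 0.026) | the reported count and frequency band of rare LOF variants |
| `shared_env_sd` | 0.0 | optional per-family shared-environment liability component; no anchored default exists, so it is off |

Deliberate non-features, hence what passing tests do **not** show about
real data: no linkage disequilibrium (the unit of analysis is the
score, not haplotypes), no ascertainment or clinical-referral modeling, no
age-of-onset hazard (affected women get `age_at_onset` equal to their
recorded age — the cohort is a retrospective snapshot), sexes and
sibships independent of genotype, and genotyping error absent. Allele
pairs for simulated variants are drawn from non-palindromic combinations
so harmonization never has to drop simulated markers.

## Calibration experiments

- **Prevalence**: 200,000 pure-noise liabilities at K = 0.0122; the
  affected fraction must sit within 3 binomial standard errors of 1.22%.
- **Effect recovery**: 500 case–control cohorts of 72 cases / 2,603
  controls drawn from a logistic model with true per-SD OR 1.24
  (retrospective sampling preserves the OR); the mean fitted OR must match
  within Monte-Carlo error. Averaging ORs rather than log-ORs carries a
  small Jensen term (≈ +0.01 at this case count), which the tolerance
  accounts for.
- **Type-I error**: 2,000 replicates of a 120-family cohort with b₁ = 0
  and prevalence raised to 0.15 (purely to populate the pair groups; the
  null is the zero slope, not the prevalence). Each replicate keeps **one
  pair per family**, because the signed-rank test assumes independent
  pairs: when one case contributes several relatives (or one relative
  several cases) the differences share a member and are positively
  correlated, which inflates Var(W) relative to the null model. The
  full enumeration with repetition — the design the pipeline reports for
  descriptive comparison groups — therefore does not carry a guaranteed
  nominal level; this is a known property of the paired design with
  relative re-use, and the deduplication flag exists for exactly this
  sensitivity analysis.

Problem sizes throughout the test suite (families per cohort, replicate
counts, variant counts) are chosen as the smallest that make the binomial
or Monte-Carlo error bands decisive for the property under test.

## Numerical conventions

Rounding of critical bounds is half-away-from-zero. Standardization and
sd(W) use exact closed forms, not simulation. The logistic slope search
brackets b₁ in [10⁻⁴, 0.8] with xtol 10⁻⁴ under common random numbers,
which makes the objective continuous and monotone in b₁. Kinship values
are cached per pedigree and invalidated when members are added. Seeds:
every stochastic routine takes a `numpy.random.Generator` or an integer
seed; identical config + seed reproduces pedigree, panel and roster
bit-for-bit.
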