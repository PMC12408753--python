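# Methods

## The problem and the approach

`burdenscan` asks a population-scale question about a quantitative blood
phenotype (LDL-C, mmol/L): for each gene, do the individuals carrying the
*highest* pathogenic variant burden in that gene have systematically
different LDL-C from the individuals carrying the *lowest* burden? Unlike
per-variant association testing, the unit of inference is the whole gene,
and the burden score deliberately pools common and rare deleterious
variation into one number per gene per person.

The pipeline has five stages, each a module:

1. **variant_qc** — call- and site-level filters on multi-sample VCF calls.
2. **genepy** — per-gene, per-participant burden scores from the surviving
   variants, plus gene-set refinement.
3. **cohort** — phenotype selection, medication and relatedness exclusions,
   age/sex stratification.
4. **scan** — the extreme-percentile bootstrap Mann–Whitney statistic with
   Benjamini–Hochberg FDR.
5. **enrichment** — hypergeometric over-representation of the significant
   genes in user-supplied gene sets.

A sixth module, **synthetic**, generates complete cohorts with known truth
so every downstream stage is testable without restricted data.

## Burden score

For a variant with deleteriousness weight `D` and population alternate
allele frequency `f`, a carrier contributes

| zygosity         | contribution              |
|------------------|---------------------------|
| heterozygous     | `D · (−log10((1−f)·f))`    |
| homozygous alt   | `D · (−log10(f²))`         |
| hemizygous alt   | `D · (−log10(f))`          |

and a gene's score for a participant is the sum over that participant's
qualifying variants. `D = CADD-Phred / normaliser`, clipped to [0,1]; the
normaliser defaults to 100, the practical ceiling of the Phred scale. An
optional switch multiplies the heterozygous product by 2 (the full
Hardy–Weinberg genotype probability `2f(1−f)`); it defaults off and only
shifts heterozygous scores by a constant `D·log10(2)`. The per-variant form
is a deliberate config-level choice: the published score family is defined
by "deleteriousness × −log10(observed-allele-frequency product)", and both
knobs that are not pinned down in print (the normaliser, the factor 2) are
explicit parameters.

Scores are non-negative, additive over variants, strictly increasing in
`D`, strictly decreasing in `f`, and zero exactly for participants with no
QC-passing alternate allele in the gene — all property-tested.

**Missing population frequencies.** `−log10` requires `f ∈ (0,1)`. Variants
absent from the frequency resource fall back, by default, to the
within-cohort alternate-allele frequency; a second policy assigns the floor
directly. Either way `f` is clipped to `[af_floor, 1−af_floor]` with
`af_floor = 1e-6` (roughly one allele in a 500k-person panel).

**Hemizygosity.** Males on chrX are scored as a single observed allele
(`−log10 f`), regardless of how the caller encoded the genotype; X-linked
genes are analysed separately per sex downstream, so het/hom conventions
for male X calls never mix sexes within one test.

## Quality control

Call level: heterozygous calls need depth `DP ≥ 8` **and** allelic balance
`AB = alt_depth/DP ≥ 0.15`; other alternate-carrying calls (hom-alt,
hemizygous-alt) are subject to the depth rule only, because the balance
rule is defined for heterozygotes; hom-ref calls are always retained.
Failing calls are set to missing, and the operation is idempotent.

Site level, in order:

- `F_MISSING < 0.12` (strict), computed **after** call-level nulling — the
  order is implicit in the source pipeline, and post-nulling is the
  interpretation that makes the threshold sensitive to genotype quality;
- exact Hardy–Weinberg test `p > 0.05 / m`, where the Bonferroni
  denominator `m` is the number of sites entering the HWE stage in the
  current run (no external denominator is defined anywhere);
- `CADD-Phred ≥ 20` (unannotated variants fail).

The HWE test is the conditional exact test (sum of probabilities of all
heterozygote counts no more probable than observed, given the minor-allele
count), computed in log space with `gammaln`; it matches a rational-
arithmetic full enumeration to 1e-12 for n ≤ 50. HWE is evaluated on
diploid genotypes only — on chrX, on females only — since hemizygotes
violate the diploid sampling model.

Every stage appends to a conservation-checked ledger
(`removed + retained = previous retained`).

## Cohort assembly

Per participant, the earliest reproducible LDL-C measurement is selected;
participants with none are excluded. Age at assay is `assay calendar year −
birth year` (whole years), matching how the fields are recorded. The
exclusion cascade is fixed — sequencing availability, LDL-C availability,
relatedness, medication — so ledgers are comparable across runs.

Relatedness pruning generalises the pairwise rule to families: build the
graph over pairs of degree ≤ 3, and within each connected component keep
exactly the youngest member (missing ages count as oldest; ties break to
the lexicographically smallest id). Keeping the youngest preserves the
participants whose measurements are least age-confounded.

Medication handling: participants on LDL-altering drugs are excluded;
participants with *no* medication data are merged into the not-on-drug
group only if a two-sample Kolmogorov–Smirnov test cannot distinguish the
two LDL-C distributions (α = 0.05 — the source analysis reports the merge
at p = 0.29 without naming a level). A Shapiro–Wilk normality check is
reported as a diagnostic only (subsampled to 5,000 with a seeded RNG for
larger cohorts); it never gates anything.

Strata: measurements taken at age < 60 vs ≥ 60, analysed separately and
combined; participants with unknown age enter only the combined analysis.

## The scan statistic

Per gene and stratum, participants are ranked by ascending burden score
into `n_bins = 100` near-equal bins (`floor(i·n_bins/n)` over sorted
positions handles `n` not divisible by `n_bins`; bin sizes differ by at
most one). The lowest and highest bins are compared on LDL-C with a
two-sided Mann–Whitney U test — two-sided because both LDL-raising and
LDL-lowering genes are real signals. Zero-score members are removed from
the *top* bin only (a zero in the top bin means the gene cannot fill 1% of
the cohort with carriers); the bottom bin keeps zeros, as only the top bin
is screened in the source procedure.

Because burden matrices are sparse, the bottom of the ranking is a sea of
exact zeros and bin membership among ties is arbitrary. The ranking is
therefore repeated `n_iterations = 1000` times with a fresh uniform
tie-break each time — equivalent to "shuffle, then stable-sort" — and the
mean and SD of the per-iteration p-values are recorded. The implementation
never materialises the full sort per iteration: membership of each extreme
bin is `{strictly below/above the boundary value} ∪ {r members of the
boundary tie block with the smallest/largest tie-break keys}`, which is
exactly the stable sort's behaviour; a literal per-iteration sort path is
kept and the two are bitwise-equivalence-tested on shared RNG streams.
When no ties straddle either bin boundary the assignment is
tie-break-invariant, so one pass is computed and `sd_p = 0` (tested equal
to the full loop).

Mann–Whitney p-values use the exact null distribution when both groups
have ≤ 8 members and no ties, otherwise the normal approximation with tie
and continuity corrections; the batched inner-loop implementation matches
scipy's asymptotic path to 1e-12 and the exact path matches full
enumeration to 1e-10. Iterations with a group below `min_group_size = 2`
are invalid; genes with no valid iterations are reported untestable and
excluded from FDR.

Per-gene RNG substreams are derived from `(master seed, CRC32(gene
symbol))`, so results are reproducible and independent of gene order.

Mean p-values are adjusted with Benjamini–Hochberg within each analysis
family — one family per (stratum × chromosome class × sex analysis), since
autosomal and X-linked results are reported separately and X genes are
tested per sex. Significance is `FDR-adjusted p < 0.01`.

### Null behaviour of the mean bootstrap p

The bootstrap mean is **conservative under the null for sparse genes**:
each iteration's low bin is a fresh random sample from the zero-score
pool, so the per-iteration p-values are nearly independent draws and their
mean concentrates near its expectation (≈ 0.5 for a null gene) instead of
being uniform. Measured on a 500-gene null cohort (n = 2,000, 100
iterations), the fraction of genes with mean p < 0.05 is 0 — far *below*
0.05 — while the tie-free path (dense genes, where the mean degenerates to
a single p) is exactly calibrated (5.25% below 0.05 over 400 runs). The
practical consequence is protective: averaging over arbitrary tie
assignments suppresses false positives; the cost is power for genes whose
signal rides on a small carrier set. FDR control on null data is clean (no
significant genes at 0.01 across seeds).

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:

- **Genotypes** drawn under Hardy–Weinberg at each variant's frequency;
  allele frequencies log-uniform over [1e-5, 0.5] (rare-variant-dominated,
  as in exome data); CADD-Phred uniform over [0, 50]; males on chrX carry
  one allele. Optional HWE violators (excess homozygosity) exercise the
  HWE filter.
- **Read depths** Poisson(30); heterozygous calls are constructed to pass
  the DP/AB thresholds except for a designated fraction (default 2%)
  forced to fail one of them, so QC removal counts are exactly known. A
  small fraction of sites (1%) gets elevated missingness to exercise the
  F_MISSING filter.
- **Phenotype**: `LDL = 3.7 + 0.02·(age − 57) + Σ planted effects +
  (−0.9)·on_drug + N(0, 0.8)` mmol/L, floored at 0.3. Baseline, spread and
  the medication shift mirror the published cohort's descriptive
  statistics (means 3.70 vs 2.79 mmol/L, SD ≈ 0.8); the age slope is a
  mild positive trend of the size reported for adult cohorts. Ages are
  uniform over 40–70 with the assay year drawn in 2006–2010, so the
  pipeline's year-arithmetic age derivation is exercised.
- **Medication**: 16% of participants on an LDL-altering drug, 28% with no
  medication data (the published cohort's proportions).
- **Relatives**: a configurable fraction of pairs created by duplicating
  one participant's genotypes with a few reversions; ages are forced to
  differ so "retain youngest" is decidable.
- **Planted effects**: a planted gene's variants are given CADD ≥ 25 and
  frequencies tuned so the HWE carrier probability is ~1.5% of the cohort;
  carriers (≥ 1 alternate allele in a CADD ≥ 20 variant of the gene) get
  the configured LDL shift. The truth table records carriers per gene.

What the generator does **not** emulate: linkage disequilibrium and
haplotype phase, sequencing-error structure beyond the DP/AB perturbation,
population stratification, ancestry structure, or any realistic
gene-length/constraint distribution. Passing tests therefore demonstrate
the statistical machinery — calibration, power against planted
percentile-scale effects, bookkeeping — not robustness to confounding in
real biobank data.

## Problem sizes and numerical choices

Calibration studies run at desk scale, chosen so each completes in minutes
on one core: the null study uses 500 genes × 2,000 participants × 100
iterations across 20 seeds; the recovery study uses 200 genes × 10,000
participants × 1,000 iterations across 20 seeds (one +1.5 mmol/L gene,
~1.5% carriers). The analysis drivers use a 150-gene, 4,000-participant
cohort with 50 bins and 200 iterations, keeping every extreme bin at ~2%
of the cohort.

Other numerical conventions: HWE tie comparison uses a 1e-9 log-space
slack so exactly-tied configurations are always included; identical
multisets in the Mann–Whitney test return p = 1 (zero-variance guard); the
SD over bootstrap iterations is the population SD of the recorded
p-values; BH adjustment goes through `statsmodels.multipletests`.

## Enrichment

One-sided hypergeometric tail per gene set against the background of genes
actually tested in the corresponding scan (not the whole genome — the
correct universe for over-representation), BH-adjusted across sets. The
combined score is `−ln(p)·z` with `z` the hypergeometric z-score of the
overlap. Service-based enrichment tools derive `z` from rank deviations
over random gene sets, a stochastic server-side quantity; the
deterministic `z` keeps output reproducible offline, and printed scores
from such services are not expected to match. Interaction-network analysis
itself is out of scope; the pipeline exports the deduplicated significant
gene list for external tools.

## Known limitations

- Scores are unphased composites of both parental haplotypes; compound-
  heterozygosity cannot be distinguished from two carriers.
- The per-variant score form and its normaliser are reconstructions,
  exposed as configuration rather than fixed constants.
- The mean-bootstrap-p statistic is conservative for sparse genes (see
  above); genes impacting well under 1% of the cohort are structurally
  hard to detect with percentile bins.
- No covariate adjustment is performed anywhere (by design — the source
  procedure performs none); age confounding is handled only by
  stratification at 60 years.
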