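# Methods

## The scan model

The pipeline assumes an inbred (fully homozygous) strain panel genotyped at
bi-allelic SNPs, coded 0 (homozygous reference), 1 (homozygous alternate)
or missing. Heterozygous calls are treated as missing rather than as a
third allele: in an inbred panel they are almost certainly genotyping
noise, and inventing a heterozygote class would distort the haplotype
grouping. Multi-allelic and non-SNP VCF records are skipped (not split),
because the block construction and the group coding are defined on
bi-allelic SNPs. Internal coordinates are 1-based closed (VCF-native); BED
input is converted at the boundary.

Association is a one-way fixed-effects ANOVA of per-strain trait values
grouped by the block's haplotype labels. The trait unit is the per-strain
replicate mean, so the factor is haplotype group *across strains* — the
between-strain distribution is what the scan interrogates; replicate noise
only enters through the precision of each strain mean. The effect size is
eta-squared, SSB/SST, the canonical ANOVA variance-explained measure; it
equals the R² of a one-factor linear model fit to the same data (a
cross-check in the test suite). The model assumes independent Gaussian
strain-level residuals with equal variance across groups; it applies no
correction for strain relatedness (kinship), which a real panel of related
classical strains would ideally include.

## Block construction

Blocks are built per chromosome by a deterministic greedy left-to-right
sweep: the current block absorbs the next retained SNP while (a) the number
of distinct complete strain allele-strings stays ≤ `H_max` and (b) the
block holds fewer than `max_snps` SNPs. The distinct-string count is taken
over strains with no missing call in the candidate block. This yields a
non-overlapping partition — simpler than enumerating overlapping candidate
windows of many sizes, deterministic, and sufficient for the downstream
ANOVA — at the cost of a resolution limit discussed under Limitations.

Strains with missing calls inside a block are resolved by unique-match
imputation: a strain is labelled only if exactly one observed haplotype is
consistent with all its non-missing positions, otherwise it is excluded
from that block's test. This never invents haplotypes. Labels are canonical
(the first complete strain carrying a haplotype defines the lowest unused
label), which makes outputs invariant, up to a label bijection, under
strain reordering.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `H_max` | 4 | haplotypes/block | local variation in inbred panels is limited; 4 balances block length against test df (df1 = G−1 ≤ 3 at N = 16) |
| `min_snps` | 1 | SNPs | single-SNP blocks are legitimate tests; shorter-than-min blocks are flagged, not dropped |
| `max_snps` | 30 | SNPs | caps block growth in low-diversity panels so df2 = N−G stays interpretable and spans stay local |
| `max_missing_frac` | 0.2 | fraction | SNPs missing in >20% of strains contribute more imputation ambiguity than signal |
| `alpha` | 0.001 | nominal P | the candidate threshold used for the per-timepoint significance call |
| `min_timepoints` | 3 | timepoints | recurrence across half the six-timepoint course; a single-timepoint hit is weak evidence |
| `promoter_kb` | 15 | kb | promoter window 5′ of the TSS used to tie blocks to genes (strand-aware); nearest-TSS assignment is available as an alternative |

Significance uses the nominal P against `alpha`; Benjamini–Hochberg
adjustment is provided (`benjamini_hochberg`) but off by default, since the
scan's primary output is a ranking and a nominal-threshold candidate list.
P values that underflow double precision are reported at the smallest
positive double with an exactness flag (`p_is_floor`), as is the SSW = 0
degenerate case (effect size 1). SSB = SSW = 0 (constant trait) yields
F = 0, P = 1, effect 0. Blocks failing the preconditions (fewer than two
occupied groups after dropping missing labels, or df2 < 1) are returned as
untestable results with a reason code rather than aborting the scan, and are
ordered after all testable blocks. Ranking ties are broken by larger effect
size, then genomic order, so outputs are fully deterministic.

## The synthetic panel generator

The generator emulates the study design the scan targets: 16 inbred
strains, a quantitative trait measured in triplicate at six timepoints
(0, 4, 16, 24, 48, 72 h), blocky local haplotype structure, and genotyping
noise as per-call allele flips and missing calls.

*Genotypes* follow a haplotype-mosaic model: block lengths are geometric
(mean 8 SNPs), each block carries 2–4 ancestral binary haplotypes drawn
uniformly (distinct), and each strain carries exactly one per block,
assigned uniformly. Inter-SNP spacing is geometric with mean 1 kb. This is
the simplest generator reproducing limited local variation; it has **no
linkage between adjacent blocks** (assignments are independent), no LD
decay, no coalescent genealogy, and no epistasis. Consequently a causal
signal lives only in blocks that physically contain causal SNPs — real
genomes would let neighbouring blocks tag the signal through LD, so the
simulation is conservative about mapping resolution and silent about LD
artefacts.

*Phenotypes*: at each timepoint, strain i's value is
`baseline + beta * c_i + e_i` with `e_i ~ N(0, strain_noise_sd²)`, where
`c_i` is the mean-centered integer code of strain i's haplotype group at
the causal block (zero at inactive timepoints); each replicate adds
`N(0, noise_sd²)`. Strain-level noise defaults to sd 1.0 (it sets the unit
of the trait's heritable scale) and replicate noise to sd 0.25, a
realistic ratio for a qPCR-style readout measured in triplicate; the true
replicate structure of such data is rarely published, so both are exposed
as parameters. The coefficient is derived from the requested
variance-explained fraction h² by matching expected between-group to total
sums of squares:

    beta² · Σc_i² = σ² · (h²(N−1) − (G−1)) / (1 − h²)

so the *expected* eta-squared at the true grouping equals h² at finite N
(the G−1 term absorbs the noise that group means capture by chance).
Requests at or below the null expectation (G−1)/(N−1) fall back to
beta = 0 with a warning; with zero strain noise any positive beta explains
everything, so beta = √h² is used as an arbitrary scale there. The realized
eta-squared of each simulated timepoint is recorded in the truth record.
A Monte-Carlo test (1,000 panels) confirms the mean realized fraction
matches the request.

All randomness derives from one master seed through documented stream
splitting (genotypes, phenotypes, causal-block selection), so stages are
bit-reproducible in isolation and adding a causal spec does not perturb
the genotype draw.

*Causal block selection.* By default the causal block is chosen uniformly
among true blocks with ≥ 2 occupied groups (optionally restricted to a
given occupied-group count). For end-to-end power validation the generator
can instead *plant* the causal block (`CausalSpec.block_snps`): one block
of exactly that many SNPs built on a complementary haplotype pair, so every
SNP in it is polymorphic. Planting a block longer than twice `max_snps`
guarantees the greedy partition places at least one inferred block wholly
inside it, i.e. the scan tests the causal grouping itself. This matters
because of the partition's resolution limit (below); the validation suite
uses 64 SNPs.

## What the validation runs compute, and at what size

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen to estimate each property precisely in seconds to minutes on one
CPU: oracle equivalence on 1,000 random ANOVA instances (N ≤ 20, G ≤ 5,
tolerance 1e−10 relative); null calibration on 16-strain panels of 3,000
SNPs (~340 blocks), 200 scans in the test suite (100 in the acceptance
script), checking pooled-P uniformity (KS, level 0.001) and the empirical
P < 0.05 rate against the binomial 99% CI; rank recovery on 100 panels
(variance explained 0.8, triplicates, replicate noise sd 0.5, 2% missing
calls) requiring the causal block in the top 1% in ≥ 90; and end-to-end
recurrence filtering on 1,500-SNP panels with a planted 64-SNP causal block
(≥ 90/100 recovery of a 3-of-6-timepoint gene; ≤ 10/100 false recovery of a
2-of-6 gene). Passing these shows the statistics, plumbing and filters are
correct under the generator's assumptions; it does not demonstrate power or
calibration on real panels with LD, relatedness and non-Gaussian noise.

## Design choices where the design was open

- **Greedy non-overlapping partition** instead of enumerating (possibly
  overlapping) candidate blocks of many sizes: deterministic and testable;
  recorded as a deliberate divergence from overlapping-enumeration
  variants of haplotype mapping.
- **Per-strain means as the trait unit**; an experimental replicate-level
  scan (strain nested within group) is deliberately not exposed until the
  mixed-model machinery to do it properly exists.
- **Eta-squared as "genetic effect size"**: the canonical ANOVA
  variance-explained measure; omega-squared could be added but changes no
  ranking.
- **Gene assignment convention**: gene body plus 15 kb strand-aware
  promoter window, with nearest-TSS as an alternative mode — a borrowed
  regulatory-annotation convention, since block-to-gene tying has no single
  standard.
- **Multi-category genes** are counted in every category they carry and
  flagged, rather than silently assigned to one.

## Limitations

- The greedy partition can absorb a short causal block into a wider block
  whose grouping refines the causal one (more groups, fewer residual df):
  the same signal is then tested at F(3, 12) instead of F(1, 14), which
  costs real power near strict thresholds. This is the method's resolution
  limit at small N, and the reason the end-to-end validation plants a
  long causal block; overlapping multi-scale block enumeration would
  remove it at substantial complexity.
- No kinship correction: related strains inflate the null at loci shared
  by descent. No permutation-based genome-wide thresholds; `alpha` is
  nominal and per-block.
- The generator's independence between blocks makes null calibration easier
  than on real genomes with long-range LD.
- Spearman correlations across timepoints use strain means and average
  ranks for ties; pairs with fewer than 3 shared strains are reported as
  undefined (NaN), not dropped silently.
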