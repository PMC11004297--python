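# Methods

## Scope and data model

`bcrclone` analyzes B-cell receptor (BCR) repertoires reconstructed from bulk
RNA-seq of sorted B-1a and B-1b cells from wildtype (WT) and TET2-knockout
(KO) mice. The unit record is a rearrangement: one receptor chain with V/D/J/C
gene calls, the CDR3 junction in nucleotide and amino-acid form, a
productivity flag, and a read/consensus abundance. A clone (clonotype) is the
set of rearrangements sharing one CDR3 amino-acid string; nucleotide variants
that translate identically are merged, because every downstream statistic is
keyed on the amino-acid CDR3. Heavy (IGH) and light (IGK + IGL) chains are
analyzed as separate chain classes.

Inputs are AIRR rearrangement TSVs or TRUST4 `*_report.tsv` tables plus a
sample manifest (`sample_id, genotype, subset, path`). Parsing keeps allele
suffixes (`*01`) verbatim and strips them only at analysis time, so storage is
lossless. Locus is taken from an explicit `locus` column when present, else
from the V-call prefix, else from the C-call prefix. Abundance comes from
`consensus_count`, then `duplicate_count`, else 1 (AIRR leaves the choice
open; TRUST4 reports use `count`). By default records must be productive with
a complete junction — leading cysteine, trailing tryptophan/phenylalanine, no
stop — because statistics on translated CDR3s require translatable junctions;
a flag disables the filter for users who want raw output.

## Replicated-sequence classification

Within a pooled group (all mice of one subset x genotype), each clone's
frequency is its pooled abundance divided by the group's total pooled
abundance. A clone is *replicated* when its frequency is strictly greater
than a threshold, 1% by default. The strict inequality matters at the
boundary: a clone at exactly 1% is not replicated. Pooling is
abundance-weighted across mice; per-sample statistics (unique-CDR3 counts)
are computed without pooling and feed the rank-sum comparison. The frequency
denominator is transcript abundance, not the count of distinct clonotypes; a
`weighting="clonotype"` switch is available in the usage/isotype statistics
where the choice is ambiguous in practice.

The replicated/non-replicated partition drives three outputs: the
replicated summary (unique counts on each side plus the fraction of all
transcripts covered by replicated clones), the 2x2 contingency table
(replicated vs non-replicated x WT vs KO, in unique-count or total-count
mode), and the replicated-only scope of the V-J pairing matrix.

## Statistical engines

**Exact rank-sum test.** Study designs of 4 vs 4 and 4 vs 3 mice make
asymptotic Mann-Whitney p-values meaningless, so the two-sided p is computed
by exact enumeration whenever `min(n1, n2) <= 8` and the data carry no ties.
The null distribution of U is built by dynamic programming: every
interleaving of the two groups corresponds to a nondecreasing sequence of
"how many opponents precede each observation", so the count of rank
assignments at each U value is the number of partitions of U into at most n1
parts each at most n2. Counts are exact integers; the two-sided p is
`min(1, 2 * min(lower tail, upper tail))` with the observed U included in
its tail. Tail doubling (rather than summing outcomes at least as extreme)
is the convention that yields the familiar small-design values 2/70 =
0.02857 (4 vs 4 complete separation) and 2/35 = 0.05714 (4 vs 3). Ties or
larger samples fall back to mid-ranks with the tie-corrected,
continuity-corrected normal approximation, and the result is flagged
`method="normal-approximation"`.

**Chi-squared association.** Pearson's statistic without continuity
correction — expected cells from the marginals, `df = (r-1)(c-1)`, p from
the chi-squared survival function. Group totals in these tables are in the
thousands, where the correction is immaterial; uncorrected Pearson is the
default reading of "chi-squared test". Degenerate tables (a zero row or
column) are rejected rather than patched.

No multiple-testing adjustment is applied to per-segment or per-isotype
comparisons by default, mirroring how per-segment Wilcoxon comparisons are
conventionally reported in repertoire panels; Benjamini-Hochberg can be
layered on by the caller.

## Synthetic repertoire generator

The generator exists so every stage of the analysis can be verified against
planted ground truth without any external data.

**Germline library.** Toy segments are generated, not copied from IMGT, to
avoid an external reference dependency: per locus, >= 8 V genes with family
structure (IGHV1/IGHV11/IGHV12 among them), 4 D genes (IGH only), 4 J genes.
Only the junction-relevant parts are modelled: V contributes a prefix
starting at the conserved cysteine codon, J a suffix ending at the conserved
W/F anchor codon. Default heavy V-family weights skew usage toward IGHV1,
IGHV11 and IGHV12 (IGHV11 top at 0.30), the skew reported for murine
peritoneal B-1 repertoires.

**Junction model.** V, (D,) J are drawn from the usage weights; each
junction edge loses a geometric number of nucleotides (mean `deletion_mean`,
default 2 nt, capped so anchors survive); N-insertions are Poisson-length
(mean `insertion_mean`, default 4 nt) with uniform bases. With
`productive_only` the draw repeats until the junction is in-frame, stop-free
and anchored, with a bounded retry budget so an inconsistent configuration
fails loudly instead of looping.

**Clone sizes.** A two-component model: `expanded_count` clones share
`expanded_mass` of the frequency vector equally, the background shares the
rest uniformly (Dirichlet and power-law backgrounds are available as
options). The uniform two-component default is deliberately the simplest
model that makes the >1% classifier's ground truth unambiguous. Expanded
clones are placed on the heavy chain, the headline chain class of the
clonality analysis. Per sample, reads are drawn multinomially from the true
clone frequencies; a clone observed at least once becomes a record whose
abundance is its read count.

**Study emulation.** `emulate_study` writes the full design — 4 WT + 4 KO
B-1a and 4 WT + 3 KO B-1b samples — as AIRR TSVs with a manifest, a
ground-truth table and the config. Defaults: 2,000 reads per sample;
WT pools of 900 clones with 3 expanded clones holding 8% of mass; KO B-1a
pools of 300 clones with 8 expanded clones holding 55%; KO B-1b 450/8/30%.
These produce the qualitative KO pattern (fewer unique CDR3s, higher
replicated coverage) with clear per-sample separation at desk-scale runtime;
the effect sizes are this package's choice, as no quantitative
clone-generation effect is published. Three expanded clones are planted in
both KO pools (`shared_ko_expanded`), giving the KO-KO repertoire overlap
its characteristic excess over WT-KO comparisons.

Per-sample library depth is gamma-distributed around `reads_per_sample`
(CV 0.2 at the study level) because real libraries never sequence to
identical depth; depth variation is what gives per-sample unique-CDR3 counts
realistic spread. At the single-pool level (`SimulationConfig`) the default
CV is 0 so read totals are exactly conserved.

**Null studies.** `zero_effect_config` gives WT and KO identical generative
parameters *and* a common clone pool per subset (`pool_per="subset"`).
Sharing the pool is essential: with separate pools, pool-level randomness
(e.g. the binomial split of clones across chains) differs between genotypes
even at identical parameters, which breaks exchangeability and inflates the
apparent type-I rate of downstream tests. With a shared pool, samples are
iid multinomial draws and the unique-count rank test rejects at exactly its
nominal level.

**Seeding.** All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (pool seeds, then per-sample seeds),
recorded in the manifest; a fixed master seed reproduces output files byte
for byte.

## What the generator does not model

No somatic hypermutation, no selection or affinity dynamics, no realistic
IMGT germline sequences, no cross-mouse "public" clone structure beyond the
explicitly planted shared expanded clones, and no sequencing error. Passing
tests therefore demonstrate that the analysis machinery is correct under a
faithful sampling model of clonal structure — not that TRUST4's
reconstruction, or any property requiring those unmodelled features, is
validated.

## Numerical and design choices

- Exact rank-sum arithmetic uses Python integers and `fractions.Fraction`;
  no floating-point enters until the final p.
- The exact path refuses ties entirely (flagged fallback) rather than
  enumerating a mid-rank distribution, keeping the enumerated null valid.
- Clone-table representative V/J calls are the highest-abundance call per
  clone, ties broken lexicographically; clone ordering in outputs is by
  descending abundance then lexicographic CDR3, so outputs are deterministic.
- Top-clone tracking breaks ties at rank k lexicographically; absent clones
  report frequency 0.
- Kappa/lambda ratios with zero IGL mass are reported infinite and flagged;
  they are excluded from rank comparisons.
- Overlap is computed on CDR3 amino-acid strings regardless of V/J context;
  a strict mode additionally requiring matching V family is available.
- Thresholds, weightings and the replicated threshold (default 0.01) are
  configurable everywhere; the strict > comparison is not.

## Problem sizes in the verification suite

Simulation-backed checks run at desk scale chosen once for the package's
test suite: recovery of planted expansions uses pools of 105 clones
(5 expanded at 12% true frequency vs 0.4% background) sampled at 10,000
reads across 4 samples over 200 seeds; null calibration uses 300 studies of
the 4-vs-3 design with 600-clone shared pools at 2,000 reads; study-level
fixtures use the default `StudyConfig`. These sizes keep every multinomial
well away from the classifier boundary, so the checks measure correctness,
not sampling luck.

## Known limitations

- The exact engine enumerates in O(n1^2 * n2^2) time, fine for the
  small-animal designs it exists for; large-sample work should use the
  (automatic) normal approximation.
- TRUST4 report parsing covers the `*_report.tsv` simplified layout, not the
  full `*_cdr3.out` or barcode-level outputs.
- The pipeline assumes one file per sorted-cell sample; technical replicates
  must be merged upstream.
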