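# Methods

This note documents the models and procedures implemented in `deeqc`,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the numerical conventions used where a published rule
leaves room for interpretation.

## Read simulator

The simulator exists to give every downstream stage a controllable ground
truth, not to reproduce any instrument's error model.

**Reference construction.** Genes are tiled across 1–3 toy chromosomes
with random intergenic spacers (100–300 bp), alternating strand. Each
gene carries `n_exons_per_gene` exons (default 1, keeping the toy genome
mappable without spliced alignment) and `n_tx_per_gene` isoforms
(default 2). For single-exon genes, additional isoforms shorten the exon
by 25 % per isoform so that isoforms share sequence and transcript
quantification must split ambiguous reads; for multi-exon genes they drop
one exon. If an adapter sequence is requested, the genome is re-drawn
until the adapter is absent from both strands so the genome-absence clip
rule can be exercised cleanly.

**Reads.** Per transcript, the read count is
`round(fold_coverage · length / read_length)` in exact-count mode
(default; a Poisson mode exists for sampling-noise studies). Defaults
describe a small but plausible bulk run: 50 genes, 100 bp single-end
reads, uniform fold coverage 2, substitution rate 0.001/base, unstranded
library (sense probability 0.5). Fragment start positions are uniform
over positions that keep the fragment inside one exon. Each read may
receive: `fiveprime_extra` random nonreference 5′ bases (emulating UMIs;
grid of interest 0/4/8/12/20); for `adapter_fraction` of reads, a
shortened insert (uniform between 18 bp and read length minus 14 bp)
whose 3′ end runs through into the adapter; iid substitution errors on
the template-derived portion; and phred scores from a parametric profile
(mean 35, linear decay of 0.15/base over the final 30 % of the read,
Gaussian jitter σ = 2, clipped to [2, 40]). Paired-end mode emits
inward-facing mates from a fixed-length fragment.

**Not emulated:** indels, quality-dependent miscall probabilities, GC or
positional coverage bias, optical duplicates, polyA tails, spliced reads
across exon junctions. Tests passing on these reads therefore demonstrate
the correctness of the decision logic under its stated assumptions, not
robustness to every artefact of real libraries.

## Pre-mapping QC decisions

**Encoding.** From a ≤4,000-read sample: any quality character below
ASCII 59 ⇒ offset 33 (Sanger); all ≥ 64 with at least one ≥ 75 ⇒ offset
64 (Illumina 1.5). The overlap zone 59–63 is reported as undetermined
rather than guessed; the caller then supplies an explicit offset.

**3′ trimming.** Terminal bases are removed while the last base's phred
is strictly below 10 (stepwise end trim, not a sliding window); reads
shorter than 18 nt are discarded. Trimming is idempotent. The QC pass
rate uses all input reads as denominator, including reads later removed
by adapter clipping.

**Adapter inference.** k-mers (k = 12) starting in the 3′ third of each
sampled read are counted; the k-mer most overrepresented relative to its
expectation under the sample's base composition (required factor > 10,
count ≥ 5) seeds a candidate, which is extended left and right by column
majority vote (≥ 70 % of voters, absolute support ≥ 3 and ≥ 30 % of the
seed's support) over reads containing it. The published rule this
re-expresses gives only the decision criteria, not the inference
algorithm, so the overrepresentation scheme is this package's own; its
thresholds are exposed as arguments. The clip decision is strict:
frequency must **exceed** 0.025 (equality does not clip), and the
candidate must be absent from the genome — interpreted as no exact
full-candidate substring match on either strand. A practical consequence,
visible in the worked example, is that deeply covered adapter-free
libraries still surface a candidate (a genomic 3′-end consensus); the
genome check is precisely what vetoes clipping there.

**Adapter clipping.** The longest read suffix aligning to an adapter
prefix with ≥ 5 bp overlap and ≤ 10 % mismatches is removed, then the
18-nt minimum-length filter is re-applied.

**5′-clip optimisation.** Each clip in {0, 4, 8, 12, 20} is applied to a
≤10,000-read sample, the sample is mapped, and the unique-mapping
proportion recorded. The chosen clip is the **smallest clip whose rate is
within 1 percentage point of the best rate**. A pure argmax was tried
first and proved fragile: with an exact-seed mapper, a read carrying a
substitution in a seed window can become mappable only at a deeper clip,
letting a one-read difference select clip 20 on a perfectly clean
library. The margin absorbs that sampling noise; it cannot mask true
contamination because residual nonreference 5′ bases fail full-length
verification and depress the rate far more than 1 point. The margin,
grid (which includes the unclipped baseline 0) and mismatch budget are
arguments.

## Mapper and counters

The mapper stands in for a spliced aligner at toy scale: exact 18-mer
seed index over the genome, seeds taken from the read at offsets 0 and
18 (the second seed rescues reads with an error in the first window),
candidates verified over the full read length with ≤ 2 mismatches, both
strands. Exactly one verified locus ⇒ unique; several ⇒ multi; none ⇒
unmapped, and the three classes always partition the input. Only unique
alignments are assignable: an alignment overlapping the merged exon union
of exactly one gene increments that gene's unstranded column always, the
forward column when read strand equals gene strand, else the reverse
column. Ambiguous (two-gene) and intergenic alignments stay unassigned.

**Strandedness** is called from the assigned-read strand totals:
stranded when one direction reaches **at least** 5× the other (the 5:1
bias is interpreted inclusively; the threshold is an argument), else
unstranded. Totals are computed over assigned reads only.

**Transcript counting** matches reads against spliced transcript
sequences with the same seed-and-verify scheme, restricted to the sense
orientation for positively stranded calls, antisense for negative, both
for unstranded. A read compatible with *m* transcripts contributes 1/*m*
to each. This uniform split is a deliberate, deterministic simplification
of likelihood-based estimated counts: it preserves the accounting
identity (total estimated counts = matched reads) and the qualitative
behaviour that matters downstream — per-isoform counts are noisy where
isoforms share sequence, while their per-gene sums are accurate, which is
why gene-aggregated transcript counts correlate with truth at least as
well as isoform-level counts in the acceptance checks.

## Quality classification

The eight rules are listed in the README. Numerical conventions: all
thresholds compare with strict `<`, so a metric exactly at a threshold
passes; count thresholds scale with the number of protein-coding genes
(for toy references, every gene counts as protein-coding); rule 8 is
advisory (warn only) and tolerant of a missing value. The pass-average
profile is the per-gene mean of RPM-normalised profiles over runs with no
rule-1–7 codes (a rule-8-only warn does not disqualify a run, and rule 8
is excluded from eligibility because it is what the profile exists to
compute), subsampled without replacement to ≤ 10,000 runs under a fixed
seed. The correlation is Pearson's r of RPM vectors, rounded to 2
significant figures with Python's round-half-even; rounding convention at
exact halves is unspecified upstream and immaterial at this precision.

## Meta-analysis

Correlation matrices use average ranks for Spearman ties; constant
vectors produce NA entries plus a warning record instead of an error.
Clustering converts correlation to distance as 1 − r (the transform is an
argument; NA correlations impute to r = 0), builds a complete-linkage
dendrogram, and cuts at `cut_fraction` × (maximum merge height);
`cut_fraction` may be any value in (0, 1], where 1 yields a single
cluster. The DE statistic requires p ∈ (0, 1]; p = 1 scores 0 regardless
of direction and a zero fold change carries sign 0. Concordance between
two DE tables is the Spearman correlation of the signed scores on the
gene intersection (≥ 3 genes required).

## Pipeline, bundle and determinism

The per-run flow is: trim → adapter inference/clip → 5′-clip
optimisation → map → gene counts → strandedness → transcript counts →
metrics → classify. With two or more runs processed together, the
pass-average profile is built and each run's correlation (rule 8) filled
in before re-classification. The seven-table bundle (gene counts,
transcript counts, gene info, transcript info, QC metrics, summary and
full metadata) plus per-run logs is written as a zip of TSV members with
pinned timestamps, so identical seeds yield byte-identical archives and
read–write round trips are lossless. TSVs use tabs, a header row, and the
literal `NA` for missing values; gzip input is detected by magic bytes.
GTF I/O converts between the 1-based inclusive convention on disk and
0-based half-open coordinates internally. Gene length is the merged exon
union across isoforms; transcript length is the sum of its exon lengths.

## Problem sizes

The bundled studies are sized for interactive use: quantification
fidelity uses 50 genes × 2 isoforms at fold coverage 2 (~900 reads);
recovery studies use 8–10 genes with 20 seeded repetitions; the deep
classification demonstration uses 10 genes at fold coverage 75 (~6,000
reads — above the 500 reads/gene warn line). The full test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* The mapper is unspliced and exact-seeded; reads spanning exon junctions
  or with >2 substitutions are unmapped. The simulator avoids junction
  reads by construction, so mapping rates on real spliced libraries would
  be lower.
* Adapter inference assumes a single dominant adapter with enough
  read-through occurrences in the sample; mixed adapters or heavily
  degraded adapters are out of scope.
* The uniform 1/m transcript split ignores coverage and length
  information that likelihood-based quantifiers exploit; isoform-level
  estimates are correspondingly rough.
* Classification thresholds are heuristics inherited from the rule table
  they re-express; nothing in this package validates them against
  external truth.
* PE support is minimal (fixed fragment length, mate1 used for adapter
  and clip decisions, pairs dropped if either mate fails the length
  filter).
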