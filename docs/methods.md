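# Methods

This note documents the models and procedures `lincpipe` implements, the
defaults it ships with, the numerical choices that matter, and what the
synthetic-data generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`; conversion
happens exactly once at the I/O boundary. GTF (1-based inclusive) and
browser-style `chrN:A-B` locus strings are shifted on read/write; BED passes
through unchanged. Printed locus strings are interpreted as 1-based
inclusive spans, the genome-browser convention. Chromosome names are matched
by exact string comparison (`chr6` ≠ `6`); `normalize_chrom` is the explicit
escape hatch, and the input validator reports style mismatches rather than
silently coercing them.

A transcript's TSS is its strand-aware 5′ end: the span start on `+`, the
span end on `-`; unstranded transcripts are treated as `+`. Transcript
length is spliced length (sum of exon lengths).

## Discovery filters

Candidates must pass, in this fixed order: (1) no exonic base shared with a
protein-coding exon on the same strand, (2) spliced length ≥ `min_length`
(default 200 nt, the conventional lncRNA floor), (3) ≥ `min_exons` exons
(default 1), (4) maximum per-condition FPKM ≥ `min_fpkm` (default 1).
The first failing filter names the rejection reason; the kept set itself is
order-independent. Thresholds are inclusive so that boundary cases are
well-defined and testable. Expression is the *maximum* over conditions so
stimulus-specific transcripts silent at baseline survive. Intronic
containment within a coding gene does not exclude a candidate — such
transcripts proceed to classification.

## Positional classification

Classes are mutually exclusive with fixed precedence
**pseudogene > antisense > lincRNA**:

* *pseudogene* — any exon overlaps the genomic span of an annotated
  pseudogene, either strand. No computational pseudogene detection is
  attempted; the annotation's biotype is authoritative.
* *antisense* — any exon overlaps a protein-coding gene on the opposite
  strand. The default compares against the gene's full genomic span, since
  antisense transcripts commonly overlap introns; `antisense_mode="exon"`
  restricts to exonic overlap.
* *lincRNA* — neither; intergenic (vacuously so on chromosomes with no
  annotated genes).

Novelty: a transcript is *known* when, in any supplied catalog, a
same-strand transcript shares exonic bases covering ≥ `min_recip_overlap`
(default 0.5, the cuffcompare-like convention) of **both** transcripts;
otherwise *novel*. Matches aggregate across catalogs by union.

Enhancer-RNA flags are strand-blind (enhancers are transcribed
bidirectionally): one shared base between any exon and any enhancer
interval flags the transcript.

Reported class percentages are integers apportioned by largest remainder so
they sum to 100, with remainder ties resolved toward the rarer class — the
convention that keeps small classes visible in a printed breakdown. The raw
(unrounded) percentages are emitted alongside.

## Differential expression

The test is a two-sample *t* on `log2(FPKM + pseudocount)` per transcript
(pseudocount 0.1), a deliberate stand-in for count-model tests that is fully
reproducible from an FPKM table alone. The pooled-variance (Student) form is
the default: with three replicates per group it holds its nominal type-I
error under the equal-variance null (measured ≈ 0.05 across seeded null
simulations), and the two-group case coincides exactly with the one-way
ANOVA used for the assay statistics. Welch's form is available via
`equal_var=False`; note that at n = 3 its Satterthwaite degrees of freedom
are estimated from two near-noise variances, making it markedly conservative
(measured level ≈ 0.036). Zero-variance groups are handled explicitly:
identical groups give p = 1.

Multiple testing uses Benjamini–Hochberg (statsmodels `fdr_bh`). Calling
requires all three criteria simultaneously, with strict inequalities:
criterion statistic < 0.05, linear fold change > 2 (equivalently
|log2 FC| > 1), and |mean FPKM difference| > 1. The significance statistic
is configurable per analysis: `q` (FDR) is the default for mRNAs, `p` for
lncRNA sets — both usages are common when the noncoding fraction is
shallowly sampled. Fold changes are reported on both linear and log2
scales.

Pathway over-representation is the one-sided hypergeometric tail on the
overlap between a DE gene set and each pathway (intersected with the
background first; pathways disjoint from the background are skipped), with
BH across pathways.

## Cis / mRNA-flanking analysis

Distance is TSS-to-TSS — the minimum over protein-coding genes on the same
chromosome, any strand, of |TSS difference| — with no cap; an unsigned
distance is reported together with a signed column (positive when the gene
TSS lies downstream in the lincRNA's orientation). Ties across genes resolve
to the lexicographically smaller gene id and all tied ids are reported. A
chromosome with no coding gene yields an explicit no-neighbor record, not an
exception. A pair is *flanking* when distance < 5,000 bp (strict).

"Nearest expressed" restricts eligible genes to those reaching
`nearest_min_fpkm` (default 1, matching the pipeline's expression floor) in
at least one condition. The cis statistic is Pearson's *r* between the
absolute log2 fold changes of flanking lincRNAs and their nearest expressed
coding genes, with the two-sided *p* from the *t* transform; pairs lacking a
fold change on either side are dropped and counted, and zero variance
produces an explicit degenerate result.

## Assay statistics

**Relative quantification.** ΔCt = Ct(target) − Ct(reference 18S);
ΔΔCt = ΔCt − mean ΔCt of the calibrator condition (per target);
RQ = 2^−ΔΔCt, amplification efficiency fixed at 2. Because centering happens
on the log (Ct) scale, the calibrator group's *geometric* mean RQ is exactly
1; its arithmetic mean exceeds 1 whenever replicates disagree (Jensen's
inequality), which is a property of the classical method, not an error.

**ANOVA + Fisher's LSD.** One-way ANOVA from sums of squares; LSD pairwise
comparisons use the pooled within-group mean square and its degrees of
freedom, uncorrected for multiplicity. By default LSD is *protected*:
pairwise p-values are reported only when the omnibus p < 0.05
(`protected=False` reports them unconditionally). With two groups the
omnibus F equals the pooled t statistic squared.

**Knockdown.** 100 × (1 − targeting/control); values below zero (no
knockdown) are clamped to 0 in reports.

**Panel screening.** Analytes with every value below the 1 pg/ml floor are
flagged not-detectable and excluded from testing; values above the
2,500 pg/ml ceiling are winsorized to the ceiling with the count of
out-of-range values propagated. The stimulant analyte can be excluded by
flag. A *responder* is an analyte with omnibus p < 0.05 **and** fold change
≥ 2 in either direction; the fold-change arm mirrors the pipeline's DE
threshold and keeps the screen's false-flag rate negligible where a pure
p < 0.05 rule would flag roughly one null analyte per two screens at
17-plex scale.

## Synthetic data: what it emulates, and what it does not

The generator plants, per seed, a single-chromosome annotation
(protein-coding genes with 4–20 exons, echoing the many-exon mRNA profile;
pseudogenes with 2–4 exons), then transfrags whose positional class is
guaranteed by construction: intergenic placements, opposite-strand
placements over coding genes, and pseudogene-overlapping placements. Gene
spans are placed disjoint with a fixed safety gap, and transfrag spans are
mutually disjoint, which makes planted classes and catalog-based novelty
exactly recoverable — the end-to-end tests exploit this. lncRNA geometry
echoes the short profile of real catalogs (~1.2 kb spliced, ~3.6 exons
drawn as 1 + Poisson(2.6), capped at 8).

A configurable fraction of lincRNAs (default 0.5, echoing the observation
that most inflammation-associated lincRNAs are mRNA-flanking) is placed
back-to-back with a coding gene on the opposite strand at a TSS distance
drawn uniformly from 200–4,500 bp — the bidirectional-promoter arrangement
typical of such loci. Each coding gene hosts at most one planted flanking
lincRNA so planted pair effects stay identifiable.

Expression: log-normal baselines (lncRNA-level median ≈ 4.7 FPKM,
mRNA-level ≈ 29.6, log2-sd 1.5), truncated at 1.5 FPKM — the generated
universe emulates an *already expression-filtered* discovery set, as a real
assembled-transcript catalog would be. Three replicates per condition with
i.i.d. normal noise on the log2 scale (default sd 0.25). Planted effects:
flanking pairs draw (|log2 FC|linc, |log2 FC|gene) from a bivariate normal
(mean 3, sd 1.5) with correlation ρ (default 0.6), both induced; a further
10% of transfrags receive an independent signed fold change (85% up),
magnitude |N(3, 1.5)| by default. Assay tables plant knockdown fractions
0.63 and 0.74 (recovered exactly at zero Ct noise; default Ct noise 0.05
cycles), five responder cytokines at 3-fold, two analytes below the
detection floor, and a high condition-independent stimulant analyte.

What the generator does **not** emulate: multi-chromosome genomes,
overlapping or nested real-world gene architecture, isoform complexity
(one transcript per gene), batch effects, count-level mean–variance
structure (FPKMs are log-normal, not NB-derived), assembly artifacts, or
partially-assembled transfrags. Tests passing on this generator therefore
demonstrate the correctness of the pipeline's logic and the calibration of
its statistics under the stated noise model — not robustness to assembler
noise or annotation ambiguity in real data.

## Problem sizes used by the test suite and acceptance script

The packaged experiments run at desk scale: 200 transfrags against an
80-coding/25-pseudogene annotation for end-to-end runs, 2,000 transcripts
for the null-calibration experiment, 90 pairs × 200 seeds for the cis
correlation recovery, and 500-gene annotations with 1,000 random queries
for index-equivalence checks. These sizes make every property statistically
decidable while keeping a full run in seconds.

## Known limitations

* The DE stand-in tests log-FPKM means; it does not model count dispersion
  and will be anticonservative for transcripts whose FPKM noise is far from
  log-normal. With deeper designs a count-based model is preferable.
* Pseudogene classification inherits the annotation's biotypes; unannotated
  pseudogenes are invisible to it.
* No coding-potential scoring: a novel transcript with no catalog match and
  no coding overlap is reported as a novel lncRNA even if it encodes a
  short ORF.
* The cis analysis is positional; it pairs by distance and correlates fold
  changes, but makes no mechanistic claim about regulation.
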