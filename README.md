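# lincpipe

Discovery, positional classification and inflammation-response analysis of
long noncoding RNAs (lncRNAs) from assembled transcript models.

`lincpipe` is written for transcriptomics analysts studying stimulus-induced
(e.g. interleukin-1β–driven) expression changes in primary cells such as
osteoarthritis chondrocytes. It takes the outputs an RNA-seq
alignment/assembly workflow already produces — assembled transfrags in GTF,
a Gencode-style reference annotation, optional lncRNA catalogs, an enhancer
atlas in BED, and a per-transcript FPKM table — and carries them through the
downstream analysis:

1. **Discovery** — filter transfrags to lncRNA candidates: no exonic overlap
   with a protein-coding exon on the same strand, spliced length ≥ 200 nt,
   expression ≥ 1 FPKM in at least one condition (all thresholds
   configurable).
2. **Classification** — every candidate gets exactly one positional class
   with fixed precedence *pseudogene > antisense > lincRNA*; novelty is
   decided by same-strand exonic reciprocal overlap (≥ 0.5 both ways)
   against each catalog; enhancer-RNA overlap is flagged strand-blind.
3. **Differential expression** — per transcript, a two-sample *t* on
   log2(FPKM + 0.1) with Benjamini–Hochberg FDR; a transcript is called
   up/down only when *q* (or *p*) < 0.05 **and** linear fold change > 2
   **and** |ΔFPKM| > 1. Pathway over-representation of DE gene sets uses the
   one-sided hypergeometric tail.
4. **Cis (mRNA-flanking) analysis** — each lincRNA is paired with the
   protein-coding gene whose strand-aware TSS is nearest (|TSS<sub>linc</sub> −
   TSS<sub>gene</sub>|, no distance cap); pairs closer than 5 kb are
   "mRNA-flanking", and Pearson's *r* is computed between the absolute log2
   fold changes of flanking lincRNAs and their nearest expressed coding genes.
5. **Assay statistics** — 2<sup>−ΔΔCt</sup> relative quantification against a
   reference gene (18S) and a calibrator condition; one-way ANOVA with
   Fisher's LSD post hoc comparisons; knockdown percentages
   (100 × (1 − targeting/control)); and screening of a 17-plex cytokine
   panel with a 1–2,500 pg/ml dynamic range.

A seeded **synthetic-data generator** produces every one of these inputs
with planted ground truth (true classes, novelty, fold changes, flanking
correlation, knockdown fractions, responder cytokines), so the entire
pipeline is testable offline.

## Worked example

```sh
lincpipe simulate --outdir demo --seed 17   # writes GTF/BED/TSV/CSV inputs + truth.json + run.yaml
lincpipe run --config demo/run.yaml
```

prints

```
wrote synthetic dataset and demo/run.yaml
INFO run complete: 200 lncRNAs, report at demo/results
200 lncRNAs; report at demo/results/report
```

and `demo/results/report/report.json` contains (abridged):

```
n_lncrnas        200
class counts     lincRNA 130 (65%), antisense 26 (13%), pseudogene 44 (22%)
novel            50 of 200 matched no catalog entry
erna_fraction    0.03
de_lncrna        76 up, 3 down of 200 tested (criterion p)
de_mrna          62 up, 0 down of 80 tested (criterion q)
cis              61 flanking pairs (< 5 kb), r = 0.49, p = 6.1e-05
lncRNA features  mean length 1.15 kb, mean 3.5 exons
```

All 200 planted class labels are recovered exactly (the generator guarantees
the geometry each label implies), the 61 mRNA-flanking pairs are the planted
back-to-back lincRNA–gene placements, and the positive *r* reflects the
correlation planted between flanking-pair fold changes. Stage outputs
(kept/rejected GTFs, classification TSV, DE tables, flanking-pair TSV) land
under `demo/results/`.

The same functionality is available as a library:

```python
from lincpipe.synthetic_data import simulate_all
from lincpipe.pipeline import RunConfig, run_all

paths = simulate_all("demo", seed=17)
report = run_all(RunConfig(
    transfrags_gtf=str(paths["transfrags"]),
    annotation_gtf=str(paths["annotation"]),
    expression_tsv=str(paths["expression"]),
    catalogs={"catalog": str(paths["catalog"])},
    enhancers_bed=str(paths["enhancers"]),
    outdir="demo/results",
))
```

## Documentation

`docs/methods.md` describes the models, default parameters, numerical
choices, what the synthetic generator does and does not emulate, and known
limitations.
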