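# mesmark

Quantification of gene-body histone marks from ChIP-seq coverage, built
around the analysis style used for MES-4–mediated H3K36me3 in
*C. elegans* embryos.

## The problem

In the worm embryo, the methyltransferase MES-4 maintains H3K36me3 on
the bodies of germline-expressed genes independently of ongoing
transcription, while the Set2 ortholog MET-1 deposits the same mark
co-transcriptionally. Profiling H3K36me3 in a *met-1* mutant therefore
isolates the MES-4-dependent, "maintenance" component of the mark. The
characteristic signatures of that component are: enrichment on
germline-expressed and ubiquitously expressed gene bodies but not on
soma-specific genes; strong depletion on the X chromosome (which
carries few germline-expressed genes); and a mild 5' bias within gene
bodies, in contrast to the usual 3' bias of transcription-coupled
H3K36me3.

`mesmark` re-implements that quantification pipeline as a tested,
reusable library plus CLI, and ships a synthetic-read simulator with
known truth labels so every stage can be validated without external
data.

## What it computes

Given mapped single-end reads (BED intervals) and a gene annotation:

1. **Coverage** — each read is extended to the expected fragment length
   (default 200 bp from 36-bp reads) in its strand's 3' direction; the
   per-base-pair count of overlapping fragments is computed; each
   replicate track is rescaled so all samples share a common
   genome-wide median; replicates are averaged base-by-base.
2. **Gene scores** — for gene *g* with body [TSS, TES), the score is
   mean coverage over the body, and log10 of that mean is used for
   sample-vs-sample scatter comparisons.
3. **Chromosome summary** — mean signal per chromosome and the ratio
   mean(X) / mean(pooled autosomes).
4. **Metagene profiles** — strand-oriented 50-bp bins from 1 kb
   upstream to 1.5 kb downstream of the TSS (1.5/1 kb around the TES),
   reporting across genes the bin mean ± 1.96·SEM (95% CI).
5. **Gene sets** — expression-breadth classes from tissue tag counts:
   *ubiquitous* (≥ 1 tag in germline, muscle, nerve and gut), *somatic*
   (≥ 8 tags in ≥ 1 somatic tissue and 0 germline tags),
   *germline-enriched* (published list minus exclusions) and
   *larval/adult germline-specific* (triple intersection).
6. **Count statistics** — integer percent-positive for embryo staining
   tables (round half away from zero), Wilson CIs, Fisher exact
   genotype comparisons, and ChIP-qPCR percent input:
   `% input = 100 · b^(−ΔCp) · (df_chip/df_input) · (f_input/100)` with
   amplification base `b = 2·efficiency` (or `1 + efficiency`).

## Worked example

```bash
mesmark demo --seed 1 --outdir demo_out
```

simulates four samples on a toy genome (three 200-kb autosomes plus an
X; 40 genes per chromosome with germline/soma/ubiquitous labels, the X
germline-poor; two replicates of 100 000 reads each): a
maintenance-marking ChIP, a transcription-coupled ChIP, a pan-H3
control and an input control. It runs the full pipeline and writes
tracks, score tables, metagene profiles, gene sets and `report.json`.
With seed 1 the report contains:

```
x_autosome_ratio:  met1_h3k36me3 0.240   n2_h3k36me3 0.596
                   pan_h3 1.007          input 0.991
germline_vs_soma_auc: 1.0
tss_profile: mean over bins (0,+500] = 78.69, over (+1000,+1500] = 68.59
gene_sets: jaccard_ubiquitous 1.00, jaccard_somatic 0.981, overlap 0
```

Read: the maintenance-marking sample is ~4-fold depleted on the X while
the flat controls sit at ratio ≈ 1; gene-body scores separate germline
from soma genes perfectly (AUC 1.0); signal just inside the TSS exceeds
the signal 1–1.5 kb downstream (the 5' bias); and the tag-count rules
recover the true expression classes almost exactly. The same stages are
available as individual subcommands (`simulate`, `coverage`, `score`,
`scatter`, `metagene`, `genesets`, `staining`, `qpcr`).

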