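# ploidymeth

Comparative whole-genome bisulfite sequencing (WGBS) methylome analysis for
two-group ploidy designs — e.g. an autotetraploid (4X) plant against its
diploid (2X) parent, three biological replicates each.  The package takes
post-alignment inputs (Bismark-style cytosine reports, a lambda spike-in
report, gene and transposable-element annotations, FPKM and
differential-expression tables) and produces the full downstream analysis:

- **Methylation-site calling.**  The non-conversion rate *r* is estimated
  from the unmethylated lambda spike-in, and each cytosine with coverage is
  tested with a one-sided binomial test: *p* = P(X ≥ mC) for
  X ~ Binomial(mC + umC, *r*).  Sites with Benjamini–Hochberg FDR < 0.05 are
  methylated.  Levels are always ML = mC / (mC + umC), per site, per 10-kb
  window, or per region (count-weighted, never a mean of ratios).
- **Profiles.**  Mean levels per CG/CHG/CHH context across genomic region
  classes (promoter, exon, intron, gene body, TE, intergenic), metagene and
  meta-TE profiles (length-normalized bodies + 2-kb flanks), and per-TE-order
  panels (Copia, Gypsy, LINE, Helitron, ...).
- **DMR calling.**  Counts are pooled within groups, smoothed over a local
  window, and tested per site; differentially methylated regions are runs of
  significant sites (*p* < 1e-5) satisfying the region rules — >50%
  significant loci, ≥3 loci, >50 bp — with same-direction regions <100 bp
  apart merged.  An exact Fisher per-site test is available as an
  alternative statistic and as the oracle-checked primitive.
- **Annotation & integration.**  DMR-to-gene anchoring (gene body TSS–TES vs
  2-kb promoter), Venn set logic, expression-class methylation profiles,
  TE-insertion expression analysis, DEG ∩ DMR quadrants
  (hyper-down / hypo-up / hyper-up / hypo-down), and a generic
  hypergeometric over-representation test.
- **Synthetic data.**  A first-class generator that emulates the assumed
  statistical structure of such an experiment (CpG-depleted genome, bimodal
  site methylation with context baselines mCG ≈ 0.40 / mCHG ≈ 0.28 /
  mCHH ≈ 0.10, beta-binomial replicate counts at ~15× Poisson depth, planted
  DMRs, TE-coupled and methylation-coupled expression), with a recorded
  ground truth for recovery testing.

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the whole pipeline on the default synthetic experiment (2 chromosomes ×
1 Mb, 3+3 replicates, ~15× depth):

```bash
ploidymeth all --outdir run --seed 5
```

This writes the dataset (`genome.fa`, `genes.gff3`, `tes.bed`,
`reports/*.cx.tsv`, expression/DE tables, `truth.json`) and every analysis
artifact.  Highlights from this exact run:

`calls/summary.tsv` — per-sample site-calling summary (sample 2X_1): 31.2%
of covered cytosines methylated overall; 51.0% of CG sites, 35.6% of CHG and
28.5% of CHH — the canonical mCG > mCHG > mCHH ordering — while 73.9% of all
methylated sites sit in CHH context, because CHH dominates the cytosine
inventory.

`dmr/summary.tsv` — DMRs by context and direction (4X vs 2X):

```
context  hyper  hypo  total
CG           4     1      5
CHG          8     3     11
CHH         60    44    104
```

`dmr/dmrs.bed` — e.g. `chr1:2677-4362 CHH hyper`, 470 member sites all
significant, mean level 0.032 (2X) vs 0.239 (4X).

`integrate/quadrants.tsv` — of the DE genes that carry a DMR, 10 are
hypermethylated-down and 7 hypomethylated-up; none fall in the positive
quadrants, reflecting the planted negative promoter-methylation coupling.

Each stage is also exposed separately (`simulate`, `call-sites`, `profile`,
`call-dmrs`, `annotate`, `integrate`), all driven by a YAML config
(`ploidymeth all --config my.yaml`); reruns with the same config and seed
are bit-identical.

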