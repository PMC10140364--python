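# Methods

## Coordinate and format conventions

All internal coordinates are 0-based half-open on the forward reference
strand; converters live at the file boundary (cytosine reports and GFF3 are
1-based inclusive on disk, BED passes through unchanged).  Context labels
are restricted to CG / CHG / CHH ("CpG" is accepted on input as an alias);
context can be re-derived from the reference triplet and mismatches
reported.  Zero-coverage cytosines are kept by the readers and filtered by
the analysis stages, so the coverage threshold is one tunable
(`min_coverage`, default 4) rather than format behaviour.

## Site calling

The lambda spike-in is fully unmethylated, so its pooled methylated-read
fraction estimates the bisulfite non-conversion rate
*r* = Σ mC / Σ (mC + umC).  A raw ratio of exactly 0 or 1 is clamped with a
pseudocount (0.5 / +1) because *r* = 0 would drive every covered site to
p = 0.  Each site with coverage ≥ `min_coverage` is tested one-sided
(methylation can only inflate the methylated-read count above the error
rate): p = P(X ≥ mC), X ~ Binomial(mC + umC, r).  Benjamini–Hochberg
correction is applied per sample over all tested sites of all contexts
jointly — a single family, the conservative choice — and sites with
q < `alpha` (0.05) are flagged methylated.  Windowed levels use the stated
count-weighted convention: the level of a 10-kb bin is the ratio of summed
counts, not the mean of per-site ratios.

## Two-group test and DMR formation

Counts are pooled within each group (replicate sums per site).  The exact
per-site primitive is a two-sided Fisher test on the 2×2 table
(m₁,u₁; m₂,u₂), implemented by vectorized hypergeometric enumeration and
checked against exact-fraction enumeration in the tests.  At ~15× per
replicate and three replicates, pooled coverage is ~45 per group, and a
single site essentially never reaches p < 1e-5 even for a methylation
difference of 0.3 — the per-site exact test has a few-percent hit rate at
that threshold.  The pipeline therefore smooths before testing, as the
beta-binomial DMR callers used in this field do: counts are summed over a
moving window (`smooth_span`, default 600 bp, per context and chromosome)
and compared with a two-proportion Wald test.  Because biological replicates
are overdispersed relative to the binomial, the Wald z-scores are deflated
by a per-context genomic-control factor, φ = (median|z| / 0.6745)², clamped
at ≥ 1 and only estimated when ≥ 500 sites are available; true DMRs are rare
enough (< a few % of sites) that the median is a robust null-scale estimate.
A genuinely genome-wide methylation shift between groups would inflate φ and
make the corrected test conservative — an accepted bias.  Full
replicate-level dispersion shrinkage (DSS-style) is intentionally out of
scope.

Region rules follow the analysis protocol exactly: candidate segments are
maximal runs of significant sites (p < 1e-5, consistent sign of the
smoothed difference) with adjacent significant sites ≤ `max_site_gap`
apart, extended to include interior tested sites; a candidate must hold ≥ 3
loci, span > 50 bp and have > 50% significant loci; surviving same-direction
regions closer than 100 bp are merged, re-validated, and dropped if the
merged region fails the criteria.  `max_site_gap` defaults to 500 bp: it
cannot meaningfully be smaller than the smoother's bandwidth, and CpG-poor
stretches longer than 300 bp occur inside real CG regions.  DMR boundaries
span the first to last member site; group means come from pooled
member-site counts, and the direction label (hyper = higher in group 2,
i.e. 4X) is recomputed from those means.  Merging across directions is
never allowed.

## Profiles

Region-class levels and metagene/TE profiles are count-weighted pools over
member sites, matching the window convention and keeping sparse CHH bins
stable.  A site overlapping several classes (e.g. exon and gene body)
counts in each; introns are per-gene body minus exons; intergenic is the
complement of gene bodies, promoters and TEs.  Metagene bodies are scaled
to `body_bins` (60) equal fractions with 2-kb flanks in `flank_bins` (20)
fixed-width bins; minus-strand features are reversed so bin 0 is always 5′.
A site's 1-bp span is distributed fractionally across the bins it covers,
so features shorter than the bin count still contribute.  Empty bins are
NaN, never zero.  The bin counts (60/20) are display-resolution choices and
configurable.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes;
its defaults are the study conditions used by the tests.

- **Genome.**  Random sequence at GC 0.36 with CpG dinucleotides retained at
  0.50 of random expectation and C-H-G trinucleotides at 0.6 (plant-like
  depletion).  This puts ~80% of cytosines in CHH context, which is what
  makes CHH the majority context among methylated sites even though its
  methylation percentage is lowest.  Genes (240 by default, 0.8–3 kb, 1–5
  exons, random strand) occupy equal-width slots with ≥ 2.2 kb margins so
  promoters and flanks never collide; TEs are placed inside gene bodies
  (15% of genes), in 2-kb flanks (15%), and intergenically.  A separate
  48,502-bp fully unmethylated chromosome plays the lambda spike-in.
- **Methylation.**  Site methylation is bimodal: each site is methylated
  with a context-specific probability π and, if methylated, carries a level
  drawn from a context Beta distribution — CG Beta(18,2) (mean 0.90), CHG
  Beta(18,3) (0.86), CHH Beta(3,6) (0.33).  π is calibrated as
  baseline_level / Beta-mean (0.444, 0.327, 0.300), so the pooled mean
  level per context converges to the configured baselines (0.40 / 0.28 /
  0.10) while the percent-methylated-sites ordering and the level-histogram
  shapes (CG/CHG mostly > 0.8, CHH mostly < 0.4) hold simultaneously.  TE
  bodies override π (0.90 / 0.85 / 0.70); gene bodies multiply π by an
  expression-tier factor (CG humped with a maximum at medium expression;
  CHG/CHH decreasing with expression), which plants the expression-class
  methylation patterns the integration stage detects.
- **Planted DMRs.**  120 by default, in CHH-dominated context proportions
  (4.5% / 9.5% / 86%), lengths 500–1500 bp, ≥ 2 kb apart, 30% in promoters
  (of expressed genes only), 25% in gene bodies, the rest intergenic; 60%
  hyper.  The effect is realized in the elevated group (4X for hyper, 2X
  for hypo) by switching unmethylated sites to the methylated state until
  the regional mean rises by `dmr_effect` (0.3), with any residual spread
  as a uniform clamped shift; placements whose mean + effect would exceed
  0.95 are re-drawn.  This guarantees every planted DMR carries the full
  nominal effect regardless of local methylation — an additive level shift
  would silently shrink to ~0.1 inside already-methylated regions.  Hypo
  DMRs are modelled as diploid-elevated regions because a low CHH baseline
  (mean 0.10) cannot lose 0.3 of level.
- **Counts.**  Per replicate, depth is Poisson(15) per site and the
  methylated count beta-binomial around level + (1 − level)·r with
  dispersion ρ = 0.05 (biological replicate overdispersion); the spike-in
  uses pure binomial conversion failures at r = 0.005.
- **Expression.**  Tier-based log2-FPKM means (low 1.0 / medium 3.5 / high
  6.0, none-expressed < 0.1), multiplicative TE effects (body ×0.3, flank
  ×2.0), and for a configurable fraction (0.5) of promoter-DMR genes an
  expression shift of 2 log2 units with sign opposite to the methylation
  change.  The DE table is constructed from the planted shifts directly
  (log2fc = shift + noise, padj ~ 10^-U(2,6) for shifted genes, U(0.1,1)
  otherwise): the differential-expression fit is an upstream tool whose
  output this pipeline consumes, and direct construction keeps the planted
  truth exact.

**What passing tests do and do not show.**  The generator has independent
sites given the regional mean (no epiallele structure), no mappability or
coverage biases, no sequence-composition realism beyond context density,
symmetric groups except for the planted differences, and DE calls that are
correct by construction.  Recovery results therefore demonstrate that the
statistics and region rules behave as designed under realistic noise — not
that real data of this design would yield the same sensitivity.

## Numerical choices

Fisher enumeration uses log-space hypergeometric pmfs with the conventional
1e-7 relative tie tolerance.  The binomial survival function, BH correction
and rank tests come from scipy/statsmodels and are oracle-checked against
enumeration.  Degenerate cases: zero-coverage levels are undefined (NaN or
an error, never 0); windows and bins with no coverage are omitted or NaN;
a pooled smoothed proportion of exactly 0 or 1 yields z = 0 (untestable);
`two_set_union_size` validates inclusion–exclusion feasibility.  All
randomness flows from one integer seed through fixed per-stage
sub-streams, so every artifact (FASTA, reports, BED, TSV) is bit-identical
under a fixed seed and config.

## Default problem sizes

The default synthetic experiment is 2 chromosomes × 1 Mb (~660 k cytosine
sites, six samples), which the full pipeline processes in well under a
minute; the calibration run uses ~110 k sites.  These sizes give stable
recovery statistics (120 planted DMRs) while keeping the whole test suite
quick to iterate on; all of them scale with the config.

## Known limitations

- The smoothed Wald statistic trades exactness for power; its φ-correction
  is genome-wide per context, not site-specific.
- Post-merge re-validation drops a failing merged region outright rather
  than restoring its parts.
- Table-style percentages use covered (tested) sites as denominators;
  whether published tables of this kind count covered or all genomic
  cytosines is generally ambiguous.
- The over-representation test is a plain hypergeometric without selection
  -bias correction (no gene-length weighting); enrichment inputs are a
  generic gene→term map.
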