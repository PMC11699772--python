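# Methods

This note documents the models and procedures `xciseq` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was open.

## Coordinates and conventions

All internal interval arithmetic is 0-based half-open; VCF positions
are 1-based and converted only at the I/O boundary. Haplotype 1 ("G1")
is the maternal, Xi-biased strain analog (129 in a *Tsix*-stop cross);
haplotype 2 ("G2") is the cast analog. Overlap always means ≥ 1 shared
base.

## Variant filtering and pseudo-genomes

A strain variant record is retained iff it is a single-nucleotide,
biallelic call with passing FILTER status and **differing** strain
alleles (a site where the strains agree cannot assign a read and is
dropped as non-diagnostic). "Low quality" is operationalized as VCF
FILTER ≠ PASS, with an optional QUAL cutoff. Multi-allelic or non-ACGT
records are dropped with a counted reason; exact duplicate records are
deduplicated; duplicates with conflicting alleles are a hard error.
Filtering satisfies the accounting identity
`input = retained + Σ removed-per-reason`, which is asserted.

The two pseudo-genomes substitute each retained allele into copies of
the reference, so chromosome lengths are preserved and the genomes
differ at exactly the retained positions (Hamming distance = retained
SNP count — a tested invariant). Sites overlapping filtered indels are
*not* additionally excluded. There is no N-masking mode and no
indel-aware coordinate lifting: indels are filtered out upstream.

## Read filtering and allele tagging

RNA-seq mode keeps mapped single-end reads with MAPQ ≥ 30 (boundary
kept); "uniquely mapped" is operationalized by the MAPQ threshold
alone, since the generator emits primary alignments only. Cut&Run mode
first requires both mates mapped on the same chromosome with fragment
length strictly < 1000 bp (999 kept, 1000 dropped), then applies the
MAPQ filter to both mates.

A read's observation at a covered SNP site matches g1 if its base
equals the haplotype-1 allele, g2 if the haplotype-2 allele; a base
matching neither is ignored as invalid (most plausibly a sequencing
error). The tag is G1 if there is ≥ 1 g1-match and no g2-match, G2
symmetrically, CF if both, UA if no valid observation. Pairs pool the
evidence of both mates before tagging. Because the simulator's
alignments are gapless and share reference coordinates across the two
pseudo-genomes, comparing bases at SNP sites is equivalent to mapping
to both genomes and comparing alignments; a brute-force dual-haplotype
string comparison is kept as an oracle in the test suite.

Tags partition the passed-filter reads (G1+G2+CF+UA = passed; asserted
per library). Summaries report the four-category taxonomy plus a
three-category RNA rollup in which "allele-uncertain" pools CF with UA.
CF reads are excluded from allelic counts downstream (conservative)
but retained in totals and summaries.

## Quantification

A read increments a gene's total count if it overlaps any exon of that
gene; reads overlapping exons of more than one gene are ambiguous and
counted in neither (with accounting), so
`Σ totals + ambiguous + intergenic = reads counted`. G1/G2 tags
increment the allelic counts, hence `g1 + g2 ≤ total` always.

CPM is count per million assigned reads; TPM divides counts by
effective length (summed exon length, kb) before normalising to 1e6.
ΣTPM = 1e6 per library to 1e-6 relative tolerance. The expression
filter keeps genes with ≥ 2.5 CPM in at least `min_libraries`
libraries; `min_libraries` is a required argument rather than a
default, because reasonable analyses use different values (2 or 4).

The differential-expression test is a deliberate *substitute* for
DESeq2, not a replication: size factors by median-of-ratios, per-gene
two-sided Welch t-test on log2(normalized count + 0.5) when both
groups have ≥ 2 replicates, Benjamini–Hochberg correction, and a call
iff FDR ≤ 0.1 and |fold| ≥ 2. With fewer than two replicates per group
no inferential call is made. Calibration (null FDR behaviour and power
on planted 4-fold changes) is measured by the acceptance scenarios.

Coverage tracks bin each chromosome at a fixed width (last bin
truncated); a bin's RPKM is
`count·1e6 / (bin_kb · total_units)` with reads as the unit in RNA
mode and sequenced fragments in Cut&Run mode (the arithmetic is ordered
so the single-bin identity N/(1 kb · N/1e6) = 1e6 is exact in floating
point). The printed form of this normalisation in some sources carries
a garbled constant (1e8); the standard per-kilobase-per-million form is
what the commonly used tooling computes and is what is implemented.
Control (IgG) subtraction is binwise and floored at zero — negative
signal has no meaning for threshold peak calling. Allelic tracks are
built from G1-only / G2-only reads, each normalized by its own tagged
total.

## Peak calling

The caller is a documented substitute for SEACR's "norm" mode (which
the upstream protocol names but does not specify): contiguous runs of
bins above a data-derived threshold merge into peaks; runs separated by
at most `bridge_gap_bins` sub-threshold bins are joined; peaks narrower
than `min_width` bp are dropped. Without a control the threshold is a
quantile (default 0.99) of the track's own nonzero bin values. With a
control track the threshold is that quantile of the **control's**
nonzero bins, and a bin must also exceed the control's corresponding
bin. A purely binwise treatment-vs-control comparison was rejected:
with equal-depth treatment and control, roughly half of all background
bins exceed the control by chance and merge into long false peaks; the
control-quantile threshold preserves the "call what rises above the
background distribution" semantics robustly at low coverage.

A peak's reported signal is the **sum** of its bin values
(`total_signal`), matching the statistic the 10 (H3K27me3 D15) and
5 (KDM6A) cutoffs are applied to; the maximum bin is retained for
inspection. Two structural facts set the remaining parameters:

- sub-400-bp supra-threshold runs are almost always pileups of a
  handful of overlapping fragments, so analyses here use
  `min_width = 400` (about two nucleosomal fragment spans);
- allele-restricted tracks are patchy, because a window with no
  diagnostic SNP yields only UA fragments regardless of depth
  ("SNP deserts", mean diagnostic-SNP spacing ~150 bp at default
  density), so allelic peak calling uses 200-bp bins with 2-bin
  bridging to ride over holes.

TSS regions are strand-aware ±5 kb windows around the transcript start
(the rightmost transcribed base for minus-strand genes), clamped to
chromosome bounds; peak–TSS overlap is collected per gene (a gene with
several transcripts counts once). Venn partitions are computed exactly
for 2–3 gene sets. Xi-specific gains are test-condition peaks that
overlap no background-condition peak, reported with the covered
fraction of the target chromosome and genomic-context counts (TSS
window takes priority over gene body, classified by peak midpoint).

## XCI reporting

The allelic ratio of a gene in a library is `g1/(g1+g2)` over
informative reads (the raw odds `g1/g2` are also emitted), computed
only for expressed genes (TPM > 1 by default) with ≥ 1 informative
read; omissions carry reasons. Under binomial read sampling this
estimator is unbiased, and its error at *n* informative reads is
≈ `sqrt(f(1-f)/n)`.

Allelic TPM splits a gene's diploid TPM proportionally to its
informative-read fractions — the standard approach where no explicit
allelic normalisation is defined. Fold-change calls average replicate
libraries (clones) per condition before the fold; a gene is increased
iff fold ≥ 1.25, decreased iff fold ≤ 1/1.25. A zero wt mean with
nonzero KO is reported as +∞/increased and flagged. Calls are
scale-invariant. Silencing-class summaries report the median Xi and Xa
expression and n per class {early, intermediate, late, escape}; class
lists are configuration inputs (the generator writes its own truth
lists). The escape classifier flags `xi_fraction ≥ 0.1` by default
(configurable). The induction contrast reports TPM(differentiated) /
TPM(undifferentiated) for a named locus per condition.

## The synthetic-data generator

The generator emulates a 129 × cast hybrid design at desk scale. All
randomness flows from one seed through fixed per-operation substreams,
so identical configurations produce byte-identical outputs.

Key defaults (units, rationale):

| parameter | default | why |
|---|---|---|
| `snp_density` | 0.008 /bp | ≈ 1 variant per 125 bp, the order of 129-vs-cast divergence |
| `indel_fraction` | 0.10 | emitted only to exercise the filter; no indel reads are simulated |
| `lowqual_fraction` | 0.10 | SNPs flagged LowQual to exercise the filter |
| `read_length` | 75 bp | single-end RNA-seq / paired-end Cut&Run read length |
| `sequencing_error_rate` | 0.002 /base | short-read substitution error scale |
| `low_mapq_fraction` | 0.05 | reads assigned MAPQ < 30 to exercise the filter deterministically |
| `fragment_mean`, `fragment_sd` | 180, 40 bp | nucleosomal Cut&Run fragments |
| `heavy_tail_fraction` | 0.02 | fragments of 1–3 kb (violate the < 1 kb rule) |
| `chimera_fraction` | 0.01 | mate pairs on different chromosomes |
| `replicate_log_sd` | 0.05 | lognormal between-replicate noise of isogenic clonal libraries |
| `reads_per_gene` | 600 | default depth; scenarios override as documented below |

Reference sequences are i.i.d. uniform ACGT; variant sites are placed
by independent Bernoulli(snp_density) draws per base, each biallelic
with either strain possibly carrying the reference base. Gene models
are non-overlapping multi-exon transcripts placed in equal slots with
random jitter; one X-linked gene is designated the Xist-like locus.

The XCI program assigns each X gene a silencing class and an
Xi-expression fraction per condition and timepoint: 0.5 everywhere
before differentiation; in differentiated wt, 0.01 / 0.03 / 0.08 /
0.30 for early / intermediate / late / escape and 0.95 for the
Xist-like locus. In the knockout, 80 % of silenced-class genes have
their Xi *output* multiplied by 1.5 (escape genes by 1.15), which
moves the Xi fraction to `kf/(1−f+kf)` and the gene's total output to
`1−f+kf`. RNA-seq reads then draw haplotype 1 with probability equal
to the gene's Xi fraction, fall within single exons (no splice
structure), and carry true coordinates.

Expression programs live in **transcriptome-share space**, because
share is exactly what TPM measures: the Xist induction factor (6.0 wt,
2.5 KO between timepoints) multiplies the locus's share of the
transcriptome, with the remaining genes rescaled so total abundance is
conserved. Without that convention the planted factor would not be
recoverable from TPM once the locus's share becomes non-negligible.

Cut&Run fragments draw midpoints from a mixture of uniform genomic
background and planted domains weighted by `(enrichment−1)·width`;
fragment lengths are clipped normal with a configurable > 1 kb heavy
tail; a fraction of mates are chimeric; domains can be allele-skewed
via `hap1_fraction` (0.95 for Xi-specific domains). The IgG library is
the same model with no domains. Every read/fragment appears exactly
once in the emitted truth table.

For differential-expression calibration the generator also draws count
matrices directly from its Poisson-lognormal count model
(`simulate_count_matrix`: per-gene lognormal means around 500 counts,
0.25 log2 between-replicate sd, planted fold changes in the test
group), since the DE operation consumes a count matrix and read-level
simulation would add nothing but runtime there.

**What the generator does not emulate:** mapping bias between the two
pseudo-genomes (reads carry true coordinates, so allelic tagging error
comes only from sequencing error), splice junctions, PCR duplicates,
indel-containing reads, base-quality strings, GC or mappability
structure, and biological replicate variation beyond a lognormal scale
factor. Passing tests therefore demonstrate the correctness and
calibration of the analysis logic under the stated statistical model,
not robustness to aligner artefacts in real data.

## Reference study scenarios

The acceptance scenarios (in `xciseq.scenarios`, also exercised by
`scripts/acceptance.py`) use these problem sizes, chosen to keep the
full suite in minutes on one CPU while leaving each measured property
several standard errors of margin:

- **Tagging fidelity** — 16 X genes on 100 kb, 10,000 error-free
  reads; tag must equal both the truth haplotype and a brute-force
  dual-haplotype oracle for every informative read.
- **Allelic-ratio recovery** — planted Xi fractions
  {0, 0.02, 0.3, 0.5} × 4 genes, 1500 reads/gene, 20 seeds; genes with
  ≥ 200 informative reads must land within ±0.05 ≥ 95 % of the time
  (binomial error at n = 500 is ~0.022, so the band is ≈ 2.3 sd).
- **Xi-scope asymmetry** — 39 silenced X genes (wt Xi fraction 0.14)
  plus 10 autosomal genes, 3 replicates per condition (mirroring a
  2-wt + CRISPR-control design), 4000 reads/gene; the KO multiplies
  Xi output 1.5× in 80 % of silenced genes. Replicates and depth put
  the per-gene Xi-fold log2 standard error near 0.1, i.e. the planted
  shift (≈ 1.45× in TPM space after compositional renormalisation)
  sits > 2 SE above the 1.25 threshold even for SNP-poor genes.
- **Xist induction** — 24 genes across an autosome and the X, 10,000
  reads per library, 20 seeds; per-seed fold noise is ~10 %, so the
  across-seed mean is the quantity compared with the planted 6.0 / 2.5.
- **Peak recovery** — five 1-kb domains at 8× enrichment on 500 kb,
  10,000 fragments (~20 kept fragments/kb) against equal-depth IgG,
  20 seeds, Jaccard-0.5 matching.
- **Xi gains** — four 2-kb KO-only domains (10×, 95 % haplotype 1) on
  a 300-kb X; G1-restricted tracks, wt as background; all and only the
  planted domains must be reported.
- **DE calibration** — 400 genes, 3 vs 3 libraries, 20 null seeds and
  20 power seeds with 10 % of genes at 4-fold.

## Known limitations

- The tagging model ignores indel evidence and secondary alignments by
  construction; real data would need aligner-level handling first.
- The DE substitute is underpowered relative to DESeq2's shrinkage
  estimators at very low replication and does not model dispersion
  trends; it is calibrated, not optimal.
- The peak caller does not reproduce SEACR's exact thresholds; the
  10/5 signal cutoffs are applied to its total-signal statistic, the
  closest analog, and whether the original cutoffs referred to total
  or maximum signal is ambiguous — total is used and logged.
- Allelic coverage tracks are undefined in SNP deserts; apparent gaps
  there are a property of the cross, not of the data.
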