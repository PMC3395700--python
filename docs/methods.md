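# Methods

`shmscan` detects genes whose 5′ regulatory regions accumulate somatic
hypermutation (SHM)-like variants, using aligned reads from an
active-promoter-mark ChIP-seq experiment (H3K4me3 or a comparable mark)
as the sequence source. This note records the model, its assumptions,
the tunable parameters, the synthetic-data generator, and the numerical
and design choices a maintainer would want to know.

## The statistical model

**Site-level variant calling.** At a genomic position covered by `n`
retained reads, let `k` be the number of reads disagreeing with the
reference. Under the null that every disagreement is a sequencing error,
`k` is a sum of independent, *non-identical* Bernoulli trials: read `j`
contributes a base sequenced at cycle `c_j`, and Illumina error depends
strongly on cycle. The per-cycle error rate is estimated once for the
whole experiment,

    p_i = (# reads mismatching the reference at cycle i) /
          (# reads longer than i bases),

and the null for a site is the Poisson-Binomial distribution of the sum
over the `n` overlapping reads' cycle-specific rates. The site p-value
is the exact upper tail `P(S ≥ k)`. Mismatches at high-error cycles are
thereby automatically down-weighted relative to mismatches at clean
cycles. The tail is computed by dynamic-programming convolution of the
per-trial probabilities — algebraically equivalent to the classical
recursion over the odds weights `w_i = p_i/(1−p_i)`, but without that
recursion's alternating-sign cancellation. Sites are scored only at
depth `n ≥ 4` and `k ≥ 1`; p-values are Benjamini–Hochberg adjusted over
all scored sites, and calls are kept at 1% FDR.

The null deliberately uses the cycles of **all** overlapping reads
(matches and mismatches alike): this is the only reading under which the
mismatch count is a well-defined `n`-trial Poisson-Binomial sum given
where the site falls inside each read.

**Confidence filtering.** Calls are filtered to a high-confidence set
by three gates: alternate-allele ratio `k/n ≥ 0.33`; mean
alternate-supporting base quality, on the raw ASCII scale, above a
threshold; and a two-sided Welch t-test comparing reference-read vs
alternate-read qualities with `p ≥ 0.05` (a quality-biased alternate
population indicates a systematic artifact). When the t-test is
undefined — `k = n`, a group smaller than two, or zero variance in both
groups — the gate passes vacuously: absence of evidence of bias cannot
reject a call.

**Promoter windows, novelty, enrichment.** A gene's 5′ regulatory
region is the 4-kb window centered on its TSS (multi-transcript genes
collapse to the 5′-most transcript start on the gene strand). A call is
*novel* if its position is absent from the supplied known-polymorphism
set, and *promoter* if it falls in a mark-enriched window. Because the
enrichment criterion of the original experiments is not recoverable,
three interchangeable modes are provided — a minimum-overlapping-read
threshold (default, N = 20), a Poisson test against the genome-wide
background rate, and intersection with an externally supplied peak BED —
and the enriched windows define the universe for everything downstream.

**Gene-level clustering.** With `T` high-confidence novel promoter SNVs
over `W` enriched windows, the expected count per window under uniform
placement is `λ = T/W`, and a gene with `k_gene` novel SNVs gets the
Poisson tail `P(X ≥ k_gene; λ)`, BH-adjusted across genes with at least
one novel SNV. The clustering gate is `k_gene ≥ 3` and adjusted
`p < 0.005`.

**Motif-context enrichment.** AID targets the G/C of RGYW/WRCY 4-mers
and (via polymerase-η repair) the A/T of WA/TW dinucleotides
(R = A/G, Y = C/T, W = A/T). Each window is scanned on one strand with
both the motif and its reverse complement, so both DNA strands are
covered; the window sequence is extended by 3 bp so motifs straddling
the boundary are found; a position counts at most once per motif class.
For each candidate gene, `obs` is the number of novel SNVs at
motif-mutable positions of a class, and the null is built by
permutation: redraw the same number of positions uniformly *without
replacement* from the window's covered positions (depth ≥ 4) and count
motif hits, 1,000 times. Then `z = (obs − exp)/sd` over the permutation
null. Proposals are drawn from covered positions, not all window
positions, because SNVs are only detectable where there is coverage;
uneven coverage would otherwise bias the expectation.

**Hotspot call.** A gene is an SHM hotspot iff `k_gene ≥ 3`, adjusted
cluster `p < 0.005`, and `z > 1` (strict) for either motif class.
Transitions are A↔G and C↔T; "downstream of TSS" is evaluated in gene
orientation with the TSS position itself counted as downstream (it is
the first transcribed base).

## Parameters

| key | default | meaning |
|---|---|---|
| `min_depth` | 4 | minimum reads for a site to be scored |
| `fdr` | 0.01 | BH FDR for site-level calling |
| `min_ratio` | 0.33 | allele-ratio confidence gate |
| `min_quality` | encoding-dependent | mean alt quality gate, raw ASCII scale |
| `quality_encoding` | `phred+33` | FASTQ offset; sets the default quality gate |
| `ttest_p` | 0.05 | quality-bias gate |
| `window` | 4000 bp | promoter window width |
| `min_snvs` | 3 | cluster-size gate |
| `gene_q` | 0.005 | adjusted cluster-p gate |
| `z_gate` | 1.0 | motif-enrichment gate (strict >) |
| `n_perm` | 1000 | permutations per motif class |
| `min_mapq` | 1 | "uniquely aligned" criterion (drop MAPQ 0) |

The quality gate deserves a note: a threshold of 90 on the raw ASCII
scale presumes Phred+64 encoding (Q ≥ 26). With the modern Phred+33
default the equivalent threshold 59 is applied automatically; both the
encoding and the threshold are configurable, and the offset is used for
the gate's arithmetic only — qualities are otherwise carried as raw
integers.

1,000 permutations bound the Monte-Carlo error of `z` well below the
`z = 1` decision boundary for the effect sizes that matter (a true
motif-context hotspot has `z` in the several-sigma range; see the
recovery experiments).

## The synthetic-data generator

The generator emulates the data model of promoter-mark ChIP-seq in
hypermutating B cells: reads tile 4-kb TSS windows at a configurable
mean depth, 50/50 on each strand, with a per-cycle error rate ramping
linearly (default 0.1% → 1% along a 50-bp read, the shape of Illumina
error); germline SNPs are planted at allele fraction 0.5 or 1.0 and
listed in the known-variant file; novel SNVs are planted at allele
fraction 0.5; SHM plants sit at motif-mutable bases, are
transition-biased (G→A, C→T, default 80%), skew 80% downstream of the
TSS, and default to allele fraction 0.6 — SHM sites observed in
promoter-mark ChIP-seq reads show alternate-allele fractions well above
the heterozygous 0.5 (a Sanger-validated example in this assay class
read 29 alternate alleles in 39 reads), consistent with allelic
chromatin bias toward the transcriptionally engaged allele. `mean_depth`
targets the *non-clonal* coverage that survives deduplication: random
tiling makes distinct molecules collide on (5′ start, strand), so the
raw read count is inflated by the exact Poisson occupancy correction.
Exact-duplicate reads are additionally injected (default 3%) to
exercise the clonal-read filter.

What the generator does **not** model — and hence what passing tests do
not show about real data: base-quality noise (qualities are flat Q35, so
the quality-bias t-test is exercised only by targeted unit tests; with
i.i.d. quality noise the t-test gate would reject ~5% of true sites by
construction, which is a property of the published filter, not of this
implementation), indels and soft-clipping, fragment-size/shift structure
of ChIP, mappability variation, GC bias, and contamination. Reads are
emitted directly as alignments; the tool's contract starts at aligned
reads, so aligner behavior is out of scope.

## Validation experiments and problem sizes

Two planted-truth experiments drive the acceptance checks, sized to run
on a single CPU in minutes:

* **SNV recovery** — 60 genes, 200 planted novel SNVs at allele
  fraction 0.5, 100 planted known SNPs, 30× non-clonal promoter depth.
  Measured: sensitivity and precision of the high-confidence novel
  promoter set, and the fraction of called planted-SNP sites flagged
  known. Typical results: sensitivity 0.96–0.98 (the residual misses
  are allele-ratio draws below 1/3 — an inherent property of the 0.33
  ratio gate at heterozygous allele fraction and 30× depth), precision
  1.0.
* **Hotspot recovery** — a universe of 300 enriched promoters per
  replicate: 10 genes seeded with 5–8 RGYW-context SHMs, 50 genes with
  0–2 scattered novel SNVs, 240 covered but quiet. The universe size
  keeps `λ ≈ 0.4`, small enough that the Poisson clustering gate is
  meaningful (the published experiments had `λ ≈ 0.02` over ~16,000
  promoters; reproducing that universe is beyond desk scale, and a
  smaller universe would push `λ` so high that legitimate 5-SNV
  clusters lose significance). Measured over 20 replicates: seeded
  recovery and the hotspot rate among non-seeded genes.

The permutation-z specificity of random (non-motif) SNV placement is
checked against the *exact* discrete null (hypergeometric/multivariate
enumeration of the integer threshold `obs > exp + sd`): at 5–8 SNVs per
gene the exceedance rate of `z > 1` for either motif class is ≈0.3, not
the ≈0.16 a normal approximation would suggest — integer effects
dominate at small counts. The count-plus-cluster gates are what keep the
background hotspot rate low, as the recovery experiment shows.

## Numerical choices and degenerate inputs

* Tails are computed in probability space with float64; the closed-form
  small-`k` path (elementary symmetric polynomials from power sums of
  `w`) is used per site and falls back to the exact DP whenever
  `k > 3` or the result is within 1e−12 of zero (cancellation guard).
  A dedicated test pins the fused fast path to the reference
  `pileup → score_sites` path site-by-site.
* Modal alternate-base ties break in fixed A<C<G<T order. `k` counts
  all non-reference reads; the reported allele is the modal one.
* BH at tied p-values shares the maximal rank (standard step-up).
* `z` with zero permutation variance: 0 if `obs = exp`, ±∞ otherwise.
* Degenerate inputs are hard errors: zero reads, a cycle with mismatch
  rate 1.0 (wrong reference), read positions beyond the profile length,
  zero enriched windows, fewer covered positions than SNVs to permute,
  unsorted alignments, overlapping synthetic windows, planted variants
  at zero depth.
* Reference-N sites are skipped; N never matches a motif.
* Reverse-strand reads contribute to the error profile at their
  *sequencing-cycle* index (the aligned offset mirrored through the
  read), since cycle-dependent error is a property of the sequencer,
  not of genomic orientation. Whether the original experiments mirrored
  strands is not documented; this choice is ours.

## Known limitations

* Substitutions only; indel evidence is discarded with the aligned-base
  extraction.
* No matched-normal model: "novel" means absent from the supplied
  polymorphism set, so private germline variants are indistinguishable
  from somatic ones (the published analysis had the same limitation and
  argued from normal-cell controls).
* Position-level dbSNP filtering by default (allele-aware mode exists
  but real dbSNP filtering practice was position-level).
* The enrichment criterion for promoters is heuristic; absolute counts
  of enriched promoters are therefore not comparable across enrichment
  modes, and downstream λ shifts accordingly.
* Whole-batch processing holds the alignment columns in memory
  (~25 bytes/aligned base); tens of millions of reads fit in a few GB,
  but chromosome-split streaming would be needed far beyond that.
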