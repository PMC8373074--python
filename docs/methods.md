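# Methods

## The score

Chromatin fractionated on a sucrose gradient by sedimentation velocity
separates by local compaction: fragments carrying few inter-nucleosomal
contacts stay near the top (Fr-1), heavily compacted fragments sediment to
the bottom (Fr-5). With per-fraction sequencing depth d_f(p) at base p, the
local compaction score is

    score(p) = log2( (d5(p) + ε) / (d1(p) + ε) ),   ε = 0.001.

Each fraction's raw coverage is first rescaled so its genome-wide total
equals a common target ("wigsum", default 8.5×10⁹), then multiplied by a
per-fraction recovered-DNA factor (default 1.0 — real experiments measure
these factors; they shift the whole score by log2(r5/r1) and carry all
inter-fraction asymmetry, since the wigsum itself cancels in the ratio).
The ε offset is applied exactly once, after all scaling, to both numerator
and denominator; it bounds the score where either fraction has zero
coverage. Scores are kept per base internally; the bedGraph writer
run-length-compresses equal adjacent values.

Five compaction classes are cut at configurable edges, default
(−4.5, −3.5, −2.5, −1.5), chosen to include the two operationally meaningful
thresholds: −3.5 (the "compacted" cut used for the genome-wide tally) and
−2.5 ("relatively open", used for TAD boundaries). These defaults are a
documented choice, not a measured quantity.

## The synthetic study

The generator plants a per-base compaction parameter c ∈ [0, 1] and
simulates everything downstream from it.

- **Landscape.** Constant baseline c = 0.8 (a well-compacted genome) with a
  Gaussian openness valley at each gene's TSS:
  c(x) = baseline − depth·exp(−(x − tss)²/(2σ²)), σ = 150 bp, truncated at
  4σ; per-gene depths uniform in [0.2, 0.8]. Depths above the baseline are
  rejected; where valleys of neighbouring genes overlap, deficits add and
  the result is clipped into [0, 1].
- **Sedimentation.** A fragment with mean compaction c̄ over its span gets
  fraction 1 + Binomial(4, c̄). This is the simplest law mapping [0, 1]
  onto five fractions with the right endpoints (c̄ = 0 → always Fr-1,
  c̄ = 1 → always Fr-5) and a strictly monotone expected fraction; it gives
  closed-form oracles (e.g. the ML compaction estimate (mean fraction −1)/4,
  and exact multinomial proportions at constant c̄). It is deliberately
  sharper than real fractionation, where even compact loci leave 10–20% of
  their DNA in Fr-1: under the binomial law, Fr-1 coverage nearly vanishes
  on the compact baseline, so baseline scores are large and positive rather
  than sitting just below zero as in real data. Relative contrasts — which
  all downstream statistics use — are unaffected.
- **Fragments.** 10⁶ fragments, uniform placement (no GC/mappability bias by
  design), lengths uniform in [300, 500] bp, matching the 2–3-nucleosome
  fragment sizes such protocols produce. Optional per-fraction thinning
  (keep-probability ≤ 1) emulates unequal DNA recovery; the default is no
  thinning because published per-fraction recovery values live in
  supplementary material we do not reproduce.
- **Expression.** log10(TPM+1) = max(0, a − b·c(TSS) + N(0, τ)), a = b =
  2.5, τ = 0.3: fully open TSSs reach TPM ≈ 315, fully compact TSSs are
  silent; the floor mirrors TPM nonnegativity. Under the demo depth range
  the planted c(TSS) spans [0, 0.6], so the Low class (log10(TPM+1) < 0.15)
  is empty; class-grouped outputs omit empty classes with a warning.
- **Nucleosome occupancy.** Baseline 0.8 with Gaussian TSS valleys of depth
  drawn independently of the landscape (uniform [0, 0.6], σ = 150 bp,
  Gaussian noise sd 0.05 truncated at zero). The independence is the point:
  it makes the NFR-vs-score and NFR-vs-expression correlations null by
  construction, so recovering |r| < 3/√n downstream is a real statistical
  check, not an artifact. Coupled occupancy (depths tied to class or to c)
  is available by passing explicit depth vectors.
- **RNAP binding.** Gaussian TSS peaks of height 10·(1 − c(TSS)), σ =
  200 bp, noise sd 0.2 — binding frequency grows with openness.
- **Repeats and TADs.** 120 repeat intervals (0.2–2 kb) scattered uniformly;
  TADs partition each chromosome into contiguous blocks of 20–80 kb,
  independent of gene placement.

What the simulator does **not** emulate: sequence content and read-level
errors, alignment and mappability, GC bias, fraction cross-contamination,
cell-to-cell heterogeneity, and the mixture character of real fractionation
(a locus distributing across all five fractions at once beyond what the
binomial law produces). Tests passing on the simulator therefore validate
the pipeline's arithmetic and its statistical behaviour under the stated
model, not the biology of any particular dataset.

## Windows, filtering, qualification

- Coordinates are 0-based half-open everywhere. The TSS window is the
  250 bp immediately upstream of, and excluding, the start base: a + strand
  gene starting at s has window [s−250, s); a − strand gene ending at e has
  [e, e+250). The TES window is mirrored downstream of transcription with
  the same size (no separate TES size is established in the field; reusing
  250 bp keeps the two statistics comparable). Windows are clipped at
  chromosome edges with a warning.
- Repeat filtering removes windows overlapping any repeat by ≥ 1 bp
  (half-open test, abutting intervals do not overlap); it applies to window
  lists, never to the score track itself.
- rcpm (read count per million mapped) of a window counts fragments
  overlapping it by ≥ 1 bp × 10⁶ / total mapped fragments. The pipeline
  pools fragments over all five fractions for this, with the pool size as
  the denominator. Genes qualify iff rcpm > 0.05 (strict) at both TSS and
  TES; qualification protects the log-ratio score from zero-coverage
  windows.
- Metagene profiles rescale each gene body to 100 bins with 40 native-scale
  bins per 2 kb flank, orient minus-strand genes so transcription runs left
  to right, average depth across genes per fraction, and report each bin's
  per-fraction proportions (columns with signal sum to 1, so the profile is
  invariant to any common rescaling of the five tracks). Genes shorter than
  the bin count or with flanks off-chromosome are skipped and counted.

## Association statistics

NFR depth is max − min occupancy over the TSS window, unsmoothed;
translation-invariant and linear in the track, so occupancy units are
irrelevant to correlations. Correlations are sample Pearson r with an OLS
approximation line; r and the two-sided p-value are reported per test with
no multiple-testing adjustment (tests are few and reported individually).
Constant inputs raise an undefined-correlation error; pipeline callers
degrade to a warning and still emit the underlying table. TAD summaries use
per-base population SD (ddof = 0); each TAD contributes both endpoints as
boundaries (deduplicated per chromosome), a boundary's score is the mean
over a symmetric 2 kb window (matching the resolution TAD callers typically
use) and it is "open" iff that mean is below −2.5. Relative-abundance
vectors use log2(amount / mean over fractions); zero amounts get the same
0.001-type offset as the score, with a warning.

Expression classes intentionally leave gaps: genes with log10(TPM+1) in
(0.15, 0.5] or (1.5, 2.0] carry no class and are excluded from class-grouped
figures but retained in scatter/correlation analyses, which use all
qualified, repeat-free genes (TSS analyses filter on the TSS window, TES
analyses on the TES window).

## Numerical and design notes

- All randomness flows through numpy Generators seeded from explicit
  integers; every generator operation salts the seed differently, so one
  config seed yields independent streams per stage and byte-identical
  outputs across reruns.
- Per-gene scores are means over the 250 bp window of the per-base score
  (not a re-ratio of window-mean depths); window means of a log-ratio and
  log-ratios of window means differ, and the per-base mean matches the
  per-base definition of the score.
- Fragment mean compaction uses a per-chromosome cumulative sum (O(1) per
  fragment); values are clipped to [0, 1] to absorb cumulative-sum drift.
- Repeat-overlap filtering uses sorted starts with a prefix maximum of ends
  (binary search per window); a brute-force all-pairs oracle checks it in
  the test suite.
- Demo problem sizes (1 chrom × 1 Mb, 200 genes, 10⁶ fragments, 10⁵
  fragments for the constant-compaction check) keep a full run to a few
  seconds while leaving ≥ 150 qualified genes for the correlation analyses.

## Known limitations

- The binomial sedimentation law has no free dispersion parameter; real
  gradients mix more.
- Recovery factors default to 1.0; with real data they must be supplied, and
  the absolute score scale (including the class-edge defaults) shifts with
  them.
- One TSS/TES per gene model; isoforms are out of scope.
- BAM ingestion is not implemented; inputs are BED/bedGraph/TSV.
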