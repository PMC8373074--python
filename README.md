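# fracscore

Chromatin-compaction scoring from sedimentation-velocity fractionation
sequencing.

Sedimentation-velocity centrifugation of crosslinked, sonicated chromatin
separates it by its degree of local compaction: open chromatin stays in the
upper gradient fractions (Fr-1), compact chromatin sediments to the lower
ones (Fr-5). Sequencing the DNA from each fraction turns this into a
genome-wide readout. `fracscore` implements the downstream analysis for
researchers working with such data:

- per-fraction fragment coverage, normalized to a common total signal
  ("wigsum") and scaled by per-fraction recovered-DNA factors;
- the per-base **Fr-5/Fr-1 compaction score**

  `score(p) = log2( (d5(p) + ε) / (d1(p) + ε) )`,  ε = 0.001,

  where very negative values mark locally open chromatin and values near or
  above the compact baseline mark closed chromatin, plus its five-class
  genome-wide binning;
- strand-aware TSS/TES window statistics (window means, read count per
  million mapped, repeat-overlap exclusion, gene qualification at
  rcpm > 0.05);
- metagene fractional-proportion profiles over scaled gene bodies;
- nucleosome-free-region (NFR) depth (max − min MNase occupancy in the
  250 bp TSS window) and TSS occupancy curves;
- gene-level association: expression classes on the log10(TPM+1) scale
  (Low < 0.15, Mid (0.5, 1.5], High > 2.0), Pearson correlations with
  least-squares approximation lines, RNAP-binding association, and TAD
  mean/SD and boundary-openness summaries.

Because public fractionation datasets are large, the package ships a
**synthetic sedimentation simulator**: it plants a known per-base compaction
landscape `c ∈ [0, 1]` (compact baseline with Gaussian openness valleys at
TSSs), sediments fragments by the law `fraction = 1 + Binomial(4, c̄)`, and
couples expression, RNAP binding and (optionally) nucleosome occupancy to
the landscape. Every pipeline stage can therefore be validated against
ground truth, end to end, with no downloads.

## Worked example

```python
from fracscore import RunConfig, run_analysis

res = run_analysis(RunConfig(seed=1))   # 1 Mb, 200 genes, 1e6 fragments
for name in ("planted_recovery", "tss_expression", "tes_expression"):
    fit = res.fits[name]
    print(f"{name}: r = {fit.r:+.4f} (n = {fit.n})")
print(f"genome above -3.5: {res.classification.pct_above_threshold:.1f}%")
```

prints

```
planted_recovery: r = +0.9199 (n = 168)
tss_expression: r = -0.7321 (n = 168)
tes_expression: r = -0.0060 (n = 168)
genome above -3.5: 93.4%
```

The planted TSS compaction and the computed TSS-window score agree at
r ≈ +0.92 — the score recovers the ground truth. Expression, which the
generator coupled to TSS openness, is strongly anticorrelated with the TSS
score and essentially uncorrelated with the TES score; and ~93% of the toy
genome sits above the −3.5 compaction cut, i.e. nearly the whole genome is
well compacted except the open TSS neighbourhoods.

The `examples/` directory contains one short script per capability
(simulation, scoring/classification, expression association, the NFR null,
TAD summaries). A thin CLI mirrors the library:
`fracscore run --config cfg.yaml -o outdir` writes per-fraction BEDs, the
score bedGraph, gene association/NFR/TAD/metagene TSVs and a manifest;
`fracscore score --fr1 fr1.bed --fr5 fr5.bed --chrom-sizes chrom.sizes -o
score.bedgraph` scores two fragment BED files directly.

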