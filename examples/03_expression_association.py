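"""Relate TSS/TES compaction scores to transcription level.

Runs the full demo study (1 Mb, 200 genes, 1e6 fragments) where expression
was planted as log10(TPM+1) = max(0, 2.5 - 2.5 * c(TSS)) + noise.  The
pipeline recovers a strong negative correlation between the TSS score and
expression, much weaker at the TES (which has no planted valley), and a
strong positive correlation between the planted TSS compaction and the
computed score — the central validation of the score as a compaction
readout.
"""

from fracscore import RunConfig, run_analysis

res = run_analysis(RunConfig(seed=1))

for name, label in [
    ("planted_recovery", "planted TSS compaction vs computed TSS score"),
    ("tss_expression", "TSS score vs log10(TPM+1)"),
    ("tes_expression", "TES score vs log10(TPM+1)"),
    ("rnap_score", "RNAP TSS binding vs TSS score"),
]:
    fit = res.fits[name]
    print(f"{label}: r = {fit.r:+.4f} (n = {fit.n}, slope = {fit.slope:+.3f})")

print("\nnegative TSS r with |r_TSS| > |r_TES|: open TSS chromatin, not gene-body")
print("chromatin, carries the expression signal.")
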