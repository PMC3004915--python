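"""Estimate a library's strand-assignment error from splice-junction reads.

Junction reads have a built-in orientation (introns are strand-specific),
so the fraction observed on the wrong strand measures the library's
background rate p_bg — the null rate the antisense caller tests against.
"""

from antiscribe import SimulationConfig, estimate_strand_specificity, simulate_annotation, simulate_junction_reads

cfg = SimulationConfig(
    n_genes=40, library_depth=60_000, junction_fraction=0.5,
    strand_error_rate=0.005, frac_antisense_loci=0.0, seed=1,
)
genes, truth = simulate_annotation(cfg)
junc = simulate_junction_reads(truth, cfg, "NM1")

spec = estimate_strand_specificity(junc, genes, "NM1")
print(f"junction reads matching annotated introns: {spec.n_junction_reads}")
print(f"wrong orientation: {spec.n_wrong_orientation}")
print(f"estimated p_bg = {spec.p_bg:.5f}  (95% CI {spec.ci_low:.5f}..{spec.ci_high:.5f})")
print(f"correct-orientation rate: {100*(1-spec.p_bg):.2f}%")
# With a true error of 0.5% the correct-orientation rate sits in the
# 99.4-99.6% regime and the exact CI covers the true rate.
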