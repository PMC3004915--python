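"""Chromatin occupancy metaprofiles for antisense vs non-antisense genes.

Simulates an H2A.Z-style tiling track elevated over antisense-positive
gene bodies, builds Gaussian-smoothed metagene profiles (gene body
scaled to 100 bins, 1 kb flanks in bp), and runs the one-sided rank-sum
group test on per-gene body means.
"""

import numpy as np

from antiscribe import (
    SimulationConfig,
    build_metaprofile,
    compare_group_occupancy,
    simulate_annotation,
    simulate_occupancy_track,
)
from antiscribe.occupancy import gene_region_summary, normalize_probes

cfg = SimulationConfig(n_genes=400, occupancy_noise_sd=0.5, seed=3)
genes, truth = simulate_annotation(cfg)
has_as = dict(zip(truth.genes.gene_id, truth.genes.mechanism != "none"))
assignment = {g: ("antisense" if has_as[g] else "background") for g in has_as}
probes = normalize_probes(
    simulate_occupancy_track(genes, assignment, cfg, group_effects={"antisense": 1.0})
)

group_as = [g for g in genes if has_as[g.gene_id]]
group_bg = [g for g in genes if not has_as[g.gene_id]]
prof_as = build_metaprofile(probes, group_as, group_id="antisense", sd=40)
prof_bg = build_metaprofile(probes, group_bg, group_id="background", sd=40)

pos = np.array(prof_as.positions)
body = (pos >= 0) & (pos <= 100)
print(f"antisense genes: {prof_as.n_genes}, background genes: {prof_bg.n_genes}")
print(f"mean body log2(IP/WCE): antisense {np.nanmean(np.array(prof_as.mean)[body]):.2f} "
      f"vs background {np.nanmean(np.array(prof_bg.mean)[body]):.2f}  (planted effect 1.0)")

summary = gene_region_summary(probes, genes, region="body")
p = compare_group_occupancy([g.gene_id for g in group_as], [g.gene_id for g in group_bg], summary)
print(f"one-sided rank-sum p (antisense > background): {p:.2e}")
# The profile recovers the planted one-log2-unit body elevation and the
# group test rejects decisively.
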