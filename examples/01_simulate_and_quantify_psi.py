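"""Simulate a two-population cohort and quantify exon-skipping PSI.

Builds a small synthetic dataset (genotypes under Balding-Nichols drift,
exon-skipping events with planted cis effects, binomial junction reads),
then estimates PSI per event and sample from the junction counts and
compares the estimates with the generator's ground truth.
"""

import numpy as np

from spliceqtl.splicing import compute_psi
from spliceqtl.synth import SimConfig, simulate_dataset

cfg = SimConfig(n_pop1=40, n_pop2=20, n_variants=120, n_genes=20, n_events=20,
                coverage_mean=150, seed=1)
ds = simulate_dataset(cfg)

psi = compute_psi(ds.events, ds.junctions, min_reads=10)
err = (psi.psi - ds.truth.true_psi).abs()

print(f"events: {len(ds.events)}  samples: {ds.genotypes.n_samples}")
print(f"mean |PSI_hat - PSI_true| = {np.nanmean(err.to_numpy()):.4f}")
print(f"missing PSI cells (coverage < 10 reads): {int(psi.psi.isna().sum().sum())}")

# The mean absolute error reflects binomial read noise at ~150 junction
# reads per event; PSI is the fraction of transcripts including the exon,
# so an error of ~0.03 means exon usage is quantified to a few percent.
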