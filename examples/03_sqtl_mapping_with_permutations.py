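"""Map cis-sQTLs and attach permutation-empirical p-values.

Variants inside each alternatively spliced exon and its flanking introns
are regressed against per-sample PSI; empirical p-values come from
permuting the phenotype's sample labels (pseudo-count estimator), the
standard defense against non-normal PSI distributions.
"""

from spliceqtl import qtl
from spliceqtl.splicing import compute_psi
from spliceqtl.synth import SimConfig, simulate_dataset

cfg = SimConfig(n_pop1=35, n_pop2=35, n_variants=150, n_genes=25, n_events=25,
                causal_fraction=0.4, beta_psi=0.8, coverage_mean=100, seed=3)
ds = simulate_dataset(cfg)
psi = compute_psi(ds.events, ds.junctions)

windows = qtl.define_splice_windows(ds.events)
assoc = qtl.map_cis_qtl(ds.genotypes, psi, windows)
assoc = qtl.empirical_pvalues(ds.genotypes, psi, assoc, n_perm=1000, seed=3)

hits = [a for a in assoc if a.p_empirical is not None and a.p_empirical < 0.05]
causal = {(vid, ev) for ev, (vid, _) in ds.truth.causal_sqtl.items()}
true_hits = [a for a in hits if (a.variant_id, a.feature_id) in causal]
print(f"tested pairs: {len(assoc)}; empirical p < 0.05: {len(hits)}")
print(f"planted causal pairs recovered: {len(true_hits)} of {len(causal)}")
for a in true_hits[:3]:
    print(f"  {a.variant_id} -> {a.feature_id}: beta={a.beta:+.3f} "
          f"p_nom={a.p_nominal:.2e} p_emp={a.p_empirical:.4f}")

# beta is the PSI change per alternate allele; with a planted logit-scale
# effect of 0.8 the linearized slope is ~0.15-0.19 depending on baseline.
# The empirical p floor is 1/(n_perm+1) ~ 0.001 at 1000 permutations.
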