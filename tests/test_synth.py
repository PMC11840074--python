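"""Generator calibration: determinism, Hardy-Weinberg, drift model, planted
effects and cross-module window consistency."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from spliceqtl import qtl
from spliceqtl.io import ValidationError
from spliceqtl.splicing import compute_psi
from spliceqtl.synth import (
    POP1,
    POP2,
    SimConfig,
    simulate_dataset,
    simulate_events,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_splicing_counts,
)
from spliceqtl.validation import spearman_assoc


SMALL = dict(n_pop1=30, n_pop2=30, n_variants=80, n_genes=15, n_events=15)


class TestGenotypes:
    def test_zero_divergence_reproduces_ancestral(self):
        cfg = SimConfig(**SMALL, fst_divergence=0.0, seed=3)
        _, truth = simulate_genotypes(cfg)
        np.testing.assert_allclose(truth.pop_af[POP1], truth.ancestral_af)
        np.testing.assert_allclose(truth.pop_af[POP2], truth.ancestral_af)

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(**SMALL, seed=9)
        g1, _ = simulate_genotypes(cfg)
        g2, _ = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)
        g3, _ = simulate_genotypes(SimConfig(**SMALL, seed=10))
        assert not np.array_equal(g1.dosage, g3.dosage)

    def test_sample_af_within_three_binomial_se(self):
        cfg = SimConfig(n_pop1=200, n_pop2=200, n_variants=400, n_genes=20,
                        n_events=20, seed=12)
        gm, truth = simulate_genotypes(cfg)
        mask = gm.population_mask(POP1)
        af = gm.dosage[mask].mean(axis=0) / 2
        p = truth.pop_af[POP1]
        se = np.sqrt(p * (1 - p) / (2 * mask.sum()))
        within = np.abs(af - p) <= 3 * se
        assert within.mean() >= 0.98

    def test_hardy_weinberg_rarely_rejected(self):
        cfg = SimConfig(n_pop1=500, n_pop2=1, n_variants=500, n_genes=30,
                        n_events=30, seed=4)
        gm, _ = simulate_genotypes(cfg)
        dos = gm.dosage[gm.population_mask(POP1)]
        rejected = 0
        tested = 0
        for j in range(dos.shape[1]):
            col = dos[:, j]
            obs = np.array([(col == k).sum() for k in (0, 1, 2)], dtype=float)
            p_hat = (obs[1] + 2 * obs[2]) / (2 * obs.sum())
            exp = obs.sum() * np.array(
                [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat ** 2]
            )
            if (exp < 5).any():
                continue
            chi2 = ((obs - exp) ** 2 / exp).sum()
            tested += 1
            if stats.chi2.sf(chi2, df=1) < 0.01:
                rejected += 1
        assert tested > 300
        assert rejected / tested <= 0.02

    def test_causal_candidates_inside_their_cis_windows(self):
        cfg = SimConfig(**SMALL, causal_fraction=1.0, seed=6)
        ds = simulate_dataset(cfg)
        pos = {v.id: v.pos for v in ds.genotypes.variants}
        splice_windows = {w.feature_id: w for w in qtl.define_splice_windows(ds.events)}
        for event_id, (vid, _) in ds.truth.causal_sqtl.items():
            assert splice_windows[event_id].contains("1", pos[vid])
        promoter_windows = {}
        for w in qtl.define_promoter_windows(ds.transcripts):
            promoter_windows.setdefault(w.feature_id, []).append(w)
        for gene, (vid, _) in ds.truth.causal_eqtl.items():
            assert any(w.contains("1", pos[vid]) for w in promoter_windows[gene])


class TestSplicingCounts:
    def test_null_generator_groups_agree(self):
        cfg = SimConfig(n_pop1=50, n_pop2=50, n_variants=20, n_genes=5, n_events=5,
                        causal_fraction=0.0, psi_noise_sd=0.0, coverage_mean=200, seed=2)
        gm, truth = simulate_genotypes(cfg)
        events = simulate_events(cfg)
        jcm = simulate_splicing_counts(gm, events, truth, cfg)
        psi = compute_psi(events, jcm)
        m1 = psi.psi.loc[:, gm.population_mask(POP1)].mean(axis=1)
        m2 = psi.psi.loc[:, gm.population_mask(POP2)].mean(axis=1)
        assert (m1 - m2).abs().max() < 0.02

    def test_saturated_baseline_gives_inclusion_only(self):
        hi = float(expit(8.0))
        cfg = SimConfig(n_pop1=20, n_pop2=20, n_variants=10, n_genes=2, n_events=2,
                        causal_fraction=0.0, psi_noise_sd=0.0,
                        baseline_psi_min=hi, baseline_psi_max=hi, seed=2)
        gm, truth = simulate_genotypes(cfg)
        events = simulate_events(cfg)
        jcm = simulate_splicing_counts(gm, events, truth, cfg)
        skip_rows = jcm.meta.index[
            jcm.meta.intron_end - jcm.meta.intron_start > 800
        ]  # the long skipping introns
        frac_skip = jcm.counts.loc[skip_rows].to_numpy().sum() / jcm.counts.to_numpy().sum()
        assert frac_skip < 0.002

    def test_reproducible_under_seed(self):
        cfg = SimConfig(**SMALL, seed=33)
        gm, truth = simulate_genotypes(cfg)
        events = simulate_events(cfg)
        j1 = simulate_splicing_counts(gm, events, truth, cfg)
        gm2, truth2 = simulate_genotypes(cfg)
        j2 = simulate_splicing_counts(gm2, events, truth2, cfg)
        np.testing.assert_array_equal(j1.counts.to_numpy(), j2.counts.to_numpy())

    def test_estimator_consistency_at_high_coverage(self):
        cfg = SimConfig(n_pop1=100, n_pop2=10, n_variants=30, n_genes=8, n_events=8,
                        causal_fraction=0.0, coverage_mean=2000, seed=14)
        gm, truth = simulate_genotypes(cfg)
        events = simulate_events(cfg)
        jcm = simulate_splicing_counts(gm, events, truth, cfg)
        psi = compute_psi(events, jcm)
        err = (psi.psi - truth.true_psi).abs().to_numpy()
        assert np.nanmean(err) < 0.02


class TestPhenotypes:
    def psi_frame(self, cfg):
        gm, truth = simulate_genotypes(cfg)
        events = simulate_events(cfg)
        simulate_splicing_counts(gm, events, truth, cfg)
        return truth.true_psi, gm

    def test_null_coupling_gives_weak_correlation(self):
        cfg = SimConfig(n_pop1=35, n_pop2=35, n_variants=10, n_genes=2, n_events=2,
                        pheno_effect=0.0, seed=19)
        true_psi, gm = self.psi_frame(cfg)
        table = simulate_phenotypes(true_psi, cfg, gm.population)
        r, _ = spearman_assoc(true_psi.iloc[0].to_numpy(), table.df["hb"].to_numpy())
        assert abs(r) < 0.2

    def test_noise_free_coupling_is_monotone(self):
        cfg = SimConfig(n_pop1=35, n_pop2=35, n_variants=10, n_genes=2, n_events=2,
                        pheno_effect=4.0, pheno_noise_sd=1e-9, seed=19)
        true_psi, gm = self.psi_frame(cfg)
        table = simulate_phenotypes(true_psi, cfg, gm.population)
        r, _ = spearman_assoc(true_psi.iloc[0].to_numpy(), table.df["hb"].to_numpy())
        assert r == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_pop1=10, n_pop2=10, n_variants=10, n_genes=2, n_events=2, seed=7)
        true_psi, gm = self.psi_frame(cfg)
        t1 = simulate_phenotypes(true_psi, cfg, gm.population)
        t2 = simulate_phenotypes(true_psi, cfg, gm.population)
        np.testing.assert_array_equal(t1.df["hb"], t2.df["hb"])


def test_config_validation():
    with pytest.raises(ValidationError):
        SimConfig(fst_divergence=1.0)
    with pytest.raises(ValidationError):
        SimConfig(n_events=10, n_genes=5)
    with pytest.raises(ValidationError):
        SimConfig(n_variants=5, n_genes=40, n_events=40)


def test_config_yaml_roundtrip(tmp_path):
    cfg = SimConfig(**SMALL, seed=42, fst_divergence=0.2)
    path = tmp_path / "sim.yaml"
    cfg.to_yaml(path)
    assert SimConfig.from_yaml(path) == cfg
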