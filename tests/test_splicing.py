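"""Event enumeration vs the brute-force oracle, PSI semantics, differential
splicing thresholds and frame/PTC/NMD annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spliceqtl import splicing
from spliceqtl.io import JunctionCountMatrix, junction_key
from spliceqtl.splicing import (
    PsiMatrix,
    annotate_consequence,
    compute_psi,
    diff_splicing,
    enumerate_events,
)
from spliceqtl.synth import SimConfig, simulate_genotypes, simulate_events, simulate_splicing_counts
from conftest import make_transcript
from oracles import bruteforce_events, event_descriptor, manual_orf_scan


def make_jcm(rows, samples=("s1", "s2")):
    """rows: {key: counts list}"""
    meta_rows, keys = [], []
    for key in rows:
        chrom, rng, strand = key.split(":")[:3]
        s, e = rng.split("-")
        tag = key.split(":")[3] if key.count(":") == 3 else ""
        keys.append(key)
        meta_rows.append(
            {"chrom": chrom, "intron_start": int(s), "intron_end": int(e), "strand": strand, "tag": tag}
        )
    meta = pd.DataFrame(meta_rows, index=pd.Index(keys, name="key"))
    counts = pd.DataFrame(
        np.array([rows[k] for k in keys]), index=meta.index, columns=list(samples)
    )
    return JunctionCountMatrix(meta, counts)


class TestEnumerateEvents:
    def test_exon_skipping_definition(self):
        t1 = make_transcript([(100, 200), (300, 400), (500, 600)], tid="T1")
        t2 = make_transcript([(100, 200), (500, 600)], tid="T2")
        events = enumerate_events([t1, t2])
        assert len(events) == 1
        ev = events[0]
        assert ev.etype == "ES"
        assert ev.coord_map["skipped"] == (300, 400)
        assert set(ev.inclusion_junctions) == {
            junction_key("1", 201, 299, "+"),
            junction_key("1", 401, 499, "+"),
        }
        assert set(ev.skipping_junctions) == {junction_key("1", 201, 499, "+")}

    def test_alt_donor_plus_strand_is_a5ss(self):
        # shared acceptor at 500, two donors for the first exon
        t1 = make_transcript([(100, 200), (500, 600)], tid="T1")
        t2 = make_transcript([(100, 250), (500, 600)], tid="T2")
        events = enumerate_events([t1, t2])
        assert [e.etype for e in events] == ["A5SS"]
        assert {event_descriptor(e) for e in events} == bruteforce_events([t1, t2])

    def test_alt_acceptor_minus_strand_is_a5ss(self):
        t1 = make_transcript([(100, 200), (500, 600)], strand="-", tid="T1")
        t2 = make_transcript([(100, 200), (450, 600)], strand="-", tid="T2")
        events = enumerate_events([t1, t2])
        assert [e.etype for e in events] == ["A5SS"]

    def test_mutually_exclusive_exons(self):
        t1 = make_transcript([(100, 200), (300, 350), (700, 800)], tid="T1")
        t2 = make_transcript([(100, 200), (500, 550), (700, 800)], tid="T2")
        events = enumerate_events([t1, t2])
        assert [e.etype for e in events] == ["MXE"]
        assert {event_descriptor(e) for e in events} == bruteforce_events([t1, t2])

    def test_intron_retention_pseudo_junctions(self):
        t1 = make_transcript([(100, 600)], tid="T1")
        t2 = make_transcript([(100, 200), (300, 600)], tid="T2")
        events = enumerate_events([t1, t2])
        assert [e.etype for e in events] == ["IR"]
        ev = events[0]
        assert set(ev.inclusion_junctions) == {
            junction_key("1", 201, 299, "+", "IR5"),
            junction_key("1", 201, 299, "+", "IR3"),
        }

    def test_single_transcript_gene_is_empty(self):
        assert enumerate_events([make_transcript([(1, 10), (20, 30)])]) == []

    def test_deduplicated_across_pairs(self):
        t1 = make_transcript([(100, 200), (300, 400), (500, 600)], tid="T1")
        t2 = make_transcript([(100, 200), (500, 600)], tid="T2")
        t3 = make_transcript([(100, 200), (500, 600), (700, 800)], tid="T3")
        events = enumerate_events([t1, t2, t3])
        assert sum(e.etype == "ES" for e in events) == 1

    @staticmethod
    def random_gene(rng):
        pool = np.sort(rng.choice(np.arange(1, 60), size=12, replace=False)) * 10
        txs = []
        for t in range(rng.integers(2, 4)):
            k = int(rng.integers(1, 4))  # up to 6 boundaries = 3 exons... allow 6 exons
            k = int(rng.integers(1, 7 // 2 + 1))
            picks = np.sort(rng.choice(len(pool), size=2 * k, replace=False))
            exons = [(int(pool[picks[2 * i]]), int(pool[picks[2 * i + 1]])) for i in range(k)]
            txs.append(make_transcript(exons, tid=f"T{t}", gene="G"))
        return txs

    def test_agrees_with_bruteforce_on_random_genes(self):
        rng = np.random.default_rng(4021)
        for _ in range(150):
            txs = self.random_gene(rng)
            got = {event_descriptor(e) for e in enumerate_events(txs)}
            assert got == bruteforce_events(txs)


class TestComputePsi:
    def ev(self):
        t1 = make_transcript([(100, 200), (300, 400), (500, 600)], tid="T1")
        t2 = make_transcript([(100, 200), (500, 600)], tid="T2")
        return enumerate_events([t1, t2])[0]

    @pytest.mark.parametrize(
        "inc1, inc2, skip, expected",
        [
            (12, 8, 0, 1.0),  # only inclusion reads: every transcript has the exon
            (0, 0, 25, 0.0),  # only skipping reads: every transcript skips it
            (6, 10, 8, 0.5),  # mean inclusion 8 equals skipping 8
        ],
    )
    def test_boundary_and_midpoint_semantics(self, inc1, inc2, skip, expected):
        ev = self.ev()
        jcm = make_jcm(
            {
                ev.inclusion_junctions[0]: [inc1, 0],
                ev.inclusion_junctions[1]: [inc2, 0],
                ev.skipping_junctions[0]: [skip, 0],
            }
        )
        mat = compute_psi([ev], jcm, min_reads=5)
        assert mat.psi.iloc[0, 0] == pytest.approx(expected)
        assert np.isnan(mat.psi.iloc[0, 1])  # zero coverage -> missing

    def test_low_coverage_is_missing(self):
        ev = self.ev()
        jcm = make_jcm(
            {
                ev.inclusion_junctions[0]: [4, 0],
                ev.inclusion_junctions[1]: [4, 0],
                ev.skipping_junctions[0]: [5, 0],
            }
        )
        mat = compute_psi([ev], jcm, min_reads=10)
        assert np.isnan(mat.psi.iloc[0, 0])  # I + S = 9 < 10

    @given(scale=st.integers(min_value=1, max_value=50))
    @settings(deadline=None, max_examples=20)
    def test_scaling_invariance(self, scale):
        ev = self.ev()
        jcm = make_jcm(
            {
                ev.inclusion_junctions[0]: [12 * scale, 0],
                ev.inclusion_junctions[1]: [8 * scale, 0],
                ev.skipping_junctions[0]: [10 * scale, 0],
            }
        )
        mat = compute_psi([ev], jcm, min_reads=1)
        assert mat.psi.iloc[0, 0] == pytest.approx(10.0 / 20.0)


class TestDiffSplicing:
    def groups(self, n1, n2):
        g = {f"a{i}": "g1" for i in range(n1)}
        g.update({f"b{i}": "g2" for i in range(n2)})
        return g

    def psi_matrix(self, rows, groups):
        return PsiMatrix(pd.DataFrame(rows, columns=list(groups)).T.pipe(lambda d: d.T))

    def test_identical_groups_not_significant(self):
        groups = self.groups(5, 5)
        vals = [0.5, 0.6, 0.4, 0.55, 0.45] * 2
        psi = PsiMatrix(pd.DataFrame([vals], index=["e1"], columns=list(groups)))
        res, skipped = diff_splicing(psi, groups)
        assert not skipped
        assert res[0].delta_psi == pytest.approx(0.0)
        assert not res[0].significant

    def test_small_delta_never_significant_despite_tiny_p(self):
        # 30 vs 30 samples, clearly separated but |dPSI| = 0.08 < 0.1
        groups = self.groups(30, 30)
        rng = np.random.default_rng(5)
        x = 0.50 + rng.normal(0, 0.005, 30)
        y = 0.42 + rng.normal(0, 0.005, 30)
        psi = PsiMatrix(pd.DataFrame([np.r_[x, y]], index=["e1"], columns=list(groups)))
        res, _ = diff_splicing(psi, groups)
        assert res[0].adj_p < 1e-6
        assert abs(res[0].delta_psi) < 0.1
        assert not res[0].significant

    def test_recovers_planted_group_difference(self):
        # true PSI 0.9 (pop1) vs 0.5 (pop2), coverage 200, n = 30/30
        cfg = SimConfig(
            n_pop1=30, n_pop2=30, n_variants=4, n_genes=2, n_events=2,
            causal_fraction=0.0, coverage_mean=200, psi_noise_sd=0.0,
            baseline_psi_min=0.5, baseline_psi_max=0.5,
            psi_pop1_shift_logit=float(np.log(0.9 / 0.1) - np.log(0.5 / 0.5 if False else 1.0)),
            seed=8,
        )
        gm, truth = simulate_genotypes(cfg)
        events = simulate_events(cfg)
        jcm = simulate_splicing_counts(gm, events, truth, cfg)
        psi = compute_psi(events, jcm)
        res, _ = diff_splicing(psi, gm.population)
        for r in res:
            assert r.significant
            assert r.delta_psi == pytest.approx(0.4, abs=0.05)

    def test_sparse_event_skipped_with_reason(self):
        groups = self.groups(3, 3)
        vals = [0.5, np.nan, np.nan, 0.4, 0.5, 0.6]
        psi = PsiMatrix(pd.DataFrame([vals], index=["e1"], columns=list(groups)))
        res, skipped = diff_splicing(psi, groups)
        assert res == [] and skipped == [("e1", "too_few_informative")]

    def test_null_false_positive_rate_controlled(self):
        cfg = SimConfig(
            n_pop1=25, n_pop2=25, n_variants=120, n_genes=60, n_events=60,
            causal_fraction=0.0, coverage_mean=100, seed=21,
        )
        gm, truth = simulate_genotypes(cfg)
        events = simulate_events(cfg)
        jcm = simulate_splicing_counts(gm, events, truth, cfg)
        res, _ = diff_splicing(compute_psi(events, jcm), gm.population)
        frac = np.mean([r.significant for r in res])
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 3 * se


NO_T = "CAGCAGCAG"  # stop codons all start with T; T-free sequence cannot stop


def _genome_for(exons, seqs, chrom="1"):
    length = max(e for _, e in exons) + 10
    genome = ["A"] * length
    for (s, e), seq in zip(exons, seqs):
        assert len(seq) == e - s + 1
        genome[s - 1 : e] = list(seq)
    return {chrom: "".join(genome)}


class TestConsequence:
    def build(self, len2, exon3_seq=None, exon3_len=120):
        e1 = (101, 199)  # 99 nt, T-free
        e2 = (301, 300 + len2)
        e3 = (1001, 1000 + exon3_len)
        e4 = (2001, 2150)  # 150 nt, stops in every frame
        exons = [e1, e2, e3, e4]
        s1 = ("CAG" * 33)
        s2 = ("CAC" * ((len2 + 2) // 3 + 1))[:len2]
        s3 = exon3_seq or ("CCA" * ((exon3_len + 2) // 3 + 1))[:exon3_len]
        s4 = ("TAA" * 50)
        tx = make_transcript(exons, cds=(1, sum(e - s + 1 for s, e in exons)))
        genome = _genome_for(exons, [s1, s2, s3, s4])
        events = enumerate_events(
            [tx, make_transcript([e1, e3, e4], tid="G.T2")]
        )
        (ev,) = [e for e in events if e.etype == "ES"]
        return ev, tx, genome, [s1, s3, s4]

    def test_in_frame_skip_without_new_stop(self):
        ev, tx, genome, exon_seqs = self.build(len2=120)
        res = annotate_consequence(ev, tx, genome)
        assert res.frame_status == "in_frame"
        assert not res.nmd_predicted
        stop, junction = manual_orf_scan(exon_seqs, 1)
        assert res.ptc_position == stop
        assert stop > junction  # first stop sits in the final exon

    def test_frameshift_with_early_ptc_triggers_nmd(self):
        # shifted frame meets TAA at altered position 103, far upstream of the
        # final junction (99 + 120 = 219): distance 114 > 55
        exon3 = "CCC" + "TAA" + ("CCA" * 40)[: 120 - 6]
        ev, tx, genome, exon_seqs = self.build(len2=119, exon3_seq=exon3)
        res = annotate_consequence(ev, tx, genome)
        stop, junction = manual_orf_scan(exon_seqs, 1)
        assert res.frame_status == "frameshift"
        assert res.ptc_position == stop == 103
        assert res.ptc_to_last_junction == junction - (stop + 2) == 114
        assert res.nmd_predicted

    def test_ptc_in_final_exon_escapes_nmd(self):
        ev, tx, genome, exon_seqs = self.build(len2=119)
        res = annotate_consequence(ev, tx, genome)
        stop, junction = manual_orf_scan(exon_seqs, 1)
        assert res.frame_status == "frameshift"
        assert res.ptc_position == stop
        assert stop > junction and not res.nmd_predicted

    def test_ptc_just_inside_55nt_boundary_escapes_nmd(self):
        # stop chosen so its end lands exactly 54 nt before the last junction
        exon3 = ("CCA" * 22)[:64] + "TAA" + ("CCA" * 20)[: 120 - 67]
        ev, tx, genome, exon_seqs = self.build(len2=119, exon3_seq=exon3)
        res = annotate_consequence(ev, tx, genome)
        stop, junction = manual_orf_scan(exon_seqs, 1)
        assert res.ptc_position == stop
        assert res.ptc_to_last_junction == junction - (stop + 2) <= 55
        assert not res.nmd_predicted

    @given(n_codons=st.integers(min_value=2, max_value=60))
    @settings(deadline=None, max_examples=15)
    def test_multiple_of_three_stop_free_exon_never_frameshifts(self, n_codons):
        ev, tx, genome, _ = self.build(len2=3 * n_codons)
        assert annotate_consequence(ev, tx, genome).frame_status == "in_frame"

    def test_no_cds_raises(self):
        ev, tx, genome, _ = self.build(len2=120)
        tx_nocds = make_transcript(tx.exons)
        with pytest.raises(Exception, match="non_coding|CDS"):
            annotate_consequence(ev, tx_nocds, genome)

    def test_other_event_types_are_non_coding(self):
        t1 = make_transcript([(100, 600)], cds=(1, 300), tid="T1")
        t2 = make_transcript([(100, 200), (300, 600)], tid="T2")
        (ev,) = enumerate_events([t1, t2])
        res = annotate_consequence(ev, t1, {"1": "A" * 700})
        assert res.frame_status == "non_coding"
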