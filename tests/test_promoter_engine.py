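"""PSSMs, motif discovery, similarity thresholds, final-set construction,
promoter ranking (with an exhaustive-scan oracle) and tailoring."""

import itertools
import math

import numpy as np
import pytest

from selectigene.promoter_engine import (MIN_W, PSSM, BackendUnavailableError,
                                         MappedMotif, PromoterRank,
                                         _combined_pvalue, _quantized_logodds,
                                         _score_pvalue_table, background_from,
                                         build_final_set, calibrate_threshold,
                                         discover_motifs,
                                         enhancing_and_anti_motifs,
                                         pssm_similarity, random_pssm,
                                         rank_promoters, read_meme,
                                         tailor_promoter, write_meme)
from selectigene.sequence_model import Microbiome
from selectigene.synthetic_fixtures import FixtureSpec, make_microbiome

from conftest import bare_host

BASES = "ACGT"


def _plant_distance(consensus: str, plants=("TATAATAT", "TATATTAT")) -> int:
    """Best ungapped-alignment Hamming distance of a recovered consensus
    against either concrete realisation of the planted TATAWTAT motif."""
    best = len(consensus)
    for plant in plants:
        short, long_ = sorted((consensus, plant), key=len)
        for off in range(len(long_) - len(short) + 1):
            best = min(best, sum(a != b for a, b in
                                 zip(short, long_[off:off + len(short)])))
    return best


def pssm_from_consensus(consensus: str, major: float = 0.85,
                        host: str = "") -> PSSM:
    probs = np.full((4, len(consensus)), (1 - major) / 3)
    for j, b in enumerate(consensus):
        probs[BASES.index(b), j] = major
    return PSSM(probs=probs, source_host=host, evalue=1e-3, name=consensus)


def _random_seqs(rng, n, length):
    return ["".join(BASES[i] for i in rng.integers(0, 4, size=length))
            for _ in range(n)]


class TestPSSM:
    def test_column_sums_validated(self):
        bad = np.full((4, 8), 0.3)
        with pytest.raises(ValueError):
            PSSM(probs=bad)

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            PSSM(probs=np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            PSSM(probs=np.full((4, 25), 0.25))

    def test_consensus_and_reverse_complement(self):
        m = pssm_from_consensus("TATAAT")
        assert m.consensus == "TATAAT"
        assert m.reverse_complement().consensus == "ATTATA"


class TestSimilarity:
    def test_identity_is_one(self):
        m = pssm_from_consensus("TATAATGC")
        assert pssm_similarity(m, m) == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        # a PSSM with 24 distinct entries, and its probability inversion
        # y = 0.5 - x (a strictly decreasing map preserving column sums):
        # the direct-orientation correlation is exactly -1; the public
        # similarity maximises over offsets and reverse complement, so it
        # is bounded below by that value
        rng = np.random.default_rng(0)
        base = np.array([[0.4], [0.3], [0.2], [0.1]]) @ np.ones((1, 6))
        jitter = rng.uniform(0, 1e-3, size=(4, 6))
        jitter -= jitter.mean(axis=0, keepdims=True)
        m = PSSM(probs=base + jitter)
        inv = PSSM(probs=0.5 - m.probs)
        from selectigene.promoter_engine import _spearman
        got = _spearman(m.probs.ravel(order="F"), inv.probs.ravel(order="F"))
        assert got == pytest.approx(-1.0, abs=1e-9)
        assert pssm_similarity(m, inv) >= got

    def test_offset_alignment_matches_brute_force(self):
        rng = np.random.default_rng(0)
        short = pssm_from_consensus("TATAAT")
        long_probs = rng.dirichlet(np.ones(4), size=10).T
        long_probs[:, 3:9] = short.probs
        long_ = PSSM(probs=long_probs)
        got = pssm_similarity(short, long_)
        from selectigene.promoter_engine import _spearman
        best = -1.0
        for cand in (long_, long_.reverse_complement()):
            for off in range(cand.length - short.length + 1):
                sl = cand.probs[:, off:off + short.length]
                best = max(best, _spearman(short.probs.ravel(order="F"),
                                           sl.ravel(order="F")))
        assert got == pytest.approx(best, abs=1e-12)
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        m1, m2 = random_pssm(rng), random_pssm(rng)
        assert pssm_similarity(m1, m2) == pytest.approx(
            pssm_similarity(m2, m1), abs=1e-12)


class TestCalibrateThreshold:
    def test_percentile_limits(self):
        S = [pssm_from_consensus("TATAATGC")]
        t_max = calibrate_threshold(S, X=100, n_random=50, seed=3)
        t_min = calibrate_threshold(S, X=0, n_random=50, seed=3)
        rng = np.random.default_rng(3)
        corrs = [pssm_similarity(S[0], random_pssm(rng)) for _ in range(50)]
        assert t_max.D_h == pytest.approx(max(corrs), abs=1e-12)
        assert t_min.D_h == pytest.approx(min(corrs), abs=1e-12)

    def test_reproducible_and_matches_percentile_oracle(self):
        S = [pssm_from_consensus("TATAATGC"), pssm_from_consensus("GGGCCCAT"),
             pssm_from_consensus("ATCGATCG")]
        t1 = calibrate_threshold(S, X=95, n_random=100, seed=11)
        t2 = calibrate_threshold(S, X=95, n_random=100, seed=11)
        assert t1.D_h == t2.D_h
        rng = np.random.default_rng(11)
        randoms = [random_pssm(rng) for _ in range(100)]
        corrs = [pssm_similarity(m, r) for m in S for r in randoms]
        assert t1.D_h == pytest.approx(np.percentile(corrs, 95), abs=1e-12)

    def test_monotone_in_x(self):
        S = [pssm_from_consensus("TATAATGC")]
        ds = [calibrate_threshold(S, X=x, n_random=60, seed=5).D_h
              for x in (10, 50, 90, 99)]
        assert all(b >= a for a, b in zip(ds, ds[1:]))


class TestDiscovery:
    def test_planted_motif_recovered(self):
        rng = np.random.default_rng(42)
        control = _random_seqs(rng, 50, 200)
        primary = []
        for s in _random_seqs(rng, 50, 200):
            inst = "".join(b if b != "W" else "AT"[rng.integers(2)]
                           for b in "TATAWTAT")
            off = int(rng.integers(0, 200 - 8))
            primary.append(s[:off] + inst + s[off + 8:])
        motifs = discover_motifs(primary, control, seed=42)
        assert motifs, "no motif found"
        assert min(_plant_distance(m.consensus) for m in motifs) <= 1
        assert all(m.evalue <= 0.05 for m in motifs)
        assert all(MIN_W <= m.length <= 20 for m in motifs)

    def test_no_enrichment_when_primary_equals_control(self):
        rng = np.random.default_rng(7)
        seqs = _random_seqs(rng, 40, 200)
        assert discover_motifs(seqs, list(seqs), seed=7) == []

    def test_short_primary_errors(self):
        with pytest.raises(ValueError):
            discover_motifs(["ACGT"], ["ACGTACGTAC"])

    def test_external_backend_missing_binary(self):
        with pytest.raises(BackendUnavailableError):
            discover_motifs(["ACGTACGTAC"] * 5, ["ACGTACGTAC"] * 5,
                            backend="external")


class TestFinalSet:
    def _scored_setup(self):
        # four motifs; motif i sits in the enhancing sets of i wanted
        # hosts, so with alpha=1 the aggregated scores are 1, 2, 3, 4
        motifs = [pssm_from_consensus(c) for c in
                  ("TATAATGC", "GGGCCCAT", "ATCGATCG", "TTTTAAAC")]
        hosts = [bare_host(f"w{i}", "wanted") for i in range(4)]
        hosts.append(bare_host("u0", "unwanted"))
        S = {f"w{i}": motifs[i:] for i in range(4)}
        S["u0"] = []
        return Microbiome(hosts=hosts), S, motifs

    def test_percentile_cut_keeps_top_motif(self):
        mb, S, motifs = self._scored_setup()
        F, scored = build_final_set(S, mb, alpha=1.0, Y=75, seed=1,
                                    full_output=True)
        aggs = sorted(s.aggregated for s in scored)
        assert aggs == [1.0, 2.0, 3.0, 4.0]
        # P75 of {1,2,3,4} with linear interpolation is 3.25
        assert np.percentile(aggs, 75) == pytest.approx(3.25)
        assert [m.consensus for m in F] == [motifs[3].consensus]

    def test_equal_scores_give_empty_set(self):
        motifs = [pssm_from_consensus("TATAATGC"),
                  pssm_from_consensus("GGGCCCAT")]
        hosts = [bare_host("w0", "wanted"), bare_host("u0", "unwanted")]
        S = {"w0": motifs, "u0": []}
        F = build_final_set(S, Microbiome(hosts=hosts), alpha=1.0, Y=75, seed=1)
        assert F == []

    def test_alpha_one_ignores_unwanted_hits(self):
        mb, S, motifs = self._scored_setup()
        S["u0"] = [motifs[0]]     # anti-motif identical to motif 0
        _, scored0 = build_final_set(S, mb, alpha=1.0, Y=75, seed=1,
                                     full_output=True)
        by = {s.motif.consensus: s.aggregated for s in scored0}
        assert by[motifs[0].consensus] == 1.0   # delta_u0 ignored at alpha=1

    def test_delta_bounds(self):
        mb, S, _ = self._scored_setup()
        _, scored = build_final_set(S, mb, alpha=0.5, Y=75, seed=1,
                                    full_output=True)
        for s in scored:
            assert 0 <= s.aggregated <= 0.5 * 4 + 0.5 * 1

    def test_empty_c_errors(self):
        hosts = [bare_host("w0", "wanted"), bare_host("u0", "unwanted")]
        with pytest.raises(ValueError):
            build_final_set({"w0": [], "u0": []}, Microbiome(hosts=hosts))


class TestRankPromoters:
    def test_consensus_hit_beats_random(self):
        rng = np.random.default_rng(9)
        F = [pssm_from_consensus("TATAATGC"), pssm_from_consensus("GGGCCCAT")]
        bgseq = "".join(BASES[i] for i in rng.integers(0, 4, size=200))
        hit = bgseq[:40] + "TATAATGC" + bgseq[48:100] + "GGGCCCAT" + bgseq[108:]
        ranks = rank_promoters(F, [("hit", hit), ("rand", bgseq)])
        assert ranks[0].promoter_id == "hit"
        assert ranks[0].evalue < ranks[1].evalue

    def test_single_motif_evalue_matches_exhaustive_scan_oracle(self):
        # 6-mer motif, one 30-bp promoter: the internal E-value must equal
        # an exhaustive enumeration over all 4^6 windows of the quantised
        # log-odds null distribution, to 1e-9 relative
        motif = pssm_from_consensus("TATAAT")
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        seq = "GCGCGCGCGCTATAATGCGCGCGCGCGCGC"
        ranks = rank_promoters([motif], [("p", seq)], background=bg)
        lods = _quantized_logodds(motif, bg)
        best = None
        for off in range(len(seq) - 6 + 1):
            s = sum(int(lods[BASES.index(seq[off + i]), i]) for i in range(6))
            best = s if best is None else max(best, s)
        p_pos = 0.0
        for word in itertools.product(range(4), repeat=6):
            s = sum(int(lods[b, i]) for i, b in enumerate(word))
            if s >= best:
                p = 1.0
                for b in word:
                    p *= bg[b]
                p_pos += p
        n_off = len(seq) - 6 + 1
        p_seq = 1 - (1 - p_pos) ** n_off
        expected = p_seq * 1     # one candidate; k=1 combined p = p itself
        assert ranks[0].evalue == pytest.approx(expected, rel=1e-9)

    def test_identical_promoters_tie_stably(self):
        motif = pssm_from_consensus("TATAAT")
        seq = "GCGCGCTATAATGCGCGCGCATGCGCAT"
        ranks = rank_promoters([motif], [("b", seq), ("a", seq)])
        assert [r.promoter_id for r in ranks] == ["a", "b"]
        assert ranks[0].evalue == ranks[1].evalue

    def test_empty_motif_set_errors(self):
        with pytest.raises(ValueError):
            rank_promoters([], [("p", "ACGTACGTAC")])

    def test_dp_pvalue_table_is_a_distribution(self):
        motif = pssm_from_consensus("TATAATGC")
        bg = np.full(4, 0.25)
        tail, smin = _score_pvalue_table(_quantized_logodds(motif, bg), bg)
        assert tail[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(tail) <= 1e-12)

    def test_combined_pvalue_formula(self):
        # MAST product convention: Q * sum_{i<k} (-ln Q)^i / i!
        pvals = [0.01, 0.2, 0.5]
        q = 0.01 * 0.2 * 0.5
        expected = q * (1 + (-math.log(q)) + (-math.log(q)) ** 2 / 2)
        assert _combined_pvalue(pvals) == pytest.approx(expected, rel=1e-12)
        assert _combined_pvalue([0.3]) == pytest.approx(0.3)


class TestTailor:
    def _rank(self, seq, mismatches, motif):
        return PromoterRank(promoter_id="p", sequence=seq, evalue=1.0,
                            mapped_motifs=[MappedMotif(motif=motif, offset=5,
                                                       strand="+",
                                                       mismatches=mismatches)])

    def test_two_mismatches_give_four_variants(self):
        motif = pssm_from_consensus("TATAAT")
        seq = "GGGGG" + "TGTAAA" + "CCCCC"     # mismatches at motif pos 1, 5
        out = tailor_promoter(self._rank(seq, [1, 5], motif))
        assert len(out) == 4
        assert out[0] == seq
        assert "GGGGG" + "TATAAA" + "CCCCC" in out
        assert "GGGGG" + "TGTAAT" + "CCCCC" in out
        assert "GGGGG" + "TATAAT" + "CCCCC" in out
        assert all(len(v) == len(seq) for v in out)

    def test_exact_match_returns_original_only(self):
        motif = pssm_from_consensus("TATAAT")
        seq = "GGGGG" + "TATAAT" + "CCCCC"
        assert tailor_promoter(self._rank(seq, [], motif)) == [seq]

    def test_corrected_variant_scores_no_worse(self):
        motif = pssm_from_consensus("TATAATGC")
        rng = np.random.default_rng(3)
        base = "".join(BASES[i] for i in rng.integers(0, 4, size=60))
        seq = base[:20] + "TGTAATGC" + base[28:]
        ranks = rank_promoters([motif], [("p", seq)])
        variants = tailor_promoter(ranks[0])
        rescored = rank_promoters(
            [motif], [(f"v{i}", v) for i, v in enumerate(variants)])
        ev = {r.promoter_id: r.evalue for r in rescored}
        assert min(ev.values()) <= ev["v0"]


def test_meme_round_trip(tmp_path):
    motifs = [pssm_from_consensus("TATAATGC"), pssm_from_consensus("GGGCCC")]
    path = write_meme(motifs, tmp_path / "m.meme")
    back = read_meme(path)
    assert len(back) == 2
    for a, b in zip(motifs, back):
        assert np.allclose(a.probs, b.probs, atol=1e-6)


def test_enhancing_and_anti_motif_sets_by_role():
    spec = FixtureSpec(seed=31, n_wanted=1, n_unwanted=1, genes_per_host=45,
                       gene_length_codons=80, planted_motif="TATAWTAT",
                       motif_fraction=0.9)
    mb = make_microbiome(spec)
    enh, anti = enhancing_and_anti_motifs(mb.A[0], seed=31)
    assert anti == [] and enh
    assert min(_plant_distance(m.consensus) for m in enh) <= 1
    enh_u, anti_u = enhancing_and_anti_motifs(mb.B[0], seed=31)
    assert enh_u == []
    # n wanted + m unwanted hosts -> n + m motif sets, one per host
    sets = [enh, anti_u]
    assert len(sets) == len(mb.hosts)
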