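"""PWM parsing, log-odds scoring, exact p-values and genome scanning."""

import math
from itertools import product

import numpy as np
import pytest

from shapebind.motifs import (
    MotifHit,
    PositionWeightMatrix,
    log_odds_score,
    read_meme_motif,
    scan_genome,
    score_pvalue,
    write_meme_motif,
)
from shapebind.shape import reverse_complement

MEME_TWO = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF first
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 1e-5
 0.25 0.25 0.25 0.25
 0.25 0.25 0.25 0.25
 0.25 0.25 0.25 0.25
 0.25 0.25 0.25 0.25

MOTIF second
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 1e-3
 0.97 0.01 0.01 0.01
 0.01 0.97 0.01 0.01
 0.01 0.01 0.97 0.01
"""


def uniform_pwm(m=4):
    return PositionWeightMatrix(
        probs=np.full((m, 4), 0.25), background=np.full(4, 0.25), pseudocount=0.0
    )


def consensus_pwm(consensus, p=1.0):
    probs = np.full((len(consensus), 4), (1 - p) / 3)
    for i, c in enumerate(consensus):
        probs[i, "ACGT".index(c)] = p
    return PositionWeightMatrix(
        probs=probs, background=np.full(4, 0.25), pseudocount=0.0
    )


def random_pwm(rng, m):
    probs = rng.dirichlet(np.ones(4), size=m)
    return PositionWeightMatrix(
        probs=probs, background=np.full(4, 0.25), pseudocount=0.0
    )


class TestMemeReader:
    def test_uniform_motif(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        pwm = read_meme_motif(path, index=1, pseudocount=0.0)
        assert pwm.length == 4
        assert np.allclose(pwm.probs, 0.25)
        assert np.allclose(pwm.background, 0.25)

    def test_second_motif_selected(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        pwm = read_meme_motif(path, index=2, pseudocount=0.0)
        assert pwm.length == 3
        assert pwm.consensus == "ACG"

    def test_index_out_of_range(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        with pytest.raises(IndexError):
            read_meme_motif(path, index=3)

    def test_bad_row_sum_rejected(self, tmp_path):
        bad = MEME_TWO.replace(" 0.97 0.01 0.01 0.01", " 0.85 0.01 0.01 0.01")
        path = tmp_path / "bad.meme"
        path.write_text(bad)
        with pytest.raises(ValueError, match="sums to"):
            read_meme_motif(path, index=2)

    def test_pseudocount_regularizes_rows(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        pwm = read_meme_motif(path, index=2, pseudocount=0.1)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert pwm.probs.min() > 0

    def test_write_read_roundtrip(self, tmp_path, rng):
        pwm = random_pwm(rng, 5)
        path = tmp_path / "rt.meme"
        write_meme_motif(path, pwm)
        back = read_meme_motif(path, pseudocount=0.0)
        assert np.allclose(back.probs, pwm.probs, atol=1e-5)


class TestLogOdds:
    def test_uniform_is_zero(self):
        assert log_odds_score(uniform_pwm(), "ACGT") == pytest.approx(0.0)

    def test_consensus_closed_form(self):
        # p=1 on one base per position, uniform background -> 2m bits
        pwm = consensus_pwm("ACGTA")
        assert log_odds_score(pwm, "ACGTA") == pytest.approx(10.0)

    def test_manual_summation_oracle(self, rng):
        pwm = random_pwm(rng, 6)
        kmer = "GATTAC"
        expected = sum(
            math.log2(pwm.probs[i, "ACGT".index(c)] / 0.25)
            for i, c in enumerate(kmer)
        )
        assert log_odds_score(pwm, kmer) == pytest.approx(expected)

    def test_length_and_alphabet_checked(self):
        with pytest.raises(ValueError):
            log_odds_score(uniform_pwm(), "ACG")
        with pytest.raises(ValueError):
            log_odds_score(uniform_pwm(), "ACGN")


class TestScorePvalue:
    def test_single_position_max(self, rng):
        pwm = random_pwm(rng, 1)
        best = float(pwm.log_odds.max())
        assert score_pvalue(pwm, best) == pytest.approx(0.25)

    def test_uniform_degenerate(self):
        assert score_pvalue(uniform_pwm(), 0.0) == pytest.approx(1.0)

    def test_minimum_score_has_pvalue_one(self, rng):
        pwm = random_pwm(rng, 3)
        worst = float(pwm.log_odds.min(axis=1).sum())
        assert score_pvalue(pwm, worst) == pytest.approx(1.0)

    def test_dp_matches_enumeration_over_all_kmers(self, rng):
        """DP p-value equals exhaustive enumeration over all 256 4-mers."""
        pwm = random_pwm(rng, 4)
        kmers = ["".join(t) for t in product("ACGT", repeat=4)]
        scores = np.array([log_odds_score(pwm, k) for k in kmers])
        for q in (0.1, 0.5, 0.9):
            s = float(np.quantile(scores, q))
            # enumeration with half-grid slack against the 1e-3-bit rounding
            enum_p = np.mean(scores >= s - 2e-3) * 1.0
            enum_p_strict = np.mean(scores >= s + 2e-3) * 1.0
            p = score_pvalue(pwm, s)
            assert enum_p_strict <= p <= enum_p


def naive_scan(genome, pwm, pthresh):
    """Brute-force oracle: score every window on both strands, exact
    enumeration p-values, same-locus better-score dedup (ties -> plus)."""
    m = pwm.length
    kmers = ["".join(t) for t in product("ACGT", repeat=m)]
    kscores = np.array([log_odds_score(pwm, k) for k in kmers])
    kprob = np.array(
        [np.prod([pwm.background["ACGT".index(c)] for c in k]) for k in kmers]
    )

    def pval(s):
        return float(kprob[kscores >= s - 1e-9].sum())

    hits = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        for start in range(len(seq) - m + 1):
            window = seq[start : start + m]
            if any(c not in "ACGT" for c in window):
                continue
            cand = []
            sp = log_odds_score(pwm, window)
            if pval(sp) <= pthresh:
                cand.append(("+", sp, window))
            sm = log_odds_score(pwm, reverse_complement(window))
            if pval(sm) <= pthresh:
                cand.append(("-", sm, reverse_complement(window)))
            if len(cand) == 2:
                cand = [max(cand, key=lambda c: (c[1], c[0] == "+"))]
            for strand, s, mseq in cand:
                hits.append((contig, start, strand, s, pval(s), mseq))
    return hits


class TestScanGenome:
    def test_planted_consensus_recovered_vs_naive_oracle(self, rng):
        """Near-deterministic 6-mer planted 10 times in 30 kb random
        background: the scanner and the brute-force oracle agree."""
        pwm = consensus_pwm("TGACGT", p=0.95)
        n = 30_000
        seq = list("ACGT"[i] for i in rng.integers(0, 4, n))
        planted = sorted(rng.choice(np.arange(100, n - 100, 120), 10, replace=False))
        for pos in planted:
            seq[pos : pos + 6] = "TGACGT"
        genome = {"chr1": "".join(seq)}
        hits = scan_genome(genome, pwm, pthresh=5e-4)
        oracle = naive_scan(genome, pwm, 5e-4)
        assert {(h.contig, h.start, h.strand) for h in hits} == {
            (c, s, st) for c, s, st, *_ in oracle
        }
        assert set(planted) <= {h.start for h in hits}
        # p-values agree with exact enumeration to discretization error
        opv = {(c, s, st): p for c, s, st, _, p, _ in oracle}
        for h in hits:
            assert h.pvalue == pytest.approx(
                opv[(h.contig, h.start, h.strand)], rel=1e-3
            )

    def test_random_pwm_matches_oracle(self, rng):
        pwm = random_pwm(rng, 4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        genome = {"c": seq}
        hits = scan_genome(genome, pwm, pthresh=2e-2)
        oracle = naive_scan(genome, pwm, 2e-2)
        assert {(h.start, h.strand) for h in hits} == {
            (s, st) for _, s, st, *_ in oracle
        }

    def test_palindrome_counted_once(self):
        pwm = consensus_pwm("ACGT")
        hits = scan_genome({"c": "AAACGTAA"}, pwm, pthresh=1e-2)
        assert len(hits) == 1
        assert hits[0].start == 2 and hits[0].strand == "+"

    def test_zero_threshold_empty(self, rng):
        pwm = random_pwm(rng, 4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        assert scan_genome({"c": seq}, pwm, pthresh=0.0) == []

    def test_monotone_in_threshold(self, rng):
        pwm = random_pwm(rng, 5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        loose = {(h.start, h.strand) for h in scan_genome({"c": seq}, pwm, 1e-2)}
        tight = {(h.start, h.strand) for h in scan_genome({"c": seq}, pwm, 1e-3)}
        assert tight <= loose

    def test_strand_symmetry(self, rng):
        """Scanning revcomp(G) with the revcomp PWM mirrors the hit list."""
        pwm = random_pwm(rng, 5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        n = len(seq)
        fwd = scan_genome({"c": seq}, pwm, 1e-2)
        rev = scan_genome(
            {"c": reverse_complement(seq)}, pwm.reverse_complement(), 1e-2
        )
        # a plus hit of the rc-PWM on rc(G) is a plus hit of the PWM on G
        # at the mirrored interval (the window itself is reverse-complemented)
        mirrored = {(n - h.end, h.strand) for h in rev}
        assert {(h.start, h.strand) for h in fwd} == mirrored

    def test_n_windows_skipped(self):
        pwm = consensus_pwm("ACGT")
        hits = scan_genome({"c": "AANCGTAAACGTA"}, pwm, pthresh=1e-2)
        assert {h.start for h in hits} == {8}

    def test_matched_seq_is_plus_orientation_of_motif(self):
        pwm = consensus_pwm("TTGACC", p=0.95)
        genome = {"c": "AAAA" + reverse_complement("TTGACC") + "AAAA"}
        hits = scan_genome(genome, pwm, pthresh=5e-4)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].matched_seq == "TTGACC"
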