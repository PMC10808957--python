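"""PWM construction, both-strand scanning, containment, enrichment."""

import math

import numpy as np
import pytest

from chromshift import (
    GenomicInterval,
    PfmRecord,
    motif_containment,
    motif_enrichment_test,
    motif_proportion_shift,
    pwm_from_pfm,
    scan_sequence,
    synthetic_pfm,
)
from chromshift.motifs import builtin_motifs

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


class TestPwmFromPfm:
    def test_uniform_pfm_uniform_background_is_zero(self):
        pwm = pwm_from_pfm(PfmRecord("u", np.full((4, 5), 10.0)))
        assert np.allclose(pwm.logodds, 0.0)

    def test_width_two_hand_arithmetic(self):
        # col total 10, pc=1, bg 0.25: match p = (10 + 0.25)/11, other p = 0.25/11
        pfm = PfmRecord("h", np.array([[10, 0], [0, 10], [0, 0], [0, 0]], dtype=float))
        pwm = pwm_from_pfm(pfm, pseudocount=1.0)
        lo_match = math.log2(41 / 11)   # (10.25/11)/0.25
        lo_other = -math.log2(11)       # (0.25/11)/0.25
        assert pwm.logodds[0, 0] == pytest.approx(lo_match)
        assert pwm.logodds[1, 1] == pytest.approx(lo_match)
        assert pwm.logodds[2, 0] == pytest.approx(lo_other)
        assert pwm.logodds[3, 1] == pytest.approx(lo_other)

    def test_score_range_is_sum_of_column_extrema(self, rng):
        pwm = pwm_from_pfm(PfmRecord("r", rng.integers(0, 50, (4, 8)) + 1.0))
        assert pwm.max_score == pytest.approx(pwm.logodds.max(axis=0).sum())
        assert pwm.min_score == pytest.approx(pwm.logodds.min(axis=0).sum())


class TestScanSequence:
    @pytest.fixture
    def pwm(self):
        return pwm_from_pfm(synthetic_pfm("t", "ACGTACGTAC"))

    def test_consensus_hits_at_zero_with_max_score(self, pwm):
        hits = scan_sequence(pwm.consensus(), pwm)
        assert len(hits) == 1
        assert hits[0].pos == 0 and hits[0].strand == "+"
        assert hits[0].score == pytest.approx(pwm.max_score)

    def test_reverse_complement_hits_minus_strand(self, pwm):
        hits = scan_sequence(revcomp(pwm.consensus()), pwm)
        assert len(hits) == 1
        assert hits[0].pos == 0 and hits[0].strand == "-"
        assert hits[0].score == pytest.approx(pwm.max_score)

    def test_sequence_shorter_than_motif(self, pwm):
        assert scan_sequence("ACG", pwm) == []

    def test_against_exhaustive_window_oracle(self, rng, pwm):
        """2 kb random sequence: hits equal per-window python scoring."""
        seq = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, 2000))
        idx = {b: i for i, b in enumerate("ACGT")}
        w = pwm.width
        thr = pwm.threshold(0.5)
        expected = []
        for p in range(len(seq) - w + 1):
            fwd = sum(pwm.logodds[idx[seq[p + j]], j] for j in range(w))
            rc = revcomp(seq[p : p + w])
            rev = sum(pwm.logodds[idx[rc[j]], j] for j in range(w))
            if fwd >= thr:
                expected.append((p, "+", round(fwd, 9)))
            if rev >= thr:
                expected.append((p, "-", round(rev, 9)))
        got = [(h.pos, h.strand, round(h.score, 9)) for h in scan_sequence(seq, pwm, 0.5)]
        assert sorted(got) == sorted(expected)

    def test_strand_involution(self, rng, pwm):
        """Scanning the reverse-complemented sequence mirrors the hit list."""
        seq = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, 500))
        seq = seq[:100] + pwm.consensus() + seq[100:]
        fwd_hits = scan_sequence(seq, pwm, 0.6)
        rc_hits = scan_sequence(revcomp(seq), pwm, 0.6)
        n, w = len(seq), pwm.width
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (n - h.pos - w, flip[h.strand], round(h.score, 9)) for h in fwd_hits
        )
        assert mirrored == sorted((h.pos, h.strand, round(h.score, 9)) for h in rc_hits)

    def test_agrees_with_biopython_pssm(self, rng):
        """Forward-strand scores match Bio.motifs log-odds on a random sequence."""
        motifs_mod = pytest.importorskip("Bio.motifs")
        from Bio.Seq import Seq

        pfm = synthetic_pfm("x", "ACGGTTACCA", match_count=12, other_count=3)
        pwm = pwm_from_pfm(pfm, pseudocount=1.0)
        counts = {b: list(pfm.matrix[i]) for i, b in enumerate("ACGT")}
        bio = motifs_mod.Motif(alphabet="ACGT", counts=counts)
        # our pc*bg[b] pseudocount with uniform bg == biopython's per-base pc/4
        bio_pssm = bio.counts.normalize(pseudocounts=0.25).log_odds()
        seq = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, 300))
        theirs = bio_pssm.calculate(Seq(seq))
        from chromshift.motifs import _encode, _window_scores

        ours = _window_scores(_encode(seq), pwm.logodds)
        assert np.allclose(ours, np.asarray(theirs), atol=1e-4)


class TestContainment:
    def make_fixture(self, rng, n_peaks=40, planted=None):
        pfm = synthetic_pfm("m", "ACGGTCAGTCAAGGTCCAGGTACCAGGT")
        seq = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, n_peaks * 300))
        peaks = [GenomicInterval("chr1", i * 300, i * 300 + 200) for i in range(n_peaks)]
        if planted:
            chars = list(seq)
            for i in planted:
                s = peaks[i].start + 80
                chars[s : s + pfm.width] = pfm.consensus()
            seq = "".join(chars)
        return peaks, {"chr1": seq}, pwm_from_pfm(pfm)

    def test_no_motifs_anywhere(self, rng):
        peaks, genome, pwm = self.make_fixture(rng)
        assert motif_containment(peaks, genome, pwm) == (0, 0.0)

    def test_planted_fraction_recovered_exactly(self, rng):
        planted = sorted(int(i) for i in rng.choice(40, 13, replace=False))
        peaks, genome, pwm = self.make_fixture(rng, planted=planted)
        n, frac = motif_containment(peaks, genome, pwm)
        assert n == 13 and frac == pytest.approx(13 / 40)

    def test_order_and_duplicate_hit_invariance(self, rng):
        planted = [0, 5, 6]
        peaks, genome, pwm = self.make_fixture(rng, planted=planted)
        shuffled = [peaks[int(i)] for i in rng.permutation(len(peaks))]
        assert motif_containment(shuffled, genome, pwm) == motif_containment(peaks, genome, pwm)

    def test_peak_beyond_chromosome_end_rejected(self, rng):
        peaks, genome, pwm = self.make_fixture(rng)
        bad = [GenomicInterval("chr1", 0, len(genome["chr1"]) + 10)]
        with pytest.raises(ValueError):
            motif_containment(bad, genome, pwm)


class TestProportionShift:
    def test_identical_sets_zero_delta(self, rng):
        pfms = builtin_motifs()[:2]
        seq = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, 5000))
        genome = {"chr1": seq}
        peaks = [GenomicInterval("chr1", i * 250, i * 250 + 200) for i in range(15)]
        table = motif_proportion_shift(peaks, peaks, genome, [pwm_from_pfm(p) for p in pfms])
        assert (table["delta"] == 0).all()

    def test_two_motifs_recovered_independently(self, rng):
        pfm1 = synthetic_pfm("m1", "ACGGTCAGTCAAGGTCCAGGTACCAGGT")
        pfm2 = synthetic_pfm("m2", "TTGCACCAGATTCGGATCCGTAGGCAAT")
        n = 30
        seq = list("".join("ACGT"[int(i)] for i in rng.integers(0, 4, n * 300)))
        peaks_a = [GenomicInterval("chr1", i * 300, i * 300 + 200) for i in range(n // 2)]
        peaks_b = [GenomicInterval("chr1", i * 300, i * 300 + 200) for i in range(n // 2, n)]
        # plant m1 in 3 A peaks; m2 in 6 B peaks
        for i in range(3):
            s = peaks_a[i].start + 20
            seq[s : s + pfm1.width] = pfm1.consensus()
        for i in range(6):
            s = peaks_b[i].start + 20
            seq[s : s + pfm2.width] = pfm2.consensus()
        genome = {"chr1": "".join(seq)}
        table = motif_proportion_shift(
            peaks_a, peaks_b, genome, [pwm_from_pfm(pfm1), pwm_from_pfm(pfm2)]
        )
        assert table.loc["m1", "fraction_a"] == pytest.approx(3 / 15)
        assert table.loc["m1", "fraction_b"] == 0.0
        assert table.loc["m2", "fraction_a"] == 0.0
        assert table.loc["m2", "fraction_b"] == pytest.approx(6 / 15)


class TestEnrichment:
    def test_null_composition_is_not_enriched(self):
        # foreground drawn to match background composition: p around 0.5 or more
        assert motif_enrichment_test(10, 100, 100, 1000) >= 0.5

    def test_closed_form_extreme_tail(self):
        # all 10 foreground peaks positive from a 10/1000 background:
        # P = C(10,10) C(990,0) / C(1000,10)
        expected = 1 / (math.comb(1000, 10))
        assert motif_enrichment_test(10, 10, 10, 1000) == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_agreement(self, rng):
        """1e5 hypergeometric draws reproduce the exact tail within 3 s.e."""
        fg_with, fg_total, bg_with, bg_total = 30, 100, 150, 1000
        exact = motif_enrichment_test(fg_with, fg_total, bg_with, bg_total)
        draws = rng.hypergeometric(bg_with, bg_total - bg_with, fg_total, size=100_000)
        mc = (draws >= fg_with).mean()
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(mc - exact) <= 3 * se + 1e-12

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment_test(11, 10, 50, 100)
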