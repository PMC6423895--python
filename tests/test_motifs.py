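"""PWM scoring: exact DP p-values vs enumeration, strand symmetry, affinity."""

import itertools

import numpy as np
import pytest

from acedhs.motifs import (
    PWM,
    MotifHit,
    SCALE,
    best_relative_score,
    compare_species_affinity,
    read_pwm,
    relative_score,
    scan_sequence,
)
from acedhs.simulate import generate_motif_fixture

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def enumerate_distribution(pwm: PWM):
    """Brute-force distribution of the discretised score over all 4^w words."""
    ints = np.rint(pwm.log_odds * SCALE).astype(np.int64)
    dist: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(ints[b, j] for j, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        dist[s] = dist.get(s, 0.0) + p
    return dist


class TestPWMConstruction:
    def test_fimo_pseudocount_convention(self):
        counts = (10.0 * np.eye(4))  # one dominant base per column, w = 4
        pwm = PWM.from_counts("M", counts)
        # (10 + 0.1*0.25) / (10 + 0.1) for the dominant base, else 0.025/10.1
        assert pwm.probs[0, 0] == pytest.approx((10 + 0.025) / 10.1, abs=1e-12)
        assert pwm.probs[2, 0] == pytest.approx(0.025 / 10.1, abs=1e-12)

    def test_uniform_counts_give_quarter_probs(self):
        pwm = PWM.from_counts("U", np.full((4, 5), 3.0))
        assert np.allclose(pwm.probs, 0.25)

    def test_negative_and_ragged_rejected(self):
        with pytest.raises(ValueError):
            PWM.from_counts("bad", np.array([[1, -1], [1, 1], [1, 1], [1, 1]]))
        with pytest.raises(ValueError):
            PWM.from_counts("bad", np.ones((3, 5)))

    def test_jaspar_and_meme_encodings_agree(self, tmp_path):
        counts = np.array(
            [[0, 3, 80, 0], [94, 75, 4, 3], [1, 0, 3, 79], [5, 22, 13, 18]],
            dtype=float,
        )
        jaspar = tmp_path / "m.jaspar"
        jaspar.write_text(
            ">M0001 toy\n"
            "A [ 0 3 80 0 ]\n"
            "C [ 94 75 4 3 ]\n"
            "G [ 1 0 3 79 ]\n"
            "T [ 5 22 13 18 ]\n"
        )
        total = counts.sum(axis=0)[0]
        freqs = counts / counts.sum(axis=0)
        lines = "\n".join(
            " ".join(f"{freqs[b, j]:.6f}" for b in range(4))
            for j in range(4)
        )
        meme = tmp_path / "m.meme"
        meme.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF M0001 toy\n"
            f"letter-probability matrix: alength= 4 w= 4 nsites= {int(total)} E= 0\n"
            f"{lines}\n"
        )
        p1 = read_pwm(jaspar)[0]
        p2 = read_pwm(meme)[0]
        assert np.allclose(p1.probs, p2.probs, atol=1e-6)


class TestScoreDistribution:
    @pytest.mark.parametrize("width", [4, 5, 6, 7, 8])
    def test_dp_matches_enumeration(self, width, rng):
        counts = rng.integers(0, 50, size=(4, width)).astype(float) + 0.5
        pwm = PWM.from_counts(f"R{width}", counts)
        dist, lo = pwm.score_distribution()
        brute = enumerate_distribution(pwm)
        dp = {lo + i: p for i, p in enumerate(dist) if p > 0}
        tv = 0.5 * sum(
            abs(dp.get(k, 0.0) - brute.get(k, 0.0))
            for k in set(dp) | set(brute)
        )
        assert tv < 1e-9
        assert abs(dist.sum() - 1.0) < 1e-9

    def test_pvalues_monotone_in_score(self, sharp_pwm):
        tail, lo = sharp_pwm.tail_pvalues()
        assert np.all(np.diff(tail) <= 1e-15)

    def test_p_equals_tail_mass_at_consensus(self, sharp_pwm):
        consensus = sharp_pwm.consensus()
        hits = scan_sequence(consensus, sharp_pwm, p_threshold=1.0)
        top = max(hits, key=lambda h: h.score)
        brute = enumerate_distribution(sharp_pwm)
        int_score = round(top.score * SCALE)
        expected = sum(p for s, p in brute.items() if s >= int_score)
        assert top.pvalue == pytest.approx(expected, abs=1e-9)


class TestScan:
    def test_uniform_pwm_yields_no_hits(self):
        pwm = PWM.from_counts("U", np.full((4, 6), 5.0))
        with pytest.warns(UserWarning):
            hits = scan_sequence("ACGTACGTACGT", pwm, p_threshold=1.0)
        assert all(h.score == 0 and h.pvalue == 1.0 for h in hits)
        assert scan_sequence("ACGTACGTACGT", pwm, p_threshold=1e-4) == []

    def test_short_sequence_empty(self, sharp_pwm):
        assert scan_sequence("ACG", sharp_pwm) == []

    def test_windows_with_n_skipped(self, sharp_pwm):
        seq = "AA" + sharp_pwm.consensus().replace("A", "N") + "AA"
        assert scan_sequence(seq, sharp_pwm, p_threshold=1.0) == [] or all(
            "N" not in seq[h.offset : h.offset + sharp_pwm.width]
            for h in scan_sequence(seq, sharp_pwm, p_threshold=1.0)
        )

    def test_reverse_complement_mirrors_hits(self, sharp_pwm, rng):
        seq = "".join(rng.choice(list(BASES), size=60))
        seq = seq[:20] + sharp_pwm.consensus() + seq[20:]
        fwd = scan_sequence(seq, sharp_pwm, p_threshold=0.01)
        rev = scan_sequence(revcomp(seq), sharp_pwm, p_threshold=0.01)
        assert len(fwd) == len(rev) > 0
        n = len(seq)
        w = sharp_pwm.width
        mirrored = sorted(
            (n - w - h.offset, {"+": "-", "-": "+"}[h.strand], round(h.score, 6))
            for h in rev
        )
        direct = sorted((h.offset, h.strand, round(h.score, 6)) for h in fwd)
        assert mirrored == direct

    def test_palindromic_motif_hits_both_strands(self):
        counts = np.zeros((4, 6))
        for j, b in enumerate("ACGCGT"):  # reverse complement of itself
            counts[BASES.index(b), j] = 50
        pwm = PWM.from_counts("PAL", counts + 0.5)
        hits = scan_sequence("TTACGCGTTT", pwm, p_threshold=0.01)
        offsets = {(h.offset, h.strand) for h in hits}
        assert (2, "+") in offsets and (2, "-") in offsets


class TestRelativeScore:
    def test_best_and_worst_words(self, sharp_pwm):
        lo = sharp_pwm.log_odds
        best = "".join(BASES[i] for i in lo.argmax(axis=0))
        worst = "".join(BASES[i] for i in lo.argmin(axis=0))
        assert relative_score(best, sharp_pwm) == pytest.approx(1.0)
        assert relative_score(worst, sharp_pwm) == pytest.approx(0.0)

    def test_mixed_word_matches_column_arithmetic(self, sharp_pwm):
        word = "TGACGA"  # last position off-consensus
        lo = sharp_pwm.log_odds
        score = sum(lo[BASES.index(b), j] for j, b in enumerate(word))
        mn, mx = lo.min(axis=0).sum(), lo.max(axis=0).sum()
        assert relative_score(word, sharp_pwm) == pytest.approx(
            (score - mn) / (mx - mn), abs=1e-12
        )

    def test_affine_shift_invariance(self, sharp_pwm):
        # adding a constant to every log-odds entry shifts max and min equally
        word = "TGACGT"
        shifted = PWM(
            sharp_pwm.id, sharp_pwm.probs.copy(), sharp_pwm.background.copy()
        )
        shifted._cache["log_odds"] = sharp_pwm.log_odds + 0.7
        assert relative_score(word, shifted) == pytest.approx(
            relative_score(word, sharp_pwm), abs=1e-9
        )


class TestAffinityComparison:
    def _hit(self, element, offset, pwm):
        return MotifHit(
            sequence_id=element.id, motif_id=pwm.id, offset=offset,
            strand="+", score=1.0, pvalue=1e-5, relative=1.0,
        )

    def test_rule_forced_gain(self, sharp_pwm):
        fixtures = generate_motif_fixture(sharp_pwm, 1, kind="human_gain", seed=3)
        aln, offset = fixtures[0]
        cmp_ = compare_species_affinity(aln, self._hit(aln, offset, sharp_pwm), sharp_pwm)
        assert cmp_.classification == "human_gain"
        assert cmp_.scores["human"] >= 0.8

    def test_conserved_when_all_above_threshold(self, sharp_pwm):
        fixtures = generate_motif_fixture(sharp_pwm, 1, kind="conserved", seed=4)
        aln, offset = fixtures[0]
        cmp_ = compare_species_affinity(aln, self._hit(aln, offset, sharp_pwm), sharp_pwm)
        assert cmp_.classification == "conserved"

    def test_too_few_species_unclassified(self, sharp_pwm):
        fixtures = generate_motif_fixture(
            sharp_pwm, 1, kind="human_gain", seed=5,
            species=("human", "chimp", "gorilla"),
        )
        aln, offset = fixtures[0]
        cmp_ = compare_species_affinity(aln, self._hit(aln, offset, sharp_pwm), sharp_pwm)
        assert cmp_.classification == "unclassified"

    def test_planted_changes_recovered(self, sharp_pwm):
        """>=90% of planted human-specific gains and losses classified right."""
        gains = generate_motif_fixture(sharp_pwm, 50, kind="human_gain", seed=6)
        losses = generate_motif_fixture(sharp_pwm, 50, kind="human_loss", seed=7)
        ok = 0
        for aln, offset in gains:
            hits = scan_sequence(aln.ungapped("human"), sharp_pwm, p_threshold=1e-3)
            if not hits:
                continue
            hit = min(hits, key=lambda h: h.pvalue)
            if compare_species_affinity(aln, hit, sharp_pwm).classification == "human_gain":
                ok += 1
        for aln, offset in losses:
            hit = self._hit(aln, offset, sharp_pwm)
            if compare_species_affinity(aln, hit, sharp_pwm).classification == "human_loss":
                ok += 1
        assert ok >= 90
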