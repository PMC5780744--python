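import numpy as np
import pytest

from epatarget import (
    Background,
    GenomicInterval,
    PWM,
    log_odds_score,
    map_motif_to_tf,
    pvalue_threshold_score,
    read_motifs,
    scan_windows,
    score_distribution,
)
from epatarget.motifs import (
    DictSequenceProvider,
    read_matches,
    reverse_complement,
    write_matches,
    write_meme,
)

import oracles

UNIFORM = Background()


def random_pwm(rng, w):
    return PWM.from_probs(f"m{w}", "TF", rng.dirichlet(np.ones(4) * 0.5, size=w))


class TestParsing:
    def test_transfac_pseudocount_rule(self, tmp_path):
        p = tmp_path / "m.transfac"
        p.write_text(
            "AC M0001\nID motif1\nNA STAT1\nP0 A C G T\n"
            "01 10 0 0 0\n02 0 10 0 0\n03 5 5 0 0\n04 0 0 0 10\n//\n"
        )
        (pwm,) = read_motifs(p, "transfac_counts")
        expected = np.array([10.25, 0.25, 0.25, 0.25]) / 11.0
        assert np.allclose(pwm.matrix[0], expected, atol=1e-9)
        assert pwm.tf_name == "STAT1"

    def test_meme_two_motifs_with_widths(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF M1 TFA\nletter-probability matrix: alength= 4 w= 2\n"
            "0.7 0.1 0.1 0.1\n0.25 0.25 0.25 0.25\n\n"
            "MOTIF M2 TFB\nletter-probability matrix: alength= 4 w= 3\n"
            "1 0 0 0\n0 1 0 0\n0 0 1 0\n"
        )
        pwms = read_motifs(p)
        assert [m.width for m in pwms] == [2, 3]
        assert all(np.all(m.matrix > 0) for m in pwms)  # zeros floored

    def test_bad_alphabet_names_line(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text("MEME version 4\nALPHABET= ACGU\n")
        with pytest.raises(ValueError, match=":2:"):
            read_motifs(p)

    def test_zero_count_column_rejected(self, tmp_path):
        p = tmp_path / "m.transfac"
        p.write_text("AC M1\nP0 A C G T\n01 0 0 0 0\n//\n")
        with pytest.raises(ValueError, match="zero total"):
            read_motifs(p, "transfac_counts")

    def test_meme_roundtrip(self, tmp_path, rng):
        pwms = [random_pwm(rng, w) for w in (4, 7)]
        out = tmp_path / "round.meme"
        write_meme(pwms, out)
        back = read_motifs(out)
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-5)


class TestScoring:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("u", "U", tuple((0.25,) * 4 for _ in range(4)))
        assert log_odds_score(pwm, UNIFORM, "ACGT") == pytest.approx(0.0)

    def test_single_position_analytic(self):
        pwm = PWM("m", "M", ((0.5, 1 / 6, 1 / 6, 1 / 6),))
        assert log_odds_score(pwm, UNIFORM, "A") == pytest.approx(1.0)

    def test_hand_sum_three_columns(self):
        rows = ((0.7, 0.1, 0.1, 0.1), (0.1, 0.7, 0.1, 0.1), (0.1, 0.1, 0.1, 0.7))
        pwm = PWM("m", "M", rows)
        expected = 2 * np.log2(0.7 / 0.25) + np.log2(0.7 / 0.25)
        assert log_odds_score(pwm, UNIFORM, "ACT") == pytest.approx(float(expected))

    def test_non_acgt_base_rejected(self):
        pwm = PWM("m", "M", ((0.25,) * 4,))
        with pytest.raises(KeyError):
            log_odds_score(pwm, UNIFORM, "N")


class TestScoreDistribution:
    def test_single_column_pmf_is_background(self):
        pwm = PWM("m", "M", ((0.5, 1 / 6, 1 / 6, 1 / 6),))
        dist = score_distribution(pwm, UNIFORM)
        support = np.nonzero(dist.pmf)[0]
        assert len(support) == 2  # three columns share the same score
        masses = sorted(dist.pmf[support])
        assert masses == pytest.approx([0.25, 0.75])

    def test_pmf_sums_to_one(self, rng):
        for w in (1, 3, 6):
            dist = score_distribution(random_pwm(rng, w), UNIFORM)
            assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tail_matches_enumeration(self, rng):
        """DP tails bracket brute-force enumeration within 10*eps in score."""
        for w in (2, 4, 6):
            pwm = random_pwm(rng, w)
            dist = score_distribution(pwm, UNIFORM)
            slack = 10 * dist.eps
            support = [(dist.offset + k) * dist.eps for k in np.nonzero(dist.pmf)[0]]
            for q in (0.9, 0.5, 0.1, 0.01):
                s = float(np.quantile(support, q))
                upper = oracles.brute_force_tail(pwm, UNIFORM, s - slack, slack=0.0)
                lower = oracles.brute_force_tail(pwm, UNIFORM, s + slack, slack=0.0)
                assert lower - 1e-12 <= dist.tail(s) <= upper + 1e-12


class TestThreshold:
    def test_alpha_one_gives_min_support(self, rng):
        dist = score_distribution(random_pwm(rng, 4), UNIFORM)
        assert pvalue_threshold_score(dist, 1.0) == pytest.approx(dist.min_score)

    def test_uniform_degenerate_flagged_unreachable(self):
        pwm = PWM("u", "U", tuple((0.25,) * 4 for _ in range(3)))
        dist = score_distribution(pwm, UNIFORM)
        assert pvalue_threshold_score(dist, 0.5) > dist.max_score

    def test_matches_brute_force_threshold(self, rng):
        for _ in range(5):
            pwm = random_pwm(rng, 6)
            dist = score_distribution(pwm, UNIFORM)
            got = pvalue_threshold_score(dist, 1e-3)
            want = oracles.brute_force_threshold(pwm, UNIFORM, 1e-3)
            # oracle returns the last score kept *above* the cut; the
            # implementation returns the minimal passing grid score
            assert dist.tail(got) <= 1e-3
            assert dist.tail(got - dist.eps) > 1e-3
            if want is not None:
                assert got <= want + 10 * dist.eps

    def test_threshold_monotone_in_alpha(self, rng):
        dist = score_distribution(random_pwm(rng, 5), UNIFORM)
        thresholds = [pvalue_threshold_score(dist, a) for a in (1e-4, 1e-3, 1e-2, 0.5)]
        assert thresholds == sorted(thresholds, reverse=True)


class TestScan:
    def _sharp(self, word):
        probs = np.full((len(word), 4), 0.1 / 3)
        for i, b in enumerate(word):
            probs[i, "ACGT".index(b)] = 0.9
        return PWM("sharp", "TF", tuple(map(tuple, probs)))

    def test_planted_consensus_found_at_exact_position(self, rng):
        word = "ACGTACGT"
        pwm = self._sharp(word)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq[:77] + word + seq[77 + len(word):]
        provider = DictSequenceProvider({"chr1": seq})
        hits = scan_windows(
            [GenomicInterval("chr1", 0, 200)], provider, pwm, UNIFORM, alpha=1e-4
        )
        plus = [h for h in hits if h.strand == "+"]
        assert [(h.interval.start, h.interval.end) for h in plus] == [(77, 85)]

    def test_window_shorter_than_motif_yields_nothing(self):
        pwm = self._sharp("ACGTACGT")
        provider = DictSequenceProvider({"chr1": "ACGTA"})
        assert scan_windows([GenomicInterval("chr1", 0, 5)], provider, pwm, UNIFORM) == []

    def test_strand_symmetry_under_reverse_complement(self, rng):
        pwm = self._sharp("ACGTTGCA")
        seq = "".join(rng.choice(list("ACGT"), size=120))
        seq = seq[:40] + "ACGTTGCA" + seq[48:]
        rc = reverse_complement(seq)
        hits_f = scan_windows(
            [GenomicInterval("chr1", 0, len(seq))],
            DictSequenceProvider({"chr1": seq}), pwm, UNIFORM, alpha=1e-4,
        )
        hits_r = scan_windows(
            [GenomicInterval("chr1", 0, len(rc))],
            DictSequenceProvider({"chr1": rc}), pwm, UNIFORM, alpha=1e-4,
        )
        mapped = sorted(
            (len(seq) - h.interval.end, len(seq) - h.interval.start,
             "+" if h.strand == "-" else "-")
            for h in hits_r
        )
        assert mapped == sorted(
            (h.interval.start, h.interval.end, h.strand) for h in hits_f
        )

    def test_scan_agrees_with_exhaustive_rescoring(self, rng):
        """Every reported match re-scores above threshold, and no position
        is missed (brute-force oracle on a small fixture)."""
        pwm = random_pwm(rng, 5)
        dist = score_distribution(pwm, UNIFORM)
        threshold = pvalue_threshold_score(dist, 0.01)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        provider = DictSequenceProvider({"chr1": seq})
        hits = scan_windows(
            [GenomicInterval("chr1", 0, 300)], provider, pwm, UNIFORM, alpha=0.01
        )
        found = {(h.interval.start, h.strand) for h in hits}
        expected = set()
        for off in range(300 - 5 + 1):
            word = seq[off : off + 5]
            if log_odds_score(pwm, UNIFORM, word) >= threshold - 1e-9:
                expected.add((off, "+"))
            if log_odds_score(pwm, UNIFORM, reverse_complement(word)) >= threshold - 1e-9:
                expected.add((off, "-"))
        assert found == expected

    def test_all_reported_pvalues_below_alpha(self, dataset):
        from epatarget.workflow import scan_all_motifs

        matches = scan_all_motifs(dataset)
        assert matches and all(m.pvalue <= 1e-5 for m in matches)


class TestTfMapping:
    ALIASES = {"STAT1": [], "MYC": ["c-Myc", "bHLHe39"], "TP53": ["p53"]}

    @pytest.mark.parametrize("name,expected", [
        ("STAT1", "STAT1"),
        ("stat1", "STAT1"),
        ("c-Myc", "MYC"),
        ("P53", "TP53"),
        ("UNKNOWN_MOTIF_1", None),
    ])
    def test_mapping(self, name, expected):
        assert map_motif_to_tf(name, self.ALIASES) == expected


def test_match_tsv_roundtrip(tmp_path, dataset):
    from epatarget.workflow import scan_all_motifs

    matches = scan_all_motifs(dataset)[:100]
    out = tmp_path / "matches.tsv"
    write_matches(matches, out)
    back = read_matches(out)
    assert [(m.motif_id, m.interval.start, m.strand) for m in back] == [
        (m.motif_id, m.interval.start, m.strand) for m in matches
    ]
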