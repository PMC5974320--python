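import itertools
import math
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tomoloc.motif_scan import (
    IUPAC_SETS, Motif, fisher_enrichment, parse_consensus, position_map,
    presence_summary, pwm_pvalue_threshold, pwm_score_distribution, scan_iupac,
    scan_pwm,
)


class TestConsensusParsing:
    def test_bracket_dialect(self):
        assert parse_consensus("[UA][UC]CAC") == "WYCAC"
        assert parse_consensus("UUCAC") == "TTCAC"

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            parse_consensus("AC0T")


class TestScanIupac:
    def test_literal_hit(self):
        hits = scan_iupac("ATTCACG", Motif(id="m", consensus="TTCAC"))
        assert [(h.start, h.matched) for h in hits] == [(1, "TTCAC")]

    def test_degenerate_hit_at_start(self):
        hits = scan_iupac("CTTCTA", Motif(id="m", consensus="[TC][TC]TCT"))
        assert [h.start for h in hits] == [0]

    def test_no_hit(self):
        assert scan_iupac("GGGGG", Motif(id="m", consensus="TTCAC")) == []

    def test_motif_wider_than_utr(self):
        assert scan_iupac("ACG", Motif(id="m", consensus="ACGTACGT")) == []

    def test_overlapping_hits_reported(self):
        hits = scan_iupac("AAAA", Motif(id="m", consensus="AA"))
        assert [h.start for h in hits] == [0, 1, 2]

    @settings(derandomize=True, max_examples=40)
    @given(seq=st.text(alphabet="ACGT", min_size=5, max_size=80),
           consensus=st.text(alphabet="ACGTRYSWKMN", min_size=2, max_size=5))
    def test_matches_regex_oracle(self, seq, consensus):
        motif = Motif(id="m", consensus=consensus)
        pattern = "".join(f"[{IUPAC_SETS[c]}]" for c in consensus)
        expected = [m.start() for m in
                    re.finditer(f"(?=({pattern}))", seq)]
        assert [h.start for h in scan_iupac(seq, motif)] == expected


def _enumerated_tail(pwm, background, score, step=1e-3):
    """Brute-force PWM p-value: enumerate all 4^w words.

    Column scores are rounded to the same grid the scanner uses (the
    discretization is part of the score definition).
    """
    total = 0.0
    w = pwm.shape[0]
    thr_int = round(score / step)
    for word in itertools.product(range(4), repeat=w):
        s = sum(round(math.log2((pwm[j, b] + 1e-4) /
                                ((background[b] + 1e-4) / (1 + 4e-4))) / step)
                for j, b in enumerate(word))
        if s >= thr_int:
            total += math.prod(background[b] for b in word)
    return total


class TestPwmPvalues:
    def test_alpha_one_accepts_everything(self):
        m = Motif(id="m", consensus="ACG")
        thr = pwm_pvalue_threshold(m, alpha=1.0)
        dist = pwm_score_distribution(m)
        assert dist.pvalue(thr) == pytest.approx(1.0)

    def test_best_word_threshold(self):
        # width-2 PWM with a unique best word; uniform background:
        # p(best word) = 1/16, so alpha = 1/16 admits exactly that word
        pwm = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]])
        m = Motif(id="m", pwm=pwm)
        dist = pwm_score_distribution(m)
        thr = dist.threshold(1 / 16)
        best = 2 * math.log2((0.7 + 1e-4) / (0.25 + 1e-4) * (1 + 4e-4))
        assert thr == pytest.approx(best, abs=2e-3)

    @pytest.mark.parametrize("width", [2, 3, 4])
    def test_dp_equals_enumeration(self, width, rng):
        pwm = rng.dirichlet(np.ones(4) * 0.7, size=width)
        m = Motif(id="m", pwm=pwm)
        background = np.full(4, 0.25)
        dist = pwm_score_distribution(m, background)
        for alpha in (0.5, 0.05, 0.001):
            thr = dist.threshold(alpha)
            brute = _enumerated_tail(pwm, background, thr)
            assert dist.pvalue(thr) == pytest.approx(brute, abs=1e-6)
            assert brute <= alpha + 1e-9


class TestScanPwm:
    def test_consensus_word_found(self):
        pwm = np.eye(4)[[3, 3, 1, 0, 1]]  # TTCAC as a 0/1 PWM
        m = Motif(id="m", pwm=(pwm + 1e-9) / (pwm + 1e-9).sum(1, keepdims=True))
        thr = pwm_pvalue_threshold(m, alpha=0.001)
        hits = scan_pwm("GGTTCACGG", m, thr)
        assert [h.start for h in hits] == [2]
        assert hits[0].p <= 0.001

    def test_threshold_above_max_score_empty(self):
        m = Motif(id="m", consensus="ACG")
        assert scan_pwm("ACGACG", m, threshold=1e6) == []

    def test_equivalence_with_iupac_scan(self, rng):
        """A 0/1 PWM over IUPAC sets scans identically to the IUPAC mode."""
        consensus = "WYCAC"
        m = Motif(id="m", consensus=consensus)
        dist = pwm_score_distribution(m)
        # admit exactly the words of the IUPAC language: threshold at the
        # minimal score of an accepted word
        n_words = math.prod(len(IUPAC_SETS[c]) for c in consensus)
        thr = dist.threshold(n_words / 4 ** len(consensus))
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 60))
            iupac_hits = [h.start for h in scan_iupac(seq, m)]
            pwm_hits = [h.start for h in scan_pwm(seq, m, thr, dist=dist)]
            assert iupac_hits == pwm_hits


class TestFisher:
    def test_no_hits_anywhere(self):
        _, p = fisher_enrichment(0, 10, 0, 10)
        assert p == 1.0

    def test_extreme_table_point_mass(self):
        _, p = fisher_enrichment(10, 0, 0, 10)
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_matches_hypergeometric_enumeration(self):
        a, b, c, d = 10, 10, 2, 18
        _, p = fisher_enrichment(a, b, c, d)
        n, K, N = a + b + c + d, a + c, a + b
        tail = sum(
            math.comb(K, x) * math.comb(n - K, N - x) / math.comb(n, N)
            for x in range(a, min(K, N) + 1)
        )
        assert p == pytest.approx(tail, rel=1e-9)

    def test_haldane_odds_ratio_finite(self):
        odds, _ = fisher_enrichment(5, 5, 0, 10)
        assert np.isfinite(odds) and odds > 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 0, 0)


class TestPresenceSummary:
    def test_proportions(self):
        utrs = {"veg": {"g1": "TTCACAA", "g2": "GGGGGGG", "g3": "TTTCACG"}}
        table = presence_summary(utrs, [Motif(id="m", consensus="TTCAC")])
        row = table.iloc[0]
        assert row["n_with_hit"] == 2
        assert row["proportion"] == pytest.approx(2 / 3)

    def test_absent_motif_zero(self):
        table = presence_summary({"c": {"g": "AAAA"}},
                                 [Motif(id="m", consensus="CCC")])
        assert table.iloc[0]["proportion"] == 0.0

    def test_single_base_motif_everywhere(self):
        table = presence_summary({"c": {"g1": "ATA", "g2": "AAA"}},
                                 [Motif(id="m", consensus="A")])
        assert table.iloc[0]["proportion"] == 1.0

    def test_occurrences_per_kbp(self):
        utrs = {"c": {"g1": "TTCAC" + "G" * 995}}
        table = presence_summary(utrs, [Motif(id="m", consensus="TTCAC")])
        assert table.iloc[0]["occ_per_kbp"] == pytest.approx(1.0)


def test_position_map_sorted_overlaps():
    out = position_map("AAAA", [Motif(id="aa", consensus="AA"),
                                Motif(id="cc", consensus="CC")])
    assert out["aa"] == [0, 1, 2]
    assert out["cc"] == []
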