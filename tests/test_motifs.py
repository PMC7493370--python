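"""PWM parsing, log-odds conversion and p-value threshold calibration."""
import itertools
import math

import numpy as np
import pytest

from scoremea.motifs import (
    Background,
    MotifMatrix,
    MotifParseError,
    make_scoring_matrix,
    parse_jaspar,
    pvalue_threshold,
    reverse_complement,
    score_distribution,
    to_log_odds,
)
from scoremea.seqio import reverse_complement_seq

from .conftest import random_motif

JASPAR_TEXT = """\
>M1 TEST
A [ 1 0 ]
C [ 0 1 ]
G [ 0 0 ]
T [ 0 0 ]
>M2
13 5 0
2 2 2
1 1 17
4 12 1
"""


class TestParseJaspar:
    def test_decorated_record(self):
        motifs = parse_jaspar(JASPAR_TEXT)
        m1 = motifs[0]
        assert (m1.motif_id, m1.motif_name, m1.width) == ("M1", "TEST", 2)
        np.testing.assert_array_equal(
            m1.counts, [[1, 0], [0, 1], [0, 0], [0, 0]]
        )

    def test_bare_block_fallback_and_default_name(self):
        motifs = parse_jaspar(JASPAR_TEXT)
        m2 = motifs[1]
        assert m2.motif_name == "M2"
        assert m2.width == 3
        np.testing.assert_array_equal(m2.counts[2], [1, 1, 17])

    def test_empty_stream(self):
        assert parse_jaspar("") == []

    @pytest.mark.parametrize(
        "text",
        [
            ">B\nA [1 2]\nC [3 4]\nG [5 6]\n",            # 3 rows
            ">B\nA [1 2]\nC [3]\nG [5 6]\nT [0 0]\n",     # ragged
            ">B\nA [1 -2]\nC [3 4]\nG [5 6]\nT [0 0]\n",  # negative
            ">B\nA [1 2]\nC [3 4]\nG [5 6]\nT [x y]\n",   # junk
        ],
    )
    def test_malformed_records_name_the_motif(self, text):
        with pytest.raises(MotifParseError, match="B"):
            parse_jaspar(text)


class TestToLogOdds:
    def test_flat_counts_give_zero_log_odds(self, uniform_bg):
        m = MotifMatrix("F", "F", np.ones((4, 5)))
        sm = to_log_odds(m, 0.7, uniform_bg)
        np.testing.assert_allclose(sm.log_odds, 0.0, atol=1e-12)

    def test_hand_arithmetic_width_one(self, uniform_bg):
        m = MotifMatrix("H", "H", np.array([[1.0], [0.0], [0.0], [0.0]]))
        sm = to_log_odds(m, 1.0, uniform_bg)
        expected = [math.log2(2.5)] + [math.log2(0.5)] * 3
        np.testing.assert_allclose(sm.log_odds.ravel(), expected)

    def test_small_pseudocount_matches_direct_formula(self, uniform_bg):
        m = MotifMatrix("H", "H", np.array([[1.0], [0.0], [0.0], [0.0]]))
        sm = to_log_odds(m, 0.001, uniform_bg)
        # independent scalar evaluation of the stated formula
        expected = [
            math.log2(((c + 0.001 * 0.25) / 1.001) / 0.25) for c in (1.0, 0.0, 0.0, 0.0)
        ]
        np.testing.assert_allclose(sm.log_odds.ravel(), expected)

    def test_column_probabilities_sum_to_one(self, uniform_bg, rng):
        for _ in range(5):
            m = random_motif(rng, int(rng.integers(1, 9)))
            sm = to_log_odds(m, 0.25, uniform_bg)
            probs = (2.0**sm.log_odds) * uniform_bg.base_probabilities[:, None]
            np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_cell_with_zero_pseudocount_errors(self, uniform_bg):
        m = MotifMatrix("Z", "Z", np.array([[1.0], [0.0], [0.0], [0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            to_log_odds(m, 0.0, uniform_bg)


def brute_force_threshold(sm, bg, pval):
    """Enumerate all 4^w words; smallest score whose >=-tail is <= pval."""
    w = sm.width
    entries = []
    for word in itertools.product(range(4), repeat=w):
        score = sum(sm.log_odds[b, j] for j, b in enumerate(word))
        prob = math.prod(bg.base_probabilities[b] for b in word)
        entries.append((score, prob))
    entries.sort(key=lambda e: e[0], reverse=True)
    best = math.inf
    tail = 0.0
    i = 0
    while i < len(entries):
        j = i
        while j < len(entries) and entries[j][0] == entries[i][0]:
            tail += entries[j][1]
            j += 1
        if tail <= pval + 1e-15:
            best = entries[i][0]
        i = j
    return best


class TestPvalueThreshold:
    def test_degenerate_all_zero_matrix_is_unmatchable(self, uniform_bg):
        sm = to_log_odds(MotifMatrix("Z", "Z", np.ones((4, 3))), 0.0, uniform_bg)
        assert pvalue_threshold(sm, uniform_bg, 0.5) == math.inf

    def test_pval_one_returns_minimum_achievable_score(self, uniform_bg, rng):
        sm = to_log_odds(random_motif(rng, 4), 0.5, uniform_bg)
        t = pvalue_threshold(sm, uniform_bg, 1.0)
        assert t == pytest.approx(sm.log_odds.min(axis=0).sum())

    @pytest.mark.parametrize("pval", [0.001, 0.01, 0.2])
    def test_matches_brute_force_oracle(self, uniform_bg, rng, pval):
        for _ in range(5):
            w = int(rng.integers(2, 8))
            sm = to_log_odds(random_motif(rng, w), 0.3, uniform_bg)
            assert pvalue_threshold(sm, uniform_bg, pval) == brute_force_threshold(
                sm, uniform_bg, pval
            )

    def test_nonuniform_background_matches_oracle(self, rng):
        bg = Background(np.array([0.4, 0.1, 0.2, 0.3]))
        sm = to_log_odds(random_motif(rng, 6), 0.3, bg)
        assert pvalue_threshold(sm, bg, 0.01) == brute_force_threshold(sm, bg, 0.01)

    def test_tail_at_threshold_never_exceeds_pval(self, uniform_bg, rng):
        for pval in (0.001, 0.05):
            sm = to_log_odds(random_motif(rng, 7), 0.2, uniform_bg)
            t = pvalue_threshold(sm, uniform_bg, pval)
            scores, probs = score_distribution(sm, uniform_bg)
            assert probs[scores >= t].sum() <= pval + 1e-12

    def test_dp_path_close_to_exact_and_conservative(self, uniform_bg, rng):
        # width 11 goes through the DP; compare with direct enumeration
        sm = to_log_odds(random_motif(rng, 11), 0.5, uniform_bg)
        t_dp = pvalue_threshold(sm, uniform_bg, 0.001)
        scores, probs = score_distribution(sm, uniform_bg)
        tails = np.cumsum(probs[::-1])[::-1]
        exact = scores[np.nonzero(tails <= 0.001)[0][0]]
        # one discretization quantum per position plus the safety shift
        assert t_dp <= exact + 1e-9
        assert exact - t_dp <= 11 * 0.0005 + 0.001 + 1e-9

    def test_bad_pval_rejected(self, uniform_bg, rng):
        sm = to_log_odds(random_motif(rng, 3), 0.5, uniform_bg)
        for pval in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pvalue_threshold(sm, uniform_bg, pval)


class TestReverseComplement:
    def test_palindromic_matrix_fixed_point(self, uniform_bg):
        m = MotifMatrix("P", "P", np.array(
            [[5, 1, 1, 1], [1, 5, 1, 1], [1, 1, 5, 1], [1, 1, 1, 5]], dtype=float
        ))
        sm = to_log_odds(m, 0.5, uniform_bg)  # consensus ACGT, a palindrome
        np.testing.assert_allclose(reverse_complement(sm).log_odds, sm.log_odds)

    def test_involution_is_exact(self, uniform_bg, rng):
        sm = to_log_odds(random_motif(rng, 5), 0.2, uniform_bg)
        np.testing.assert_array_equal(
            reverse_complement(reverse_complement(sm)).log_odds, sm.log_odds
        )

    def test_a_row_moves_to_t_row_reversed(self, uniform_bg):
        m = MotifMatrix("W", "W", np.array(
            [[1, 2], [1, 1], [1, 1], [1, 1]], dtype=float
        ))
        sm = to_log_odds(m, 0.5, uniform_bg)
        rc = reverse_complement(sm)
        np.testing.assert_allclose(rc.log_odds[3], sm.log_odds[0, ::-1])

    def test_word_score_equals_revcomp_score(self, uniform_bg, rng):
        sm = to_log_odds(random_motif(rng, 6), 0.2, uniform_bg)
        rc = reverse_complement(sm)
        for _ in range(20):
            word = "".join(rng.choice(list("ACGT"), size=6))
            assert sm.score_word(word) == pytest.approx(
                rc.score_word(reverse_complement_seq(word)), abs=1e-12
            )

    def test_threshold_carried_over(self, uniform_bg, rng):
        sm = make_scoring_matrix(random_motif(rng, 5), 0.1, 0.01, uniform_bg)
        assert reverse_complement(sm).threshold == sm.threshold
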