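"""Position weight scoring matrices: pseudocounts, conservation, scoring."""

import itertools
import math

import numpy as np
import pytest

import ionbind as ib
from ionbind.alphabets import ALPHABETS, TrackAlphabet
from ionbind.pwsm import PWSM, empirical_background, encode_windows

TOY = TrackAlphabet("toy", ("a", "b", "X"))


def random_pwsm(alphabet, length, seed, low=1, high=40):
    rng = np.random.default_rng(seed)
    counts = rng.integers(low, high, size=(length, alphabet.size))
    background = rng.uniform(0.05, 1.0, size=alphabet.size)
    background /= background.sum()
    return PWSM.from_counts(counts, alphabet, background)


class TestProbabilities:
    def test_pseudocount_hand_value(self):
        """N_i=4 concentrated on one of 21 symbols: p = (4 + 2/21) / 6."""
        counts = np.zeros((1, 21), dtype=int)
        counts[0, 0] = 4
        pwsm = PWSM.from_counts(counts, ALPHABETS["amino"], np.full(21, 1 / 21))
        assert pwsm.probs[0, 0] == pytest.approx((4 + 2 / 21) / 6, abs=1e-9)
        assert pwsm.probs[0, 0] == pytest.approx(0.682540, abs=1e-6)

    def test_rows_normalize_exactly(self):
        for seed in range(25):
            pwsm = random_pwsm(ALPHABETS["amino"], 9, seed, low=0)
            assert np.allclose(pwsm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_position_has_uniform_probs_and_zero_conservation(self):
        counts = np.ones((1, 21), dtype=int)
        pwsm = PWSM.from_counts(counts, ALPHABETS["amino"], np.full(21, 1 / 21))
        assert np.allclose(pwsm.probs[0], 1 / 21, atol=1e-12)
        assert pwsm.conservation[0] == pytest.approx(0.0, abs=1e-9)

    def test_conservation_bounded_and_monotone_in_concentration(self):
        prev = -1.0
        for bulk in (1, 4, 16, 64, 256):
            counts = np.ones((1, 4), dtype=int)
            counts[0, 0] += bulk
            pwsm = PWSM.from_counts(counts, ALPHABETS["ss"], np.full(4, 0.25))
            c = pwsm.conservation[0]
            assert 0.0 < c < 100.0
            assert c > prev
            prev = c


class TestErrors:
    def test_zero_background_entry_rejected(self):
        with pytest.raises(ValueError, match="background"):
            PWSM.from_counts(np.ones((2, 3), int), TOY, np.array([0.5, 0.5, 0.0]))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PWSM.from_windows([], TOY, np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            empirical_background([], TOY)

    def test_uninformative_matrix_refuses_to_score(self):
        counts = np.ones((3, 3), dtype=int)
        pwsm = PWSM.from_counts(counts, TOY, np.full(3, 1 / 3))
        with pytest.raises(ValueError, match="uninformative"):
            pwsm.score(np.zeros((1, 3), dtype=int))

    def test_wrong_window_length_rejected(self):
        pwsm = random_pwsm(TOY, 4, 0)
        with pytest.raises(ValueError):
            pwsm.profile(np.zeros((1, 3), dtype=int))


class TestScore:
    def test_argmax_window_scores_one_argmin_scores_zero(self):
        pwsm = random_pwsm(ALPHABETS["amino"], 7, seed=2)
        best = pwsm.logodds.argmax(axis=1)[None, :]
        worst = pwsm.logodds.argmin(axis=1)[None, :]
        assert pwsm.score(best)[0] == pytest.approx(1.0, abs=1e-12)
        assert pwsm.score(worst)[0] == pytest.approx(0.0, abs=1e-12)

    def test_score_matches_brute_force_reevaluation_on_toy_matrix(self):
        """Independent direct evaluation of the weighted scoring formula
        over every one of the 3^4 windows of a toy length-4 matrix."""
        pwsm = random_pwsm(TOY, 4, seed=7)
        a = TOY.size
        # independent oracle from the definition, scalar arithmetic only
        p = [[(pwsm.counts[i][j] + math.sqrt(sum(pwsm.counts[i])) / a)
              / (sum(pwsm.counts[i]) + math.sqrt(sum(pwsm.counts[i])))
              for j in range(a)] for i in range(4)]
        m = [[math.log(p[i][j] / pwsm.background[j]) for j in range(a)]
             for i in range(4)]
        c = [100 / math.log(a) * (sum(pij * math.log(pij) for pij in p[i])
                                  + math.log(a)) for i in range(4)]
        denom = sum(c[i] * (max(m[i]) - min(m[i])) for i in range(4))
        for window in itertools.product(range(a), repeat=4):
            expected = sum(
                c[i] * (m[i][window[i]] - min(m[i])) for i in range(4)
            ) / denom
            got = pwsm.score(np.array([window]))[0]
            assert got == pytest.approx(expected, abs=1e-9)
            assert -1e-12 <= got <= 1 + 1e-12

    def test_window_string_api_agrees_with_encoded_api(self):
        pwsm = random_pwsm(TOY, 4, seed=3)
        window = "abXa"
        enc = np.array([TOY.encode(window)])
        assert ib.pwsm_score(window, pwsm) == pytest.approx(pwsm.score(enc)[0])


class TestProfile:
    def test_identical_matrices_give_mirrored_halves(self):
        pwsm = random_pwsm(TOY, 4, seed=1)
        prof = ib.position_profile("abXa", pwsm, pwsm)
        assert len(prof) == 8
        assert np.allclose(prof[:4], prof[4:])

    def test_profile_returns_row_lookups(self):
        pwsm = random_pwsm(TOY, 4, seed=4)
        enc = encode_windows(["aaXb"], TOY)
        got = pwsm.profile(enc)[0]
        for i, j in enumerate(enc[0]):
            assert got[i] == pwsm.logodds[i, j]


class TestBackground:
    def test_empirical_frequencies(self):
        # all symbols observed: exact empirical frequencies, no flooring
        bg = empirical_background(["aX", "ab"], TOY)
        assert np.allclose(bg, [0.5, 0.25, 0.25])
        # absent 'X': floored at 1/(10*A*total) then renormalized
        bg = empirical_background(["aa", "ab"], TOY)
        floor = 1 / (10 * 3 * 4)
        expected = np.array([0.75, 0.25, floor])
        assert np.allclose(bg, expected / expected.sum())
        assert bg.sum() == pytest.approx(1.0)

    def test_absent_symbol_floored_not_zero(self):
        bg = empirical_background(["aaaa"], TOY)
        assert bg[TOY.index("b")] > 0
        assert bg[TOY.index("X")] > 0


def test_serialization_round_trip_and_verification():
    pwsm = random_pwsm(ALPHABETS["charge"], 5, seed=6)
    restored = PWSM.from_json(pwsm.to_json())
    assert np.allclose(restored.logodds, pwsm.logodds)
    assert np.allclose(restored.conservation, pwsm.conservation)
    import json

    payload = json.loads(pwsm.to_json())
    payload["logodds"][0][0] += 1.0
    with pytest.raises(ValueError, match="disagree"):
        PWSM.from_json(json.dumps(payload))
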