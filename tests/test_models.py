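import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orthosim.models import (
    CalibrationResult,
    MatchResult,
    UndefinedScoreError,
    binary_ob_match,
    calibrate_noise,
    gradient_match,
    noisy_bigram_code,
    noisy_ob_match,
    score_pair,
    slot_coding_match,
    weighted_ob_match,
)
from orthosim.orthography import (
    CodingPolicy,
    LetterString,
    OpenBigram,
    ValidationError,
    normalize_string,
)

from conftest import ALPHABET, brute_force_pairs, random_no_repeat_word

SERIOL_WEIGHTS = {0: 1.0, 1: 0.8, 2: 0.4}


def oracle_weighted_score(prime: str, target: str) -> float:
    """Brute-force weighted enumeration, independent of the package path:
    per-gap weights over all ordered pairs, repeated pairs at max weight."""

    def weighted_pairs(text: str) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for i, j in itertools.combinations(range(len(text)), 2):
            w = SERIOL_WEIGHTS.get(j - i - 1, 0.0)
            if w > 0:
                key = (text[i], text[j])
                out[key] = max(out.get(key, 0.0), w)
        return out

    p, t = weighted_pairs(prime.upper()), weighted_pairs(target.upper())
    denom = sum(t.values())
    return sum(min(p[k], t[k]) for k in p.keys() & t.keys()) / denom


class TestBinaryMatch:
    def test_tl_prime_scores_nine_tenths(self, unbounded):
        res = binary_ob_match(
            normalize_string("jugde"), normalize_string("JUDGE"), unbounded
        )
        assert res.score == pytest.approx(0.9)
        assert len(res.shared) == 9

    def test_sl_prime_scores_three_tenths(self, unbounded):
        res = binary_ob_match(
            normalize_string("junpe"), normalize_string("JUDGE"), unbounded
        )
        assert res.score == pytest.approx(0.3)
        assert {b.pair for b in res.shared} == {"JU", "JE", "UE"}

    def test_repeated_bigram_degenerate_full_match(self):
        policy = CodingPolicy.binary(max_gap=2, include_edges=True)
        res = binary_ob_match(
            normalize_string("casaca"), normalize_string("CASA"), policy
        )
        assert res.score == 1.0

    def test_reversed_two_letter_prime_scores_zero(self, unbounded):
        res = binary_ob_match(
            normalize_string("fo"), normalize_string("OF"), unbounded
        )
        assert res.score == 0.0
        assert res.shared == frozenset()

    @pytest.mark.parametrize("word", ["OF", "THE", "JUDGE", "ABOLISH"])
    def test_identity_scores_one(self, word, unbounded):
        s = normalize_string(word)
        assert binary_ob_match(s, s, unbounded).score == 1.0

    def test_single_letter_target_undefined(self, unbounded):
        with pytest.raises(UndefinedScoreError):
            binary_ob_match(LetterString("A"), LetterString("B"), unbounded)


class TestWeightedMatch:
    # frozen from the brute-force weighted enumeration oracle:
    # denominator 6*1.0 + 5*0.8 + 4*0.4 = 11.6
    def test_contiguous_bigram_prime(self):
        res = weighted_ob_match(normalize_string("bo"), normalize_string("ABOLISH"))
        assert res.score == pytest.approx(1.0 / 11.6)
        assert res.score == pytest.approx(oracle_weighted_score("bo", "ABOLISH"))

    def test_one_gap_bigram_prime(self):
        res = weighted_ob_match(normalize_string("bl"), normalize_string("ABOLISH"))
        assert res.score == pytest.approx(0.8 / 11.6)
        assert res.score == pytest.approx(oracle_weighted_score("bl", "ABOLISH"))

    def test_three_gap_bigram_prime_scores_zero(self):
        res = weighted_ob_match(normalize_string("bs"), normalize_string("ABOLISH"))
        assert res.score == 0.0

    def test_identity_scores_one(self):
        s = normalize_string("ABOLISH")
        assert weighted_ob_match(s, s).score == pytest.approx(1.0)

    def test_agrees_with_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            prime = random_no_repeat_word(rng, rng.randint(2, 8))
            target = random_no_repeat_word(rng, rng.randint(2, 8))
            assert weighted_ob_match(prime, target).score == pytest.approx(
                oracle_weighted_score(prime.text, target.text)
            )


def mc_pair_activations(
    text: str, sd: float, n_draws: int, seed: int
) -> dict[tuple[str, str], tuple[float, float]]:
    """Monte-Carlo oracle: sample perceived positions and estimate each
    ordered pair's order probability.  Returns pair -> (activation, 3 SE)."""
    rng = np.random.default_rng(seed)
    n = len(text)
    positions = np.arange(1, n + 1) + rng.normal(0.0, sd, size=(n_draws, n))
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, j in itertools.combinations(range(n), 2):
        w = SERIOL_WEIGHTS.get(j - i - 1, 0.0)
        if w == 0.0:
            continue
        p_fwd = float(np.mean(positions[:, i] < positions[:, j]))
        se = math.sqrt(max(p_fwd * (1 - p_fwd), 1e-12) / n_draws)
        for key, p in (((text[i], text[j]), p_fwd), ((text[j], text[i]), 1 - p_fwd)):
            act, err = w * p, 3 * w * se
            if key not in out or act > out[key][0]:
                out[key] = (act, err)
    return out


def oracle_noisy_score(prime: str, target: str, sd: float, n_draws=200_000, seed=7):
    p_acts = mc_pair_activations(prime.upper(), sd, n_draws, seed)
    t_acts = mc_pair_activations(target.upper(), sd, n_draws, seed + 1)
    denom = sum(a for a, _ in t_acts.values())
    num = sum(
        min(p_acts[k][0], t_acts[k][0]) for k in p_acts.keys() & t_acts.keys()
    )
    return num / denom


class TestNoisyMatch:
    def test_zero_noise_equals_weighted(self, rng):
        policy = CodingPolicy.seriol(noise_sd=0.0)
        for _ in range(25):
            prime = random_no_repeat_word(rng, rng.randint(2, 7))
            target = random_no_repeat_word(rng, rng.randint(2, 7))
            assert noisy_ob_match(prime, target, policy).score == pytest.approx(
                weighted_ob_match(prime, target).score
            )

    def test_convergence_to_weighted_as_noise_vanishes(self, rng):
        policy = CodingPolicy.seriol(noise_sd=1e-4)
        for _ in range(25):
            prime = random_no_repeat_word(rng, rng.randint(2, 7))
            target = random_no_repeat_word(rng, rng.randint(2, 7))
            noisy = noisy_ob_match(prime, target, policy).score
            weighted = weighted_ob_match(prime, target).score
            assert abs(noisy - weighted) < 1e-6

    def test_reversed_two_letter_prime_between_zero_and_identity(self):
        policy = CodingPolicy.seriol(noise_sd=0.5)
        of = normalize_string("OF")
        reversed_score = noisy_ob_match(normalize_string("fo"), of, policy).score
        identity_score = noisy_ob_match(normalize_string("of"), of, policy).score
        assert 0.0 < reversed_score < identity_score
        assert identity_score == pytest.approx(1.0)

    def test_matches_monte_carlo_oracle(self):
        policy = CodingPolicy.seriol(noise_sd=0.5)
        for prime, target in [("fo", "OF"), ("hte", "THE"), ("ob", "ABOLISH")]:
            implemented = noisy_ob_match(
                normalize_string(prime), normalize_string(target), policy
            ).score
            assert implemented == pytest.approx(
                oracle_noisy_score(prime, target, 0.5), abs=0.005
            )

    def test_mc_oracle_pair_activations_within_three_se(self):
        # per-pair closed-form activations sit inside the MC oracle's 3-SE band
        policy = CodingPolicy.seriol(noise_sd=0.5)
        code = noisy_bigram_code(normalize_string("THE"), policy)
        mc = mc_pair_activations("THE", 0.5, 200_000, seed=11)
        for bigram, act in code.entries.items():
            mc_act, mc_err = mc[(bigram.first, bigram.second)]
            assert abs(act - mc_act) <= mc_err

    def test_gap3_reversed_prime_scores_zero_under_seriol(self):
        policy = CodingPolicy.seriol(noise_sd=0.5)
        ab = normalize_string("ABOLISH")
        assert noisy_ob_match(normalize_string("sb"), ab, policy).score == 0.0
        assert noisy_ob_match(normalize_string("bs"), ab, policy).score == 0.0

    def test_reversed_activation_increases_with_noise(self):
        ab = normalize_string("AB")
        sigmas = [0.2, 0.4, 0.6, 0.8, 1.0, 1.2]
        rev = [
            noisy_bigram_code(ab, CodingPolicy.seriol(noise_sd=s)).weight_of(
                OpenBigram("B", "A")
            )
            for s in sigmas
        ]
        fwd = [
            noisy_bigram_code(ab, CodingPolicy.seriol(noise_sd=s)).weight_of(
                OpenBigram("A", "B")
            )
            for s in sigmas
        ]
        assert all(a < b for a, b in zip(rev, rev[1:]))
        assert all(a > b for a, b in zip(fwd, fwd[1:]))


class TestSlotCoding:
    def test_tl_prime(self):
        res = slot_coding_match(normalize_string("jugde"), normalize_string("JUDGE"))
        assert res.score == pytest.approx(0.6)

    def test_sl_prime_equals_tl_prime(self):
        tl = slot_coding_match(normalize_string("jugde"), normalize_string("JUDGE"))
        sl = slot_coding_match(normalize_string("junpe"), normalize_string("JUDGE"))
        assert tl.score == sl.score == pytest.approx(0.6)

    def test_anagram_shares_only_final_slot(self):
        # C_1 A_2 T_3 vs A_1 C_2 T_3: only the T in slot 3 coincides
        res = slot_coding_match(normalize_string("CAT"), normalize_string("ACT"))
        assert res.score == pytest.approx(1 / 3)

    def test_fully_disjoint_slots(self):
        assert slot_coding_match(normalize_string("ab"), normalize_string("BA")).score == 0.0

    def test_left_alignment_with_unequal_lengths(self):
        res = slot_coding_match(normalize_string("pray"), normalize_string("SPRAY"))
        assert res.score == 0.0


class TestGradientMatch:
    def test_identity(self):
        s = normalize_string("ABOLISH")
        assert gradient_match(s, s).score == pytest.approx(1.0)

    def test_letter_disjoint_prime_scores_zero(self):
        res = gradient_match(normalize_string("we"), normalize_string("ABOLISH"))
        assert res.score == 0.0

    def test_contiguous_beats_distant_bigram_prime(self):
        ab = normalize_string("ABOLISH")
        near = gradient_match(normalize_string("bo"), ab).score
        far = gradient_match(normalize_string("bs"), ab).score
        assert near > far > 0.0

    @pytest.mark.parametrize("decay", [0.0, 1.0, -0.5, 1.5])
    def test_decay_bounds(self, decay):
        with pytest.raises(ValidationError):
            gradient_match(normalize_string("cat"), normalize_string("CAT"), decay)


class TestCalibrateNoise:
    POLICY = CodingPolicy.seriol()
    PUBLISHED = [
        (normalize_string("fo"), normalize_string("OF"), 0.27),
        (normalize_string("hte"), normalize_string("THE"), 0.62),
    ]

    def test_empty_published_list_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_noise([], self.POLICY)

    def test_agrees_with_grid_search_oracle(self):
        result = calibrate_noise(self.PUBLISHED, self.POLICY)
        assert isinstance(result, CalibrationResult)
        assert result.converged
        # independent grid search over sigma in (0, 3]
        grid = np.arange(0.01, 3.001, 0.01)
        sses = [
            sum(
                (
                    noisy_ob_match(p, t, self.POLICY.with_noise(float(s))).score
                    - published
                )
                ** 2
                for p, t, published in self.PUBLISHED
            )
            for s in grid
        ]
        best = float(grid[int(np.argmin(sses))])
        assert result.noise_sd == pytest.approx(best, abs=0.01)
        assert result.sse <= min(sses) + 1e-9
        assert len(result.residuals) == 2

    def test_self_consistency_recovers_known_sigma(self):
        true_sigma = 0.7
        pol = self.POLICY.with_noise(true_sigma)
        synthetic = [
            (p, t, noisy_ob_match(p, t, pol).score)
            for p, t, _ in self.PUBLISHED
        ]
        result = calibrate_noise(synthetic, self.POLICY)
        assert result.noise_sd == pytest.approx(true_sigma, abs=0.01)
        assert all(abs(r) < 1e-5 for r in result.residuals)


class TestCrossModelInvariants:
    MODELS = ["binary", "weighted", "noisy", "slot", "gradient"]

    @given(
        data=st.tuples(
            st.integers(2, 8),
            st.integers(2, 8),
            st.randoms(use_true_random=False),
        )
    )
    def test_scores_in_unit_interval(self, data):
        n1, n2, r = data
        prime = LetterString("".join(r.sample(ALPHABET, n1)))
        target = LetterString("".join(r.sample(ALPHABET, n2)))
        for model in self.MODELS:
            assert 0.0 <= score_pair(prime, target, model).score <= 1.0

    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("word", ["OF", "THE", "JUDGE", "ABOLISH"])
    def test_identity_scores_one(self, model, word):
        s = normalize_string(word)
        assert score_pair(s, s, model).score == pytest.approx(1.0)

    @pytest.mark.parametrize("model", MODELS)
    def test_letter_disjoint_scores_zero(self, model, rng):
        for _ in range(10):
            letters = rng.sample(ALPHABET, 10)
            prime = LetterString("".join(letters[:4]))
            target = LetterString("".join(letters[4:]))
            assert score_pair(prime, target, model).score == 0.0

    def test_binary_equals_brute_force_on_random_pairs(self, rng, unbounded):
        for _ in range(100):
            prime = random_no_repeat_word(rng, rng.randint(2, 8))
            target = random_no_repeat_word(rng, rng.randint(2, 8))
            for max_gap in (None, 1, 2):
                policy = CodingPolicy.binary(max_gap=max_gap)
                shared = brute_force_pairs(prime.text, max_gap) & brute_force_pairs(
                    target.text, max_gap
                )
                expected = len(shared) / len(brute_force_pairs(target.text, max_gap))
                assert binary_ob_match(prime, target, policy).score == pytest.approx(
                    expected
                )

    def test_unknown_model_rejected(self):
        with pytest.raises(ValidationError):
            score_pair(normalize_string("cat"), normalize_string("CAT"), "nope")

    def test_match_result_rejects_out_of_range_score(self):
        with pytest.raises(ValidationError):
            MatchResult(shared=frozenset(), score=1.5, model="binary")
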