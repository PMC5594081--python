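import numpy as np
import pytest

from chronnect.chronnectomics import (
    ChronnectomicFeatures,
    assemble_features,
    ci_zscore,
    comodulogram,
    complexity_index,
    compute_chronnectomics,
    empirical_markov,
    entropy_rate,
    flexibility_index,
    sample_entropy,
    stationary_distribution,
    trajectory_entropy,
    transition_matrix,
    transition_rate,
)
from chronnect.synthgen import worked_example_sequences, gen_markov_sequence


def random_irreducible_chain(k, rng):
    """Strictly positive row-stochastic matrix (hence irreducible)."""
    P = rng.uniform(0.05, 1.0, size=(k, k))
    return P / P.sum(axis=1, keepdims=True)


class TestTransitionRate:
    @pytest.mark.parametrize(
        "seq,expected",
        [([1, 1, 2, 2, 1], 0.5), ([3, 3, 3, 3], 0.0),
         ([1, 2] * 5, 1.0)],
    )
    def test_examples(self, seq, expected):
        assert transition_rate(np.array(seq)) == pytest.approx(expected)

    def test_too_short(self):
        with pytest.raises(ValueError):
            transition_rate(np.array([1]))


class TestTransitionMatrix:
    def test_worked_example(self):
        tm = transition_matrix(np.array([1, 2, 1, 2, 2]), k=2)
        assert np.allclose(tm, [[0.0, 0.5], [0.25, 0.25]])

    def test_constant_sequence(self):
        tm = transition_matrix(np.array([1, 1, 1]), k=2)
        assert np.allclose(tm, [[1.0, 0.0], [0.0, 0.0]])

    def test_counts_recoverable_and_sum_one(self, rng):
        for _ in range(20):
            seq = rng.integers(1, 5, size=50)
            tm = transition_matrix(seq, k=4)
            assert tm.sum() == pytest.approx(1.0)
            counts = tm * (len(seq) - 1)
            assert np.allclose(counts, np.round(counts))
            # independent counter
            naive = np.zeros((4, 4))
            for a, b in zip(seq[:-1], seq[1:]):
                naive[a - 1, b - 1] += 1
            assert np.allclose(counts, naive)

    def test_reversal_transposes(self, rng):
        seq = rng.integers(1, 4, size=100)
        tm_fwd = transition_matrix(seq, k=3)
        tm_rev = transition_matrix(seq[::-1], k=3)
        assert np.allclose(tm_rev, tm_fwd.T)


class TestFlexibilityIndex:
    def test_pair_series(self):
        modes = np.array([3, 3, 9, 9]).reshape(4, 1, 1)
        assert flexibility_index(modes)[0, 0] == pytest.approx(1 / 3)

    def test_constant_modes_zero(self):
        modes = np.full((5, 3, 3), 7)
        assert not flexibility_index(modes).any()

    def test_zero_label_counts_as_change(self):
        modes = np.array([0, 3, 0, 3]).reshape(4, 1, 1)
        assert flexibility_index(modes)[0, 0] == pytest.approx(1.0)


class TestComodulogram:
    def test_all_delta(self):
        modes = np.ones((4, 3, 3), dtype=int)
        for t in range(4):
            np.fill_diagonal(modes[t], 0)
        com = comodulogram(modes)
        assert com[0, 0] == pytest.approx(1.0)
        assert com.sum() == pytest.approx(1.0)

    def test_equal_split(self):
        labels = np.array([1, 9, 1, 9])
        com = comodulogram(labels)
        assert com[0, 0] == pytest.approx(0.5)
        assert com[0, 1] == pytest.approx(0.5)

    def test_sums_to_one_random(self, rng):
        labels = rng.integers(0, 37, size=500)
        if (labels > 0).any():
            assert comodulogram(labels).sum() == pytest.approx(1.0)

    def test_all_zero_warns(self, caplog):
        com = comodulogram(np.zeros(10, dtype=int))
        assert not com.any()

    def test_invalid_labels(self):
        with pytest.raises(ValueError):
            comodulogram(np.array([40]))


class TestComplexityIndex:
    def test_printed_worked_examples(self):
        seq_alt, seq_const, seq_mixed = worked_example_sequences()
        assert complexity_index(seq_alt, 2) == 4
        assert complexity_index(seq_const, 2) == 2
        assert complexity_index(seq_mixed, 2) == 6

    def test_matches_brute_force_oracle(self, rng):
        def oracle(seq, max_len):
            s = ",".join(str(x) for x in seq) + ","
            words = set()
            tokens = [str(x) for x in seq]
            for length in range(1, max_len + 1):
                for i in range(len(tokens) - length + 1):
                    words.add("|".join(tokens[i : i + length]))
            return len(words)

        for _ in range(20):
            n = int(rng.integers(20, 500))
            k = int(rng.integers(2, 9))
            L = int(rng.integers(1, 8))
            seq = rng.integers(1, k + 1, size=n)
            assert complexity_index(seq, L) == oracle(seq, L)

    def test_empty_and_short(self):
        with pytest.raises(ValueError):
            complexity_index(np.array([]), 2)
        with pytest.raises(ValueError):
            complexity_index(np.array([1, 2]), 5)


class TestCiZscore:
    def test_constant_sequence_guard(self):
        assert ci_zscore(np.ones(50, dtype=int), 2, n_shuffles=20, seed=0) == 0.0

    def test_periodic_below_shuffled(self):
        seq = np.tile([1, 2], 50)
        z = ci_zscore(seq, max_word_len=5, n_shuffles=200, seed=1)
        assert z < 0

    def test_reproducible(self, rng):
        seq = rng.integers(1, 4, size=80)
        a = ci_zscore(seq, 4, n_shuffles=100, seed=7)
        b = ci_zscore(seq, 4, n_shuffles=100, seed=7)
        assert a == b


class TestStationaryDistribution:
    def test_two_state_symmetric(self):
        assert np.allclose(stationary_distribution(np.array([[0.0, 1.0], [1.0, 0.0]])),
                           [0.5, 0.5])
        assert np.allclose(stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]])),
                           [0.5, 0.5])

    def test_matches_power_iteration(self, rng):
        for _ in range(10):
            P = random_irreducible_chain(5, rng)
            mu = stationary_distribution(P)
            v = np.full(5, 0.2)
            for _ in range(10000):
                v = v @ P
            assert np.allclose(mu, v, atol=1e-10)

    def test_reducible_restricts_to_recurrent_class(self):
        P = np.array([[0.5, 0.5, 0.0],
                      [0.0, 0.4, 0.6],
                      [0.0, 0.7, 0.3]])  # state 0 transient
        mu = stationary_distribution(P)
        assert mu[0] == 0.0
        assert mu.sum() == pytest.approx(1.0)


class TestEntropyRate:
    def test_deterministic_cycle_zero(self):
        assert entropy_rate(np.array([[0.0, 1.0], [1.0, 0.0]])) == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_uniform_chain_log2k(self, k):
        P = np.full((k, k), 1.0 / k)
        assert entropy_rate(P) == pytest.approx(np.log2(k))


class TestTrajectoryEntropy:
    def test_deterministic_cycle_zero_matrix(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(trajectory_entropy(P), 0.0, atol=1e-12)

    def test_diagonal_identity(self, rng):
        """H_ii = H(X)/mu_i for random irreducible chains."""
        for _ in range(50):
            k = int(rng.integers(2, 7))
            P = random_irreducible_chain(k, rng)
            H = trajectory_entropy(P)
            mu = stationary_distribution(P)
            hx = entropy_rate(P, mu)
            assert np.allclose(np.diag(H), hx / mu, atol=1e-9)

    def test_a_convention_immaterial(self, rng):
        """H is invariant to the two printed conventions for the matrix A.

        The trajectory-entropy matrix subtracts per-column baselines
        (K - K'), which absorbs exactly the per-column offsets the
        transposed-A variant induces in K.
        """
        for _ in range(10):
            P = random_irreducible_chain(int(rng.integers(2, 6)), rng)
            assert np.allclose(trajectory_entropy(P),
                               trajectory_entropy(P, transposed_a=True), atol=1e-10)

    def test_two_state_closed_form(self):
        """Off-diagonal matches the geometric-path closed form."""
        P = np.array([[0.7, 0.3], [0.4, 0.6]])
        H = trajectory_entropy(P)

        def h_first_passage(p_stay, p_go):
            return (p_stay / p_go) * (-np.log2(p_stay)) - np.log2(p_go)

        assert H[0, 1] == pytest.approx(h_first_passage(0.7, 0.3))
        assert H[1, 0] == pytest.approx(h_first_passage(0.6, 0.4))

    def test_reducible_rejected(self):
        P = np.eye(3)
        with pytest.raises(ValueError):
            trajectory_entropy(P)

    def test_nonnegative(self, rng):
        for _ in range(20):
            P = random_irreducible_chain(4, rng)
            assert (trajectory_entropy(P) >= 0).all()


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(100), m=2, r=0.1) == pytest.approx(0.0)

    def test_matches_naive_oracle(self, rng):
        x = rng.uniform(0, 1, 300)
        r = 0.2 * x.std()

        def naive(x, m, r):
            n = len(x)
            def count(mm):
                c = 0
                # both template lengths range over the same n-m start points
                for i in range(n - m):
                    for j in range(i + 1, n - m):
                        if max(abs(x[i + l] - x[j + l]) for l in range(mm)) < r:
                            c += 1
                return c
            return -np.log(count(m + 1) / count(m))

        assert sample_entropy(x, m=2, r=r) == pytest.approx(naive(x, 2, r), abs=1e-12)

    def test_periodic_below_iid(self, rng):
        t = np.arange(400)
        periodic = np.sin(2 * np.pi * t / 25)
        iid = rng.uniform(-1, 1, 400)
        assert (sample_entropy(periodic, 2, 0.2 * periodic.std())
                < sample_entropy(iid, 2, 0.2 * iid.std()))

    def test_no_matches_inf(self):
        x = np.array([0.0, 100.0, -50.0, 1000.0, 3.0])
        assert sample_entropy(x, m=2, r=1e-9) == np.inf

    def test_too_short(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(3), m=2)


class TestFeatureAssembly:
    def _features(self, k, n, rng):
        seq = gen_markov_sequence(np.full((k, k), 1.0 / k), 120, seed=1)
        modes = rng.integers(0, 37, size=(30, n, n))
        modes = np.maximum(modes, modes.transpose(0, 2, 1))
        strength = rng.uniform(0, 5, 30)
        return compute_chronnectomics(seq, modes, strength, k,
                                      n_shuffles=50, seed=0)

    def test_canonical_length_k8_n64(self, rng):
        feats = self._features(8, 64, rng)
        vec = assemble_features(feats)
        assert len(vec) == 4263

    def test_small_length_k2_n4(self, rng):
        feats = self._features(2, 4, rng)
        vec = assemble_features(feats)
        assert len(vec) == 1 + 4 + 16 + 36 + 1 + 4 + 1

    def test_names_unique_and_stable(self, rng):
        feats = self._features(3, 5, rng)
        v1 = assemble_features(feats)
        v2 = assemble_features(feats)
        assert v1.index.is_unique
        assert list(v1.index) == list(v2.index)

    def test_shape_mismatch_rejected(self, rng):
        feats = self._features(3, 5, rng)
        feats.k = 4
        with pytest.raises(ValueError):
            assemble_features(feats)
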