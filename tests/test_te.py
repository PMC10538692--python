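"""Transfer entropy: plug-in estimator, surrogates, band pairs."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amcascade.te import (
    TeValidationError,
    band_pair_te,
    quantile_symbols,
    surrogate_null,
    transfer_entropy,
)

# ---------------------------------------------------------------------------
# independent oracle: exact TE by enumeration of a joint Markov chain


def exact_te_markov(T, n_sym, L=1):
    """Exact T(X->Y) for a stationary joint Markov chain.

    ``T`` is the transition matrix over pair states z=(x, y), row-stochastic,
    indexed z = x * n_sym + y.  Computed by enumerating the stationary
    distribution and the joint law of (Z_{t-1}, Y_t).
    """
    assert L == 1
    evals, evecs = np.linalg.eig(T.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    nz = T.shape[0]
    # joint P(z_prev, y_next)
    p_zy = np.zeros((nz, n_sym))
    for z in range(nz):
        for znext in range(nz):
            p_zy[z, znext % n_sym] += pi[z] * T[z, znext]

    def H(p):
        p = p[p > 1e-15]
        return float(-(p * np.log2(p)).sum())

    # H(Y_t | Y_{t-1}, X_{t-1}) = H(Z_prev, Y_t) - H(Z_prev)
    h_y_given_zx = H(p_zy.ravel()) - H(pi)
    # marginalize x_prev: P(y_prev, y_next)
    p_yy = np.zeros((n_sym, n_sym))
    for z in range(nz):
        p_yy[z % n_sym] += p_zy[z]
    h_y_given_y = H(p_yy.ravel()) - H(p_yy.sum(axis=1))
    return h_y_given_y - h_y_given_zx


def sample_joint_chain(T, n_sym, n, rng):
    nz = T.shape[0]
    cum = T.cumsum(axis=1)
    z = rng.integers(nz)
    xs = np.empty(n, dtype=np.int64)
    ys = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    for t in range(n):
        z = int(np.searchsorted(cum[z], u[t]))
        xs[t], ys[t] = divmod(z, n_sym)
    return xs.astype(float), ys.astype(float)


def random_markov_chain(n_sym, rng, coupling=2.0):
    nz = n_sym * n_sym
    T = rng.gamma(1.0, 1.0, size=(nz, nz))
    # make y_next prefer x_prev (directed x -> y coupling)
    for z in range(nz):
        x_prev = z // n_sym
        for znext in range(nz):
            if znext % n_sym == x_prev:
                T[z, znext] *= coupling
    return T / T.sum(axis=1, keepdims=True)


class TestTransferEntropy:
    def test_independent_series_near_zero(self, rng):
        x = rng.random(10000)
        y = rng.random(10000)
        assert transfer_entropy(x, y, 1, 2) < 0.01

    def test_deterministic_chain_one_bit(self, rng):
        x = rng.integers(0, 2, 100000).astype(float)
        y = np.roll(x, 1)  # y_t = x_{t-1}
        assert transfer_entropy(x, y, 1, 2) == pytest.approx(1.0, abs=0.02)
        assert transfer_entropy(y, x, 1, 2) == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("n_sym,seed", [(2, 0), (2, 1), (3, 2), (3, 3)])
    def test_matches_exact_enumeration_on_markov_chains(self, n_sym, seed):
        rng = np.random.default_rng(seed)
        T = random_markov_chain(n_sym, rng)
        expected = exact_te_markov(T, n_sym)
        x, y = sample_joint_chain(T, n_sym, 100000, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = transfer_entropy(x, y, 1, n_sym)
        assert est == pytest.approx(expected, abs=0.02)

    def test_coupled_ar_direction_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 5000
            x = np.zeros(n)
            y = np.zeros(n)
            e = rng.standard_normal((2, n))
            for t in range(1, n):
                x[t] = 0.7 * x[t - 1] + e[0, t]
                y[t] = 0.5 * y[t - 1] + 0.5 * x[t - 1] + e[1, t]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hits += transfer_entropy(x, y) > transfer_entropy(y, x)
        assert hits >= 9

    def test_nonnegative_after_clipping(self, rng):
        for _ in range(20):
            te = transfer_entropy(rng.random(300), rng.random(300), 1, 2)
            assert te >= 0.0

    def test_plug_in_bias_decreases_with_n(self):
        raws = []
        for n in (500, 5000, 50000):
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, raw = transfer_entropy(
                        rng.random(n), rng.random(n), 1, 4, return_raw=True
                    )
                vals.append(raw)
            raws.append(np.mean(vals))
        assert raws[0] > raws[1] > raws[2]

    def test_noise_on_source_does_not_create_coupling(self, rng):
        """y independent of x: adding noise to x leaves TE at bias level."""
        clean, noisy = [], []
        for seed in range(10):
            g = np.random.default_rng(seed)
            x = g.standard_normal(5000)
            y = g.standard_normal(5000)
            clean.append(transfer_entropy(x, y))
            noisy.append(transfer_entropy(x + g.standard_normal(5000), y))
        assert abs(np.mean(clean) - np.mean(noisy)) < 0.005

    def test_constant_series_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert transfer_entropy(np.ones(100), np.arange(100.0)) == 0.0

    def test_validation_errors(self, rng):
        with pytest.raises(TeValidationError):
            transfer_entropy(rng.random(10), rng.random(9))
        with pytest.raises(TeValidationError):
            transfer_entropy(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 1)
        bad = rng.random(100)
        bad[0] = np.inf
        with pytest.raises(TeValidationError):
            transfer_entropy(bad, rng.random(100))


class TestQuantileBinning:
    @given(seed=st.integers(0, 200), n_bins=st.sampled_from([2, 3, 4]))
    def test_equal_occupancy(self, seed, n_bins):
        x = np.random.default_rng(seed).standard_normal(400)
        sym = quantile_symbols(x, n_bins)
        counts = np.bincount(sym, minlength=n_bins)
        assert counts.max() - counts.min() <= 1

    def test_monotone_transform_invariance_exact(self, rng):
        x = rng.standard_normal(3000)
        y = rng.standard_normal(3000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = transfer_entropy(x, y, 1, 4)
            trans = transfer_entropy(np.exp(x), y**3, 1, 4)
        assert base == trans  # identical symbols, identical estimate


class TestSurrogates:
    def test_independent_series_within_null(self):
        inside = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = rng.random(4000), rng.random(4000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                te = transfer_entropy(x, y)
                mu, sd = surrogate_null(x, y, seed=seed)
            inside += abs(te - mu) <= 2 * sd
        assert inside >= 17

    def test_deterministic_chain_beats_all_surrogates(self, rng):
        x = rng.integers(0, 2, 5000).astype(float)
        y = np.roll(x, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            te = transfer_entropy(x, y, 1, 2)
            mu, sd = surrogate_null(x, y, n_surrogates=99, seed=0, n_bins=2)
        assert te > mu + 4 * sd

    def test_same_seed_identical_statistics(self, rng):
        x, y = rng.random(2000), rng.random(2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = surrogate_null(x, y, seed=3)
            b = surrogate_null(x, y, seed=3)
        assert a == b

    def test_too_few_surrogates_rejected(self, rng):
        with pytest.raises(TeValidationError):
            surrogate_null(rng.random(100), rng.random(100), n_surrogates=5)


class TestBandPairTe:
    def test_six_results_cover_pairs_and_directions(self, nested_hierarchy):
        results = band_pair_te(nested_hierarchy)
        assert len(results) == 6
        pairs = {(r.pair, r.direction) for r in results}
        assert pairs == {
            (p, d)
            for p in ("prosody_syllable", "prosody_phoneme", "syllable_phoneme")
            for d in ("top_down", "bottom_up")
        }

    def test_direction_labels_follow_band_order(self, nested_hierarchy):
        for r in band_pair_te(nested_hierarchy):
            if r.direction == "top_down":
                assert r.source_band in ("delta", "theta_alpha")
            assert r.te_bits >= 0.0
            assert np.isfinite(r.surrogate_mean_bits)
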