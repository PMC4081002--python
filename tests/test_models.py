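import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logsumexp

from spikebm.models import (
    DynamicBias,
    IndependentModel,
    IsingModel,
    IsingParams,
    RBMModel,
    RBMParams,
    SpikeRaster,
    SRBMModel,
    SRBMParams,
    StimulusModel,
    ising_energy,
    psth_dynamic_bias,
    rbm_free_energy,
    softplus,
    srbm_free_energy,
    stimulus_model_energy,
)
from spikebm.partition import enumerate_states, exact_log_partition

from conftest import random_model, random_rbm, random_srbm


def brute_force_free_energy(x, W, b_h, b_v, J=None):
    """Oracle: -log sum over all hidden configurations of exp(-E_joint)."""
    h = b_h.shape[0]
    terms = []
    for hh in itertools.product((0, 1), repeat=h):
        hh = np.array(hh, dtype=float)
        e = -(b_v @ x + b_h @ hh + hh @ W @ x)
        if J is not None:
            e -= 0.5 * x @ J @ x
        terms.append(-e)
    return -logsumexp(terms)


class TestSpikeRaster:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            SpikeRaster(np.array([[0, 2], [1, 0]]))

    def test_rejects_bad_bin_width(self):
        with pytest.raises(ValueError, match="bin_width"):
            SpikeRaster(np.zeros((2, 3)), bin_width=0.0)

    def test_rejects_label_mismatch(self):
        with pytest.raises(ValueError, match="unit_labels"):
            SpikeRaster(np.zeros((2, 3)), unit_labels=["a"])

    def test_shapes_and_rates(self):
        r = SpikeRaster(np.array([[1, 1, 0, 0], [1, 0, 0, 0]]), 20.0)
        assert (r.n_units, r.n_bins) == (2, 4)
        np.testing.assert_allclose(r.rates(), [0.5, 0.25])
        assert r.population_rate() == 0.75


class TestIsingEnergy:
    def test_all_zero_state(self, rng):
        p = IsingParams(np.zeros((3, 3)), rng.normal(size=3))
        assert ising_energy(np.zeros(3), p) == 0.0

    def test_single_unit(self):
        p = IsingParams(np.zeros((1, 1)), np.array([-2.0]))
        assert ising_energy(np.array([1.0]), p) == 2.0

    def test_two_unit_hand_value(self):
        J = np.array([[0.0, 0.5], [0.5, 0.0]])
        p = IsingParams(J, np.array([-1.0, -1.0]))
        assert ising_energy(np.ones(2), p) == pytest.approx(1.5)

    def test_dimension_mismatch(self):
        p = IsingParams(np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError, match="dimension"):
            ising_energy(np.zeros(3), p)

    def test_params_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            IsingParams(np.array([[0.0, 1.0], [0.0, 0.0]]), np.zeros(2))
        with pytest.raises(ValueError, match="diagonal"):
            IsingParams(np.eye(2), np.zeros(2))


class TestRBMFreeEnergy:
    def test_free_hidden_bit(self):
        p = RBMParams(np.zeros((1, 2)), np.zeros(1), np.zeros(2))
        assert rbm_free_energy(np.array([1.0, 0.0]), p) == pytest.approx(
            -np.log(2)
        )

    def test_decoupled_hidden_units(self, rng):
        b_h, b_v = rng.normal(size=3), rng.normal(size=4)
        p = RBMParams(np.zeros((3, 4)), b_h, b_v)
        x = np.array([1.0, 0.0, 1.0, 1.0])
        expected = -b_v @ x - softplus(b_h).sum()
        assert rbm_free_energy(x, p) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d, h = 4, 3
        m = random_rbm(d, h, rng)
        for x in enumerate_states(d):
            expected = brute_force_free_energy(x, m.W, m.b_h, m.b_v)
            assert m.energy(x) == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestSRBMFreeEnergy:
    def test_hidden_frozen_off_limit(self, rng):
        d = 3
        J = np.array([[0, 0.4, 0], [0.4, 0, -0.2], [0, -0.2, 0]], dtype=float)
        ip = IsingParams(J, rng.normal(size=d))
        p = SRBMParams(ip, RBMParams(np.ones((2, d)), np.full(2, -200.0),
                                     np.zeros(d)))
        m = SRBMModel(p)
        x = np.array([1.0, 1.0, 0.0])
        assert m.energy(x) == pytest.approx(ising_energy(x, ip), abs=1e-12)

    def test_zero_couplings_reduces_to_rbm(self, rng):
        d, h = 4, 2
        W, b_h = rng.normal(size=(h, d)), rng.normal(size=h)
        b_v = rng.normal(size=d)
        srbm = SRBMParams(
            IsingParams(np.zeros((d, d)), b_v),
            RBMParams(W, b_h, np.zeros(d)),
        )
        rbm = RBMParams(W, b_h, b_v)
        for x in enumerate_states(d)[::3]:
            assert srbm_free_energy(x, srbm) == pytest.approx(
                rbm_free_energy(x, rbm)
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_srbm(3, 3, rng)
        for x in enumerate_states(3):
            expected = brute_force_free_energy(x, m.W, m.b_h, m.b_v, m.J)
            assert m.energy(x) == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_nonzero_rbm_visible_bias_rejected(self):
        with pytest.raises(ValueError, match="b_v"):
            SRBMParams(
                IsingParams(np.zeros((2, 2)), np.zeros(2)),
                RBMParams(np.zeros((1, 2)), np.zeros(1), np.ones(2)),
            )


class TestDynamicBias:
    def test_logit_symmetry_point(self):
        db = psth_dynamic_bias(np.full((2, 3), 0.5), 1e-3)
        np.testing.assert_allclose(db.bias, 0.0)

    def test_degenerate_bin_floored(self):
        db = psth_dynamic_bias(np.array([[0.0]]), 1e-3)
        expected = np.log(1e-3) - np.log1p(-1e-3)
        assert db.bias[0, 0] == pytest.approx(expected)
        assert db.bias[0, 0] == pytest.approx(-6.9068, abs=1e-4)

    def test_validation(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            psth_dynamic_bias(np.array([[1.2]]), 1e-3)
        with pytest.raises(ValueError, match="epsilon"):
            psth_dynamic_bias(np.array([[0.5]]), 0.7)

    def test_psth_only_model_reproduces_psth(self, rng):
        # sampling oracle: forward-sampling the PSTH-only model recovers
        # the per-bin firing probabilities
        psth = rng.uniform(0.05, 0.6, size=(3, 40))
        db = psth_dynamic_bias(psth, 1e-4)
        p = expit(db.bias)
        n = 3000
        draws = rng.random((n, 3, 40)) < p
        est = draws.mean(axis=0)
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(est - psth) < 4 * se + 1e-3).all()


class TestStimulusModelEnergy:
    def test_pure_psth_energy(self, rng):
        d = 3
        base = IsingModel(IsingParams(np.zeros((d, d)), np.zeros(d)))
        db = psth_dynamic_bias(rng.uniform(0.1, 0.9, (d, 5)), 1e-3)
        x = np.array([1.0, 0.0, 1.0])
        for t in range(5):
            assert stimulus_model_energy(x, t, base, db) == pytest.approx(
                -db.bias[:, t] @ x
            )

    def test_zero_bias_identity(self, rng):
        m = random_model("ising", 4, 0, rng)
        db = DynamicBias(np.zeros((4, 6)), np.zeros((4, 6)), 1e-3)
        x = np.array([1.0, 1.0, 0.0, 1.0])
        assert stimulus_model_energy(x, 2, m, db) == pytest.approx(m.energy(x))

    def test_two_unit_hand_sum(self):
        J = np.array([[0.0, 0.3], [0.3, 0.0]])
        base = IsingModel(IsingParams(J, np.array([-0.5, 0.2])))
        h = np.array([[0.7], [-0.4]])
        db = DynamicBias(h, expit(h), 1e-3)
        x = np.ones(2)
        expected = -(-0.5 + 0.2 + 0.3) - (0.7 - 0.4)
        assert stimulus_model_energy(x, 0, base, db) == pytest.approx(expected)

    def test_bin_out_of_range(self, rng):
        m = random_model("ising", 2, 0, rng)
        db = DynamicBias(np.zeros((2, 3)), np.zeros((2, 3)), 1e-3)
        stim = StimulusModel(m, db)
        with pytest.raises(IndexError):
            stim.energy(np.ones(2), np.array([5]))


class TestInvariants:
    @pytest.mark.parametrize("kind", ["independent", "ising", "rbm", "srbm"])
    def test_probabilities_normalize(self, kind, rng):
        m = random_model(kind, 6, 3, rng)
        S = enumerate_states(6)
        log_z = exact_log_partition(m)
        assert np.exp(-m.energy(S) - log_z).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["ising", "rbm", "srbm"])
    def test_zero_couplings_give_independent_bernoulli(self, kind, rng):
        d = 5
        b = rng.normal(size=d)
        if kind == "ising":
            m = IsingModel(IsingParams(np.zeros((d, d)), b))
        elif kind == "rbm":
            m = RBMModel(RBMParams(np.zeros((2, d)), rng.normal(size=2), b))
        else:
            m = SRBMModel(
                SRBMParams(
                    IsingParams(np.zeros((d, d)), b),
                    RBMParams(np.zeros((2, d)), rng.normal(size=2),
                              np.zeros(d)),
                )
            )
        S = enumerate_states(d)
        p = np.exp(-m.energy(S) - exact_log_partition(m))
        q = expit(b)
        expected = np.prod(S * q + (1 - S) * (1 - q), axis=1)
        np.testing.assert_allclose(p, expected, rtol=1e-10)

    @pytest.mark.parametrize("kind", ["rbm", "srbm"])
    def test_hidden_permutation_invariance(self, kind, rng):
        m = random_model(kind, 4, 3, rng)
        m2 = m.copy()
        perm = np.array([2, 0, 1])
        m2.W = m.W[perm]
        m2.b_h = m.b_h[perm]
        S = enumerate_states(4)
        np.testing.assert_allclose(m.energy(S), m2.energy(S), rtol=1e-12)

    @pytest.mark.parametrize("kind", ["independent", "ising", "rbm", "srbm"])
    def test_flip_diffs_match_energy(self, kind, rng):
        m = random_model(kind, 5, 3, rng)
        X = (rng.random((20, 5)) < 0.3).astype(float)
        dE = m.flip_diffs(X)
        for i in range(5):
            Xf = X.copy()
            Xf[:, i] = 1 - Xf[:, i]
            np.testing.assert_allclose(
                dE[:, i], m.energy(Xf) - m.energy(X), atol=1e-10
            )

    @pytest.mark.parametrize("kind", ["independent", "ising", "rbm", "srbm"])
    def test_theta_roundtrip(self, kind, rng):
        m = random_model(kind, 4, 2, rng)
        theta = m.get_theta()
        m2 = m.copy()
        m2.set_theta(rng.normal(size=theta.shape))
        m2.set_theta(theta)
        np.testing.assert_array_equal(m2.get_theta(), theta)
        S = enumerate_states(4)
        np.testing.assert_allclose(m.energy(S), m2.energy(S))


@given(st.floats(min_value=-1e6, max_value=1e6))
@settings(max_examples=200, deadline=None)
def test_softplus_stable_and_correct(a):
    v = softplus(np.array([a]))[0]
    assert np.isfinite(v)
    assert v >= max(a, 0.0)
    if abs(a) < 30:
        assert v == pytest.approx(np.log1p(np.exp(a)), rel=1e-12)
    else:
        assert v == pytest.approx(max(a, 0.0), rel=1e-10)


@given(st.integers(min_value=0, max_value=2**6 - 1))
@settings(max_examples=60, deadline=None)
def test_batch_energy_matches_single(idx):
    rng = np.random.default_rng(7)
    m = random_model("srbm", 6, 2, rng)
    x = ((idx >> np.arange(6)) & 1).astype(float)
    batch = m.energy(np.tile(x, (3, 1)))
    assert np.allclose(batch, m.energy(x))
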