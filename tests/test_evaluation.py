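import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom

import spikebm as sb
from spikebm.evaluation import (
    conditional_likelihood_per_cell,
    conditional_spike_probability,
    exact_entropy,
    excess_log_likelihood,
    independent_baseline,
    model_entropy,
    pattern_log_likelihood,
    pattern_scatter,
    synchrony_distribution,
)
from spikebm.models import IndependentModel, IsingModel, IsingParams, SpikeRaster
from spikebm.partition import NormalizedModel, enumerate_states, exact_log_partition

from conftest import random_model


class TestIndependentBaseline:
    def test_fair_coin_entropy(self):
        # every cell fires in exactly half the bins -> -d bits/pattern
        P = np.tile([1, 0], (4, 50))
        r = SpikeRaster(P, 20.0)
        nm = independent_baseline(r)
        assert pattern_log_likelihood(r, nm) == pytest.approx(-4.0)

    def test_silent_cell_floored(self):
        P = np.zeros((3, 100), dtype=int)
        P[0, ::10] = 1
        r = SpikeRaster(P, 20.0)
        nm = independent_baseline(r)
        ll = pattern_log_likelihood(r, nm)
        assert np.isfinite(ll)
        assert expit(nm.model.b_v[1]) == pytest.approx(1.0 / 200)

    def test_matches_zero_coupling_ising_enumeration(self, sparse_raster):
        nm = independent_baseline(sparse_raster)
        d = sparse_raster.n_units
        ising = IsingModel(IsingParams(np.zeros((d, d)), nm.model.b_v))
        nm_ising = NormalizedModel(ising, exact_log_partition(ising), "exact")
        assert pattern_log_likelihood(sparse_raster, nm) == pytest.approx(
            pattern_log_likelihood(sparse_raster, nm_ising), rel=1e-12
        )


class TestExcessLogLikelihood:
    def test_model_equals_baseline_gives_zero(self, sparse_raster):
        nm = independent_baseline(sparse_raster)
        rep = excess_log_likelihood(sparse_raster, nm, nm)
        assert rep.excess_over_independent == 0.0

    def test_invariant_to_duplicating_patterns(self, rng):
        m = random_model("ising", 5, 0, rng)
        data = sb.sample_exact(m, 500, seed=1)
        doubled = SpikeRaster(np.concatenate([data.patterns, data.patterns],
                                             axis=1), data.bin_width)
        nm = sb.normalize_model(m)
        base = independent_baseline(data)
        base2 = independent_baseline(doubled)
        r1 = excess_log_likelihood(data, nm, base)
        r2 = excess_log_likelihood(doubled, nm, base2)
        assert r1.excess_over_independent == pytest.approx(
            r2.excess_over_independent, rel=1e-12
        )

    def test_report_invariant_holds(self, rng):
        m = random_model("ising", 5, 0, rng)
        data = sb.sample_exact(m, 400, seed=2)
        rep = excess_log_likelihood(data, sb.normalize_model(m),
                                    independent_baseline(data))
        delta = rep.log_likelihood_per_pattern - rep.baseline_log_likelihood
        assert rep.excess_over_independent == pytest.approx(
            delta / rep.population_rate_per_bin
        )

    def test_state_space_mismatch(self, rng):
        m5 = sb.normalize_model(random_model("ising", 5, 0, rng))
        m4 = sb.normalize_model(random_model("ising", 4, 0, rng))
        data = sb.sample_exact(m5.model, 50, seed=0)
        with pytest.raises(ValueError, match="state space"):
            excess_log_likelihood(data, m5, m4)


class TestPatternScatter:
    def test_two_unit_hand_computed(self):
        # model: independent, p = (0.5, 0.5); data has known pattern counts
        m = IndependentModel(np.zeros(2))
        nm = NormalizedModel(m, exact_log_partition(m), "exact")
        P = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        diag = pattern_scatter(SpikeRaster(P, 20.0), nm)
        np.testing.assert_allclose(diag.model_prob, 0.25)
        np.testing.assert_allclose(diag.empirical_freq, 0.25)
        np.testing.assert_array_equal(np.sort(diag.active_count), [0, 1, 1, 2])

    def test_envelope_is_central_binomial(self, rng):
        m = random_model("ising", 4, 0, rng)
        nm = sb.normalize_model(m)
        data = sb.sample_exact(m, 2000, seed=3)
        diag = pattern_scatter(data, nm)
        lo = binom.ppf(0.05, 2000, diag.model_prob) / 2000
        hi = binom.ppf(0.95, 2000, diag.model_prob) / 2000
        np.testing.assert_allclose(diag.envelope_low, lo)
        np.testing.assert_allclose(diag.envelope_high, hi)

    def test_independent_model_on_correlated_data(self, rng):
        # correlated generator scored by an independent model: frequent
        # sparse (singleton) patterns sit above the counting-noise envelope
        spec = sb.GeneratorSpec(kind="rbm", n_cells=8, target_rate=0.1,
                                assembly_layout=((0, 8, 2.5),),
                                hidden_bias=-1.5, seed=4)
        truth = sb.make_ground_truth_model(spec)
        data = sb.sample_exact(truth, 20_000, seed=5)
        nm_ind = independent_baseline(data)
        diag = pattern_scatter(data, nm_ind)
        assert diag.fraction_inside_envelope(min_count=10) < 0.85


class TestSynchrony:
    def test_all_zero_raster(self):
        pk = synchrony_distribution(SpikeRaster(np.zeros((4, 30), dtype=int)))
        assert pk[0] == 1.0 and pk.sum() == pytest.approx(1.0)

    def test_binomial_closed_form(self):
        d, p = 10, 0.1
        b = np.log(p / (1 - p))
        m = IndependentModel(np.full(d, b))
        nm = sb.normalize_model(m)
        pk = synchrony_distribution(nm)
        expected = binom.pmf(np.arange(d + 1), d, p)
        np.testing.assert_allclose(pk, expected, rtol=1e-9, atol=1e-12)

    def test_model_vs_empirical_on_model_data(self, rng):
        m = random_model("ising", 8, 0, rng)
        nm = sb.normalize_model(m)
        n = 30_000
        data = sb.sample_exact(m, n, seed=6)
        pk_model = synchrony_distribution(nm)
        pk_emp = synchrony_distribution(data)
        sigma = np.sqrt(pk_model * (1 - pk_model) / n)
        assert (np.abs(pk_emp - pk_model) < 3 * sigma + 5e-4).all()


class TestConditional:
    def test_independent_ignores_context(self, rng):
        b = rng.normal(size=4)
        m = IndependentModel(b)
        for i in range(4):
            ctx = (rng.random(4) < 0.5).astype(float)
            ctx[i] = np.nan
            assert conditional_spike_probability(ctx, m) == pytest.approx(
                expit(b[i])
            )

    def test_equals_exact_joint_ratio(self, rng):
        m = random_model("srbm", 5, 2, rng)
        lz = exact_log_partition(m)
        for i in range(5):
            x = (rng.random(5) < 0.4).astype(float)
            x0, x1 = x.copy(), x.copy()
            x0[i], x1[i] = 0.0, 1.0
            p0 = np.exp(-m.energy(x0) - lz)
            p1 = np.exp(-m.energy(x1) - lz)
            p = conditional_spike_probability(
                np.where(np.arange(5) == i, np.nan, x), m
            )
            assert p == pytest.approx(p1 / (p0 + p1), rel=1e-10)

    def test_completions_sum_to_one(self, rng):
        m = random_model("rbm", 4, 2, rng)
        x = np.array([1.0, np.nan, 0.0, 1.0])
        p1 = conditional_spike_probability(x, m)
        # flipping the roles: P(x_i=0 | rest) must be the complement
        assert p1 >= 0 and p1 <= 1

    def test_rejects_multiple_masks(self, rng):
        m = random_model("ising", 3, 0, rng)
        with pytest.raises(ValueError, match="masked"):
            conditional_spike_probability(np.array([np.nan, np.nan, 1.0]), m)


class TestConditionalLikelihoodPerCell:
    def test_independent_with_true_rates_is_zero(self, sparse_raster):
        nm = independent_baseline(sparse_raster)
        rates = expit(nm.model.b_v)
        gains = conditional_likelihood_per_cell(sparse_raster, nm.model, rates)
        np.testing.assert_allclose(gains, 0.0, atol=1e-12)

    def test_invariant_to_relabeling_other_cells(self, rng):
        m = random_model("ising", 5, 0, rng)
        data = sb.sample_exact(m, 300, seed=8)
        rates = np.clip(data.rates(), 1e-3, 1 - 1e-3)
        g1 = conditional_likelihood_per_cell(data, m, rates, cells=[0])
        # permute the other cells consistently in both data and model
        perm = np.array([0, 3, 4, 2, 1])
        m2 = IsingModel(IsingParams(m.J[np.ix_(perm, perm)], m.b_v[perm]))
        data2 = SpikeRaster(data.patterns[perm], data.bin_width)
        g2 = conditional_likelihood_per_cell(data2, m2, rates[perm], cells=[0])
        assert g1[0] == pytest.approx(g2[0], rel=1e-10)

    def test_positive_for_coupled_generator(self, rng):
        spec = sb.GeneratorSpec(kind="ising", n_cells=6, target_rate=0.15,
                                assembly_layout=((0, 6, 1.2),), seed=9)
        truth = sb.make_ground_truth_model(spec)
        data = sb.sample_exact(truth, 20_000, seed=10)
        rates = data.rates()
        gains = conditional_likelihood_per_cell(data, truth, rates)
        assert (gains > 0).all()


class TestEntropy:
    def test_uniform_model_exactly_one_bit(self):
        d = 6
        m = IndependentModel(np.zeros(d))
        nm = sb.normalize_model(m)
        h = model_entropy(nm, None, n_chains=50, n_sweeps=1, seed=0)
        assert h == pytest.approx(1.0, abs=1e-12)

    def test_matches_exact_entropy_small_model(self, rng):
        m = random_model("ising", 8, 0, rng)
        nm = sb.normalize_model(m)
        data = sb.sample_exact(m, 2000, seed=11)
        h = model_entropy(nm, data, n_chains=6000, n_sweeps=40, seed=1)
        h_exact = exact_entropy(nm) / 8
        assert h == pytest.approx(h_exact, abs=0.01)

    def test_requires_scalar_log_z(self, rng):
        m = random_model("ising", 3, 0, rng)
        nm = NormalizedModel(m, np.array([1.0, 2.0]), "exact")
        with pytest.raises(ValueError, match="log Z"):
            model_entropy(nm, None, n_chains=10, n_sweeps=1)
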