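"""Likelihood-based model comparison and diagnostic statistics.

Reported quantities are in bits (log base 2); all internal math is in nats.
The central quantity is the excess log-likelihood over the independent
firing-rate model, normalized by the population firing rate per time bin to
give bits/spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import binom

from .models import EnergyModel, IndependentModel, SpikeRaster
from .partition import (
    LN2,
    NormalizedModel,
    enumerate_states,
    gibbs_sweep,
    sample_gibbs,
)

__all__ = [
    "LikelihoodReport",
    "PatternDiagnostics",
    "independent_baseline",
    "pattern_log_likelihood",
    "excess_log_likelihood",
    "pattern_scatter",
    "synchrony_distribution",
    "conditional_spike_probability",
    "conditional_likelihood_per_cell",
    "model_entropy",
]


@dataclass
class LikelihoodReport:
    """Normalized held-out likelihood of a model against a baseline."""

    log_likelihood_per_pattern: float       # bits/pattern, model
    baseline_log_likelihood: float          # bits/pattern, baseline
    excess_over_independent: float          # bits/spike
    population_rate_per_bin: float          # spikes/bin
    n_patterns: int
    bin_width: float                        # ms
    model_ref: str = ""
    baseline_ref: str = ""
    excess_over_psth: float | None = None

    @property
    def excess_bits_per_second(self) -> float:
        """Same gain expressed per unit time instead of per spike."""
        delta = self.log_likelihood_per_pattern - self.baseline_log_likelihood
        return delta / (self.bin_width / 1000.0)

    def to_dict(self) -> dict:
        return {
            "log_likelihood_per_pattern_bits": self.log_likelihood_per_pattern,
            "baseline_log_likelihood_bits": self.baseline_log_likelihood,
            "excess_over_independent_bits_per_spike":
                self.excess_over_independent,
            "excess_bits_per_second": self.excess_bits_per_second,
            "population_rate_per_bin": self.population_rate_per_bin,
            "n_patterns": self.n_patterns,
            "bin_width_ms": self.bin_width,
            "model": self.model_ref,
            "baseline": self.baseline_ref,
            "excess_over_psth_bits_per_spike": self.excess_over_psth,
        }


@dataclass
class PatternDiagnostics:
    """Per-pattern scatter data and synchrony distributions."""

    patterns: np.ndarray            # (n_distinct, d) binary
    counts: np.ndarray              # observed occurrences
    empirical_freq: np.ndarray
    model_prob: np.ndarray
    active_count: np.ndarray        # spikes per pattern
    envelope_low: np.ndarray        # 5% bound on frequency given model prob
    envelope_high: np.ndarray       # 95% bound
    pk_empirical: np.ndarray        # P(K), K = 0..d
    pk_model: np.ndarray
    n_test: int = 0

    def __post_init__(self) -> None:
        for v in (self.pk_empirical, self.pk_model):
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError("P(K) must sum to 1")

    def fraction_inside_envelope(self, min_count: int = 10) -> float:
        """Fraction of patterns seen >= min_count times whose empirical
        frequency falls inside the counting-noise envelope."""
        sel = self.counts >= min_count
        if not sel.any():
            return float("nan")
        inside = (
            (self.empirical_freq[sel] >= self.envelope_low[sel])
            & (self.empirical_freq[sel] <= self.envelope_high[sel])
        )
        return float(inside.mean())


# ---------------------------------------------------------------------------
# baselines and likelihoods
# ---------------------------------------------------------------------------


def independent_baseline(data: SpikeRaster) -> NormalizedModel:
    """Independent Bernoulli model with per-cell rates from the data.

    Rates are floored at 1/(2 T) (and capped at 1 - 1/(2 T)) so silent or
    saturated cells keep a finite likelihood; log Z is closed-form.
    """
    if data.n_bins == 0:
        raise ValueError("empty raster")
    floor = 1.0 / (2.0 * data.n_bins)
    p = np.clip(data.rates(), floor, 1.0 - floor)
    b = np.log(p) - np.log1p(-p)
    model = IndependentModel(b)
    log_z = float(np.sum(np.log1p(np.exp(-np.abs(b))) + np.maximum(b, 0)))
    return NormalizedModel(model, log_z, "exact",
                           {"n_states": 1 << model.n_units})


def pattern_log_likelihood(
    data: SpikeRaster | np.ndarray,
    model: NormalizedModel,
    bins: np.ndarray | None = None,
) -> float:
    """Mean log2-likelihood per pattern (bits) under a normalized model."""
    X = data.X if isinstance(data, SpikeRaster) else np.atleast_2d(
        np.asarray(data, dtype=float)
    )
    return float(model.log_prob(X, bins).mean() / LN2)


def excess_log_likelihood(
    data: SpikeRaster,
    model: NormalizedModel,
    baseline: NormalizedModel,
    bins: np.ndarray | None = None,
    baseline_bins: np.ndarray | None = None,
) -> LikelihoodReport:
    """Held-out likelihood gain over a baseline in bits/spike.

    The gain (bits/pattern) is divided by the population firing rate per bin
    (spikes/bin), so the report is invariant to duplicating the test set.
    May be negative: a fitted model can lose to the baseline on held-out
    data.
    """
    if model.model.n_units != baseline.model.n_units:
        raise ValueError("model and baseline act on different state spaces")
    ll_model = pattern_log_likelihood(data, model, bins)
    ll_base = pattern_log_likelihood(data, baseline, baseline_bins)
    pop_rate = data.population_rate()
    excess = (ll_model - ll_base) / pop_rate if pop_rate > 0 else float("nan")
    return LikelihoodReport(
        log_likelihood_per_pattern=ll_model,
        baseline_log_likelihood=ll_base,
        excess_over_independent=excess,
        population_rate_per_bin=pop_rate,
        n_patterns=data.n_bins,
        bin_width=data.bin_width,
        model_ref=model.model.kind,
        baseline_ref=baseline.model.kind,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def pattern_scatter(
    data: SpikeRaster,
    model: NormalizedModel,
) -> PatternDiagnostics:
    """Empirical vs model probability for every distinct observed pattern,
    with a central-90% binomial counting-noise envelope around the identity.
    Time-invariant models only.
    """
    X = data.X
    n = X.shape[0]
    U, counts = np.unique(X, axis=0, return_counts=True)
    logp = model.log_prob(U)
    p_model = np.exp(logp)
    lo = binom.ppf(0.05, n, p_model) / n
    hi = binom.ppf(0.95, n, p_model) / n
    return PatternDiagnostics(
        patterns=U,
        counts=counts,
        empirical_freq=counts / n,
        model_prob=p_model,
        active_count=U.sum(axis=1).astype(int),
        envelope_low=lo,
        envelope_high=hi,
        pk_empirical=synchrony_distribution(data),
        pk_model=synchrony_distribution(model),
        n_test=n,
    )


def synchrony_distribution(
    x: SpikeRaster | NormalizedModel,
    n_samples: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """P(K): probability that exactly K units are active in one bin.

    Empirical histogram for rasters; for normalized models, an exact sum
    over states grouped by active count when d <= 20, Monte-Carlo via Gibbs
    sampling otherwise.  Returns a vector of length d + 1.
    """
    if isinstance(x, SpikeRaster):
        K = x.patterns.sum(axis=0)
        pk = np.bincount(K, minlength=x.n_units + 1).astype(float)
        return pk / pk.sum()
    model = x.model
    d = model.n_units
    if d <= 20:
        pk = np.zeros(d + 1)
        from .partition import _state_chunks

        parts = [[] for _ in range(d + 1)]
        for S in _state_chunks(d):
            neg_e = -model.energy(S)
            k = S.sum(axis=1).astype(int)
            for kk in range(d + 1):
                sel = k == kk
                if sel.any():
                    parts[kk].append(logsumexp(neg_e[sel]))
        log_pk = np.array(
            [logsumexp(p) if p else -np.inf for p in parts]
        )
        log_pk -= logsumexp(log_pk)
        return np.exp(log_pk)
    rng = np.random.default_rng(seed)
    S = sample_gibbs(model, n_samples, rng, burn_in=200, thin=2)
    K = S.sum(axis=1).astype(int)
    pk = np.bincount(K, minlength=d + 1).astype(float)
    return pk / pk.sum()


def conditional_spike_probability(
    x_context: np.ndarray,
    model: EnergyModel,
    masked: int | None = None,
    bins: np.ndarray | None = None,
) -> np.ndarray:
    """p(x_i = 1 | all other units) for the single masked element.

    ``masked`` gives the index explicitly, or exactly one entry of
    ``x_context`` may be NaN.  Needs no partition function: the two
    completions normalize in closed form,
    p = 1 / (1 + exp(E(x1) - E(x0))).
    """
    X = np.atleast_2d(np.asarray(x_context, dtype=float)).copy()
    if masked is None:
        nan_cols = np.unique(np.nonzero(np.isnan(X))[1])
        if nan_cols.size != 1 or np.isnan(X[:, nan_cols[0]]).sum() != X.shape[0]:
            raise ValueError("exactly one element/column must be masked")
        masked = int(nan_cols[0])
    if np.isnan(np.delete(X, masked, axis=1)).any():
        raise ValueError("more than one masked element")
    X[:, masked] = 0.0
    p = expit(model.cond_logit(X, masked, bins))
    return p[0] if np.asarray(x_context).ndim == 1 else p


def conditional_likelihood_per_cell(
    data: SpikeRaster,
    model: EnergyModel,
    baseline_rates: np.ndarray,
    bins: np.ndarray | None = None,
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell likelihood gain (bits/s) of single-cell predictions
    conditioned on the rest of the network state.

    For each retained cell and each bin, compares log2 p_model(x_i | rest)
    against the rate-only Bernoulli log2 p(x_i); the mean gain per bin is
    divided by the bin width in seconds.
    """
    X = data.X
    rates = np.clip(np.asarray(baseline_rates, dtype=float), 1e-12, 1 - 1e-12)
    cells = np.arange(data.n_units) if cells is None else np.asarray(cells)
    gains = np.empty(len(cells))
    seconds = data.bin_width / 1000.0
    for k, i in enumerate(cells):
        p = expit(model.cond_logit(X, i, bins))
        xi = X[:, i]
        ll_model = xi * np.log2(p) + (1 - xi) * np.log2(1 - p)
        ll_rate = xi * np.log2(rates[i]) + (1 - xi) * np.log2(1 - rates[i])
        gains[k] = (ll_model - ll_rate).mean() / seconds
    return gains


def model_entropy(
    model: NormalizedModel,
    init_data: SpikeRaster | np.ndarray | None = None,
    n_chains: int = 100_000,
    n_sweeps: int = 2000,
    seed: int = 0,
    n_frames: int = 1,
) -> float:
    """Entropy H = <E> + log Z in bits per unit per frame.

    <E> is estimated from ``n_chains`` Gibbs chains initialized at patterns
    resampled from ``init_data`` (uniform random states if None) and run for
    ``n_sweeps`` full sweeps.  For spatiotemporal models pass the number of
    concatenated frames so the result is per unit per frame.
    """
    if np.ndim(model.log_z) != 0:
        raise ValueError("model_entropy expects a single global log Z")
    m = model.model
    d = m.n_units
    rng = np.random.default_rng(seed)
    if init_data is None:
        X = (rng.random((n_chains, d)) < 0.5).astype(float)
    else:
        D = init_data.X if isinstance(init_data, SpikeRaster) else np.asarray(
            init_data, dtype=float
        )
        idx = rng.integers(0, D.shape[0], size=n_chains)
        X = D[idx].copy()
    for _ in range(n_sweeps):
        gibbs_sweep(X, m, rng)
    mean_e = float(m.energy(X).mean())
    h_nats = mean_e + float(model.log_z)
    units = d // n_frames
    return h_nats / LN2 / units / n_frames


def exact_entropy(model: NormalizedModel) -> float:
    """-sum p log2 p by enumeration (d <= 20); in bits per state, total."""
    m = model.model
    if m.n_units > 20:
        raise ValueError("exact_entropy is limited to 20 units")
    S = enumerate_states(m.n_units)
    logp = -m.energy(S) - float(model.log_z)
    p = np.exp(logp)
    return float(-(p * logp).sum() / LN2)
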