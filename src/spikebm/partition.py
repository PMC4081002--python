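"""Model normalization: exact state enumeration, Gibbs sampling, and
annealed importance sampling (AIS) with a chain-length convergence ladder.

log Z is handled in nats internally; conversion to bits happens only at
reporting boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .models import DynamicBias, EnergyModel, StimulusModel

__all__ = [
    "AISConfig",
    "NormalizedModel",
    "enumerate_states",
    "exact_log_partition",
    "exact_probabilities",
    "gibbs_sweep",
    "gibbs_step",
    "sample_gibbs",
    "ais_log_partition",
    "psth_partition_functions",
    "normalize_model",
    "LN2",
    "EXACT_MAX_UNITS",
]

LN2 = float(np.log(2.0))
EXACT_MAX_UNITS = 25
_ENUM_CHUNK = 1 << 16


@dataclass
class AISConfig:
    """Settings for annealed importance sampling.

    ``n_steps_schedule`` is the ladder of annealing-chain lengths used for
    convergence monitoring; the estimate at the longest rung is reported.
    Convergence is declared when the last two rungs agree within
    ``convergence_tol_bits`` bits of log Z.
    """

    n_samples: int = 500
    n_steps_schedule: tuple[int, ...] = (100, 1000, 10000)
    seed: int = 0
    convergence_tol_bits: float = 0.02
    schedule: str = "linear"  # or "geometric"
    beta_schedule: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        steps = tuple(int(s) for s in self.n_steps_schedule)
        if not steps or any(s <= 0 for s in steps):
            raise ValueError("n_steps_schedule must contain positive lengths")
        self.n_steps_schedule = tuple(sorted(steps))
        if self.beta_schedule is not None:
            b = np.asarray(self.beta_schedule, dtype=float)
            if b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) < 0):
                raise ValueError(
                    "beta_schedule must be nondecreasing from 0 to 1"
                )
            self.beta_schedule = b

    def betas(self, n_steps: int) -> np.ndarray:
        if self.beta_schedule is not None:
            return self.beta_schedule
        if self.schedule == "linear":
            return np.linspace(0.0, 1.0, n_steps + 1)
        if self.schedule == "geometric":
            # dense near beta=0 where the distribution changes fastest
            return np.concatenate(
                [[0.0], np.geomspace(1.0 / n_steps, 1.0, n_steps)]
            )
        raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class NormalizedModel:
    """A model together with its (estimated) log partition function."""

    model: EnergyModel
    log_z: float | np.ndarray  # nats; vector over segment bins for PSTH models
    method: str                # "exact" | "ais"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("exact", "ais"):
            raise ValueError("method must be 'exact' or 'ais'")
        if self.method == "exact" and self.diagnostics:
            # exact normalization is deterministic; keep the contract visible
            extra = set(self.diagnostics) - {"n_states"}
            if extra:
                raise ValueError(
                    f"exact normalization carries no chain diagnostics: {extra}"
                )

    @property
    def log_z_bits(self):
        return self.log_z / LN2

    def log_prob(self, x, bins=None) -> np.ndarray:
        """log p(x) in nats; for PSTH models ``bins`` selects log Z_t."""
        E = self.model.energy(x, bins)
        if np.ndim(self.log_z) == 0:
            return -E - self.log_z
        if bins is None:
            raise ValueError("per-bin log Z requires bin indices")
        return -E - np.asarray(self.log_z)[np.asarray(bins, dtype=int)]


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------


def enumerate_states(d: int, dtype=float) -> np.ndarray:
    """All 2^d binary states as a (2^d, d) matrix (unit 0 flips fastest)."""
    if d > EXACT_MAX_UNITS:
        raise ValueError(f"refusing to enumerate 2^{d} states")
    idx = np.arange(1 << d, dtype=np.int64)
    return ((idx[:, None] >> np.arange(d)) & 1).astype(dtype)


def _state_chunks(d: int):
    n = 1 << d
    cols = np.arange(d)
    for lo in range(0, n, _ENUM_CHUNK):
        idx = np.arange(lo, min(lo + _ENUM_CHUNK, n), dtype=np.int64)
        yield ((idx[:, None] >> cols) & 1).astype(float)


def exact_log_partition(model: EnergyModel, bins: np.ndarray | None = None) -> float:
    """log Z by summing exp(-E) over all 2^d states.

    Guarded at d <= 25; larger models must use :func:`ais_log_partition`.
    """
    d = model.n_units
    if d > EXACT_MAX_UNITS:
        raise ValueError(
            f"{d} units exceeds the exact-enumeration guard "
            f"({EXACT_MAX_UNITS}); use ais_log_partition instead"
        )
    parts = [
        logsumexp(-model.energy(S, bins)) for S in _state_chunks(d)
    ]
    return float(logsumexp(parts))


def exact_probabilities(model: EnergyModel, bins=None) -> np.ndarray:
    """Exact probability of every state in enumeration order (small d only)."""
    d = model.n_units
    if d > 20:
        raise ValueError("exact_probabilities is limited to d <= 20")
    S = enumerate_states(d)
    logp = -model.energy(S, bins)
    logp -= logsumexp(logp)
    return np.exp(logp)


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------


def gibbs_sweep(
    X: np.ndarray,
    model: EnergyModel,
    rng: np.random.Generator,
    beta: float = 1.0,
    bins: np.ndarray | None = None,
    order: np.ndarray | None = None,
) -> np.ndarray:
    """One full in-place sweep: every unit resampled from its exact
    conditional given all others (free-energy conditionals for RBM/sRBM).

    ``beta`` tempers the energy (AIS intermediate distributions).  Rows of
    ``X`` are independent chains updated in parallel.
    """
    n = X.shape[0]
    if order is None:
        order = np.arange(model.n_units)
    for i in order:
        logit = beta * model.cond_logit(X, i, bins)
        X[:, i] = rng.random(n) < expit(logit)
    return X


def gibbs_step(
    x: np.ndarray,
    model: EnergyModel,
    rng: np.random.Generator,
    bins: np.ndarray | None = None,
) -> np.ndarray:
    """One sweep over a single state (convenience wrapper; returns a copy)."""
    X = np.atleast_2d(np.asarray(x, dtype=float)).copy()
    gibbs_sweep(X, model, rng, bins=bins)
    return X[0] if np.asarray(x).ndim == 1 else X


def sample_gibbs(
    model: EnergyModel,
    n_samples: int,
    rng: np.random.Generator,
    burn_in: int = 1000,
    thin: int = 10,
    n_chains: int | None = None,
    init: np.ndarray | None = None,
    bins: np.ndarray | None = None,
) -> np.ndarray:
    """Gibbs-sample ``n_samples`` states (rows) after burn-in, thinned."""
    d = model.n_units
    if n_chains is None:
        n_chains = min(n_samples, 256)
    if init is None:
        X = (rng.random((n_chains, d)) < 0.5).astype(float)
    else:
        X = np.asarray(init, dtype=float).copy()
        n_chains = X.shape[0]
    for _ in range(burn_in):
        gibbs_sweep(X, model, rng, bins=bins)
    out = np.empty((n_samples, d))
    filled = 0
    while filled < n_samples:
        for _ in range(thin):
            gibbs_sweep(X, model, rng, bins=bins)
        take = min(n_chains, n_samples - filled)
        out[filled:filled + take] = X[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# annealed importance sampling
# ---------------------------------------------------------------------------


def _ais_single_run(
    model: EnergyModel, n_steps: int, cfg: AISConfig,
    rng: np.random.Generator,
) -> tuple[float, dict]:
    """One AIS estimate: n_samples chains annealed over n_steps temperatures.

    Base distribution is uniform over {0,1}^d (log Z_base = d log 2); the
    k-th intermediate distribution is proportional to exp(-beta_k E(x)).
    """
    d = model.n_units
    betas = cfg.betas(n_steps)
    m = cfg.n_samples
    X = (rng.random((m, d)) < 0.5).astype(float)
    log_w = np.zeros(m)
    for k in range(1, len(betas)):
        E = model.energy(X)
        log_w -= (betas[k] - betas[k - 1]) * E
        order = rng.permutation(d)
        gibbs_sweep(X, model, rng, beta=betas[k], order=order)
    log_z = d * LN2 + logsumexp(log_w) - np.log(m)
    # effective sample size of the importance weights
    ess = float(np.exp(2 * logsumexp(log_w) - logsumexp(2 * log_w)))
    return float(log_z), {"ess": ess, "log_w_std": float(np.std(log_w))}


def ais_log_partition(model: EnergyModel, cfg: AISConfig) -> NormalizedModel:
    """Estimate log Z by AIS over the chain-length ladder in ``cfg``.

    Returns the estimate at the longest rung; ``diagnostics`` records the
    per-rung estimates and importance-weight ESS.  Non-convergence (last two
    rungs differing by more than the tolerance, in bits) produces a warning
    and ``converged=False``, never an exception.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rungs = []
    for n_steps, child in zip(
        cfg.n_steps_schedule, ss.spawn(len(cfg.n_steps_schedule))
    ):
        rng = np.random.default_rng(child)
        log_z, diag = _ais_single_run(model, n_steps, cfg, rng)
        rungs.append({"n_steps": n_steps, "log_z": log_z, **diag})
    estimates_bits = np.array([r["log_z"] for r in rungs]) / LN2
    if len(estimates_bits) >= 2:
        converged = bool(
            abs(estimates_bits[-1] - estimates_bits[-2])
            <= cfg.convergence_tol_bits
        )
    else:
        converged = True
    if not converged:
        warnings.warn(
            "AIS ladder did not stabilize: last two rungs differ by "
            f"{abs(estimates_bits[-1] - estimates_bits[-2]):.4f} bits "
            f"(tolerance {cfg.convergence_tol_bits})",
            stacklevel=2,
        )
    return NormalizedModel(
        model=model,
        log_z=rungs[-1]["log_z"],
        method="ais",
        diagnostics={
            "rungs": rungs,
            "converged": converged,
            "seed": cfg.seed,
            "n_samples": cfg.n_samples,
        },
    )


# ---------------------------------------------------------------------------
# PSTH (per-bin) partition functions
# ---------------------------------------------------------------------------


def psth_partition_functions(
    model: EnergyModel, db: DynamicBias | None = None
) -> np.ndarray:
    """One exact log Z per stimulus-segment bin, dynamic bias folded in.

    ``model`` may be a :class:`StimulusModel` (``db`` taken from it) or a
    base model paired with an explicit ``db``.  Limited to d <= 20.
    """
    if isinstance(model, StimulusModel):
        base, db = model.base, model.dynamic_bias
    else:
        base = model
        if db is None:
            raise ValueError("db is required for a bare base model")
    d = base.n_units
    if d > 20:
        raise ValueError(
            "per-bin exact normalization is limited to 20 units"
        )
    T = db.n_segment_bins
    parts = []
    for S in _state_chunks(d):
        neg_e = -base.energy(S)                    # (m,)
        proj = S @ db.bias                         # (m, T)
        parts.append(logsumexp(neg_e[:, None] + proj, axis=0))
    return logsumexp(np.stack(parts, axis=0), axis=0) if len(parts) > 1 \
        else parts[0]


def normalize_model(
    model: EnergyModel,
    method: str = "auto",
    ais_config: AISConfig | None = None,
    exact_max_units: int = 20,
) -> NormalizedModel:
    """Normalize by exact enumeration when feasible, AIS otherwise."""
    if isinstance(model, StimulusModel):
        log_z = psth_partition_functions(model)
        return NormalizedModel(model, log_z, "exact",
                               {"n_states": 1 << model.n_units})
    if method == "auto":
        method = "exact" if model.n_units <= exact_max_units else "ais"
    if method == "exact":
        return NormalizedModel(
            model, exact_log_partition(model), "exact",
            {"n_states": 1 << model.n_units},
        )
    if method == "ais":
        return ais_log_partition(model, ais_config or AISConfig())
    raise ValueError(f"unknown normalization method {method!r}")
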