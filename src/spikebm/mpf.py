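"""Minimum Probability Flow estimation with single-bit-flip connectivity.

The objective measures the flow of probability out of observed states into
their single-bit-flip neighbours,

    K(theta) = (1/N) sum_{x in D} sum_{i} exp((E(x) - E(flip_i x)) / 2)
               + lambda * sum |theta_couplings|,

and is minimized with L-BFGS using analytic gradients.  The L1 penalty
applies to coupling/weight entries only (never biases) and is smoothed as
sqrt(theta^2 + eps^2) so a plain quasi-Newton driver applies; couplings
below a hard threshold are zeroed after optimization when lambda > 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .models import (
    EnergyModel,
    IndependentModel,
    IsingModel,
    IsingParams,
    RBMModel,
    RBMParams,
    SRBMModel,
    SRBMParams,
    SpikeRaster,
    StimulusModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MPFConfig",
    "FitResult",
    "bit_flip_neighbors",
    "mpf_objective",
    "fit_mpf",
    "cross_validate_lambda",
    "initial_model",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (0.0, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1)


@dataclass
class MPFConfig:
    """Estimation settings.

    ``lambda_l1`` is the sparseness penalty on coupling parameters;
    ``lambda_grid`` the candidate set for cross-validation (ascending).
    """

    lambda_l1: float = 0.0
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    max_iterations: int = 1000
    gradient_tolerance: float = 1e-7
    seed: int = 0
    folds: int = 4
    l1_epsilon: float = 1e-8
    exp_clip: float = 30.0
    zero_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be nonnegative")
        grid = tuple(float(v) for v in self.lambda_grid)
        if any(v < 0 for v in grid) or list(grid) != sorted(grid):
            raise ValueError("lambda_grid must be nonnegative and ascending")
        self.lambda_grid = grid
        if self.max_iterations <= 0 or self.folds <= 0:
            raise ValueError("max_iterations and folds must be positive")


@dataclass
class FitResult:
    """Outcome of an MPF fit."""

    params: EnergyModel
    objective_trace: np.ndarray
    lambda_selected: float
    cv_table: dict | None
    seed: int
    converged: bool
    n_iterations: int = 0
    message: str = ""


def bit_flip_neighbors(x: np.ndarray) -> np.ndarray:
    """All d states at Hamming distance 1 from ``x``, as rows."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a single state vector")
    d = x.shape[0]
    return np.abs(np.tile(x, (d, 1)) - np.eye(d))


def _collapse(X: np.ndarray, bins: np.ndarray | None):
    """Unique data rows with multiplicities (joint with bin index if given)."""
    if bins is None:
        U, w = np.unique(X, axis=0, return_counts=True)
        return U, None, w.astype(float)
    key = np.column_stack([X, np.asarray(bins, dtype=float)])
    U, w = np.unique(key, axis=0, return_counts=True)
    return U[:, :-1], U[:, -1].astype(int), w.astype(float)


def _flow_matrix(
    model: EnergyModel, X, bins, cfg: MPFConfig
) -> np.ndarray:
    """exp(-dE/2) per (pattern, flip), exponent clipped at cfg.exp_clip."""
    dE = model.flip_diffs(X, bins)
    if not np.isfinite(dE).all():
        raise FloatingPointError(
            "non-finite energy difference during MPF evaluation; "
            f"theta snapshot: {model.get_theta()!r}"
        )
    expo = -0.5 * dE
    if np.any(expo > cfg.exp_clip):
        warnings.warn(
            "MPF exponent clipped; large flows indicate divergence",
            stacklevel=3,
        )
        expo = np.minimum(expo, cfg.exp_clip)
    return np.exp(expo)


def _objective_and_grad(
    model: EnergyModel,
    X: np.ndarray,
    bins: np.ndarray | None,
    weights: np.ndarray,
    cfg: MPFConfig,
) -> tuple[float, np.ndarray]:
    N = weights.sum()
    G = _flow_matrix(model, X, bins, cfg)
    K = float((weights * G.sum(axis=1)).sum() / N)
    C = (weights[:, None] / N) * G
    grad = model.mpf_flow_grad(X, C)
    lam = cfg.lambda_l1
    if lam > 0:
        mask = model.penalty_mask()
        theta = model.get_theta()
        smooth = np.sqrt(theta[mask] ** 2 + cfg.l1_epsilon**2)
        K += lam * float(smooth.sum())
        pen_grad = np.zeros_like(theta)
        pen_grad[mask] = lam * theta[mask] / smooth
        grad = grad + pen_grad
    return K, grad


def mpf_objective(
    data: SpikeRaster | np.ndarray,
    model: EnergyModel,
    cfg: MPFConfig | None = None,
    bins: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Penalized MPF objective K and its analytic gradient.

    ``data`` may be a :class:`SpikeRaster` or an (n, d) pattern matrix;
    ``weights`` are optional pattern multiplicities.
    """
    cfg = cfg or MPFConfig()
    X = data.X if isinstance(data, SpikeRaster) else np.atleast_2d(
        np.asarray(data, dtype=float)
    )
    if X.shape[0] == 0:
        raise ValueError("MPF requires nonempty data")
    if X.shape[1] != model.n_units:
        raise ValueError(
            f"data dimension {X.shape[1]} != model dimension {model.n_units}"
        )
    w = np.ones(X.shape[0]) if weights is None else np.asarray(
        weights, dtype=float
    )
    return _objective_and_grad(model, X, bins, w, cfg)


def fit_mpf(
    data: SpikeRaster | np.ndarray,
    init: EnergyModel,
    cfg: MPFConfig | None = None,
    bins: np.ndarray | None = None,
) -> FitResult:
    """Minimize the penalized MPF objective with L-BFGS.

    Deterministic given (data, init, cfg).  Non-convergence within
    ``cfg.max_iterations`` flags the result instead of raising.
    """
    cfg = cfg or MPFConfig()
    X = data.X if isinstance(data, SpikeRaster) else np.atleast_2d(
        np.asarray(data, dtype=float)
    )
    if X.shape[0] == 0:
        raise ValueError("MPF requires nonempty data")
    U, ubins, w = _collapse(X, bins)
    model = init.copy()
    theta0 = model.get_theta()
    trace: list[float] = []
    last_val = [np.inf]

    def objective(theta):
        model.set_theta(theta)
        K, grad = _objective_and_grad(model, U, ubins, w, cfg)
        last_val[0] = K
        return K, grad

    def callback(theta):
        trace.append(last_val[0])

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": cfg.max_iterations,
            "gtol": cfg.gradient_tolerance,
            "ftol": 1e-12,
        },
    )
    model.set_theta(res.x)
    if cfg.lambda_l1 > 0:
        theta = model.get_theta()
        mask = model.penalty_mask() & (np.abs(theta) < cfg.zero_threshold)
        theta[mask] = 0.0
        model.set_theta(theta)
    if not res.success:
        logger.warning("MPF fit did not converge: %s", res.message)
    return FitResult(
        params=model,
        objective_trace=np.asarray(trace),
        lambda_selected=cfg.lambda_l1,
        cv_table=None,
        seed=cfg.seed,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        message=str(res.message),
    )


def initial_model(
    kind: str,
    data: SpikeRaster | np.ndarray,
    cfg: MPFConfig | None = None,
    n_hidden: int | None = None,
) -> EnergyModel:
    """Standard initialization from the config seed.

    Visible biases start at the logit of each unit's mean rate and pairwise
    couplings at N(0, 0.01^2).  Hidden weights start at N(0, 0.5^2) with
    hidden biases at -1: near W = 0 the hidden-unit part of the MPF
    objective has a symmetric saddle, and a tiny-weight start collapses
    there (the L1 penalty then zeroes W entirely), so the hidden layer
    needs a broken-symmetry start.

    ``n_hidden`` defaults to the number of visible units.
    """
    cfg = cfg or MPFConfig()
    X = data.X if isinstance(data, SpikeRaster) else np.atleast_2d(
        np.asarray(data, dtype=float)
    )
    d = X.shape[1]
    p = np.clip(X.mean(axis=0), 1e-4, 1 - 1e-4)
    b = np.log(p) - np.log1p(-p)
    h = d if n_hidden is None else int(n_hidden)
    rng = np.random.default_rng(cfg.seed)
    if kind == "independent":
        return IndependentModel(b)
    if kind == "ising":
        Jr = rng.normal(0.0, 0.01, size=(d, d))
        J = np.triu(Jr, 1) + np.triu(Jr, 1).T
        return IsingModel(IsingParams(J, b))
    if kind == "rbm":
        W = rng.normal(0.0, 0.5, size=(h, d))
        return RBMModel(RBMParams(W, np.full(h, -1.0), b))
    if kind == "srbm":
        Jr = rng.normal(0.0, 0.01, size=(d, d))
        J = np.triu(Jr, 1) + np.triu(Jr, 1).T
        W = rng.normal(0.0, 0.5, size=(h, d))
        return SRBMModel(
            SRBMParams(
                IsingParams(J, b),
                RBMParams(W, np.full(h, -1.0), np.zeros(d)),
            )
        )
    raise ValueError(f"unknown model kind {kind!r}")


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def cross_validate_lambda(
    data: SpikeRaster,
    kind: str,
    cfg: MPFConfig | None = None,
    n_hidden: int | None = None,
    bins: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Select the L1 penalty by k-fold cross-validated holdout likelihood.

    Scores each lambda by the mean normalized validation log-likelihood
    (exact normalization; models here are <= 20 units by construction).
    Ties break toward the larger (sparser) lambda.
    """
    from .evaluation import pattern_log_likelihood
    from .partition import normalize_model

    cfg = cfg or MPFConfig()
    if len(cfg.lambda_grid) == 0:
        raise ValueError("lambda_grid must contain at least one value")
    X = data.X
    n = X.shape[0]
    folds = _fold_indices(n, cfg.folds, cfg.seed)
    table: dict[float, list[float]] = {lam: [] for lam in cfg.lambda_grid}
    n_failed = 0
    for f, val_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        train = SpikeRaster(data.patterns[:, train_mask], data.bin_width)
        val = SpikeRaster(data.patterns[:, ~train_mask], data.bin_width)
        init = initial_model(kind, train, cfg, n_hidden)
        for lam in cfg.lambda_grid:
            try:
                fit = fit_mpf(train, init, replace(cfg, lambda_l1=lam),
                              bins=None if bins is None else bins[train_mask])
                nm = normalize_model(fit.params)
                ll = pattern_log_likelihood(
                    val, nm,
                    bins=None if bins is None else bins[~train_mask],
                )
                table[lam].append(float(ll))
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("fold %d lambda %g failed: %s", f, lam, exc)
                n_failed += 1
                table[lam].append(np.nan)
    means = {lam: np.nanmean(v) for lam, v in table.items()}
    if all(np.isnan(list(means.values()))):
        raise RuntimeError("all cross-validation fits failed")
    best = np.nanmax(list(means.values()))
    # ties toward larger lambda (sparser model)
    selected = max(lam for lam, m in means.items() if m >= best - 1e-12)
    cv_table = {
        "lambda_grid": list(cfg.lambda_grid),
        "fold_log_likelihood_bits": {
            str(lam): list(map(float, v)) for lam, v in table.items()
        },
        "mean_log_likelihood_bits": {
            str(lam): float(m) for lam, m in means.items()
        },
        "selected": float(selected),
        "n_failed": n_failed,
    }
    return float(selected), cv_table
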