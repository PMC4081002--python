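"""Energy-based models over binary population activity patterns.

All states are vectors in {0,1}^d and probability is proportional to
``exp(-E(x))``: lower energy means higher probability.  Four model families
are provided:

* :class:`IndependentModel` -- per-unit biases only (factorized Bernoulli),
* :class:`IsingModel` -- biases plus symmetric pairwise couplings,
* :class:`RBMModel` -- bipartite visible/hidden weights, hidden units
  analytically marginalized (the "free energy" form),
* :class:`SRBMModel` -- pairwise couplings *and* marginalized hidden units.

Any of them can be wrapped in a :class:`StimulusModel`, which adds a fixed,
time-varying bias derived from trial-averaged firing probabilities
(:func:`psth_dynamic_bias`).

Every model exposes the same vectorized surface: ``energy``, ``flip_diffs``
(energy change for each single-bit flip, the workhorse of both MPF and Gibbs
sampling), ``cond_logit`` (exact single-unit conditional), a flat parameter
vector with an L1-penalty mask, and an analytic MPF value/gradient kernel.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "SpikeRaster",
    "IsingParams",
    "RBMParams",
    "SRBMParams",
    "DynamicBias",
    "EnergyModel",
    "IndependentModel",
    "IsingModel",
    "RBMModel",
    "SRBMModel",
    "StimulusModel",
    "softplus",
    "ising_energy",
    "rbm_free_energy",
    "srbm_free_energy",
    "psth_dynamic_bias",
    "stimulus_model_energy",
    "model_from_params",
]


def softplus(a: np.ndarray) -> np.ndarray:
    """Overflow-safe log(1 + exp(a)) = max(a, 0) + log1p(exp(-|a|))."""
    a = np.asarray(a, dtype=float)
    return np.maximum(a, 0.0) + np.log1p(np.exp(-np.abs(a)))


def _as_state_matrix(x: np.ndarray, d: int, name: str = "x") -> np.ndarray:
    """Coerce a state or batch of states to a float (n, d) matrix."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != d:
        raise ValueError(
            f"{name} has dimension {X.shape[1]}, model expects {d}"
        )
    return X


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class SpikeRaster:
    """Binary population activity: a (units x bins) 0/1 matrix plus metadata.

    Parameters
    ----------
    patterns
        Binary matrix, one row per unit, one column per time bin.
    bin_width
        Bin duration in milliseconds; must be positive.
    unit_labels, layer_labels
        Optional per-unit identifiers / group tags.
    """

    patterns: np.ndarray
    bin_width: float = 20.0
    unit_labels: list[str] | None = None
    layer_labels: list[str] | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.patterns)
        if P.ndim != 2:
            raise ValueError("patterns must be a 2-D (units x bins) matrix")
        if P.size and not np.isin(P, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.patterns = P.astype(np.uint8)
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        for attr in ("unit_labels", "layer_labels"):
            labels = getattr(self, attr)
            if labels is not None:
                labels = list(labels)
                if len(labels) != self.patterns.shape[0]:
                    raise ValueError(
                        f"{attr} has {len(labels)} entries for "
                        f"{self.patterns.shape[0]} units"
                    )
                setattr(self, attr, labels)

    @property
    def n_units(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_bins(self) -> int:
        return self.patterns.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Patterns as a float (bins x units) design matrix."""
        return self.patterns.T.astype(float)

    def rates(self) -> np.ndarray:
        """Per-unit firing probability per bin."""
        return self.patterns.mean(axis=1)

    def population_rate(self) -> float:
        """Mean number of active units per bin (spikes/bin)."""
        return float(self.patterns.sum(axis=0).mean())

    def select_units(self, idx: Sequence[int]) -> "SpikeRaster":
        idx = list(idx)
        return SpikeRaster(
            self.patterns[idx],
            self.bin_width,
            [self.unit_labels[i] for i in idx] if self.unit_labels else None,
            [self.layer_labels[i] for i in idx] if self.layer_labels else None,
        )

    def select_bins(self, idx: np.ndarray) -> "SpikeRaster":
        return SpikeRaster(
            self.patterns[:, idx], self.bin_width, self.unit_labels,
            self.layer_labels,
        )


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class IsingParams:
    """Symmetric pairwise couplings J (zero diagonal) and visible biases."""

    J: np.ndarray
    b_v: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.b_v = np.asarray(self.b_v, dtype=float)
        d = self.b_v.shape[0]
        if self.J.shape != (d, d):
            raise ValueError("J must be square and match the bias dimension")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have a zero diagonal")
        self.J = 0.5 * (self.J + self.J.T)
        np.fill_diagonal(self.J, 0.0)

    @property
    def n_units(self) -> int:
        return self.b_v.shape[0]


@dataclass
class RBMParams:
    """Visible-hidden weights W (hidden x visible), hidden & visible biases."""

    W: np.ndarray
    b_h: np.ndarray
    b_v: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.b_v = np.asarray(self.b_v, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be a (hidden x visible) matrix")
        if self.W.shape != (self.b_h.shape[0], self.b_v.shape[0]):
            raise ValueError("W shape must be (len(b_h), len(b_v))")

    @property
    def n_units(self) -> int:
        return self.b_v.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.b_h.shape[0]


@dataclass
class SRBMParams:
    """Ising couplings plus an RBM component; the visible bias lives in
    ``ising`` only (``rbm.b_v`` must be identically zero)."""

    ising: IsingParams
    rbm: RBMParams

    def __post_init__(self) -> None:
        if self.ising.n_units != self.rbm.n_units:
            raise ValueError("visible dimensions of ising and rbm differ")
        if np.any(self.rbm.b_v != 0.0):
            raise ValueError(
                "rbm.b_v must be zero in SRBMParams; visible bias is stored "
                "in the ising component"
            )

    @property
    def n_units(self) -> int:
        return self.ising.n_units


@dataclass
class DynamicBias:
    """Per-unit, per-bin stimulus bias derived from a trial-averaged PSTH."""

    bias: np.ndarray        # (units x segment bins)
    source_psth: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.source_psth = np.asarray(self.source_psth, dtype=float)
        if not np.isfinite(self.bias).all():
            raise ValueError("dynamic bias must be finite everywhere")
        if self.source_psth.min() < 0 or self.source_psth.max() > 1:
            raise ValueError("source_psth entries must lie in [0, 1]")

    @property
    def n_units(self) -> int:
        return self.bias.shape[0]

    @property
    def n_segment_bins(self) -> int:
        return self.bias.shape[1]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class EnergyModel(abc.ABC):
    """Uniform surface for MPF estimation, Gibbs sampling and normalization.

    ``bins`` arguments are ignored by time-invariant models and required by
    :class:`StimulusModel`, where they index the stimulus segment bin of each
    pattern.
    """

    kind: str = "abstract"

    @property
    @abc.abstractmethod
    def n_units(self) -> int:
        ...

    @abc.abstractmethod
    def energy(self, x: np.ndarray, bins: np.ndarray | None = None) -> np.ndarray:
        """E(x) for a state (d,) or batch (n, d); returns (n,) (or scalar)."""

    @abc.abstractmethod
    def flip_diffs(self, X: np.ndarray, bins: np.ndarray | None = None) -> np.ndarray:
        """Matrix (n, d) of E(flip_i(x)) - E(x) for every single-bit flip."""

    @abc.abstractmethod
    def cond_logit(
        self, X: np.ndarray, i: int, bins: np.ndarray | None = None
    ) -> np.ndarray:
        """Log-odds of unit i being active given all other units: E0 - E1."""

    @abc.abstractmethod
    def get_theta(self) -> np.ndarray:
        ...

    @abc.abstractmethod
    def set_theta(self, theta: np.ndarray) -> None:
        ...

    @abc.abstractmethod
    def penalty_mask(self) -> np.ndarray:
        """Boolean mask over theta marking coupling/weight entries (L1)."""

    @abc.abstractmethod
    def mpf_flow_grad(
        self,
        X: np.ndarray,
        C: np.ndarray,
        extra_flip_diffs: np.ndarray | None = None,
    ) -> np.ndarray:
        """Gradient of sum_{n,i} C_ni * (E(x_n) - E(x'_ni)) / 2 w.r.t. theta.

        ``C`` carries the per-(pattern, flip) flow weights (already scaled by
        pattern multiplicities and 1/N).  ``extra_flip_diffs`` is unused by
        base models; stimulus wrappers delegate here since the dynamic bias
        carries no trainable parameters.
        """

    def copy(self) -> "EnergyModel":
        clone = self.__class__.__new__(self.__class__)
        clone.__dict__.update(
            {k: (v.copy() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        )
        return clone

    def _check_batch(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        scalar = np.asarray(x).ndim == 1
        return _as_state_matrix(x, self.n_units), scalar


class IndependentModel(EnergyModel):
    """Factorized Bernoulli model: E(x) = -b_v . x."""

    kind = "independent"

    def __init__(self, b_v: np.ndarray):
        self.b_v = np.asarray(b_v, dtype=float)

    @property
    def n_units(self) -> int:
        return self.b_v.shape[0]

    def energy(self, x, bins=None):
        X, scalar = self._check_batch(x)
        E = -X @ self.b_v
        return E[0] if scalar else E

    def flip_diffs(self, X, bins=None):
        X = _as_state_matrix(X, self.n_units)
        return -(1.0 - 2.0 * X) * self.b_v

    def cond_logit(self, X, i, bins=None):
        X = _as_state_matrix(X, self.n_units)
        return np.full(X.shape[0], self.b_v[i])

    def rates(self) -> np.ndarray:
        return expit(self.b_v)

    def get_theta(self):
        return self.b_v.copy()

    def set_theta(self, theta):
        self.b_v = np.asarray(theta, dtype=float).copy()

    def penalty_mask(self):
        return np.zeros(self.n_units, dtype=bool)

    def mpf_flow_grad(self, X, C, extra_flip_diffs=None):
        X = _as_state_matrix(X, self.n_units)
        A = 0.5 * C * (1.0 - 2.0 * X)
        return A.sum(axis=0)


class IsingModel(EnergyModel):
    """Pairwise model: E(x) = -(b . x + sum_{i<j} J_ij x_i x_j)."""

    kind = "ising"

    def __init__(self, params: IsingParams):
        self.J = params.J.copy()
        self.b_v = params.b_v.copy()

    @property
    def params(self) -> IsingParams:
        return IsingParams(self.J.copy(), self.b_v.copy())

    @property
    def n_units(self) -> int:
        return self.b_v.shape[0]

    def energy(self, x, bins=None):
        X, scalar = self._check_batch(x)
        E = -(X @ self.b_v) - 0.5 * np.einsum("ni,ni->n", X @ self.J, X)
        return E[0] if scalar else E

    def flip_diffs(self, X, bins=None):
        X = _as_state_matrix(X, self.n_units)
        return -(1.0 - 2.0 * X) * (X @ self.J + self.b_v)

    def cond_logit(self, X, i, bins=None):
        X = _as_state_matrix(X, self.n_units)
        return self.b_v[i] + X @ self.J[:, i]

    def _iu(self):
        return np.triu_indices(self.n_units, k=1)

    def get_theta(self):
        return np.concatenate([self.b_v, self.J[self._iu()]])

    def set_theta(self, theta):
        d = self.n_units
        theta = np.asarray(theta, dtype=float)
        self.b_v = theta[:d].copy()
        J = np.zeros((d, d))
        J[self._iu()] = theta[d:]
        self.J = J + J.T

    def penalty_mask(self):
        d = self.n_units
        return np.concatenate(
            [np.zeros(d, dtype=bool), np.ones(d * (d - 1) // 2, dtype=bool)]
        )

    def mpf_flow_grad(self, X, C, extra_flip_diffs=None):
        X = _as_state_matrix(X, self.n_units)
        A = 0.5 * C * (1.0 - 2.0 * X)
        grad_b = A.sum(axis=0)
        G = A.T @ X
        grad_J = (G + G.T)[self._iu()]
        return np.concatenate([grad_b, grad_J])


_CHUNK = 4096  # rows per block for (n, hidden, d) intermediates


class RBMModel(EnergyModel):
    """RBM with hidden units marginalized out.

    F(x) = -b_v . x - sum_j softplus(W_j . x + b_h_j), so that
    exp(-F(x)) = sum_h exp(-E_joint(x, h)) with
    E_joint(x, h) = -(b_v . x + b_h . h + h . W x).
    """

    kind = "rbm"

    def __init__(self, params: RBMParams):
        self.W = params.W.copy()
        self.b_h = params.b_h.copy()
        self.b_v = params.b_v.copy()

    @property
    def params(self) -> RBMParams:
        return RBMParams(self.W.copy(), self.b_h.copy(), self.b_v.copy())

    @property
    def n_units(self) -> int:
        return self.b_v.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.b_h.shape[0]

    def _hidden_input(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W.T + self.b_h

    def energy(self, x, bins=None):
        X, scalar = self._check_batch(x)
        F = -(X @ self.b_v) - softplus(self._hidden_input(X)).sum(axis=1)
        return F[0] if scalar else F

    def flip_diffs(self, X, bins=None):
        X = _as_state_matrix(X, self.n_units)
        n = X.shape[0]
        out = np.empty((n, self.n_units))
        for lo in range(0, n, _CHUNK):
            sl = slice(lo, min(lo + _CHUNK, n))
            Xc = X[sl]
            delta = 1.0 - 2.0 * Xc
            a = self._hidden_input(Xc)                       # (m, h)
            Ap = a[:, :, None] + delta[:, None, :] * self.W  # (m, h, d)
            out[sl] = (
                -delta * self.b_v
                - (softplus(Ap).sum(axis=1) - softplus(a).sum(axis=1)[:, None])
            )
        return out

    def cond_logit(self, X, i, bins=None):
        X = _as_state_matrix(X, self.n_units)
        a0 = self._hidden_input(X) - X[:, [i]] * self.W[:, i]
        return self.b_v[i] + (
            softplus(a0 + self.W[:, i]) - softplus(a0)
        ).sum(axis=1)

    def get_theta(self):
        return np.concatenate([self.b_v, self.b_h, self.W.ravel()])

    def set_theta(self, theta):
        d, h = self.n_units, self.n_hidden
        theta = np.asarray(theta, dtype=float)
        self.b_v = theta[:d].copy()
        self.b_h = theta[d:d + h].copy()
        self.W = theta[d + h:].reshape(h, d).copy()

    def penalty_mask(self):
        d, h = self.n_units, self.n_hidden
        return np.concatenate(
            [np.zeros(d + h, dtype=bool), np.ones(h * d, dtype=bool)]
        )

    def _hidden_flow_grad(self, X, C):
        """(grad_b_h, grad_W) for the softplus part of the flow gradient."""
        d, h = self.n_units, self.n_hidden
        grad_c = np.zeros(h)
        grad_W = np.zeros((h, d))
        n = X.shape[0]
        for lo in range(0, n, _CHUNK):
            sl = slice(lo, min(lo + _CHUNK, n))
            Xc, Cc = X[sl], C[sl]
            delta = 1.0 - 2.0 * Xc
            a = self._hidden_input(Xc)
            S = expit(a)                                     # (m, h)
            Sp = expit(a[:, :, None] + delta[:, None, :] * self.W)  # (m,h,d)
            g = Cc.sum(axis=1)                               # (m,)
            Vp = np.einsum("ni,nji->nj", Cc, Sp)             # (m, h)
            grad_c += 0.5 * (Vp.sum(axis=0) - S.T @ g)
            grad_W += 0.5 * (
                Vp.T @ Xc
                - S.T @ (g[:, None] * Xc)
                + np.einsum("njk,nk->jk", Sp, Cc * delta)
            )
        return grad_c, grad_W

    def mpf_flow_grad(self, X, C, extra_flip_diffs=None):
        X = _as_state_matrix(X, self.n_units)
        A = 0.5 * C * (1.0 - 2.0 * X)
        grad_bv = A.sum(axis=0)
        grad_c, grad_W = self._hidden_flow_grad(X, C)
        return np.concatenate([grad_bv, grad_c, grad_W.ravel()])


class SRBMModel(EnergyModel):
    """Pairwise couplings plus marginalized hidden units.

    F(x) = ising_energy(x) - sum_j softplus(W_j . x + b_h_j); the visible
    bias enters only through the Ising term.
    """

    kind = "srbm"

    def __init__(self, params: SRBMParams):
        self.J = params.ising.J.copy()
        self.b_v = params.ising.b_v.copy()
        self.W = params.rbm.W.copy()
        self.b_h = params.rbm.b_h.copy()

    @property
    def params(self) -> SRBMParams:
        d = self.n_units
        return SRBMParams(
            IsingParams(self.J.copy(), self.b_v.copy()),
            RBMParams(self.W.copy(), self.b_h.copy(), np.zeros(d)),
        )

    @property
    def n_units(self) -> int:
        return self.b_v.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.b_h.shape[0]

    def _ising_view(self) -> IsingModel:
        m = IsingModel.__new__(IsingModel)
        m.J, m.b_v = self.J, self.b_v
        return m

    def _rbm_view(self) -> RBMModel:
        m = RBMModel.__new__(RBMModel)
        m.W, m.b_h = self.W, self.b_h
        m.b_v = np.zeros(self.n_units)
        return m

    def energy(self, x, bins=None):
        X, scalar = self._check_batch(x)
        E = self._ising_view().energy(X) - softplus(
            X @ self.W.T + self.b_h
        ).sum(axis=1)
        return E[0] if scalar else E

    def flip_diffs(self, X, bins=None):
        X = _as_state_matrix(X, self.n_units)
        rbm = self._rbm_view()
        return self._ising_view().flip_diffs(X) + rbm.flip_diffs(X)

    def cond_logit(self, X, i, bins=None):
        X = _as_state_matrix(X, self.n_units)
        return self._ising_view().cond_logit(X, i) + (
            self._rbm_view().cond_logit(X, i)
        )

    def _iu(self):
        return np.triu_indices(self.n_units, k=1)

    def get_theta(self):
        return np.concatenate(
            [self.b_v, self.J[self._iu()], self.b_h, self.W.ravel()]
        )

    def set_theta(self, theta):
        d, h = self.n_units, self.n_hidden
        n_j = d * (d - 1) // 2
        theta = np.asarray(theta, dtype=float)
        self.b_v = theta[:d].copy()
        J = np.zeros((d, d))
        J[self._iu()] = theta[d:d + n_j]
        self.J = J + J.T
        self.b_h = theta[d + n_j:d + n_j + h].copy()
        self.W = theta[d + n_j + h:].reshape(h, d).copy()

    def penalty_mask(self):
        d, h = self.n_units, self.n_hidden
        n_j = d * (d - 1) // 2
        return np.concatenate(
            [
                np.zeros(d, dtype=bool),
                np.ones(n_j, dtype=bool),
                np.zeros(h, dtype=bool),
                np.ones(h * d, dtype=bool),
            ]
        )

    def mpf_flow_grad(self, X, C, extra_flip_diffs=None):
        X = _as_state_matrix(X, self.n_units)
        ising_grad = self._ising_view().mpf_flow_grad(X, C)
        grad_c, grad_W = self._rbm_view()._hidden_flow_grad(X, C)
        return np.concatenate([ising_grad, grad_c, grad_W.ravel()])


class StimulusModel(EnergyModel):
    """Base model plus a fixed per-bin dynamic bias: E_t(x) = E(x) - h_t . x.

    The dynamic bias is frozen at its closed-form value and carries no
    trainable parameters; theta is the base model's theta.
    """

    def __init__(self, base: EnergyModel, dynamic_bias: DynamicBias):
        if base.n_units != dynamic_bias.n_units:
            raise ValueError("base model and dynamic bias dimensions differ")
        self.base = base
        self.dynamic_bias = dynamic_bias

    @property
    def kind(self) -> str:  # type: ignore[override]
        return f"{self.base.kind}+psth"

    @property
    def n_units(self) -> int:
        return self.base.n_units

    @property
    def n_segment_bins(self) -> int:
        return self.dynamic_bias.n_segment_bins

    def _bias_rows(self, bins: np.ndarray | None, n: int) -> np.ndarray:
        if bins is None:
            raise ValueError("StimulusModel requires per-pattern bin indices")
        bins = np.asarray(bins, dtype=int)
        if bins.ndim == 0:
            bins = np.full(n, int(bins))
        if bins.min() < 0 or bins.max() >= self.n_segment_bins:
            raise IndexError("bin index outside the stimulus segment")
        return self.dynamic_bias.bias[:, bins].T  # (n, d)

    def energy(self, x, bins=None):
        X, scalar = self._check_batch(x)
        H = self._bias_rows(bins, X.shape[0])
        E = self.base.energy(X) - np.einsum("nd,nd->n", H, X)
        return E[0] if scalar else E

    def flip_diffs(self, X, bins=None):
        X = _as_state_matrix(X, self.n_units)
        H = self._bias_rows(bins, X.shape[0])
        return self.base.flip_diffs(X) - (1.0 - 2.0 * X) * H

    def cond_logit(self, X, i, bins=None):
        X = _as_state_matrix(X, self.n_units)
        H = self._bias_rows(bins, X.shape[0])
        return self.base.cond_logit(X, i) + H[:, i]

    def get_theta(self):
        return self.base.get_theta()

    def set_theta(self, theta):
        self.base.set_theta(theta)

    def penalty_mask(self):
        return self.base.penalty_mask()

    def mpf_flow_grad(self, X, C, extra_flip_diffs=None):
        return self.base.mpf_flow_grad(X, C)

    def at_bin(self, t: int) -> EnergyModel:
        """Time-invariant view of the model frozen at segment bin ``t``."""
        return _FrozenBinModel(self, int(t))

    def copy(self) -> "StimulusModel":
        return StimulusModel(self.base.copy(), self.dynamic_bias)


class _FrozenBinModel(EnergyModel):
    """StimulusModel restricted to one segment bin (for enumeration/Gibbs)."""

    def __init__(self, stim: StimulusModel, t: int):
        self._stim = stim
        self._t = t
        self.kind = f"{stim.kind}@bin{t}"

    @property
    def n_units(self) -> int:
        return self._stim.n_units

    def _bins(self, n: int) -> np.ndarray:
        return np.full(n, self._t)

    def energy(self, x, bins=None):
        X, scalar = self._check_batch(x)
        E = self._stim.energy(X, self._bins(X.shape[0]))
        return E[0] if scalar else E

    def flip_diffs(self, X, bins=None):
        X = _as_state_matrix(X, self.n_units)
        return self._stim.flip_diffs(X, self._bins(X.shape[0]))

    def cond_logit(self, X, i, bins=None):
        X = _as_state_matrix(X, self.n_units)
        return self._stim.cond_logit(X, i, self._bins(X.shape[0]))

    def get_theta(self):
        return self._stim.get_theta()

    def set_theta(self, theta):
        self._stim.set_theta(theta)

    def penalty_mask(self):
        return self._stim.penalty_mask()

    def mpf_flow_grad(self, X, C, extra_flip_diffs=None):
        raise NotImplementedError("fit the StimulusModel with bin indices")


# ---------------------------------------------------------------------------
# functional forms
# ---------------------------------------------------------------------------


def ising_energy(x: np.ndarray, p: IsingParams) -> np.ndarray:
    """E(x) = -(sum_i b_i x_i + sum_{i<j} J_ij x_i x_j)."""
    return IsingModel(p).energy(x)


def rbm_free_energy(x: np.ndarray, p: RBMParams) -> np.ndarray:
    """F(x) = -b_v . x - sum_j softplus(W_j . x + b_h_j).

    exp(-F(x)) equals the sum of exp(-E_joint(x, h)) over all hidden
    configurations h.
    """
    return RBMModel(p).energy(x)


def srbm_free_energy(x: np.ndarray, p: SRBMParams) -> np.ndarray:
    """Ising energy plus the marginalized hidden-unit softplus terms."""
    return SRBMModel(p).energy(x)


def psth_dynamic_bias(psth: np.ndarray, epsilon: float) -> DynamicBias:
    """Closed-form stimulus bias h_it = logit(clip(p_it, eps, 1-eps)).

    A model with only this term reproduces the (clipped) trial-averaged
    firing probabilities exactly.
    """
    psth = np.asarray(psth, dtype=float)
    if psth.size and (psth.min() < 0 or psth.max() > 1):
        raise ValueError("psth entries must lie in [0, 1]")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    p = np.clip(psth, epsilon, 1.0 - epsilon)
    return DynamicBias(bias=np.log(p) - np.log1p(-p), source_psth=psth,
                       epsilon=epsilon)


def stimulus_model_energy(
    x: np.ndarray, t: int, base: EnergyModel, db: DynamicBias
) -> np.ndarray:
    """Energy of the stimulus-augmented model at segment bin ``t``."""
    stim = StimulusModel(base, db)
    X, scalar = stim._check_batch(x)
    E = stim.energy(X, np.full(X.shape[0], int(t)))
    return E[0] if scalar else E


def model_from_params(params) -> EnergyModel:
    """Build the matching model for a parameter container (or pass through)."""
    if isinstance(params, EnergyModel):
        return params
    if isinstance(params, IsingParams):
        return IsingModel(params)
    if isinstance(params, RBMParams):
        return RBMModel(params)
    if isinstance(params, SRBMParams):
        return SRBMModel(params)
    raise TypeError(f"unsupported parameter container: {type(params)!r}")
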