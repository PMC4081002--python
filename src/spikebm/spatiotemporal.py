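"""Spatiotemporal pattern construction: concatenate consecutive time bins
into flat patterns of dimension n_cells * n_frames and predict single-cell
activity conditioned on network history.

Flat layout is frame-major: slot (cell, lag) maps to ``lag * n_cells +
cell`` with lag 0 the oldest frame and lag n_frames-1 the most recent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .models import EnergyModel, SpikeRaster
from .partition import enumerate_states

__all__ = [
    "SpatiotemporalSpec",
    "concat_time_steps",
    "unflatten_pattern",
    "select_top_rate_cells",
    "predict_next_bin",
]


@dataclass
class SpatiotemporalSpec:
    """Geometry of the concatenation: cells, frames, blocking mode."""

    n_cells: int
    n_frames: int
    bin_width: float = 6.7
    blocking: str = "disjoint"  # or "sliding"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not 1 <= self.n_frames <= 15:
            raise ValueError("n_frames must lie in 1..15")
        if self.blocking not in ("disjoint", "sliding"):
            raise ValueError("blocking must be 'disjoint' or 'sliding'")

    @property
    def flat_dim(self) -> int:
        return self.n_cells * self.n_frames

    def flat_index(self, cell: int, lag: int) -> int:
        """Bijective (cell, lag) -> flat slot; lag n_frames-1 is newest."""
        if not (0 <= cell < self.n_cells and 0 <= lag < self.n_frames):
            raise IndexError("cell/lag out of range")
        return lag * self.n_cells + cell


def concat_time_steps(
    raster: SpikeRaster, spec: SpatiotemporalSpec
) -> SpikeRaster:
    """Concatenate blocks of ``n_frames`` consecutive bins into flat
    patterns.  Disjoint blocking yields floor(T / n_frames) patterns,
    sliding yields T - n_frames + 1.
    """
    if raster.n_units != spec.n_cells:
        raise ValueError("raster unit count does not match spec.n_cells")
    T, f = raster.n_bins, spec.n_frames
    if T < f:
        raise ValueError(f"need at least {f} bins, raster has {T}")
    P = raster.patterns  # (cells, T)
    if spec.blocking == "disjoint":
        n_blocks = T // f
        # (cells, n_blocks, f) -> (n_blocks, f, cells) -> flat frame-major
        B = P[:, : n_blocks * f].reshape(spec.n_cells, n_blocks, f)
        flat = B.transpose(1, 2, 0).reshape(n_blocks, spec.flat_dim)
    else:
        n_blocks = T - f + 1
        idx = np.arange(f)[None, :] + np.arange(n_blocks)[:, None]  # (n, f)
        flat = P.T[idx].reshape(n_blocks, spec.flat_dim)
    return SpikeRaster(flat.T, raster.bin_width)


def unflatten_pattern(x: np.ndarray, spec: SpatiotemporalSpec) -> np.ndarray:
    """Inverse of the flattening: flat vector -> (cells, frames) block."""
    x = np.asarray(x)
    if x.shape[-1] != spec.flat_dim:
        raise ValueError("pattern length does not match spec")
    return x.reshape(spec.n_frames, spec.n_cells).T


def select_top_rate_cells(raster: SpikeRaster, k: int) -> SpikeRaster:
    """Keep the k highest-rate cells, preserving original order; ties break
    toward the earlier cell."""
    if not 0 < k <= raster.n_units:
        raise ValueError(f"k must lie in 1..{raster.n_units}")
    rates = raster.rates()
    # stable argsort on negated rates keeps input order among ties
    top = np.sort(np.argsort(-rates, kind="stable")[:k])
    return raster.select_units(top)


def predict_next_bin(
    history: np.ndarray,
    model: EnergyModel,
    spec: SpatiotemporalSpec,
    observed_last: np.ndarray | None = None,
    marginalize_max_cells: int = 12,
) -> np.ndarray:
    """Per-cell spike probability for the newest frame given the history.

    ``history`` is (cells, n_frames - 1), oldest frame first.  With
    ``observed_last`` given, each cell is conditioned on the simultaneous
    observed values of the other last-frame cells; otherwise the other
    last-frame cells are marginalized by exact enumeration (cells <=
    ``marginalize_max_cells``).
    """
    c, f = spec.n_cells, spec.n_frames
    if model.n_units != spec.flat_dim:
        raise ValueError("model dimension does not match spec")
    history = np.asarray(history, dtype=float)
    if history.shape != (c, f - 1):
        raise ValueError(f"history must be (cells, n_frames-1) = ({c},{f - 1})")
    hist_flat = history.T.ravel()  # frame-major, oldest first

    if observed_last is not None:
        from .evaluation import conditional_spike_probability

        obs = np.asarray(observed_last, dtype=float)
        probs = np.empty(c)
        for i in range(c):
            x = np.concatenate([hist_flat, obs])
            probs[i] = conditional_spike_probability(
                x, model, masked=spec.flat_index(i, f - 1)
            )
        return probs

    if c > marginalize_max_cells:
        raise ValueError(
            "marginal prediction enumerates 2^cells last-frame states; "
            f"{c} cells exceeds the limit — pass observed_last instead"
        )
    last = enumerate_states(c)  # (2^c, c)
    full = np.concatenate(
        [np.tile(hist_flat, (last.shape[0], 1)), last], axis=1
    )
    logp = -model.energy(full)
    logp -= logsumexp(logp)
    return np.exp(logp) @ last
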