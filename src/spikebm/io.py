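"""Readers and writers for rasters and model containers, spike-time
binning, and train/test splitting.

Rasters travel as (a) dense 0/1 CSV with unit labels as the row index and
the bin width in a header comment, (b) an ``.npz`` array container, or (c)
per-neuron spike-time text files binned on load.  Models serialize to a
single self-describing JSON container carrying a kind tag, parameter
arrays, and normalization/provenance metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .models import (
    DynamicBias,
    EnergyModel,
    IndependentModel,
    IsingModel,
    IsingParams,
    RBMModel,
    RBMParams,
    SpikeRaster,
    SRBMModel,
    SRBMParams,
    StimulusModel,
)
from .partition import NormalizedModel

logger = logging.getLogger(__name__)

__all__ = [
    "bin_spike_times",
    "split_train_test",
    "read_raster_csv",
    "write_raster_csv",
    "read_raster_npz",
    "write_raster_npz",
    "read_spike_times",
    "load_raster",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# binning and splitting
# ---------------------------------------------------------------------------


def bin_spike_times(
    spike_times: list[np.ndarray],
    bin_width: float,
    t_start: float,
    t_end: float,
    unit_labels: list[str] | None = None,
) -> SpikeRaster:
    """Bin per-neuron spike times (ms) into a binary raster.

    Bins are half-open [t_start + k w, t_start + (k+1) w); a spike exactly
    on an edge goes to the later bin.  Any count >= 1 becomes 1.  Times
    outside [t_start, t_end) are dropped (count logged); unsorted input is
    tolerated.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n_bins = int(np.floor((t_end - t_start) / bin_width))
    patterns = np.zeros((len(spike_times), n_bins), dtype=np.uint8)
    n_dropped = 0
    for i, times in enumerate(spike_times):
        t = np.sort(np.asarray(times, dtype=float))
        in_range = (t >= t_start) & (t < t_start + n_bins * bin_width)
        n_dropped += int((~in_range).sum())
        k = np.floor((t[in_range] - t_start) / bin_width).astype(int)
        patterns[i, k] = 1
    if n_dropped:
        logger.info("bin_spike_times dropped %d out-of-range spikes", n_dropped)
    return SpikeRaster(patterns, bin_width, unit_labels)


def split_train_test(
    raster: SpikeRaster,
    fractions: tuple[float, ...] = (0.5, 0.5),
    seed: int = 0,
) -> tuple[SpikeRaster, ...]:
    """Random pattern-level partition of the bins into disjoint subsets.

    ``fractions`` must sum to 1; the split is seeded, disjoint, exhaustive.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    n = raster.n_bins
    perm = np.random.default_rng(seed).permutation(n)
    edges = np.floor(np.cumsum(fractions) * n + 1e-9).astype(int)
    parts = []
    lo = 0
    for hi in edges:
        idx = np.sort(perm[lo:hi])
        parts.append(raster.select_bins(idx))
        lo = hi
    return tuple(parts)


# ---------------------------------------------------------------------------
# raster formats
# ---------------------------------------------------------------------------


def write_raster_csv(raster: SpikeRaster, path: str | Path) -> None:
    path = Path(path)
    labels = raster.unit_labels or [f"u{i}" for i in range(raster.n_units)]
    with path.open("w") as fh:
        fh.write(f"# bin_width_ms={raster.bin_width}\n")
        for label, row in zip(labels, raster.patterns):
            fh.write(label + "," + ",".join(map(str, row)) + "\n")


def read_raster_csv(path: str | Path, bin_width: float | None = None) -> SpikeRaster:
    path = Path(path)
    labels, rows = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "bin_width_ms=" in line and bin_width is None:
                    bin_width = float(line.split("bin_width_ms=")[1])
                continue
            parts = line.split(",")
            labels.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
    return SpikeRaster(np.array(rows, dtype=np.uint8), bin_width or 20.0,
                       labels)


def write_raster_npz(raster: SpikeRaster, path: str | Path) -> None:
    np.savez_compressed(
        Path(path),
        patterns=raster.patterns,
        bin_width=raster.bin_width,
        labels=np.array(raster.unit_labels or [], dtype=object),
    )


def read_raster_npz(path: str | Path) -> SpikeRaster:
    with np.load(Path(path), allow_pickle=True) as z:
        labels = [str(x) for x in z["labels"]] if z["labels"].size else None
        return SpikeRaster(z["patterns"], float(z["bin_width"]), labels)


def read_spike_times(
    path: str | Path,
    bin_width: float,
    t_start: float | None = None,
    t_end: float | None = None,
) -> SpikeRaster:
    """Per-neuron spike-time text: one neuron per line, times in ms,
    optionally prefixed with ``label:``."""
    labels, trains = [], []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line:
            label, rest = line.split(":", 1)
        else:
            label, rest = f"u{i}", line
        labels.append(label.strip())
        trains.append(np.array([float(v) for v in rest.split()]))
    if t_start is None:
        t_start = 0.0
    if t_end is None:
        t_end = max((t.max() for t in trains if t.size), default=0.0) + bin_width
    return bin_spike_times(trains, bin_width, t_start, t_end, labels)


def load_raster(path: str | Path, bin_width: float | None = None) -> SpikeRaster:
    """Dispatch on file suffix: .csv/.tsv, .npz, or spike-time .txt."""
    path = Path(path)
    if path.suffix == ".npz":
        return read_raster_npz(path)
    if path.suffix in (".csv", ".tsv"):
        return read_raster_csv(path, bin_width)
    return read_spike_times(path, bin_width or 20.0)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


def model_to_dict(model: EnergyModel, meta: dict | None = None) -> dict:
    """Self-describing JSON-ready container for any model kind."""
    payload: dict = {"format": "spikebm-model-v1", "meta": meta or {}}
    if isinstance(model, StimulusModel):
        payload["kind"] = model.kind
        payload["base"] = model_to_dict(model.base)
        payload["dynamic_bias"] = {
            "bias": model.dynamic_bias.bias.tolist(),
            "source_psth": model.dynamic_bias.source_psth.tolist(),
            "epsilon": model.dynamic_bias.epsilon,
        }
        return payload
    payload["kind"] = model.kind
    if isinstance(model, IndependentModel):
        payload["arrays"] = {"b_v": model.b_v.tolist()}
    elif isinstance(model, IsingModel):
        payload["arrays"] = {"J": model.J.tolist(), "b_v": model.b_v.tolist()}
    elif isinstance(model, RBMModel):
        payload["arrays"] = {
            "W": model.W.tolist(),
            "b_h": model.b_h.tolist(),
            "b_v": model.b_v.tolist(),
        }
    elif isinstance(model, SRBMModel):
        payload["arrays"] = {
            "J": model.J.tolist(),
            "b_v": model.b_v.tolist(),
            "W": model.W.tolist(),
            "b_h": model.b_h.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize model type {type(model)!r}")
    return payload


def model_from_dict(payload: dict) -> EnergyModel:
    kind = payload["kind"]
    if kind.endswith("+psth"):
        base = model_from_dict(payload["base"])
        db = payload["dynamic_bias"]
        return StimulusModel(
            base,
            DynamicBias(
                np.array(db["bias"]),
                np.array(db["source_psth"]),
                float(db["epsilon"]),
            ),
        )
    a = {k: np.array(v) for k, v in payload["arrays"].items()}
    if kind == "independent":
        return IndependentModel(a["b_v"])
    if kind == "ising":
        return IsingModel(IsingParams(a["J"], a["b_v"]))
    if kind == "rbm":
        return RBMModel(RBMParams(a["W"], a["b_h"], a["b_v"]))
    if kind == "srbm":
        return SRBMModel(
            SRBMParams(
                IsingParams(a["J"], a["b_v"]),
                RBMParams(a["W"], a["b_h"], np.zeros(a["b_v"].shape[0])),
            )
        )
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(
    model: EnergyModel | NormalizedModel,
    path: str | Path,
    meta: dict | None = None,
) -> None:
    if isinstance(model, NormalizedModel):
        payload = model_to_dict(model.model, meta)
        payload["normalization"] = {
            "log_z": np.asarray(model.log_z).tolist(),
            "method": model.method,
            "diagnostics": model.diagnostics,
        }
    else:
        payload = model_to_dict(model, meta)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path) -> EnergyModel | NormalizedModel:
    payload = json.loads(Path(path).read_text())
    model = model_from_dict(payload)
    norm = payload.get("normalization")
    if norm is None:
        return model
    log_z = np.asarray(norm["log_z"], dtype=float)
    if log_z.ndim == 0:
        log_z = float(log_z)
    return NormalizedModel(model, log_z, norm["method"],
                           norm.get("diagnostics", {}))
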