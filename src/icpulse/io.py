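"""File formats: pulse-matrix tables and model checkpoints.

Records and truth tables live in :mod:`icpulse.simulate`; this module adds
the delimited pulse-matrix format (provenance columns followed by the 180
sample columns) and npz checkpoints that bundle every trainable parameter,
batch-norm running statistics and the builder configuration, so a model
round-trips bit-identically.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import networks
from .networks import (BiLSTM, Layer, SelectorCNN, SelectorLSTM,
                       SelectorLSTMFCN, Sequential, UNet1d)
from .nn import BatchNorm1d
from .preprocess import NormalizedPulse, PulseMatrix

_VALUE_COLS = [f"v{i}" for i in range(networks.PULSE_LEN)]


def write_pulse_matrix(path, matrix: PulseMatrix) -> None:
    rows = []
    for p in matrix.pulses:
        row = {"onset_sample": p.onset_sample,
               "duration_samples": p.duration_samples,
               "raw_min": p.raw_min, "raw_max": p.raw_max}
        row.update(dict(zip(_VALUE_COLS, p.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pulse_matrix(path) -> PulseMatrix:
    df = pd.read_csv(path)
    matrix = PulseMatrix()
    values = df[_VALUE_COLS].to_numpy()
    for i, row in df.iterrows():
        matrix.pulses.append(NormalizedPulse(
            values=values[i], onset_sample=int(row["onset_sample"]),
            duration_samples=int(row["duration_samples"]),
            raw_min=float(row["raw_min"]), raw_max=float(row["raw_max"])))
    return matrix


def _primitive_layers(layer: Layer):
    """Depth-first traversal down to parameter-bearing primitive layers."""
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _primitive_layers(sub)
    elif isinstance(layer, BiLSTM):
        yield layer.fwd
        yield layer.bwd
    elif isinstance(layer, (SelectorCNN, SelectorLSTM)):
        yield from _primitive_layers(layer.net)
    elif isinstance(layer, SelectorLSTMFCN):
        yield from _primitive_layers(layer.encoder)
        yield from _primitive_layers(layer.lstm)
        yield from _primitive_layers(layer.head)
    elif isinstance(layer, UNet1d):
        for part in (layer.enc1, layer.enc2, layer.bottom, layer.dec2,
                     layer.dec1, layer.final):
            yield from _primitive_layers(part)
    else:
        yield layer


def _state_arrays(net: Layer) -> list[np.ndarray]:
    arrays = [p.value for p in net.parameters()]
    for sub in _primitive_layers(net):
        if isinstance(sub, BatchNorm1d):
            arrays += [sub.running_mean, sub.running_var]
    return arrays


def _load_state(net: Layer, arrays: list[np.ndarray]) -> None:
    params = net.parameters()
    buffers = [sub for sub in _primitive_layers(net)
               if isinstance(sub, BatchNorm1d)]
    expected = len(params) + 2 * len(buffers)
    if len(arrays) != expected:
        raise ValueError(f"checkpoint has {len(arrays)} arrays, "
                         f"model expects {expected}")
    for p, a in zip(params, arrays):
        if p.value.shape != a.shape:
            raise ValueError("checkpoint incompatible with model architecture")
        p.value[...] = a
    rest = arrays[len(params):]
    for bn, mean, var in zip(buffers, rest[0::2], rest[1::2]):
        bn.running_mean[...] = mean
        bn.running_var[...] = var


def save_checkpoint(path, net: Layer, config: dict,
                    history: pd.DataFrame | None = None) -> None:
    """Serialize a trained network with its builder configuration."""
    arrays = {f"arr_{i}": a for i, a in enumerate(_state_arrays(net))}
    meta = {"config": config}
    if history is not None:
        meta["history"] = history.to_dict(orient="list")
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict, list[np.ndarray], pd.DataFrame | None]:
    """Returns (config, state arrays, training history or None)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data) - 1)]
    history = (pd.DataFrame(meta["history"]) if "history" in meta else None)
    return meta["config"], arrays, history


def save_selector(path, selector) -> None:
    config = {"stage": "selector", "params": selector.get_params()}
    save_checkpoint(path, selector.net_, config,
                    getattr(selector, "history_", None))


def load_selector(path):
    from .selection import PulseSelector, build_selector
    config, arrays, history = load_checkpoint(path)
    if config.get("stage") != "selector":
        raise ValueError("not a selector checkpoint")
    params = config["params"]
    for key in ("channels", "dense"):
        params[key] = tuple(params[key])
    est = PulseSelector(**params)
    est.net_ = build_selector(est._config(), seed=est.random_state)
    _load_state(est.net_, arrays)
    est.classes_ = np.array([False, True])
    if history is not None:
        est.history_ = history
    return est


def save_designator(path, designator) -> None:
    config = {"stage": "designator", "params": designator.get_params()}
    save_checkpoint(path, designator.net_, config,
                    getattr(designator, "history_", None))


def load_designator(path):
    from .designation import SubpeakDesignator, build_designator
    config, arrays, history = load_checkpoint(path)
    if config.get("stage") != "designator":
        raise ValueError("not a designator checkpoint")
    params = config["params"]
    params["channels"] = tuple(params["channels"])
    est = SubpeakDesignator(**params)
    est.net_ = build_designator(est.kind, seed=est.random_state,
                                channels=est.channels, kernel=est.kernel,
                                lstm_hidden=est.lstm_hidden,
                                dropout=est.dropout)
    _load_state(est.net_, arrays)
    if history is not None:
        est.history_ = history
    return est
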