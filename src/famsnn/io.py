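"""HDF5 checkpoints for networks and connection groups."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .dynamics import LayerParams, NeuronLayerState
from .network import BalancingCoefficients, Network, NetworkConfig
from .plasticity import ConnectionGroup, ConnectionKind

__all__ = ["save_network", "load_network"]

_STATE_FIELDS = ("V", "V_th", "refractory_remaining", "a", "theta", "spiked")


def config_to_dict(config: NetworkConfig) -> dict:
    d = dataclasses.asdict(config)
    d["layer_sizes"] = list(config.layer_sizes)
    return d


def config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    d["layer_sizes"] = tuple(d["layer_sizes"])
    for key in ("hidden_params", "output_params", "input_params"):
        if d.get(key) is not None:
            d[key] = LayerParams(**d[key])
    if d.get("balancing") is not None:
        d["balancing"] = BalancingCoefficients(**d["balancing"])
    return NetworkConfig(**d)


def save_network(net: Network, path) -> None:
    """Write a full checkpoint: config, layer states, and every group.

    Each connection group is one HDF5 group holding the weight matrix and
    its per-weight decay timestamps, with kind/bounds/learning-rate as
    attributes, so a checkpoint is inspectable with any HDF5 browser.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "famsnn-checkpoint-v1"
        f.attrs["t_now"] = net.t_now
        f.attrs["config_json"] = json.dumps(config_to_dict(net.config))
        sgrp = f.create_group("states")
        for name, state in net.states.items():
            g = sgrp.create_group(name)
            for fld in _STATE_FIELDS:
                g.create_dataset(fld, data=getattr(state, fld))
        cgrp = f.create_group("groups")
        for name, group in net.groups.items():
            g = cgrp.create_group(name)
            g.create_dataset("W", data=group.W)
            g.create_dataset("last_update_time", data=group.last_update_time)
            g.attrs["kind"] = group.kind.value
            g.attrs["bounds"] = group.bounds
            g.attrs["learning_rate"] = group.learning_rate
            g.attrs["tau_decay"] = group.tau_decay
            g.attrs["plastic"] = group.plastic


def load_network(path) -> Network:
    """Re-create a network bit-identically from a checkpoint."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "famsnn-checkpoint-v1":
            raise ValueError(f"{path} is not a famsnn checkpoint")
        config = config_from_dict(json.loads(f.attrs["config_json"]))
        states = {}
        for name, g in f["states"].items():
            states[name] = NeuronLayerState(
                **{fld: np.asarray(g[fld]) for fld in _STATE_FIELDS})
        groups = {}
        for name, g in f["groups"].items():
            groups[name] = ConnectionGroup(
                W=np.asarray(g["W"]),
                kind=ConnectionKind(g.attrs["kind"]),
                learning_rate=float(g.attrs["learning_rate"]),
                tau_decay=float(g.attrs["tau_decay"]),
                plastic=bool(g.attrs["plastic"]),
                last_update_time=np.asarray(g["last_update_time"]),
            )
        return Network(config=config, states=states, groups=groups,
                       t_now=float(f.attrs["t_now"]))
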