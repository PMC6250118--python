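"""Experiment configuration files and run manifests.

An experiment is described by one YAML file with four sections — ``network``,
``protocol``, ``schedule`` and ``data`` — plus a top-level ``seed``.  Every
hyperparameter is named explicitly (tau_m, tau_a, tau_theta, tau_th, tau_ref,
tau_decay, alpha, beta, gamma, eta, delta_V_th, I_supervised, ...); unknown
keys raise immediately so a misspelled name can never fall back to a silent
default.

Each run writes a :class:`RunManifest` (JSON) next to its outputs capturing
the full config snapshot, seed, package version and dataset descriptor, which
is sufficient to re-create the run bit-identically on the same platform.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from . import __version__
from .dynamics import LayerParams
from .network import BalancingCoefficients, NetworkConfig
from .stimuli import StimulusProtocol, SyntheticSpec
from .training import TrainSchedule

__all__ = ["ExperimentConfig", "RunManifest", "load_config", "save_config",
           "experiment_from_dict", "experiment_to_dict"]

_NETWORK_KEYS = {
    "layer_sizes", "tau_m", "tau_ref", "tau_a", "tau_theta", "tau_th",
    "delta_V_th", "V_th_init", "V_th_floor", "threshold_scaling",
    "tau_decay", "alpha", "beta", "gamma", "eta", "I_supervised",
    "enabled", "balancing", "feedforward_rule", "hidden_overrides",
    "output_overrides", "input_overrides",
}
_LAYER_KEYS = {"tau_m", "tau_ref", "tau_a", "tau_theta", "tau_th",
               "delta_V_th", "V_th_init", "V_th_floor", "threshold_scaling",
               "dt"}
_PROTOCOL_KEYS = {"T_input", "T_silence", "rate_max", "readout_window", "dt"}
_SCHEDULE_KEYS = {"mode", "n_supervised", "n_train_total", "eval_every",
                  "n_eval"}
_DATA_KEYS = {"kind", "synthetic", "train_images", "train_labels",
              "test_images", "test_labels"}
_SYNTH_KEYS = {"n_classes", "image_side", "prototype_density",
               "noise_flip_prob", "intensity_jitter", "n_train_per_class",
               "n_test_per_class", "seed"}
_TOP_KEYS = {"seed", "network", "protocol", "schedule", "data"}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}; "
            f"allowed keys are {sorted(allowed)}")


@dataclass
class DataSpec:
    """Where the train/test images come from."""

    kind: str = "synthetic"                       # "synthetic" | "idx"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    train_images: str | None = None
    train_labels: str | None = None
    test_images: str | None = None
    test_labels: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("synthetic", "idx"):
            raise ValueError(f"data kind must be 'synthetic' or 'idx', "
                             f"got {self.kind!r}")
        if self.kind == "idx":
            missing = [k for k in ("train_images", "train_labels",
                                   "test_images", "test_labels")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(f"idx data requires paths for {missing}")


@dataclass
class ExperimentConfig:
    network: NetworkConfig
    protocol: StimulusProtocol
    schedule: TrainSchedule
    data: DataSpec
    seed: int = 0


def _layer_params(n: int, flat: dict, overrides: dict | None) -> LayerParams:
    kw = dict(flat)
    if overrides:
        _check_keys("layer overrides", overrides, _LAYER_KEYS)
        kw.update(overrides)
    return LayerParams(N=n, **kw)


def experiment_from_dict(d: dict) -> ExperimentConfig:
    _check_keys("<top level>", d, _TOP_KEYS)
    seed = int(d.get("seed", 0))

    nd = dict(d.get("network", {}))
    _check_keys("network", nd, _NETWORK_KEYS)
    layer_sizes = tuple(nd.pop("layer_sizes"))
    flat = {k: nd.pop(k) for k in list(nd)
            if k in _LAYER_KEYS and k != "dt"}
    hid_over = nd.pop("hidden_overrides", None)
    out_over = nd.pop("output_overrides", None)
    in_over = nd.pop("input_overrides", None)

    pd = dict(d.get("protocol", {}))
    _check_keys("protocol", pd, _PROTOCOL_KEYS)
    if "readout_window" in pd:
        pd["readout_window"] = tuple(pd["readout_window"])
    protocol = StimulusProtocol(**pd)
    flat["dt"] = protocol.dt

    if "balancing" in nd:
        nd["balancing"] = BalancingCoefficients(**nd["balancing"])
    network = NetworkConfig(
        layer_sizes=layer_sizes,
        hidden_params=_layer_params(layer_sizes[1], flat, hid_over),
        output_params=_layer_params(layer_sizes[2], flat, out_over),
        input_params=_layer_params(layer_sizes[0], flat, in_over),
        seed=seed,
        **nd,
    )

    sd = dict(d.get("schedule", {}))
    _check_keys("schedule", sd, _SCHEDULE_KEYS)
    schedule = TrainSchedule(**sd)

    dd = dict(d.get("data", {}))
    _check_keys("data", dd, _DATA_KEYS)
    if "synthetic" in dd:
        _check_keys("data.synthetic", dd["synthetic"], _SYNTH_KEYS)
        dd["synthetic"] = SyntheticSpec(**dd["synthetic"])
    data = DataSpec(**dd)

    return ExperimentConfig(network=network, protocol=protocol,
                            schedule=schedule, data=data, seed=seed)


def experiment_to_dict(exp: ExperimentConfig) -> dict:
    hp = exp.network.hidden_params
    net = {
        "layer_sizes": list(exp.network.layer_sizes),
        "tau_m": hp.tau_m, "tau_ref": hp.tau_ref, "tau_a": hp.tau_a,
        "tau_theta": hp.tau_theta, "tau_th": hp.tau_th,
        "delta_V_th": hp.delta_V_th, "V_th_init": hp.V_th_init,
        "V_th_floor": hp.V_th_floor,
        "threshold_scaling": hp.threshold_scaling,
        "tau_decay": exp.network.tau_decay,
        "alpha": exp.network.alpha, "beta": exp.network.beta,
        "gamma": exp.network.gamma, "eta": exp.network.eta,
        "I_supervised": exp.network.I_supervised,
        "enabled": dict(exp.network.enabled),
        "balancing": dataclasses.asdict(exp.network.balancing),
        "feedforward_rule": exp.network.feedforward_rule,
    }
    for name, params in (("hidden_overrides", exp.network.hidden_params),
                         ("output_overrides", exp.network.output_params),
                         ("input_overrides", exp.network.input_params)):
        over = {k: getattr(params, k) for k in sorted(_LAYER_KEYS - {"dt"})
                if getattr(params, k) != net.get(k)}
        if over:
            net[name] = over
    return {
        "seed": exp.seed,
        "network": net,
        "protocol": {
            "T_input": exp.protocol.T_input,
            "T_silence": exp.protocol.T_silence,
            "rate_max": exp.protocol.rate_max,
            "readout_window": list(exp.protocol.readout_window),
            "dt": exp.protocol.dt,
        },
        "schedule": dataclasses.asdict(exp.schedule),
        "data": {
            "kind": exp.data.kind,
            **({"synthetic": dataclasses.asdict(exp.data.synthetic)}
               if exp.data.kind == "synthetic" else
               {k: getattr(exp.data, k) for k in
                ("train_images", "train_labels", "test_images", "test_labels")}),
        },
    }


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return experiment_from_dict(raw)


def save_config(exp: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(experiment_to_dict(exp), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Reproducibility record written next to every run's outputs."""

    command: str
    seed: int
    config: dict
    dataset: dict
    version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)

    @staticmethod
    def now() -> str:
        return datetime.datetime.now(datetime.timezone.utc).isoformat()

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        payload.pop("config_hash", None)
        return cls(**payload)
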