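"""Three-layer recurrent spiking network assembly and stepping.

The reference architecture is input-hidden-output (e.g. 784-100-10): Poisson
input units project excitatory feedforward synapses onto a hidden LIF layer,
the hidden layer projects onto an output LIF layer with one neuron per
class, the output layer projects excitatory *reciprocal* synapses back onto
the hidden layer, and both LIF layers carry learnable lateral inhibition.
All connection kinds are dense ("fully interconnected").

Currents are weighted sums of pre-synaptic instant activities, one balancing
coefficient per current type:

    I_hidden = c_ff_hidden * a_in  @ W_in_hid
             + c_lat_hidden * a_hid @ W_hid_hid     (<= 0)
             + c_rec * a_out @ W_out_hid
    I_output = c_ff_output * a_hid @ W_hid_out
             + c_lat_output * a_out @ W_out_out     (<= 0)

During a labeled presentation an additional constant teacher current
``I_supervised`` is injected into the output neuron of the true class.

One :func:`simulate_step` is a pure function of the previous state: currents
are computed from the traces of the previous step (input traces lead by one
step since input units have no membrane), then membrane integration and
spiking, threshold adaptation, trace updates, and finally plasticity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import (
    LayerParams,
    NeuronLayerState,
    step_activity,
    step_membrane,
    step_threshold,
)
from .plasticity import (
    ConnectionGroup,
    ConnectionKind,
    update_feedforward,
    update_hidden_lateral,
    update_output_inhibition,
    update_reciprocal,
)

__all__ = ["BalancingCoefficients", "NetworkConfig", "Network",
           "build_network", "compute_currents", "simulate_step"]


@dataclass
class BalancingCoefficients:
    """Multipliers on each current type, equalizing their effect per neuron.

    A spiking neuron attenuates its input nonlinearly, so the feedforward,
    lateral and reciprocal currents need per-type scaling to compete on equal
    terms; the useful values depend on layer sizes and input statistics.
    """

    c_ff_hidden: float = 1.0
    c_ff_output: float = 1.0
    c_lat_hidden: float = 1.0
    c_lat_output: float = 1.0
    c_rec: float = 1.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"balancing coefficient {name} must be >= 0")


@dataclass
class NetworkConfig:
    """Complete, seedable description of one network."""

    layer_sizes: tuple[int, int, int]  # (n_input, n_hidden, n_output)
    hidden_params: LayerParams | None = None
    output_params: LayerParams | None = None
    input_params: LayerParams | None = None  # traces only; no membrane
    enabled: dict = field(default_factory=lambda: {
        "output_inhibition": True, "hidden_inhibition": True, "reciprocal": True,
    })
    balancing: BalancingCoefficients = field(default_factory=BalancingCoefficients)
    alpha: float = 0.1    # feedforward learning rate
    beta: float = 0.3     # reciprocal learning rate
    gamma: float = 0.1    # output-lateral learning rate
    eta: float = 0.15     # hidden-lateral learning rate
    tau_decay: float = 10_000.0  # weight decay constant, ms (10 s)
    tau_decay_lateral: float | None = None  # lateral kinds; None = tau_decay
    I_supervised: float = 30.0   # teacher current amplitude, a.u.
    seed: int = 0
    feedforward_rule: str = "activity_difference"  # or "bcm"

    def __post_init__(self) -> None:
        n_in, n_hid, n_out = self.layer_sizes
        if min(n_in, n_hid, n_out) < 1:
            raise ValueError(f"all layer sizes must be >= 1, got {self.layer_sizes}")
        unknown = set(self.enabled) - {"output_inhibition", "hidden_inhibition",
                                       "reciprocal"}
        if unknown:
            raise ValueError(f"unknown enabled flags: {sorted(unknown)}")
        for k in ("output_inhibition", "hidden_inhibition", "reciprocal"):
            self.enabled.setdefault(k, True)
        if self.hidden_params is None:
            self.hidden_params = LayerParams(N=n_hid)
        if self.output_params is None:
            self.output_params = LayerParams(N=n_out)
        if self.input_params is None:
            # input units share the trace constants of the hidden layer
            self.input_params = replace(self.hidden_params, N=n_in)
        if self.hidden_params.N != n_hid or self.output_params.N != n_out \
                or self.input_params.N != n_in:
            raise ValueError("LayerParams.N inconsistent with layer_sizes")
        dts = {self.input_params.dt, self.hidden_params.dt, self.output_params.dt}
        if len(dts) != 1:
            raise ValueError("all layers must share one simulation step dt")
        if self.feedforward_rule not in ("activity_difference", "bcm"):
            raise ValueError(f"unknown feedforward_rule {self.feedforward_rule!r}")

    @property
    def dt(self) -> float:
        return self.hidden_params.dt


@dataclass
class Network:
    """Live simulation state: layer states, connection groups, and the clock."""

    config: NetworkConfig
    states: dict          # {"input", "hidden", "output"} -> NeuronLayerState
    groups: dict          # connection name -> ConnectionGroup (enabled only)
    t_now: float = 0.0

    def snapshot(self) -> dict:
        """Deep copy of everything that evolves, for save/restore."""
        return {
            "states": {k: s.copy() for k, s in self.states.items()},
            "groups": {k: g.copy() for k, g in self.groups.items()},
            "t_now": self.t_now,
        }

    def restore(self, snap: dict) -> None:
        self.states = {k: s.copy() for k, s in snap["states"].items()}
        self.groups = {k: g.copy() for k, g in snap["groups"].items()}
        self.t_now = snap["t_now"]

    def copy(self) -> "Network":
        net = Network(config=copy.deepcopy(self.config), states={}, groups={})
        net.restore(self.snapshot())
        return net

    def weight_checksum(self) -> float:
        return float(sum(g.W.sum() for g in self.groups.values()))


def build_network(config: NetworkConfig, rng: np.random.Generator | None = None
                  ) -> Network:
    """Construct and initialize a network from its config.

    Feedforward weights start uniform on [0, 1]; lateral inhibitory weights
    start at -1 (maximal competition, zero diagonal); reciprocal weights
    start at 0 and can only grow through learning.  Deterministic given the
    config seed.
    """
    n_in, n_hid, n_out = config.layer_sizes
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB111D]))
    tau_lat = (config.tau_decay if config.tau_decay_lateral is None
               else config.tau_decay_lateral)

    def ff(shape, lr):
        return ConnectionGroup(W=rng.uniform(0.0, 1.0, size=shape),
                               kind=ConnectionKind.FEEDFORWARD,
                               learning_rate=lr, tau_decay=config.tau_decay)

    groups = {
        "in_hid": ff((n_in, n_hid), config.alpha),
        "hid_out": ff((n_hid, n_out), config.alpha),
    }
    if config.enabled["reciprocal"]:
        groups["rec"] = ConnectionGroup(
            W=np.zeros((n_out, n_hid)), kind=ConnectionKind.RECIPROCAL,
            learning_rate=config.beta, tau_decay=config.tau_decay)
    if config.enabled["hidden_inhibition"]:
        W = -np.ones((n_hid, n_hid))
        np.fill_diagonal(W, 0.0)
        groups["lat_hid"] = ConnectionGroup(
            W=W, kind=ConnectionKind.LATERAL_HIDDEN,
            learning_rate=config.eta, tau_decay=tau_lat)
    if config.enabled["output_inhibition"]:
        W = -np.ones((n_out, n_out))
        np.fill_diagonal(W, 0.0)
        groups["lat_out"] = ConnectionGroup(
            W=W, kind=ConnectionKind.LATERAL_OUTPUT,
            learning_rate=config.gamma, tau_decay=tau_lat)

    states = {
        "input": NeuronLayerState.zeros(config.input_params),
        "hidden": NeuronLayerState.zeros(config.hidden_params),
        "output": NeuronLayerState.zeros(config.output_params),
    }
    return Network(config=config, states=states, groups=groups, t_now=0.0)


def compute_currents(net: Network, supervised_target: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Input currents for the hidden and output layers from current traces."""
    cfg = net.config
    bal = cfg.balancing
    a_in = net.states["input"].a
    a_hid = net.states["hidden"].a
    a_out = net.states["output"].a

    I_hidden = bal.c_ff_hidden * (a_in @ net.groups["in_hid"].W)
    if "lat_hid" in net.groups:
        I_hidden += bal.c_lat_hidden * (a_hid @ net.groups["lat_hid"].W)
    if "rec" in net.groups:
        I_hidden += bal.c_rec * (a_out @ net.groups["rec"].W)

    I_output = bal.c_ff_output * (a_hid @ net.groups["hid_out"].W)
    if "lat_out" in net.groups:
        I_output += bal.c_lat_output * (a_out @ net.groups["lat_out"].W)

    if supervised_target is not None:
        n_out = cfg.layer_sizes[2]
        if not 0 <= supervised_target < n_out:
            raise ValueError(
                f"supervised_target {supervised_target} out of range "
                f"for {n_out} output neurons")
        I_output[supervised_target] += cfg.I_supervised
    return I_hidden, I_output


def simulate_step(net: Network, input_spikes: np.ndarray,
                  supervised_target: int | None = None,
                  learning: bool = True) -> Network:
    """Advance the whole network by one time step (mutates ``net``).

    Order: input-trace update from the given spikes; currents; membrane
    integration and spike detection in hidden and output layers; threshold
    adaptation; trace updates; plasticity (when ``learning``); clock advance.
    With ``learning=False`` both the rules and the weight decay are
    suspended, so evaluation passes leave every weight untouched.
    """
    cfg = net.config
    input_spikes = np.asarray(input_spikes)
    if input_spikes.shape != (cfg.layer_sizes[0],):
        raise ValueError(
            f"input_spikes must have shape ({cfg.layer_sizes[0]},), "
            f"got {input_spikes.shape}")

    inp = net.states["input"]
    hid = net.states["hidden"]
    out = net.states["output"]

    inp.spiked = input_spikes.astype(float)
    step_activity(inp, cfg.input_params)

    I_hidden, I_output = compute_currents(net, supervised_target)

    step_membrane(hid, I_hidden, cfg.hidden_params)
    step_membrane(out, I_output, cfg.output_params)
    step_threshold(hid, cfg.hidden_params)
    step_threshold(out, cfg.output_params)
    step_activity(hid, cfg.hidden_params)
    step_activity(out, cfg.output_params)

    t_spike = net.t_now + cfg.dt
    if learning:
        hid_spiked = hid.spiked.any()
        out_spiked = out.spiked.any()
        if hid_spiked:
            if cfg.feedforward_rule == "bcm":
                from .plasticity import update_bcm
                update_bcm(net.groups["in_hid"], inp, hid, hid.spiked,
                           cfg.alpha, t_spike)
            else:
                update_feedforward(net.groups["in_hid"], inp, hid.spiked,
                                   cfg.alpha, t_spike)
        if out_spiked:
            if cfg.feedforward_rule == "bcm":
                from .plasticity import update_bcm
                update_bcm(net.groups["hid_out"], hid, out, out.spiked,
                           cfg.alpha, t_spike)
            else:
                update_feedforward(net.groups["hid_out"], hid, out.spiked,
                                   cfg.alpha, t_spike)
            if "rec" in net.groups:
                update_reciprocal(net.groups["rec"], net.groups["hid_out"],
                                  hid, out.spiked, cfg.beta, t_spike)
            if "lat_out" in net.groups:
                update_output_inhibition(net.groups["lat_out"], out, out.spiked,
                                         cfg.gamma, t_spike)
        if hid_spiked and "lat_hid" in net.groups:
            update_hidden_lateral(net.groups["lat_hid"], hid, hid.spiked,
                                  cfg.eta, t_spike)
    net.t_now = t_spike
    return net
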