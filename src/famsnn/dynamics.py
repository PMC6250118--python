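"""Single-layer spiking dynamics.

A layer of leaky integrate-and-fire (LIF) neurons with three coupled pieces of
per-neuron state:

* the membrane potential ``V``, integrated with explicit Euler,
  ``tau_m * dV/dt = -V + I``;
* an adaptive threshold component ``V_th`` that decays exponentially with time
  constant ``tau_th`` and jumps by a fixed increment whenever the neuron
  spikes, equalizing competition between neurons of very different drive;
* two exponential moving averages (EMAs) of the spike train: a fast "instant
  activity" ``a`` (time constant ``tau_a``) and a slow "average activity"
  ``theta`` (time constant ``tau_theta``).  All plasticity rules act on the
  difference ``a - theta``, which behaves as a novelty detector: it is
  positive while a neuron fires above its recent average and negative when it
  falls below it.

Input-layer units are pure Poisson generators and have no membrane, but they
carry ``a``/``theta`` traces because downstream currents and weight updates
are computed from pre-synaptic instant activities.

All state updates mutate the :class:`NeuronLayerState` in place and return it,
so they can be chained; a fresh state is cheap to create via
:meth:`NeuronLayerState.zeros`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerParams",
    "NeuronLayerState",
    "step_activity",
    "step_membrane",
    "step_threshold",
    "lif_isi_closed_form",
    "threshold_increment",
]

#: Allowed scalings of the per-spike threshold increment with layer size N.
THRESHOLD_SCALINGS = ("divide", "multiply", "none")


@dataclass
class LayerParams:
    """Parameters of one neuron layer.

    Times are in milliseconds; potentials, currents and thresholds share one
    arbitrary unit (a.u.).  Defaults are the reference simulation values.
    """

    N: int
    tau_m: float = 20.0       # membrane time constant, ms
    tau_ref: float = 2.0      # refractory period, ms
    tau_th: float = 50.0      # threshold decay constant, ms
    delta_V_th: float = 0.1   # threshold increment constant, a.u.
    V_th_init: float = 0.1    # initial adaptive-threshold value, a.u.
    V_th_floor: float = 0.0   # static threshold baseline added to V_th, a.u.
    tau_a: float = 15.0       # instant-activity EMA time constant, ms
    tau_theta: float = 150.0  # average-activity EMA time constant, ms
    dt: float = 1.0           # simulation step, ms
    threshold_scaling: str = "divide"  # how delta_V_th couples to N

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"layer size N must be >= 1, got {self.N}")
        for name in ("tau_m", "tau_th", "tau_a", "tau_theta", "dt"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.tau_ref < 0:
            raise ValueError(f"tau_ref must be >= 0, got {self.tau_ref}")
        if not self.tau_a < self.tau_theta:
            raise ValueError(
                f"tau_a ({self.tau_a}) must be smaller than tau_theta "
                f"({self.tau_theta}); the plasticity drive a - theta needs a "
                "fast and a slow trace"
            )
        if not self.dt < min(self.tau_a, self.tau_m, self.tau_th):
            raise ValueError(
                f"dt ({self.dt}) must be smaller than every time constant it "
                "discretizes (tau_a, tau_m, tau_th)"
            )
        if self.delta_V_th < 0 or self.V_th_init < 0 or self.V_th_floor < 0:
            raise ValueError("threshold constants must be >= 0")
        if self.threshold_scaling not in THRESHOLD_SCALINGS:
            raise ValueError(
                f"threshold_scaling must be one of {THRESHOLD_SCALINGS}, "
                f"got {self.threshold_scaling!r}"
            )


def threshold_increment(params: LayerParams) -> float:
    """Per-spike increment of the adaptive threshold.

    The increment couples to the layer size ``N``: dividing by ``N``
    (default) keeps the summed adaptation per layer constant, multiplying
    makes the threshold a strong per-neuron rate controller.  Both readings
    are selectable because the coupling direction is a modelling choice.
    """
    if params.threshold_scaling == "divide":
        return params.delta_V_th / params.N
    if params.threshold_scaling == "multiply":
        return params.delta_V_th * params.N
    return params.delta_V_th


@dataclass
class NeuronLayerState:
    """Mutable per-neuron state of one layer (arrays of length ``N``)."""

    V: np.ndarray                     # membrane potential, a.u.
    V_th: np.ndarray                  # adaptive threshold component, a.u.
    refractory_remaining: np.ndarray  # time left refractory, ms
    a: np.ndarray                     # instant activity, spikes/ms
    theta: np.ndarray                 # average activity, spikes/ms
    spiked: np.ndarray = field(default=None)  # 0/1 spike flag this step

    def __post_init__(self) -> None:
        if self.spiked is None:
            self.spiked = np.zeros_like(self.V)

    @classmethod
    def zeros(cls, params: LayerParams) -> "NeuronLayerState":
        n = params.N
        return cls(
            V=np.zeros(n),
            V_th=np.full(n, float(params.V_th_init)),
            refractory_remaining=np.zeros(n),
            a=np.zeros(n),
            theta=np.zeros(n),
            spiked=np.zeros(n),
        )

    def copy(self) -> "NeuronLayerState":
        return NeuronLayerState(
            V=self.V.copy(),
            V_th=self.V_th.copy(),
            refractory_remaining=self.refractory_remaining.copy(),
            a=self.a.copy(),
            theta=self.theta.copy(),
            spiked=self.spiked.copy(),
        )


def step_activity(state: NeuronLayerState, params: LayerParams) -> NeuronLayerState:
    """Advance the two EMA activity traces by one step.

    ``a <- (1 - dt/tau_a) a + s/tau_a`` and the same for ``theta`` with
    ``tau_theta``, where ``s`` is the binary spike indicator already set for
    this step.  With per-step spike probability ``p`` the stationary mean of
    both traces is ``p/dt`` (a firing rate in spikes/ms).
    """
    dt = params.dt
    s = state.spiked
    state.a *= 1.0 - dt / params.tau_a
    state.a += s / params.tau_a
    state.theta *= 1.0 - dt / params.tau_theta
    state.theta += s / params.tau_theta
    if not math.isfinite(float(state.a.sum() + state.theta.sum())):
        # non-finite traces can only come from a mis-configured layer
        raise FloatingPointError(
            "activity traces became non-finite; check tau_a/tau_theta/dt"
        )
    return state


def step_membrane(
    state: NeuronLayerState, I: np.ndarray, params: LayerParams
) -> NeuronLayerState:
    """One explicit-Euler membrane step with spike detection and reset.

    Non-refractory neurons integrate ``V += (dt/tau_m)(-V + I)`` and fire
    when ``V`` reaches the effective threshold ``V_th_floor + V_th``; a firing
    neuron resets ``V`` to 0 and becomes refractory for ``tau_ref``.
    Refractory neurons are clamped at ``V = 0``, receive no current, and run
    down their refractory timer.  A neuron can spike only if its timer was
    already 0 at the start of the step, so the minimum inter-spike interval is
    ``tau_ref + dt``.
    """
    dt = params.dt
    eligible = state.refractory_remaining <= 0.0
    refr = ~eligible

    state.V[eligible] += (dt / params.tau_m) * (-state.V[eligible] + I[eligible])
    state.V[refr] = 0.0
    state.refractory_remaining[refr] = np.maximum(
        state.refractory_remaining[refr] - dt, 0.0
    )

    thresh = params.V_th_floor + state.V_th
    fired = eligible & (state.V >= thresh)
    state.spiked = fired.astype(float)
    state.V[fired] = 0.0
    state.refractory_remaining[fired] = params.tau_ref
    return state


def step_threshold(state: NeuronLayerState, params: LayerParams) -> NeuronLayerState:
    """Decay the adaptive threshold and bump it for neurons that just spiked.

    ``V_th <- V_th (1 - dt/tau_th) + increment * spiked`` with the increment
    given by :func:`threshold_increment`.  ``V_th`` stays non-negative.
    """
    state.V_th *= 1.0 - params.dt / params.tau_th
    if state.spiked.any():
        state.V_th += threshold_increment(params) * state.spiked
    return state


def lif_isi_closed_form(I: float, V_thr: float, params: LayerParams) -> float:
    """Exact inter-spike interval of a LIF neuron under constant current.

    For constant supra-threshold current ``I`` and a fixed firing threshold
    ``V_thr`` (no adaptation), integrating the membrane equation from the
    post-spike reset ``V = 0`` gives

        ISI = tau_ref + tau_m * ln(I / (I - V_thr)).

    Used as an independent oracle for the simulated dynamics.
    """
    if not V_thr > 0:
        raise ValueError(f"V_thr must be positive, got {V_thr}")
    if not I > V_thr:
        raise ValueError(
            f"current I={I} must exceed the threshold V_thr={V_thr}; "
            "otherwise the neuron never fires"
        )
    return params.tau_ref + params.tau_m * math.log(I / (I - V_thr))
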