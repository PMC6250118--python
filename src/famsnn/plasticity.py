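"""Local, event-driven synaptic plasticity.

Every rule in this module follows one principle: a neuron tries to maximize
its own firing activity while competing with its neighbours for limited
drive.  The rules are rate-based (BCM-like) rather than spike-timing based:
they read the difference between a neuron's fast and slow activity EMAs,
``a - theta``, and they are applied only at the moments a relevant neuron
spikes.  Each weight also decays exponentially toward 0 with time constant
``tau_decay``; because the rules are event-driven, the decay is applied
lazily, as a single exponential factor over the time elapsed since the
weight was last touched, which is exactly equivalent to integrating the
decay term continuously.

The four connection kinds and their rules:

``feedforward`` (bounds [0, 1])
    At a spike of post-synaptic neuron j:  ``w_ij += alpha (a_i - theta_i)``.
    The post neuron strengthens synapses from pre neurons that are more
    active than their own average and weakens the rest.

``reciprocal`` (bounds [0, 1], output layer back onto hidden)
    At a spike of output neuron k:  ``w_kj += beta (a_j - theta_j) w_jk``.
    The output neuron feeds extra current back to currently-active hidden
    neurons, gated by the strength of the forward synapse it receives from
    them.

``lateral_output`` (bounds [-1, 0], within the output layer)
    At a spike of output neuron k':  ``w_kk' -= gamma (a_k - theta_k)``.
    A highly active competitor k strengthens (makes more negative) its
    inhibition onto the spiker; a weakly active one relinquishes it.

``lateral_hidden`` (bounds [-1, 0], within the hidden layer)
    At a spike of hidden neuron j:  ``w_jj' += eta (a_j - theta_j)(a_j' -
    theta_j')``.  Co-active pairs relax their mutual inhibition toward 0
    (cooperation — the seed of neuron "families"); discordant pairs drive it
    toward -1 (competition).

An optional classical BCM rule is provided for feedforward connections for
rule-comparison experiments; it multiplies the pre-synaptic rate in instead
of the pre-synaptic rate *difference*.

Index convention: ``W[pre, post]`` throughout.  For the lateral kinds
``W[j, jp]`` is the inhibitory synapse from j onto jp and the diagonal is
structurally zero (no self-inhibition).

Update order within one event is fixed: lazy decay, then the rule increment,
then clamping to the kind's bounds.  Weights stick at the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .dynamics import NeuronLayerState

__all__ = [
    "ConnectionKind",
    "ConnectionGroup",
    "lazy_decay",
    "clamp",
    "update_feedforward",
    "update_reciprocal",
    "update_output_inhibition",
    "update_hidden_lateral",
    "update_bcm",
]


class ConnectionKind(str, Enum):
    FEEDFORWARD = "feedforward"
    RECIPROCAL = "reciprocal"
    LATERAL_OUTPUT = "lateral_output"
    LATERAL_HIDDEN = "lateral_hidden"

    @property
    def bounds(self) -> tuple[float, float]:
        if self in (ConnectionKind.FEEDFORWARD, ConnectionKind.RECIPROCAL):
            return (0.0, 1.0)
        return (-1.0, 0.0)

    @property
    def lateral(self) -> bool:
        return self in (ConnectionKind.LATERAL_OUTPUT, ConnectionKind.LATERAL_HIDDEN)


@dataclass
class ConnectionGroup:
    """One weight matrix ``W[pre, post]`` with its plasticity bookkeeping."""

    W: np.ndarray
    kind: ConnectionKind
    learning_rate: float
    tau_decay: float = 10_000.0  # ms
    plastic: bool = True
    last_update_time: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.kind = ConnectionKind(self.kind)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be a 2-D matrix [pre, post]")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive (np.inf disables decay)")
        if self.kind.lateral:
            if self.W.shape[0] != self.W.shape[1]:
                raise ValueError("lateral weight matrices must be square")
            if np.any(np.diag(self.W) != 0.0):
                raise ValueError("lateral matrices must have a zero diagonal "
                                 "(no self-inhibition)")
        lo, hi = self.kind.bounds
        if np.any(self.W < lo) or np.any(self.W > hi):
            raise ValueError(f"weights outside bounds [{lo}, {hi}] for {self.kind}")
        if self.last_update_time is None:
            self.last_update_time = np.zeros_like(self.W)
        elif self.last_update_time.shape != self.W.shape:
            raise ValueError("last_update_time must match W's shape")

    @property
    def bounds(self) -> tuple[float, float]:
        return self.kind.bounds

    def copy(self) -> "ConnectionGroup":
        return ConnectionGroup(
            W=self.W.copy(),
            kind=self.kind,
            learning_rate=self.learning_rate,
            tau_decay=self.tau_decay,
            plastic=self.plastic,
            last_update_time=self.last_update_time.copy(),
        )


def _zero_diagonal(group: ConnectionGroup, idx: np.ndarray, axis: int) -> None:
    """Restore the structural zero diagonal on touched rows/columns."""
    group.W[idx, idx] = 0.0


def lazy_decay(
    group: ConnectionGroup,
    t_now: float,
    *,
    rows: np.ndarray | None = None,
    cols: np.ndarray | None = None,
) -> ConnectionGroup:
    """Apply the accumulated exponential decay to a subset of weights.

    ``W <- W * exp(-(t_now - last_update_time)/tau_decay)`` for the affected
    weights (all rows/columns when ``rows``/``cols`` are both None; otherwise
    the given rows or columns), then stamps them with ``t_now``.  Decay pulls
    weights of either sign toward 0.
    """
    if rows is not None and cols is not None:
        raise ValueError("pass rows or cols, not both")
    if rows is not None:
        sl = (rows, slice(None))
    elif cols is not None:
        sl = (slice(None), cols)
    else:
        sl = (slice(None), slice(None))
    last = group.last_update_time[sl]
    elapsed = t_now - last
    if np.any(elapsed < 0):
        raise ValueError(
            f"t_now={t_now} is earlier than a stored update timestamp "
            f"(max {last.max()}); simulation clock must be monotone"
        )
    if np.isfinite(group.tau_decay):
        group.W[sl] = group.W[sl] * np.exp(-elapsed / group.tau_decay)
    group.last_update_time[sl] = t_now
    return group


def clamp(group: ConnectionGroup) -> ConnectionGroup:
    """Project every weight onto the group's bounds (weights stick there)."""
    lo, hi = group.kind.bounds
    np.clip(group.W, lo, hi, out=group.W)
    return group


def _clip_slice(group: ConnectionGroup, sl) -> None:
    # fancy-indexed views are copies, so assign the clipped block back
    lo, hi = group.kind.bounds
    group.W[sl] = np.clip(group.W[sl], lo, hi)


def _spike_indices(spikes: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.asarray(spikes) > 0)


def update_feedforward(
    group: ConnectionGroup,
    pre_state: NeuronLayerState,
    post_spikes: np.ndarray,
    alpha: float,
    t_now: float,
) -> ConnectionGroup:
    """Activity-maximization rule for excitatory feedforward synapses.

    For every post neuron j that spiked this step, its incoming column is
    decayed and then incremented by ``alpha * (a_pre - theta_pre)``.
    """
    if group.kind is not ConnectionKind.FEEDFORWARD:
        raise ValueError(f"expected a feedforward group, got {group.kind}")
    if not group.plastic:
        return group
    js = _spike_indices(post_spikes)
    if js.size == 0:
        return group
    lazy_decay(group, t_now, cols=js)
    drive = alpha * (pre_state.a - pre_state.theta)
    group.W[:, js] += drive[:, None]
    _clip_slice(group, (slice(None), js))
    return group


def update_reciprocal(
    rec_group: ConnectionGroup,
    fwd_group: ConnectionGroup,
    hidden_state: NeuronLayerState,
    output_spikes: np.ndarray,
    beta: float,
    t_now: float,
) -> ConnectionGroup:
    """Backward (output-to-hidden) excitatory rule.

    At a spike of output neuron k, row k of the reciprocal matrix grows by
    ``beta * (a_hid - theta_hid) * w_forward``, where ``w_forward`` is read
    from the matching hidden-to-output group at its current value.
    """
    if rec_group.kind is not ConnectionKind.RECIPROCAL:
        raise ValueError(f"expected a reciprocal group, got {rec_group.kind}")
    if rec_group.W.shape != fwd_group.W.shape[::-1]:
        raise ValueError(
            f"reciprocal shape {rec_group.W.shape} does not match transposed "
            f"forward shape {fwd_group.W.shape[::-1]}"
        )
    if not rec_group.plastic:
        return rec_group
    ks = _spike_indices(output_spikes)
    if ks.size == 0:
        return rec_group
    lazy_decay(rec_group, t_now, rows=ks)
    diff = hidden_state.a - hidden_state.theta
    rec_group.W[ks, :] += beta * diff[None, :] * fwd_group.W[:, ks].T
    _clip_slice(rec_group, (ks, slice(None)))
    return rec_group


def update_output_inhibition(
    group: ConnectionGroup,
    output_state: NeuronLayerState,
    output_spikes: np.ndarray,
    gamma: float,
    t_now: float,
) -> ConnectionGroup:
    """Learnable winner-take-all competition in the output layer.

    At a spike of output neuron k', every incoming lateral weight changes by
    ``-gamma * (a_k - theta_k)``: competitors that are more active than their
    average deepen their inhibition onto the spiker.
    """
    if group.kind is not ConnectionKind.LATERAL_OUTPUT:
        raise ValueError(f"expected a lateral_output group, got {group.kind}")
    if not group.plastic:
        return group
    kps = _spike_indices(output_spikes)
    if kps.size == 0:
        return group
    lazy_decay(group, t_now, cols=kps)
    diff = output_state.a - output_state.theta
    group.W[:, kps] -= gamma * diff[:, None]
    _zero_diagonal(group, kps, axis=1)
    _clip_slice(group, (slice(None), kps))
    return group


def update_hidden_lateral(
    group: ConnectionGroup,
    hidden_state: NeuronLayerState,
    hidden_spikes: np.ndarray,
    eta: float,
    t_now: float,
) -> ConnectionGroup:
    """Cooperation/competition rule inside the hidden layer.

    At a spike of hidden neuron j, its outgoing row changes by
    ``eta * (a_j - theta_j)(a_j' - theta_j')``: concordant activity relaxes
    mutual inhibition (families form), discordant activity deepens it.
    The matrix is not forced symmetric; analysis symmetrizes when needed.
    """
    if group.kind is not ConnectionKind.LATERAL_HIDDEN:
        raise ValueError(f"expected a lateral_hidden group, got {group.kind}")
    if not group.plastic:
        return group
    js = _spike_indices(hidden_spikes)
    if js.size == 0:
        return group
    lazy_decay(group, t_now, rows=js)
    diff = hidden_state.a - hidden_state.theta
    group.W[js, :] += eta * diff[js, None] * diff[None, :]
    _zero_diagonal(group, js, axis=0)
    _clip_slice(group, (js, slice(None)))
    return group


def update_bcm(
    group: ConnectionGroup,
    pre_state: NeuronLayerState,
    post_state: NeuronLayerState,
    post_spikes: np.ndarray,
    rate: float,
    t_now: float,
) -> ConnectionGroup:
    """Classical BCM-style alternative for feedforward synapses.

    At a spike of post neuron j: ``w_ij += rate * a_i * (a_j - theta_j)``.
    The sliding-threshold factor acts on the *post*-synaptic rate difference,
    and the pre rate enters multiplicatively; the post-rate factor of the
    continuous rule is absorbed by triggering on post spikes.
    """
    if group.kind is not ConnectionKind.FEEDFORWARD:
        raise ValueError(f"expected a feedforward group, got {group.kind}")
    if not group.plastic:
        return group
    js = _spike_indices(post_spikes)
    if js.size == 0:
        return group
    lazy_decay(group, t_now, cols=js)
    post_diff = post_state.a - post_state.theta
    group.W[:, js] += rate * pre_state.a[:, None] * post_diff[js][None, :]
    _clip_slice(group, (slice(None), js))
    return group
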