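"""Reference experiment presets.

:func:`synthetic_default` is the desk-scale reference condition used
throughout the test-suite and the reproduction script: the 5-class 16x16
synthetic prototype task, a 256-30-5 network, and a supervised schedule of
1,000 presentations.  Balancing coefficients and threshold settings here
were calibrated once on pilot runs (see docs/methods.md) and are part of the
reference condition.

:func:`mnist_default` is the overnight full-scale condition (784-100-10 on
IDX files) with the reference hyperparameter table; it requires the MNIST
files locally and several hours of CPU time.
"""

from __future__ import annotations

from .config import DataSpec, ExperimentConfig
from .dynamics import LayerParams
from .network import BalancingCoefficients, NetworkConfig
from .stimuli import StimulusProtocol, SyntheticSpec
from .training import TrainSchedule

__all__ = ["synthetic_default", "mnist_default"]


def synthetic_default(seed: int = 0, mode: str = "supervised",
                      n_train_total: int = 1000) -> ExperimentConfig:
    """Desk-scale reference experiment (see docs/methods.md for rationale)."""
    n_in, n_hid, n_out = 256, 30, 5
    layer_kw = dict(
        tau_m=20.0, tau_ref=2.0, tau_th=50.0, delta_V_th=0.1,
        V_th_init=0.0, V_th_floor=0.1, tau_a=15.0, tau_theta=150.0,
        dt=1.0, threshold_scaling="none",
    )
    # the hidden layer uses a slow, small threshold adaptation: fatigue that
    # outlives one presentation spreads neurons across classes (homeostatic
    # recruitment) at this small scale
    hidden_kw = dict(layer_kw, tau_th=1500.0, delta_V_th=0.04)
    network = NetworkConfig(
        layer_sizes=(n_in, n_hid, n_out),
        hidden_params=LayerParams(N=n_hid, **hidden_kw),
        output_params=LayerParams(N=n_out, **layer_kw),
        input_params=LayerParams(N=n_in, **layer_kw),
        balancing=BalancingCoefficients(
            c_ff_hidden=0.03, c_ff_output=1.0,
            c_lat_hidden=0.75, c_lat_output=1.0, c_rec=2.0,
        ),
        alpha=0.3, beta=0.3, gamma=0.1, eta=5.0,
        tau_decay=100_000.0, tau_decay_lateral=float("inf"),
        I_supervised=30.0, seed=seed,
    )
    protocol = StimulusProtocol(T_input=100.0, T_silence=100.0,
                                rate_max=250.0, readout_window=(50.0, 100.0))
    schedule = TrainSchedule(mode=mode, n_supervised=50,
                             n_train_total=n_train_total,
                             eval_every=100, n_eval=100)
    data = DataSpec(kind="synthetic", synthetic=SyntheticSpec(seed=seed))
    return ExperimentConfig(network=network, protocol=protocol,
                            schedule=schedule, data=data, seed=seed)


def mnist_default(train_images: str, train_labels: str, test_images: str,
                  test_labels: str, seed: int = 0,
                  mode: str = "supervised", n_hidden: int = 100
                  ) -> ExperimentConfig:
    """Full-scale 784-N-10 condition on locally available IDX files."""
    network = NetworkConfig(layer_sizes=(784, n_hidden, 10), seed=seed)
    protocol = StimulusProtocol()
    schedule = TrainSchedule(mode=mode, n_supervised=400,
                             n_train_total=30_400, eval_every=50,
                             n_eval=None)
    data = DataSpec(kind="idx", train_images=train_images,
                    train_labels=train_labels, test_images=test_images,
                    test_labels=test_labels)
    return ExperimentConfig(network=network, protocol=protocol,
                            schedule=schedule, data=data, seed=seed)
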