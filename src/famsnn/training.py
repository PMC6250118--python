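"""Presentation loop, teacher scheduling, readout, and evaluation.

An image presentation runs ``T_input`` ms of Poisson-coded input (plus a
constant teacher current into the true class's output neuron when a label is
supplied) followed by ``T_silence`` ms of empty input with no teacher.  The
network's answer is the argmax over output neurons of the time-mean instant
activity inside the readout window (50-100 ms of the stimulus by default);
ties break to the lowest class index, so a completely silent output layer
answers class 0.

Three schedules are supported: ``supervised`` (teacher on every image),
``partial_unsupervised`` (teacher only on the first ``n_supervised`` images,
then learning continues from the same local rules without any label), and
``unsupervised`` (no teacher at all; learning leans entirely on random
initial similarities).

Evaluation freezes everything: plasticity and weight decay are off, and the
dynamic state (potentials, traces, thresholds, clock) is restored afterwards,
so an evaluation is invisible to the training trajectory and repeatable
bit-for-bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .network import Network, simulate_step
from .stimuli import Dataset, StimulusProtocol, encode_poisson

__all__ = ["TrainSchedule", "LearningCurve", "PresentationRecord",
           "present_image", "evaluate", "train"]

MODES = ("supervised", "partial_unsupervised", "unsupervised")


@dataclass
class TrainSchedule:
    """How many images to present and when the teacher is active."""

    mode: str = "supervised"
    n_supervised: int = 400      # teacher-on prefix in partial mode
    n_train_total: int = 1000    # images presented
    eval_every: int = 50         # images between test evaluations
    n_eval: int | None = None    # test images per evaluation (None = all)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")
        if (self.mode == "partial_unsupervised"
                and self.n_supervised > self.n_train_total):
            raise ValueError("n_supervised cannot exceed n_train_total")

    def teacher_active(self, image_index: int) -> bool:
        if self.mode == "supervised":
            return True
        if self.mode == "partial_unsupervised":
            return image_index < self.n_supervised
        return False


@dataclass
class LearningCurve:
    """(images_seen, test accuracy) pairs collected during training."""

    points: list = field(default_factory=list)  # (images_seen, accuracy)
    mode: str = "supervised"
    seed: int = 0

    def append(self, images_seen: int, accuracy: float) -> None:
        if self.points and images_seen <= self.points[-1][0]:
            raise ValueError("images_seen must be strictly increasing")
        if not 0.0 <= accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        self.points.append((images_seen, accuracy))

    @property
    def final_accuracy(self) -> float:
        return self.points[-1][1]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["images_seen", "accuracy"])
            writer.writerows(self.points)


@dataclass
class PresentationRecord:
    """Diagnostics from one presentation."""

    prediction: int
    readout: np.ndarray           # window-mean instant activity per class
    output_spike_counts: np.ndarray
    hidden_spike_counts: np.ndarray


def present_image(net: Network, image: np.ndarray, label: int | None,
                  protocol: StimulusProtocol,
                  rng: np.random.Generator, learning: bool = True,
                  readout: str = "activity") -> PresentationRecord:
    """Present one image (stimulus + silence) and read out the answer.

    ``readout`` may be ``"activity"`` (window-mean instant activity, the
    default) or ``"threshold"`` (window-mean adaptive threshold, which
    tracks firing rate closely and can serve as an alternative response
    variable).
    """
    cfg = net.config
    n_out = cfg.layer_sizes[2]
    if label is not None and not 0 <= label < n_out:
        raise ValueError(f"label {label} out of range for {n_out} classes")
    if readout not in ("activity", "threshold"):
        raise ValueError(f"unknown readout {readout!r}")

    spikes = encode_poisson(image, protocol, rng)
    zeros = np.zeros(cfg.layer_sizes[0])
    start, end = protocol.readout_window
    dt = protocol.dt

    acc = np.zeros(n_out)
    n_window = 0
    out_counts = np.zeros(n_out)
    hid_counts = np.zeros(cfg.layer_sizes[1])
    out_state = net.states["output"]

    for i in range(protocol.n_input_steps):
        simulate_step(net, spikes[i], supervised_target=label,
                      learning=learning)
        out_counts += out_state.spiked
        hid_counts += net.states["hidden"].spiked
        t_in_stim = i * dt  # time at the start of this step
        if start <= t_in_stim < end:
            acc += out_state.V_th if readout == "threshold" else out_state.a
            n_window += 1
    for _ in range(protocol.n_silence_steps):
        simulate_step(net, zeros, supervised_target=None, learning=learning)

    mean = acc / max(n_window, 1)
    return PresentationRecord(prediction=int(np.argmax(mean)), readout=mean,
                              output_spike_counts=out_counts,
                              hidden_spike_counts=hid_counts)


def evaluate(net: Network, test_set: Dataset, protocol: StimulusProtocol,
             seed: int = 0, n_eval: int | None = None,
             readout: str = "activity") -> float:
    """Frozen-weight accuracy on (a seeded subsample of) the test set.

    Plasticity and decay are off, and the full dynamic state is restored
    afterwards, so evaluation neither erodes weights nor perturbs the
    training trajectory.  The same seed gives bit-identical results.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE7A1]))
    # shuffled order: adaptation carries across images, so presenting a test
    # set grouped by class would fatigue each class's assembly in turn
    idx = rng.permutation(len(test_set))
    if n_eval is not None and n_eval < len(test_set):
        idx = idx[:n_eval]

    snap = net.snapshot()
    correct = 0
    for i in idx:
        rec = present_image(net, test_set.images[i], None, protocol, rng,
                            learning=False, readout=readout)
        if rec.prediction == test_set.labels[i]:
            correct += 1
    net.restore(snap)
    return correct / len(idx)


def train(net: Network, dataset: Dataset, schedule: TrainSchedule,
          protocol: StimulusProtocol, test_set: Dataset | None = None,
          seed: int = 0, progress: callable = None
          ) -> tuple[LearningCurve, Network]:
    """Run one training schedule, evaluating periodically.

    The training set is shuffled once (seeded) and presented sequentially,
    cycling if ``n_train_total`` exceeds its size.  Every ``eval_every``
    presentations — and once more at the end — the test accuracy is appended
    to the learning curve.  Identical seeds and configs reproduce the curve
    bit-for-bit.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    ss = np.random.SeedSequence([seed, 0x7EA0])
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    encode_rng = np.random.default_rng(ss.spawn(1)[0])
    eval_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2 ** 31))

    order = shuffle_rng.permutation(len(dataset))
    curve = LearningCurve(mode=schedule.mode, seed=seed)

    def run_eval(images_seen: int) -> None:
        if test_set is None:
            return
        acc = evaluate(net, test_set, protocol, seed=eval_seed,
                       n_eval=schedule.n_eval)
        curve.append(images_seen, acc)
        if progress is not None:
            progress(images_seen, acc)

    for i in range(schedule.n_train_total):
        j = order[i % len(order)]
        label = int(dataset.labels[j]) if schedule.teacher_active(i) else None
        present_image(net, dataset.images[j], label, protocol, encode_rng,
                      learning=True)
        seen = i + 1
        if seen % schedule.eval_every == 0 and seen < schedule.n_train_total:
            run_eval(seen)
    run_eval(schedule.n_train_total)
    return curve, net
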