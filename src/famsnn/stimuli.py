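"""Stimulus generation: rate coding, IDX ingestion, synthetic patterns.

Images are presented to the network as Poisson spike trains: each pixel of
intensity ``p`` (0-255) spikes independently at every step with probability
``(p/255) * rate_max * dt / 1000`` — the dt-discretization of a Poisson
process whose rate is linear in intensity, capped at ``rate_max`` (250 Hz by
default).  A stimulus lasts ``T_input`` ms and is followed by ``T_silence``
ms of empty input so currents and activities can relax before the next
image; there is no state reset between images.

The built-in synthetic generator provides a desk-scale stand-in for a digit
benchmark: K random binary prototypes over a small pixel grid, corrupted per
sample by independent pixel flips and multiplicative intensity jitter.  The
standard MNIST-style IDX container (optionally gzipped) is also readable, so
the same pipelines run on real handwritten-digit data when the files are
available locally.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusProtocol", "SyntheticSpec", "Dataset", "SyntheticDataset",
           "encode_poisson", "read_idx", "generate_synthetic"]

_IDX_IMAGE_MAGIC = 0x00000803
_IDX_LABEL_MAGIC = 0x00000801


@dataclass
class StimulusProtocol:
    """Timing and intensity scaling of one image presentation."""

    T_input: float = 100.0     # stimulus duration, ms
    T_silence: float = 100.0   # inter-stimulus silence, ms
    rate_max: float = 250.0    # firing rate of a full-intensity pixel, Hz
    readout_window: tuple[float, float] = (50.0, 100.0)  # ms within stimulus
    dt: float = 1.0            # ms; must match the network's dt

    def __post_init__(self) -> None:
        start, end = self.readout_window
        if not (0 <= start < end <= self.T_input):
            raise ValueError(
                f"readout_window {self.readout_window} must satisfy "
                f"0 <= start < end <= T_input ({self.T_input})")
        if self.rate_max * self.dt / 1000.0 > 1.0:
            raise ValueError(
                f"rate_max {self.rate_max} Hz at dt {self.dt} ms implies a "
                "per-step spike probability > 1")
        if self.T_silence < 0:
            raise ValueError("T_silence must be >= 0")

    @property
    def n_input_steps(self) -> int:
        return int(round(self.T_input / self.dt))

    @property
    def n_silence_steps(self) -> int:
        return int(round(self.T_silence / self.dt))


@dataclass
class Dataset:
    """Flat image array ``(n, n_pixels)`` in [0, 255] with integer labels."""

    images: np.ndarray
    labels: np.ndarray
    n_classes: int
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels")
        if self.labels.size and not (
                (self.labels >= 0) & (self.labels < self.n_classes)).all():
            raise ValueError("labels out of range [0, n_classes)")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic class-prototype task.

    Defaults define the reference desk-scale condition: 5 classes of 16x16
    binary prototypes with a quarter of the pixels active, 5% per-pixel flip
    noise, 20% multiplicative intensity jitter, 200 training and 100 test
    samples per class.
    """

    n_classes: int = 5
    image_side: int = 16
    prototype_density: float = 0.25
    noise_flip_prob: float = 0.05
    intensity_jitter: float = 0.2
    n_train_per_class: int = 200
    n_test_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prototype_density < 1:
            raise ValueError(
                f"prototype_density must be in (0, 1) exclusive, got "
                f"{self.prototype_density} (degenerate prototypes)")
        if not 0 <= self.noise_flip_prob < 0.5:
            raise ValueError("noise_flip_prob must be in [0, 0.5)")
        if not 0 <= self.intensity_jitter < 1:
            raise ValueError("intensity_jitter must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_pixels(self) -> int:
        return self.image_side ** 2


@dataclass
class SyntheticDataset:
    train: Dataset
    test: Dataset
    prototypes: np.ndarray  # (n_classes, n_pixels) binary
    spec: SyntheticSpec


def encode_poisson(image: np.ndarray, protocol: StimulusProtocol,
                   rng: np.random.Generator) -> np.ndarray:
    """Poisson-encode one image as a ``(n_input_steps, n_pixels)`` 0/1 array.

    Only the stimulus window is returned; the silent window is by definition
    all zeros and is not materialized.
    """
    image = np.asarray(image, dtype=float).ravel()
    if image.size and (image.min() < 0 or image.max() > 255):
        raise ValueError(
            f"pixel intensities must lie in [0, 255], got range "
            f"[{image.min()}, {image.max()}]")
    p = (image / 255.0) * protocol.rate_max * protocol.dt / 1000.0
    draws = rng.random((protocol.n_input_steps, image.size))
    return (draws < p).astype(np.uint8)


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_idx_array(path, expected_magic: int) -> np.ndarray:
    with _open_maybe_gzip(path) as fh:
        header = fh.read(4)
        if len(header) < 4:
            raise ValueError(f"{path}: truncated before magic (offset 0)")
        (magic,) = struct.unpack(">I", header)
        if magic != expected_magic:
            raise ValueError(
                f"{path}: bad magic 0x{magic:08x} at offset 0, expected "
                f"0x{expected_magic:08x}")
        ndim = magic & 0xFF
        dims = []
        for i in range(ndim):
            raw = fh.read(4)
            if len(raw) < 4:
                raise ValueError(f"{path}: truncated header at offset {4 + 4 * i}")
            dims.append(struct.unpack(">I", raw)[0])
        count = int(np.prod(dims))
        data = fh.read(count)
        if len(data) != count:
            raise ValueError(
                f"{path}: expected {count} data bytes, got {len(data)} "
                f"(truncated at offset {4 + 4 * ndim + len(data)})")
        return np.frombuffer(data, dtype=np.uint8).reshape(dims)


def read_idx(images_path, labels_path) -> Dataset:
    """Read an IDX image/label file pair (gzip-transparent) as a Dataset."""
    images = _read_idx_array(images_path, _IDX_IMAGE_MAGIC)
    labels = _read_idx_array(labels_path, _IDX_LABEL_MAGIC)
    if images.ndim != 3:
        raise ValueError(f"{images_path}: expected 3-D image tensor")
    if len(images) != len(labels):
        raise ValueError(
            f"image/label count mismatch: {len(images)} images in "
            f"{images_path} vs {len(labels)} labels in {labels_path}")
    n, h, w = images.shape
    return Dataset(images=images.reshape(n, h * w).astype(np.uint8),
                   labels=labels.astype(np.int64),
                   n_classes=int(labels.max()) + 1 if n else 0,
                   image_shape=(h, w))


def _sample_class(rng, prototype, spec: SyntheticSpec, n: int) -> np.ndarray:
    flips = rng.random((n, spec.n_pixels)) < spec.noise_flip_prob
    active = np.logical_xor(prototype[None, :].astype(bool), flips)
    jitter = rng.uniform(1.0 - spec.intensity_jitter,
                         1.0 + spec.intensity_jitter,
                         size=(n, spec.n_pixels))
    images = np.where(active, np.clip(255.0 * jitter, 0, 255), 0.0)
    return images.astype(np.uint8)


def generate_synthetic(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a seeded synthetic prototype-classification dataset.

    Each class is a random binary prototype with ``prototype_density`` of
    the pixels active; every sample is its class prototype with independent
    pixel flips and intensity jitter.  Classes are balanced, prototypes are
    pairwise distinct, and the whole dataset is a deterministic function of
    the spec (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5D47A]))
    n_active = max(1, round(spec.prototype_density * spec.n_pixels))
    prototypes = np.zeros((spec.n_classes, spec.n_pixels), dtype=np.uint8)
    seen = set()
    for k in range(spec.n_classes):
        while True:
            idx = rng.choice(spec.n_pixels, size=n_active, replace=False)
            key = tuple(sorted(idx))
            if key not in seen:
                seen.add(key)
                break
        prototypes[k, idx] = 1

    def make_split(n_per_class: int) -> Dataset:
        images, labels = [], []
        for k in range(spec.n_classes):
            images.append(_sample_class(rng, prototypes[k], spec, n_per_class))
            labels.append(np.full(n_per_class, k, dtype=np.int64))
        return Dataset(images=np.concatenate(images),
                       labels=np.concatenate(labels),
                       n_classes=spec.n_classes,
                       image_shape=(spec.image_side, spec.image_side))

    return SyntheticDataset(train=make_split(spec.n_train_per_class),
                            test=make_split(spec.n_test_per_class),
                            prototypes=prototypes, spec=spec)
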