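"""Dataset I/O, normalization, inverse-frequency sampling and augmentation.

Datasets use the MedMNIST3D NPZ dialect: one ``.npz`` file with keys
``{split}_images`` (N x D x H x W, uint8) and ``{split}_labels`` (N x 1,
integer) for splits train/val/test. Reading rescales intensities linearly
to [0, 1] (division by 255) — the only transform ever applied at
validation/test time. A file produced by the phantom generator and a real
MedMNIST3D download are interchangeable here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Dataset",
    "AugmentationPolicy",
    "SamplerWeights",
    "read_npz_dataset",
    "write_npz_dataset",
    "class_sampling_probabilities",
    "augment",
]

SPLITS = ("train", "val", "test")


@dataclass
class Dataset:
    """One split of labelled volumes, intensities already in [0, 1]."""

    images: np.ndarray  # (N, D, H, W) float
    labels: np.ndarray  # (N,) int
    split: str = "train"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels).reshape(-1).astype(int)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"image/label count mismatch: {len(self.images)} vs {len(self.labels)}"
            )
        if self.images.size and not np.all(np.isfinite(self.images)):
            raise ValueError("images contain non-finite values")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def batch(self, idx) -> np.ndarray:
        """Volumes at ``idx`` as a channel-first (B, 1, D, H, W) batch."""
        return self.images[np.asarray(idx)][:, None]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Dual-domain stochastic augmentation policy.

    Spatial domain: per-axis mirror flips, 90-degree in-plane rotations and
    small integer translations (edge-padded) — all topology-preserving.
    Photometric domain: multiplicative/additive intensity jitter and
    additive Gaussian noise, clipped back to [0, 1].
    """

    p_flip: float = 0.5
    p_rot90: float = 0.5
    max_shift_voxels: int = 2
    intensity_scale_range: tuple[float, float] = (0.9, 1.1)
    intensity_shift_range: tuple[float, float] = (-0.05, 0.05)
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        for p in (self.p_flip, self.p_rot90):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.intensity_scale_range[0] > self.intensity_scale_range[1]:
            raise ValueError("intensity_scale_range must be ordered")
        if self.intensity_shift_range[0] > self.intensity_shift_range[1]:
            raise ValueError("intensity_shift_range must be ordered")
        if self.max_shift_voxels < 0 or self.noise_sd < 0:
            raise ValueError("max_shift_voxels and noise_sd must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        """Zero-magnitude policy: augment() becomes the identity map."""
        return cls(p_flip=0.0, p_rot90=0.0, max_shift_voxels=0,
                   intensity_scale_range=(1.0, 1.0),
                   intensity_shift_range=(0.0, 0.0), noise_sd=0.0)


@dataclass(frozen=True)
class SamplerWeights:
    """Per-sample draw probabilities, constant within each class."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("sampler probabilities must sum to 1")


def read_npz_dataset(path, split: str) -> Dataset:
    """Read one split from a MedMNIST3D-dialect NPZ file.

    Images are cast to float and divided by 255 so that a uint8 value of
    255 maps to exactly 1.0; labels are flattened from (N, 1) to (N,).
    """
    if split not in SPLITS:
        raise ValueError(f"split must be one of {SPLITS}, got {split!r}")
    with np.load(path) as z:
        for key in (f"{split}_images", f"{split}_labels"):
            if key not in z.files:
                raise KeyError(f"{path}: missing required key {key!r}")
        images = np.asarray(z[f"{split}_images"], dtype=float) / 255.0
        labels = np.asarray(z[f"{split}_labels"])
    if len(images) != len(labels):
        raise ValueError(
            f"{path}: {split} has {len(images)} images but {len(labels)} labels"
        )
    return Dataset(images=images, labels=labels.reshape(-1), split=split)


def write_npz_dataset(datasets: dict[str, Dataset], path) -> None:
    """Write splits to one NPZ file in the MedMNIST3D dialect.

    Images are stored as uint8 (values rounded onto 0..255) and labels as
    an (N, 1) integer column; ``read_npz_dataset`` inverts this exactly on
    the uint8 representation. Splits absent from ``datasets`` are omitted
    with a warning.
    """
    arrays = {}
    shape = None
    for split in SPLITS:
        if split not in datasets:
            warnings.warn(f"split {split!r} missing; omitted from {path}", stacklevel=2)
            continue
        ds = datasets[split]
        if ds.images.size:
            if shape is None:
                shape = ds.images.shape[1:]
            elif ds.images.shape[1:] != shape:
                raise ValueError(
                    f"inconsistent volume shapes across splits: {ds.images.shape[1:]} vs {shape}"
                )
        arrays[f"{split}_images"] = np.clip(np.rint(ds.images * 255), 0, 255).astype(np.uint8)
        arrays[f"{split}_labels"] = ds.labels.reshape(-1, 1).astype(np.int64)
    np.savez(path, **arrays)


def class_sampling_probabilities(labels) -> SamplerWeights:
    """Inverse-class-frequency draw probabilities.

    ``p_i = (1/n_{c_i}) / sum_j (1/n_{c_j})`` where ``n_c`` is the class
    count, so every class receives equal expected sampled mass regardless
    of its prevalence.
    """
    labels = np.asarray(labels).reshape(-1)
    if labels.size == 0:
        raise ValueError("cannot build sampler weights from empty labels")
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inverse]
    return SamplerWeights(probs=w / w.sum())


def augment(volume: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator) -> np.ndarray:
    """Apply one stochastic dual-domain augmentation to a single volume.

    Order: axis flips, axis-aligned 90-degree rotations, integer shifts
    (edge padding), intensity scale/shift, Gaussian noise; the result is
    clipped to [0, 1] and has the input's shape. With a zero-magnitude
    policy the input is returned bit-exactly.
    """
    v = np.asarray(volume, dtype=float)
    out = v
    for axis in range(3):
        if policy.p_flip > 0 and rng.random() < policy.p_flip:
            out = np.flip(out, axis=axis)
    if policy.p_rot90 > 0 and rng.random() < policy.p_rot90:
        k = int(rng.integers(1, 4))
        ax = tuple(int(a) for a in rng.choice(3, size=2, replace=False))
        if out.shape[ax[0]] == out.shape[ax[1]]:  # keep non-cubic shapes intact
            out = np.rot90(out, k=k, axes=ax)
    if policy.max_shift_voxels > 0:
        shift = rng.integers(-policy.max_shift_voxels, policy.max_shift_voxels + 1, size=3)
        if np.any(shift):
            out = ndimage.shift(out, shift, order=0, mode="nearest")
    lo, hi = policy.intensity_scale_range
    if (lo, hi) != (1.0, 1.0):
        out = out * rng.uniform(lo, hi)
    lo, hi = policy.intensity_shift_range
    if (lo, hi) != (0.0, 0.0):
        out = out + rng.uniform(lo, hi)
    if policy.noise_sd > 0:
        out = out + rng.normal(0.0, policy.noise_sd, size=out.shape)
    if out is v:  # identity policy: no copy, no clip — bit-exact passthrough
        return v
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)
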