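"""Seeded 3-D phantom generator for three structure families.

The generator produces small labelled grayscale volumes that emulate the
*task structure* of common volumetric benchmarks — not their image
statistics:

* ``nodule``  — compact blobs; class 0 is a small smooth sphere, class 1 a
  larger sphere with angular surface perturbation (spiculation).
* ``vessel``  — a curved tube crossing the volume; class 1 adds a
  spherical bulge (an aneurysm) on the tube path.
* ``synapse`` — blurred blobs; class 0 a single Gaussian blob, class 1 two
  partially overlapping blobs.

Foreground intensities are drawn in [0.6, 1.0] on a 0.05 background, then
Gaussian-blurred and corrupted with additive noise, clipped to [0, 1].
Every volume is a deterministic function of the generator state, so a
fixed seed reproduces a dataset bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import Dataset, write_npz_dataset

__all__ = ["PhantomSpec", "generate_volume", "generate_phantom_dataset", "FAMILIES"]

FAMILIES = ("nodule", "vessel", "synapse")

BACKGROUND = 0.05
FOREGROUND_RANGE = (0.6, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one generated phantom dataset.

    ``positive_fraction`` controls the class balance of the *training*
    split only; val/test are balanced 50/50 so threshold metrics stay
    interpretable. The default imbalance (0.11 positives) mirrors the
    minority-positive regime typical of vessel-malformation screening.
    """

    family: str
    n: int = 400
    side: int = 28
    positive_fraction: float = 0.11
    noise_sd: float = 0.02
    blur_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if self.side < 12:
            raise ValueError("side must be >= 12 voxels to contain the structures")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.noise_sd < 0 or self.blur_sd < 0:
            raise ValueError("noise_sd and blur_sd must be non-negative")


def _grid(side: int):
    ax = np.arange(side)
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _sphere_mask(side, center, radius):
    zz, yy, xx = _grid(side)
    r = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    return r <= radius


def _nodule_mask(side, label, rng):
    center = side / 2 + rng.uniform(-side / 10, side / 10, size=3)
    if label == 0:
        return _sphere_mask(side, center, rng.uniform(2.0, 4.0))
    # spiculated: radius modulated over direction angles
    radius = rng.uniform(4.0, 6.0)
    amp = rng.uniform(0.15, 0.3)
    freq = int(rng.integers(3, 6))
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    zz, yy, xx = _grid(side)
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, dz / np.maximum(r, 1e-9), 1.0), -1, 1))
    phi = np.arctan2(dy, dx)
    surface = radius * (1 + amp * np.sin(freq * phi + ph1) * np.sin(freq * theta + ph2))
    return r <= surface


def _bezier_curve(p0, p1, p2, t):
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _vessel_mask(side, label, rng):
    # quadratic Bezier tube entering and leaving through opposite faces
    axis = int(rng.integers(0, 3))
    lo = rng.uniform(0.2 * side, 0.8 * side, size=3)
    hi = rng.uniform(0.2 * side, 0.8 * side, size=3)
    lo[axis], hi[axis] = 0.0, side - 1.0
    mid = (lo + hi) / 2 + rng.uniform(-0.25 * side, 0.25 * side, size=3)
    mid[axis] = side / 2
    t = np.linspace(0, 1, 4 * side)
    pts = _bezier_curve(lo, mid, hi, t)
    tube_r = rng.uniform(1.0, 2.0)

    zz, yy, xx = _grid(side)
    mask = np.zeros((side, side, side), dtype=bool)
    # distance to the polyline, chunked over curve points
    coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    d2 = np.full(len(coords), np.inf)
    for p in pts:
        d2 = np.minimum(d2, np.sum((coords - p) ** 2, axis=1))
    mask |= (d2 <= tube_r**2).reshape(side, side, side)

    bulge_t = rng.uniform(0.3, 0.7)
    bulge_r = rng.uniform(2.0, 3.0) * tube_r
    if label == 1:
        center = _bezier_curve(lo, mid, hi, np.array([bulge_t]))[0]
        mask |= _sphere_mask(side, center, bulge_r)
    return mask


def _synapse_field(side, label, rng):
    # Gaussian blobs returned as a continuous field in [0, 1]
    zz, yy, xx = _grid(side)

    def blob(center, sd):
        return np.exp(
            -((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
            / (2 * sd**2)
        )

    c1 = side / 2 + rng.uniform(-side / 8, side / 8, size=3)
    sd = rng.uniform(1.5, 2.5)
    field = blob(c1, sd)
    if label == 1:
        offset = rng.uniform(1.5, 2.5) * sd
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        field = np.maximum(field, blob(c1 + offset * direction, sd * rng.uniform(0.8, 1.2)))
    return field


def generate_volume(family: str, label: int, side: int, rng: np.random.Generator) -> np.ndarray:
    """One phantom volume (side^3 float array in [0, 1]) without noise/blur.

    The same generator state yields, for vessel phantoms, the identical
    tube path for either label — class 1 only adds the bulge — so matched
    pairs differ exactly by the malformation.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if side < 12:
        raise ValueError("side too small to contain the structure")
    fg = rng.uniform(*FOREGROUND_RANGE)
    if family == "synapse":
        field = _synapse_field(side, label, rng)
        vol = BACKGROUND + (fg - BACKGROUND) * field
    else:
        mask = _nodule_mask(side, label, rng) if family == "nodule" else _vessel_mask(side, label, rng)
        vol = np.full((side, side, side), BACKGROUND)
        vol[mask] = fg
    return np.clip(vol, 0.0, 1.0)


def _finalize(vol: np.ndarray, blur_sd: float, noise_sd: float, rng) -> np.ndarray:
    if blur_sd > 0:
        vol = ndimage.gaussian_filter(vol, blur_sd)
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return np.clip(vol, 0.0, 1.0)


def _split_sizes(n: int) -> tuple[int, int, int]:
    n_val = max(1, round(0.15 * n))
    n_test = max(1, round(0.15 * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError(f"n={n} too small for non-empty train/val/test splits")
    return n_train, n_val, n_test


def _labels_for_split(n: int, positive_fraction: float, rng) -> np.ndarray:
    n_pos = int(np.clip(round(positive_fraction * n), 1, n - 1))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)
    return labels


def generate_phantom_dataset(spec: PhantomSpec, out_path=None) -> dict[str, Dataset]:
    """Generate train/val/test splits (70/15/15) for a phantom spec.

    Training labels follow ``spec.positive_fraction``; val and test are
    balanced 50/50 (within one sample for odd counts). If ``out_path`` is
    given the splits are written as a MedMNIST3D-dialect NPZ plus a JSON
    sidecar recording the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n_train, n_val, n_test = _split_sizes(spec.n)
    split_labels = {
        "train": _labels_for_split(n_train, spec.positive_fraction, rng),
        "val": _labels_for_split(n_val, 0.5, rng),
        "test": _labels_for_split(n_test, 0.5, rng),
    }
    out: dict[str, Dataset] = {}
    for split, labels in split_labels.items():
        vols = np.stack(
            [
                _finalize(
                    generate_volume(spec.family, int(lab), spec.side, rng),
                    spec.blur_sd,
                    spec.noise_sd,
                    rng,
                )
                for lab in labels
            ]
        )
        out[split] = Dataset(images=vols, labels=labels, split=split)
    if out_path is not None:
        out_path = Path(out_path)
        write_npz_dataset(out, out_path)
        out_path.with_suffix(".json").write_text(json.dumps(asdict(spec), indent=2))
    return out
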