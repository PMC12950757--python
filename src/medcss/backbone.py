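"""3-D squeeze-and-excitation residual encoder with hierarchical feature taps.

The encoder is a 3-D ResNet: a 7x7x7 stride-2 stem convolution, group
normalization, ReLU and a 3x3x3 stride-2 max-pool, followed by four
residual stages whose blocks carry squeeze-and-excitation (SE) channel
gating. Depth 10 and 18 use basic (two-conv) blocks, depth 50 bottleneck
(1-3-1) blocks with expansion 4.

The forward pass exposes, for one batch:

* ``f3``/``f4`` — the raw activation maps of stages 3 and 4 (mid-level
  morphology vs. global semantics),
* ``z3``/``z4`` — their global-average-pooled vectors,
* ``h3``/``h4`` — two-layer projection heads mapping z3/z4 into a shared
  latent space of dimension ``proj_dim``, where their empirical
  distributions are compared by the alignment loss,
* ``logits``/``yhat`` — a single affine prediction head on z4 with sigmoid
  (binary) or softmax (multiclass) output.

All layers are pure functions of a flat parameter dict (see ``nn``), so
the same code path serves deterministic inference and autograd training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import autograd.numpy as anp
import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "FeatureBundle",
    "Model",
    "build_model",
    "forward_features",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1

# blocks per stage and block type for each supported depth
_DEPTH_SPECS = {
    10: ("basic", (1, 1, 1, 1)),
    18: ("basic", (2, 2, 2, 2)),
    50: ("bottleneck", (3, 4, 6, 3)),
}
_EXPANSION = {"basic": 1, "bottleneck": 4}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``base_width`` is the channel count of stage 1 (stages double it:
    w, 2w, 4w, 8w). The default of 16 keeps CPU inference on 28^3 volumes
    fast; 64 recovers the classic ResNet widths. ``se_reduction`` is the
    bottleneck ratio of the SE gate; the gate's hidden width is clamped to
    at least 1. ``se_enabled=False`` forces every SE gate to 1 (plain
    residual network), used for ablations.
    """

    depth: int = 10
    in_channels: int = 1
    num_classes: int = 2
    se_reduction: int = 16
    proj_dim: int = 128
    task: str = "binary"
    base_width: int = 16
    se_enabled: bool = True

    def __post_init__(self) -> None:
        if self.depth not in _DEPTH_SPECS:
            raise ValueError(f"unsupported depth {self.depth}; pick one of {sorted(_DEPTH_SPECS)}")
        if self.task not in ("binary", "multiclass"):
            raise ValueError(f"task must be 'binary' or 'multiclass', got {self.task!r}")
        if self.proj_dim < 2:
            raise ValueError("proj_dim must be >= 2")
        if self.num_classes < 1 or self.in_channels < 1:
            raise ValueError("num_classes and in_channels must be positive")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be positive")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")

    @property
    def stage_channels(self) -> tuple[int, ...]:
        w = self.base_width
        exp = _EXPANSION[_DEPTH_SPECS[self.depth][0]]
        return tuple(w * m * exp for m in (1, 2, 4, 8))


@dataclass
class FeatureBundle:
    """Everything one forward pass produces for a batch."""

    f3: np.ndarray
    f4: np.ndarray
    z3: np.ndarray
    z4: np.ndarray
    h3: np.ndarray
    h4: np.ndarray
    logits: np.ndarray
    yhat: np.ndarray


@dataclass
class Model:
    """A configured encoder: architecture config + parameter dict."""

    cfg: ModelConfig
    params: dict = field(repr=False)
    seed: int = 0

    def forward(self, batch: np.ndarray) -> FeatureBundle:
        return forward_features(self, batch)

    def num_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def _num_groups(c: int) -> int:
    g = min(8, c)
    while c % g:
        g -= 1
    return g


def _conv_init(rng, cin, cout, k):
    # He initialization scaled by fan-out, as is standard for ReLU convnets
    std = np.sqrt(2.0 / (cout * k**3))
    return rng.normal(0.0, std, size=(cin * k**3, cout))


def _dense_init(rng, din, dout):
    std = np.sqrt(2.0 / din)
    return rng.normal(0.0, std, size=(din, dout))


def _add_norm(params, name, c, zero_scale=False):
    params[f"{name}.g"] = np.zeros(c) if zero_scale else np.ones(c)
    params[f"{name}.b"] = np.zeros(c)


def _add_block(params, rng, name, cin, cout, block, se_reduction):
    """Allocate one residual block's parameters."""
    if block == "basic":
        params[f"{name}.conv1.w"] = _conv_init(rng, cin, cout, 3)
        params[f"{name}.conv1.b"] = np.zeros(cout)
        _add_norm(params, f"{name}.norm1", cout)
        params[f"{name}.conv2.w"] = _conv_init(rng, cout, cout, 3)
        params[f"{name}.conv2.b"] = np.zeros(cout)
        # zero-init of the branch's final norm scale: blocks start as identity
        _add_norm(params, f"{name}.norm2", cout, zero_scale=True)
    else:  # bottleneck
        mid = cout // 4
        params[f"{name}.conv1.w"] = _conv_init(rng, cin, mid, 1)
        params[f"{name}.conv1.b"] = np.zeros(mid)
        _add_norm(params, f"{name}.norm1", mid)
        params[f"{name}.conv2.w"] = _conv_init(rng, mid, mid, 3)
        params[f"{name}.conv2.b"] = np.zeros(mid)
        _add_norm(params, f"{name}.norm2", mid)
        params[f"{name}.conv3.w"] = _conv_init(rng, mid, cout, 1)
        params[f"{name}.conv3.b"] = np.zeros(cout)
        _add_norm(params, f"{name}.norm3", cout, zero_scale=True)
    hidden = max(1, cout // se_reduction)
    params[f"{name}.se.fc1.w"] = _dense_init(rng, cout, hidden)
    params[f"{name}.se.fc1.b"] = np.zeros(hidden)
    params[f"{name}.se.fc2.w"] = _dense_init(rng, hidden, cout)
    params[f"{name}.se.fc2.b"] = np.zeros(cout)
    if cin != cout:
        params[f"{name}.down.w"] = _conv_init(rng, cin, cout, 1)
        params[f"{name}.down.b"] = np.zeros(cout)
        _add_norm(params, f"{name}.downnorm", cout)


def build_model(cfg: ModelConfig, seed: int = 0) -> Model:
    """Allocate and initialize all parameters for the configured depth."""
    block, counts = _DEPTH_SPECS[cfg.depth]
    chans = cfg.stage_channels
    rng = np.random.default_rng(seed)
    params: dict = {}

    stem_out = cfg.base_width
    params["stem.conv.w"] = _conv_init(rng, cfg.in_channels, stem_out, 7)
    params["stem.conv.b"] = np.zeros(stem_out)
    _add_norm(params, "stem.norm", stem_out)

    cin = stem_out
    for s, (cout, n_blocks) in enumerate(zip(chans, counts), start=1):
        for b in range(n_blocks):
            _add_block(params, rng, f"s{s}.b{b}", cin, cout, block, cfg.se_reduction)
            cin = cout

    params["proj3.fc1.w"] = _dense_init(rng, chans[2], cfg.proj_dim)
    params["proj3.fc1.b"] = np.zeros(cfg.proj_dim)
    params["proj3.fc2.w"] = _dense_init(rng, cfg.proj_dim, cfg.proj_dim)
    params["proj3.fc2.b"] = np.zeros(cfg.proj_dim)
    params["proj4.fc1.w"] = _dense_init(rng, chans[3], cfg.proj_dim)
    params["proj4.fc1.b"] = np.zeros(cfg.proj_dim)
    params["proj4.fc2.w"] = _dense_init(rng, cfg.proj_dim, cfg.proj_dim)
    params["proj4.fc2.b"] = np.zeros(cfg.proj_dim)

    params["head.w"] = _dense_init(rng, chans[3], cfg.num_classes) * 0.1
    params["head.b"] = np.zeros(cfg.num_classes)
    return Model(cfg=cfg, params=params, seed=seed)


def _se_gate(params, name, x, enabled):
    if not enabled:
        return x
    c = x.shape[1]
    s = nn.global_avg_pool(x)
    s = nn.relu(nn.dense(s, params[f"{name}.fc1.w"], params[f"{name}.fc1.b"]))
    s = nn.sigmoid(nn.dense(s, params[f"{name}.fc2.w"], params[f"{name}.fc2.b"]))
    return x * anp.reshape(s, (x.shape[0], c, 1, 1, 1))


def _block_forward(params, name, x, block, stride, se_enabled):
    cin = x.shape[1]
    if block == "basic":
        cout = params[f"{name}.conv2.w"].shape[1]
        h = nn.conv3d(x, params[f"{name}.conv1.w"], params[f"{name}.conv1.b"], stride=stride)
        h = nn.relu(nn.group_norm(h, params[f"{name}.norm1.g"], params[f"{name}.norm1.b"], _num_groups(h.shape[1])))
        h = nn.conv3d(h, params[f"{name}.conv2.w"], params[f"{name}.conv2.b"], stride=1)
        h = nn.group_norm(h, params[f"{name}.norm2.g"], params[f"{name}.norm2.b"], _num_groups(h.shape[1]))
    else:
        cout = params[f"{name}.conv3.w"].shape[1]
        h = nn.conv3d(x, params[f"{name}.conv1.w"], params[f"{name}.conv1.b"], stride=1)
        h = nn.relu(nn.group_norm(h, params[f"{name}.norm1.g"], params[f"{name}.norm1.b"], _num_groups(h.shape[1])))
        h = nn.conv3d(h, params[f"{name}.conv2.w"], params[f"{name}.conv2.b"], stride=stride)
        h = nn.relu(nn.group_norm(h, params[f"{name}.norm2.g"], params[f"{name}.norm2.b"], _num_groups(h.shape[1])))
        h = nn.conv3d(h, params[f"{name}.conv3.w"], params[f"{name}.conv3.b"], stride=1)
        h = nn.group_norm(h, params[f"{name}.norm3.g"], params[f"{name}.norm3.b"], _num_groups(h.shape[1]))
    # SE recalibration on the residual branch, before the skip addition
    h = _se_gate(params, f"{name}.se", h, se_enabled)
    if cin != cout or stride != 1:
        skip = nn.conv3d(x, params[f"{name}.down.w"], params[f"{name}.down.b"], stride=stride, pad=0) \
            if f"{name}.down.w" in params else _strided_identity(x, stride)
        if f"{name}.downnorm.g" in params:
            skip = nn.group_norm(skip, params[f"{name}.downnorm.g"], params[f"{name}.downnorm.b"], _num_groups(cout))
    else:
        skip = x
    return nn.relu(h + skip)


def _strided_identity(x, stride):
    return x[:, :, ::stride, ::stride, ::stride]


def forward_core(params, x, cfg: ModelConfig):
    """Differentiable forward pass; returns a dict of (possibly boxed) arrays."""
    block, counts = _DEPTH_SPECS[cfg.depth]
    h = nn.conv3d(x, params["stem.conv.w"], params["stem.conv.b"], stride=2)
    h = nn.relu(nn.group_norm(h, params["stem.norm.g"], params["stem.norm.b"], _num_groups(h.shape[1])))
    h = nn.max_pool3d(h, k=3, stride=2, pad=1)

    taps = {}
    for s, n_blocks in enumerate(counts, start=1):
        for b in range(n_blocks):
            # only the first block of stages 2-4 downsamples; maps already at
            # a single voxel keep stride 1 (adaptive behaviour for small inputs)
            st = 2 if (s > 1 and b == 0) else 1
            if st == 2 and min(h.shape[2:]) == 1:
                st = 1
            h = _block_forward(params, f"s{s}.b{b}", h, block, st, cfg.se_enabled)
        if s == 3:
            taps["f3"] = h
    taps["f4"] = h

    z3 = nn.global_avg_pool(taps["f3"])
    z4 = nn.global_avg_pool(taps["f4"])
    h3 = nn.dense(nn.relu(nn.dense(z3, params["proj3.fc1.w"], params["proj3.fc1.b"])),
                  params["proj3.fc2.w"], params["proj3.fc2.b"])
    h4 = nn.dense(nn.relu(nn.dense(z4, params["proj4.fc1.w"], params["proj4.fc1.b"])),
                  params["proj4.fc2.w"], params["proj4.fc2.b"])
    logits = nn.dense(z4, params["head.w"], params["head.b"])
    return {"f3": taps["f3"], "f4": taps["f4"], "z3": z3, "z4": z4,
            "h3": h3, "h4": h4, "logits": logits}


def forward_features(model: Model, batch: np.ndarray) -> FeatureBundle:
    """Inference forward pass returning a plain-numpy :class:`FeatureBundle`.

    ``batch`` is (B, C, D, H, W) with each spatial dimension at least 8 so
    that all four downsampling stages remain valid.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 5:
        raise ValueError(f"batch must be 5-D (B, C, D, H, W), got shape {batch.shape}")
    if min(batch.shape[2:]) < 8:
        raise ValueError(
            f"spatial dimensions must be >= 8 for four downsampling stages, got {batch.shape[2:]}"
        )
    out = forward_core(model.params, batch, model.cfg)
    yhat = predict_proba(out["logits"], model.cfg.task)
    return FeatureBundle(
        f3=np.asarray(out["f3"]), f4=np.asarray(out["f4"]),
        z3=np.asarray(out["z3"]), z4=np.asarray(out["z4"]),
        h3=np.asarray(out["h3"]), h4=np.asarray(out["h4"]),
        logits=np.asarray(out["logits"]), yhat=np.asarray(yhat),
    )


def predict_proba(logits, task: str):
    """Map logits to probabilities.

    binary: element-wise sigmoid of the positive-class (last) logit column,
    returned as a 1-D score vector. multiclass: row softmax.
    """
    arr = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logits contain non-finite entries")
    if task == "binary":
        col = arr[..., -1] if arr.ndim >= 1 else arr
        return nn.sigmoid(col)
    if task == "multiclass":
        shifted = arr - np.max(arr, axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / np.sum(e, axis=-1, keepdims=True)
    raise ValueError(f"unknown task {task!r}")


def save_checkpoint(model: Model, path) -> None:
    """Persist weights + config + seed as a single NPZ archive."""
    meta = json.dumps({"version": CHECKPOINT_VERSION, "seed": model.seed,
                       "config": asdict(model.cfg)})
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        params = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    cfg = ModelConfig(**meta["config"])
    return Model(cfg=cfg, params=params, seed=meta["seed"])
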