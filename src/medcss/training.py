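"""Joint optimization loop and the controlled ablation harness.

One training step draws a class-rebalanced batch (inverse-frequency
sampling with replacement), augments each volume, runs a single forward
pass, and minimizes

    L_total = L_sup + lambda_align * L_align + lambda_crr * L_crr

with Adam, where L_sup is weighted cross-entropy on the prediction head,
L_align the Jensen-Shannon alignment between the h3/h4 projection
distributions, and L_crr the coding-rate-reduction hinge on the pooled
z3/z4 features. Runs are fully seeded: parameter init, sampling and
augmentation all derive from ``TrainConfig.seed``, so two runs with an
identical config reproduce each other exactly on a single CPU thread.

The four ablation variants differ only in which loss weights are active:
baseline (both zero), naive_align (alignment only), cr_only (coding-rate
only) and full (both). ``ablation_suite`` trains all four under one seed
and backbone so the comparison is controlled.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import grad
from autograd.tracer import getval

from . import nn
from .backbone import Model, ModelConfig, build_model, forward_core, save_checkpoint
from .data import AugmentationPolicy, Dataset, augment, class_sampling_probabilities
from .evaluation import MetricsReport, auc, evaluate, predict_scores
from .objectives import CodingRateParams, alignment_loss, coding_rate, crr_loss

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "AblationResult",
    "VARIANTS",
    "supervised_loss",
    "train",
    "ablation_suite",
]

VARIANTS = ("baseline", "naive_align", "cr_only", "full")


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    The variant forces its loss weights: ``baseline`` zeroes both,
    ``naive_align`` zeroes lambda_crr, ``cr_only`` zeroes lambda_align,
    ``full`` keeps both as given. Defaults: Adam at lr 1e-3 with no
    schedule, lambda_align=0.1, lambda_crr=0.01, alpha=1.
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    lambda_align: float = 0.1
    lambda_crr: float = 0.01
    alpha: float = 1.0
    jitter: float = 1e-6
    variant: str = "full"
    seed: int = 0
    align_across_views: bool = False
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate > 0")
        if self.lambda_align < 0 or self.lambda_crr < 0:
            raise ValueError("loss weights must be non-negative")
        if self.variant == "baseline":
            self.lambda_align = 0.0
            self.lambda_crr = 0.0
        elif self.variant == "naive_align":
            self.lambda_crr = 0.0
        elif self.variant == "cr_only":
            self.lambda_align = 0.0

    def config_hash(self) -> str:
        """Hash of the backbone config — identical across ablation variants."""
        blob = json.dumps(asdict(self.model), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    records: list = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def series(self, key: str) -> list:
        return [r[key] for r in self.records]


@dataclass
class AblationResult:
    """Per-variant outcome of the controlled ablation suite."""

    variant: str
    report: MetricsReport
    history: TrainHistory
    model: Model
    config_hash: str


def supervised_loss(logits, labels, class_weights=None, task: str = "binary"):
    """Weighted cross-entropy, differentiable through the logits.

    ``class_weights`` is one weight per class (default: uniform); the loss
    is the weight-normalized mean ``sum_i w_{y_i} ce_i / sum_i w_{y_i}``,
    so uniform weights reproduce the unweighted mean exactly. For the
    binary task the positive-class (last) logit column feeds a numerically
    stable sigmoid cross-entropy.
    """
    labels = np.asarray(labels).reshape(-1).astype(int)
    n_classes = int(getval(logits).shape[-1]) if getval(logits).ndim > 1 else 2
    if labels.min() < 0 or labels.max() >= max(n_classes, 2):
        raise ValueError(f"label out of range [0, {n_classes}) in {np.unique(labels)}")
    if class_weights is None:
        w = np.ones(len(labels))
    else:
        class_weights = np.asarray(class_weights, dtype=float)
        w = class_weights[labels]
    if task == "binary":
        ell = logits[:, -1] if getval(logits).ndim > 1 else logits
        y = labels.astype(float)
        # stable log(1 + exp(-|l|)) form of BCE-with-logits
        ce = anp.maximum(ell, 0.0) - ell * y + anp.log1p(anp.exp(-anp.abs(ell)))
    elif task == "multiclass":
        shifted = logits - anp.max(logits, axis=1, keepdims=True)
        logz = anp.log(anp.sum(anp.exp(shifted), axis=1))
        ce = logz - shifted[anp.arange(len(labels)), labels]
    else:
        raise ValueError(f"unknown task {task!r}")
    return anp.sum(w * ce) / anp.sum(w)


def _inverse_frequency_weights(labels: np.ndarray, num_classes: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=num_classes).astype(float)
    counts[counts == 0] = np.inf  # absent classes get zero weight
    w = 1.0 / counts
    return w / w[np.isfinite(w)].mean() if np.any(np.isfinite(w)) else np.ones(num_classes)


def probe_coding_rates(model: Model, probe: np.ndarray, alpha: float, jitter: float = 1e-6):
    """R(z3), R(z4) of a fixed probe batch — the quantity the CRR hinge acts on."""
    out = forward_core(model.params, probe, model.cfg)
    params = CodingRateParams(alpha=alpha, jitter=jitter)
    return float(coding_rate(np.asarray(out["z3"]), params)), float(
        coding_rate(np.asarray(out["z4"]), params)
    )


def train(
    datasets: dict[str, Dataset],
    cfg: TrainConfig,
    out_dir=None,
    progress: bool = False,
) -> tuple[Model, TrainHistory]:
    """Run the joint objective on the train split; select by validation AUC.

    ``datasets`` maps split names to :class:`Dataset`; ``train`` is
    required, ``val`` is used for model selection when present (falling
    back to the final weights otherwise). Returns the best-validation-AUC
    model and the per-epoch history. With ``out_dir`` set, a checkpoint,
    a JSON-lines run log and a config snapshot are written there.
    """
    train_ds = datasets["train"]
    if len(train_ds) == 0:
        raise ValueError("train split is empty")
    labels = train_ds.labels
    if len(np.unique(labels)) < 2 and cfg.model.num_classes > 1:
        raise ValueError("train split needs at least one sample of each class")

    rng = np.random.default_rng(cfg.seed)
    model = build_model(cfg.model, seed=cfg.seed)
    sampler = class_sampling_probabilities(labels)
    class_w = _inverse_frequency_weights(labels, cfg.model.num_classes)
    cr_params = CodingRateParams(alpha=cfg.alpha, jitter=cfg.jitter)

    n = len(train_ds)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    probe_idx = np.arange(min(32, n))
    probe = train_ds.batch(probe_idx)

    comps: dict = {}

    def loss_fn(params, xb, yb, xb2):
        out = forward_core(params, xb, cfg.model)
        sup = supervised_loss(out["logits"], yb, class_w, cfg.model.task)
        if cfg.lambda_align > 0:
            if xb2 is not None:
                out2 = forward_core(params, xb2, cfg.model)
                align = alignment_loss(out["h3"], out2["h4"])
            else:
                align = alignment_loss(out["h3"], out["h4"])
        else:
            align = 0.0
        crr = crr_loss(out["z3"], out["z4"], cr_params) if cfg.lambda_crr > 0 else 0.0
        total = sup + cfg.lambda_align * align + cfg.lambda_crr * crr
        comps.update(
            sup=float(getval(sup)),
            align=float(getval(align)) if cfg.lambda_align > 0 else 0.0,
            crr=float(getval(crr)) if cfg.lambda_crr > 0 else 0.0,
            total=float(getval(total)),
        )
        return total

    grad_fn = grad(loss_fn)
    opt = nn.AdamState(model.params)
    params = model.params
    history = TrainHistory()
    best = {"auc": -np.inf, "params": None, "epoch": -1}
    log_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "log.jsonl"
        log_path.write_text("")

    for epoch in range(cfg.epochs):
        sums = {"sup": 0.0, "align": 0.0, "crr": 0.0, "total": 0.0}
        for step in range(steps_per_epoch):
            idx = rng.choice(n, size=min(cfg.batch_size, n), replace=True, p=sampler.probs)
            xb = np.stack([augment(train_ds.images[i], cfg.augmentation, rng) for i in idx])[:, None]
            xb2 = None
            if cfg.align_across_views and cfg.lambda_align > 0:
                xb2 = np.stack(
                    [augment(train_ds.images[i], cfg.augmentation, rng) for i in idx]
                )[:, None]
            g = grad_fn(params, xb, idx_labels := labels[idx], xb2)
            if not np.isfinite(comps["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}: {comps}"
                )
            params = nn.adam_step(params, g, opt, lr=cfg.learning_rate)
            for k in sums:
                sums[k] += comps[k]

        model = Model(cfg=cfg.model, params=params, seed=cfg.seed)
        r3, r4 = probe_coding_rates(model, probe, cfg.alpha, cfg.jitter)
        record = {
            "epoch": epoch,
            **{f"loss_{k}": v / steps_per_epoch for k, v in sums.items()},
            "probe_R_z3": r3,
            "probe_R_z4": r4,
        }
        if "val" in datasets and len(datasets["val"]):
            val = datasets["val"]
            scores = predict_scores(model, val)
            record["val_acc"] = float(np.mean((scores >= 0.5).astype(int) == val.labels))
            both = len(np.unique(val.labels)) == 2
            record["val_auc"] = auc(scores, val.labels) if both else float("nan")
            if np.isfinite(record["val_auc"]) and record["val_auc"] > best["auc"]:
                best = {"auc": record["val_auc"], "params": copy.deepcopy(params), "epoch": epoch}
        history.append(**record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
        if progress:
            print(
                f"epoch {epoch}: total {record['loss_total']:.4f}"
                + (f"  val_auc {record.get('val_auc', float('nan')):.4f}" if "val_auc" in record else "")
            )

    if best["params"] is not None:
        model = Model(cfg=cfg.model, params=best["params"], seed=cfg.seed)
    if out_dir is not None:
        save_checkpoint(model, out_dir / "checkpoint.npz")
        (out_dir / "config.json").write_text(
            json.dumps(_config_to_jsonable(cfg), indent=2)
        )
    return model, history


def _config_to_jsonable(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d


def ablation_suite(
    datasets: dict[str, Dataset],
    base_cfg: TrainConfig,
    variants: tuple[str, ...] = VARIANTS,
) -> dict[str, AblationResult]:
    """Train every ablation variant under identical seed and backbone.

    Only the loss weights differ between rows; seed, architecture,
    sampler, augmentation and optimizer are shared so that metric
    differences are attributable to the loss components. Reports are
    computed on the test split (falling back to val if no test split).
    """
    eval_split = "test" if "test" in datasets else "val"
    results: dict[str, AblationResult] = {}
    for variant in variants:
        cfg = copy.deepcopy(base_cfg)
        cfg.variant = variant
        cfg.__post_init__()  # re-apply variant weight forcing
        model, history = train(datasets, cfg)
        report = evaluate(model, datasets[eval_split])
        results[variant] = AblationResult(
            variant=variant,
            report=report,
            history=history,
            model=model,
            config_hash=cfg.config_hash(),
        )
    return results
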