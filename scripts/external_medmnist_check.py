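#!/usr/bin/env python
"""EXTERNAL sanity check against a real MedMNIST3D download (not part of CI).

Requires network access and the optional ``medmnist`` package; neither is
assumed by the test suite or the acceptance script. Downloads
NoduleMNIST3D, trains a scaled-down baseline and full model under a
matched budget, and reports whether the full variant's held-out AUC
exceeds the baseline's.

Usage:
    pip install medmnist
    python scripts/external_medmnist_check.py --epochs 5 --out scratch/medmnist_check.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

import medcss as m


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--epochs", type=int, default=5)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--subsample", type=int, default=400,
                    help="training volumes kept (budget control)")
    ap.add_argument("--out", type=Path, default=Path("scratch/medmnist_check.json"))
    args = ap.parse_args()

    try:
        import medmnist  # noqa: F401
        from medmnist import NoduleMNIST3D
    except ImportError:
        raise SystemExit(
            "the optional 'medmnist' package is required for this external check: "
            "pip install medmnist"
        )

    root = Path("scratch/medmnist")
    root.mkdir(parents=True, exist_ok=True)
    # triggers the download; we then read the NPZ through the package reader
    NoduleMNIST3D(split="train", root=str(root), download=True)
    npz = root / "nodulemnist3d.npz"

    rng = np.random.default_rng(args.seed)
    splits = {}
    for split in ("train", "val", "test"):
        ds = m.read_npz_dataset(npz, split)
        if split == "train" and len(ds) > args.subsample:
            keep = rng.choice(len(ds), size=args.subsample, replace=False)
            ds = m.Dataset(images=ds.images[keep], labels=ds.labels[keep], split=split)
        splits[split] = ds

    results = {}
    for variant in ("baseline", "full"):
        cfg = m.TrainConfig(
            model=m.ModelConfig(depth=10, base_width=16, proj_dim=32),
            epochs=args.epochs, batch_size=16, variant=variant, seed=args.seed,
        )
        model, _ = m.train(splits, cfg, progress=True)
        report = m.evaluate(model, splits["test"])
        results[variant] = report.to_dict()
        print(f"{variant}: acc {report.acc:.4f} auc {report.auc:.4f}")

    results["full_beats_baseline_auc"] = (
        results["full"]["auc"] > results["baseline"]["auc"]
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
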