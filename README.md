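# medcss

Causal self-supervised hierarchical feature consistency for 3-D medical
image classification.

Small-volume medical classification tasks — lung-nodule malignancy,
vessel-malformation screening, synapse identification — are plagued by
class imbalance, tiny training sets and poor cross-domain transfer,
because a plain CNN learns whatever correlations separate the training
split. `medcss` trains a 3-D squeeze-and-excitation ResNet with two
auxiliary constraints on its feature *hierarchy* that push it toward
structurally consistent, compressed representations:

* **Cross-level alignment.** The stage-3 and stage-4 features are pooled
  (`z3 = GAP(f3)`, `z4 = GAP(f4)`), projected into a shared latent space
  (`h3 = φ3(z3)`, `h4 = φ4(z4)`), reduced to empirical categorical
  distributions, and pulled together with the Jensen–Shannon divergence:

      L_align = JS(p(h3) ‖ p(h4))      (base-2, bounded by 1 bit)

* **Coding-rate reduction (CRR).** For a feature batch `F ∈ R^{B×d}`
  with covariance `Σ = (1/B)(F−F̄)ᵀ(F−F̄)`, the coding rate
  `R(F) = ½ log det(I + αΣ)` measures the batch's feature redundancy.
  Deeper features should be more compressed, so the hinge

      L_crr = max(0, R(z3) − R(z4))

  penalizes information inflation along the hierarchy.

* **Joint objective.**

      L_total = L_sup + λ_align·L_align + λ_crr·L_crr

  with weighted cross-entropy as `L_sup`, inverse-class-frequency batch
  sampling and dual-domain (spatial + photometric) augmentation.

A seeded 3-D phantom generator (compact nodules, curved vessels with
bulges, paired synapse blobs; MedMNIST3D NPZ dialect) makes the entire
pipeline runnable and testable end-to-end with no downloads. The
training stack is pure numpy with reverse-mode autodiff — no GPU
required, deterministic on a single CPU thread.

## Worked example

```python
import medcss as m

splits = m.generate_phantom_dataset(
    m.PhantomSpec(family="vessel", n=400, side=16, positive_fraction=0.11, seed=0)
)
cfg = m.TrainConfig(
    model=m.ModelConfig(depth=10, base_width=16, proj_dim=32),
    epochs=8, batch_size=16, variant="full", seed=0,
)
model, history = m.train(splits, cfg)
report = m.evaluate(model, splits["test"])
```

Output (examples/03_train_and_evaluate.py, ~2 min on one CPU core):

```
test: acc 0.7667  recall 1.0000  f1 0.8108  auc 0.9944  (n=60)
probability separation |E[s|y=1] - E[s|y=0]| = 0.4571
probe hinge gap R(z3)-R(z4): epoch 0 -0.2470 -> final -1.8799
```

The model ranks held-out vessel phantoms almost perfectly (AUC 0.994)
and catches every malformation (recall 1.0) at the 0.5 threshold; the
accuracy reflects the deliberately conservative operating point that
inverse-frequency sampling produces on an 11%-positive training set. The
hinge gap `R(z3) − R(z4)` moving from −0.25 to −1.88 on a fixed probe
batch shows the deepest features ending far more compressed than the
intermediate ones — the state the CRR term drives the encoder toward.

The loss components themselves have closed forms on tiny batches
(examples/02_loss_components.py):

```
coding rate of [[-1],[1]]: 0.346574 nats (closed form 0.346574)
crr_loss(wide -> narrow): 0.693147 (active)
alignment_loss(H3, H3) = 0.000000 bits
```

## Command line

```sh
medcss synth --family vessel --n 400 --side 16 --positive-fraction 0.11 --seed 0 --out vessel.npz
medcss train --data vessel.npz --epochs 8 --base-width 16 --variant full --out run/
medcss eval --model run/checkpoint.npz --data vessel.npz --out report.json
medcss transfer --model run/checkpoint.npz --data other.npz
medcss ablate --data vessel.npz --epochs 8 --out ablation/
```

Every run writes a config snapshot, a line-delimited JSON log and its
result artifacts into `--out`; reruns with the same seed are identical.

## Library layout

| module | contents |
| --- | --- |
| `medcss.objectives` | coding rate, CRR hinge, batch distributions, JS divergence, joint objective |
| `medcss.backbone` | 3-D SE-ResNet (depths 10/18/50), feature taps, projection heads, checkpoints |
| `medcss.data` | NPZ dataset I/O, inverse-frequency sampler, dual-domain augmentation |
| `medcss.synthdata` | seeded nodule / vessel / synapse phantom generator |
| `medcss.training` | Adam training loop, ablation variants, run logging |
| `medcss.evaluation` | ACC/recall/F1, Mann–Whitney AUC, ROC, probability histograms, transfer |
| `medcss.cli` | the `medcss` entry point: synth, train, eval, transfer, ablate |

See `docs/methods.md` for the model's assumptions, parameter defaults
and the design decisions behind them, and `examples/` for short
narrative scripts.

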