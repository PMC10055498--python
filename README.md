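# mssit — Multiscale Surface Vision Transformer

`mssit` is a hierarchical transformer for scalar signals on sphericalised
cortical meshes: per-vertex metrics such as sulcal depth, curvature,
cortical thickness or T1w/T2w myelin, sampled on a regular icosphere. It
targets the two workhorse tasks of cortical surface analysis —
**phenotype regression/classification** (e.g. postmenstrual age at scan)
and **vertex-wise parcellation** — with a single backbone.

## The model

The input `X ∈ R^{|V6|×C}` lives on the 6th-order icosphere
`I6 = (V6, F6)`, `|V6| = 40962`. Patching by the ico5 faces yields a
sequence of `|F5| = 20480` triangular patches of `|t5| = 6` vertices each,
flattened to tokens `X0 ∈ R^{|F5|×6C}`. Four encoder levels follow; level
`l` projects to a `2^(l−1)·D`-dimensional embedding, applies local
multi-head self-attention blocks, and merges sibling patches 4-to-1, so
the token counts shrink 20480 → 5120 → 1280 → 320 while features double.

Attention is computed inside non-overlapping **mesh windows**: at level
`l` the windows are the faces of the icosphere three orders below the
sequence grid, i.e. 64 consecutive patches per window (at the coarsest
level a single global window covers the 320 ico2 patches). Each block
alternates windowed attention (W-MHSA) with **shifted-window** attention
(SW-MHSA), which cyclically rolls the sequence by half a window so
information crosses window boundaries:

```
X̂  = W-MSA(LN(X)) + X          Z = FFN(LN(X̂)) + X̂
Ẑ  = SW-MSA(LN(Z)) + Z         X' = FFN(LN(Ẑ)) + Ẑ
```

This reduces the attention cost at level `l` from `O(|F6−l|²)` to
`O(w·|F6−l|)` with `w = 64`. For regression the final sequence is averaged
into one token and fed to a linear head; for segmentation a U-shaped
decoder mirrors the encoder with 1-to-4 patch partition and skip
connections, predicting per-vertex class logits.

Because no GPU framework is assumed, the network runs on a small
reverse-mode autodiff engine over numpy arrays that is part of the
package; every operator's gradient is verified against finite differences
in the test suite.

Training follows the recipe the architecture was designed with: AdamW with
linear warmup + cosine decay, MSE loss (regression) or Dice +
cross-entropy (segmentation), inverse-bin-frequency balanced sampling for
regression, and online surface augmentation (80% probability; random
rotations or coarse-grid elastic warps, 50/50). See `docs/methods.md` for
the full account.

## Worked example

Generate a synthetic cohort (smooth spherical-harmonic channels whose
coefficients depend on a hidden age-like scalar), train a small model on
an ico4 grid, and evaluate:

```bash
mssit make-synthetic --task regression --out data --seed 0 \
    --n-subjects 64 --mesh-order 4 --n-channels 4
mssit train --config examples/regression_ico4.yaml \
    --manifest data/manifest.csv --checkpoint ck.npz
mssit evaluate --checkpoint ck.npz --manifest data/manifest.csv
mssit predict --checkpoint ck.npz --metric data/sub-0000.shape.gii --out pred.csv
```

which prints

```
wrote data/manifest.csv
best validation metric: 0.4424
checkpoint written to ck.npz
MAE: 0.5165
wrote pred.csv
```

The "best validation metric" is the held-out mean absolute error in target
units (weeks for an age-like target) at the best epoch; the final `MAE`
line re-evaluates the restored best checkpoint over the whole manifest.
For this cohort the targets span 26–45 weeks, so a constant-mean predictor
scores an MAE of ≈ 4.7 weeks; the trained model's ≈ 0.5 means it recovers
the hidden scalar almost exactly. `pred.csv` contains the single-subject
prediction (here 32.58 vs a true target of 33.24).

The same workflow with `--task segmentation` trains the U-shaped variant
and `mssit predict` then writes a GIFTI `.label.gii` parcellation.

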