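# pestnet

Fine-grained insect-pest image classification built from:

- an **OSA backbone** — one-shot-aggregation blocks in a 57-layer staging
  (stem 64/64/128; per-layer widths 128/160/192/224; stage outputs
  256/512/768/1024; 1/1/4/3 blocks per stage);
- **boundary-aware channel-spatial attention** after every stage: a channel
  gate from mean + standard-deviation pooling (`sigmoid(W_c·[μ,σ])`) and a
  spatial gate from fixed, non-trainable Sobel edge responses
  (`sigmoid(W_s·(E_x+E_y))`), fused residually as
  `f·(1+α·g_c)·(1+β·g_s)`;
- a **generalized p-norm pooling** head with a learnable exponent
  (`p=1` is average pooling, large `p` approaches max pooling);
- a **scheduled mixed loss** `λ·CE + (1−λ)·focal` with
  `λ(t)=λ_max·(1−t/T)` and label smoothing on the CE term;
- **growth-stage auxiliary supervision**: species classes are split into
  Adult/Larva/Pupa/Egg training classes whenever a stage subgroup holds
  strictly more than `min_count` images; predictions are collapsed back to
  species level for evaluation.

The default full model (224×224 input, 168-class training head) has
**35.65 M** trainable parameters.

The network runs on a small numpy-based autodiff engine (`pestnet.nn`)
with im2col convolutions, batch norm, 2×2 max pooling and AdamW — no GPU
framework required, so the whole pipeline (including training a reduced
model) runs on one CPU. A fully seeded synthetic scene generator
(`pestnet.synthetic`) produces stage-structured, long-tailed, cluttered
insect scenes used by the tests in place of a field-collected dataset.

## CLI

```sh
# 1. generate a synthetic dataset (spec.yaml holds DatasetSpec fields)
pestnet generate --spec spec.yaml --out ds/

# 2. build the stage-refined label hierarchy from a manifest
pestnet refine-labels --manifest ds/train.csv --min-count 30 --out hierarchy.json

# 3. train (config.yaml mirrors TrainConfig; unknown keys are errors)
pestnet train --config config.yaml --data ds/ --hierarchy ds/hierarchy.json --out run/

# 4. evaluate at species level (confusion CSV + JSON report)
pestnet evaluate --checkpoint run/best.ckpt.npz --manifest ds/test.csv \
    --hierarchy ds/hierarchy.json --report report/ --data-root ds/
```

Manifests are CSV with header `image_path,species_id,species_name,stage`
(blank stage = unannotated); the hierarchy file is JSON with
`n_species`, `n_refined`, `min_count`, `parent_of` (plus optional
`stages`/`names`).

## Layout

| module | contents |
| --- | --- |
| `pestnet.nn` | numpy autodiff tensors, layers, AdamW |
| `pestnet.backbone` | OSA blocks, backbone staging, parameter counting, pretrained-weight loading |
| `pestnet.bcsa` | channel/spatial attention gates, Sobel edges (plus plain-numpy cross-check path) |
| `pestnet.gpp` | generalized p-norm pooling |
| `pestnet.losses` | smoothed CE, focal loss, λ schedule, mixed training objective |
| `pestnet.labels` | refined label space build/refine/collapse, JSON persistence |
| `pestnet.metrics` | confusion matrix, accuracy, macro/weighted F1, exact McNemar |
| `pestnet.synthetic` | seeded procedural scene generator, complex-background subset |
| `pestnet.engine` | preprocessing, training loop, early stopping, checkpoints, evaluation |
| `pestnet.cli` | `pestnet` command group |
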