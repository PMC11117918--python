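# promptad

Zero-shot anomaly classification and segmentation for 2-D biomedical-style
images, built on vision–language ideas: a pair of **text prototype anchors**
(one describing the normal state, one the abnormal state) scores frozen
image features by similarity, and a small trainable **feature adapter**
re-shapes those features using *normal images only* so that the anchors
separate lesions from healthy anatomy.

The package is aimed at method developers who want to study this family of
detectors — prompt ensembling, hierarchical patch features, intra-/inter-
modal contrastive constraints, adapter fine-tuning, AUROC evaluation —
without downloading pre-trained weights or clinical data: a seeded phantom
generator provides organ-like images with exact lesion masks, and a
deterministic toy encoder pair stands in for a pre-trained backbone behind
the same contract that a real one would use.

## The model

Text anchors. Prompt templates (class-specific `spd`, e.g. *"A medical
photo of a healthy brain"*, and class-agnostic `cad`, e.g. *"A medical
photo of something abnormal"*) are crossed with state-descriptor lexicons
and ensembled:

    f_normal   = normalize( mean_i  g_theta(prompt_normal_i) )
    f_abnormal = normalize( mean_j  g_theta(prompt_abnormal_j) )

Scoring. For a unit-norm feature `x` (the global feature for image-level
classification, per-patch features for segmentation) the abnormality score
is a two-anchor softmax at temperature τ:

    s(x) = exp(⟨x, f_abn⟩/τ) / ( exp(⟨x, f_abn⟩/τ) + exp(⟨x, f_norm⟩/τ) )

Per-level patch score maps are bilinearly upsampled to pixel resolution and
averaged across hierarchy levels; both image-level (AC) and pixel-level
(AS) performance are measured by AUROC (Mann–Whitney, ties = ½).

Adapter. Frozen features pass through a residual affine map

    v = normalize( α·W u + (1−α)·u ),     ||W − I||_F ≤ R,

trained on normal images only by minimising a two-anchor cross-entropy
(each normal feature matched to `f_normal`, with `f_abnormal` supplying the
negative) plus an intramodal *irregular* constraint that matches the
off-diagonal image–image similarity structure to a β-scaled text–text
structure:

    L = L_cl + mean_{j≠k} ( ⟨v_j, v'_k⟩ − β·⟨t_j, t_k⟩ )²,   β = 0.4,

where `v'` are features of augmented views. A matching map on the text
anchors is trained jointly. Training runs 50 epochs, batch 16, learning
rate 2·10⁻⁴ (Adam), with analytic gradients in NumPy — no deep-learning
framework required.

## Worked example

```bash
promptad simulate --out data/train --n-normal 100 --n-abnormal 0  --seed 1
promptad simulate --out data/test  --n-normal 50  --n-abnormal 50 --seed 2
promptad train --data data/train --adapter run/adapter.json \
               --log run/train_log.csv --seed 1
promptad score --adapter run/adapter.json --images data/test --out run/pred
promptad eval  --pred run/pred --truth data/test --out run/eval.json
```

The `train` step reports the loss trajectory
(`loss 0.3540 -> 0.0775`) and the `eval` step prints:

```json
{
  "ac_auroc": 0.8928,
  "as_auroc": 0.9835312952763845,
  "n_images": 100,
  "n_pixels": 409600
}
```

`ac_auroc` is the probability that a random abnormal image outscores a
random normal one; `as_auroc` is the same probability for pixels, pooled
over all test masks. Omitting `--adapter` in the `score` step scores with
the untrained (near-identity) adapter — the zero-shot baseline; the same
data then evaluates to `ac_auroc = 0.7192`, `as_auroc = 0.8639`. That
roughly ten-point with/without-adapter contrast is what the method is
about.

Two ablation harnesses mirror the standard experiments in this literature:

```bash
promptad ablate-beta    --out run/beta_sweep.csv       --seed 1   # β sweep
promptad ablate-prompts --out run/prompt_ablation.csv  --seed 1   # spd/cad
```

## Layout

| module | contents |
|---|---|
| `promptad.prompts` | templates, descriptor lexicons, prompt compilation/import, text bank |
| `promptad.encoders` | encoder contracts, hierarchical features, toy backbone pair |
| `promptad.losses` | InfoNCE, cross-modal squared constraint (λ), intramodal structure constraint (β) |
| `promptad.adapter` | residual feature adapter, NumPy training loop, serialization |
| `promptad.scoring` | two-anchor scores, anomaly maps, AUROC, evaluation reports |
| `promptad.phantom` | seeded phantom generator with exact lesion masks |
| `promptad.pipeline` | end-to-end benchmark, β sweep, prompt ablation |
| `promptad.cli` | `promptad` command-line interface |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
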