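# Methods

This note records the model as implemented, the defaults and why they are
set where they are, what the synthetic benchmark does and does not emulate,
and the numerical choices a maintainer would otherwise have to reverse-
engineer from the code.

## Problem setting

Given only *normal* images of one anatomy at training time, score unseen
images (abnormal vs normal, image level) and localize the abnormality
(pixel level). Supervision comes from language: prompt ensembles describing
the normal and the abnormal state are encoded into two unit-norm anchors
`f_normal`, `f_abnormal`, and every image or patch feature is scored by a
two-anchor softmax over its cosine similarities to them. A small residual
adapter, trained on the normal images alone, re-shapes the frozen features
so that this fixed text-anchored score separates better.

## Prompt engine

Templates come in two scopes: `spd` (class-dependent, contains `{class}`)
and `cad` (class-agnostic). Compilation substitutes every state descriptor
of a lexicon into every template and pools both scopes into one corpus;
spd-only / cad-only pools are available for ablation. Deduplication is
whitespace-normalizing but case-sensitive, since templates may legitimately
differ only in casing. Ensembling is the arithmetic mean of the encoded
prompts followed by L2 normalization — the standard prompt-ensemble
convention; no weighting is attempted. Externally generated prompt text
(e.g. from a language model queried offline) can be imported from a
sectioned plain-text file and is treated identically downstream.

The shipped lexicon seeds the descriptor lists with the usual radiological
phrasing ("normal", "healthy", "intact structure", "enhanced contrast" vs
"presence of lesions", "indications of calcifications", …) plus single-word
synonyms; users extend it per domain.

## Encoders

Everything upstream of scoring is expressed against a small contract: an
image encoder returns a unit-norm global feature plus one unit-norm patch-
feature grid per hierarchy level (levels 6/12/18/24 by convention for
transformer backbones); a text encoder returns unit-norm embeddings of the
same dimension. Real pre-trained backbones attach behind this contract as
plugins; nothing in the library requires them.

The toy image encoder emulates the hierarchy with patch sizes 32/16/8/4 px
standing in for increasing depth. Per patch it computes 12 fixed statistics
(mean, std, min, max, gradient energy, bright-/dark-tail fractions, five
quantiles), augments them with their squares, and projects through a
seeded Gaussian matrix (one per patch size), then normalizes. The global
feature is the normalized mean of the finest-level patch features. All
patch features are strictly local to their pixel window.

The toy text encoder hashes tokens to seeded random unit embeddings and
averages them per prompt. On its own it is *unaligned* with the image
encoder — exactly like two encoders that never saw each other during
pre-training — and zero-shot scoring with such a pair is a coin flip whose
sign depends on the seed. `toy_encoder_pair` therefore emulates what
pre-training actually provides: a weak, fixed cross-modal alignment.
Tokens naming abnormal states point (weight 0.85, remainder random) along
the image encoder's *anomaly direction* — the summed projection rows of
gradient energy (weight 3), bright-tail fraction (1) and max intensity
(0.5), linear and squared — and tokens naming normal states along a
*tissue direction* whose response peaks at the nominal tissue intensity.
The gradient-heavy mix reproduces the characteristic zero-shot behaviour
of vision–language anomaly detectors: rims, edges and enhancing structures
light up, flat lesion interiors are missed, and the zero-shot baseline is
respectable but clearly improvable. The benchmark uses one fixed backbone
seed (7): a pre-trained backbone is a fixed artifact, not something
resampled per experiment; run seeds steer only data and training.

## Loss family

All losses act on unit-norm feature rows.

* `cross_modal_infonce` — symmetrized InfoNCE at temperature τ, matched
  pairs on the diagonal.
* `cross_clip_loss` — mean over matched×mismatched combinations of
  `(⟨img_i,txt_i⟩ − λ·⟨img_k,txt_j⟩)²`, the asymmetric squared cross-modal
  constraint; λ ∈ [0,1], deterministic full enumeration rather than
  sampled negatives.
* `intra_structure_loss` — the irregular intramodal constraint: off-
  diagonal entries of the image–image Gram matrix (image vs augmented
  view) matched to β times the text–text Gram; β < 1 keeps the image side
  looser than the text side. The diagonal is excluded because unit-norm
  self-similarity is identically 1 and would add a constant. The 1/N
  normalization is read as the mean over enumerated pairs. A signed
  difference of intramodal InfoNCE terms is kept behind
  `irc_form="signed"` purely for ablation; the squared form is canonical
  because it is bounded below.
* `combined_loss` — `w_cl · InfoNCE + w_irc · intra`, weights (1, 1).

When every training image shares the same matched text (the normal-only
regime), batch InfoNCE degenerates to the constant `log n`; training
therefore uses the two-anchor specialization `anchor_infonce`, a per-sample
cross-entropy over (f_normal, f_abnormal). The generic batch losses remain
the public API and are verified against scalar double-loop oracles.

## Adapter and training

The adapter is one residual affine map per modality,
`v = normalize(α·W u + (1−α)·u)`, applied to the global feature and to all
patch features (a per-level variant exists behind `per_level`). Defaults
and their reasons:

| parameter | default | why |
|---|---|---|
| epochs / batch / lr | 50 / 16 / 2·10⁻⁴ | the study's training regime |
| optimizer | Adam | plain SGD at this lr leaves the map unmoved in 50 epochs |
| α (residual mixing) | 0.5 | 0.2 cannot re-shape features enough within the step budget; 0.8 destabilizes |
| trust region `max_drift` | 3 (image), 8 (text) | unconstrained training collapses W toward rank one — every input maps to the normal-anchor ray and the score becomes constant; the Frobenius cap keeps the map a bounded perturbation of the identity, which is what "residual adapter" means |
| training τ | 0.4 | at the CLIP inference temperature 0.07 the two-anchor cross-entropy saturates at a margin of ≈6τ and gradients die long before the map has learned anything; image-level AUROC is invariant to the scoring τ, so one τ = 0.4 is used throughout |
| β (irregular factor) | 0.4 | the study's setting |
| `adapt_text` | on | with a frozen text side the anchor difference vector cannot be rotated away from normal-feature noise; training both sides is what closes the last ~5 AUROC points at image level. `adapt_text=False` retains image-only adaptation |

Training samples are the global feature plus a seeded subsample
(`patches_per_level = 8`) of patch features per image and level, each
paired with `f_normal`; augmented views (horizontal flip + light pixel
noise, mirrored patch indexing) feed the intramodal term. The backbone is
frozen throughout: features are encoded once, and a regression test checks
bit-identical encoder outputs before and after training.

Gradients of the objective with respect to both maps are derived by hand
(chain rule through the affine map and the row normalization) and verified
against central finite differences; the loop is plain NumPy. Runs are
deterministic given the config seed; order is reshuffled each epoch from
the same stream.

## Scoring and evaluation

Image score: two-anchor softmax on the adapted global feature. Pixel map:
the same softmax per patch and level, upsampled bilinearly from patch
centers (half-open windows, edge values clamped) and averaged across
levels with equal weights; optional Gaussian smoothing (σ = 2 px) is off
by default. AUROC uses the Mann–Whitney rank statistic with average ranks
on ties; pixel AUROC pools all pixels across the test set by default, with
a per-image-averaged variant behind a flag. Both variants are exposed
because published pixel-AUROC numbers are ambiguous between them.

## Synthetic benchmark

Each phantom is a rotated soft-edged ellipse ("organ", intensity
0.55 ± 0.05) on a dark background, with two-scale smooth tissue texture
(σ = 0.05 at 3 px and 8 px), 2–5 benign bright blobs (Gaussian, σ 1–2.5 px,
amplitude 0.20–0.45 — enhancing vessels/calcifications that belong to
normal anatomy), and i.i.d. sensor noise (σ = 0.02), clipped to [0, 1].
Abnormal phantoms add one high-contrast disk lesion (radius 9–14 px,
contrast 0.25–0.45) strictly inside the organ, with its exact pixel mask;
a ring lesion type exists. Per-sample seeds spawn from the master seed, so
datasets are reproducible and disjoint seeds give disjoint streams.

The benchmark conditions are: 100 normal training phantoms, 50 normal +
50 abnormal test phantoms at 64×64. These sizes keep a full
simulate–train–score–evaluate cycle at a few seconds on one CPU; the β
sweep and prompt ablation harnesses run the same pipeline at 30 training
and 15+15 test phantoms per cell for the same reason. A typical run
reports, in percent: AC AUROC ≈ 93 with the trained adapter vs ≈ 82
without, AS AUROC ≈ 99 vs ≈ 86 — the with/without-adapter contrast of
roughly ten points that motivates the adapter in the first place.

What the generator does *not* emulate: real anatomy and modality physics
(MRI/CT formation, partial-volume effects), multi-class test domains,
non-focal pathologies, annotation noise, and 3-D structure. Passing the
benchmark shows the machinery — prompt anchoring, hierarchical scoring,
normal-only adaptation — works end to end and that the adapter's benefit
is measurable under controlled conditions; it does not certify clinical
performance.

## Numerical choices and degenerate inputs

Log-sum-exp is max-shifted; norms are floored at 1e-12 before division;
non-finite similarities or losses raise immediately rather than propagate.
Batches need n ≥ 2 (the structure term has no off-diagonal otherwise);
single-class label vectors make AUROC undefined and raise. Images with a
channel axis are reduced by the channel mean before encoding. 16-bit PNG
is used for phantom intensities so disk round trips lose < 1e-4.

## Known limitations

* AUROC at n = 100 test images has a sampling standard error of a few
  points; single-seed comparisons near a threshold should be read
  accordingly.
* The toy backbone's alignment is engineered, not learned; conclusions
  about *which* prompts or β values win do not transfer to real backbones.
* The adapter is a single affine map; it cannot express the quadratic
  (Mahalanobis-style) decision boundary an oracle on the same features
  could, and its image-level gains depend on the anchors carrying a usable
  prior.
* Only 2-D grayscale inputs; one anatomy class per run config.
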