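"""Encoder contracts and deterministic toy encoders.

The framework is backbone-agnostic: anything that maps an image to a
unit-norm global feature plus per-level unit-norm patch-feature grids, and
text to unit-norm embeddings of the same dimension, can drive prompt
compilation, adapter training and scoring. A pre-trained vision-language
backbone attaches behind the same contract as a plugin; the toy encoders
below let the whole pipeline run deterministically with no weights.

The toy image encoder emulates a feature hierarchy by computing fixed patch
statistics (moments, quantiles, gradient energy, tail fractions) at several
patch sizes and projecting them through a seeded random matrix. Coarse
patches stand in for shallow transformer depths and fine patches for deep
ones, preserving the coarse-to-fine semantics of taking representations at
several encoder depths.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncoderSpec",
    "ImageFeatures",
    "encode_image_hierarchical",
    "toy_image_encoder",
    "toy_text_encoder",
    "check_image_encoder",
    "check_text_encoder",
]

#: encoder depths conventionally tapped for hierarchical features
DEFAULT_LEVELS = (6, 12, 18, 24)
#: toy stand-in: one patch size per level, coarse -> fine
DEFAULT_PATCH_SIZES = (32, 16, 8, 4)


@dataclass(frozen=True)
class EncoderSpec:
    """Declares the shared embedding dimension and the feature hierarchy."""

    feature_dim: int = 128
    levels: tuple[int, ...] = DEFAULT_LEVELS
    patch_sizes: tuple[int, ...] = DEFAULT_PATCH_SIZES

    def __post_init__(self):
        if self.feature_dim < 8:
            raise ValueError("feature_dim must be at least 8")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if list(self.levels) != sorted(set(self.levels)):
            raise ValueError("levels must be strictly increasing")
        if len(self.patch_sizes) != len(self.levels):
            raise ValueError("one patch size per level required")
        if any(p <= 0 for p in self.patch_sizes):
            raise ValueError("patch sizes must be positive")

    @property
    def finest_level(self) -> int:
        """Level with the smallest patch size (finest spatial resolution)."""
        return self.levels[int(np.argmin(self.patch_sizes))]


@dataclass
class ImageFeatures:
    """Unit-norm global feature plus one unit-norm patch grid per level."""

    global_feat: np.ndarray                       # (d,)
    level_feats: dict[int, np.ndarray]            # level -> (rows, cols, d)
    source_size: tuple[int, int]
    patch_sizes: dict[int, int] = field(default_factory=dict)


def _l2norm(x: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(x, axis=axis, keepdims=True)
    return x / np.maximum(n, 1e-12)


def _as_intensity(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite pixels")
    return arr


def _patch_blocks(image: np.ndarray, patch: int) -> np.ndarray:
    """Crop to a multiple of ``patch`` and return (rows, cols, patch, patch)."""
    h, w = image.shape
    r, c = h // patch, w // patch
    if r == 0 or c == 0:
        raise ValueError(f"image {image.shape} smaller than patch size {patch}")
    img = image[: r * patch, : c * patch]
    return img.reshape(r, patch, c, patch).transpose(0, 2, 1, 3)


def _patch_statistics(blocks: np.ndarray) -> np.ndarray:
    """Fixed per-patch statistics vector, shape (rows, cols, 12)."""
    r, c, p, _ = blocks.shape
    flat = blocks.reshape(r, c, p * p)
    q = np.quantile(flat, [0.1, 0.25, 0.5, 0.75, 0.9], axis=-1)  # (5, r, c)
    gy = np.abs(np.diff(blocks, axis=2)).mean(axis=(2, 3)) if p > 1 else np.zeros((r, c))
    gx = np.abs(np.diff(blocks, axis=3)).mean(axis=(2, 3)) if p > 1 else np.zeros((r, c))
    stats = np.stack(
        [
            flat.mean(axis=-1),
            flat.std(axis=-1),
            flat.min(axis=-1),
            flat.max(axis=-1),
            gy + gx,                               # gradient energy
            (flat > 0.75).mean(axis=-1),           # bright-tail fraction
            (flat < 0.25).mean(axis=-1),           # dark-tail fraction
            *q,
        ],
        axis=-1,
    )
    return stats


class ToyImageEncoder:
    """Seeded random-projection encoder over fixed patch statistics.

    Per patch the 12 statistics are expanded with their squares and pushed
    through a fixed Gaussian projection (one matrix per patch size, drawn
    once from the seed), then L2-normalized. The global feature is the
    normalized mean of the finest-level patch features. Every output is a
    deterministic function of (seed, image).
    """

    N_STATS = 12

    def __init__(self, seed: int, spec: EncoderSpec):
        self.seed = int(seed)
        self.spec = spec
        rng = np.random.default_rng([self.seed, 0x1A6E])
        self._proj = {
            p: rng.standard_normal((2 * self.N_STATS, spec.feature_dim))
            / np.sqrt(2 * self.N_STATS)
            for p in spec.patch_sizes
        }

    def __call__(self, image: np.ndarray) -> ImageFeatures:
        img = _as_intensity(image)
        level_feats: dict[int, np.ndarray] = {}
        patch_sizes: dict[int, int] = {}
        for level, patch in zip(self.spec.levels, self.spec.patch_sizes):
            stats = _patch_statistics(_patch_blocks(img, patch))
            feats = np.concatenate([stats, stats**2], axis=-1) @ self._proj[patch]
            level_feats[level] = _l2norm(feats)
            patch_sizes[level] = patch
        finest = self.spec.finest_level
        global_feat = _l2norm(level_feats[finest].reshape(-1, self.spec.feature_dim).mean(axis=0))
        return ImageFeatures(
            global_feat=global_feat,
            level_feats=level_feats,
            source_size=img.shape,
            patch_sizes=patch_sizes,
        )


#: state vocabulary carrying cross-modal grounding in an aligned toy pair;
#: tokens on the abnormal side point along the image encoder's
#: anomaly-statistic directions, tokens on the normal side point away.
ABNORMAL_TOKENS = frozenset({
    "abnormal", "anomaly", "anomalous", "lesion", "lesions", "tumor",
    "calcification", "calcifications", "defect", "defects", "diseased",
})
NORMAL_TOKENS = frozenset({"normal", "healthy", "intact", "unremarkable", "regular"})


class ToyTextEncoder:
    """Hash-token bag-of-embeddings text encoder, deterministic per seed.

    Each token maps to a seeded random unit embedding; a prompt embedding
    is the normalized mean of its token embeddings. Optionally a small set
    of grounded tokens receives a weak fixed component along a supplied
    direction (see :func:`toy_encoder_pair`), emulating the cross-modal
    alignment a pre-trained vision-language pair would have; ungrounded
    tokens stay near-orthogonal to everything for large d.
    """

    def __init__(self, seed: int, feature_dim: int,
                 grounding: dict[str, np.ndarray] | None = None,
                 grounding_weight: float = 0.25):
        if feature_dim < 8:
            raise ValueError("feature_dim must be at least 8")
        if not (0.0 <= grounding_weight < 1.0):
            raise ValueError("grounding weight must lie in [0, 1)")
        self.seed = int(seed)
        self.feature_dim = int(feature_dim)
        self.grounding = grounding or {}
        self.grounding_weight = float(grounding_weight)

    def _token_embedding(self, token: str) -> np.ndarray:
        th = zlib.crc32(token.encode("utf-8"))
        vec = _l2norm(np.random.default_rng([self.seed, th]).standard_normal(self.feature_dim))
        direction = self.grounding.get(token)
        if direction is not None:
            w = self.grounding_weight
            vec = np.sqrt(1.0 - w**2) * vec + w * _l2norm(direction)
        return _l2norm(vec)

    def __call__(self, text: str) -> np.ndarray:
        tokens = [t for t in "".join(ch.lower() if ch.isalnum() else " " for ch in text).split() if t]
        if not tokens:
            raise ValueError("cannot encode an empty prompt")
        emb = np.stack([self._token_embedding(t) for t in tokens]).mean(axis=0)
        return _l2norm(emb)


def toy_image_encoder(seed: int, spec: EncoderSpec | None = None) -> ToyImageEncoder:
    return ToyImageEncoder(seed, spec or EncoderSpec())


def toy_text_encoder(seed: int, feature_dim: int = 128) -> ToyTextEncoder:
    return ToyTextEncoder(seed, feature_dim)


def anomaly_direction(image_encoder: ToyImageEncoder,
                      weights: dict[int, float] | None = None) -> np.ndarray:
    """Feature-space direction of atypical patch statistics.

    Sums, over hierarchy levels, the projection rows of statistics that
    respond to conspicuous structure, weighted per statistic axis, plus
    their squared counterparts. The default leans on gradient energy with
    smaller max-intensity and bright-tail terms: pre-trained anomaly
    prompts respond above all to edges and salient texture, which is also
    why zero-shot segmentation highlights lesion rims and healthy
    boundaries alike while missing flat lesion interiors.
    """
    n = ToyImageEncoder.N_STATS
    if weights is None:
        weights = {3: 0.5, 4: 3.0, 5: 1.0}  # max, gradient energy, bright-tail
    direction = np.zeros(image_encoder.spec.feature_dim)
    for proj in image_encoder._proj.values():
        for ax, wt in weights.items():
            direction += wt * (proj[ax] + proj[ax + n])
    return _l2norm(direction)


def tissue_direction(image_encoder: ToyImageEncoder,
                     tissue_intensity: float = 0.55) -> np.ndarray:
    """Feature-space direction of typical soft-tissue appearance.

    Built from the patch mean and its square so that the inner product with
    a patch feature peaks when the patch mean sits at ``tissue_intensity``:
    the combination 2*t*mean - mean^2 is maximal at mean == t. Dark
    background and saturated-bright patches both score low, which is what
    pre-training aligns phrases like "healthy tissue" with.
    """
    n = ToyImageEncoder.N_STATS
    direction = np.zeros(image_encoder.spec.feature_dim)
    for proj in image_encoder._proj.values():
        direction += 2 * tissue_intensity * proj[0] - proj[n]  # mean, mean^2
    return _l2norm(direction)


def toy_encoder_pair(seed: int, spec: EncoderSpec | None = None,
                     alignment: float = 0.85):
    """A weakly aligned (image, text) toy pair sharing one backbone seed.

    Emulates what pre-training gives a real vision-language backbone: text
    tokens describing abnormal states point weakly along the image
    encoder's anomaly-statistic direction, and normal-state tokens along
    its typical-tissue direction. Zero-shot scoring therefore starts with
    the correct sign but inherits the classic failure mode of
    vision-language anomaly detection — background regions that look
    nothing like healthy tissue score as anomalous — leaving the feature
    adapter to learn the normal appearance distribution away.
    """
    spec = spec or EncoderSpec()
    img_enc = ToyImageEncoder(seed, spec)
    grounding = {t: anomaly_direction(img_enc) for t in ABNORMAL_TOKENS}
    grounding.update({t: tissue_direction(img_enc) for t in NORMAL_TOKENS})
    txt_enc = ToyTextEncoder(seed, spec.feature_dim, grounding=grounding,
                             grounding_weight=alignment)
    return img_enc, txt_enc


def encode_image_hierarchical(image: np.ndarray, encoder, spec: EncoderSpec) -> ImageFeatures:
    """Run ``encoder`` on ``image`` and verify the feature contract.

    Validates input pixels, then checks that the encoder returned one grid
    per declared level and that every vector is unit-norm.
    """
    img = _as_intensity(image)
    if min(img.shape) < min(spec.patch_sizes):
        raise ValueError("image smaller than the smallest patch size")
    feats = encoder(img)
    if set(feats.level_feats) != set(spec.levels):
        raise ValueError("encoder returned the wrong set of levels")
    vecs = [feats.global_feat.reshape(1, -1)] + [
        g.reshape(-1, spec.feature_dim) for g in feats.level_feats.values()
    ]
    for v in vecs:
        if v.shape[-1] != spec.feature_dim:
            raise ValueError("encoder feature dimension mismatch")
        norms = np.linalg.norm(v, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("encoder produced non-unit-norm features")
    return feats


def check_image_encoder(encoder, spec: EncoderSpec, seed: int = 0) -> None:
    """Conformance probe: determinism, shapes and normalization on a random image."""
    side = int(max(spec.patch_sizes)) * 2
    img = np.random.default_rng(seed).uniform(size=(side, side))
    f1 = encode_image_hierarchical(img, encoder, spec)
    f2 = encode_image_hierarchical(img, encoder, spec)
    if not np.array_equal(f1.global_feat, f2.global_feat):
        raise ValueError("image encoder is not deterministic")
    for lv in spec.levels:
        if not np.array_equal(f1.level_feats[lv], f2.level_feats[lv]):
            raise ValueError("image encoder is not deterministic")


def check_text_encoder(encoder, feature_dim: int) -> None:
    v1 = encoder("a probe sentence")
    v2 = encoder("a probe sentence")
    if v1.shape != (feature_dim,) or not np.array_equal(v1, v2):
        raise ValueError("text encoder violates the contract")
    if not np.isclose(np.linalg.norm(v1), 1.0, atol=1e-6):
        raise ValueError("text encoder output not unit-norm")
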