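"""Anomaly scoring and AUROC evaluation.

Image-level classification uses the global feature; pixel-level
segmentation uses the hierarchical patch features. Both score abnormality
by a two-anchor softmax against the text bank at temperature tau:

    score = exp(<f, f_abn>/tau) / (exp(<f, f_abn>/tau) + exp(<f, f_norm>/tau))

which lies in [0, 1] and is 0.5 when a feature sits equidistant from the
two anchors. Per-level patch score maps are bilinearly upsampled to the
source resolution (patch windows mapped to their pixel centers) and
averaged across levels; an optional Gaussian smoothing is off by default.

Both metrics are AUROC, computed by the Mann-Whitney rank statistic with
ties counted one half: image scores against image labels (anomaly
classification, AC) and pooled pixel map values against pooled binary
masks (anomaly segmentation, AS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .encoders import ImageFeatures
from .prompts import TextBank

__all__ = ["AnomalyOutput", "EvalReport", "classify", "segment", "auroc", "evaluate_run"]


@dataclass
class AnomalyOutput:
    score: float                     # image-level abnormality in [0, 1]
    map: np.ndarray                  # (H, W) pixel abnormality in [0, 1]
    levels_used: list[int]
    image_id: str | None = None


@dataclass
class EvalReport:
    ac_auroc: float
    as_auroc: float | None
    n_images: int
    n_pixels: int


def _two_anchor_score(feat: np.ndarray, bank: TextBank, tau: float) -> np.ndarray:
    """Softmax abnormality of feature rows against (f_abnormal, f_normal)."""
    s_abn = feat @ bank.f_abnormal
    s_norm = feat @ bank.f_normal
    # numerically stable two-way softmax
    delta = (s_norm - s_abn) / tau
    return 1.0 / (1.0 + np.exp(delta))


def classify(feats: ImageFeatures, bank: TextBank, tau: float = 0.07) -> float:
    """Image-level abnormality score from the global feature."""
    if feats.global_feat.shape != bank.f_normal.shape:
        raise ValueError("feature/bank dimension mismatch")
    return float(_two_anchor_score(feats.global_feat.reshape(1, -1), bank, tau)[0])


def _upsample_patch_map(patch_map: np.ndarray, patch: int, size: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling from patch centers to pixel resolution.

    Patch (r, c) covers the half-open window [r*p, (r+1)*p) x [c*p, (c+1)*p)
    and is anchored at its center pixel; pixels beyond the outermost
    centers take the edge value.
    """
    h, w = size
    rows, cols = patch_map.shape
    centers_y = np.arange(rows) * patch + (patch - 1) / 2.0
    centers_x = np.arange(cols) * patch + (patch - 1) / 2.0
    yy = np.clip(np.arange(h), centers_y[0], centers_y[-1])
    xx = np.clip(np.arange(w), centers_x[0], centers_x[-1])
    iy = np.clip(np.searchsorted(centers_y, yy) - 1, 0, max(rows - 2, 0))
    ix = np.clip(np.searchsorted(centers_x, xx) - 1, 0, max(cols - 2, 0))
    if rows == 1:
        fy = np.zeros(h)
        iy = np.zeros(h, dtype=int)
        iy1 = iy
    else:
        fy = (yy - centers_y[iy]) / (centers_y[iy + 1] - centers_y[iy])
        iy1 = iy + 1
    if cols == 1:
        fx = np.zeros(w)
        ix = np.zeros(w, dtype=int)
        ix1 = ix
    else:
        fx = (xx - centers_x[ix]) / (centers_x[ix + 1] - centers_x[ix])
        ix1 = ix + 1
    tl = patch_map[np.ix_(iy, ix)]
    tr = patch_map[np.ix_(iy, ix1)]
    bl = patch_map[np.ix_(iy1, ix)]
    br = patch_map[np.ix_(iy1, ix1)]
    top = tl + (tr - tl) * fx[None, :]
    bot = bl + (br - bl) * fx[None, :]
    return top + (bot - top) * fy[:, None]


def segment(feats: ImageFeatures, bank: TextBank, tau: float = 0.07,
            smoothing_sigma: float = 0.0) -> np.ndarray:
    """Pixel-level anomaly map: per-level two-anchor scores, upsampled, averaged."""
    if not feats.level_feats:
        raise ValueError("no hierarchy levels present")
    h, w = feats.source_size
    maps = []
    for lv, grid in feats.level_feats.items():
        rows, cols, d = grid.shape
        scores = _two_anchor_score(grid.reshape(-1, d), bank, tau).reshape(rows, cols)
        patch = feats.patch_sizes.get(lv, h // rows)
        maps.append(_upsample_patch_map(scores, patch, (h, w)))
    amap = np.mean(maps, axis=0)
    if smoothing_sigma > 0:
        amap = ndimage.gaussian_filter(amap, smoothing_sigma)
    return np.clip(amap, 0.0, 1.0)


def score_image(feats: ImageFeatures, bank: TextBank, tau: float = 0.07,
                smoothing_sigma: float = 0.0, image_id: str | None = None) -> AnomalyOutput:
    """Convenience wrapper producing both the score and the map."""
    return AnomalyOutput(score=classify(feats, bank, tau),
                         map=segment(feats, bank, tau, smoothing_sigma),
                         levels_used=sorted(feats.level_feats),
                         image_id=image_id)


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals the probability that a random abnormal item outscores a random
    normal one, ties counted one half. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_run(outputs, labels, masks=None, per_image_pixel_auroc: bool = False) -> EvalReport:
    """AC AUROC over image scores; AS AUROC over pixel maps vs masks.

    Pixel AUROC pools all pixels across the test set by default; with
    ``per_image_pixel_auroc`` it instead averages the per-image AUROC over
    images whose masks contain both classes.
    """
    outputs = list(outputs)
    labels = [int(l) for l in labels]
    if len(outputs) != len(labels):
        raise ValueError("outputs and labels differ in length")
    ac = auroc([o.score for o in outputs], labels)
    as_val, n_pixels = None, 0
    if masks is not None:
        masks = list(masks)
        if len(masks) != len(outputs):
            raise ValueError("outputs and masks differ in length")
        if per_image_pixel_auroc:
            vals = []
            for o, m in zip(outputs, masks):
                m = np.asarray(m).astype(int)
                n_pixels += m.size
                if 0 < m.sum() < m.size:
                    vals.append(auroc(o.map.ravel(), m.ravel()))
            as_val = float(np.mean(vals)) if vals else None
        else:
            flat_scores = np.concatenate([o.map.ravel() for o in outputs])
            flat_masks = np.concatenate([np.asarray(m).astype(int).ravel() for m in masks])
            n_pixels = flat_masks.size
            as_val = auroc(flat_scores, flat_masks)
    return EvalReport(ac_auroc=ac, as_auroc=as_val,
                      n_images=len(outputs), n_pixels=n_pixels)
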