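"""Contrastive and similarity-structure losses.

Three constraints drive adapter training:

* a symmetrized cross-modal InfoNCE loss with temperature tau, matching
  image row i to text row i against all other texts (and vice versa);
* a cross-modal squared constraint with asymmetry factor lambda, pulling
  matched image-text similarities apart from lambda-scaled mismatched ones;
* an intramodal "irregular" constraint with factor beta, matching the
  off-diagonal image-image similarity structure to a beta-scaled text-text
  similarity structure. beta < 1 leaves the image side looser than the
  text side, which is the asymmetry that matters for anomaly detection:
  image features may spread while text anchors stay tight.

All losses take unit-norm rows. The canonical intramodal form is the
bounded squared-structure matching; a signed difference of intramodal
InfoNCE terms is available as ``irc_form="signed"`` for ablation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "BatchFeatures",
    "cross_modal_infonce",
    "cross_clip_loss",
    "intra_structure_loss",
    "combined_loss",
    "anchor_infonce",
]


@dataclass(frozen=True)
class LossConfig:
    tau: float = 0.07        # softmax temperature
    lam: float = 0.5         # asymmetry factor of the cross-modal squared constraint
    beta: float = 0.4        # irregular factor of the intramodal constraint
    w_cl: float = 1.0        # weight of the cross-modal contrastive term
    w_irc: float = 1.0       # weight of the intramodal term
    irc_form: str = "squared"  # "squared" (canonical) or "signed" (ablation)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("lam and beta must lie in [0, 1]")
        if self.w_cl < 0 or self.w_irc < 0 or not np.isfinite(self.w_cl + self.w_irc):
            raise ValueError("term weights must be finite and non-negative")
        if self.irc_form not in ("squared", "signed"):
            raise ValueError(f"unknown irc_form {self.irc_form!r}")


@dataclass
class BatchFeatures:
    """Aligned unit-norm feature rows: images, augmented images, texts."""

    img: np.ndarray                      # (n, d)
    txt: np.ndarray                      # (n, d), row i matched to img row i
    img_aug: np.ndarray | None = None    # (n, d) augmented views; defaults to img

    def __post_init__(self):
        self.img = np.asarray(self.img, dtype=float)
        self.txt = np.asarray(self.txt, dtype=float)
        if self.img_aug is None:
            self.img_aug = self.img
        self.img_aug = np.asarray(self.img_aug, dtype=float)
        if not (self.img.shape == self.txt.shape == self.img_aug.shape):
            raise ValueError("img, txt and img_aug must share shape (n, d)")
        if self.img.ndim != 2 or self.img.shape[0] < 2:
            raise ValueError("batches need at least two samples")
        for block in (self.img, self.txt, self.img_aug):
            if not np.allclose(np.linalg.norm(block, axis=1), 1.0, atol=1e-6):
                raise ValueError("feature rows must be unit-norm")

    @property
    def n(self) -> int:
        return self.img.shape[0]


def _check_finite(sim: np.ndarray) -> np.ndarray:
    if not np.isfinite(sim).all():
        raise FloatingPointError("non-finite similarity encountered")
    return sim


def _infonce_direction(sim: np.ndarray, tau: float) -> float:
    """-mean_i log softmax_i over row logits sim[i, :] / tau, target i."""
    logits = sim / tau
    logits = logits - logits.max(axis=1, keepdims=True)  # stable log-sum-exp
    lse = np.log(np.exp(logits).sum(axis=1))
    n = sim.shape[0]
    return float(np.mean(lse - logits[np.arange(n), np.arange(n)]))


def cross_modal_infonce(batch: BatchFeatures, tau: float) -> float:
    """Symmetrized image<->text InfoNCE at temperature ``tau``.

    Row i of the image block is the positive for row i of the text block;
    all other rows of the opposite modality are negatives. The
    image-to-text and text-to-image directions are averaged.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    sim = _check_finite(batch.img @ batch.txt.T)
    return 0.5 * (_infonce_direction(sim, tau) + _infonce_direction(sim.T, tau))


def cross_clip_loss(batch: BatchFeatures, lam: float) -> float:
    """Cross-modal squared constraint with asymmetry factor ``lam``.

    Every matched similarity <img_i, txt_i> is compared against every
    mismatched similarity <img_k, txt_j> (k != j); the loss is the mean of
    (matched - lam * mismatched)^2 over all such combinations.
    """
    sim = _check_finite(batch.img @ batch.txt.T)
    n = batch.n
    matched = np.diag(sim)                          # (n,)
    off = sim[~np.eye(n, dtype=bool)]               # (n(n-1),)
    diff = matched[:, None] - lam * off[None, :]
    return float(np.mean(diff**2))


def intra_structure_loss(batch: BatchFeatures, beta: float) -> float:
    """Intramodal similarity-structure constraint with irregular factor ``beta``.

    G_I[j, k] = <img_j, img_aug_k> and G_T[j, k] = <txt_j, txt_k>; the loss
    is the mean over off-diagonal entries of (G_I - beta * G_T)^2. The
    diagonal is excluded: self-similarity of unit-norm rows is identically
    one and would only add a constant bias.
    """
    g_img = _check_finite(batch.img @ batch.img_aug.T)
    g_txt = _check_finite(batch.txt @ batch.txt.T)
    off = ~np.eye(batch.n, dtype=bool)
    return float(np.mean((g_img[off] - beta * g_txt[off]) ** 2))


def _intra_signed(batch: BatchFeatures, beta: float, tau: float) -> float:
    """Ablation-only signed form: InfoNCE(img, img_aug) - beta * InfoNCE(txt, txt)."""
    img_term = _infonce_direction(_check_finite(batch.img @ batch.img_aug.T), tau)
    txt_term = _infonce_direction(_check_finite(batch.txt @ batch.txt.T), tau)
    beta = float(np.clip(beta, 0.0, 1.0))
    return img_term - beta * txt_term


def combined_loss(batch: BatchFeatures, cfg: LossConfig) -> dict[str, float]:
    """Weighted training objective: w_cl * contrastive + w_irc * intramodal.

    Returns every component alongside the total for logging.
    """
    loss_cl = cross_modal_infonce(batch, cfg.tau)
    if cfg.irc_form == "squared":
        loss_irc = intra_structure_loss(batch, cfg.beta)
    else:
        loss_irc = _intra_signed(batch, cfg.beta, cfg.tau)
    total = cfg.w_cl * loss_cl + cfg.w_irc * loss_irc
    if not np.isfinite(total):
        raise FloatingPointError("non-finite loss")
    return {"loss_cl": loss_cl, "loss_irc": loss_irc, "total": float(total)}


def anchor_infonce(img: np.ndarray, f_pos: np.ndarray, f_neg: np.ndarray,
                   tau: float) -> float:
    """Two-anchor specialization of the cross-modal loss for normal-only data.

    When every training image shares the same matched text (the normal
    anchor), the generic batch loss degenerates; the abnormal anchor then
    supplies the negatives, giving per image a two-way cross-entropy over
    (f_pos, f_neg). Used by the adapter training loop.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    img = np.asarray(img, dtype=float)
    logits = np.stack([img @ f_pos, img @ f_neg], axis=1) / tau
    logits = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(logits).sum(axis=1))
    return float(np.mean(lse - logits[:, 0]))
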