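"""Trainable feature adapter over frozen encoder outputs.

Pre-trained vision-language features are organized for classification, not
anomaly detection; a small trainable map re-projects them so that normal
images cluster at the normal text anchor while anomalous structure falls
away from it. The adapter is a single residual affine map

    v  =  normalize( alpha * W u + (1 - alpha) * u ),

applied to the global feature and to every patch feature; ``alpha`` in
[0, 1] controls how far the map may move a feature from its frozen input,
and W is initialized near the identity so the untrained adapter is a
no-op. Optionally the text anchors pass through their own map.

Training follows the normal-only regime: the backbone stays frozen, every
normal feature is paired with the normal text anchor (the abnormal anchor
supplying the negatives), and the objective adds the intramodal
similarity-structure constraint on augmented feature pairs. Because the
adapter is one affine map, gradients are derived analytically and the loop
runs in plain NumPy; a finite-difference check in the test suite pins the
gradient down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoders import EncoderSpec, ImageFeatures, encode_image_hierarchical
from .losses import LossConfig
from .prompts import PromptSet, TextBank, build_text_bank

__all__ = [
    "AdapterState",
    "TrainConfig",
    "init_adapter",
    "apply_adapter",
    "adapt_text_bank",
    "train_adapter",
    "save_adapter",
    "load_adapter",
]

_FORMAT_VERSION = 1


@dataclass
class AdapterState:
    w_img: np.ndarray                      # (d, d) shared image map
    alpha: float = 0.2                     # residual mixing coefficient
    w_txt: np.ndarray | None = None        # (d, d) text map; None = identity
    w_img_levels: dict[int, np.ndarray] = field(default_factory=dict)  # per-level maps
    rng_seed: int = 0
    trained: bool = False

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not np.isfinite(self.w_img).all():
            raise ValueError("adapter map contains non-finite values")

    @property
    def dim(self) -> int:
        return self.w_img.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 2e-4
    loss: LossConfig = field(default_factory=lambda: LossConfig(tau=0.4))
    seed: int = 0
    alpha: float = 0.5
    optimizer: str = "adam"          # "adam" or "sgd"
    max_drift: float | None = 3.0    # trust region: Frobenius cap on ||W - I||
    txt_max_drift: float | None = 8.0  # looser cap for the text-side map
    adapt_text: bool = True
    per_level: bool = False
    patches_per_level: int = 8       # training patch features subsampled per image+level
    aug_noise: float = 0.01          # pixel noise of the augmented view

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate < 0:
            raise ValueError("epochs and batch_size must be positive, learning_rate >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def init_adapter(dim: int, cfg: TrainConfig) -> AdapterState:
    """Near-identity initialization: outputs match inputs to ~1e-3."""
    rng = np.random.default_rng([int(cfg.seed), 0xADA9])
    w = np.eye(dim) + 1e-3 * rng.standard_normal((dim, dim)) / np.sqrt(dim)
    state = AdapterState(w_img=w, alpha=cfg.alpha, rng_seed=int(cfg.seed))
    if cfg.adapt_text:
        wt = np.eye(dim) + 1e-3 * rng.standard_normal((dim, dim)) / np.sqrt(dim)
        state.w_txt = wt
    return state


def _adapt_rows(u: np.ndarray, w: np.ndarray, alpha: float):
    """Forward pass; returns (v, z_norm) with v the unit-norm adapted rows."""
    z = alpha * (u @ w.T) + (1.0 - alpha) * u
    nz = np.linalg.norm(z, axis=-1, keepdims=True)
    nz = np.maximum(nz, 1e-12)
    return z / nz, nz


def _backprop_w(dv: np.ndarray, v: np.ndarray, nz: np.ndarray, u: np.ndarray,
                alpha: float) -> np.ndarray:
    """Gradient of the loss w.r.t. W given dL/dv for rows v = z/|z|, z = aWu+(1-a)u."""
    dz = (dv - (dv * v).sum(axis=-1, keepdims=True) * v) / nz
    return alpha * dz.T @ u


def _apply_vec(v: np.ndarray, w: np.ndarray | None, alpha: float) -> np.ndarray:
    if w is None:
        return v
    out, _ = _adapt_rows(v.reshape(1, -1), w, alpha)
    return out[0]


def apply_adapter(feats: ImageFeatures, state: AdapterState) -> ImageFeatures:
    """Map global and per-level patch features; outputs are re-normalized."""
    if feats.global_feat.shape[0] != state.dim:
        raise ValueError("feature dimension does not match adapter")
    g = _apply_vec(feats.global_feat, state.w_img, state.alpha)
    level_feats = {}
    for lv, grid in feats.level_feats.items():
        w = state.w_img_levels.get(lv, state.w_img)
        rows, _ = _adapt_rows(grid.reshape(-1, state.dim), w, state.alpha)
        level_feats[lv] = rows.reshape(grid.shape)
    return ImageFeatures(global_feat=g, level_feats=level_feats,
                         source_size=feats.source_size,
                         patch_sizes=dict(feats.patch_sizes))


def adapt_text_bank(bank: TextBank, state: AdapterState) -> TextBank:
    """Pass the two anchors through the text map (identity unless trained)."""
    return TextBank(f_normal=_apply_vec(bank.f_normal, state.w_txt, state.alpha),
                    f_abnormal=_apply_vec(bank.f_abnormal, state.w_txt, state.alpha))


class _Optimizer:
    """Adam or plain SGD, with an optional trust region around the identity.

    The trust region keeps the adapter a bounded perturbation of the
    identity, matching its residual design: an unconstrained map trained to
    pull every normal feature onto the normal anchor eventually collapses
    toward a rank-one projection, which maps unseen (anomalous) directions
    onto the same ray and erases the very signal scoring needs.
    """

    def __init__(self, kind: str, lr: float, shape, max_drift: float | None = None):
        self.kind, self.lr, self.t = kind, lr, 0
        self.max_drift = max_drift
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)

    def step(self, w: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.kind == "sgd":
            w = w - self.lr * grad
        else:
            self.t += 1
            b1, b2, eps = 0.9, 0.999, 1e-8
            self.m = b1 * self.m + (1 - b1) * grad
            self.v = b2 * self.v + (1 - b2) * grad**2
            mh = self.m / (1 - b1**self.t)
            vh = self.v / (1 - b2**self.t)
            w = w - self.lr * mh / (np.sqrt(vh) + eps)
        if self.max_drift is not None and w.shape[0] == w.shape[1]:
            eye = np.eye(w.shape[0])
            drift = w - eye
            norm = np.linalg.norm(drift)
            if norm > self.max_drift:
                w = eye + drift * (self.max_drift / norm)
        return w


def _training_samples(images, image_encoder, spec: EncoderSpec, cfg: TrainConfig,
                      rng: np.random.Generator):
    """Frozen (feature, augmented-feature, group) rows from the normal set.

    One global feature per image plus a seeded subsample of patch features
    at every level; the augmented counterpart comes from a horizontally
    flipped, lightly noised copy (patch indices mirrored so content lines
    up). Grouping by level supports per-level adapter maps.
    """
    rows, rows_aug, groups = [], [], []
    for image in images:
        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        aug = img[:, ::-1] + rng.standard_normal(img.shape) * cfg.aug_noise
        f = encode_image_hierarchical(img, image_encoder, spec)
        fa = encode_image_hierarchical(aug, image_encoder, spec)
        rows.append(f.global_feat)
        rows_aug.append(fa.global_feat)
        groups.append("global")
        for lv in spec.levels:
            grid, grid_a = f.level_feats[lv], fa.level_feats[lv]
            r, c, _ = grid.shape
            k = min(cfg.patches_per_level, r * c)
            idx = rng.choice(r * c, size=k, replace=False)
            for j in idx:
                pr, pc = divmod(int(j), c)
                rows.append(grid[pr, pc])
                rows_aug.append(grid_a[pr, c - 1 - pc])  # mirrored column
                groups.append(lv)
    return np.stack(rows), np.stack(rows_aug), np.array(groups, dtype=object)


def _batch_loss_and_grads(u, u_aug, state: AdapterState, w, f_n, f_a, lc: LossConfig,
                          want_text_grads: bool):
    """Objective on one batch and analytic gradients w.r.t. the maps.

    Cross-modal term: two-anchor InfoNCE of the adapted rows against
    (f_normal, f_abnormal). Intramodal term: off-diagonal structure of the
    adapted rows against their augmented views, matched to beta times the
    text-side structure (identically one here since all matched texts are
    the same anchor).
    """
    b = u.shape[0]
    v, nz = _adapt_rows(u, w, state.alpha)
    v2, nz2 = _adapt_rows(u_aug, w, state.alpha)
    tau, beta = lc.tau, lc.beta

    # --- cross-modal two-anchor cross-entropy
    logits = np.stack([v @ f_n, v @ f_a], axis=1) / tau
    shifted = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(shifted)
    p /= p.sum(axis=1, keepdims=True)
    loss_cl = float(np.mean(np.log(np.exp(shifted).sum(axis=1)) - shifted[:, 0]))
    dcl_dv = ((p[:, 0] - 1.0)[:, None] * f_n + p[:, 1][:, None] * f_a) / (tau * b)

    # --- intramodal structure term (text-side off-diagonal structure == 1)
    off = ~np.eye(b, dtype=bool)
    g = v @ v2.T
    err = np.where(off, g - beta, 0.0)
    m = b * (b - 1)
    loss_irc = float((err**2).sum() / m)
    dg = 2.0 * err / m
    dirc_dv = dg @ v2
    dirc_dv2 = dg.T @ v

    dv = lc.w_cl * dcl_dv + lc.w_irc * dirc_dv
    dv2 = lc.w_irc * dirc_dv2
    grad_w = _backprop_w(dv, v, nz, u, state.alpha) + _backprop_w(dv2, v2, nz2, u_aug, state.alpha)

    grads_txt = None
    if want_text_grads:
        # only the cross-modal term touches the anchors (the text-side
        # structure matrix is constant at one regardless of the map)
        d_fn = lc.w_cl * ((p[:, 0] - 1.0)[:, None] * v).sum(axis=0) / (tau * b)
        d_fa = lc.w_cl * (p[:, 1][:, None] * v).sum(axis=0) / (tau * b)
        grads_txt = (d_fn, d_fa)

    total = lc.w_cl * loss_cl + lc.w_irc * loss_irc
    return {"loss_cl": loss_cl, "loss_irc": loss_irc, "total": total}, grad_w, grads_txt


def train_adapter(normal_images, prompts, image_encoder, text_encoder,
                  spec: EncoderSpec, cfg: TrainConfig):
    """Fit the adapter on normal-only images; returns (state, per-epoch log).

    ``prompts`` may be a :class:`PromptSet` (the text bank is built here) or
    a ready :class:`TextBank`. The backbone is frozen: all features are
    encoded once up front and only the adapter maps move. Deterministic for
    a fixed config seed.
    """
    normal_images = list(normal_images)
    if not normal_images:
        raise ValueError("training set is empty")
    if isinstance(prompts, PromptSet):
        bank = build_text_bank(prompts, text_encoder)
    elif isinstance(prompts, TextBank):
        bank = prompts
    else:
        raise TypeError("prompts must be a PromptSet or TextBank")

    state = init_adapter(spec.feature_dim, cfg)
    rng = np.random.default_rng([int(cfg.seed), 0x7A11])
    u_all, u_aug_all, groups = _training_samples(normal_images, image_encoder, spec, cfg, rng)
    if cfg.per_level:
        for lv in spec.levels:
            state.w_img_levels[lv] = state.w_img.copy()

    # map each sample group to the weight key it trains
    def _key(grp):
        return grp if (cfg.per_level and grp != "global") else "shared"

    weights: dict = {"shared": state.w_img}
    if cfg.per_level:
        weights.update({lv: state.w_img_levels[lv] for lv in spec.levels})
    opts = {k: _Optimizer(cfg.optimizer, cfg.learning_rate, w.shape, cfg.max_drift)
            for k, w in weights.items()}
    opt_txt = _Optimizer(cfg.optimizer, cfg.learning_rate,
                         (spec.feature_dim, spec.feature_dim), cfg.txt_max_drift) \
        if cfg.adapt_text else None

    n = u_all.shape[0]
    log = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {"loss_cl": 0.0, "loss_irc": 0.0, "total": 0.0}
        nb = 0
        bank_a = adapt_text_bank(bank, state)
        f_n, f_a = bank_a.f_normal, bank_a.f_abnormal
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue  # structure term needs at least a pair
            if cfg.adapt_text:  # anchors move with the text map
                bank_a = adapt_text_bank(bank, state)
                f_n, f_a = bank_a.f_normal, bank_a.f_abnormal
            # one optimizer step per weight key present in the batch
            batch_keys = {_key(g) for g in groups[idx]}
            comp_acc = None
            for k in batch_keys:
                sel = idx[[_key(g) == k for g in groups[idx]]]
                if sel.size < 2:
                    continue
                comps, grad_w, grads_txt = _batch_loss_and_grads(
                    u_all[sel], u_aug_all[sel], state, weights[k],
                    f_n, f_a, cfg.loss, cfg.adapt_text)
                if not np.isfinite(comps["total"]):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                weights[k] = opts[k].step(weights[k], grad_w)
                if cfg.adapt_text and grads_txt is not None:
                    d_fn, d_fa = grads_txt
                    gt = _anchor_grad_to_map(bank, state, d_fn, d_fa)
                    state.w_txt = opt_txt.step(state.w_txt, gt)
                comp_acc = comps if comp_acc is None else \
                    {kk: comp_acc[kk] + comps[kk] for kk in comps}
            if comp_acc is not None:
                for kk in sums:
                    sums[kk] += comp_acc[kk]
                nb += 1
        state.w_img = weights["shared"]
        if cfg.per_level:
            state.w_img_levels = {lv: weights[lv] for lv in spec.levels}
        log.append({"epoch": epoch, **{k: s / max(nb, 1) for k, s in sums.items()}})
    state.trained = cfg.learning_rate > 0 and cfg.epochs > 0
    return state, log


def _anchor_grad_to_map(bank: TextBank, state: AdapterState, d_fn, d_fa) -> np.ndarray:
    u = np.stack([bank.f_normal, bank.f_abnormal])
    v, nz = _adapt_rows(u, state.w_txt, state.alpha)
    dv = np.stack([d_fn, d_fa])
    return _backprop_w(dv, v, nz, u, state.alpha)


def save_adapter(state: AdapterState, path: str | Path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "alpha": state.alpha,
        "rng_seed": state.rng_seed,
        "trained": state.trained,
        "w_img": state.w_img.tolist(),
        "w_txt": None if state.w_txt is None else state.w_txt.tolist(),
        "w_img_levels": {str(k): v.tolist() for k, v in state.w_img_levels.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_adapter(path: str | Path) -> AdapterState:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported adapter file version")
    return AdapterState(
        w_img=np.asarray(payload["w_img"], dtype=float),
        alpha=float(payload["alpha"]),
        w_txt=None if payload["w_txt"] is None else np.asarray(payload["w_txt"], dtype=float),
        w_img_levels={int(k): np.asarray(v, dtype=float)
                      for k, v in payload["w_img_levels"].items()},
        rng_seed=int(payload["rng_seed"]),
        trained=bool(payload["trained"]),
    )
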