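"""Independent brute-force oracles used to pin down vectorized code.

Everything here is written as explicit Python double loops over scalars, on
purpose: these functions must stay independent of the implementations they
check.
"""

from __future__ import annotations

import math

import numpy as np


def infonce_oracle(img, txt, tau: float) -> float:
    """Symmetrized InfoNCE by explicit per-sample log-sum-exp loops."""
    n = len(img)

    def direction(a, b):
        total = 0.0
        for i in range(n):
            pos = float(np.dot(a[i], b[i])) / tau
            denom = 0.0
            for j in range(n):
                denom += math.exp(float(np.dot(a[i], b[j])) / tau)
            total += -(pos - math.log(denom))
        return total / n

    return 0.5 * (direction(img, txt) + direction(txt, img))


def cross_clip_oracle(img, txt, lam: float) -> float:
    """Mean over matched (i,i) x mismatched (k,j), k != j, of squared gaps."""
    n = len(img)
    total, count = 0.0, 0
    for i in range(n):
        matched = float(np.dot(img[i], txt[i]))
        for k in range(n):
            for j in range(n):
                if k == j:
                    continue
                mismatched = float(np.dot(img[k], txt[j]))
                total += (matched - lam * mismatched) ** 2
                count += 1
    return total / count


def intra_structure_oracle(img, img_aug, txt, beta: float) -> float:
    """Mean over off-diagonal (j, k) of (G_I - beta * G_T)^2."""
    n = len(img)
    total, count = 0.0, 0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            gi = float(np.dot(img[j], img_aug[k]))
            gt = float(np.dot(txt[j], txt[k]))
            total += (gi - beta * gt) ** 2
            count += 1
    return total / count


def auroc_oracle(scores, labels) -> float:
    """Pair counting: P(abnormal > normal), ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_unit_rows(rng, n: int, d: int) -> np.ndarray:
    x = rng.standard_normal((n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
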