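"""PNG input/output for phantom images, masks and anomaly heatmaps.

Images are stored as 16-bit grayscale PNG (intensities in [0, 1] scaled to
the full range) so that round-tripping through disk loses essentially no
precision; masks are 8-bit with nonzero meaning abnormal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask", "write_heatmap"]

_U16 = 65535.0


def write_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * _U16 + 0.5).astype(np.uint16)).save(str(path))


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG as a float intensity array in [0, 1].

    8-bit and 16-bit grayscale are rescaled by their bit depth; RGB(A) images
    are reduced to intensity by the channel mean.
    """
    img = Image.open(str(path))
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if img.mode in ("I;16", "I"):
        return arr / _U16
    return arr / 255.0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(str(path))


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return (arr > 0).astype(np.uint8)


def write_heatmap(path: str | Path, amap: np.ndarray) -> None:
    """Write an anomaly map in [0, 1] as an 8-bit PNG on the fixed [0, 1] scale."""
    arr = np.clip(np.asarray(amap, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255 + 0.5).astype(np.uint8)).save(str(path))
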