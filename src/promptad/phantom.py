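"""Seeded synthetic phantom images for anomaly-detection benchmarking.

Each phantom is a smooth elliptical "organ" on a dark background with
low-frequency texture and sensor noise. Abnormal variants carry one or more
geometric lesions (bright disks or rings) drawn strictly inside the organ,
together with an exact binary ground-truth mask. The generator is fully
deterministic per (config, seed), so training sets, test sets and ablation
sweeps can be regenerated anywhere without shipping image data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pngio import write_image, write_mask

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom family.

    Sizes are pixels; intensities live in [0, 1]. ``lesion_contrast`` is the
    additive intensity offset of the lesion relative to the organ tissue, so
    a contrast of 0.35 on a 0.55-intensity organ saturates near white.
    """

    size: tuple[int, int] = (64, 64)
    organ_center_jitter: float = 3.0        # px, per-sample jitter of the organ center
    organ_axes: tuple[float, float] = (22.0, 18.0)   # semi-axes, px
    organ_axes_jitter: float = 2.0
    organ_intensity: float = 0.55
    organ_intensity_jitter: float = 0.05     # per-sample tissue brightness variation
    background_intensity: float = 0.10
    edge_sigma: float = 1.5                  # px, softness of the organ boundary
    texture_sigma: float = 0.05              # amplitude of smooth tissue texture
    texture_scale: float = 3.0               # px, correlation length (fine scale)
    texture_scale_coarse: float = 8.0        # px, second, coarser texture component
    lesion_shape: str = "disk"               # "disk" or "ring"
    lesion_radius: tuple[float, float] = (9.0, 14.0)
    lesion_contrast: tuple[float, float] = (0.25, 0.45)
    ring_width: float = 2.5                  # px, only for ring lesions
    n_lesions: int = 1
    # benign enhancing structures (vessels/ducts): small smooth bright blobs
    # present in normal anatomy; they are NOT part of the anomaly mask
    n_distractors: tuple[int, int] = (2, 5)
    distractor_sigma: tuple[float, float] = (1.0, 2.5)       # px
    distractor_amplitude: tuple[float, float] = (0.20, 0.45)  # above tissue
    noise_sigma: float = 0.02                # i.i.d. sensor noise

    def validate(self) -> None:
        h, w = self.size
        if h < 8 or w < 8:
            raise ValueError("phantom size must be at least 8x8")
        if self.lesion_radius[0] > self.lesion_radius[1]:
            raise ValueError("lesion radius range inverted")
        if self.lesion_radius[1] >= min(h, w) / 2:
            raise ValueError("lesion radius must be smaller than half the image")
        if self.lesion_shape not in ("disk", "ring"):
            raise ValueError(f"unknown lesion shape {self.lesion_shape!r}")
        lo, hi = self.lesion_contrast
        if lo == 0.0 and hi == 0.0:
            raise ValueError("lesion contrast must be nonzero for abnormal samples")
        if self.lesion_radius[1] >= min(self.organ_axes) - 1.0:
            raise ValueError("lesion cannot fit inside the organ")


@dataclass
class PhantomSample:
    image: np.ndarray                # (H, W) float in [0, 1]
    label: int                       # 0 normal, 1 abnormal
    mask: np.ndarray                 # (H, W) uint8 in {0, 1}; exact lesion support
    meta: dict = field(default_factory=dict)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float, scale: float) -> np.ndarray:
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, scale)
    sd = sm.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return sigma * sm / sd


def generate_phantom(cfg: PhantomConfig, abnormal: bool, seed: int) -> PhantomSample:
    """Draw one phantom; bit-identical for identical (cfg, abnormal, seed)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    h, w = cfg.size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    cy = h / 2 + rng.uniform(-cfg.organ_center_jitter, cfg.organ_center_jitter)
    cx = w / 2 + rng.uniform(-cfg.organ_center_jitter, cfg.organ_center_jitter)
    ay = cfg.organ_axes[0] + rng.uniform(-cfg.organ_axes_jitter, cfg.organ_axes_jitter)
    ax = cfg.organ_axes[1] + rng.uniform(-cfg.organ_axes_jitter, cfg.organ_axes_jitter)
    phi = rng.uniform(0, np.pi)  # ellipse orientation
    tissue = cfg.organ_intensity + rng.uniform(-cfg.organ_intensity_jitter,
                                               cfg.organ_intensity_jitter)

    # signed "inside-ness" of the rotated ellipse, softened into a smooth edge
    yr = (yy - cy) * np.cos(phi) + (xx - cx) * np.sin(phi)
    xr = -(yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
    r2 = (yr / ay) ** 2 + (xr / ax) ** 2
    organ = 1.0 / (1.0 + np.exp((np.sqrt(r2) - 1.0) * max(ay, ax) / cfg.edge_sigma))
    image = cfg.background_intensity + (tissue - cfg.background_intensity) * organ
    texture = _smooth_noise(rng, (h, w), cfg.texture_sigma, cfg.texture_scale) \
        + _smooth_noise(rng, (h, w), cfg.texture_sigma, cfg.texture_scale_coarse)
    image = image + texture * organ

    # benign bright structures inside the organ, part of normal anatomy
    n_distr = int(rng.integers(cfg.n_distractors[0], cfg.n_distractors[1] + 1))
    for _ in range(n_distr):
        sig = rng.uniform(*cfg.distractor_sigma)
        amp = rng.uniform(*cfg.distractor_amplitude)
        theta = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(rng.uniform(0, 1))
        dy = cy + rho * (ay - 3 * sig) * np.sin(theta)
        dx = cx + rho * (ax - 3 * sig) * np.cos(theta)
        image = image + amp * np.exp(-(((yy - dy) ** 2 + (xx - dx) ** 2) / (2 * sig**2)))

    mask = np.zeros((h, w), dtype=np.uint8)
    lesions = []
    if abnormal:
        for _ in range(cfg.n_lesions):
            radius = rng.uniform(*cfg.lesion_radius)
            contrast = rng.uniform(*cfg.lesion_contrast)
            # keep the lesion inside the organ: sample its center within a
            # shrunken ellipse so that the whole lesion support fits
            margin_y = ay - radius - 1.0
            margin_x = ax - radius - 1.0
            if margin_y <= 0 or margin_x <= 0:
                raise ValueError("lesion cannot fit inside organ")
            theta = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1))
            ly = cy + rho * margin_y * np.sin(theta)
            lx = cx + rho * margin_x * np.cos(theta)
            d = np.sqrt((yy - ly) ** 2 + (xx - lx) ** 2)
            if cfg.lesion_shape == "disk":
                support = d <= radius
            else:
                support = (d <= radius) & (d >= radius - cfg.ring_width)
            image = np.where(support, image + contrast, image)
            mask |= support.astype(np.uint8)
            lesions.append({"shape": cfg.lesion_shape, "cy": float(ly), "cx": float(lx),
                            "radius": float(radius), "contrast": float(contrast)})

    image = image + rng.standard_normal((h, w)) * cfg.noise_sigma
    image = np.clip(image, 0.0, 1.0)

    label = int(abnormal)
    if label == 1 and mask.sum() == 0:
        raise ValueError("abnormal sample produced an empty mask")
    return PhantomSample(image=image, label=label, mask=mask,
                         meta={"seed": int(seed), "lesions": lesions})


def generate_dataset(cfg: PhantomConfig, n_normal: int, n_abnormal: int, seed: int,
                     out_dir: str | Path | None = None) -> list[PhantomSample]:
    """Generate a labelled phantom dataset; optionally write PNGs + manifest.

    Per-sample seeds are drawn from a ``SeedSequence`` spawned off the master
    seed, so disjoint master seeds yield disjoint sample streams.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("sample counts must be non-negative")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_normal + n_abnormal)
    # keep per-sample seeds in the signed-int range accepted everywhere
    child_seeds = [int(s) % (2 ** 31) for s in child_seeds]
    samples = []
    for i in range(n_normal + n_abnormal):
        abnormal = i >= n_normal
        samples.append(generate_phantom(cfg, abnormal, child_seeds[i]))

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.csv", "w", newline="") as fh:
            wcsv = csv.writer(fh)
            wcsv.writerow(["id", "label", "seed", "lesions"])
            for i, s in enumerate(samples):
                sid = f"{i:05d}"
                write_image(out / "images" / f"{sid}.png", s.image)
                write_mask(out / "masks" / f"{sid}.png", s.mask)
                wcsv.writerow([sid, s.label, s.meta["seed"], repr(s.meta["lesions"])])
    return samples
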