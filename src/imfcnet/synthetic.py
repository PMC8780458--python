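"""Synthetic shoulder-implant radiograph generator.

Emulates the salient structure of implant X-rays so every pipeline stage can
run without the clinical dataset: a dark noisy background, a bright
elongated stem, and a humeral-head disc carrying class-specific geometry —
the number of dark fixation holes punched into the head and the number of
bright fins radiating from it differ per manufacturer class, which makes the
four classes separable by construction.  Default per-class counts mirror the
real collection (83 Cofield, 294 Depuy, 71 Tornier, 149 Zimmer; 597 total).

Rendering is analytic (signed-distance style masks on a rotated coordinate
grid), so rotation/jitter never resample pixels; identical seeds give
bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .cp_heads import CLASS_LABELS
from .data import DatasetIndex, Record


@dataclass(frozen=True)
class ClassGeometry:
    """Geometry of one manufacturer's synthetic implant."""

    hole_count: int
    fin_count: int
    head_radius: float = 0.19      # fraction of half-width
    hole_radius: float = 0.045
    stem_width: float = 0.11
    stem_length: float = 0.62
    fin_length: float = 0.10
    fin_width_rad: float = 0.22    # angular half-width of a fin wedge


DEFAULT_GEOMETRY: dict[str, ClassGeometry] = {
    "Cofield": ClassGeometry(hole_count=1, fin_count=0),
    "Depuy": ClassGeometry(hole_count=2, fin_count=1),
    "Tornier": ClassGeometry(hole_count=3, fin_count=2),
    "Zimmer": ClassGeometry(hole_count=4, fin_count=3),
}


@dataclass
class SyntheticConfig:
    class_counts: dict[str, int] = field(default_factory=lambda: {
        "Cofield": 83, "Depuy": 294, "Tornier": 71, "Zimmer": 149})
    image_size: int = 256
    geometry: dict[str, ClassGeometry] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY))
    background: float = 25.0       # mean background intensity, 0-255
    stem_intensity: float = 185.0
    head_intensity: float = 215.0
    noise_sigma: float = 6.0       # additive Gaussian, 0-255 scale
    intensity_jitter: float = 0.08  # multiplicative, uniform +-
    rotation_range: float = 15.0   # global in-plane rotation, degrees
    seed: int = 0

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def _smooth_mask(d: np.ndarray, edge: float = 0.01) -> np.ndarray:
    """Soft inside-mask from a signed distance (negative = inside)."""
    return np.clip(0.5 - d / edge, 0.0, 1.0)


def render_implant(geometry: ClassGeometry, size: int,
                   rng: np.random.Generator, *, background: float = 25.0,
                   stem_intensity: float = 185.0,
                   head_intensity: float = 215.0, noise_sigma: float = 6.0,
                   intensity_jitter: float = 0.08,
                   rotation_range: float = 15.0) -> np.ndarray:
    """Render one synthetic radiograph as (size, size) uint8."""
    theta = np.deg2rad(rng.uniform(-rotation_range, rotation_range))
    dx, dy = rng.uniform(-0.06, 0.06, size=2)
    scale = rng.uniform(0.92, 1.08)
    gain = 1.0 + rng.uniform(-intensity_jitter, intensity_jitter)

    lin = np.linspace(-1.0, 1.0, size, dtype=np.float64)
    xx, yy = np.meshgrid(lin, lin)
    # rotate/translate/scale the model frame
    xr = (np.cos(theta) * (xx - dx) + np.sin(theta) * (yy - dy)) / scale
    yr = (-np.sin(theta) * (xx - dx) + np.cos(theta) * (yy - dy)) / scale

    g = geometry
    head_c = (0.0, -0.30)
    img = np.full((size, size), background, dtype=np.float64)

    # stem: rounded vertical bar below the head
    stem_d = np.maximum(np.abs(xr) - g.stem_width / 2,
                        np.maximum(head_c[1] - yr,
                                   yr - (head_c[1] + g.stem_length)))
    stem = _smooth_mask(stem_d)
    img += stem * (stem_intensity - background)

    # head disc
    rad = np.hypot(xr - head_c[0], yr - head_c[1])
    head = _smooth_mask(rad - g.head_radius)
    img = np.maximum(img, background + head * (head_intensity - background))

    # fins: bright wedges on the head rim, evenly spaced
    if g.fin_count:
        ang = np.arctan2(yr - head_c[1], xr - head_c[0])
        ring = _smooth_mask(np.maximum(rad - (g.head_radius + g.fin_length),
                                       g.head_radius * 0.8 - rad))
        for k in range(g.fin_count):
            a0 = -np.pi / 2 + 2 * np.pi * k / max(g.fin_count, 1)
            dang = np.angle(np.exp(1j * (ang - a0)))
            wedge = _smooth_mask(np.abs(dang) - g.fin_width_rad, edge=0.05)
            img = np.maximum(img, background + ring * wedge *
                             (head_intensity - background))

    # holes: dark discs inside the head, on a small circle
    for k in range(g.hole_count):
        a = 2 * np.pi * k / max(g.hole_count, 1) + np.pi / 4
        hx = head_c[0] + 0.5 * g.head_radius * np.cos(a)
        hy = head_c[1] + 0.5 * g.head_radius * np.sin(a)
        hole = _smooth_mask(np.hypot(xr - hx, yr - hy) - g.hole_radius)
        img = img * (1 - hole) + hole * background

    img = background + (img - background) * gain
    img += rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_synthetic(config: SyntheticConfig | None = None,
                       out_dir=None) -> DatasetIndex:
    """Write the synthetic class-per-directory tree and its manifest.

    The manifest (``manifest.csv`` at the root) records the geometry used for
    every image.  The same config (seed included) reproduces the tree
    bit-identically.
    """
    import pandas as pd

    config = config or SyntheticConfig()
    if out_dir is None:
        raise ValueError("out_dir is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    class_seeds = root_ss.spawn(len(config.class_counts))
    records: list[Record] = []
    manifest_rows = []
    classes = tuple(sorted(config.class_counts))
    for cls, ss in zip(classes, class_seeds):
        geometry = config.geometry[cls]
        cls_dir = out / cls
        cls_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(ss)
        for i in range(config.class_counts[cls]):
            arr = render_implant(
                geometry, config.image_size, rng,
                background=config.background,
                stem_intensity=config.stem_intensity,
                head_intensity=config.head_intensity,
                noise_sigma=config.noise_sigma,
                intensity_jitter=config.intensity_jitter,
                rotation_range=config.rotation_range)
            p = cls_dir / f"{cls.lower()}_{i:04d}.png"
            Image.fromarray(arr).save(p)
            records.append(Record(str(p), cls, p.stem))
            manifest_rows.append({
                "path": str(p), "class": cls,
                "hole_count": geometry.hole_count,
                "fin_count": geometry.fin_count,
                "head_radius": geometry.head_radius,
                "stem_width": geometry.stem_width,
            })
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    return DatasetIndex(records, classes)


def small_config(per_class: int = 10, image_size: int = 128,
                 seed: int = 0) -> SyntheticConfig:
    """A reduced, fully separable configuration for quick experiments:
    ``per_class`` images per manufacturer at a smaller raster."""
    return SyntheticConfig(
        class_counts={c: per_class for c in CLASS_LABELS},
        image_size=image_size, seed=seed)
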