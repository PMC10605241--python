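"""Synthetic two-class H&E-like texture cohorts.

Real cohorts of tumor and normal tissue tiles are replaced by a parametric
texture model whose two presets move every one of the 15 discriminative
features in the reported direction. Tumor-like tiles combine a dark, rough,
noisy cellular bulk, dense dark nuclei-like blobs and pale necrotic plateaus
(raising contrast, the entropies, dissimilarity, gray-level non-uniformity
and the low-gray-level run emphases, because the cellular bulk occupies the
low gray levels); normal-like tiles are bright, homogeneous and finely
textured (raising energy, maximum probability, the homogeneity pair and the
normalized inverse differences).

The generator targets feature-direction fidelity, not visual realism.
Intensity is built as a grayscale field and then mapped through a fixed
purple-to-pink palette so tiles resemble H&E color images; the luminance
conversion downstream inverts this monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import RawImage

__all__ = [
    "ClassTextureParams",
    "CohortConfig",
    "generate_image",
    "generate_cohort",
    "default_separable_presets",
    "hard_presets",
]

#: Default tile size mirroring the capture resolution of the source slides.
DEFAULT_TILE_SIZE = (839, 1304)

# H&E-like palette anchors: dark hematoxylin purple -> light eosin pink.
_DARK_RGB = np.array([64.0, 32.0, 112.0])
_LIGHT_RGB = np.array([244.0, 198.0, 212.0])


@dataclass(frozen=True)
class ClassTextureParams:
    """Texture knobs for one class.

    correlation_length : px — Gaussian smoothing scale of the base random
        field; larger means smoother, finer-grained-looking tissue.
    contrast_amplitude : intensity units — standard deviation of the base
        field around ``base_intensity``.
    blob_density : nuclei-like dark blobs per 10^4 px².
    blob_radius_range : px — uniform radius range of the blobs.
    necrosis_fraction : fraction of the tile covered by pale necrosis-like
        plateaus (0 disables them).
    base_intensity : mean gray level of the tissue background, in [0, 255].
    noise_sd : intensity units — i.i.d. Gaussian pixel noise.
    jitter_cv : coefficient of variation of a per-image lognormal jitter
        applied to contrast_amplitude and noise_sd (models slide-to-slide
        variability; used by the overlapping "hard" presets).
    """

    correlation_length: float = 3.0
    contrast_amplitude: float = 40.0
    blob_density: float = 1.0
    blob_radius_range: tuple[float, float] = (2.0, 6.0)
    necrosis_fraction: float = 0.0
    base_intensity: float = 170.0
    noise_sd: float = 5.0
    jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        if min(
            self.correlation_length,
            self.contrast_amplitude,
            self.blob_density,
            self.noise_sd,
            self.jitter_cv,
        ) < 0:
            raise ValueError("texture parameters must be non-negative")
        if not 0.0 <= self.necrosis_fraction <= 1.0:
            raise ValueError("necrosis_fraction must lie in [0, 1]")
        if not 0.0 <= self.base_intensity <= 255.0:
            raise ValueError("base_intensity must lie in [0, 255]")


@dataclass(frozen=True)
class CohortConfig:
    """Two-class cohort layout: per-class size, tile size, presets and seed."""

    n_per_class: int = 100
    image_size: tuple[int, int] = DEFAULT_TILE_SIZE
    params_normal: ClassTextureParams = ClassTextureParams()
    params_gbm: ClassTextureParams = ClassTextureParams()
    images_per_patient: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.image_size) < 32:
            raise ValueError("image size must be at least 32x32")


def _he_palette(gray: np.ndarray) -> np.ndarray:
    """Map a [0, 255] grayscale field through the purple->pink palette."""
    t = gray[..., None] / 255.0
    rgb = _DARK_RGB + t * (_LIGHT_RGB - _DARK_RGB)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def generate_image(
    params: ClassTextureParams,
    seed: int | np.random.Generator,
    size: tuple[int, int] = DEFAULT_TILE_SIZE,
    source_id: str = "",
    label: str = "UNKNOWN",
    patient_id: str = "",
) -> RawImage:
    """Render one tile: smooth field + blobs + dark patches + noise, H&E palette.

    Fully deterministic for a fixed ``(params, seed, size)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = size

    amp = params.contrast_amplitude
    noise_sd = params.noise_sd
    if params.jitter_cv > 0:
        cv = params.jitter_cv
        sigma = np.sqrt(np.log1p(cv * cv))
        amp *= rng.lognormal(-sigma * sigma / 2.0, sigma)
        noise_sd *= rng.lognormal(-sigma * sigma / 2.0, sigma)

    # tissue-scale background: fixed-amplitude, very smooth illumination/density
    # structure shared by both classes, so the min-max quantization range is
    # anchored and contrast_amplitude genuinely controls *local* variation
    background = ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 6.0, mode="reflect")
    bsd = background.std()
    if bsd > 0:
        background = background / bsd * 2.0

    field = rng.standard_normal((h, w))
    if params.correlation_length > 0:
        field = ndimage.gaussian_filter(field, params.correlation_length, mode="reflect")
    sd = field.std()
    if sd > 0:
        field /= sd
    gray = params.base_intensity + background + amp * field

    n_blobs = rng.poisson(params.blob_density * h * w / 1e4)
    if params.blob_density > 0:
        # every tissue tile contains at least a couple of nuclei; a floor also
        # keeps the per-tile intensity range anchored by the darkest structures
        n_blobs = max(n_blobs, 2)
    if n_blobs > 0:
        rows = rng.uniform(0, h, n_blobs)
        cols = rng.uniform(0, w, n_blobs)
        radii = rng.uniform(*params.blob_radius_range, n_blobs)
        depths = rng.uniform(90.0, 210.0, n_blobs)
        for r0, c0, rad, depth in zip(rows, cols, radii, depths):
            rr = np.arange(max(0, int(r0 - rad - 1)), min(h, int(r0 + rad + 2)))
            cc = np.arange(max(0, int(c0 - rad - 1)), min(w, int(c0 + rad + 2)))
            if len(rr) == 0 or len(cc) == 0:
                continue
            d2 = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
            gray[np.ix_(rr, cc)] -= depth * (d2 <= rad * rad)

    if params.necrosis_fraction > 0:
        patch_field = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), max(4.0, min(h, w) / 8.0), mode="reflect"
        )
        thr = np.quantile(patch_field, params.necrosis_fraction)
        # necrotic regions read as pale, nearly featureless plateaus; they anchor
        # the top of the per-tile intensity range so the cellular bulk stays in
        # the low gray levels after min-max quantization
        gray = np.where(patch_field <= thr, 230.0 + (gray - params.base_intensity) * 0.1, gray)

    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, (h, w))

    gray = np.clip(gray, 0.0, 255.0)
    return RawImage(_he_palette(gray), source_id=source_id, label=label, patient_id=patient_id)


def generate_cohort(cfg: CohortConfig) -> tuple[list[RawImage], pd.DataFrame]:
    """Generate ``n_per_class`` tiles per class with synthetic patient ids.

    Images are grouped ``images_per_patient`` to a patient so patient-level
    splitting can be exercised. Returns the images and a manifest DataFrame
    (source_id, patient_id, label, seed).
    """
    master = np.random.default_rng(cfg.seed)
    images: list[RawImage] = []
    records = []
    for label, params in (("NORMAL", cfg.params_normal), ("GBM", cfg.params_gbm)):
        seeds = master.integers(0, 2**31 - 1, size=cfg.n_per_class)
        for k, img_seed in enumerate(seeds):
            patient = f"{label.lower()}-p{k // cfg.images_per_patient:04d}"
            source = f"{label.lower()}-{k:05d}"
            img = generate_image(
                params,
                int(img_seed),
                cfg.image_size,
                source_id=source,
                label=label,
                patient_id=patient,
            )
            images.append(img)
            records.append(
                {"source_id": source, "patient_id": patient, "label": label, "seed": int(img_seed)}
            )
    return images, pd.DataFrame(records)


def default_separable_presets() -> tuple[ClassTextureParams, ClassTextureParams]:
    """Well-separated presets: every one of the 15 rule directions holds on
    class means (normal smooth/homogeneous, tumor rough/noisy with dark
    necrosis-like patches)."""
    normal = ClassTextureParams(
        correlation_length=2.0,
        contrast_amplitude=10.0,
        blob_density=0.8,
        blob_radius_range=(1.5, 3.0),
        necrosis_fraction=0.0,
        base_intensity=215.0,
        noise_sd=1.8,
    )
    gbm = ClassTextureParams(
        correlation_length=1.5,
        contrast_amplitude=20.0,
        blob_density=2.0,
        blob_radius_range=(3.0, 8.0),
        necrosis_fraction=0.2,
        base_intensity=28.0,
        noise_sd=12.0,
    )
    return normal, gbm


def hard_presets() -> tuple[ClassTextureParams, ClassTextureParams]:
    """Heavily overlapping presets: a small mean shift buried under large
    per-image parameter jitter, so no classifier can separate the classes
    reliably. Used to show the pipeline measures texture signal, not leakage."""
    base = ClassTextureParams(
        correlation_length=3.0,
        contrast_amplitude=40.0,
        blob_density=1.0,
        blob_radius_range=(2.0, 6.0),
        necrosis_fraction=0.05,
        base_intensity=170.0,
        noise_sd=8.0,
        jitter_cv=0.40,
    )
    normal = base
    gbm = replace(base, contrast_amplitude=42.0, noise_sd=8.4)
    return normal, gbm
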