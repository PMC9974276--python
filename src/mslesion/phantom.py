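"""Synthetic FLAIR-like axial brain phantoms with ground-truth labels.

Each phantom is a 2D slice mimicking the gross appearance of an axial FLAIR
brain image: a bright elliptical parenchyma on a dark background, optionally
surrounded by a bright skull annulus, and — for the MS class — one or more
hyperintense lesion blobs with a smooth Gaussian profile placed inside the
parenchyma. Additive Gaussian noise is applied last. The grayscale content is
replicated to three channels so every slice matches the 224x224x3 geometry the
downstream feature extractors expect.

The generator is fully seeded: the same configuration and seed always produce
bit-identical rasters, which makes every downstream stage testable without any
external dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError

LABEL_NORMAL = "normal"
LABEL_MS = "MS"
LABELS = (LABEL_NORMAL, LABEL_MS)

# Fixed gray levels of the phantom tissue model (8-bit scale).
BACKGROUND_LEVEL = 10.0
PARENCHYMA_LEVEL = 130.0
SKULL_LEVEL = 230.0


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom slice generator.

    Attributes
    ----------
    image_size : int
        Side length in pixels of the square slice (>= 32).
    with_skull : bool
        Whether to draw a bright skull annulus outside the parenchyma.
    lesion_count_range : tuple[int, int]
        Inclusive range of the number of lesion blobs for MS slices.
    lesion_radius_range : tuple[float, float]
        Inclusive range of lesion radii in pixels (Gaussian sigma = radius/2).
    lesion_intensity_gain : float
        Peak lesion intensity as a multiple of the parenchyma level (> 1).
    parenchyma_axes : tuple[float, float]
        Semi-axes (row, column) of the parenchyma ellipse in pixels.
    noise_sigma : float
        Standard deviation of the additive Gaussian noise in gray levels.
    seed : int
        Base seed used when the caller does not provide one per slice.
    """

    image_size: int = 224
    with_skull: bool = True
    lesion_count_range: tuple[int, int] = (2, 5)
    lesion_radius_range: tuple[float, float] = (5.0, 12.0)
    lesion_intensity_gain: float = 1.6
    parenchyma_axes: tuple[float, float] = (85.0, 70.0)
    noise_sigma: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError(f"image_size must be >= 32, got {self.image_size}")
        if self.lesion_intensity_gain <= 1.0:
            raise ConfigurationError(
                f"lesion_intensity_gain must exceed 1, got {self.lesion_intensity_gain}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        lo, hi = self.lesion_count_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"empty lesion_count_range {self.lesion_count_range}")
        rlo, rhi = self.lesion_radius_range
        if not (0 < rlo <= rhi):
            raise ConfigurationError(f"empty lesion_radius_range {self.lesion_radius_range}")
        a, b = self.parenchyma_axes
        if a <= 0 or b <= 0 or max(a, b) >= self.image_size / 2:
            raise ConfigurationError(
                f"parenchyma_axes {self.parenchyma_axes} do not fit inside a "
                f"{self.image_size}px image"
            )


@dataclass
class SliceImage:
    """One slice: an 8-bit HxWx3 raster plus label, skull flag and provenance id.

    The three channels are identical at generation time; colour never carries
    information in this pipeline.
    """

    pixels: np.ndarray
    label: str | None = None
    skull: bool = False
    uid: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ConfigurationError(f"pixels must be HxWx3, got shape {px.shape}")
        if self.label is not None and self.label not in LABELS:
            raise ConfigurationError(f"label must be one of {LABELS}, got {self.label!r}")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def gray(self) -> np.ndarray:
        """Single-channel view (channel 0; channels are replicated)."""
        return self.pixels[:, :, 0]


def _ellipse_mask(size: int, axes: tuple[float, float]) -> np.ndarray:
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    a, b = axes
    return ((rr - c) / a) ** 2 + ((cc - c) / b) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, label: str, rng_seed: int) -> SliceImage:
    """Render one labeled phantom slice.

    MS slices receive at least one hyperintense Gaussian lesion blob whose peak
    exceeds the parenchyma level by ``lesion_intensity_gain``; normal slices
    receive none. Deterministic given ``rng_seed``.
    """
    config.validate()
    if label not in LABELS:
        raise ConfigurationError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(rng_seed)
    s = config.image_size
    canvas = np.full((s, s), BACKGROUND_LEVEL, dtype=np.float64)

    paren = _ellipse_mask(s, config.parenchyma_axes)
    canvas[paren] = PARENCHYMA_LEVEL

    if config.with_skull:
        a, b = config.parenchyma_axes
        outer = _ellipse_mask(s, (a + 14.0, b + 14.0))
        inner = _ellipse_mask(s, (a + 7.0, b + 7.0))
        canvas[outer & ~inner] = SKULL_LEVEL

    if label == LABEL_MS:
        lo, hi = config.lesion_count_range
        n_lesions = max(1, int(rng.integers(lo, hi + 1)))
        c = (s - 1) / 2.0
        a, b = config.parenchyma_axes
        rr, cc = np.mgrid[0:s, 0:s]
        peak = (config.lesion_intensity_gain - 1.0) * PARENCHYMA_LEVEL
        for _ in range(n_lesions):
            radius = rng.uniform(*config.lesion_radius_range)
            # rejection-sample a centre well inside the parenchyma ellipse
            while True:
                u, v = rng.uniform(-1, 1, size=2)
                if (u * u + v * v) <= 1.0:
                    cy = c + u * (a - radius - 2.0)
                    cx = c + v * (b - radius - 2.0)
                    if ((cy - c) / a) ** 2 + ((cx - c) / b) ** 2 <= 0.85:
                        break
            sigma = radius / 2.0
            blob = peak * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sigma**2))
            canvas += blob * paren

    if config.noise_sigma > 0:
        canvas += rng.normal(0.0, config.noise_sigma, size=canvas.shape)

    gray = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    pixels = np.repeat(gray[:, :, None], 3, axis=2)
    uid = f"phantom-{label}-{rng_seed}"
    return SliceImage(pixels=pixels, label=label, skull=config.with_skull, uid=uid)


def parenchyma_mean_intensity(image: SliceImage, config: PhantomConfig) -> float:
    """Mean gray level inside the parenchyma ellipse (class-separating statistic)."""
    mask = _ellipse_mask(config.image_size, config.parenchyma_axes)
    return float(image.gray[mask].mean())


def generate_dataset(
    config: PhantomConfig, n_per_class: int, seed: int, out_dir: str | Path
) -> pd.DataFrame:
    """Write a balanced phantom dataset (PNGs + manifest CSV) and return the manifest.

    The manifest has columns ``uid,path,label,skull`` with exactly
    ``n_per_class`` rows per class; paths are relative to ``out_dir``.
    """
    config.validate()
    if n_per_class < 1:
        raise ConfigurationError(f"n_per_class must be >= 1, got {n_per_class}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    slice_seeds = ss.generate_state(2 * n_per_class) % (2**31)
    records = []
    idx = 0
    for label in LABELS:
        for k in range(n_per_class):
            img = generate_phantom(config, label, int(slice_seeds[idx]))
            idx += 1
            uid = f"{label}-{k:05d}"
            fname = f"{uid}.png"
            Image.fromarray(img.pixels).save(out / fname)
            records.append(
                {"uid": uid, "path": fname, "label": label, "skull": config.with_skull}
            )
    manifest = pd.DataFrame.from_records(records, columns=["uid", "path", "label", "skull"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_slices(
    config: PhantomConfig, n_per_class: int, seed: int
) -> tuple[list[SliceImage], np.ndarray]:
    """In-memory variant of :func:`generate_dataset`.

    Returns the slices and a 0/1 label vector (1 = MS), ordered normals first.
    """
    config.validate()
    if n_per_class < 1:
        raise ConfigurationError(f"n_per_class must be >= 1, got {n_per_class}")
    ss = np.random.SeedSequence(seed)
    slice_seeds = ss.generate_state(2 * n_per_class) % (2**31)
    slices: list[SliceImage] = []
    idx = 0
    for label in LABELS:
        for _ in range(n_per_class):
            slices.append(generate_phantom(config, label, int(slice_seeds[idx])))
            idx += 1
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    return slices, labels


def config_from_dict(d: dict) -> PhantomConfig:
    """Build a :class:`PhantomConfig` from a (YAML-loaded) mapping."""
    fields = {f.name for f in dataclasses.fields(PhantomConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ConfigurationError(f"unknown phantom config keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("lesion_count_range", "lesion_radius_range", "parenchyma_axes"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    cfg = PhantomConfig(**kwargs)
    cfg.validate()
    return cfg
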