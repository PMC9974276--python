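"""Hand-crafted texture descriptors: multi-radius uniform LBP and PHOG.

The local binary pattern (LBP) block stacks uniform-mapping histograms at
radii W = 1..4 with 8 circular neighbours each. The uniform mapping over 8
neighbours yields 58 distinct uniform codes plus one catch-all bin, i.e. 59
bins per radius and 4 * 59 = 236 for the block. Circular neighbours are
sampled with bilinear interpolation; a neighbour equal to the centre compares
as >= and codes 1. Only interior pixels (where the full neighbourhood fits in
the image) contribute, and each histogram is normalized to sum 1.

The pyramid histogram of oriented gradients (PHOG) descriptor bins signed
gradient orientations over [0, 360) degrees, weighted by gradient magnitude on
Canny edge pixels, at pyramid level 0 (whole image) and level 1 (2x2 cells),
level 0 first then the cells row-major. Each level's block is L1-normalized
unless its mass is zero (blank image), in which case it is left at zero. Two
bin settings are used — 17 and 34 bins — giving descriptors of length
17*5 = 85 and 34*5 = 170, 255 in total. The combined hand-crafted vector is
[LBP-236 | PHOG-85 | PHOG-170], 491 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny, local_binary_pattern

from .errors import ConfigurationError, DimensionError
from .phantom import SliceImage

LBP_BINS = 59  # 8-neighbour uniform mapping: 58 uniform codes + 1 catch-all
LBP_BLOCK_DIM = 4 * LBP_BINS  # 236
PHOG_BLOCK_DIM = 85 + 170  # 255
HCF_DIM = LBP_BLOCK_DIM + PHOG_BLOCK_DIM  # 491

HCF_BLOCK_OFFSETS = {"lbp": (0, LBP_BLOCK_DIM), "phog": (LBP_BLOCK_DIM, HCF_DIM)}


@dataclass(frozen=True)
class LBPConfig:
    """Multi-radius uniform LBP settings; ``weights`` are the radii in pixels."""

    weights: tuple[int, ...] = (1, 2, 3, 4)
    neighbors: int = 8
    mapping: str = "uniform"
    bins_per_weight: int = LBP_BINS

    def validate(self) -> None:
        if any(w <= 0 for w in self.weights) or not self.weights:
            raise ConfigurationError(f"weights must be positive, got {self.weights}")
        if self.mapping != "uniform":
            raise ConfigurationError(f"only the uniform mapping is supported, got {self.mapping!r}")
        expected = self.neighbors * (self.neighbors - 1) + 3
        if self.bins_per_weight != expected:
            raise ConfigurationError(
                f"uniform mapping with {self.neighbors} neighbours has {expected} bins, "
                f"got bins_per_weight={self.bins_per_weight}"
            )


@dataclass(frozen=True)
class PHOGConfig:
    """PHOG settings: two orientation-bin counts over a 2-level pyramid."""

    orientation_bins_setting1: int = 17
    orientation_bins_setting2: int = 34
    pyramid_levels: tuple[int, ...] = (0, 1)
    angle_range: float = 360.0
    canny_sigma: float = 1.0
    canny_low: float = 0.1  # fraction of the intensity scale
    canny_high: float = 0.2

    def validate(self) -> None:
        if self.orientation_bins_setting1 < 1 or self.orientation_bins_setting2 < 1:
            raise ConfigurationError("orientation bin counts must be >= 1")
        if tuple(self.pyramid_levels) != (0, 1):
            raise ConfigurationError("only pyramid levels (0, 1) are supported")


@dataclass
class HCFBlock:
    """n_slices x 491 hand-crafted feature matrix with block offsets."""

    matrix: np.ndarray
    block_offsets: dict = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != HCF_DIM:
            raise ConfigurationError(
                f"hand-crafted matrix must be n x {HCF_DIM}, got {self.matrix.shape}"
            )
        if self.block_offsets is None:
            self.block_offsets = dict(HCF_BLOCK_OFFSETS)


def _as_gray(image: SliceImage | np.ndarray) -> np.ndarray:
    if isinstance(image, SliceImage):
        return image.gray.astype(np.float64)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2D grayscale raster, got shape {arr.shape}")
    return arr


def lbp_histogram(
    image: np.ndarray, weight: int, config: LBPConfig | None = None
) -> np.ndarray:
    """Uniform-LBP histogram (59 bins) at radius ``weight``, normalized to sum 1.

    Codes are computed for interior pixels only — those whose circular
    neighbourhood of radius ``weight`` lies fully inside the image.
    """
    config = config or LBPConfig()
    config.validate()
    if isinstance(image, SliceImage):
        gray = image.gray
    else:
        gray = np.asarray(image)
        if gray.ndim == 3:
            gray = gray[:, :, 0]
    if gray.ndim != 2:
        raise DimensionError(f"expected a 2D grayscale raster, got shape {gray.shape}")
    if not np.issubdtype(gray.dtype, np.integer):
        # skimage warns on float input; LBP codes depend only on ordering, so
        # integer inputs are preferred — keep float inputs as given.
        gray = gray.astype(np.float64)
    w = int(weight)
    if w <= 0:
        raise ConfigurationError(f"weight must be positive, got {weight}")
    if gray.shape[0] < 2 * w + 1 or gray.shape[1] < 2 * w + 1:
        raise DimensionError(
            f"image {gray.shape} too small for LBP radius {w} (needs >= {2 * w + 1} per side)"
        )
    codes = local_binary_pattern(gray, P=config.neighbors, R=w, method="nri_uniform")
    interior = codes[w:-w, w:-w].astype(np.intp)
    hist = np.bincount(interior.ravel(), minlength=config.bins_per_weight).astype(np.float64)
    return hist / hist.sum()


def lbp_block(image: np.ndarray, config: LBPConfig | None = None) -> np.ndarray:
    """Concatenate the per-radius histograms in weight order (default 4*59 = 236)."""
    config = config or LBPConfig()
    config.validate()
    return np.concatenate([lbp_histogram(image, w, config) for w in config.weights])


def _gradients(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    magnitude = np.hypot(gx, gy)
    orientation = np.rad2deg(np.arctan2(gy, gx)) % 360.0
    return magnitude, orientation


def _orientation_hist(
    orientation: np.ndarray, weights: np.ndarray, bins: int, angle_range: float
) -> np.ndarray:
    hist, _ = np.histogram(
        orientation, bins=bins, range=(0.0, angle_range), weights=weights
    )
    return hist


def phog_descriptor(
    image: np.ndarray, bins: int, config: PHOGConfig | None = None
) -> np.ndarray:
    """PHOG vector of length ``bins * 5``: level 0 plus the four 2x2 cells."""
    config = config or PHOGConfig()
    config.validate()
    if bins < 1:
        raise ConfigurationError(f"bins must be >= 1, got {bins}")
    gray = _as_gray(image) / 255.0
    edges = canny(
        gray,
        sigma=config.canny_sigma,
        low_threshold=config.canny_low,
        high_threshold=config.canny_high,
    )
    magnitude, orientation = _gradients(gray)
    weights = np.where(edges, magnitude, 0.0)

    level0 = _orientation_hist(orientation, weights, bins, config.angle_range)
    h, w = gray.shape
    cells = []
    row_edges = (0, h // 2, h)
    col_edges = (0, w // 2, w)
    for i in range(2):
        for j in range(2):
            sl = (slice(row_edges[i], row_edges[i + 1]), slice(col_edges[j], col_edges[j + 1]))
            cells.append(
                _orientation_hist(orientation[sl], weights[sl], bins, config.angle_range)
            )
    level1 = np.concatenate(cells)

    descriptor = []
    for block in (level0, level1):
        mass = block.sum()
        descriptor.append(block / mass if mass > 0 else block.astype(np.float64))
    return np.concatenate(descriptor)


def extract_hcf(
    image: SliceImage | np.ndarray,
    lbp: LBPConfig | None = None,
    phog: PHOGConfig | None = None,
) -> np.ndarray:
    """The 491-vector [LBP-236 | PHOG-85 | PHOG-170] for one slice."""
    lbp = lbp or LBPConfig()
    phog = phog or PHOGConfig()
    gray = _as_gray(image)
    return np.concatenate(
        [
            lbp_block(gray, lbp),
            phog_descriptor(gray, phog.orientation_bins_setting1, phog),
            phog_descriptor(gray, phog.orientation_bins_setting2, phog),
        ]
    )


def extract_hcf_block(
    slices: list[SliceImage],
    lbp: LBPConfig | None = None,
    phog: PHOGConfig | None = None,
) -> HCFBlock:
    """Stack per-slice hand-crafted vectors into an n x 491 block."""
    matrix = np.stack([extract_hcf(s, lbp, phog) for s in slices])
    return HCFBlock(matrix=matrix)
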