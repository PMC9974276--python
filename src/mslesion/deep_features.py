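"""Deep feature extraction: one 1000-dimensional vector per 224x224x3 slice.

Backbones are frozen feature extractors — nothing is trained here. The
pretrained ImageNet networks (AlexNet, VGG16/19, ResNet18/50) are optional
backends that require torch/torchvision; their 1000-wide logit layer is the
feature vector. The default ``test_projection`` backbone is a deterministic
seeded random affine map over the global average intensity of each channel
and needs no download. Global pooling is the fully position-tolerant limit of
the average pooling the pretrained networks end in: it mimics the one
property of CNN features the downstream stages rely on — class content, not
lesion position, drives the representation — while remaining linear in pixel
intensities up to the bias term.
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass

import numpy as np
from skimage.measure import block_reduce

from .errors import ConfigurationError, DependencyError
from .phantom import SliceImage

FEATURE_DIM = 1000  # every backbone emits exactly 1000 features
_POOL_GRID = 1  # test_projection pools each channel to its global average

PRETRAINED_BACKBONES = ("alexnet", "vgg16", "vgg19", "resnet18", "resnet50")
BACKBONES = PRETRAINED_BACKBONES + ("test_projection",)


@dataclass(frozen=True)
class BackboneSpec:
    """Backbone choice plus the bookkeeping hyperparameters.

    ``batch_size``/``epochs``/``optimizer``/``pooling`` are recorded for
    provenance; only ``batch_size`` affects execution (pretrained inference
    batching), since no backbone is trained.
    """

    name: str = "test_projection"
    batch_size: int = 8
    epochs: int = 100
    optimizer: str = "adam"
    pooling: str = "average"
    seed: int = 0

    def validate(self) -> None:
        if self.name not in BACKBONES:
            raise ConfigurationError(f"unknown backbone {self.name!r}; choose from {BACKBONES}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")


@dataclass
class DeepFeatureBlock:
    """n_slices x 1000 feature matrix with its backbone provenance."""

    matrix: np.ndarray
    backbone_name: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != FEATURE_DIM:
            raise ConfigurationError(
                f"deep feature matrix must be n x {FEATURE_DIM}, got {self.matrix.shape}"
            )
        if not np.isfinite(self.matrix).all():
            raise ConfigurationError("deep feature matrix contains non-finite entries")


def _as_pixels(image: SliceImage | np.ndarray) -> np.ndarray:
    px = image.pixels if isinstance(image, SliceImage) else np.asarray(image)
    if px.shape[-3:] != (224, 224, 3) and px.shape != (224, 224, 3):
        raise ConfigurationError(f"expected a 224x224x3 raster, got shape {px.shape}")
    return px


def projection_weights(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """The fixed (seeded) linear map of the test backbone: weights and bias."""
    d_in = _POOL_GRID * _POOL_GRID * 3
    rng = np.random.default_rng(seed)
    weights = rng.standard_normal((FEATURE_DIM, d_in)) / np.sqrt(d_in)
    bias = 0.1 * rng.standard_normal(FEATURE_DIM)
    return weights, bias


def pooled_intensities(image: SliceImage | np.ndarray) -> np.ndarray:
    """Average-pool each channel of a 224x224x3 slice to its global mean."""
    px = _as_pixels(image).astype(np.float64) / 255.0
    block = 224 // _POOL_GRID
    pooled = block_reduce(px, block_size=(block, block, 1), func=np.mean)
    return pooled.ravel()


def test_projection_backbone(
    image: SliceImage | np.ndarray, seed: int, include_bias: bool = True
) -> np.ndarray:
    """Deterministic 1000-vector: seeded random projection of pooled intensities."""
    weights, bias = projection_weights(seed)
    out = weights @ pooled_intensities(image)
    if include_bias:
        out = out + bias
    return out


def _pretrained_extract(slices: list[SliceImage], spec: BackboneSpec) -> np.ndarray:
    if importlib.util.find_spec("torch") is None or importlib.util.find_spec("torchvision") is None:
        raise DependencyError(
            f"backbone {spec.name!r} needs the optional torch/torchvision backend "
            "(install the 'backbones' extra); use the default 'test_projection' "
            "backbone for a dependency-free deterministic extractor"
        )
    import torch
    from torchvision import models

    factory = getattr(models, spec.name)
    model = factory(weights="IMAGENET1K_V1")
    model.eval()
    mean = np.array([0.485, 0.456, 0.406])
    std = np.array([0.229, 0.224, 0.225])
    rows = []
    with torch.no_grad():
        for start in range(0, len(slices), spec.batch_size):
            batch = slices[start : start + spec.batch_size]
            arr = np.stack([s.pixels.astype(np.float64) / 255.0 for s in batch])
            arr = (arr - mean) / std
            tens = torch.as_tensor(arr.transpose(0, 3, 1, 2), dtype=torch.float32)
            rows.append(model(tens).numpy())
    return np.concatenate(rows, axis=0).astype(np.float64)


def extract_deep(slices: list[SliceImage], spec: BackboneSpec) -> DeepFeatureBlock:
    """Extract the n x 1000 deep feature matrix for a list of slices."""
    spec.validate()
    if spec.name == "test_projection":
        weights, bias = projection_weights(spec.seed)
        pooled = np.stack([pooled_intensities(s) for s in slices])
        matrix = pooled @ weights.T + bias
    else:
        for s in slices:
            _as_pixels(s)
        matrix = _pretrained_extract(slices, spec)
    return DeepFeatureBlock(matrix=matrix, backbone_name=spec.name)
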