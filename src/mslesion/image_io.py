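"""Slice/volume ingestion, geometry standardization, manifests and splits.

Manifests are plain pandas DataFrames with columns ``uid, path, label, skull``
and, once a split has been assigned, an extra ``split`` column taking values
``train`` / ``test`` / ``validation``. Labels are ``normal`` / ``MS``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, FormatError
from .phantom import LABELS, SliceImage

SPLIT_NAMES = ("train", "test", "validation")


def load_slice(path: str | Path) -> SliceImage:
    """Read a PNG/JPEG slice; grayscale input is replicated to 3 channels."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im.convert("L") if im.mode not in ("RGB", "L") else im)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return SliceImage(pixels=arr, label=None, uid=path.stem)


def save_slice(image: SliceImage, path: str | Path) -> None:
    """Write a slice raster as PNG/JPEG (format inferred from the suffix)."""
    Image.fromarray(image.pixels).save(Path(path))


def extract_axial_slices(volume_path: str | Path) -> list[SliceImage]:
    """Split a NIfTI volume into axial (third-axis) 2D slices.

    Each slice is min-max rescaled to [0, 255] independently and replicated to
    three channels. A constant-valued slice (degenerate intensity range) maps
    to all zeros. The third array axis is taken as axial, the standard
    RAS-oriented layout; permute the volume beforehand if it differs.
    """
    volume_path = Path(volume_path)
    try:
        vol = nib.load(str(volume_path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI volume {volume_path}: {exc}") from exc
    data = np.asanyarray(vol.dataobj).astype(np.float64)
    if data.ndim < 3:
        raise FormatError(f"volume must have >= 3 dimensions, got shape {data.shape}")
    if data.ndim > 3:  # keep the first volume of a 4D+ series
        data = data.reshape(*data.shape[:3], -1)[:, :, :, 0]
    slices = []
    for k in range(data.shape[2]):
        plane = data[:, :, k]
        lo, hi = plane.min(), plane.max()
        if hi > lo:
            gray = np.rint((plane - lo) / (hi - lo) * 255.0).astype(np.uint8)
        else:
            gray = np.zeros_like(plane, dtype=np.uint8)
        pixels = np.repeat(gray[:, :, None], 3, axis=2)
        slices.append(SliceImage(pixels=pixels, uid=f"{volume_path.stem}-z{k:04d}"))
    return slices


def resize_to_standard(image: SliceImage, size: int = 224) -> SliceImage:
    """Bilinearly resample a slice to ``size`` x ``size`` x 3, clipped to [0, 255]."""
    px = image.pixels
    if px.size == 0:
        raise ConfigurationError("cannot resize an empty raster")
    if px.shape[0] == size and px.shape[1] == size:
        return SliceImage(px.copy(), label=image.label, skull=image.skull, uid=image.uid)
    out = _sk_resize(
        px.astype(np.float64),
        (size, size, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return SliceImage(out, label=image.label, skull=image.skull, uid=image.uid)


def bilinear_resample_reference(gray: np.ndarray, size: int) -> np.ndarray:
    """Independent bilinear resampler (pixel-centre aligned, scipy-based).

    Used as a cross-check for :func:`resize_to_standard`; kept in the package
    so users can audit the resampling convention.
    """
    h, w = gray.shape
    rows = (np.arange(size) + 0.5) * h / size - 0.5
    cols = (np.arange(size) + 0.5) * w / size - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(
        gray.astype(np.float64), [rr, cc], order=1, mode="nearest"
    )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load a manifest CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = {"uid", "path", "label", "skull"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns {sorted(missing)}")
    _validate_manifest(df)
    return df


def _validate_manifest(df: pd.DataFrame) -> None:
    if df["uid"].duplicated().any():
        dupes = df.loc[df["uid"].duplicated(), "uid"].tolist()
        raise FormatError(f"duplicate uids in manifest: {dupes[:5]}")
    bad = set(df["label"].unique()) - set(LABELS)
    if bad:
        raise FormatError(f"labels must be in {LABELS}, found {sorted(bad)}")


def split_dataset(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each record to train/test/validation, stratified by label.

    Per-class counts follow the fractions by the largest-remainder rule, so
    they differ from the exact products by at most one. Deterministic given
    ``seed``; returns a copy of the manifest with a ``split`` column.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigurationError(f"need 3 non-negative fractions, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got sum {sum(fractions)!r}")
    _validate_manifest(manifest)
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = ""
    for label in sorted(out["label"].unique()):
        idx = out.index[out["label"] == label].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        counts = _largest_remainder(len(idx), fractions)
        start = 0
        for name, cnt in zip(SPLIT_NAMES, counts):
            out.loc[idx[start : start + cnt], "split"] = name
            start += cnt
    return out


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [f * n for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    short = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts
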