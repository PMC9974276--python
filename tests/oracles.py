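"""Independent reference implementations used as test oracles.

Everything here is deliberately written as slow, explicit pure-Python/numpy
code, sharing no logic with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def bilinear_sample(img: np.ndarray, r: float, c: float) -> float:
    """Bilinear interpolation with zero padding outside the image."""
    h, w = img.shape
    minr, minc = int(np.floor(r)), int(np.floor(c))
    dr, dc = r - minr, c - minc

    def px(i: int, j: int) -> float:
        return float(img[i, j]) if 0 <= i < h and 0 <= j < w else 0.0

    return (
        (1 - dr) * (1 - dc) * px(minr, minc)
        + (1 - dr) * dc * px(minr, minc + 1)
        + dr * (1 - dc) * px(minr + 1, minc)
        + dr * dc * px(minr + 1, minc + 1)
    )


def nri_uniform_code(bits: list[int]) -> int:
    """Bin index of an 8-bit circular pattern under the non-rotation-invariant
    uniform mapping: 58 uniform codes, then all-ones, then the catch-all."""
    P = len(bits)
    changes = sum(bits[i] != bits[(i + 1) % P] for i in range(P))
    n_ones = sum(bits)
    if changes > 2:
        return P * (P - 1) + 2
    if n_ones == 0:
        return 0
    if n_ones == P:
        return P * (P - 1) + 1
    first_one = bits.index(1)
    first_zero = bits.index(0)
    rot_index = (n_ones - first_zero) if first_one == 0 else (P - first_one)
    return 1 + (n_ones - 1) * P + rot_index


def lbp_code_at(img: np.ndarray, r: int, c: int, radius: int = 1, P: int = 8) -> int:
    """Uniform LBP code of one pixel: circular neighbours sampled bilinearly,
    neighbour >= centre codes 1."""
    bits = []
    for i in range(P):
        rr = r - radius * np.sin(2 * np.pi * i / P)
        cc = c + radius * np.cos(2 * np.pi * i / P)
        bits.append(1 if bilinear_sample(img, rr, cc) - img[r, c] >= 0 else 0)
    return nri_uniform_code(bits)


def lbp_histogram_bruteforce(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Per-pixel histogram over all interior pixels, normalized to sum 1."""
    h, w = img.shape
    hist = np.zeros(59)
    for r in range(radius, h - radius):
        for c in range(radius, w - radius):
            hist[lbp_code_at(img.astype(np.float64), r, c, radius)] += 1
    return hist / hist.sum()


def masked_centroid_distance(
    mask: np.ndarray, X: np.ndarray, y: np.ndarray
) -> float:
    """Direct evaluation of the selection fitness: z-score every feature over
    all samples, take the two class means, and measure their Euclidean
    distance over the masked coordinates."""
    X = np.asarray(X, dtype=float)
    Z = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        sd = col.std()
        Z[:, j] = (col - col.mean()) / sd if sd > 0 else 0.0
    classes = np.unique(y)
    m0 = Z[y == classes[0]].mean(axis=0)
    m1 = Z[y == classes[1]].mean(axis=0)
    diff = (m1 - m0)[np.asarray(mask, dtype=bool)]
    return float(np.sqrt((diff**2).sum()))


def informative_dataset(
    n_per_class: int = 30,
    n_informative: int = 3,
    n_distractor: int = 9,
    gap_sigma: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class Gaussian data: the first ``n_informative`` features have a
    class-mean gap of ``gap_sigma`` standard deviations, the rest none.

    Returns (X, y, informative_indices).
    """
    rng = np.random.default_rng(seed)
    d = n_informative + n_distractor
    X = rng.normal(0.0, 1.0, size=(2 * n_per_class, d))
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X[y == 1, :n_informative] += gap_sigma
    return X, y, np.arange(n_informative)
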