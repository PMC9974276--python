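"""Brownian-walk firefly algorithm (BFA) for fixed-size feature selection.

The firefly algorithm is a swarm metaheuristic in which dimmer (less fit)
solutions move toward brighter ones, with attraction decaying in the distance
between them. This variant replaces the classical Levy-flight perturbation
with a Brownian (Gaussian) walk:

    x_i <- x_i + beta0 * exp(-gamma * d_ij^2) * (x_j - x_i) + N(0, scale^2)

with d_ij the Euclidean (Cartesian) distance between fireflies i and j, and
positions kept in the unit hypercube. Each firefly's continuous position is
binarized by rank — its ``target_k`` largest coordinates mark the retained
features — so every candidate mask has exactly the requested size.

Fitness of a mask is the Euclidean distance between the two class-mean
vectors restricted to the selected features, computed on per-feature z-scored
data: subsets that spread the normal and MS centroids far apart are bright.
Because this distance is additively separable across features, the selection
pressure is toward features with large standardized class-mean gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ConfigurationError, DataValidationError, DimensionError

DEFAULT_DEEP_K = 618  # reduced size of the 1000-dim deep block
DEFAULT_HCF_K = 224  # reduced size of the 491-dim hand-crafted block


@dataclass(frozen=True)
class BFAConfig:
    """Swarm hyperparameters.

    beta0 is the attractiveness at zero distance, gamma the light-absorption
    coefficient (attraction decays as exp(-gamma d^2)), brownian_scale the
    standard deviation of the Gaussian walk in position space.
    """

    population: int = 20
    iterations: int = 100
    beta0: float = 1.0
    gamma: float = 1.0
    brownian_scale: float = 0.1
    target_k: int = DEFAULT_DEEP_K
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.population < 2:
            raise ConfigurationError(f"population must be >= 2, got {self.population}")
        if self.iterations < 1:
            raise ConfigurationError(f"iterations must be >= 1, got {self.iterations}")
        if min(self.beta0, self.gamma, self.brownian_scale) < 0:
            raise ConfigurationError("beta0, gamma and brownian_scale must be >= 0")
        if self.target_k < 1:
            raise ConfigurationError(f"target_k must be >= 1, got {self.target_k}")
        if n_features is not None and self.target_k > n_features:
            raise ConfigurationError(
                f"target_k={self.target_k} exceeds feature dimension {n_features}"
            )


@dataclass
class SelectionResult:
    """Binary mask of exactly target_k retained features plus the fitness trace."""

    mask: np.ndarray
    selected_indices: np.ndarray
    fitness: float
    fitness_trace: np.ndarray

    @property
    def k(self) -> int:
        return int(self.mask.sum())


def cartesian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-length vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def brownian_step(d: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """An i.i.d. Gaussian(0, scale^2) perturbation of dimension ``d``."""
    if scale < 0:
        raise ConfigurationError(f"scale must be >= 0, got {scale}")
    if scale == 0:
        return np.zeros(d)
    return rng.normal(0.0, scale, size=d)


def update_position(
    xi: np.ndarray, xj: np.ndarray, config: BFAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Move firefly i toward brighter firefly j; result clipped to [0, 1]."""
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    d = cartesian_distance(xi, xj)
    attraction = config.beta0 * np.exp(-config.gamma * d * d)
    new = xi + attraction * (xj - xi) + brownian_step(xi.size, config.brownian_scale, rng)
    return np.clip(new, 0.0, 1.0)


def _standardized_class_deltas(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature class-mean gap on z-scored data (normal vs MS centroids)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise DimensionError(f"features must be 2D, got shape {X.shape}")
    classes = np.unique(y)
    if classes.size != 2:
        raise DataValidationError(f"need exactly two classes, found {classes.tolist()}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features contribute zero gap
    Z = (X - mu) / sd
    return Z[y == classes[1]].mean(axis=0) - Z[y == classes[0]].mean(axis=0)


def subset_fitness(mask: np.ndarray, features: np.ndarray, labels: np.ndarray) -> float:
    """Distance between class centroids restricted to the masked features."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DataValidationError("mask selects no features")
    deltas = _standardized_class_deltas(features, labels)
    if mask.shape != deltas.shape:
        raise DimensionError(f"mask length {mask.size} != feature dimension {deltas.size}")
    return float(np.sqrt(np.sum(deltas[mask] ** 2)))


def _binarize_by_rank(position: np.ndarray, k: int) -> np.ndarray:
    """Top-k coordinates -> 1; ties broken toward lower indices."""
    order = np.argsort(-position, kind="stable")
    mask = np.zeros(position.size, dtype=bool)
    mask[order[:k]] = True
    return mask


def select_features(
    features: np.ndarray, labels: np.ndarray, config: BFAConfig
) -> SelectionResult:
    """Run the swarm and return the elitist best mask of exactly target_k features.

    Within one iteration every firefly i moves toward each brighter firefly j
    in index order (brightness cached at the start of the iteration); a fly
    with no brighter neighbour takes a pure Brownian step so the swarm cannot
    stagnate once all masks coincide. Masks are re-evaluated after the sweep
    and the best mask ever seen is retained (elitism).
    """
    X = np.asarray(features, dtype=np.float64)
    config.validate(n_features=X.shape[1])
    deltas_sq = _standardized_class_deltas(X, labels) ** 2
    d = deltas_sq.size
    k = config.target_k
    rng = np.random.default_rng(config.seed)

    positions = rng.uniform(0.0, 1.0, size=(config.population, d))

    def mask_fitness(pos_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        masks = np.stack([_binarize_by_rank(p, k) for p in pos_matrix])
        fits = np.sqrt(masks @ deltas_sq)
        return masks, fits

    masks, fits = mask_fitness(positions)
    best_idx = int(np.argmax(fits))
    best_mask = masks[best_idx].copy()
    best_fit = float(fits[best_idx])
    trace = []

    for _ in range(config.iterations):
        snapshot_fits = fits.copy()
        for i in range(config.population):
            moved = False
            for j in range(config.population):
                if snapshot_fits[j] > snapshot_fits[i]:
                    positions[i] = update_position(positions[i], positions[j], config, rng)
                    moved = True
            if not moved:
                # a fly with no brighter neighbour explores by a pure
                # Brownian step (elitism keeps the best mask found so far)
                positions[i] = np.clip(
                    positions[i] + brownian_step(d, config.brownian_scale, rng), 0.0, 1.0
                )
        masks, fits = mask_fitness(positions)
        it_best = int(np.argmax(fits))
        if fits[it_best] > best_fit:
            best_fit = float(fits[it_best])
            best_mask = masks[it_best].copy()
        trace.append(best_fit)

    return SelectionResult(
        mask=best_mask,
        selected_indices=np.flatnonzero(best_mask),
        fitness=best_fit,
        fitness_trace=np.asarray(trace),
    )


def brute_force_select(
    features: np.ndarray, labels: np.ndarray, k: int, max_subsets: int = 100_000
) -> SelectionResult:
    """Exhaustive maximization of subset_fitness; test oracle for small problems.

    Ties are broken by lexicographic index order (the first optimum found).
    """
    X = np.asarray(features, dtype=np.float64)
    d = X.shape[1]
    if not 1 <= k <= d:
        raise ConfigurationError(f"k={k} out of range for {d} features")
    from math import comb

    if comb(d, k) > max_subsets:
        raise DimensionError(f"C({d},{k}) = {comb(d, k)} exceeds the {max_subsets} bound")
    deltas_sq = _standardized_class_deltas(X, labels) ** 2
    best_combo = None
    best_val = -np.inf
    for combo in combinations(range(d), k):
        val = float(np.sqrt(deltas_sq[list(combo)].sum()))
        if val > best_val:
            best_val = val
            best_combo = combo
    mask = np.zeros(d, dtype=bool)
    mask[list(best_combo)] = True
    return SelectionResult(
        mask=mask,
        selected_indices=np.flatnonzero(mask),
        fitness=best_val,
        fitness_trace=np.asarray([best_val]),
    )
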