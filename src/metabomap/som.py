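"""Multilayer self-organizing map on a toroidal hexagonal grid.

One shared unit grid carries five codebook layers (glucose, C-peptide,
insulin, FFA, anthropometry); the best-matching unit minimizes the sum of
per-layer squared Euclidean distances, each layer normalized by its
data-wide mean squared deviation so all layers contribute comparably.

Training is sequential (one sample at a time): per pass, samples are visited
in random order, the BMU and its Gaussian neighborhood move toward the
sample with a linearly decaying learning rate, and the neighborhood radius
shrinks linearly from the 67th percentile of inter-unit distances toward 0.
Random restarts keep the model with the lowest quantization error.

The inner loop is numba-compiled when numba is importable and falls back to
the same pure-Python code otherwise; both paths are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from metabomap.preprocess import LAYER_NAMES, FeatureLayers

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


_H_MIN = 1e-12  # neighborhood weights below this skip the update

_SQ32 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class SOMGrid:
    """Hexagonal unit lattice with toroidal wrap-around.

    ``coords`` embeds units in the plane (odd rows offset by half a cell);
    ``distances`` is the toroidal inter-unit distance matrix: the minimum
    planar distance over the nine wrap translations. An odd row count makes
    the vertical seam slightly irregular (the wrap shifts parity); this is
    accepted and documented — 27 units cannot tile a perfect hex torus.
    """

    rows: int
    cols: int
    coords: np.ndarray
    distances: np.ndarray

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


def build_grid(rows: int = 3, cols: int = 9) -> SOMGrid:
    if rows <= 0 or cols <= 0:
        raise ValueError("grid dimensions must be positive")
    n = rows * cols
    coords = np.empty((n, 2))
    for r in range(rows):
        for c in range(cols):
            coords[r * cols + c] = (c + 0.5 * (r % 2), r * _SQ32)

    # toroidal distance = min over the 3x3 wrap translations; vertical wrap
    # of an odd row count lands on opposite parity, hence the half-cell
    # x-shift tied to di.
    shifts = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            shifts.append(
                (dj * cols + di * 0.5 * (rows % 2), di * rows * _SQ32)
            )
    dist = np.full((n, n), np.inf)
    for sx, sy in shifts:
        shifted = coords + np.array([sx, sy])
        delta = coords[:, None, :] - shifted[None, :, :]
        dist = np.minimum(dist, np.sqrt((delta**2).sum(axis=2)))
    dist = np.minimum(dist, dist.T)  # seam asymmetry: symmetrize explicitly
    np.fill_diagonal(dist, 0.0)
    coords.setflags(write=False)
    dist.setflags(write=False)
    return SOMGrid(rows=rows, cols=cols, coords=coords, distances=dist)


@njit(cache=True)
def _train_kernel(X, W, feat_w, grid_dist, order, alphas, sigmas):
    n, d = X.shape
    m = W.shape[0]
    n_epochs = alphas.shape[0]
    for t in range(n_epochs):
        alpha = alphas[t]
        sigma = sigmas[t]
        two_s2 = 2.0 * sigma * sigma
        for k in range(n):
            i = order[t, k]
            # best-matching unit under the layer-normalized metric
            best = 0
            best_dist = np.inf
            for u in range(m):
                acc = 0.0
                for f in range(d):
                    diff = X[i, f] - W[u, f]
                    acc += feat_w[f] * diff * diff
                if acc < best_dist:
                    best_dist = acc
                    best = u
            if sigma <= 0.0:
                for f in range(d):
                    W[best, f] += alpha * (X[i, f] - W[best, f])
                continue
            for u in range(m):
                g = grid_dist[best, u]
                h = math.exp(-(g * g) / two_s2)
                if h < _H_MIN:
                    continue
                ah = alpha * h
                for f in range(d):
                    W[u, f] += ah * (X[i, f] - W[u, f])


@dataclass
class SOMModel:
    grid: SOMGrid
    codebooks: np.ndarray          # (n_units, 15), layers concatenated
    feature_weights: np.ndarray    # (15,) layer-normalized metric weights
    layer_norms: np.ndarray        # (5,) data-wide mean squared deviations
    quantization_error: float
    seed: object
    training_log: dict

    def layer_codebooks(self) -> dict:
        out = {}
        for li, name in enumerate(LAYER_NAMES):
            out[name] = self.codebooks[:, 3 * li : 3 * li + 3]
        return out

    def normalized_codebooks(self) -> np.ndarray:
        """Codebooks rescaled so plain Euclidean distance equals the
        layer-normalized training metric (used for Ward/silhouette)."""
        return self.codebooks * np.sqrt(self.feature_weights)


def _layer_norms(stacked: np.ndarray) -> np.ndarray:
    """Per-layer mean squared deviation from the layer mean vector."""
    norms = np.empty(len(LAYER_NAMES))
    for li in range(len(LAYER_NAMES)):
        block = stacked[:, 3 * li : 3 * li + 3]
        centered = block - block.mean(axis=0)
        norms[li] = float((centered**2).sum(axis=1).mean())
    return np.maximum(norms, 1e-300)


def _feature_weights(layer_norms: np.ndarray,
                     layer_weights=None) -> np.ndarray:
    lw = np.ones(len(LAYER_NAMES)) if layer_weights is None else np.asarray(
        layer_weights, dtype=float
    )
    if lw.shape != (len(LAYER_NAMES),) or np.any(lw < 0):
        raise ValueError("layer_weights must be 5 non-negative values")
    return np.repeat(lw / layer_norms, 3)


def _weighted_sq_dists(X: np.ndarray, W: np.ndarray,
                       feat_w: np.ndarray) -> np.ndarray:
    """(n, m) matrix of layer-normalized squared distances."""
    Xw = X * np.sqrt(feat_w)
    Ww = W * np.sqrt(feat_w)
    d2 = (
        (Xw**2).sum(axis=1)[:, None]
        - 2.0 * Xw @ Ww.T
        + (Ww**2).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def quantization_error(X: np.ndarray, W: np.ndarray,
                       feat_w: np.ndarray) -> float:
    """Mean distance (sqrt of the weighted squared metric) to the BMU."""
    d2 = _weighted_sq_dists(X, W, feat_w)
    return float(np.sqrt(d2.min(axis=1)).mean())


def train_som(
    layers: FeatureLayers,
    grid: SOMGrid,
    iterations: int = 500,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
    seed=0,
    sigma_start: float | None = None,
    layer_weights=None,
) -> SOMModel:
    """Train one SOM. ``iterations`` counts passes over the data (epochs),
    each in a fresh random order. Deterministic given ``seed`` (int or
    :class:`numpy.random.SeedSequence`)."""
    X = np.ascontiguousarray(layers.stacked(), dtype=float)
    n, d = X.shape
    m = grid.n_units
    if n < m:
        raise ValueError(f"need at least {m} subjects, got {n}")
    if np.isnan(X).any():
        raise ValueError("NaN in features; apply exclusions first")
    if iterations < 0:
        raise ValueError("iterations must be non-negative")

    norms = _layer_norms(X)
    feat_w = _feature_weights(norms, layer_weights)

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n, size=m, replace=False)
    W = np.ascontiguousarray(X[init_idx].copy())

    if sigma_start is None:
        off_diag = grid.distances[~np.eye(m, dtype=bool)]
        sigma0 = float(np.percentile(off_diag, 67.0))
    else:
        sigma0 = float(sigma_start)

    if iterations > 0:
        denom = max(iterations - 1, 1)
        alphas = lr_start + (lr_end - lr_start) * np.arange(iterations) / denom
        sigmas = sigma0 * (1.0 - np.arange(iterations) / iterations)
        order = np.empty((iterations, n), dtype=np.int64)
        for t in range(iterations):
            order[t] = rng.permutation(n)
        _train_kernel(X, W, feat_w, grid.distances, order, alphas, sigmas)
    qe = quantization_error(X, W, feat_w)
    return SOMModel(
        grid=grid,
        codebooks=W,
        feature_weights=feat_w,
        layer_norms=norms,
        quantization_error=qe,
        seed=seed,
        training_log={
            "iterations": iterations,
            "lr_start": lr_start,
            "lr_end": lr_end,
            "sigma_start": sigma0,
        },
    )


def restart_best(
    layers: FeatureLayers,
    grid: SOMGrid,
    n_restarts: int = 1000,
    seed=0,
    **train_kwargs,
) -> SOMModel:
    """Best-of-``n_restarts`` by quantization error.

    Restart seeds are spawned from one master ``seed`` via SeedSequence, so
    the first k restarts of a larger run replicate a smaller run exactly;
    ties keep the earliest restart in the stream.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    master = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = master.spawn(n_restarts)
    best = None
    errors = []
    for child in children:
        model = train_som(layers, grid, seed=child, **train_kwargs)
        errors.append(model.quantization_error)
        if best is None or model.quantization_error < best.quantization_error:
            best = model
    best.training_log["restart_errors"] = errors
    best.training_log["n_restarts"] = n_restarts
    return best


def map_subjects(model: SOMModel, layers: FeatureLayers):
    """BMU index and BMU distance per subject."""
    X = layers.stacked()
    if X.shape[1] != model.codebooks.shape[1]:
        raise ValueError("feature dimensionality does not match codebooks")
    d2 = _weighted_sq_dists(X, model.codebooks, model.feature_weights)
    bmu = d2.argmin(axis=1)
    return bmu, np.sqrt(d2[np.arange(len(X)), bmu])
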