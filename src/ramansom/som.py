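"""Kohonen self-organising map: lattice, schedules, training loop.

A rectangular, open-boundary (no wraparound) lattice of x_dim x y_dim nodes
with coordinate (0, 0) at the bottom-left, each node carrying a weight vector
of the spectral dimension N.  Training is online competitive learning: at
each step one observation is drawn with replacement, its best-matching unit
(BMU) found by Euclidean distance, and all node weights pulled toward the
observation by alpha(t) * h_k(t), where h_k is a Gaussian neighbourhood
factor in lattice distance from the BMU.

Decay schedules:
    sigma(t) = sigma0 / (1 + t * C),  C = (sigma0 - 1) / t_max
        so sigma(t_max) = 1 exactly for any sigma0 > 1;
    alpha(t) = alpha0 / (1 + t / (0.5 * t_max))   (asymptotic decay),
        so alpha(t_max) = alpha0 / 3.

The hot loop is compiled with numba when available; a pure-numpy path with
identical arithmetic is used otherwise.  ``train_naive`` is a deliberately
independent, loop-over-everything reference used as a cross-check oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SOMConfig", "SOMGrid", "normalize_rows", "init_grid", "bmu",
    "sigma_at", "alpha_at", "neighborhood_weights", "train", "train_naive",
    "map_observations", "quantization_error",
]

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class SOMConfig:
    """Lattice dimensions, decay-schedule anchors, iteration count, seed.

    x_dim and y_dim must differ (symmetry breaking on the rectangular
    lattice speeds learning); the default 14 x 10 lattice and schedule
    anchors sigma0 = 3.0, alpha0 = 0.75, t_max = 1e6, seed = 1 are the
    pipeline's standard operating point.
    """

    x_dim: int = 14
    y_dim: int = 10
    sigma0: float = 3.0
    alpha0: float = 0.75
    t_max: int = 1_000_000
    seed: int = 1

    def validate(self) -> list[str]:
        problems = []
        if self.x_dim == self.y_dim:
            problems.append("x_dim and y_dim must differ (symmetry breaking)")
        if self.x_dim * self.y_dim < 4:
            problems.append("lattice needs at least 4 nodes")
        if self.sigma0 < 1:
            problems.append("sigma0 must be >= 1")
        if not (0.0 < self.alpha0 <= 1.0):
            problems.append("alpha0 must lie in (0, 1]")
        if self.t_max < 1:
            problems.append("t_max must be >= 1")
        return problems

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class SOMGrid:
    """Node weights (n_nodes x N) plus the lattice geometry.

    Node k sits at column x = k % x_dim, row y = k // x_dim, i.e. row-major
    over (y, x) with (0, 0) the bottom-left corner and
    (x_dim - 1, y_dim - 1) the top-right.
    """

    weights: np.ndarray
    x_dim: int
    y_dim: int

    def __post_init__(self) -> None:
        self.weights = np.ascontiguousarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.x_dim * self.y_dim:
            raise ValueError("weight rows must equal x_dim * y_dim")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def coords(self) -> np.ndarray:
        """(n_nodes, 2) integer array of (x, y) per node, row-major order."""
        k = np.arange(self.n_nodes)
        return np.column_stack([k % self.x_dim, k // self.x_dim])

    def node_index(self, x: int, y: int) -> int:
        if not (0 <= x < self.x_dim and 0 <= y < self.y_dim):
            raise IndexError(f"node ({x}, {y}) outside the lattice")
        return y * self.x_dim + x

    def node_weights(self, x: int, y: int) -> np.ndarray:
        return self.weights[self.node_index(x, y)]

    def copy(self) -> "SOMGrid":
        return SOMGrid(self.weights.copy(), self.x_dim, self.y_dim)


def normalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Divide each row by its Euclidean (Frobenius) norm."""
    matrix = np.asarray(matrix, float)
    norms = np.linalg.norm(matrix, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalise a zero row")
    return matrix / norms


def _rng(seed: int, stream: int) -> np.random.Generator:
    # separate deterministic streams for initialisation and sampling
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def init_grid(config: SOMConfig, n_features: int) -> SOMGrid:
    """Random grid: weights i.i.d. uniform on [0, 1), reproducible from seed."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = _rng(config.seed, 0)
    w = rng.random((config.x_dim * config.y_dim, n_features))
    return SOMGrid(w, config.x_dim, config.y_dim)


def bmu(grid: SOMGrid, v: np.ndarray) -> tuple[int, int]:
    """Coordinate (x, y) of the node nearest to ``v`` (Euclidean).

    Ties resolve to the smallest row-major node index.
    """
    v = np.asarray(v, float)
    if v.shape != (grid.n_features,):
        raise ValueError("input vector length must match the weight length")
    d2 = np.einsum("ij,ij->i", grid.weights - v, grid.weights - v)
    k = int(np.argmin(d2))
    return k % grid.x_dim, k // grid.x_dim


def sigma_at(t: float, config: SOMConfig) -> float:
    """Neighbourhood radius sigma(t) = sigma0 / (1 + t*C), C = (sigma0-1)/t_max."""
    c = (config.sigma0 - 1.0) / config.t_max
    return config.sigma0 / (1.0 + t * c)


def alpha_at(t: float, config: SOMConfig) -> float:
    """Learning rate alpha(t) = alpha0 / (1 + t / (0.5 * t_max))."""
    return config.alpha0 / (1.0 + t / (0.5 * config.t_max))


def neighborhood_weights(grid: SOMGrid, bmu_coord: tuple[int, int],
                         sigma: float) -> np.ndarray:
    """Gaussian factor h_k = exp(-d^2 / (2 sigma^2)) per node.

    d is the Euclidean lattice distance from node k to the BMU in integer
    node coordinates; h equals 1 at the BMU.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    coords = grid.coords().astype(float)
    d2 = (coords[:, 0] - bmu_coord[0]) ** 2 + (coords[:, 1] - bmu_coord[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma))


if _HAVE_NUMBA:

    # fastmath only permits reassociation fixed at compile time, so the
    # trained grid stays bit-identical across repeated calls
    @numba.njit(cache=True, fastmath=True)
    def _train_loop(weights, data, sample_idx, xs, ys, sigma0, alpha0, t_max):
        n_nodes, n_feat = weights.shape
        c = (sigma0 - 1.0) / t_max
        for t in range(sample_idx.shape[0]):
            v = data[sample_idx[t]]
            # BMU competition
            best = 0
            best_d = np.inf
            for k in range(n_nodes):
                s = 0.0
                for j in range(n_feat):
                    diff = weights[k, j] - v[j]
                    s += diff * diff
                if s < best_d:
                    best_d = s
                    best = k
            sigma = sigma0 / (1.0 + t * c)
            alpha = alpha0 / (1.0 + t / (0.5 * t_max))
            bx = xs[best]
            by = ys[best]
            denom = 2.0 * sigma * sigma
            for k in range(n_nodes):
                dx = xs[k] - bx
                dy = ys[k] - by
                ah = alpha * np.exp(-(dx * dx + dy * dy) / denom)
                if ah > 1e-300:
                    for j in range(n_feat):
                        weights[k, j] += ah * (v[j] - weights[k, j])
        return weights


def _train_loop_numpy(weights, data, sample_idx, xs, ys, sigma0, alpha0, t_max):
    # same arithmetic as the compiled loop, vectorised over nodes
    c = (sigma0 - 1.0) / t_max
    for t in range(sample_idx.shape[0]):
        v = data[sample_idx[t]]
        diff = weights - v
        d2 = np.einsum("ij,ij->i", diff, diff)
        best = int(np.argmin(d2))
        sigma = sigma0 / (1.0 + t * c)
        alpha = alpha0 / (1.0 + t / (0.5 * t_max))
        dx = xs - xs[best]
        dy = ys - ys[best]
        h = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
        weights -= (alpha * h)[:, None] * diff
    return weights


def train(grid: SOMGrid, data: np.ndarray, config: SOMConfig,
          n_steps: int | None = None) -> SOMGrid:
    """Run ``n_steps`` (default config.t_max) online updates; returns a new grid.

    One observation is drawn with replacement per step, from the stream
    seeded by ``config.seed``; given identical data, grid and config the
    trained grid is bit-identical across calls.  ``data`` is expected to be
    row-normalised already (see :func:`normalize_rows`).
    """
    data = np.ascontiguousarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a non-empty 2-D matrix")
    if data.shape[1] != grid.n_features:
        raise ValueError("data width must match the grid's weight length")
    steps = config.t_max if n_steps is None else int(n_steps)
    if steps < 1:
        raise ValueError("number of training steps must be >= 1")
    rng = _rng(config.seed, 1)
    sample_idx = rng.integers(0, data.shape[0], size=steps)
    coords = grid.coords().astype(float)
    xs = np.ascontiguousarray(coords[:, 0])
    ys = np.ascontiguousarray(coords[:, 1])
    out = grid.copy()
    loop = _train_loop if _HAVE_NUMBA else _train_loop_numpy
    loop(out.weights, data, sample_idx, xs, ys,
         float(config.sigma0), float(config.alpha0), float(config.t_max))
    return out


def train_naive(grid: SOMGrid, data: np.ndarray, config: SOMConfig,
                n_steps: int | None = None) -> SOMGrid:
    """Reference trainer: explicit per-node loops built from the public
    primitives (:func:`bmu`, :func:`sigma_at`, :func:`alpha_at`,
    :func:`neighborhood_weights`).  Slow; used as an independent oracle for
    the fast loop on small problems.
    """
    data = np.asarray(data, float)
    steps = config.t_max if n_steps is None else int(n_steps)
    rng = _rng(config.seed, 1)
    sample_idx = rng.integers(0, data.shape[0], size=steps)
    out = grid.copy()
    for t in range(steps):
        v = data[sample_idx[t]]
        bx, by = bmu(out, v)
        h = neighborhood_weights(out, (bx, by), sigma_at(t, config))
        a = alpha_at(t, config)
        for k in range(out.n_nodes):
            out.weights[k] = out.weights[k] + a * h[k] * (v - out.weights[k])
    return out


def map_observations(grid: SOMGrid, data: np.ndarray) -> dict[tuple[int, int], list[int]]:
    """Assign every observation to its BMU; returns coord -> observation ids."""
    data = np.asarray(data, float)
    # ||w||^2 - 2 w.v + ||v||^2 ; the ||v||^2 term is constant per row
    w2 = np.einsum("ij,ij->i", grid.weights, grid.weights)
    d2 = w2[None, :] - 2.0 * data @ grid.weights.T
    ks = np.argmin(d2, axis=1)
    hits: dict[tuple[int, int], list[int]] = {}
    for i, k in enumerate(ks):
        coord = (int(k % grid.x_dim), int(k // grid.x_dim))
        hits.setdefault(coord, []).append(i)
    return hits


def quantization_error(grid: SOMGrid, data: np.ndarray) -> float:
    """Mean Euclidean distance of each observation to its BMU's weights."""
    data = np.asarray(data, float)
    dists = np.empty(data.shape[0])
    for i, v in enumerate(data):
        x, y = bmu(grid, v)
        dists[i] = np.linalg.norm(v - grid.node_weights(x, y))
    return float(dists.mean())
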