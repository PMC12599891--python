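"""Tiled convolution with distance-k weight tying and TICA pooling.

A tiled convolutional layer shares weights only between output units whose
spatial offsets are congruent modulo the tile size k; adjacent units within
a tile carry independent weight banks.  Unsupervised pretraining minimizes
the summed square-root pooled energies of the first-layer responses under
three structural constraints, re-imposed after every gradient step by
projection: locality (weights vanish outside each unit's s x s x C
receptive field), tying (rows congruent modulo k are equal), and local
orthonormality (rows sharing a receptive-field location are orthonormal).
The optimizer is a backtracking line search on the pooled-energy objective.

During pretraining the weights live as a dense (units x patch-input) matrix
so that the three projections can be applied literally; the tied bank tensor
is contracted back out at the end.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TiledWeights",
    "PoolingTopology",
    "TICAConfig",
    "PretrainResult",
    "TilingStructure",
    "init_tiled_weights",
    "tiled_conv_forward",
    "tica_activation",
    "tica_objective",
    "tica_gradient",
    "localize",
    "tie_weights",
    "orthogonalize_local_rf",
    "pretrain_tica",
    "extract_patches",
    "save_weights",
    "load_weights",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weight bank and pooling topology

@dataclass
class TiledWeights:
    """First-layer weight bank.

    ``banks`` has shape [L maps, k, k, s, s, C]: the unit at output offset
    (u, v) in map l applies ``banks[l, u % k, v % k]`` to its s x s x C
    input patch.  No bias term.
    """

    banks: np.ndarray
    tile_k: int
    rf_s: int
    n_maps: int

    def __post_init__(self) -> None:
        self.banks = np.asarray(self.banks, dtype=float)
        expected = (self.n_maps, self.tile_k, self.tile_k,
                    self.rf_s, self.rf_s)
        if self.banks.shape[:5] != expected or self.banks.ndim != 6:
            raise ValueError(
                f"banks shape {self.banks.shape} incompatible with "
                f"(L={self.n_maps}, k={self.tile_k}, s={self.rf_s})")

    @property
    def n_channels(self) -> int:
        return self.banks.shape[5]

    def bank(self, l: int, u: int, v: int) -> np.ndarray:
        """Weight bank used by the unit at output offset (u, v) of map l."""
        return self.banks[l, u % self.tile_k, v % self.tile_k]

    def effective_row(self, l: int, u: int, v: int,
                      input_shape: Tuple[int, int, int]) -> np.ndarray:
        """Unit (l, u, v)'s weights over the full flattened input: zero
        outside its receptive field (stride-1 layout)."""
        H, W, C = input_shape
        row = np.zeros((H, W, C))
        s = self.rf_s
        row[u:u + s, v:v + s, :] = self.bank(l, u, v)
        return row.ravel()


def init_tiled_weights(n_maps: int, tile_k: int, rf_s: int, n_channels: int,
                       seed: int = 0) -> TiledWeights:
    """Seeded standard-normal bank initialization (project before use)."""
    rng = np.random.default_rng(seed)
    banks = rng.standard_normal(
        (n_maps, tile_k, tile_k, rf_s, rf_s, n_channels))
    return TiledWeights(banks=banks, tile_k=tile_k, rf_s=rf_s, n_maps=n_maps)


@dataclass
class PoolingTopology:
    """Fixed nonnegative pooling matrix over a (H, W, L) simple-unit grid.

    Each pooled unit sums the squared responses in a wrap-around spatial
    neighborhood of the given radius within its own map; there is one pooled
    unit per simple unit.  Never updated by learning.
    """

    grid: Tuple[int, int]
    n_maps: int
    radius: int = 1

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1] * self.n_maps

    def _axis_offsets(self, size: int) -> np.ndarray:
        # unique wrap-around neighbor offsets on an axis of this size
        offs = np.arange(-self.radius, self.radius + 1)
        return np.unique(offs % size) if size > 0 else np.array([0])

    def apply(self, energies: np.ndarray) -> np.ndarray:
        """Neighborhood sum of ``energies`` (..., H, W, L) -> same shape.

        The wrap-around box sum is a symmetric operator, so this is also
        its own adjoint (used by backpropagation).
        """
        e = np.asarray(energies, dtype=float)
        H, W = self.grid
        if e.shape[-3:] != (H, W, self.n_maps):
            raise ValueError(f"expected trailing shape {(H, W, self.n_maps)}, "
                             f"got {e.shape}")
        out = np.zeros_like(e)
        ax_u = self._axis_offsets(H)
        ax_v = self._axis_offsets(W)
        for du in ax_u:
            rolled_u = np.roll(e, -int(du), axis=-3)
            for dv in ax_v:
                out += np.roll(rolled_u, -int(dv), axis=-2)
        return out

    def matrix(self) -> np.ndarray:
        """Dense (M, m) 0/1 matrix; simple units flattened in (H, W, L)
        C-order.  Intended for small grids (tests, pretraining)."""
        H, W = self.grid
        L = self.n_maps
        m = H * W * L
        V = np.zeros((m, m))
        ax_u = self._axis_offsets(H)
        ax_v = self._axis_offsets(W)
        for u, v, l in itertools.product(range(H), range(W), range(L)):
            i = (u * W + v) * L + l
            for du in ax_u:
                for dv in ax_v:
                    j = (((u + du) % H) * W + (v + dv) % W) * L + l
                    V[i, j] = 1.0
        return V


# ---------------------------------------------------------------------------
# Tiled convolution

def _patch_view(x: np.ndarray, s: int) -> np.ndarray:
    # (B, H, W, C) -> view (B, H-s+1, W-s+1, C, s, s)
    return sliding_window_view(x, (s, s), axis=(1, 2))


def tiled_conv_forward(x: np.ndarray, weights: TiledWeights,
                       stride: int = 1) -> np.ndarray:
    """Forward pass of the tiled layer.

    ``x`` is (H, W, C) or a batch (B, H, W, C); returns (..., Ho, Wo, L)
    where the unit at output offset (u, v) of map l dot-products its patch
    with ``banks[l, u % k, v % k]``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("input must be (H, W, C) or (B, H, W, C)")
    B, H, W, C = x.shape
    s, k, L = weights.rf_s, weights.tile_k, weights.n_maps
    if s > H or s > W:
        raise ValueError(f"receptive field {s} exceeds input side {min(H, W)}")
    if C != weights.n_channels:
        raise ValueError(f"input has {C} channels, weights expect "
                         f"{weights.n_channels}")
    patches = _patch_view(x, s)[:, ::stride, ::stride]
    B_, Ho, Wo = patches.shape[:3]
    out = np.empty((B, Ho, Wo, L))
    for l in range(L):
        for a in range(min(k, Ho)):
            for b in range(min(k, Wo)):
                sub = patches[:, a::k, b::k]
                out[:, a::k, b::k, l] = np.tensordot(
                    sub, weights.banks[l, a, b], axes=([4, 5, 3], [0, 1, 2]))
    return out[0] if single else out


def tiled_conv_bank_gradient(x: np.ndarray, weights: TiledWeights,
                             d_out: np.ndarray) -> np.ndarray:
    """Gradient of sum(d_out * forward(x)) w.r.t. the banks: gradients of
    tied unit copies sum into their shared bank (stride 1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x[None]
        d_out = d_out[None]
    s, k, L = weights.rf_s, weights.tile_k, weights.n_maps
    patches = _patch_view(x, s)
    Ho, Wo = patches.shape[1:3]
    grad = np.zeros_like(weights.banks)
    for l in range(L):
        for a in range(min(k, Ho)):
            for b in range(min(k, Wo)):
                sub = patches[:, a::k, b::k]
                dsub = d_out[:, a::k, b::k, l]
                g = np.tensordot(dsub, sub, axes=([0, 1, 2], [0, 1, 2]))
                grad[l, a, b] = np.moveaxis(g, 0, -1)  # (C,s,s) -> (s,s,C)
    return grad


# ---------------------------------------------------------------------------
# Dense tiling structure used by pretraining

class TilingStructure:
    """Bookkeeping between the tied bank tensor and the dense
    (units x patch-inputs) weight matrix used during pretraining.

    Units are laid out on the stride-1 output grid of a patch, flattened in
    (u, v, l) C-order so that the ordering matches the pooling topology.
    """

    def __init__(self, patch_shape: Tuple[int, int, int], n_maps: int,
                 tile_k: int, rf_s: int):
        self.patch_shape = tuple(patch_shape)
        P_h, P_w, C = self.patch_shape
        if rf_s > P_h or rf_s > P_w:
            raise ValueError("receptive field larger than patch")
        self.n_maps, self.tile_k, self.rf_s = n_maps, tile_k, rf_s
        self.grid = (P_h - rf_s + 1, P_w - rf_s + 1)
        self.n_inputs = P_h * P_w * C
        self.n_units = self.grid[0] * self.grid[1] * n_maps

        q_h, q_w = self.grid
        s = rf_s
        # flat input indices of the RF anchored at (u, v): shape (q_h, q_w, s*s*C)
        ii, jj, cc = np.meshgrid(np.arange(s), np.arange(s), np.arange(C),
                                 indexing="ij")
        base = (ii * P_w + jj) * C + cc  # (s, s, C)
        anchors = (np.arange(q_h)[:, None] * P_w + np.arange(q_w)[None, :]) * C
        self._rf_idx = anchors[:, :, None] + base.ravel()[None, None, :]
        self._unit_index = np.arange(self.n_units).reshape(q_h, q_w, n_maps)

    # -- index helpers -----------------------------------------------------
    def unit(self, l: int, u: int, v: int) -> int:
        return int(self._unit_index[u, v, l])

    def rf_indices(self, u: int, v: int) -> np.ndarray:
        return self._rf_idx[u, v]

    def tie_classes(self):
        """Yield (l, a, b, member (u, v) offsets) for each tying class."""
        q_h, q_w = self.grid
        k = self.tile_k
        for l in range(self.n_maps):
            for a in range(min(k, q_h)):
                for b in range(min(k, q_w)):
                    us = np.arange(a, q_h, k)
                    vs = np.arange(b, q_w, k)
                    yield l, a, b, us, vs

    def default_topology(self, radius: int = 1) -> PoolingTopology:
        return PoolingTopology(grid=self.grid, n_maps=self.n_maps,
                               radius=radius)

    # -- bank <-> dense ----------------------------------------------------
    def expand(self, banks: np.ndarray) -> np.ndarray:
        """Tied banks -> dense (n_units, n_inputs) matrix."""
        W = np.zeros((self.n_units, self.n_inputs))
        q_h, q_w = self.grid
        for l in range(self.n_maps):
            for u in range(q_h):
                for v in range(q_w):
                    W[self.unit(l, u, v), self.rf_indices(u, v)] = \
                        banks[l, u % self.tile_k, v % self.tile_k].ravel()
        return W

    def contract_mean(self, W: np.ndarray) -> np.ndarray:
        """Dense matrix -> banks, averaging RF-restricted rows over each
        tying class."""
        s, C = self.rf_s, self.patch_shape[2]
        banks = np.zeros((self.n_maps, self.tile_k, self.tile_k, s, s, C))
        for l, a, b, us, vs in self.tie_classes():
            rows = [W[self.unit(l, u, v), self.rf_indices(u, v)]
                    for u in us for v in vs]
            banks[l, a, b] = np.mean(rows, axis=0).reshape(s, s, C)
        return banks

    def contract_sum(self, G: np.ndarray) -> np.ndarray:
        """Dense gradient -> bank gradient: tied copies sum into the bank."""
        s, C = self.rf_s, self.patch_shape[2]
        grad = np.zeros((self.n_maps, self.tile_k, self.tile_k, s, s, C))
        for l, a, b, us, vs in self.tie_classes():
            rows = [G[self.unit(l, u, v), self.rf_indices(u, v)]
                    for u in us for v in vs]
            grad[l, a, b] = np.sum(rows, axis=0).reshape(s, s, C)
        return grad

    # -- the three projections --------------------------------------------
    def localize(self, W: np.ndarray) -> np.ndarray:
        """Zero every entry outside the unit's receptive field."""
        out = np.zeros_like(W)
        q_h, q_w = self.grid
        for l in range(self.n_maps):
            for u in range(q_h):
                for v in range(q_w):
                    i = self.unit(l, u, v)
                    idx = self.rf_indices(u, v)
                    out[i, idx] = W[i, idx]
        return out

    def tie_weights(self, W: np.ndarray) -> np.ndarray:
        """Replace each tying class's RF-restricted rows by their mean."""
        out = W.copy()
        for l, a, b, us, vs in self.tie_classes():
            members = [(u, v) for u in us for v in vs]
            mean = np.mean([W[self.unit(l, u, v), self.rf_indices(u, v)]
                            for u, v in members], axis=0)
            for u, v in members:
                out[self.unit(l, u, v), self.rf_indices(u, v)] = mean
        return out

    def orthogonalize_local_rf(self, W: np.ndarray) -> np.ndarray:
        """Symmetric (Loewdin) orthonormalization of each local group: the
        rows of all maps anchored at the same receptive-field location.

        Because tied rows have identical RF-restricted coordinates, the
        same transform is computed for congruent locations, so tying is
        preserved exactly.
        """
        out = W.copy()
        q_h, q_w = self.grid
        for u in range(q_h):
            for v in range(q_w):
                idx = self.rf_indices(u, v)
                units = [self.unit(l, u, v) for l in range(self.n_maps)]
                A = W[np.ix_(units, idx)]
                out[np.ix_(units, idx)] = _lowdin(A, group=(u, v))
        return out

    def project(self, W: np.ndarray) -> np.ndarray:
        return self.orthogonalize_local_rf(self.tie_weights(self.localize(W)))

    # -- diagnostics -------------------------------------------------------
    def constraint_violations(self, W: np.ndarray) -> dict:
        """Max deviations from locality / tying / local orthonormality."""
        q_h, q_w = self.grid
        loc_mask = np.ones_like(W, dtype=bool)
        for l in range(self.n_maps):
            for u in range(q_h):
                for v in range(q_w):
                    loc_mask[self.unit(l, u, v), self.rf_indices(u, v)] = False
        locality = float(np.max(np.abs(W[loc_mask]))) if loc_mask.any() else 0.0
        tying = 0.0
        for l, a, b, us, vs in self.tie_classes():
            rows = np.array([W[self.unit(l, u, v), self.rf_indices(u, v)]
                             for u in us for v in vs])
            tying = max(tying, float(np.max(np.abs(rows - rows[0]))))
        orth = 0.0
        for u in range(q_h):
            for v in range(q_w):
                units = [self.unit(l, u, v) for l in range(self.n_maps)]
                A = W[np.ix_(units, self.rf_indices(u, v))]
                orth = max(orth, float(np.max(np.abs(
                    A @ A.T - np.eye(len(units))))))
        return {"locality": locality, "tying": tying, "orthonormality": orth}


def _lowdin(A: np.ndarray, group=None) -> np.ndarray:
    """(A A^T)^{-1/2} A; raises on a rank-deficient row group."""
    G = A @ A.T
    lam, Q = np.linalg.eigh(G)
    if lam[-1] <= 0 or lam[0] < 1e-12 * lam[-1]:
        raise ValueError(
            f"rank-deficient local RF group {group}: Gram eigenvalues {lam}")
    return (Q * (1.0 / np.sqrt(lam))) @ Q.T @ A


# Module-level wrappers mirroring the projection step names.

def localize(W: np.ndarray, structure: TilingStructure) -> np.ndarray:
    return structure.localize(W)


def tie_weights(W: np.ndarray, structure: TilingStructure) -> np.ndarray:
    return structure.tie_weights(W)


def orthogonalize_local_rf(W: np.ndarray,
                           structure: TilingStructure) -> np.ndarray:
    return structure.orthogonalize_local_rf(W)


# ---------------------------------------------------------------------------
# TICA objective / gradient

def _as_pool_matrix(V, n_simple: int) -> np.ndarray:
    if isinstance(V, PoolingTopology):
        V = V.matrix()
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] != n_simple:
        raise ValueError(f"pooling matrix shape {V.shape} incompatible with "
                         f"{n_simple} simple units")
    if np.any(V < 0):
        raise ValueError("pooling matrix must be nonnegative")
    return V


def _simple_responses(x, W) -> np.ndarray:
    """First-layer responses for one input; flattened in (u, v, l) order
    when W is a TiledWeights."""
    if isinstance(W, TiledWeights):
        return tiled_conv_forward(np.asarray(x, dtype=float), W).ravel()
    W = np.asarray(W, dtype=float)
    return W @ np.asarray(x, dtype=float).ravel()


def tica_activation(x, W, V, epsilon: float = 1e-8) -> np.ndarray:
    """Pooled activations p_i = sqrt(epsilon + sum_k V_ik (W_k . x)^2)."""
    r = _simple_responses(x, W)
    if isinstance(V, PoolingTopology):
        H, Wd = V.grid
        pooled = V.apply((r * r).reshape(H, Wd, V.n_maps)).ravel()
    else:
        pooled = _as_pool_matrix(V, r.size) @ (r * r)
    return np.sqrt(epsilon + pooled)


def _batch_matrix(batch) -> np.ndarray:
    X = np.asarray(batch, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    elif X.ndim > 2:
        X = X.reshape(X.shape[0], -1)
    return X


def tica_objective(batch, W, V, epsilon: float = 1e-8) -> float:
    """f = sum over the batch and pooled units of the activations."""
    X = _batch_matrix(batch)
    if X.shape[0] == 0:
        raise ValueError("tica_objective requires a nonempty batch")
    if isinstance(W, TiledWeights):
        return float(sum(tica_activation(x, W, V, epsilon).sum()
                         for x in np.asarray(batch, dtype=float)))
    W = np.asarray(W, dtype=float)
    R = X @ W.T
    Vm = _as_pool_matrix(V, R.shape[1])
    P = np.sqrt(epsilon + (R * R) @ Vm.T)
    return float(P.sum())


def _dense_gradient(X: np.ndarray, W: np.ndarray, Vm: np.ndarray,
                    epsilon: float) -> np.ndarray:
    R = X @ W.T                                   # (T, m)
    P = np.sqrt(epsilon + (R * R) @ Vm.T)         # (T, M)
    S = R * ((1.0 / P) @ Vm)                      # (T, m)
    return S.T @ X                                # (m, n)


def tica_gradient(batch, W, V, epsilon: float = 1e-8,
                  structure: Optional[TilingStructure] = None):
    """Exact gradient of :func:`tica_objective`.

    For a dense matrix ``W`` the gradient has the same shape as ``W``.  For
    :class:`TiledWeights` the gradient is returned in bank shape, with the
    gradients of tied unit copies summed into their shared bank (chain rule
    through the tying map).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0 for gradient computation")
    X = _batch_matrix(batch)
    if X.shape[0] == 0:
        raise ValueError("tica_gradient requires a nonempty batch")
    if isinstance(W, TiledWeights):
        arr = np.asarray(batch, dtype=float)
        patch_shape = arr.shape[1:] if arr.ndim == 4 else None
        if structure is None:
            if patch_shape is None:
                raise ValueError("need (T, H, W, C) patches or an explicit "
                                 "TilingStructure for TiledWeights gradients")
            structure = TilingStructure(patch_shape, W.n_maps, W.tile_k,
                                        W.rf_s)
        Vm = _as_pool_matrix(V, structure.n_units)
        G = _dense_gradient(X, structure.expand(W.banks), Vm, epsilon)
        return structure.contract_sum(G)
    W = np.asarray(W, dtype=float)
    Vm = _as_pool_matrix(V, W.shape[0])
    return _dense_gradient(X, W, Vm, epsilon)


# ---------------------------------------------------------------------------
# Pretraining (projected line search)

@dataclass
class TICAConfig:
    epsilon: float = 1e-8
    alpha0: float = 1.0
    alpha_decay: float = 0.5
    max_inner: int = 30
    max_outer: int = 100
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_decay < 1:
            raise ValueError("alpha_decay must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class PretrainResult:
    weights: TiledWeights
    objective_trace: np.ndarray
    converged: bool
    n_outer: int
    constraint_violations: List[dict] = field(default_factory=list)


def pretrain_tica(patches, w0: TiledWeights,
                  topology: Optional[PoolingTopology] = None,
                  config: Optional[TICAConfig] = None,
                  check_constraints: bool = True) -> PretrainResult:
    """Unsupervised pretraining by projected backtracking line search.

    Outer loop: evaluate the objective and its dense gradient; inner loop:
    propose ``W - alpha * g``, re-impose locality -> tying -> local
    orthonormality (in that order), and halve ``alpha`` until the objective
    strictly decreases or ``max_inner`` halvings are spent.  A failed inner
    search is treated as convergence.  Deterministic: no randomness beyond
    the seeded initialization of ``w0``.
    """
    config = config or TICAConfig()
    arr = np.asarray(patches, dtype=float)
    if arr.size == 0:
        raise ValueError("pretrain_tica requires a nonempty patch batch")
    if arr.ndim == 2:
        side = int(round(np.sqrt(arr.shape[1] / w0.n_channels)))
        patch_shape = (side, side, w0.n_channels)
        if side * side * w0.n_channels != arr.shape[1]:
            raise ValueError("cannot infer patch shape from flat patches")
    elif arr.ndim == 3:
        patch_shape = arr.shape[1:] + (1,)
    elif arr.ndim == 4:
        patch_shape = arr.shape[1:]
    else:
        raise ValueError("patches must be (T, n), (T, H, W) or (T, H, W, C)")
    X = arr.reshape(arr.shape[0], -1)

    structure = TilingStructure(patch_shape, w0.n_maps, w0.tile_k, w0.rf_s)
    topo = topology or structure.default_topology()
    Vm = _as_pool_matrix(topo, structure.n_units)
    eps = config.epsilon

    W = structure.project(structure.expand(w0.banks))
    f = tica_objective(X, W, Vm, eps)
    trace = [f]
    violations: List[dict] = []
    converged = False
    n_outer = 0
    for it in range(config.max_outer):
        n_outer = it + 1
        f_old = f
        g = _dense_gradient(X, W, Vm, eps)
        f_new = np.inf
        alpha = config.alpha0
        inner = 0
        W_new = W
        while f_new >= f_old and inner < config.max_inner:
            W_new = structure.project(W - alpha * g)
            f_new = tica_objective(X, W_new, Vm, eps)
            alpha *= config.alpha_decay
            inner += 1
        if not f_new < f_old:
            logger.info("line search exhausted at outer iter %d; treating "
                        "as convergence", it)
            converged = True
            break
        W, f = W_new, f_new
        trace.append(f)
        if check_constraints:
            violations.append(structure.constraint_violations(W))
        if (f_old - f_new) < config.tol * abs(f_old):
            converged = True
            break

    weights = TiledWeights(banks=structure.contract_mean(W),
                           tile_k=w0.tile_k, rf_s=w0.rf_s, n_maps=w0.n_maps)
    return PretrainResult(weights=weights,
                          objective_trace=np.asarray(trace),
                          converged=converged, n_outer=n_outer,
                          constraint_violations=violations)


def extract_patches(images: np.ndarray, patch_size: int, n_patches: int,
                    seed: int = 0) -> np.ndarray:
    """Random square patches from a stack of (N, H, W, C) images."""
    images = np.asarray(images, dtype=float)
    if images.ndim != 4:
        raise ValueError("images must be (N, H, W, C)")
    N, H, W, C = images.shape
    if patch_size > H or patch_size > W:
        raise ValueError("patch_size larger than image side")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, N, size=n_patches)
    us = rng.integers(0, H - patch_size + 1, size=n_patches)
    vs = rng.integers(0, W - patch_size + 1, size=n_patches)
    return np.stack([images[i, u:u + patch_size, v:v + patch_size]
                     for i, u, v in zip(idx, us, vs)])


# ---------------------------------------------------------------------------
# Checkpoint I/O

def save_weights(path, weights: TiledWeights,
                 trace: Optional[np.ndarray] = None,
                 config: Optional[TICAConfig] = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("banks", data=weights.banks)
        f.attrs["tile_k"] = weights.tile_k
        f.attrs["rf_s"] = weights.rf_s
        f.attrs["n_maps"] = weights.n_maps
        if trace is not None:
            f.create_dataset("objective_trace", data=np.asarray(trace))
        if config is not None:
            f.attrs["config"] = json.dumps(asdict(config))


def load_weights(path) -> TiledWeights:
    import h5py

    with h5py.File(path, "r") as f:
        return TiledWeights(banks=f["banks"][...],
                            tile_k=int(f.attrs["tile_k"]),
                            rf_s=int(f.attrs["rf_s"]),
                            n_maps=int(f.attrs["n_maps"]))
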