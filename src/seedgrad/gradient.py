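"""Connectivity-gradient engine.

Builds the seed-to-brain Fisher-z connectivity matrix, row-sparsifies it
(top fraction of positive connections retained), forms a cosine-similarity
affinity between seed voxels, and embeds it with an anisotropic diffusion
map. Component 1 of the embedding is the dominant gradient: the axis along
which the voxels' whole-brain connectivity profiles change most.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import skew

from .io import ConnectivityMatrix, GroupTimeSeries, VoxelGrid

__all__ = [
    "AffinityMatrix",
    "GradientSet",
    "compute_fc_matrix",
    "sparsify_rows",
    "cosine_affinity",
    "diffusion_embedding",
    "run_gradient_pipeline",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class AffinityMatrix:
    """Symmetric non-negative seed x seed similarity of connectivity profiles."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("affinity must be square")
        self.values = v


@dataclass
class GradientSet:
    """Diffusion-map embedding of seed voxels.

    ``coordinates[:, 0]`` is the dominant gradient; ``variance_explained``
    is each retained eigenvalue over the sum of all positive non-trivial
    eigenvalues.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    alpha: float
    n_components: int
    grid: VoxelGrid | None = None

    @property
    def dominant(self) -> np.ndarray:
        return self.coordinates[:, 0]


def _standardize_rows(x):
    """Zero-mean unit-norm rows; constant rows become zero (flag returned)."""
    x = np.asarray(x, dtype=np.float64)
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    flat = norm[:, 0] == 0
    norm[flat] = 1.0
    xn = xc / norm
    xn[flat] = 0.0
    return xn, flat


def compute_fc_matrix(group: GroupTimeSeries, targets: GroupTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlate every seed voxel with every target voxel, Fisher-z transform.

    Correlations are computed over the full concatenated time axis, clipped
    to +/-(1 - 1e-7) before arctanh so perfectly (anti-)correlated pairs map
    to finite extremes. Constant series give z = 0.
    """
    if group.n_timepoints != targets.n_timepoints:
        raise ValueError("seed and target series must share time length")
    seed_coords = group.grid.coords_mm
    target_coords = targets.grid.coords_mm
    # overlap check: identical mm coordinates mean the same voxel
    if len(seed_coords) and len(target_coords):
        seed_keys = {tuple(np.round(c, 6)) for c in seed_coords}
        overlap = sum(tuple(np.round(c, 6)) in seed_keys for c in target_coords)
        if overlap:
            raise ValueError(
                f"{overlap} target voxel(s) overlap the seed region; "
                "targets must exclude the seed"
            )
    s, _ = _standardize_rows(group.values)
    t, _ = _standardize_rows(targets.values)
    r = s @ t.T
    np.clip(r, -R_CLIP, R_CLIP, out=r)
    z = np.arctanh(r)
    return ConnectivityMatrix(
        z_values=z, seed_grid=group.grid, target_grid=targets.grid
    )


def sparsify_rows(fc: ConnectivityMatrix, retain_fraction: float = 0.10) -> ConnectivityMatrix:
    """Per row: zero negative connections, then keep only the top fraction.

    Retains ceil(fraction * n_targets) largest remaining values per row;
    ties at the cutoff keep the lower target index. Rows with no positive
    connection are left all-zero with a warning.
    """
    if not 0 < retain_fraction < 1:
        raise ValueError("retain_fraction must be in (0, 1)")
    z = np.asarray(fc.z_values, dtype=np.float64)
    n_targets = z.shape[1]
    k = math.ceil(retain_fraction * n_targets)
    pos = np.where(z > 0, z, 0.0)
    out = np.zeros_like(pos)
    # stable ranking: descending value, ascending index on ties
    order = np.argsort(-pos, axis=1, kind="stable")
    rows = np.arange(z.shape[0])[:, None]
    top = order[:, :k]
    out[rows, top] = pos[rows, top]
    dead = ~(out > 0).any(axis=1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} seed row(s) have no positive connections; left all-zero",
            stacklevel=2,
        )
    return ConnectivityMatrix(
        z_values=out,
        seed_grid=fc.seed_grid,
        target_grid=fc.target_grid,
        sparsity_applied=retain_fraction,
    )


def cosine_affinity(fc_sparse: ConnectivityMatrix) -> AffinityMatrix:
    """Cosine similarity between all pairs of sparsified connectivity rows.

    affinity(i, j) = <row_i, row_j> / (|row_i| |row_j|). Zero-norm rows get
    affinity 0 to all others and 1 on the diagonal. Result is symmetric and
    in [0, 1] because rows are non-negative after sparsification.
    """
    x = np.asarray(fc_sparse.z_values, dtype=np.float64)
    norm = np.linalg.norm(x, axis=1)
    flat = norm == 0
    safe = np.where(flat, 1.0, norm)
    xn = x / safe[:, None]
    a = xn @ xn.T
    a = np.clip(a, 0.0, 1.0)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    a[flat, :] = 0.0
    a[:, flat] = 0.0
    a[np.ix_(flat, flat)] = 0.0
    a[flat, flat] = 1.0
    return AffinityMatrix(values=a, grid=fc_sparse.seed_grid)


def diffusion_embedding(
    affinity: AffinityMatrix | np.ndarray,
    alpha: float = 0.5,
    n_components: int = 10,
    grid: VoxelGrid | None = None,
) -> GradientSet:
    """Anisotropic diffusion-map embedding of an affinity matrix.

    With W the affinity and d its row sums, forms W' = D^-a W D^-a, then
    the Markov matrix P = D'^-1 W'. The spectrum of P is computed via the
    symmetric conjugate D'^1/2 P D'^-1/2 (guaranteed real). The trivial
    constant eigenvector (eigenvalue 1) is discarded; component k is
    lambda_k * psi_k (one-step diffusion scaling), ordered by decreasing
    eigenvalue. variance_explained is each eigenvalue over the sum of all
    positive non-trivial eigenvalues.

    Sign convention: each component is flipped so its skewness is positive;
    if skewness is ~0, so that its maximum-magnitude entry is positive.

    Raises
    ------
    ValueError
        For non-symmetric input or a disconnected affinity graph (repeated
        unit eigenvalue).
    """
    if isinstance(affinity, AffinityMatrix):
        w = affinity.values
        grid = grid if grid is not None else affinity.grid
    else:
        w = np.asarray(affinity, dtype=np.float64)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ValueError("affinity must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(w < -1e-12):
        raise ValueError("affinity must be non-negative")
    if not 1 <= n_components < n:
        raise ValueError("need 1 <= n_components < n_voxels")

    d = w.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError(
            "affinity graph has isolated node(s); densify the affinity "
            "(e.g. lower sparsity) before embedding"
        )
    d_alpha = d ** (-alpha)
    w_prime = w * d_alpha[:, None] * d_alpha[None, :]
    d_prime = w_prime.sum(axis=1)
    # symmetric conjugate S = D'^-1/2 W' D'^-1/2 shares eigenvalues with P
    inv_sqrt = 1.0 / np.sqrt(d_prime)
    s = w_prime * inv_sqrt[:, None] * inv_sqrt[None, :]
    s = 0.5 * (s + s.T)
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if n > 1 and evals[1] > 1.0 - 1e-10:
        raise ValueError(
            "affinity graph appears disconnected (repeated unit eigenvalue); "
            "densify the affinity before embedding"
        )
    # back-transform to eigenvectors of P, drop the trivial constant one
    psi = evecs * inv_sqrt[:, None]
    lam = evals[1 : n_components + 1]
    psi = psi[:, 1 : n_components + 1]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    coords = psi * lam[None, :]
    coords = _fix_signs(coords)
    pos = evals[1:][evals[1:] > 0]
    total = pos.sum()
    var = np.where(lam > 0, lam, 0.0) / total if total > 0 else np.zeros_like(lam)
    return GradientSet(
        coordinates=coords,
        eigenvalues=lam,
        variance_explained=var,
        alpha=alpha,
        n_components=n_components,
        grid=grid,
    )


def _fix_signs(coords):
    """Deterministic eigenvector signs: positive skewness, else positive max-|.| entry."""
    out = coords.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        sk = skew(col) if col.std() > 0 else 0.0
        if abs(sk) >= 1e-12:
            if sk < 0:
                out[:, k] = -col
        else:
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                out[:, k] = -col
    return out


def run_gradient_pipeline(
    seed: GroupTimeSeries,
    targets: GroupTimeSeries,
    retain_fraction: float = 0.10,
    alpha: float = 0.5,
    n_components: int = 10,
):
    """FC matrix -> sparsify -> cosine affinity -> diffusion embedding.

    Returns (GradientSet, ConnectivityMatrix (sparse), AffinityMatrix).
    """
    fc = compute_fc_matrix(seed, targets)
    fc_sparse = sparsify_rows(fc, retain_fraction)
    aff = cosine_affinity(fc_sparse)
    grads = diffusion_embedding(aff, alpha=alpha, n_components=n_components)
    return grads, fc_sparse, aff
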