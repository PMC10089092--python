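"""Transcriptome-gradient association via first-component PLS regression.

Tissue samples are mapped onto the dominant gradient by averaging the
gradient within a closed sphere (default radius 3 mm) around each sample's
MNI coordinate. The first PLS component of expression predicting the
per-sample gradient is then fitted in closed form — for a univariate
response the component-1 weight vector is exactly the normalized
cross-covariance Xc' yc, so no iterative NIPALS pass is needed — and
assessed by a sample-shuffle permutation test. Per-gene loadings (Pearson r
between a gene's expression and the PLS scores) rank genes; the top 25% of
positive- and of negative-loading genes form the strongly contributing
PLS+ and PLS- sets.

Gene columns are mean-centred but not variance-scaled by default (the
expression input is assumed already normalized); ``scale=True`` enables
unit-variance scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import ExpressionPanel, VoxelGrid

__all__ = [
    "PlsAssociation",
    "map_samples_to_gradient",
    "pls1_fit",
    "pls_permutation_test",
    "gene_loadings",
    "select_contributing_genes",
]


@dataclass
class PlsAssociation:
    sample_gradient: np.ndarray  # per kept sample
    scores: np.ndarray  # per-sample component-1 gene score
    weights: np.ndarray  # per-gene component-1 weight (unit norm)
    loadings: np.ndarray  # per-gene Pearson r with scores
    gene_symbols: np.ndarray
    r_scores_gradient: float
    p_perm: float | None = None
    n_perm: int | None = None
    n_exceed: int | None = None
    pls_plus: list[str] | None = None
    pls_minus: list[str] | None = None

    @property
    def p_label(self) -> str:
        if self.p_perm is None:
            return "NA"
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_perm:g}"


def map_samples_to_gradient(
    panel: ExpressionPanel, gradient, grid: VoxelGrid, radius_mm: float = 3.0
):
    """Mean gradient within a closed ball of ``radius_mm`` around each sample.

    Voxel membership is by centre coordinate, distance <= radius inclusive.
    Samples with no voxel in radius are dropped with a warning; dropping all
    samples is a hard error.

    Returns
    -------
    (sample_gradient, kept) : per-kept-sample mean gradient and a boolean
    mask over the panel's samples.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    g = np.asarray(gradient, dtype=np.float64)
    dist = cdist(panel.sample_coords_mm, grid.coords_mm)
    inside = dist <= radius_mm
    kept = inside.any(axis=1)
    if not kept.any():
        raise ValueError("no sample has a seed voxel within the sphere radius")
    if not kept.all():
        warnings.warn(
            f"{int((~kept).sum())} sample(s) have no seed voxel within "
            f"{radius_mm} mm; dropped",
            stacklevel=2,
        )
    vals = np.array([g[row].mean() for row in inside[kept]])
    return vals, kept


def _center(x, scale=False):
    xc = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = xc.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        xc = xc / sd
    return xc


def pls1_fit(expression, y, gene_symbols=None, scale: bool = False) -> PlsAssociation:
    """First PLS component of expression (X) against a univariate response y.

    w = Xc' yc / |Xc' yc|; scores = Xc w, sign-aligned so corr(scores, y) >= 0.
    Constant gene columns get weight 0 (their centred column is zero) and a
    warning.
    """
    x = np.asarray(expression, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, g = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if y.shape != (n,):
        raise ValueError("y must have one value per sample")
    if y.std() == 0:
        raise ValueError("response is constant")
    if gene_symbols is None:
        gene_symbols = np.array([f"g{i}" for i in range(g)])
    const = x.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene column(s): weight 0",
                      stacklevel=2)
    xc = _center(x, scale=scale)
    yc = y - y.mean()
    w = xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("expression carries no covariance with the response")
    w = w / norm
    scores = xc @ w
    r = _pearson(scores, y)
    if r < 0:
        w, scores, r = -w, -scores, -r
    loadings = gene_loadings(x, scores)
    return PlsAssociation(
        sample_gradient=y,
        scores=scores,
        weights=w,
        loadings=loadings,
        gene_symbols=np.asarray(gene_symbols),
        r_scores_gradient=float(r),
    )


def _pearson(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    az = a - a.mean()
    bz = b - b.mean()
    denom = np.linalg.norm(az) * np.linalg.norm(bz)
    return float(az @ bz / denom) if denom > 0 else 0.0


def pls_permutation_test(
    expression, fit: PlsAssociation, n_perm: int = 5000,
    seed: int | None = None, scale: bool = False, exhaustive: bool = False,
) -> PlsAssociation:
    """Sample-shuffle permutation test of the score-gradient correlation.

    Per permutation the response is shuffled over samples and the
    component-1 fit repeated; p = #{r_null >= r_obs} / n_perm, one-sided on
    the sign-aligned r. With ``exhaustive=True`` (small n only) all n!
    sample orders are enumerated. Updates the fit in place and returns it.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(expression, dtype=np.float64)
    xc = _center(x, scale=scale)
    y = fit.sample_gradient
    # closed form: scores for shuffled y* are Xc Xc' y*c up to scale, and
    # Pearson r is scale-invariant, so the Gram matrix suffices per draw
    gram = xc @ xc.T
    r_obs = fit.r_scores_gradient
    n = y.size

    def _null_r(yp):
        s = gram @ (yp - yp.mean())
        return abs(_pearson(s, yp))  # sign alignment == absolute value

    if exhaustive:
        import itertools

        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9")
        nulls = [_null_r(y[list(p)]) for p in itertools.permutations(range(n))]
        n_perm = len(nulls)
    else:
        rng = np.random.default_rng(seed)
        nulls = [_null_r(y[rng.permutation(n)]) for _ in range(n_perm)]
    n_exceed = int(np.sum(np.asarray(nulls) >= r_obs - 1e-12))
    fit.p_perm = n_exceed / n_perm
    fit.n_perm = n_perm
    fit.n_exceed = n_exceed
    return fit


def gene_loadings(expression, scores) -> np.ndarray:
    """Pearson r between each gene's expression and the PLS scores.

    Constant genes load 0.
    """
    x = np.asarray(expression, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    xc = x - x.mean(axis=0, keepdims=True)
    sc = s - s.mean()
    xn = np.linalg.norm(xc, axis=0)
    sn = np.linalg.norm(sc)
    denom = xn * sn
    flat = denom == 0
    denom[flat] = 1.0
    loadings = (xc.T @ sc) / denom
    loadings[flat] = 0.0
    return loadings


def select_contributing_genes(loadings, gene_symbols, top_fraction: float = 0.25):
    """Top fraction of positive- and of negative-loading genes (PLS+ / PLS-).

    Positives sorted descending, negatives ascending (most negative first);
    each set takes floor(fraction * count). Zero-loading genes belong to
    neither pool. Empty pools warn and return empty lists.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    loadings = np.asarray(loadings, dtype=np.float64)
    gene_symbols = np.asarray(gene_symbols)
    pos = np.flatnonzero(loadings > 0)
    neg = np.flatnonzero(loadings < 0)
    if pos.size == 0:
        warnings.warn("no positive-loading genes; PLS+ empty", stacklevel=2)
    if neg.size == 0:
        warnings.warn("no negative-loading genes; PLS- empty", stacklevel=2)
    k_pos = math.floor(top_fraction * pos.size)
    k_neg = math.floor(top_fraction * neg.size)
    pos_order = pos[np.lexsort((pos, -loadings[pos]))][:k_pos]
    neg_order = neg[np.lexsort((neg, loadings[neg]))][:k_neg]
    return list(gene_symbols[pos_order]), list(gene_symbols[neg_order])
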