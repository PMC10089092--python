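"""Relation of the dominant gradient to intrinsic geometry.

Correlates the gradient with Euclidean distance from its peak voxel and
assesses the correlation with a voxel-shuffle permutation test (two-sided
on |r|; gradient values are permuted over voxel positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import VoxelGrid

__all__ = ["GeometryResult", "distance_from_peak", "gradient_distance_test"]


@dataclass
class GeometryResult:
    peak_voxel_id: int
    distances_mm: np.ndarray
    r_observed: float | None = None
    p_perm: float | None = None
    n_perm: int | None = None
    n_exceed: int | None = None
    hemisphere: str = "both"

    @property
    def p_label(self) -> str:
        """Permutation p for reporting; '< 1/n_perm' when no null exceeds |r|."""
        if self.p_perm is None:
            return "NA"
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_perm:g}"


def distance_from_peak(gradient, grid: VoxelGrid, hemisphere: str = "both") -> GeometryResult:
    """Euclidean mm distance from every voxel to the gradient's peak voxel.

    The peak is the argmax of the gradient; ties go to the lowest voxel id
    with a warning. An all-equal gradient has no meaningful peak and raises.
    """
    g = np.asarray(gradient, dtype=np.float64)
    if g.size < 2:
        raise ValueError("need at least 2 voxels")
    if np.ptp(g) == 0:
        raise ValueError("gradient is constant; no meaningful peak")
    peaks = np.flatnonzero(g == g.max())
    if peaks.size > 1:
        warnings.warn(
            f"{peaks.size} voxels tie at the gradient maximum; using lowest id",
            stacklevel=2,
        )
    peak = int(peaks[0])
    diff = grid.coords_mm - grid.coords_mm[peak]
    dist = np.sqrt((diff**2).sum(axis=1))
    return GeometryResult(peak_voxel_id=peak, distances_mm=dist, hemisphere=hemisphere)


def gradient_distance_test(
    gradient,
    distances,
    n_perm: int = 5000,
    seed: int | None = None,
    hemisphere: str = "both",
    peak_voxel_id: int = -1,
    exhaustive: bool = False,
) -> GeometryResult:
    """Permutation test of the gradient-distance Pearson correlation.

    The null shuffles gradient values across voxel positions and recomputes
    r each time; p = #{|r_null| >= |r_obs|} / n_perm, reported as
    "< 1/n_perm" when the count is zero. With ``exhaustive=True`` (small n
    only) all n! permutations are enumerated instead of sampled.
    """
    g = np.asarray(gradient, dtype=np.float64)
    d = np.asarray(distances, dtype=np.float64)
    if g.shape != d.shape:
        raise ValueError("gradient and distances must have equal length")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if g.std() == 0 or d.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    gz = (g - g.mean()) / g.std()
    dz = (d - d.mean()) / d.std()
    n = g.size
    r_obs = float(gz @ dz / n)
    if exhaustive:
        import itertools
        import math

        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9")
        r_null = np.array(
            [gz[list(p)] @ dz / n for p in itertools.permutations(range(n))]
        )
        n_perm = math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        r_null = np.empty(n_perm)
        for i in range(n_perm):
            r_null[i] = gz[rng.permutation(n)] @ dz / n
    n_exceed = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))
    return GeometryResult(
        peak_voxel_id=peak_voxel_id,
        distances_mm=d,
        r_observed=r_obs,
        p_perm=n_exceed / n_perm,
        n_perm=n_perm,
        n_exceed=n_exceed,
        hemisphere=hemisphere,
    )


def geometry_analysis(
    gradient,
    grid: VoxelGrid,
    hemisphere: str = "both",
    n_perm: int = 5000,
    seed: int | None = None,
) -> GeometryResult:
    """Peak, distances and permutation test, optionally within one hemisphere."""
    g = np.asarray(gradient, dtype=np.float64)
    if hemisphere in ("L", "R"):
        keep = grid.hemisphere == hemisphere
        if keep.sum() < 2:
            raise ValueError(f"fewer than 2 voxels in hemisphere {hemisphere}")
        g = g[keep]
        grid = grid.subset(keep)
    res = distance_from_peak(g, grid, hemisphere=hemisphere)
    return gradient_distance_test(
        g,
        res.distances_mm,
        n_perm=n_perm,
        seed=seed,
        hemisphere=hemisphere,
        peak_voxel_id=res.peak_voxel_id,
    )
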