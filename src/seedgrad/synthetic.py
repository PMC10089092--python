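"""Synthetic worlds with planted structure for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* BOLD series whose voxel-to-brain connectivity varies smoothly along one
  planted latent axis. Each voxel mixes a bank of shared latent sources
  with Gaussian coupling weights centred at the voxel's latent position,
  so the correlation between two voxels decays with their latent distance.
  The seed's latent axis is laid out along one spatial (y) axis of a 3 mm
  voxel lattice.
* Target voxels labeled with seven canonical-style networks whose latent
  centres place a DMN-like network at one extreme of the axis and
  visual/sensorimotor-like networks at the other.
* Meta-analytic term z-maps peaking at chosen latent positions.
* An expression panel in which a known subset of genes tracks the planted
  axis (half with positive, half with negative effect).
* Annotation sets, one planted to be enriched in the positive-effect
  tracking genes.

Everything planted is recorded in :class:`SyntheticTruth`; all generators
are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionPanel, AnnotationSets, VoxelGrid

__all__ = [
    "SyntheticTruth",
    "NETWORK_CENTRES",
    "make_connectivity_world",
    "make_expression_panel",
    "make_term_maps",
    "make_annotation_sets",
]

VOXEL_MM = 3.0

# latent centre per network: DMN-like at one extreme, visual/SMN-like at the other
NETWORK_CENTRES = {
    "visual": 0.0,
    "sensorimotor": 0.15,
    "limbic": 0.35,
    "dorsal_attention": 0.5,
    "ventral_attention": 0.65,
    "frontoparietal": 0.85,
    "default_mode": 1.0,
}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated world."""

    latent: np.ndarray  # per seed voxel, in [0, 1]
    target_latent: np.ndarray
    network_labels: np.ndarray  # per target voxel
    network_centres: dict[str, float]
    seed_network_labels: np.ndarray  # best-correlated network per seed voxel
    tracking_genes: dict[str, float] = field(default_factory=dict)  # gene -> beta
    term_peaks: dict[str, float] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)


def _box_grid(n, dims, origin_ijk, affine):
    """First ``n`` voxels (C-order) of a dims-shaped box placed at origin_ijk."""
    nx, ny, nz = dims
    ijk = np.argwhere(np.ones((nx, ny, nz), dtype=bool))[:n] + np.asarray(origin_ijk)
    import nibabel as nib

    coords = nib.affines.apply_affine(affine, ijk)
    return ijk, coords


def make_connectivity_world(
    n_seed: int = 200,
    n_target: int = 1000,
    n_time: int = 200,
    n_subjects: int = 3,
    coupling_width: float = 0.1,
    noise: float = 1.0,
    seed: int = 42,
    n_sources: int = 15,
):
    """Generate per-subject BOLD with connectivity structured by a latent axis.

    Voxel v's series is ``sum_k exp(-(latent_v - p_k)^2 / (2 sigma_c^2)) *
    source_k``, unit-variance normalized, plus ``noise * N(0,1)`` — so at the
    default ``noise=1.0`` the signal-to-noise ratio is 1. The seed latent
    increases along the lattice's y axis (with small within-level jitter, so
    it still correlates > 0.99 with the y coordinate).

    Returns
    -------
    (per_subject_seed, per_subject_target, seed_grid, target_grid, truth)
        Lists of voxel x time matrices per subject for seed and target
        regions, their grids, and the :class:`SyntheticTruth`.
    """
    if n_time < 50:
        raise ValueError("n_time must be >= 50")
    if coupling_width <= 0 or noise < 0:
        raise ValueError("coupling_width must be > 0 and noise >= 0")
    if n_seed < 20 or n_target < len(NETWORK_CENTRES):
        raise ValueError("world too small")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(4)
    rng_geom, rng_net, rng_sig, rng_noise = (np.random.default_rng(c) for c in child)

    affine = np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])
    affine[:3, 3] = [-6.0, -30.0, 0.0]

    # seed lattice: x 5 wide (straddling x=0 for two hemispheres), latent along y
    nx, nz = 5, 2
    ny = math.ceil(n_seed / (nx * nz))
    seed_ijk, seed_coords = _box_grid(n_seed, (nx, ny, nz), (0, 1, 10), affine)
    j_idx = seed_ijk[:, 1] - 1
    jitter = rng_geom.uniform(-0.3, 0.3, n_seed)
    latent = np.clip((j_idx + jitter) / max(ny - 1, 1), 0.0, 1.0)
    tert = np.quantile(latent, [1 / 3, 2 / 3])
    region = np.where(latent <= tert[0], "Sa", np.where(latent <= tert[1], "Sb", "Sc"))
    seed_grid = VoxelGrid(
        voxel_ids=np.arange(n_seed),
        coords_mm=seed_coords,
        region_label=region.astype(object),
        hemisphere=np.where(seed_coords[:, 0] >= 0, "R", "L"),
        ijk=seed_ijk,
        shape=(16, 22, 12),
        affine=affine,
    )

    # target lattice, spatially disjoint from the seed
    nt_x, nt_z = 10, 10
    nt_y = math.ceil(n_target / (nt_x * nt_z))
    target_ijk, target_coords = _box_grid(n_target, (nt_x, nt_y, nt_z), (6, 1, 0), affine)
    names = list(NETWORK_CENTRES)
    labels = np.asarray(names, dtype=object)[rng_net.integers(0, len(names), n_target)]
    centres = np.array([NETWORK_CENTRES[l] for l in labels])
    target_latent = np.clip(centres + rng_net.normal(0.0, 0.05, n_target), 0.0, 1.0)
    target_grid = VoxelGrid(
        voxel_ids=np.arange(n_target),
        coords_mm=target_coords,
        region_label=np.full(n_target, "cerebrum", dtype=object),
        hemisphere=np.where(target_coords[:, 0] >= 0, "R", "L"),
        ijk=target_ijk,
        shape=(16, 22, 12),
        affine=affine,
    )

    # Gaussian coupling of voxels to shared latent sources
    p = np.linspace(0.0, 1.0, n_sources)
    w_seed = np.exp(-((latent[:, None] - p[None, :]) ** 2) / (2 * coupling_width**2))
    w_target = np.exp(-((target_latent[:, None] - p[None, :]) ** 2) / (2 * coupling_width**2))
    w_seed_n = w_seed / np.linalg.norm(w_seed, axis=1, keepdims=True)
    w_target_n = w_target / np.linalg.norm(w_target, axis=1, keepdims=True)

    per_subject_seed, per_subject_target = [], []
    for _ in range(n_subjects):
        sources = rng_sig.standard_normal((n_sources, n_time))
        per_subject_seed.append(
            w_seed_n @ sources + noise * rng_noise.standard_normal((n_seed, n_time))
        )
        per_subject_target.append(
            w_target_n @ sources + noise * rng_noise.standard_normal((n_target, n_time))
        )

    seed_net = _expected_best_network(w_seed_n, w_target_n, labels, names, noise)
    truth = SyntheticTruth(
        latent=latent,
        target_latent=target_latent,
        network_labels=labels,
        network_centres=dict(NETWORK_CENTRES),
        seed_network_labels=seed_net,
        seeds={"master": seed},
    )
    return per_subject_seed, per_subject_target, seed_grid, target_grid, truth


def _expected_best_network(w_seed_n, w_target_n, labels, names, noise):
    """Population-level best-correlated network per seed voxel.

    Computed from the generator's own coupling weights and noise level, so
    'correct assignment' is well defined even for voxels near a boundary.
    """
    best = np.empty(w_seed_n.shape[0], dtype=object)
    net_mean_w, net_var = [], []
    for name in names:
        sel = labels == name
        mw = w_target_n[sel].mean(axis=0)
        var = mw @ mw + (noise**2) / sel.sum()
        net_mean_w.append(mw)
        net_var.append(var)
    net_mean_w = np.asarray(net_mean_w)
    net_var = np.asarray(net_var)
    cov = w_seed_n @ net_mean_w.T  # voxel variance is 1 + noise^2 (constant)
    corr = cov / np.sqrt(net_var)[None, :]
    for v in range(w_seed_n.shape[0]):
        best[v] = names[int(np.argmax(corr[v]))]
    return best


def make_expression_panel(
    truth: SyntheticTruth,
    seed_grid: VoxelGrid,
    n_samples: int = 25,
    n_genes: int = 500,
    frac_tracking: float = 0.1,
    beta: float = 1.0,
    sigma: float = 0.5,
    seed: int = 1042,
) -> ExpressionPanel:
    """Expression panel whose tracking genes follow the planted axis.

    Samples sit at distinct seed-voxel coordinates. Tracking genes (a
    ``frac_tracking`` subset, half with effect +beta and half with -beta)
    have expression ``beta * z + sigma * N(0,1)`` where z is the sample
    latent standardized across samples, so beta is an effect size in units
    of the axis's across-sample spread; background genes are pure
    standard-normal noise. Updates ``truth.tracking_genes``.
    """
    if not 0 < frac_tracking < 1:
        raise ValueError("frac_tracking must be in (0, 1)")
    if n_samples > seed_grid.n_voxels:
        raise ValueError("more samples than seed voxels")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vox = rng.choice(seed_grid.n_voxels, size=n_samples, replace=False)
    coords = seed_grid.coords_mm[vox]
    sample_latent = truth.latent[vox]
    genes = np.array([f"GENE{i:04d}" for i in range(n_genes)])
    n_track = max(2, int(round(frac_tracking * n_genes)))
    track_idx = rng.choice(n_genes, size=n_track, replace=False)
    betas = np.zeros(n_genes)
    half = n_track // 2
    betas[track_idx[:half]] = beta
    betas[track_idx[half:]] = -beta
    if sample_latent.std() == 0:
        raise ValueError("sampled voxels share one latent value; cannot plant an axis")
    z = (sample_latent - sample_latent.mean()) / sample_latent.std()
    expr = rng.standard_normal((n_samples, n_genes))
    tracked = betas != 0
    expr[:, tracked] = (
        betas[tracked][None, :] * z[:, None]
        + sigma * rng.standard_normal((n_samples, tracked.sum()))
    )
    truth.tracking_genes = {genes[i]: float(betas[i]) for i in np.flatnonzero(tracked)}
    truth.seeds["expression"] = seed
    return ExpressionPanel(
        sample_ids=np.array([f"sample_{i:02d}" for i in range(n_samples)]),
        sample_coords_mm=coords,
        expression=expr,
        gene_symbols=genes,
    )


def make_term_maps(
    truth: SyntheticTruth,
    n_terms: int = 8,
    peak_width: float = 0.1,
    amplitude: float = 5.0,
    seed: int = 2042,
    noise_sd: float = 0.1,
) -> dict[str, np.ndarray]:
    """Per-term z-maps peaking at evenly spaced latent positions.

    ``z_t(v) = amplitude * exp(-(latent_v - peak_t)^2 / (2 w^2)) + noise``.
    Peaks are recorded in ``truth.term_peaks``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    peaks = np.linspace(0.0, 1.0, n_terms)
    maps = {}
    for t, pk in enumerate(peaks):
        name = f"term_{t:02d}"
        maps[name] = (
            amplitude * np.exp(-((truth.latent - pk) ** 2) / (2 * peak_width**2))
            + noise_sd * rng.standard_normal(truth.latent.size)
        )
        truth.term_peaks[name] = float(pk)
    truth.seeds["terms"] = seed
    return maps


def make_annotation_sets(
    truth: SyntheticTruth,
    gene_symbols,
    n_sets: int = 20,
    planted_overlap_frac: float = 0.5,
    set_size: int = 40,
    seed: int = 3042,
) -> AnnotationSets:
    """Annotation sets with one planted to overlap the tracking genes.

    The planted set draws ``planted_overlap_frac`` of its members from the
    positive-effect tracking genes (the pool the PLS+ selection can
    recover) and the rest from non-tracking genes; the remaining sets are
    drawn uniformly from the whole panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = np.asarray(gene_symbols)
    pos_track = [g for g, b in truth.tracking_genes.items() if b > 0]
    non_track = [g for g in genes if g not in truth.tracking_genes]
    n_planted = min(int(round(planted_overlap_frac * set_size)), len(pos_track))
    sets = {}
    planted = list(rng.choice(pos_track, size=n_planted, replace=False)) + list(
        rng.choice(non_track, size=set_size - n_planted, replace=False)
    )
    sets["planted_set"] = planted
    for i in range(1, n_sets):
        sets[f"random_set_{i:02d}"] = list(
            rng.choice(genes, size=set_size, replace=False)
        )
    truth.seeds["annotations"] = seed
    return AnnotationSets(sets=sets, background=list(genes))
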