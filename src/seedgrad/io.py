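"""Domain containers and I/O for volumes, tables and annotation sets.

All voxel-level maps in the package share one spatial frame, the
:class:`VoxelGrid`: voxels in ascending linear (C-order) index within a
binary mask, with millimetre coordinates obtained by applying the volume's
affine to 0-based voxel indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "GroupTimeSeries",
    "ConnectivityMatrix",
    "ExpressionPanel",
    "AnnotationSets",
    "load_masked_bold",
    "load_masked_map",
    "save_voxel_map",
    "standardize_and_concatenate",
    "regress_confounds",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
]


@dataclass
class VoxelGrid:
    """Spatial frame of a masked region.

    Parameters
    ----------
    voxel_ids : (n,) int array
        Contiguous indices 0..n-1 in mask order (ascending linear index).
    coords_mm : (n, 3) float array
        MNI millimetre coordinate of each voxel centre.
    region_label : (n,) array of str
        Anatomical subregion tag per voxel (e.g. A39c / A39rd / A39rv, or
        synthetic tags).
    hemisphere : (n,) array of str
        'L' or 'R' per voxel.
    ijk : (n, 3) int array, optional
        0-based voxel indices in the source volume, kept so maps can be
        written back as NIfTI.
    shape, affine : optional
        Shape and affine of the source volume.
    """

    voxel_ids: np.ndarray
    coords_mm: np.ndarray
    region_label: np.ndarray
    hemisphere: np.ndarray
    ijk: np.ndarray | None = None
    shape: tuple | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        n = self.voxel_ids.size
        if not np.array_equal(self.voxel_ids, np.arange(n)):
            raise ValueError("voxel_ids must be unique and contiguous from 0")
        if self.coords_mm.shape != (n, 3) or not np.all(np.isfinite(self.coords_mm)):
            raise ValueError("coords_mm must be (n, 3) and finite")
        self.region_label = np.asarray(self.region_label)
        self.hemisphere = np.asarray(self.hemisphere)
        if self.region_label.shape != (n,) or self.hemisphere.shape != (n,):
            raise ValueError("region_label and hemisphere must have one entry per voxel")

    @property
    def n_voxels(self) -> int:
        return self.voxel_ids.size

    def subset(self, keep: np.ndarray) -> "VoxelGrid":
        """Return a new grid restricted to a boolean/index selection, re-indexed from 0."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VoxelGrid(
            voxel_ids=np.arange(keep.size),
            coords_mm=self.coords_mm[keep],
            region_label=self.region_label[keep],
            hemisphere=self.hemisphere[keep],
            ijk=None if self.ijk is None else self.ijk[keep],
            shape=self.shape,
            affine=self.affine,
        )


@dataclass
class GroupTimeSeries:
    """Standardized BOLD series concatenated across subjects (voxel x time)."""

    values: np.ndarray
    subject_boundaries: list[tuple[int, int]]
    grid: VoxelGrid
    constant_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Seed-voxel x target-voxel Fisher-z connectivity."""

    z_values: np.ndarray
    seed_grid: VoxelGrid
    target_grid: VoxelGrid
    sparsity_applied: float | None = None


@dataclass
class ExpressionPanel:
    """Tissue samples with MNI coordinates x normalized gene expression."""

    sample_ids: np.ndarray
    sample_coords_mm: np.ndarray
    expression: np.ndarray
    gene_symbols: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids)
        self.sample_coords_mm = np.asarray(self.sample_coords_mm, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        self.gene_symbols = np.asarray(self.gene_symbols)
        n, g = self.expression.shape
        if self.sample_coords_mm.shape != (n, 3):
            raise ValueError("one 3-vector coordinate required per sample")
        if len(set(self.gene_symbols.tolist())) != g:
            raise ValueError("gene_symbols must be unique")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression values must be finite")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


@dataclass
class AnnotationSets:
    """Named gene sets (GMT-style) with an optional explicit background."""

    sets: dict[str, list[str]]
    background: list[str] | None = None

    def __post_init__(self):
        if len(self.sets) == 0:
            raise ValueError("no annotation sets provided")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"annotation set {name!r} is empty")


# ---------------------------------------------------------------------------
# Volume I/O


def load_masked_bold(volume_path, mask_path):
    """Extract a voxel x time matrix from a 4D volume under a binary 3D mask.

    Rows are ordered by ascending linear (C-order) voxel index; millimetre
    coordinates come from the volume affine applied to 0-based indices.

    Returns
    -------
    (values, grid) : (n_voxels, n_time) float array and :class:`VoxelGrid`.
    """
    img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    if img.shape[:3] != mask_img.shape[:3]:
        raise ValueError(
            f"shape mismatch between volume {volume_path} {img.shape[:3]} "
            f"and mask {mask_path} {mask_img.shape[:3]}"
        )
    if not np.allclose(img.affine, mask_img.affine, atol=1e-4):
        raise ValueError(
            f"affine mismatch between volume {volume_path} and mask {mask_path}"
        )
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError(f"mask {mask_path} selects no voxels")
    grid = _grid_from_mask(mask, img.affine)
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., None]
    values = data[mask].astype(np.float64)  # C-order: ascending linear index
    return values, grid


def load_masked_map(volume_path, mask_path):
    """Extract a per-voxel scalar map (3D volume) under a mask; same ordering rules."""
    values, grid = load_masked_bold(volume_path, mask_path)
    return values[:, 0], grid


def save_voxel_map(values, grid: VoxelGrid, out_path):
    """Write per-voxel values back into the grid's source volume geometry."""
    if grid.ijk is None or grid.shape is None or grid.affine is None:
        raise ValueError("grid lacks volume geometry (ijk/shape/affine)")
    vol = np.zeros(grid.shape, dtype=np.float64)
    vol[tuple(grid.ijk.T)] = np.asarray(values, dtype=np.float64)
    nib.save(nib.Nifti1Image(vol, grid.affine), str(out_path))


def _grid_from_mask(mask, affine, region_label=None, hemisphere=None):
    ijk = np.argwhere(mask)  # argwhere is C-order == ascending linear index
    n = ijk.shape[0]
    coords = nib.affines.apply_affine(affine, ijk)
    if region_label is None:
        region_label = np.full(n, "seed", dtype=object)
    if hemisphere is None:
        # NIfTI MNI convention: +x is right
        hemisphere = np.where(coords[:, 0] >= 0, "R", "L")
    return VoxelGrid(
        voxel_ids=np.arange(n),
        coords_mm=coords,
        region_label=np.asarray(region_label),
        hemisphere=np.asarray(hemisphere),
        ijk=ijk,
        shape=mask.shape,
        affine=np.asarray(affine, dtype=float),
    )


# ---------------------------------------------------------------------------
# Group assembly


def standardize_and_concatenate(per_subject, grid: VoxelGrid) -> GroupTimeSeries:
    """z-score each subject block per voxel over time, then concatenate in time.

    Uses the population (n) standard deviation. Rows that are constant within
    a block are set to zero for that block and recorded in
    ``constant_voxels`` with a warning.
    """
    if len(per_subject) == 0:
        raise ValueError("no subjects supplied")
    n_vox = per_subject[0].shape[0]
    for i, block in enumerate(per_subject):
        if block.shape[0] != n_vox:
            raise ValueError(
                f"subject {i} has {block.shape[0]} voxels, expected {n_vox}"
            )
    blocks = []
    boundaries = []
    constant = np.zeros(n_vox, dtype=bool)
    t0 = 0
    for block in per_subject:
        block = np.asarray(block, dtype=np.float64)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)  # population sd
        flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
        sd[flat] = 1.0
        z = (block - mu) / sd
        z[flat] = 0.0
        constant |= flat
        blocks.append(z)
        boundaries.append((t0, t0 + block.shape[1]))
        t0 += block.shape[1]
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant voxel time series zeroed",
            stacklevel=2,
        )
    return GroupTimeSeries(
        values=np.concatenate(blocks, axis=1),
        subject_boundaries=boundaries,
        grid=grid,
        constant_voxels=np.flatnonzero(constant),
    )


def regress_confounds(series, confounds=None):
    """Residualize each voxel's time series against confound regressors.

    An intercept column is always included, so with no confounds the output
    is the demeaned input. Collinear confound columns are dropped with a
    warning. Residuals are orthogonal to every retained confound column.
    """
    series = np.asarray(series, dtype=np.float64)
    n_t = series.shape[1]
    if confounds is None or np.size(confounds) == 0:
        conf = np.empty((n_t, 0))
    else:
        conf = np.asarray(confounds, dtype=np.float64)
        if conf.ndim == 1:
            conf = conf[:, None]
        if conf.shape[0] != n_t:
            raise ValueError(
                f"confounds have {conf.shape[0]} timepoints, series has {n_t}"
            )
    design = np.column_stack([np.ones(n_t), conf])
    # rank check: drop collinear columns (keep earliest)
    q, r, piv = _qr_rank(design)
    if q.shape[1] < design.shape[1]:
        warnings.warn(
            f"dropped {design.shape[1] - q.shape[1]} collinear confound column(s)",
            stacklevel=2,
        )
    beta = q.T @ series.T
    resid = series.T - q @ beta
    return resid.T


def _qr_rank(design, tol=1e-10):
    """Column-pivoted QR keeping an independent column basis in original order."""
    from scipy.linalg import qr

    q, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * max(diag[0], 1.0))) if diag.size else 0
    keep = np.sort(piv[:rank])
    q2, _ = np.linalg.qr(design[:, keep])
    return q2, design[:, keep], keep


# ---------------------------------------------------------------------------
# Tables and annotation files


def read_expression_table(path) -> ExpressionPanel:
    """Read a tab-delimited expression table.

    Dialect: header row required; first column ``sample_id``, then ``x``,
    ``y``, ``z`` MNI coordinates, then one column per gene.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols[:4] != ["sample_id", "x", "y", "z"]:
        raise ValueError(
            "expression table must start with columns sample_id, x, y, z"
        )
    genes = cols[4:]
    return ExpressionPanel(
        sample_ids=df["sample_id"].to_numpy(),
        sample_coords_mm=df[["x", "y", "z"]].to_numpy(dtype=float),
        expression=df[genes].to_numpy(dtype=float),
        gene_symbols=np.asarray(genes),
    )


def write_expression_table(panel: ExpressionPanel, path) -> None:
    df = pd.DataFrame(panel.expression, columns=panel.gene_symbols)
    df.insert(0, "z", panel.sample_coords_mm[:, 2])
    df.insert(0, "y", panel.sample_coords_mm[:, 1])
    df.insert(0, "x", panel.sample_coords_mm[:, 0])
    df.insert(0, "sample_id", panel.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> AnnotationSets:
    """Read GMT-style annotation sets.

    Accepts both ``name<TAB>description<TAB>gene1<TAB>gene2...`` (classic GMT)
    and ``name<TAB>gene1,gene2,...`` (comma-list) dialects.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate annotation set name {name!r}")
            if len(parts) == 2:
                genes = [g for g in parts[1].split(",") if g]
            else:
                genes = [g for g in parts[2:] if g]
                if len(genes) == 1 and "," in genes[0]:
                    genes = [g for g in genes[0].split(",") if g]
            sets[name] = genes
    return AnnotationSets(sets=sets)


def write_gmt(sets: AnnotationSets, path, description="na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            fh.write(f"{name}\t{description}\t" + "\t".join(genes) + "\n")
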