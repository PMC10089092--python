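"""End-to-end orchestration: config, stage chaining, manifests.

``run_all`` executes gradient -> geometry -> parcellation -> decoding ->
transcriptomics -> enrichment from one :class:`RunConfig`, skipping stages
whose inputs are absent, and writes a run manifest (config hash, derived
seeds, SHA-256 checksum of every output file).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import decoding, geometry, gradient, parcellation, transcriptome
from .enrichment import fisher_enrichment
from .io import (
    GroupTimeSeries,
    load_masked_bold,
    load_masked_map,
    read_expression_table,
    read_gmt,
    regress_confounds,
    save_voxel_map,
    standardize_and_concatenate,
)

__all__ = ["RunConfig", "run_all", "simulate_to_dir"]


@dataclass
class RunConfig:
    """All inputs and tunables of a full run; defaults follow the method's
    standard settings (top-10% sparsity, alpha 0.5, 5000 permutations,
    3 mm sphere, z > 2.3, top 25%, q <= 0.05)."""

    bold: list[str] = field(default_factory=list)  # per-subject 4D NIfTI
    seed_mask: str | None = None
    cerebrum_mask: str | None = None
    network_labels: str | None = None  # 3D label volume over target voxels
    term_maps: str | None = None  # directory of NIfTI z-maps or TSV matrix
    expression: str | None = None  # tab-delimited panel
    annotation_sets: str | None = None  # GMT file
    out_dir: str = "run_out"
    retain_fraction: float = 0.10
    alpha: float = 0.5
    n_components: int = 10
    n_perm_geometry: int = 5000
    n_perm_pls: int = 5000
    radius_mm: float = 3.0
    z_threshold: float = 2.3
    top_fraction: float = 0.25
    q_threshold: float = 0.05
    master_seed: int = 42
    gsr: bool = False
    hemisphere: str = "both"  # L | R | both

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self):
        if not 0 < self.retain_fraction < 1:
            raise ValueError("retain_fraction must be in (0, 1)")
        if self.hemisphere not in ("L", "R", "both"):
            raise ValueError("hemisphere must be L, R or both")
        return self


def _child_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig) -> Path:
    """Execute every stage whose inputs are present; return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.master_seed, 4)
    outputs: list[Path] = []
    stage = "load"
    try:
        if not (config.bold and config.seed_mask and config.cerebrum_mask):
            raise ValueError("bold, seed_mask and cerebrum_mask are required")
        seed_blocks, target_blocks = [], []
        seed_grid = target_grid = None
        for path in config.bold:
            sv, seed_grid = load_masked_bold(path, config.seed_mask)
            tv, target_grid = load_masked_bold(path, config.cerebrum_mask)
            if config.gsr:
                gs = np.vstack([sv, tv]).mean(axis=0)
                sv = regress_confounds(sv, gs[:, None])
                tv = regress_confounds(tv, gs[:, None])
            seed_blocks.append(sv)
            target_blocks.append(tv)
        seed_ts = standardize_and_concatenate(seed_blocks, seed_grid)
        target_ts = standardize_and_concatenate(target_blocks, target_grid)

        stage = "gradient"
        grads, fc_sparse, aff = gradient.run_gradient_pipeline(
            seed_ts,
            target_ts,
            retain_fraction=config.retain_fraction,
            alpha=config.alpha,
            n_components=config.n_components,
        )
        save_voxel_map(grads.dominant, seed_grid, out / "gradient_1.nii")
        outputs.append(out / "gradient_1.nii")
        eig = pd.DataFrame(
            {
                "component": np.arange(1, grads.eigenvalues.size + 1),
                "eigenvalue": grads.eigenvalues,
                "variance_explained": grads.variance_explained,
            }
        )
        _write_tsv(eig, out / "eigenvalues.tsv")
        outputs.append(out / "eigenvalues.tsv")

        stage = "geometry"
        hemis = ["both", "L", "R"] if config.hemisphere == "both" else [config.hemisphere]
        geo_rows = []
        for hemi in hemis:
            try:
                res = geometry.geometry_analysis(
                    grads.dominant,
                    seed_grid,
                    hemisphere=hemi,
                    n_perm=config.n_perm_geometry,
                    seed=seeds[0],
                )
            except ValueError as exc:
                warnings.warn(f"geometry ({hemi}) skipped: {exc}", stacklevel=2)
                continue
            geo_rows.append(
                (hemi, res.peak_voxel_id, res.r_observed, res.p_perm, res.p_label,
                 res.n_perm)
            )
        _write_tsv(
            pd.DataFrame(
                geo_rows,
                columns=["hemisphere", "peak_voxel_id", "r", "p_perm", "p_label",
                         "n_perm"],
            ),
            out / "geometry.tsv",
        )
        outputs.append(out / "geometry.tsv")

        if config.network_labels:
            stage = "parcellation"
            labels, _ = load_masked_map(config.network_labels, config.cerebrum_mask)
            means, names = parcellation.network_mean_timecourses(
                target_ts, labels.astype(int)
            )
            parc = parcellation.winner_take_all(seed_ts, means, names, grads.dominant)
            _write_tsv(parc.subdivision_summary, out / "subdivisions.tsv")
            outputs.append(out / "subdivisions.tsv")
            idx = {n: i + 1 for i, n in enumerate(names)}
            label_map = np.array(
                [idx.get(a, 0) for a in parc.assignment], dtype=float
            )
            save_voxel_map(label_map, seed_grid, out / "parcellation.nii")
            outputs.append(out / "parcellation.nii")

        if config.term_maps:
            stage = "decoding"
            maps = _load_term_maps(config.term_maps, config.seed_mask)
            masks = decoding.bin_gradient(grads.dominant)
            profile = decoding.decode_terms(
                masks, maps, z_threshold=config.z_threshold, gradient=grads.dominant
            )
            _write_tsv(profile.to_frame(), out / "term_profile.tsv")
            outputs.append(out / "term_profile.tsv")

        pls_fit = None
        if config.expression:
            stage = "transcriptome"
            panel = read_expression_table(config.expression)
            y, kept = transcriptome.map_samples_to_gradient(
                panel, grads.dominant, seed_grid, radius_mm=config.radius_mm
            )
            pls_fit = transcriptome.pls1_fit(
                panel.expression[kept], y, gene_symbols=panel.gene_symbols
            )
            pls_fit = transcriptome.pls_permutation_test(
                panel.expression[kept], pls_fit,
                n_perm=config.n_perm_pls, seed=seeds[1],
            )
            plus, minus = transcriptome.select_contributing_genes(
                pls_fit.loadings, pls_fit.gene_symbols, config.top_fraction
            )
            pls_fit.pls_plus, pls_fit.pls_minus = plus, minus
            _write_tsv(
                pd.DataFrame(
                    [(pls_fit.r_scores_gradient, pls_fit.p_perm, pls_fit.p_label,
                      pls_fit.n_perm, int(kept.sum()), len(plus), len(minus))],
                    columns=["r", "p_perm", "p_label", "n_perm", "n_samples",
                             "n_pls_plus", "n_pls_minus"],
                ),
                out / "pls_report.tsv",
            )
            outputs.append(out / "pls_report.tsv")
            in_set = np.full(pls_fit.gene_symbols.size, "none", dtype=object)
            in_set[np.isin(pls_fit.gene_symbols, plus)] = "PLS+"
            in_set[np.isin(pls_fit.gene_symbols, minus)] = "PLS-"
            _write_tsv(
                pd.DataFrame(
                    {
                        "gene": pls_fit.gene_symbols,
                        "weight": pls_fit.weights,
                        "loading": pls_fit.loadings,
                        "set": in_set,
                    }
                ),
                out / "gene_loadings.tsv",
            )
            outputs.append(out / "gene_loadings.tsv")

        if config.annotation_sets and pls_fit is not None:
            stage = "enrichment"
            sets = read_gmt(config.annotation_sets)
            background = list(pls_fit.gene_symbols)
            for label, query in (("plus", pls_fit.pls_plus),
                                 ("minus", pls_fit.pls_minus)):
                if not query:
                    continue
                res = fisher_enrichment(
                    query, sets, background, q_threshold=config.q_threshold
                )
                _write_tsv(res, out / f"enrichment_pls_{label}.tsv")
                outputs.append(out / f"enrichment_pls_{label}.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "derived_seeds": seeds,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _load_term_maps(path, seed_mask):
    """Term maps from a directory of NIfTI z-maps or a TSV term x voxel table."""
    p = Path(path)
    if p.is_dir():
        maps = {}
        for f in sorted(p.glob("*.nii")) + sorted(p.glob("*.nii.gz")):
            values, _ = load_masked_map(f, seed_mask)
            maps[f.name.split(".nii")[0]] = values
        if not maps:
            raise ValueError(f"no NIfTI term maps found in {path}")
        return maps
    df = pd.read_csv(p, sep="\t", index_col=0)
    return {term: row.to_numpy(dtype=float) for term, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Writing a synthetic world to disk (the `simulate` subcommand)


def simulate_to_dir(
    out_dir,
    seed: int = 42,
    n_seed: int = 200,
    n_target: int = 1000,
    n_time: int = 200,
    n_subjects: int = 3,
    noise: float = 1.0,
) -> Path:
    """Generate a synthetic world and write every pipeline input plus truth.json."""
    from . import synthetic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_blocks, target_blocks, seed_grid, target_grid, truth = (
        synthetic.make_connectivity_world(
            n_seed=n_seed, n_target=n_target, n_time=n_time,
            n_subjects=n_subjects, noise=noise, seed=seed,
        )
    )
    shape, affine = seed_grid.shape, seed_grid.affine
    seed_mask = np.zeros(shape, dtype=np.uint8)
    seed_mask[tuple(seed_grid.ijk.T)] = 1
    target_mask = np.zeros(shape, dtype=np.uint8)
    target_mask[tuple(target_grid.ijk.T)] = 1
    nib.save(nib.Nifti1Image(seed_mask, affine), str(out / "seed_mask.nii"))
    nib.save(nib.Nifti1Image(target_mask, affine), str(out / "cerebrum_mask.nii"))

    names = list(synthetic.NETWORK_CENTRES)
    net_ids = np.array([names.index(l) + 1 for l in truth.network_labels])
    net_vol = np.zeros(shape, dtype=np.int16)
    net_vol[tuple(target_grid.ijk.T)] = net_ids
    nib.save(nib.Nifti1Image(net_vol, affine), str(out / "network_labels.nii"))

    for s in range(n_subjects):
        vol = np.zeros(shape + (n_time,), dtype=np.float32)
        vol[tuple(seed_grid.ijk.T)] = seed_blocks[s]
        vol[tuple(target_grid.ijk.T)] = target_blocks[s]
        nib.save(nib.Nifti1Image(vol, affine), str(out / f"bold_sub-{s:02d}.nii"))

    term_dir = out / "term_maps"
    term_dir.mkdir(exist_ok=True)
    maps = synthetic.make_term_maps(truth)
    for name, zvals in maps.items():
        vol = np.zeros(shape, dtype=np.float64)
        vol[tuple(seed_grid.ijk.T)] = zvals
        nib.save(nib.Nifti1Image(vol, affine), str(term_dir / f"{name}.nii"))

    panel = synthetic.make_expression_panel(truth, seed_grid)
    from .io import write_expression_table, write_gmt

    write_expression_table(panel, out / "expression.tsv")
    sets = synthetic.make_annotation_sets(truth, panel.gene_symbols)
    write_gmt(sets, out / "annotations.gmt")

    (out / "truth.json").write_text(
        json.dumps(
            {
                "latent": truth.latent.tolist(),
                "target_latent": truth.target_latent.tolist(),
                "network_labels": truth.network_labels.tolist(),
                "network_centres": truth.network_centres,
                "seed_network_labels": truth.seed_network_labels.tolist(),
                "tracking_genes": truth.tracking_genes,
                "term_peaks": truth.term_peaks,
                "seeds": truth.seeds,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return out


def config_for_world(world_dir, out_dir, **overrides) -> RunConfig:
    """RunConfig pointing at the files `simulate_to_dir` writes."""
    world = Path(world_dir)
    cfg = RunConfig(
        bold=[str(p) for p in sorted(world.glob("bold_sub-*.nii"))],
        seed_mask=str(world / "seed_mask.nii"),
        cerebrum_mask=str(world / "cerebrum_mask.nii"),
        network_labels=str(world / "network_labels.nii"),
        term_maps=str(world / "term_maps"),
        expression=str(world / "expression.tsv"),
        annotation_sets=str(world / "annotations.gmt"),
        out_dir=str(out_dir),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
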