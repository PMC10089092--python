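# seedgrad

Functional-connectivity **gradients** of a seed brain region, with the
analyses that typically surround them: relation to intrinsic geometry,
winner-take-all network parcellation, meta-analytic term decoding, and a
PLS-based association between the gradient and spatial gene expression,
followed by gene-set enrichment.

The package is aimed at neuroimaging researchers who want to characterize
the internal organization of a region of interest (an association-cortex
seed such as the angular gyrus, a subcortical nucleus, ...) from
resting-state fMRI, and at methods developers who need a tested, scriptable
reference implementation of this analysis family.

## The method

Given preprocessed BOLD volumes, a binary seed mask and a cerebrum (target)
mask in a common space:

1. **Connectivity.** Per-subject series are z-scored per voxel and
   concatenated in time; the seed-to-cerebrum functional connectivity matrix
   is `z = arctanh(r)` of the Pearson correlation between every seed voxel
   and every target voxel.
2. **Affinity.** Per seed row, negative connections are zeroed and only the
   top 10% of connections are retained; the affinity between seed voxels *i*
   and *j* is the cosine similarity of their sparsified connectivity rows.
3. **Diffusion-map embedding.** With affinity *W* and degrees
   *d*, the anisotropic operator `W' = D^-α W D^-α` (α = 0.5) is
   row-normalized to a Markov matrix *P* and eigendecomposed. Dropping the
   trivial constant eigenvector, component *k* assigns each voxel the
   coordinate `λ_k ψ_k(v)`; the eigenvalue fraction `λ_k / Σ_j λ_j` is the
   variance explained. Component 1 is the **dominant gradient** — the axis
   along which connectivity profiles change most.
4. **Correlates.** The dominant gradient is (a) correlated with Euclidean
   distance from its peak voxel, with a 5000-fold voxel-shuffle permutation
   test; (b) summarized per winner-take-all network subdivision; (c) sliced
   into 10 rank-based percentile bins to profile term z-maps (terms with a
   bin mean > 2.3 are retained); and (d) regressed against a tissue-sample ×
   gene expression panel via first-component PLS (`w ∝ Xᶜᵀyᶜ`), with a
   5000-fold sample-shuffle permutation test, per-gene loadings, top-25%
   PLS+/PLS− gene selection, and Fisher's-exact / FDR-BH enrichment.

A synthetic-data generator (`seedgrad.synthetic`) builds worlds in which a
known latent axis structures connectivity, network labels, term maps,
expression and annotations, so every stage can be validated against planted
ground truth without any data download.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from seedgrad import io, gradient, synthetic
from seedgrad.geometry import geometry_analysis

blocks_seed, blocks_target, seed_grid, target_grid, truth = \
    synthetic.make_connectivity_world(seed=42)
seed_ts = io.standardize_and_concatenate(blocks_seed, seed_grid)
target_ts = io.standardize_and_concatenate(blocks_target, target_grid)
grads, fc_sparse, affinity = gradient.run_gradient_pipeline(seed_ts, target_ts)

print(f"variance explained (first 3): {np.round(grads.variance_explained[:3], 3)}")
rho = spearmanr(grads.dominant, truth.latent).statistic
print(f"dominant gradient vs planted axis: Spearman rho = {rho:.3f}")

geo = geometry_analysis(grads.dominant, seed_grid, n_perm=5000, seed=0)
print(f"gradient vs distance from peak: r = {geo.r_observed:.4f}, p_perm {geo.p_label}")
```

prints

```
variance explained (first 3): [0.119 0.113 0.106]
dominant gradient vs planted axis: Spearman rho = -0.999
gradient vs distance from peak: r = -0.9893, p_perm < 0.0002
```

The dominant gradient recovers the planted latent axis almost perfectly
(the embedding's sign is arbitrary, so the correlation may come out
negative), it explains the largest share of connectivity variance, and it
decreases smoothly with distance from its peak voxel — the geometric
signature the analysis is designed to detect.

## Command line

```bash
gradients simulate --out world/ --seed 42        # write a synthetic world
gradients run --config run.yaml                  # full pipeline from a config
gradients demo --seed 42                         # simulate + run in one step
gradients geometry --gradient g1.nii --mask seed_mask.nii --n-perm 5000
gradients enrich --query pls_plus.txt --sets go_bp.gmt --background panel.txt
```

Every run writes its outputs (`gradient_1.nii`, `eigenvalues.tsv`,
`geometry.tsv`, `subdivisions.tsv`, `term_profile.tsv`, `pls_report.tsv`,
`gene_loadings.tsv`, enrichment tables) plus a `manifest.json` with the
configuration hash, derived seeds and a SHA-256 checksum of every file, so
identical configurations yield bitwise-identical results.

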