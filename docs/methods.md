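# Methods

This note documents the models, conventions and design choices behind
`seedgrad`, in the spirit of the methods documentation of packages such as
scanpy or statsmodels. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Group time series

Per-subject voxel × time matrices are z-scored per voxel within each
subject (population standard deviation, i.e. divisor *n*) and concatenated
along time. Constant voxel series are set to zero, recorded, and excluded
from correlation (their connectivity entries are 0) rather than propagating
NaNs. Confound residualization (used for the global-signal-regression
sensitivity switch) fits ordinary least squares per voxel with an intercept
always included; collinear confound columns are dropped with a warning.
Inputs are assumed preprocessed — motion correction, normalization,
filtering and nuisance modelling are upstream of this package.

## Connectivity, sparsification, affinity

Correlations are computed over the full concatenated time axis and
variance-stabilized with Fisher's z = arctanh(r); r is clipped to
±(1 − 1e−7) so perfectly correlated pairs map to finite extremes.
Row sparsification first zeroes negative connections (their biological
interpretation is contested), then keeps the `ceil(fraction · n_targets)`
largest values per row; the default fraction is 0.10, with 0.20 and 0.30 as
standard sensitivity settings. Ties at the cutoff keep the lower target
index so results are reproducible. Rows left without positive connections
stay all-zero with a warning and receive zero affinity to all other voxels
(unit self-affinity), which keeps the affinity matrix well defined.

The affinity is cosine similarity between sparsified rows — non-negative,
symmetric, unit-diagonal.

## Diffusion-map embedding

With affinity `W` and degree vector `d = W·1`:

1. `W' = D^-α W D^-α` with α = 0.5 (the density-normalization setting
   standard for connectivity data; α = 0 maximal density influence, α = 1
   none);
2. `P = D'^-1 W'`, the Markov transition matrix (rows sum to 1);
3. the spectrum of `P` is obtained from the symmetric conjugate
   `D'^1/2 P D'^-1/2`, which guarantees a real spectrum and stable
   eigenvectors; eigenvectors are mapped back and unit-normalized;
4. the trivial constant eigenvector (eigenvalue 1) is discarded; a repeated
   eigenvalue ≈ 1 means the affinity graph is disconnected, which is an
   error instructing the user to densify (lower sparsity) rather than a
   silent multi-component embedding;
5. component *k*'s per-voxel coordinate is `λ_k ψ_k` — a one-step
   (diffusion time t = 1) scaling. The choice of t rescales components
   monotonically and is irrelevant to the rank- and correlation-based
   analyses downstream; it is fixed here for definiteness.
6. variance explained of component *k* is `λ_k / Σ_j λ_j` over all
   positive non-trivial eigenvalues. Other conventions (squared
   eigenvalues, truncated sums) exist in the literature; reported
   percentages are only interpretable relative to the stated convention.

Eigenvector signs are arbitrary, so a deterministic convention is applied:
each component is flipped to positive skewness, falling back (at |skewness|
< 1e−12) to making the largest-magnitude entry positive. The convention
makes reruns bitwise identical but does **not** tie the sign to any
external axis: analyses that compare the gradient to a known reference
(e.g. the planted axis of a synthetic world) must resolve orientation by
correlation with that reference first. Ten components are retained by
default; only component 1 (the dominant gradient) feeds the downstream
stages.

The dense symmetric eigensolver is used throughout; seed regions at the
scale this package targets (10²–10⁴ voxels) are comfortably within its
range.

## Geometry

The peak is the argmax of the dominant gradient (ties go to the lowest
voxel id, with a warning); distances are Euclidean millimetres from the
affine-derived voxel-centre coordinates. The permutation test shuffles
gradient values over voxel positions and recomputes Pearson's r;
significance is two-sided on |r|: a rule comparing signed null r's against
a negative observed correlation would be vacuous, and magnitude comparison
is the evident intent of the procedure. p is reported as `< 1/n_perm`
when no null statistic reaches the observed magnitude; n_perm defaults to
5000. Hemispheres can be analyzed separately (peak and distances are then
computed within the hemisphere). Euclidean distance underestimates true
cortical (geodesic) distance across sulci; geodesic distance is out of
scope.

## Winner-take-all parcellation

Network mean time courses are computed over **target** voxels only, so a
seed voxel is never correlated with a mean containing itself (avoiding
self-correlation inflation). Each seed voxel is assigned to the
best-correlated network; ties go to the lowest network index with a
warning, zero-variance voxels are labeled `unassigned` and excluded from
summaries. Networks to which no voxel is assigned are reported with zero
counts rather than raised as errors — real seeds routinely lack a
subdivision for one or more canonical networks. Subdivision summaries
(count, mean and SD of the dominant gradient) are sorted by mean gradient.

## Term decoding

The gradient is split into 10 rank-based, equal-count bins (ties broken by
voxel id), so duplicated gradient values can never empty a bin — a
value-based percentile split could. A term's profile is its mean z per
bin; a term is retained when its **maximum** bin mean exceeds the z
threshold (default 2.3, strict inequality). The retention statistic had to
be fixed at one of max-over-bins / any-bin / whole-seed mean; max-over-bins
is used because the bin profile is the only term-level statistic the
procedure produces. For visualization order, each term gets the
positive-part centre of mass `Σ_b b·max(profile_b,0) / Σ_b max(profile_b,0)`
(b = 1..10), which reproduces the familiar staircase layout
deterministically.

## Transcriptome association

Samples are mapped onto the gradient by averaging it over seed voxels whose
centres lie within a closed ball (≤ radius, default 3 mm) of the sample's
coordinate; samples with no voxel in range are dropped with a warning.

PLS is fitted for component 1 only, by the exact closed form for a
univariate response: `w ∝ Xᶜᵀ yᶜ` normalized to unit length, scores
`Xᶜ w`. This equals the first NIPALS/SIMPLS component (the test suite
cross-checks against scikit-learn's NIPALS implementation); no deflation is
needed because later components are not used. Gene columns are centred but
not variance-scaled by default — the expected input is an
already-normalized expression panel — with unit-variance scaling available
as a switch. The score sign is aligned so the score–gradient correlation
is non-negative. The permutation test shuffles samples, refits, and counts
null correlations ≥ the observed one (one-sided on the sign-aligned
statistic, ties counted); with few samples and many genes the first PLS
component correlates highly with *any* response, so the permutation null —
not the raw correlation — carries the inference. Loadings are Pearson
correlations of each gene with the scores; constant genes load 0. PLS+ and
PLS− are the top `floor(0.25 · count)` of positive- and negative-loading
genes respectively (the floor reproduces the 1988 → 497 and 3025 → 756
arithmetic of a 5013-gene panel); zero-loading genes belong to neither.

## Enrichment

Each annotation set is intersected with the background before testing; the
background defaults to the analyzed gene panel, because enrichment must be
conditional on what could have been selected — a whole-genome background
would overstate significance. The 2×2 table is tested with the two-sided
minimum-likelihood Fisher's exact test; odds ratios apply the Haldane 0.5
correction when a cell is zero. FDR-BH adjustment is applied per query
(PLS+ and PLS− separately) and per annotation file, mirroring per-panel
reporting; `rich_factor` is the fraction of the background-restricted set
recovered by the query.

## Synthetic worlds

`make_connectivity_world` plants a latent position in [0, 1] per voxel.
Voxels mix a bank of 15 shared Gaussian-coupled sources (coupling width
0.1 in latent units), giving connectivity that decays smoothly with latent
distance; the per-voxel signal is unit-variance normalized and independent
Gaussian noise of SD `noise` is added, so `noise = 1` (the default) means
SNR 1 — a deliberately hard but realistic regime for group-level fMRI
connectivity. The seed latent runs along the lattice's y axis with small
within-level jitter (correlation with the spatial axis stays above 0.99);
target voxels carry one of seven network labels whose latent centres put a
default-mode-like network at one extreme and visual/sensorimotor-like
networks at the other. Each seed voxel's true network is defined from the
generator's own coupling weights (the population-level best-correlated
network), so "correct assignment" is well defined even near boundaries.

Defaults — 200 seed voxels, 1000 target voxels, 3 subjects × 200
timepoints, 25 expression samples, 500 genes with 10% tracking genes —
keep the few-samples/many-genes regime of real imaging-transcriptomics
panels while letting the full pipeline and its replicate-based checks run
in well under five minutes on one CPU. All generators are pure functions
of their seed (one master seed, spawned child streams, all recorded in the
truth object).

Expression: tracking genes follow `β·z + σ·ε`, where **z is the sample
latent standardized across samples** — i.e. β is an effect size in units
of the axis's across-sample spread, the usual convention for simulated
effect sizes. With the defaults β = 1, σ = 0.5 a tracking gene correlates
≈ 0.9 with the axis; stating the effect on the raw [0, 1] latent instead
would make the planted effect scale-dependent and much weaker (r ≈ 0.5)
for the same nominal β. Half the tracking genes carry −β. The planted
annotation set draws half its members from the **positive**-effect tracking
genes: it emulates a gene set enriched in genes tracking the axis in one
direction, which is what the PLS+ selection can recover (a sign-mixed draw
would split its signal between PLS+ and PLS−).

What the generator does **not** emulate: hemodynamic autocorrelation,
spatial autocorrelation of fMRI noise, donor structure and spatial
clustering of expression samples, or annotation-set overlap structure.
Passing recovery tests therefore demonstrates correctness of the
computations and sensible behaviour under noise, not performance on real
data; in particular the spatial-permutation nulls here do not face the
autocorrelation problem that motivates spin tests and generative null
models on real cortical maps.

## Numerical conventions and degenerate inputs

- Correlation clipping at ±(1 − 1e−7) before arctanh.
- Affinity symmetrized and clipped to [0, 1] before embedding; symmetry is
  asserted at 1e−10.
- Disconnected affinity graphs and isolated nodes raise errors rather than
  producing silent multi-component embeddings.
- Constant series/genes: zeroed or zero-weighted, warned, never NaN.
- Tie-breaks are always by lowest index (sparsification cutoff, gradient
  peak, winner-take-all, bin assignment) so every result is deterministic.
- Permutation p-values use ≥ with a 1e−12 tolerance at the observed value
  and are floored at `1/n_perm` in reports (`< 1/n_perm`).
- Exhaustive permutation enumeration is available for n ≤ 9 in both
  permutation tests, for exact small-sample verification.

## Problem sizes used in validation

The shipped checks run the default synthetic world (200 × 1000 voxels,
600 concatenated timepoints), 50 random affinities up to n = 200 for the
eigen-oracle, 400 replicates × 500 permutations for geometry-test
calibration, 200 replicates for the PLS null, and 50 replicates for
planted-set enrichment detection — sizes chosen so the whole validation
remains a desk-scale computation while each statistical check retains
enough replicates to be meaningful.

## Known limitations

- Group-level gradients only; no individual-level embedding or cross-run
  alignment (Procrustes) is provided.
- Euclidean, not geodesic, distances.
- Single-component PLS; no bootstrap standard errors on loadings.
- Enrichment treats annotation sets as flat gene lists (no ontology graph
  propagation), and pSI-style specificity lists are consumed as ordinary
  annotation files, not computed.
- The variance-explained convention is one of several in use; percentages
  from different packages are not directly comparable.
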