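# Methods

This note documents the models, parameter choices and numerical decisions
behind `scenersa`, and what the synthetic generators do and do not emulate.

## GIST descriptor

An image is represented by the energy of a bank of frequency-domain Gabor
filters pooled over a coarse spatial grid. The defaults — 4 scales × 8
orientations × a 4×4 grid — give the canonical 512-value descriptor; this
is the only factorisation consistent with a 512-length vector over 16
spatial locations.

Filters are built directly in the frequency domain. The radial term is a
log-Gaussian centered on 0.25/2^s cycles/pixel for scale s (periods of 4,
8, 16 and 32 pixels at the four scales) with bandwidth ratio σ_f/f₀ = 0.65;
the angular term is a Gaussian in orientation distance wrapped modulo π
with σ_θ = π/(2·orientations). Wrapping modulo π makes each transfer
function symmetric under point reflection, so impulse responses are real
and "orientation" means undirected orientation, as it should. The DC bin is
exactly zero, so a constant image maps to the zero descriptor. Boundary
handling is circular (everything happens in the FFT domain).

Before filtering, an optional prefilter (on by default) subtracts a
Gaussian low-pass estimate of local luminance (cutoff 4 cycles/image) and
divides by a low-passed local contrast estimate (ε = 0.2 in the divisive
denominator to avoid amplifying silence). This makes descriptor energies
reflect structure rather than local lighting.

Stimulus preprocessing follows the presentation pipeline: BT.601 grayscale,
center crop to square, bilinear resize to 256×256, then mean-luminance and
RMS-contrast equalisation (defaults 0.5 and 0.14 in [0,1] luminance units;
RMS contrast is the luminance standard deviation). Equalised values are
clipped to [0,1]; clipping is flagged because it perturbs the equalisation.
A zero-variance image cannot have its contrast equated and is returned flat
at the target mean with a warning flag.

## Stimulus selection

Corpus normalisation is two-step: each descriptor component is scaled to
sum to 1 across images (all-zero components left zero), then each image
vector is scaled to unit magnitude (all-zero rows left zero and flagged).
PCA is mean-centred without whitening; 20 components by default; component
signs follow a largest-loading-positive convention so runs are bitwise
reproducible. k-means uses Euclidean distance, k-means++ initialisation, 10
restarts and a fixed seed; final assignments are recomputed against the
returned centroids (ties to the lowest cluster index) and an empty cluster
is re-seeded at the farthest point. Selection takes the 24 members nearest
each centroid, ties broken by image id.

The cluster-level feature similarity matrix uses leave-one-image-out
cross-validation with one image per cluster left out per iteration (this
requires equal cluster sizes, which selection guarantees, and yields
exactly 24 iterations with every image left out once). Per iteration, each
left-out vector is Pearson-correlated against every cluster's
mean-of-the-rest; iteration matrices are averaged and symmetrised by
(M + Mᵀ)/2. Note one consequence of this scheme: the matrix diagonal is
invariant to image ordering, but the off-diagonals average over
cross-cluster pairings of left-out images and therefore depend (mildly) on
within-cluster order; reruns are nonetheless exactly reproducible because
member order is deterministic.

MDS is classical (Torgerson) scaling on dissimilarity 1 − r, with
zero-padding and a warning when fewer positive eigenvalues than requested
dimensions exist.

## Neural-pattern analysis

The blocked design presents 6 images per block (0.75 s on, 0.25 s off → 6 s
blocks), 4 blocks per condition (40 blocks for 10 conditions) in a seeded
pseudo-random order, separated by 9 s rest, sampled at TR = 3 s. The block
order is an unconstrained seeded permutation; no counterbalancing
constraint is imposed (configurable seed). Boxcars are convolved with a
single-gamma HRF parameterised to peak at 6 s with 3 s dispersion
(shape 3 + 2√2, scale 6/(shape − 1), peak-normalised), at 50 ms resolution.
GLM fitting is voxel-wise OLS; rank-deficient designs are rejected naming
the collinear columns; only task betas are returned.

ROIs are grown by flood fill on a statistic map: bisection on the threshold
between the map minimum and the seed's value, taking the 6-connected
component containing the seed, stopping within ±2 voxels of the 500-voxel
target (best-so-far returned otherwise). Keeping the threshold at or below
the seed value guarantees seed membership. 500 voxels at 2 mm isotropic is
4000 mm³ per hemisphere.

LOPO MVPA: per fold, the group pattern is the arithmetic mean of the
remaining subjects' ROI betas — the fixed-effects limit of a group model,
chosen over a mixed-effects group GLM as out-of-scope infrastructure that
does not change the LOPO logic. Group and left-out patterns are normalised
by subtracting each voxel's mean across conditions (so a per-voxel,
condition-independent offset cancels exactly — asserted in the tests), then
every group condition pattern is Pearson-correlated with every left-out
condition pattern. The resulting k×k matrix is inherently asymmetric; the
discrimination test uses its diagonal versus all k²−k off-diagonal cells,
and the matrix is symmetrised before RSA vectorisation.

Discrimination: per fold, mean Fisher-z diagonal (within) minus mean
Fisher-z off-diagonal (between), paired t across folds (df = folds − 1),
Cohen's d = mean/SD of differences. Noise ceilings use each fold's
symmetrised, Fisher-z off-diagonal vector: the upper bound correlates each
fold with the mean of all folds (optimistic, the fold is in its own
target), the lower bound with the mean of the remaining folds.

Correlation matrices (GIST, MVPA, semantic) are Fisher-z transformed before
averaging and testing; the perceptual dot-product matrix is never
z-transformed because it is not a correlation. Entries at ±1 (matrix
diagonals) are clipped to ±(1 − 1e−7) with a warning before atanh.

## Semantic and perceptual models

Semantic vectors count the proportion of pixels carrying each of the 22
vocabulary labels, over **all** pixels (unlabelled pixels dilute every
label but contribute to none — "proportion of the image" is read as
image-total), then scale to unit magnitude. Cluster similarity reuses the
LOIO machinery.

The perceptual model counts each participant's cards per cluster × stack;
similarity between clusters i and j is the dot product Σ_s c_is·c_js
(co-occurrence frequency, counts² scale); the full symmetric matrix is
materialised (downstream RSA uses unique off-diagonals only) and averaged
across participants. Card subsets are counterbalanced by consuming each
cluster's seed-shuffled member list in a rotating window, so usage counts
across subjects differ by at most one.

## RSA statistics

Pearson correlations throughout (the parametric df/p reporting convention
implies Pearson; a rank-based variant would be a one-line change at the
call sites). Partial correlations residualise both vectors on the
covariates plus intercept via OLS (df = n − 2 − c); the three-variable
closed form serves only as a test oracle. Semi-partial correlations
residualise only the competing predictor (df = n − 3). Collinear or
constant covariates are rejected rather than silently absorbed.
Holm–Bonferroni: sort ascending, adjusted_i = max_{j≤i} (m−j+1)·p_(j),
capped at 1, returned in input order; equivalent to the step-down rejection
rule at every level (asserted against a brute-force implementation and
statsmodels).

## Searchlight

Sphere membership is computed between voxel centers in millimetres through
the affine, so anisotropic grids are handled; boundary spheres are kept if
they contain at least `min_voxels` (default 10) in-mask voxels, and skipped
centers carry the sentinel p = 1 plus a companion evaluated-centers mask.
Per sphere, the LOPO fold RDMs are recomputed from the sphere's voxels and
either the discrimination paired t or the RSA of the fold-averaged
off-diagonals against a model vector is run; the p-value lands at the
center voxel. No multiple-comparison correction is applied to maps;
thresholding is a display-layer decision.

A calibration caveat documented deliberately: under pure noise the RSA
searchlight's parametric p-values are well calibrated (~5% of centers below
0.05), but the within/between discrimination t is anti-conservative,
because LOPO folds share N−2 subjects and are therefore positively
correlated, violating the paired t-test's independence assumption. The
calibration test in the suite therefore targets the RSA searchlight; the
discrimination searchlight is validated by planted-region localisation
instead.

## Synthetic data: what it emulates, and what it does not

- **Texture corpus**: each latent group owns one grating orientation
  (0°/45°/90°/135°), one spatial period (4/8/16/32 px) and one active
  quadrant — exactly the three attributes the GIST pools over — plus iid
  pixel noise (default SD 0.05, a level at which a 10-group corpus is still
  recovered perfectly by GIST + PCA + k-means). It emulates a corpus with
  separable visual structure, not photographic scenes: no semantic content,
  no natural image statistics.
- **Voxel datasets**: a shared condition × voxel signal is drawn as L·Z
  with L the Cholesky factor of the model matrix (shrunk toward the
  identity by the smallest λ restoring positive semi-definiteness, plus
  1e−6, since user RDMs may be indefinite); each subject adds iid Gaussian
  noise. Default signal and noise SD are both 1.0 — an SNR at which 8
  subjects × 2000 voxels recover a planted 10×10 model at r > 0.8 but
  single folds are visibly noisy. No spatial autocorrelation, no
  physiological noise, no inter-subject anatomical variability: passing
  recovery tests shows the estimator logic is right, not that real fMRI
  reaches this SNR.
- **Card sorts**: clusters with model similarity above 0.5 (configurable)
  share a stack prototype; each card goes to the stack with maximal
  prototype affinity plus Gaussian noise (default SD 0.35, which spreads
  cards across stacks without destroying structure). This is a stand-in
  process, not a behavioural claim; real card-sort noise is uncharacterised.
- **Label masks**: labels painted as contiguous raster bands matching
  requested pixel fractions to within one row; geometry is meaningless,
  only the proportions matter to the semantic model.

In the end-to-end pipeline the synthetic "PPA" is planted with the
GIST-derived similarity structure, "OPA" with identity structure
(discriminable but unstructured), and "RSC" with no condition signal, and
the card sorts are driven by the same planted matrix — so in the demo run
the perceptual model tracks the GIST model. This is a choice of synthetic
ground truth for verifying the estimators, not a reproduction of any
empirical dissociation between models.

## Problem sizes and determinism

Default synthetic scales (2,000-image corpus at 64×64 for selection; 6–20
subjects at 300–3,000 voxels for the neural analyses; 18³–24³ volumes for
searchlight) are chosen so every analysis completes in seconds to a few
minutes on a single CPU while leaving the structural parameters (k = 10,
24 images/cluster, 20 PCs, 45 off-diagonals) at their study values. Every
generator is a pure function of its arguments including the seed; all
randomness flows from one `numpy` Generator per call, and end-to-end reruns
with the same config are byte-identical.

## Known limitations

- The GIST parameterisation matches the canonical descriptor's structure
  but not any specific implementation bit-for-bit; absolute energies are
  implementation-specific, and all downstream use is correlation-based.
- The one-per-cluster LOIO scheme's off-diagonal pairing dependence (above)
  means LOIO matrices from differently-ordered but identical corpora can
  differ slightly off-diagonal.
- The discrimination searchlight's p-values should be treated as a ranking
  statistic, not calibrated tail probabilities (see the calibration caveat).
- `min_voxels` spheres at volume boundaries make boundary p-values noisier
  than interior ones.
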