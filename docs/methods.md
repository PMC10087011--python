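# Methods

This note records what `msiroi` computes, the assumptions behind it, the
defaults that matter, and the numerical choices made where the design was
genuinely open. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

A mass spectrometry imaging (MSI) dataset is a hyperspectral cube: one
mass spectrum per raster pixel. The H&E whole-slide image of a serial
section is converted into a second cube on the same grid by tiling (one
tile per MSI pixel) and encoding each tile as a histomorphological-feature
(HF) spectrum. Both cubes are segmented independently by spectral
clustering, and the agreement between the two segmentations — Cohen's
kappa, maximized over cluster-label permutations — is used as an external
validity measure. The number of clusters K* is chosen to maximize that
agreement; pixels on which the modalities disagree at K* are excluded from
the final ROIs.

The underlying assumption is that biological structure is reproduced by
both molecular and morphological contrast, while modality-specific noise
(DESI salt-and-pepper pixels, staining artifacts) is not. Kappa's chance
correction matters here: raw percentage agreement is inflated at small K,
whereas p_e (the product of marginal proportions summed over classes)
removes that bias, so curves for different K are comparable.

### Cohen's kappa and label alignment

κ = (p_o − p_e)/(1 − p_e) is computed on the contingency table of the two
labelings over the pixels foreground in *both* modalities (the
intersection; pixels one modality never observed cannot attest agreement).
Because p_e depends on how the marginals are paired, the alignment
maximizes κ itself, not merely the diagonal count: exhaustively over all
K! permutations for K ≤ 9 (≤ 362,880 evaluations, vectorized, well under
a second), with ties broken toward the lexicographically smallest
permutation. For K > 9 a Hungarian assignment on the agreement matrix
seeds a pairwise-swap ascent and a suboptimality warning is emitted. The
degenerate case of two identical constant labelings has p_e = 1; κ is
defined as 1 there, with a warning. Ties in the K* curve resolve to the
smallest K (parsimony).

## Stage-by-stage choices

**MSI preprocessing.** Stage order is fixed: TIC normalization →
Savitzky–Golay smoothing (window 9, polyorder 3) → grey-opening baseline
removal → peak picking at SNR 3 (noise = robust MAD of the first
difference) → alignment by greedy 1-D gap clustering at 0.05 Da →
binning (bin center = mean of contributing centroids) → dropping bins
present in < 1% of foreground pixels. The TIC target is the mean
foreground TIC rather than 1, keeping intensities in acquisition-like
units. Foreground pixels are found by Otsu-thresholding the summed image
of tissue-specific ions; when no ion list is given, the channels surviving
a provisional background-dominance screen are used (self-consistent
bootstrap). Ion channels whose mean background intensity exceeds their
mean foreground intensity are removed outright — they carry no tissue
information.

**HF encoding.** Tiles are anchored at the image origin; partial edge
tiles are dropped; the MSI/H&E pixel-size ratio must be within 1% of an
integer. A tile is foreground iff its tissue fraction is ≥ 0.9
(inclusive). The `densenet201` backend resizes tiles to 224×224
(bilinear), scales to [0, 1] and centers with the ImageNet channel
statistics, then pools the `conv5_block32_concat` tensor (1,920
channels). The forward pass is implemented directly on numpy (im2col +
BLAS); kernels come from an `.npz` when supplied, otherwise from a seeded
He-normal draw with identity batch norm — a weight-free instantiation that
is deterministic and architecture-faithful, suitable for dimensionality
verification and for tests, though its features are not transfer-learning
features. The `classical` backend is a 40-dimensional color/texture
descriptor (channel means/stds, 8-bin histograms, GLCM statistics,
gradient statistics) and is the default in tests. Feature scaling is
feature-wise min–max over the foreground tiles; constant features map to
0 and are flagged.

**Registration.** Each cube is reduced by NMF (rank 8, NNDSVD-A
initialization, fixed seed) to spatial score maps; one HF/MSI pair —
chosen manually, or automatically as the cross-modal pair with the largest
|Pearson r| on a 32×32 common grid (floor 0.3) — drives the registration.
MSI is the moving image. Both maps are min–max rescaled to [0, 1]. The
transform is affine followed by a B-spline free-form deformation (control
spacing 8 px, order 3), both optimized under Mattes mutual information
(32 bins, full sampling, 3-level pyramid with shrink 4/2/1). Three
numerical choices were needed to make this robust on sparse, blob-like
score maps:

1. *Translation initialization by phase cross-correlation.* The MI
   gradient's capture range is smaller than realistic serial-section
   offsets; FFT cross-correlation finds the bulk shift globally, and the
   affine stage is seeded with it.
2. *Regular-step gradient descent* (relaxation 0.5) for both stages;
   plain gradient descent oscillated at these image sizes.
3. *Per-stage acceptance by cross-correlation.* Once two maps roughly
   agree, MI can still be increased by spurious deformation (histogram
   sharpening). After each stage the plain NCC of the warped maps is
   compared to the previous stage's; a stage that lowers it is rolled
   back. With identical inputs this leaves the transform at identity
   (mean displacement ≪ 0.1 px) while genuine warps are kept.

A registration whose final MI is worse than the identity's raises an
error with the metric trace. Warping applies the fitted transform to
every ion channel (linear interpolation) and to the foreground mask
(nearest neighbour); the m/z axis is untouched. QC reports the Dice and
Jaccard overlap of the HF and warped-MSI tissue masks.

**Segmentation.** Foreground spectra are standardized, reduced to at most
50 principal components, connected in a k = 15 nearest-neighbour graph,
embedded with the normalized Laplacian and partitioned by k-means (10
restarts, fixed seed). Cluster ids are reassigned by decreasing cluster
size, which removes k-means' arbitrary label permutation. Well-separated
clusters routinely disconnect the k-NN graph; by default the components
are bridged with the minimum-spanning-tree edges of the pairwise
distances at a small weight (0.01) — strong enough for connectivity,
too weak to drag the bridged pixels' embedding coordinates across
clusters. `connect="error"` restores strict failure. No spatial
smoothing is applied anywhere: scattered mislabeled pixels are meant to
surface as cross-modal disagreement, not to be blended away.

**Baselines.** The PC criterion renders a 3-component nonlinear embedding
(UMAP by default, PCA optionally) of the spectra as an RGB image and
correlates its Canny edges (σ = 1, union over channels) with the edges of
the segmentation map rendered in random region colors; the mean ± std over
5 color draws is reported per K and the argmax selected. The DBI baseline
is the standard Davies–Bouldin index on the same prepared features,
argmin selected. Both are single-modality criteria retained for
comparison, not used for the final selection.

**ROIs.** At K*, the stored permutation aligns the HF labeling to the MSI
labeling; agreeing pixels form per-region masks (ids follow the MSI
labeling), disagreeing pixels form the unconfident mask, and the two
together tile exactly the shared foreground. The rendering blends
unconfident pixels toward the background at α = 0.5 by default
(configurable — reasonable renderings range from 20% to 50% opacity).
Ion rankings are Pearson correlations between each ion image and the
region's binary mask over the shared foreground; zero-variance channels
are excluded; the top ion per region is the characteristic ion. Overlays
upsample grid-resolution maps by the tile size (order-3 spline for ion
images, nearest for label maps) and blend onto the H&E image.

## The phantom generator

The generator emulates a serial-section experiment at desk scale:

- **Geometry.** A wobbled elliptical tissue blob on a 60×60 grid,
  partitioned into K_true = 4 contiguous regions by seeded Voronoi growth
  under a smoothly distorted metric (mirroring a whole-organ section with
  a few anatomical compartments).
- **MSI side** (120 channels): each region has a signature of 8 Gaussian
  peaks (amplitudes 2–10 over a 0.02 baseline); pixels get a log-normal
  TIC factor (cv 0.2) and additive half-normal noise at 10% of the mean
  signal; 1% of foreground pixels swap to another region's signature
  (salt-and-pepper mislabels); 10 channels are background-dominated
  (planted noise ions); the last 4 channels are reserved as per-region
  marker ions for colocalization experiments.
- **HF side** (64 features): per-region prototypes in [0.15, 0.85] plus
  Gaussian noise (σ 0.05), clipped to [0, 1]; additionally one region —
  the largest — carries a smooth within-region texture gradient
  (amplitude 0.06 along a random feature direction), because real
  histology varies coherently inside a region rather than i.i.d.; this is
  what a K_true + 1 clustering of the histology legitimately splits. A
  procedural H&E-like texture image (8 px per tile, distinct
  pattern/palette per region) lets the tiling and feature-extraction path
  run end to end.
- **Mismatch.** The MSI grid samples the ground truth through a smooth
  random displacement field (Gaussian-filtered noise, default max 2 px)
  plus an optional bulk translation. The "deformation enabled" study
  condition used in the registration experiments is a 3 px offset plus
  the 2 px warp: serial sections are offset in practice, and with no bulk
  offset the two grids already agree on ~95–100% of pixels, leaving no
  headroom any registration could consistently improve.
- **Spurious region.** Optionally, a disc inside the *smallest* region
  that can hold it is relabeled as an MSI-only region (K_true + 1) with
  its own spectral signature and no histological counterpart — the
  unvalidatable-segment scenario. It is hosted away from the textured
  region so the histology's extra structure at K + 1 arises elsewhere.

What the phantom does **not** emulate: realistic lipid chemistry or
isotope patterns, profile-mode peak shapes at full resolution, staining
variability between slides, and pixel-size-dependent partial-volume
mixing at region boundaries. Passing tests therefore demonstrate the
correctness and robustness of the algorithmic chain under controlled
conditions, not instrument-level performance on real data.

## Problem sizes and determinism

All simulation-backed checks run on 60×60 phantoms (≈ 1,800 foreground
pixels, 120 channels), K swept over 2–8, five seeds where a success rate
is asserted — sizes at which every stage is exercised in seconds while
preserving the qualitative regime (regions of a few hundred pixels,
boundary mixing, noise). Every stochastic step (NMF initialization,
k-means, UMAP, phantom draws) takes an explicit seed; the pipeline fans a
single global seed out to per-stage seeds by hashing the stage name, so
stages are reproducible in isolation and a rerun with the same config
reproduces all numeric outputs bit for bit.

## Known limitations

- The exhaustive kappa alignment is factorial in K; beyond K = 9 the
  swap-ascent fallback is a heuristic (flagged by a warning).
- Registration quality depends on the chosen score-map pair; the
  automatic chooser maximizes plain correlation and can pick a
  structurally poor pair on pathological data — manual choice remains
  available and is the conservative option.
- The weight-free DenseNet encoder verifies architecture and
  dimensionality but does not reproduce transfer-learning features;
  quantitative comparisons with pretrained-feature results require
  supplying kernels.
- Pixels foreground in only one modality are treated as background for
  ROI purposes; they are neither confident nor unconfident.
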