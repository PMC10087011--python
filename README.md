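# msiroi

Multimodally corroborated spatial segmentation for mass spectrometry
imaging (MSI).

## The problem

Spatial segmentation — clustering MSI pixels by their mass-spectral
similarity — is the standard way to delineate regions of interest (ROIs)
in a tissue section. Its weakest link is choosing the number of clusters
*K*: set it too high and the clustering starts tracing instrumental noise
and acquisition artifacts, producing "regions" that are not biologically
real. Internal validity indices judge the clustering only on the MSI data
itself, so they inherit the same noise.

`msiroi` uses the H&E histology image of a serial section as an external
referee. Both modalities are segmented independently, and only structure
that is reproduced by both is trusted:

1. **HF spectra.** The whole-slide H&E image is split into tiles whose
   physical size equals one MSI pixel (e.g. a 100 µm MSI pixel over a
   0.5 µm slide scan → 200 × 200 px tiles). Each tile with ≥ 90% tissue is
   encoded into a *histomorphological-feature (HF) spectrum* — the
   globally average-pooled `conv5_block32_concat` tensor of DenseNet-201
   (1,920 features), or a classical color/texture descriptor. The tiles
   form a second hyperspectral cube whose depth is HF instead of *m/z*.
2. **Registration.** Each cube is reduced by non-negative matrix
   factorization to spatial score maps; a matched pair of maps drives an
   affine + B-spline free-form registration under a mutual-information
   metric, and the fitted transform warps every ion image onto the HF
   grid.
3. **Consistency scoring.** Both cubes are segmented by spectral
   clustering for K = 2…8. For each K, agreement is measured by Cohen's
   kappa

   κ = (p_o − p_e) / (1 − p_e),

   where p_o is the observed per-pixel agreement and p_e the agreement
   expected by chance from the marginal cluster proportions. Because
   cluster ids are arbitrary, κ is maximized over all K! relabelings of
   one side before comparison. The K with the largest aligned κ is
   selected; identical labelings give κ = 1, unrelated ones ≈ 0.
4. **Confidence-masked ROIs.** At the selected K, pixels whose aligned
   labels agree become solid-colored ROIs; disagreeing pixels are flagged
   unconfident and rendered translucent. Ions characteristic of each ROI
   are ranked by the Pearson correlation between their ion image and the
   ROI's binary mask.

The Pearson-edge-correlation (PC) and Davies–Bouldin (DBI) internal
criteria are included as baselines for comparison.

## Worked example

The built-in phantom generator draws a paired MSI/H&E dataset with a known
number of tissue regions, region-specific peak signatures, noise, scattered
mislabeled pixels, and a serial-section-style deformation:

```python
from msiroi.phantom import PhantomParams, generate_phantom
from msiroi.segmentation import sweep_k
from msiroi.validation import cks_curve_select

phantom = generate_phantom(PhantomParams(), seed=0)
msi_labels = sweep_k(phantom.msi, range(2, 9), seed=1)
hf_labels = sweep_k(phantom.hf, range(2, 9), seed=2)
curve = cks_curve_select(msi_labels, hf_labels)
for k, kappa in zip(curve.ks, curve.kappas):
    print(f"K={k}  CKS={kappa:.3f}"
          + ("  <-- selected" if k == curve.best_k else ""))
print(f"true region count: {phantom.truth.labels_hf.max()}")
```

prints

```
K=2  CKS=0.671
K=3  CKS=0.735
K=4  CKS=0.913  <-- selected
K=5  CKS=0.610
K=6  CKS=0.493
K=7  CKS=0.436
K=8  CKS=0.326
true region count: 4
```

The consistency curve peaks at the phantom's true region count: both
modalities reproduce the four planted regions, while finer segmentations
split along modality-specific noise that the other side does not confirm.

The same analysis runs from the shell. `msiroi run --seed 1 -o out/`
executes phantom generation (or imzML + TIFF ingestion), feature
extraction, registration, the K sweep, K selection and ROI delineation,
writing the consistency curve (`cks_curve.csv/.png`), labelings, ROI
masks, ion rankings and QC reports into the run directory; each stage is
also available as its own subcommand (`msiroi phantom|preprocess|features|
register|segment|select-k|rois`).

## Layout

| module | role |
| --- | --- |
| `msiroi.cubes` / `msiroi.dataio` | hyperspectral cube types; imzML, TIFF/PNG and HDF5 I/O |
| `msiroi.preprocess` | TIC normalization, peak pipeline, foreground and noisy-ion logic |
| `msiroi.histofeat` / `msiroi.densenet` | tiling and HF encoding of the H&E slide |
| `msiroi.registration` | NMF score maps, affine + FFD mutual-information registration |
| `msiroi.segmentation` | spectral clustering and the K sweep |
| `msiroi.validation` | Cohen's kappa, permutation alignment, K selection, PC/DBI baselines |
| `msiroi.roi` | confidence-masked ROIs, ion ranking, overlays |
| `msiroi.phantom` | paired synthetic data with ground truth |
| `msiroi.cli` / `msiroi.pipeline` / `msiroi.config` | orchestration |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
numerical choices.
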