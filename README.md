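# mmfscope

Desk-scale simulator for multimode-fiber (MMF) transmission-matrix
microendoscopy through a biopsy needle, with a tissue-texture analysis
pipeline that discriminates tumor from normal tissue along a puncture path.

The package has six modules:

| Module | What it does |
| --- | --- |
| `mmfscope.fiber_optics` | Random transmission matrices (TMs), phase-conjugate focusing, binary Lee-style hologram encoding, simulated off-axis interferometric TM calibration, angular-spectrum free-space propagation, HDF5 persistence. |
| `mmfscope.scanner` | Point-scan image formation (`ideal_psf` Airy-convolution mode and `speckle` TM mode), Brenner-function sharpness, autofocus over candidate planes, depth-indexed puncture series, TIFF persistence. |
| `mmfscope.phantoms` | Synthetic phantoms: ordered alveolar textures (normal), disordered heterogeneous textures (tumor), line-pair and two-point resolution targets, labeled cohorts with manifests. |
| `mmfscope.texture_features` | Six per-image metrics: GLCM contrast and homogeneity, average magnitude spectrum, high-frequency energy, spectral frequency contrast, spectral frequency variance; pooled min-max normalization. |
| `mmfscope.group_stats` | Assumption-driven test selection (Shapiro-Wilk / Levene → Student's t, Welch's t, or Mann-Whitney U), Benjamini-Hochberg FDR across the six metrics, Cliff's delta effect sizes. |
| `mmfscope.discrimination` | Dual-view unsupervised classification: intensity-histogram and Canny/Sobel edge features, PCA + K-means (k=2), accuracy-maximizing label alignment, OR-toward-tumor view combination, seeded t-SNE visualization. |

## Command line

All stages are exposed under a single `mmfscope` entry point:

```bash
# simulate a transmission matrix
mmfscope simulate-tm --na 0.37 --wavelength-um 0.785 --modes 256 --seed 0 --out tm.h5

# phantoms and targets
mmfscope phantom alveoli --out normal.tiff
mmfscope phantom tumor --disorder 1.0 --out tumor.tiff
mmfscope phantom lines --lp-per-mm 450 --pixel-um 0.1 --out lines.tiff
mmfscope phantom cohort --n-per-class 100 --seed 0 --out cohort/

# imaging
mmfscope scan --phantom normal.tiff --mode ideal_psf --out scan.tiff
mmfscope autofocus --phantom volume.tiff --z-list 0,20,40 --out best.tiff

# analysis pipeline
mmfscope metrics --images cohort/ --labels cohort/manifest.csv --out metrics.csv
mmfscope stats --metrics metrics.csv --q 0.05 --out results.csv
mmfscope cluster --images cohort/ --labels cohort/manifest.csv --rule or_tumor --seed 0 --out clusters/
```

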