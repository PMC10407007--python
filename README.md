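# myotex

Radiomic texture analysis of myocardial-perfusion SPECT for predicting
whether a patient's left-ventricular ejection fraction (EF) will improve
after percutaneous coronary intervention (PCI).

## The problem

Revascularization only helps when enough of the poorly perfused myocardium
is hibernating rather than scarred. The working hypothesis of this pipeline
is that the *spatial heterogeneity* of tracer uptake in the left ventricle —
scattered regions of hibernation, infarct and scar — carries that
information, and that engineered texture features can read it out. Patients
are grouped into three outcome classes: class 1 (no improvement or
deterioration of EF), class 2 (EF improved by 0–5 %) and class 3 (EF
improved by more than 5 %).

Because no imaging cohort of this kind is publicly deposited, the package is
exercised end-to-end on synthetic left-ventricle phantoms: ellipsoidal
myocardial shells in a 64×64×S grid with a reduced-uptake defect, a
class-dependent log-Gaussian heterogeneity field, PSF blur and
intensity-proportional noise. The phantom generator is first-class, tested
code — it defines the study conditions for every downstream claim.

## The pipeline

1. **Preprocessing / segmentation** — min–max gray-level normalization
   `I' = (I − min I)/(max I − min I)`; k-means intensity clustering seeds the
   myocardium and a morphological active contour refines it slice by slice.
2. **2D in-house texture battery** (440 features per volume) — per-pixel
   Haralick statistics from rotation-pooled co-occurrence matrices (distance
   1; orientations 0°/45°/90°/135°; 4–16 gray levels; 3×3/5×5/7×7 kernels),
   25 LAWS texture-energy masks, a 48-filter Gabor bank (6 wavelengths × 8
   orientations) and 3×3 median-image statistics, each feature map reduced
   over the ROI by average, variance, median, skewness and kurtosis.
3. **3D IBSI-style battery** (269 features) — 50 first-order, 29 morphology,
   and six texture-matrix families under dual aggregation: GLCM 25×2,
   GLRLM 16×2, GLSZM 16×2, GLDZM 16×2, NGTDM 5×2, NGLDM 17×2.
4. **Feature selection** — z-scoring, then NCA (diagonal neighbourhood
   component analysis), mRMR (MID variant) and L1 multinomial logistic
   regression, each keeping a 7-feature working set; pairwise Wilcoxon
   rank-sum screening across the class pairs C1C2 / C1C3 / C2C3.
5. **Classification** — cosine KNN, fine KNN, subspace KNN, cross-entropy
   tree, RUSBoosted trees, cubic SVM and random forest, evaluated over
   repeated stratified 2-per-class holdouts (train 46 / validate 6 on a
   24/12/16 cohort) with per-class accuracy, AUC, sensitivity, specificity,
   precision and F-score.
6. **Consensus clustering** — 1000 iterations of subsampled (80 %)
   average-linkage hierarchical clustering with Pearson distance, cut at
   k = 3, plus clustergram and feature-correlation analyses.

## Worked example

```python
import numpy as np
from myotex.phantom import PhantomConfig, generate_lv_phantom
from myotex import preprocess, radiomics3d

vol, truth = generate_lv_phantom(PhantomConfig(seed=1))
seg = preprocess.segment_lv(vol, seed=0)
print("Dice vs truth:", round(preprocess.dice(seg, truth), 3))

feats = radiomics3d.extract_all(preprocess.normalize_gray_levels(vol),
                                seg, spacing=vol.spacing)
print(len(feats), "features;",
      "NGTDM_Complexity =", round(feats["NGTDM_Complexity"], 3))
```

prints

```
Dice vs truth: 0.968
269 features; NGTDM_Complexity = 5714.591
```

i.e. the automatic segmentation overlaps the true shell at Dice 0.97 and the
3D battery returns its full 269-feature vector, including the neighbourhood
gray-tone complexity that indexes rapid local uptake changes.

The numbered scripts under `analysis/` run the full study on the synthetic
cohort — simulate, segment, extract, select, classify, cluster — each
printing what it found and writing its tables under `results/analysis/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_segment.py
python analysis/03_extract_features.py --truth-masks
python analysis/04_select_features.py
python analysis/05_classify.py
python analysis/06_cluster.py
```

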