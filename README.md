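# nucseg

Segmentation and classification of **dysmorphic nuclei** in fluorescence
microscopy.

Nuclei with blebs, folds and crevices are a hallmark of laminopathies,
viral infection and cancer, but they defeat ordinary intensity
segmentation: blebs are often much dimmer than the nuclear body and are
attached through narrow, low-intensity crevices, so a single global
threshold either loses the bleb or fuses neighbouring nuclei.  `nucseg`
implements a segmentation pipeline built for exactly this phenotype,
together with the evaluation metrics, morpho-textural features and
classifiers needed to quantify and detect nuclear dysmorphy — all
exercisable on synthetic images with known ground truth.

## The method

**Two-pass thresholding.**  A global auto-threshold (any of 8 ImageJ-style
histogram methods: Huang, Isodata, Li, MaxEntropy, Mean, Otsu, Triangle,
Yen) yields seed regions.  Seeds are conditionally dilated — grown by at
most 3 µm but clipped to their Voronoi cells so neighbours never fuse —
and a *local* threshold is recomputed from each dilated region's own pixel
population, recovering dim structures the global pass missed.

**Contour refinement by optimal-path finding.**  A 2 µm band around each
contour is straightened into a matrix *P* (rows = normal offsets, columns
= arc positions), edges are enhanced with a vertical Sobel derivative, and
each column is divided by its maximum (matrix *N*) so dim bleb edges weigh
as much as bright body edges.  The boundary is then re-detected as the
left-to-right path through *N* maximizing the **path strength**

    s = gain / loss
      = (sum of normalized edge intensity along the path) / (number of cells traversed),

with vertical runs of any height allowed (propagation up to 90°), which
lets the path descend into crevices around blebs.  The ratio objective is
solved exactly by Dinkelbach parametric linearization (iterated additive
dynamic programs on `gain − λ·loss`); the per-element strength/gain/loss
recursion matrices (*S*, *G*, *L*) are exposed for inspection.  Refinement
is iterated so indentations deeper than the 1 µm half-band are reached.

**Conditional watershed.**  A distance-transform watershed proposes
separation lines inside each ROI; a split is accepted only if both
fragments exceed a minimum area **and** the median perpendicular intensity
profile across the line drops enough (min/max ratio ≤ 0.75 by default).
Touching nuclei show a background-level valley and are split; bleb necks
do not, and stay attached.

**Validation metrics.**  Automatic contours *C* are scored against
multi-observer manual ground truth *GT_k* with the average Hausdorff
distance `AHD = mean_k max[h(C,GT_k), h(GT_k,C)]` and the non-similarity
index `NSI = (A_C + A_GT − 2·A_∩)/(A_C + A_GT)`, each scaled by the
observers' own pairwise values (positive control) and averaged into one
integrated error — *error < 1 means the algorithm is closer to the
observers than they are to each other*.

**Features and classification.**  Shape (area, perimeter, fitted ellipse,
circularity, solidity), total absolute boundary curvature,
rotation-invariant elliptic Fourier descriptors (summed normalized
amplitudes over harmonics ≥ 2 score deviation from an ellipse), and
GLCM texture (ASM, contrast, correlation, homogeneity, entropy averaged
over 0°/45°/90°/135°).  Classifiers (SVM-RBF, random forest, plus
LDA/QDA/NB baselines) are trained on class-balanced data with a stratified
2/3–1/3 split and 10-fold cross-validated tuning, reporting MCR and FNR
(dysmorphic = positive class).  A non-interactive retraining path appends
newly labelled nuclei and refits.

## Worked example

```python
from nucseg.synth import BlebSpec, FieldSpec, NucleusSpec, render_field
from nucseg.config import PipelineConfig
from nucseg.pipeline import run_pipeline

# a 28 x 28 um field with one blebbed nucleus (bleb at 30% body intensity)
bleb = BlebSpec(neck_angle=0.5, neck_width_um=1.8, bleb_radius_um=2.0,
                intensity_fraction=0.3)
nuc = NucleusSpec(center_um=(14, 14), semi_axes_um=(5.5, 4.5), blebs=(bleb,))
image, gt_mask, _ = render_field(FieldSpec(shape_px=(140, 140), nuclei=(nuc,),
                                           seed=3))

cfg = PipelineConfig.model_validate(
    {"segment": {"global_method": "otsu", "local_method": "triangle"}})
result = run_pipeline(image, cfg)
row = result.features.iloc[0]
print(len(result.contours), round(row.area_um2, 1),
      round(row.solidity, 3), round(row.efd_sum, 3))
```

prints

```
1 89.0 0.913 0.648
```

one nucleus, 89.0 µm² (ellipse ≈ 78 µm² plus the bleb), solidity 0.913 and
summed EFD 0.648 — both far from an ovoid nucleus (solidity ≈ 1,
EFD ≈ 0.05), flagging the bleb.  On this fixture the global Otsu threshold
alone recovers ~1% of the bleb's pixels; the local pass recovers ~87% and
refinement ~98%.

The same pipeline is available from the shell:

```bash
nucseg simulate --preset benchmark --seed 1 --out fixtures/
nucseg pipeline --image fixtures/seg_field_00.tif --out out/
nucseg classify train --features features.csv --model svm_rbf --seed 1 --out model.joblib
```

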