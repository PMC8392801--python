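# petdmax

Lesion-dissemination metrics and prognostic evaluation for baseline FDG-PET
of lymphoma.

In diffuse large B-cell lymphoma (DLBCL), how far apart the lesions sit in
the body carries prognostic information beyond the total tumor burden. The
spread is summarized by the largest distance between lymphoma sites (Dmax),
standardized by body surface area to give **SDmax** (units m⁻¹). `petdmax`
computes the full family of such features from a SUV-calibrated PET volume
plus lesion seed masks, and provides the survival-analysis machinery needed
to evaluate their prognostic value on a cohort.

## Features computed

For a patient with lesions segmented at 41% of each lesion's SUVmax:

- **SDmax_Euc / SDmax_Man / SDmax_Tch** — the largest Euclidean / Manhattan
  / Chebyshev distance between lesion *centroids*,
  `d(A,B) = √(Σᵢ Δᵢ²)`, `Σᵢ |Δᵢ|`, `maxᵢ |Δᵢ|` respectively, with axes the
  patient-aligned world axes of the image;
- **SDmax_Euc_Vox / SDmax_Man_Vox / SDmax_Tch_Vox** — the same maxima taken
  over the two most distant *voxels* of the total metabolic tumor volume,
  regardless of lesion membership (applicable when a segmentation yields
  tumor voxels without separated lesions, e.g. deep-learning masks);
- **SD_TSP** — the length of the shortest closed loop through all lesion
  centroids (a Travelling-Salesman tour), sensitive to the number of sites
  as well as their spread.

Each raw distance (mm) is standardized as `SD = (d/1000) / BSA` with the
Mosteller body surface area `BSA = √(height·weight/3600)` (height in cm,
weight in kg, BSA in m²), yielding m⁻¹.

The evaluation layer implements ROC AUC with DeLong variance and paired
DeLong AUC comparison, optimal-cutpoint search (Youden and maximally
selected log-rank with optional permutation correction), Kaplan–Meier with
Greenwood bands, the log-rank test, and Cox proportional-hazards models
(Efron/Breslow ties) both univariable and adjusted for tumor burden
(MTV > 220 cm³) and performance status (ECOG ≥ 2), plus Cohen's kappa for
agreement between the high/low groups induced by different features.

A synthetic-fixtures module generates ellipsoid-lesion PET phantoms with
analytic ground truth and proportional-hazards cohorts with known hazard
ratios, so every stage is testable without patient data.

## Worked example

Two 10 mm-radius spherical lesions, centres 200 mm apart, on a 2 mm grid:

```python
from petdmax import (PatientBody, PhantomSpec, LesionSpec, make_phantom,
                     build_lesion_set, compute_features)

spec = PhantomSpec(
    shape=(130, 30, 30), spacing_mm=(2.0, 2.0, 2.0),
    lesions=(
        LesionSpec(center_mm=(20, 30, 30), radii_mm=(10, 10, 10), peak_suv=8.0),
        LesionSpec(center_mm=(220, 30, 30), radii_mm=(10, 10, 10), peak_suv=8.0),
    ),
    background_suv=0.0,
)
grid, seeds, truth = make_phantom(spec)
lesions = build_lesion_set(grid, seeds)          # 41% SUVmax rule per seed
feats = compute_features(lesions, PatientBody(height_cm=170, weight_kg=80))
```

This prints (via the obvious f-strings):

```
n_lesions = 2, MTV = 8.24 cm3, BSA = 1.9437 m2
Dmax (centroid, Euclidean) = 200.0 mm -> SDmax_Euc = 0.1029 m^-1
Dmax (voxel,    Euclidean) = 220.0 mm -> SDmax_Euc_Vox = 0.1132 m^-1
TSP loop = 400.0 mm -> SD_TSP = 0.2058 m^-1
```

The centroid distance recovers the 200 mm truth exactly; the voxel-based
distance is larger by one diameter (220 mm = surface-to-surface extremes),
illustrating that the voxel variant majorizes the centroid variant; with
two lesions the TSP loop is out-and-back, twice the centroid distance.

## Command line

```
petdmax segment  <pet.nii.gz> <seeds.nii.gz> --out-csv lesions.csv
petdmax features <metadata.csv> --volume-dir <dir> --out-csv features.csv
petdmax survival <cohort.csv> --out-json report.json
petdmax simulate --kind cohort --seed 1 --n 290 --out-dir bundle/
```

`survival` emits, per feature: AUC (95% CI) for PFS and OS, the optimal
PFS-derived cutoff (reused for OS), sensitivity/specificity, kappa against
the Euclidean-centroid reference, log-rank χ²/p, and univariable plus
MTV/ECOG-adjusted Cox hazard ratios, together with a pairwise DeLong
p-value matrix. All outputs embed the package version and a config hash.

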