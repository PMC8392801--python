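# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `petdmax`, in the package's own terms.

## Coordinate contract

All geometry is computed on voxel-center coordinates in world millimetres:
`world(i,j,k) = origin + (i,j,k) ⊙ spacing`, spacing strictly positive.
NIfTI affines with negative diagonal scales (RAS-style flips) are folded
into an axis flip at load; any rotation or shear beyond a relative 1e-3 is
rejected rather than resampled. The Manhattan and Chebyshev distances are
axis-dependent, so silently resampling onto different axes would change the
features; refusing is the only honest behaviour. The axes used are the
patient-aligned scanner axes — the only axes the data defines. Euclidean
features are rotation-invariant; the other two are not, which the tests
document explicitly.

## Segmentation

Each seed region is thresholded at `fraction × SUVmax` (default fraction
0.41, the standard EANM-style rule), with SUVmax taken per seed region, not
globally — a global threshold would merge or lose lesions of dissimilar
uptake. Thresholding can shatter a seed region; of the surviving voxels we
keep the 26-connected component containing the SUVmax voxel (lexicographic
first among maxima), a deterministic rule. Connectivity is configurable
(6/18/26, default 26, the most permissive and the common choice in PET
tooling). Lesion volume is voxel count × voxel volume; MTV is the sum over
lesions. Inclusion/exclusion of ambiguous foci (e.g. diffuse bone-marrow
uptake) is a human curation step and is represented only as the choice of
seed labels supplied to the tool, not automated.

## Dissemination features

- Centroid features: the lesion centroid is the unweighted mean of voxel
  centres by default; an SUV-weighted mean is available
  (`centroid_weighting="suv"`) since "center of mass" is ambiguous between
  the two. The maximal pairwise centroid distance is computed by direct
  scan (lesion counts are small); ties break to the lowest lexicographic
  index pair for determinism.
- Voxel features: the farthest pair over the union of lesion voxels uses
  exact fast paths — Chebyshev diameter = max axis range; Manhattan
  diameter = max range of the four sign-pattern functionals s·p with
  s ∈ {+++, ++−, +−+, +−−} (the L1 diameter equals the L∞ diameter in the
  transformed coordinates); Euclidean diameter = brute force over convex
  hull vertices (the diameter of a finite set is attained at hull
  vertices), falling back to the full scan for degenerate (collinear /
  coplanar) clouds where the hull construction fails. All three paths are
  tested equal to the O(n²) all-pairs oracle.
- TSP loop: the shortest *closed* tour through all centroids. n=2 is
  out-and-back (2d); n=3 has a single tour. The heuristic is
  nearest-neighbour construction from every start followed by full 2-opt
  until no improving swap, deterministic given input order; the exact mode
  enumerates the (n−1)!/2 distinct tours and is limited to n ≤ 10. The
  heuristic is provably ≥ the optimum and empirically within 5% of it at
  cohort-scale lesion counts. Euclidean edge lengths by default
  (configurable); no voxel-based TSP variant exists since the tour needs
  identified lesion foci.
- Standardization: `SD = (d_mm / 1000) / BSA` with Mosteller
  BSA = √(height·weight/3600). The standardized features are in m⁻¹. With
  fewer than two lesions every distance feature is NaN and a warning is
  emitted; the patient is excluded from cohort-level analysis.

Structural invariants maintained and tested: Tch ≤ Euc ≤ Man ≤ 3·Tch;
every voxel feature ≥ its centroid counterpart; TSP loop ≥ 2 × Euclidean
Dmax; translation invariance of everything and rotation invariance of the
Euclidean features only.

## Survival evaluation

- ROC outcome: the observed event indicator over full follow-up. Censoring
  does not enter the ROC — a documented simplification; a fixed-horizon
  variant (event observed by `horizon_months`, default 48) is available.
- AUC: Mann–Whitney with ties counted ½; variance and paired AUC
  comparison by DeLong's structural components (O(m·n) direct form —
  cohort sizes here never warrant the midrank O(N log N) version).
- Cutpoint search: `youden` maximizes Se+Sp−1 over midpoints between
  consecutive unique scores (strict `score > cutoff` high-risk rule);
  `maxstat` (the default, an X-tile-style search) scans unique score
  values between the 10th and 90th percentiles maximizing the log-rank χ²,
  ties to the lower cutoff. Minimum-p selection inflates type-I error; the
  naive p is labelled as such and a permutation-adjusted p (scores permuted
  against (time,event)) is available. Cutoffs are derived on PFS and
  reused for OS, mirroring standard practice for these features.
- Log-rank: vectorized O(n log n) hypergeometric-variance form, verified
  against both a textbook O–E/V summation oracle and lifelines. Zero
  events in both groups gives χ²=0, p=1 by convention.
- Kaplan–Meier: product-limit via lifelines, with a plain Greenwood
  normal-scale 95% band computed from the event table and clipped to
  [0,1].
- Cox PH: Newton–Raphson partial-likelihood maximization via statsmodels
  `PHReg`; Efron ties by default (monthly-scale times produce ties; Efron
  is less biased than Breslow, which is also offered). Wald CI
  exp(β̂ ± 1.96·SE). Monotone likelihood (complete separation) is flagged
  as non-convergence with a warning, never silent. A score test at β=0 is
  provided and coincides with the log-rank statistic on tie-free data —
  used as a cross-route consistency check. The multivariable model is
  {high feature, MTV > 220 cm³, ECOG ≥ 2}, thresholds configurable.
- Agreement: Cohen's kappa between the binary high/low groups of each
  feature and the Euclidean-centroid reference.

## Synthetic fixtures

Phantoms are ellipsoidal lesions (closed-form centroids and volumes) with
uniform or Gaussian profiles on a constant background, optional Gaussian
noise (clipped at 0), and seed labels equal to the ellipsoid support. The
Gaussian profile uses σ = radii/2, so the 41% iso-surface is the ellipsoid
of scaled radius √(2 ln(1/0.41)) σ ≈ 0.667 × radii, giving an analytic
iso-volume against which segmentation is checked (within 5% at 2 mm
spacing; the voxelization error shrinks with spacing, tested at 4 vs
2 mm). Overlapping lesions are rejected by a bounding-sphere test unless
explicitly allowed. Phantoms emulate lesion geometry only — no PET physics
(PSF, scatter, reconstruction), so passing tests certify the geometry and
statistics pipeline, not robustness to scanner effects.

Cohorts follow the proportional-hazards form the Cox analysis assumes:
exponential baseline (0.0044 events/month for the reference patient) times
exp of a linear predictor over three dichotomies, with independent
Uniform(0, 84 months) censoring. Defaults describe a large elderly DLBCL
trial population: n = 290; P(ECOG ≥ 2) = 0.16; P(MTV > 220 cm³) = 0.55;
latent SDmax log-normal with median 0.232 m⁻¹ and log-SD 0.69 (quartiles
≈ 0.13–0.33 m⁻¹), dichotomized at 0.33 m⁻¹; true hazard ratios 2.9 (high
SDmax), 2.1 (high MTV), 2.3 (poor ECOG); the baseline hazard is set so the
expected event rate is ≈ 0.35 under this mixture (computed analytically
from E[1 − (1−e^{−λc})/(λc)]). The companion features (Manhattan,
Chebyshev, voxel variants, TSP) are derived from the latent SDmax with
multipliers that respect the structural inequalities above, so simulated
feature tables are shaped like real ones (high inter-feature kappa); they
are stand-ins for geometry the cohort generator does not render. The OS
endpoint shares the linear predictor at half the baseline hazard.
Everything is deterministic given the spec seed.

## Problem sizes in tests

The test and acceptance runs use phantom grids of 10⁵–10⁶ voxels at 2–4 mm
spacing, point clouds up to n = 2000 for the farthest-pair oracle, 20-seed
TSP batches at n = 8 plus exhaustive checks to n = 10, 200 replicates of
n = 290 cohorts for Cox coverage and 400 for the log-rank null — sizes at
which every oracle comparison is exact or the Monte-Carlo error is well
inside the asserted bands.

## Known limitations

- ROC ignores censoring except via the fixed-horizon option; no
  time-dependent ROC.
- Axis-dependent metrics assume the scanner axes are patient-aligned;
  tilted acquisitions are rejected, not corrected.
- The maxstat naive p-value is anti-conservative by construction; use the
  permutation-adjusted value for inference.
- The cohort generator draws covariates independently; real MTV, ECOG and
  dissemination are correlated, so simulated multivariable HRs are cleaner
  than real ones.
- No DICOM input, SUV computation, registration or scanner harmonization:
  inputs are SUV-calibrated, axis-aligned NIfTI volumes.
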