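# Methods

This note records the models, conventions and parameter choices behind
`abdomct`, and what the synthetic data can and cannot say about real scans.

## Voxel model and geometry

A CT volume is a 3-D grid of integer Hounsfield units with per-axis voxel
spacing and an origin in millimetres. The grid axis convention is fixed:
axis 0 left-right, axis 1 dorsal-ventral, axis 2 cranial-caudal with the
index increasing cranial → caudal; DICOM series are re-ordered to this
convention at load regardless of file naming. Stored DICOM values are
converted to HU with each file's rescale slope/intercept and rounded
half-away-from-zero (HU are integer-quantised in practice; this rounding is
deterministic and sign-symmetric). The slice spacing is taken from the
physical inter-slice distance along the slice normal; if it disagrees by
more than 1% with the nominal `SliceThickness` tag a warning is emitted and
the positional spacing wins. Valid HU are clamped to [−1024, 4000].

## Abdominal slab and threshold convention

The abdominal volume of interest is the stack of transverse slices between
two user-supplied landmark indices — anatomically, the cranial margin of
T10 to the cranial margin of S1 (T11 from S1 in dogs with eight lumbar
vertebrae). Automatic vertebral localisation is out of scope; the CLI
records the landmark rule used. The slab is half-open `[cranial, caudal)`
so adjacent slabs tile without double counting; whether the caudal landmark
slice itself should count is a convention, not an anatomical fact, and this
is ours. Manual per-slice inclusion masks may be attached; each mask
applies only to its own slice (no inter-slice interpolation), and repeated
masks on one slice intersect.

Tissue classes are HU intervals. Published abutting ranges (−250/−25,
−25/150, 150/2000) are interpreted closed-open `[lo, hi)`, with a range
whose upper bound equals the global ceiling (2000 HU, configurable) closed
at the top. This makes fat/lean/bone exactly tile the all-tissue interval
−250/2000, so the per-class voxel counts partition the all-tissue count —
an invariant the test suite asserts exactly. The 2000 HU ceiling reflects
the observation that raising the upper bound beyond 2000 HU does not
increase segmented volume in dogs. Volumes are
`voxel_count × voxel_volume(mm³) × 10⁻⁶` litres, exactly.

The threshold catalogue keeps every trialled and literature range,
including ranges that were excluded from further analysis (upper bound
1000 HU missing cortical bone; −105/150 admitting fat into lean;
3000 HU upper bounds duplicating 2000 HU results). Excluded entries always
carry their exclusion reason as an annotation and produce annotation-only
rows in validation reports, so the published comparison is reproducible
with its caveats attached. Partial literature sets (the prior canine
fat-only range −135/−105) skip the percentage-sum invariant and are flagged
non-tiling.

## Calibration and agreement statistics

* **Calibration**: OLS of DXA mass (kg) on CT volume (L), per component.
  CIs use the t distribution with n−2 df; r² is the squared Pearson
  correlation. Fitting is delegated to `statsmodels`; the tests verify the
  results against hand-written normal equations to 1e−10.
* **Lin's concordance** uses n-divisor (population) moments — the original
  Lin (1989) convention. The published analysis ran an SPSS syntax script
  whose internal divisor convention is unstated; at n = 22 the difference
  is small but nonzero, and this choice is therefore documented rather
  than assumed equivalent. The 95% CI is built on the atanh scale with
  Lin's large-sample standard error (2000 erratum) and back-transformed.
  Values within 1e−12 of ±1 snap to exactly ±1 with a degenerate CI, so
  noiseless pipelines earn the "perfect" label. When the Pearson
  correlation is exactly zero the large-sample SE diverges and the CI is
  reported as (−1, 1).
* **Bland-Altman** on percentage differences:
  `d = 100·(measured − reference)/D` with `D` the pairwise mean by default
  (the reference value is selectable, since the published denominator is
  unstated); bias is the mean of `d`, SD uses n−1, and LOA are
  `bias ± 1.96·SD` with the fixed 1.96 multiplier (not a t quantile).
* **Categories**: correlation labels (perfect = 1.00, very strong > 0.90,
  strong 0.70–0.90, moderate 0.50–0.70, poor 0.30–0.50, negligible below)
  applied to |r|; agreement labels (near perfect > 0.99, substantial
  0.95–0.99, moderate 0.90–0.95, poor < 0.90) applied to the *lower* 95%
  confidence limit of r_c. Boundary values go to the higher category,
  consistent with the ">" notation of the top class.
* **Validation report**: for each (component, range) row, fit the
  calibration, predict in-sample (fit and evaluate on the same cohort — a
  leave-one-out mode exists but is off by default), then concordance and
  Bland-Altman between predictions and DXA values. In-sample prediction
  implies the analytic identity `r_c = 2r²/(1+r²)`, which the tests verify
  on simulated data. Reliability (intra-/inter-observer repeat
  segmentation) reuses the same two statistics on paired repeat volumes.

## Synthetic phantoms

Phantoms are nested axis-aligned boxes on an air (−1000 HU) background:
an outer fat shell, a lean core, and a bone rod, on a default 64×64×40 grid
at 1.0×1.0×0.75 mm spacing. Voxel membership is index arithmetic, so
ground-truth counts and litres are exact and independent of the HU draw.
Per-compartment HU are normal draws — fat (−100, 15), lean (60, 12), bone
(700, 100) — rounded to integers; each mean is required to sit at least
five SDs inside its recommended threshold interval, bounding the per-voxel
misclassification probability below 1e−6, so seeded default-noise phantoms
segment to their exact ground truth with overwhelming probability. What
phantoms do *not* emulate: partial-volume voxels at tissue interfaces,
beam hardening, reconstruction-kernel texture, or anatomy; passing phantom
tests therefore demonstrates the counting/volumetry machinery, not
robustness to scanner physics.

## Synthetic cohorts

A simulated dog is a total abdominal volume, a (fat, lean, bone) share
vector, and four DXA masses. Defaults encode the published study
conditions:

* **Total volume** is log-uniform over the interval obtained by inverting
  the total-mass line `y = 3.46x + 0.02` at the cohort weight range
  5.1–60 kg, i.e. ≈1.47–17.3 L. Log-uniform matches a wide, right-skewed
  size interval.
* **Tissue shares** are Dirichlet with mean (0.37, 0.58, 0.05) and
  concentration 60. No published distribution of abdominal tissue shares
  across dogs exists; these are plausible placeholders chosen to give
  realistic DXA panels (≈23% body fat, ≈75% lean, ≈3–4% BMC at the
  23.4 kg cohort mean) and should be treated as such.
* **DXA masses** are generated independently per component from that
  component's published line plus homoscedastic Gaussian noise — mirroring
  that the published rows are separate regressions, so fat + lean + BMC
  need not close to the total. The noise SD per component is derived
  analytically from the variance decomposition
  `σ = |slope|·sd(V_c)·sqrt((1−r²)/r²)`, using closed-form log-uniform and
  Dirichlet moments for `sd(V_c)`, so the population r² matches the
  published value (0.985 total, 0.981 fat, 0.972 lean, 0.900 bone).
* **Positivity** is enforced by redrawing the noise (up to 100 attempts)
  rather than clipping, keeping the noise distribution interpretable.

Known limitation: for the bone component the line value of the smallest
dogs (~0.27 kg) is comparable to the derived noise SD (~0.27 kg), so the
positivity redraw truncates the noise there and inflates the realised bone
r² to ≈0.908 at large n, slightly above its 0.900 target; total, fat and
lean realise their targets within 0.005. An optional "mass-closed" rescaling
of components to the total is deliberately not applied by default.

With these defaults, OLS refitting recovers the generating slopes without
bias (mean fitted total slope over 200 replicates of n = 22 within
Monte-Carlo error of 3.46 kg/L) and the mean in-sample concordance lands at
`2r²/(1+r²) ≈ 0.992`, next to the published 0.993.

## Problem sizes and numerical choices

The test suite runs on small grids (6×6×5 to 8×8×6 random volumes, the
64×64×40 default phantom) and 200 replicate cohorts of n = 22 — sizes at
which the brute-force per-voxel oracle and the Monte-Carlo checks complete
in seconds while the quantities of interest (voxel counts, slope/r²/r_c
means) are already stable. All randomness flows through
`numpy.random.default_rng` with explicit seeds; generation order is fixed,
so outputs are reproducible across runs and platforms. Percentages are
undefined (and raise) when the all-tissue volume is zero; Bland-Altman
raises on a zero pairwise mean, naming the offending pair.

## Out of scope

Visceral/subcutaneous compartmentalisation, automatic vertebral landmark
detection, contrast-phase or kernel emulation, resampling/registration,
histogram-based threshold derivation, and Deming or Passing-Bablok
regression.
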