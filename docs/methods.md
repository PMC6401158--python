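# Methods

This note records the models, conventions and design choices behind
`xerosubvol`, in the order the pipeline applies them.

## Coordinate frame and voxel classification

One fixed frame for the whole package: axis 0 = x (patient right -> left),
axis 1 = y (anterior -> posterior), axis 2 = z (inferior -> superior).
Voxels are classified by their center point; all masks and the dose grid of
one patient must share dims, spacing and origin. Subvolume volumes are
reported as voxel count x voxel volume, exactly.

## Subvolume derivation

* **Laterality.** Paired organs on the primary-tumor side are ipsilateral,
  the others contralateral; the mandible is unpaired.
* **Expansion.** PG and SMG contours are expanded by a 3 mm Euclidean
  margin that includes the original volume ("contour + 3 mm shell"),
  computed with a distance transform honoring anisotropic spacing. The
  expansion is monotone in the margin by construction.
* **Superior-inferior thirds.** The z-extent of the expanded gland's own
  voxel centers is cut at 1/3 and 2/3. A center exactly on a cut plane is
  assigned to the more inferior section.
* **Radial sectors.** Three 120-degree wedges in the axial plane about the
  whole-gland centroid, with a single angular frame shared by all three SI
  sections. Per-slice centroids were rejected because they make sectors
  non-convex for tilted glands; the global frame is the simpler convention
  and is stated here because the choice is genuinely open. The medial wedge
  is centered on the medial unit vector (-x for a left gland, +x for a
  right gland); the anterior wedge center is that vector rotated 120
  degrees toward anterior; boundaries sit at +/-60 degrees and a voxel on a
  boundary joins the next sector in the cyclic order medial -> anterior ->
  posterior. The angle is computed from dot and cross products so mirror-
  image glands yield bit-identical sectors.
* **Oral-cavity surrogate.** All voxels at or below the superior bound of
  the lower 2/3 of the parotid union, at or above the inferior-most SMG
  voxel, with y inside the mandible's anterior/posterior extent and x
  inside the lateral extent of the two expanded parotids, minus every organ
  voxel. The lateral x-bound is an added closure: the anatomical definition
  bounds the region on four sides only, which leaves it laterally unbounded
  on a finite grid. The region is split at the plane halfway between the
  two parotid centroids' x-coordinates (robust to off-center patients; a
  voxel centered exactly on the plane joins the left half), ipsilateral
  half on the tumor side.

The 9 sectors of each parotid tile the expanded gland voxel-for-voxel, and
the whole derivation is deterministic; both properties are asserted, not
assumed.

## DVH features

The DVH is the exact descending voxel-dose sample — no dose binning, so no
bin-width parameter. Dx (dose covering the hottest x% of the subvolume) is
linear interpolation of that sample at the 0-based rank position
`x/100 * (N-1)`. At least four Dx conventions are in circulation and they
disagree on small subvolumes; this one is fixed, logged, and written into
report manifests. Features are D10..D90 in 10% steps for each of the 22
subvolumes (198 columns, subvolume name lexical then x ascending), kept in
cGy; standardization happens only inside model training folds.

Clinical covariates add 16 columns: age > 65, male, race dummies (white
reference), chemotherapy, five tumor-site dummies ("others" reference), and
the six subvolume-group volumes in cc — 214 predictors, the only encoding
consistent with the feature counts above.

## Outcome labels

Injury: any CTCAE grade >= 2 at <= 183 days post-RT. Recovery (defined for
injured patients only; the recovery model population is the injured
subset): the last assessment at <= 548 days has grade < 2. A patient with
no assessment inside the 18-month window is excluded with a signal, not an
error.

## Max-T permutation test

Per feature, the observed statistic is the two-sample mean difference over
its pooled standard error; one-sided (injury: higher dose in injured;
recovery: higher dose in non-recovered; both directions exposed). For each
of B label permutations the maximum statistic across features is recorded;
adjusted p = (1 + #{M_b >= T_j}) / (1 + B). The +1 corrections keep p > 0
and make the test valid at finite B. Constant features get T = 0 with a
warning. Single-step max-T control of the family-wise error rate is checked
by simulation in the test suite.

## Ridge logistic regression and nested CV

The fit minimizes the penalized negative log-likelihood
`-l(b) + (lambda/2)||b||^2` with an unpenalized intercept, by damped Newton
iteration on internally standardized predictors (binary dummies included),
stopping at gradient norm < 1e-6. scikit-learn's LBFGS solution of the same
objective serves as an independent cross-check in the tests.

Nested CV: stratified 5-fold outer splits; per outer training set, lambda
is chosen by stratified 5-fold inner CV maximizing validation AUC (default
grid: 30 log-spaced values in [1e-3, 1e3]; ties go to the stronger
penalty); the model is refit on the outer training set and scored on the
held-out fold. Outer-test scores are pooled into one AUC per iteration;
sensitivity and specificity are read off at the Youden-optimal threshold on
the pooled scores (the threshold rule is otherwise unspecified in this
family of analyses, so the standard choice is used and stated). Splits are
resampled over 50 iterations by default; means and standard deviations are
reported over iterations, with the fold-level SD also available since the
two conventions differ by an order of magnitude. Standardization, lambda
selection and fitting see training rows only — asserted by instrumentation
in the tests. The final importance vector comes from a refit on all rows at
the modal selected lambda: dose coefficients rescaled by
`100 / max_k |beta_k|` (dose features only, so the spatial map is not
compressed by large clinical coefficients), giving a [-100, 100] map whose
extreme is exactly +/-100 whenever any dose coefficient is nonzero.

## Synthetic cohort generator

The generator emulates the data this analysis consumes, with a known
mechanism:

* **Anatomy.** Parotids: ellipsoids with 15x20x25 mm semi-axes centered
  (+/-52, 12, 10) mm; SMGs: 12x15x10 mm at (+/-26, -12, -20); mandible: a
  parabolic arc band anterior-medial to both. Per-patient jitter is uniform
  +/-15% on semi-axes and +/-4 mm on centers. Jittered ellipsoids can graze
  one another; disjointness is restored by subtraction with priority
  PG > SMG > mandible. The parotids' inferior extent overlaps the SMGs'
  superior extent so the OC band never collapses. Default grid: 68x44x40
  voxels at 2.5 mm — a typical clinical dose-grid resolution.
* **Dose.** A Gaussian kernel (sigma 35 mm) peaking at the prescription
  (7000 cGy) near the ipsilateral parotid's medial-inferior aspect, times a
  smooth multiplicative modulation field (relative amplitude 0.5,
  correlation length 12 mm) emulating per-plan fluence variability, capped
  at the prescription (plan normalization), plus truncated Gaussian voxel
  noise (sd 150 cGy, clipped at +/-3 sd and at zero dose). Without the
  modulation field, neighboring subvolume features are correlated at
  0.93-0.96 and no method could attribute an effect to a specific
  subvolume; with it, correlations drop to ~0.7-0.8 and feature
  coefficients of variation (0.23-0.39) approach the spread seen in real
  cohorts, where e.g. a contralateral superior-parotid D50 can range over
  two orders of magnitude between patients.
* **Outcomes.** Injury ~ Bernoulli(logistic(intercept + sum of weights x
  features/1000 cGy)); among the injured, recovery likewise. Dose features
  enter the logit in units of 1000 cGy so unit weights are interpretable.
  Defaults plant the injury effect on `cPG_mid_ant_D30` and
  `cPG_mid_post_D30` (weight +10 each) and the recovery effect on
  `cPG_sup_ant_D50` / `cPG_sup_post_D50` (weight -10 each: dose impairs
  recovery); intercepts (-6.08, +6.25) are calibrated so a default cohort
  lands near 68% injury prevalence and 77% recovery among the injured —
  the proportions of the clinical cohorts this design mirrors. Effect
  sizes are chosen for testability: real effect sizes for this mechanism
  are not established, so the defaults aim for a regime where detection
  and localization are demanding but achievable at a few hundred patients.
* **Timelines.** Visits at days 42, 90, 180, 270, 365, 450, 548 post-RT
  (6-week follow-up, then quarterly). Injured patients first show grade
  >= 2 at the on-treatment, 3-month or 6-month visit (probabilities
  0.85/0.10/0.05); recovered patients follow a monotone-recovery template
  dropping below grade 2 strictly after onset and no later than the
  18-month visit, which is always present. Deriving labels from the
  emitted timeline reproduces the latent labels exactly (a round-trip
  property asserted for every synthetic patient). The onset mix makes the
  on-treatment grade >= 2 prevalence ~58% and the 18-month prevalence
  ~16% of the cohort, matching the longitudinal pattern of the clinical
  population the generator mirrors.
* **Clinical covariates.** Drawn independently of dose (except through
  laterality) from category mixes matching a 258-patient head-and-neck
  cohort; confounding hooks are deliberately out of scope.

What the generator does *not* emulate: realistic gland shapes (meshes),
treatment-plan optimization, CT appearance, dose-covariate confounding, or
inter-visit variability beyond the monotone template. Passing tests
therefore demonstrate correctness of the geometry, feature extraction and
statistics under a controlled mechanism — not clinical validity of any
particular dose threshold.

## Problem sizes in the checks

The test suite validates family-wise error control with 200 global-null
simulations (n=60, 198 factor-correlated features, 500 permutations) and
signal recovery on 20 replicate cohorts of 400 patients with a reduced
penalty grid (8 log-spaced values) and one resampling iteration per
replicate; the acceptance script analyses one 258-patient cohort with 1000
permutations and 10 resampling iterations. These sizes keep each check in
minutes while leaving the statistical guarantees testable; all defaults in
the library itself remain at full strength (1000 permutations, 50
iterations, 30-value grid).

## Known limitations

* Ellipsoid anatomy cannot probe sensitivity of sector definitions to
  realistic gland shapes (tilted, crescent-shaped parotids); the shared
  angular frame decision matters most there.
* The OC surrogate inherits the geometric definition's coarseness; its
  volume depends on mandible extent conventions.
* The modulation field makes regional doses partly independent, which is
  what real modulated plans produce, but its parameters are stylized; the
  generator is a testbed, not a planning simulator.
* Metric SDs over resampling iterations are small by construction (the
  same rows are re-scored); fold-level SDs are an order of magnitude
  larger and are reported alongside.
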