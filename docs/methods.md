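# Methods

## Change matrices and sign conventions

Both analyses operate on subject × feature matrices of longitudinal change.
For the functional modality a scan is a T × 53 matrix of network time
courses; static FNC is the Pearson correlation matrix of the cleaned
columns, vectorized as the row-major upper triangle (1378 cells for 53
networks). Change is **baseline minus follow-up** throughout (F0 − F2 for
FNC cells, G0 − G2 for GMV voxels). A consequence used everywhere
downstream: if a pattern's expression grows over the two years, its loading
mean is negative, so a *negative* one-sample T on a loading column is
labelled "increase-with-age". The constant
`deltafuse.connectivity.DELTA_CONVENTION` is the single source of truth and
`inference.label_direction` asserts against it.

## Time-course postprocessing

Four ordered steps, mirroring common FNC practice for pediatric data:

1. polynomial detrending up to cubic (least squares on a Vandermonde basis);
2. despiking: samples with robust z (median/MAD) above 3 are replaced by
   cubic-spline interpolation of the surrounding good samples (linear
   fallback when fewer than 4 good points remain);
3. regression of the 6 rigid-body motion parameters and their first
   (backward) differences; the polynomial basis is kept in this design so
   the motion removal stays an exact projection after step 1;
4. zero-phase (forward–backward) 5th-order Butterworth bandpass,
   0.01–0.15 Hz. At TR 0.8 s this attenuates a 0.2 Hz signal by ≈ 31 dB
   (two-pass). Inputs shorter than the filter's stable padding length are
   rejected with the minimum length in the error message.

Quality control compares per-scan brain masks (voxels above 90% of the
whole-volume mean of the first frame) with a group mask (voxels present in
more than 90% of scans): spatial correlations over the top 10 axial slices,
bottom 10 slices and the whole volume must exceed 0.75 / 0.55 / 0.8. Two
binary slabs that are bitwise identical are assigned r = 1 even when
constant; a constant-but-different slab gives r = 0.

## Asymmetric arm: infomax ICA

`X ≈ A·S` with subjects as mixture channels. The matrix is row-centred and
reduced to k whitened rows by SVD; natural-gradient infomax with the
logistic nonlinearity estimates the square unmixing W on the whitened data;
loadings return through the de-whitening transform. Hyperparameters
(configurable): learning rate 0.01, annealed ×0.9 whenever successive
updates turn by more than 60°; convergence when the largest weight change
falls below 1e−6; iteration cap 2048 (the natural-gradient fixed point on
these problem sizes is typically reached between 1000 and 2000 iterations;
a non-converged run returns `converged=False` with a warning rather than
raising). Initialization is a seeded random orthogonal matrix, so a seed
fully determines the run. One run per seed; no multi-run clustering.

Sources are canonicalized by `fix_signs_and_order`: rows scaled to unit
norm (loadings absorb the scale), sign flipped so the largest-magnitude
element of the (joint) source row is positive, components ordered by
explained variance in the FNC modality. The operation leaves `A·S`
unchanged and is idempotent up to round-off.

## Symmetric arm: mCCA + joint ICA

Pipeline per fusion call:

1. **normalization** — z-score each feature column, then divide each
   modality by its root-mean-square so neither dominates the joint step;
2. **feature PCA** — economy SVD per modality, keep k score columns;
3. **mCCA** — stage-wise maximization of the SSQCOR objective (sum of
   squared pairwise correlations between same-index variates), each stage a
   fixed-point/power iteration in the whitened bases with deflation
   enforcing within-set orthogonality (tolerance 1e−13, up to 5000
   iterations per stage). With exactly two sets the iteration is the power
   method on the cross-correlation operator and reproduces classical CCA to
   machine precision — the closed-form SVD oracle in the tests;
4. **joint ICA** — least-squares associated maps `C_k = D_k⁺·X_k` are
   concatenated `[C_F | C_G]` and whitened **without row-centring** (the
   sparse source rows are already near zero-mean, and skipping the centring
   keeps the noiseless reconstruction `X_k = A_k·S_k + column means` exact),
   then unmixed by the same infomax core. Loadings are `A_k = D_k·W⁻¹`.

Estimated sources are reported **on the raw feature scale** (the per-column
z-scoring is undone, feature means stored in the result metadata): the maps
are then in the units of the input change matrices and directly comparable
to planted or anatomical patterns. Component count defaults to a fixed
k (the analysis scripts use 5); the elbow criterion
(`select_components_elbow`) is available as a diagnostic — note that the
literal max-distance-to-chord knee of a cliff-shaped spectrum lands on the
first noise eigenvalue, so on a planted rank-5 cohort it suggests 6; the
override argument exists precisely because model order is a judgement call.

## Coupling analyses and inference

* **Voxel-wise coupling**: Pearson r of one loading column against every
  ΔGMV voxel, p from the t distribution with n − 2 dof, BH-FDR across all
  in-mask voxels with defined correlations (constant voxels are excluded
  from the family and logged). One FDR family per map, not across
  components.
* **Sex contrasts**: per-sex coupling (voxel maps in the asymmetric arm, the
  k × k grid of GMV-by-FNC loading correlations in the symmetric arm),
  difference female − male, per-element Fisher-z two-independent-sample
  test, BH-FDR at q < 0.001 by default. Whether the 0.001 threshold applies
  to adjusted q (default) or raw p is switchable (`on="p"`).
* **Quartile contrasts**: lower group = scores ≤ first quartile, upper
  group = scores ≥ third quartile (empirical quantiles with linear
  interpolation; ties keep all tied subjects; both groups are therefore at
  least a quarter of the scored subjects and disjoint whenever the
  quartiles differ, which is enforced). Per-group FDR-corrected maps plus
  an upper − lower difference with its own Fisher-z test.
* **Loading t-tests**: one-sample tests per modality × component are
  corrected jointly across the 2k family; the sex two-sample test is the
  Welch (unequal-variance) flavor with sorted group levels, so "F" − "M"
  is the reported direction.
* **Site residualization** uses deviation-coded site indicators: per-site
  mean differences are removed exactly while the grand mean is preserved,
  so one-sample tests keep their target effect and the with/without-site
  robustness comparison is meaningful. Sites with fewer than two subjects
  are dropped from the design with a warning.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
every quantity a deterministic function of one integer seed:

* **Functional sources**: symmetric zero-diagonal 53×53 patterns whose
  nonzero entries fill 2–3 domain-by-domain blocks (7-domain partition:
  subcortical 5, auditory 2, sensorimotor 9, visual 9, cognitive control
  17, default mode 7, cerebellar 4 — configurable), block amplitude
  Uniform(0.5, 1) with random sign. Components draw *disjoint* block
  supports, making planted sources exactly orthogonal — a deliberately
  identifiable, strongly supergaussian structure.
* **Structural sources**: sums of 1–3 isotropic Gaussian blobs (σ 1.5–2.5
  voxels) inside the mask, peak-normalized to 1, on a 12×14×12 grid (2016
  voxels, full mask) by default.
* **Loadings**: per component, bivariate normal with unit variances and
  correlation `rho + rho_sex` for females, `rho` for males; defaults
  n = 500 subjects, k = 5, rho = 0.5, rho_sex = 0.
* **Data**: `A·S` plus i.i.d. Gaussian noise, SD 0.2 — a signal-to-noise
  regime in which block amplitudes (0.5–1) remain clearly separable but
  recovery is not trivial.
* **Δ-scores**: linear in chosen loading columns plus Gaussian noise
  (SD 1); demographics (ages ≈ 119 ± 8 months at baseline, +24 at
  follow-up; 4 sites; balanced sex) are plausible-looking covariates, not
  fits to any real table.

What the generator does **not** emulate: spatial autocorrelation of real
GMV noise, site/scanner effects on the data matrices themselves, heavy-tailed
motion artifacts, non-Gaussian loading distributions, or any real composite
score construction. Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under their own model
assumptions — not performance on real cohort data.

## Numerical and degenerate-input choices

* Whitening tolerances: projected covariance must equal identity to 1e−8;
  rank checks use a 1e−10 relative singular-value cutoff and reject k above
  the numerical rank.
* Zero-variance time courses produce NaN FNC entries flagged in
  `FNCMatrix.undefined`; constant voxels are excluded from FDR families.
* Degenerate elbow spectra (flat or linear) return 1 with a warning.
* Fisher z clips correlations to ±(1 − 1e−12) before `arctanh`.
* Subjects missing either timepoint are excluded from Δ-matrices and
  logged; zero overlap raises.
* Serialization: matrices in `.npz` containers, tables as TSV; scores and
  loadings are stored in binary form (the npz) so reruns round-trip
  bit-exactly, with TSVs written alongside for human inspection.

## Known limitations

* The mCCA variant is SSQCOR with stage-wise deflation; other multiset
  objectives (MAXVAR, GENVAR) are not implemented, and equivalence is only
  guaranteed against classical CCA in the two-set limit.
* Joint ICA assumes a shared square mixing across modalities after the
  mCCA alignment; modality-unique components are not modelled.
* No ICASSO-style multi-run stability analysis; a single seeded run per
  fusion.
* Linear models throughout; no mixed-effects growth modelling, no
  covariates beyond site.
* Spatial inference is voxel-wise FDR only — no cluster-extent or
  permutation-based spatial statistics.
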