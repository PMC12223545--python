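# deltafuse

Multimodal fusion of longitudinal brain-change matrices: linking functional
network connectivity (FNC) change to gray matter volume (GMV) change in the
developing brain.

## The problem

Longitudinal neuroimaging studies of adolescence collect, per subject, a
resting-state scan (summarized as a 53-network FNC correlation matrix) and a
structural scan (summarized as a voxel-wise GMV map) at baseline and again
two years later. Subtracting the two visits gives per-subject **change
matrices**:

* `ΔFNC`: subjects × 1378 connectivity cells (upper triangle of the 53×53
  matrix), with Δ = baseline − follow-up (F0 − F2),
* `ΔGMV`: subjects × in-mask voxels (G0 − G2).

The question is how functional and structural change *covary* across
subjects. `deltafuse` implements two complementary answers:

**Asymmetric arm** — infomax ICA decomposes the functional change matrix

    X = A · S

into k functional change patterns (rows of `S`) with subject loadings `A`;
each loading column is then correlated voxel-by-voxel against the raw ΔGMV
matrix, giving an FDR-corrected structure–function coupling map per
component.

**Symmetric arm** — mCCA + joint ICA fuses both modalities at once,

    X_k = A_k · S_k ,   k ∈ {FNC, GMV}

by (1) per-modality feature PCA, (2) multiset canonical correlation
analysis (SSQCOR objective) aligning the two score matrices into maximally
correlated canonical variates `D_k`, and (3) a single infomax ICA on the
horizontally concatenated associated maps, so the two modalities share a
mixing structure with `A_k = D_k·W⁻¹`. Cross-modal coupling is then simply
the correlation between the FNC and GMV loading columns.

On top of either arm the package provides loading-level one- and two-sample
t-tests with Benjamini–Hochberg FDR (under the F0 − F2 convention a
**negative** T means the pattern's expression *increases* with age), sex
contrasts of coupling (female − male, Fisher-z tested), score-quartile
contrasts against Δ-composite psychopathology/cognition scores, and site
residualization.

Real cohort data of this kind are access-controlled, so the package ships a
first-class synthetic cohort generator (`deltafuse.simulate`) that plants
block-modular connectivity sources, Gaussian-blob voxel sources, linked
loadings with known cross-modal correlation `rho` (optionally sex-offset by
`rho_sex`), and linear loading→score effects — giving every analysis a
ground truth to recover.

## Worked example

```python
import deltafuse as df

cohort = df.simulate_cohort(seed=20)           # 500 subjects, k=5, rho=0.5
result = df.mcca_jica(cohort.delta_fnc, cohort.delta_gmv, k=5, seed=40)
print(result.canonical_correlations.round(3))
```

Running the bundled drivers end to end (`python analysis/01_simulate_cohort.py`
… `05_gender_and_quartile_contrasts.py`) prints, among other things:

```
canonical correlations: [0.579 0.556 0.516 0.474 0.426]
FNC source recovery |r|: median 0.990, min 0.964
GMV source recovery |r|: median 0.987, min 0.980
cross-modal loading correlations (planted rho = 0.5): [0.537 0.48  0.529 0.486 0.533]
site robustness: max one-sample-T shift after site residualization = 0.0000
planted sex offset 0.2 on component 3 → estimated pair (3,3): Δr = +0.167, q = 4.45e-06, flagged=True
flagged pairs at q<0.001: 1 of 25
```

Reading: the canonical correlations hover around the planted cross-modal
coupling of 0.5; both modalities' planted change patterns are recovered
almost perfectly (matched |r| ≈ 0.99); the estimated loading–loading
correlations scatter around the planted 0.5; and the planted female-specific
coupling offset on one component is the only pair flagged by the
female-minus-male contrast at q < 0.001.

The CLI mirrors the drivers:

```bash
deltafuse simulate  --out ws/cohort --n-subjects 500 --seed 1
deltafuse fuse-sym  --cohort ws/cohort --out ws/sym --seed 1
deltafuse contrasts --cohort ws/cohort --fusion ws/sym --out ws/contrasts
```

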