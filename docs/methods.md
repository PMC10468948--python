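# Methods

## Model

The package links three observables of liver fat. Fat and water MR signals
are proportional to mass over mass density times proton density, so the
fat-to-water signal ratio is R_s = f·R_M with
f = (ρ_F·D_W)/(ρ_W·D_F) = 0.7035 for ρ_F = 70.35 mmol/l,
ρ_W = 111.11 mmol/l, D_F = 0.9 g/ml, D_W = 1 g/ml. PDFF is the signal
fraction R_s/(1+R_s); the tissue mass fat fraction is
TMFF = R_M·L_W/(R_M·L_W + 1), where L_W is the free-water fraction of
tissue (0.711 in healthy liver). Both maps are strictly monotone with
closed-form inverses, so PDFF ↔ TMFF conversion is exact given L_W. At
L_W = 0.711 the composite map is within one percentage point of the
identity for PDFF ≤ 0.4, which is why the two endpoints are
interchangeable in healthy liver and diverge when tissue water rises.

Tissue water is estimated from T1. Under fast exchange between free and
bound water pools, 1/T1_obs = W_F/T1_free + (1−W_F)/T1_bound, a linear
solve for the free water fraction W_F. A three-compartment bookkeeping
model (free water L_W, bound water L_B, non-water L_N, summing to 1) then
maps W_F to the tissue free-water fraction of non-healthy liver:

    L_W† = W_F†·(L_B + L_W − k·L_W) / (1 − k·W_F†)

where k ∈ [0,1] is the proportion of a free-water change drawn from the
non-water compartment (k = 0: entirely from bound water; k = 1: entirely
from non-water tissue). The formula follows from requiring the compartments
to stay a partition while free water changes by Δ, bound water by −(1−k)Δ
and non-water by −kΔ; a symbolic re-derivation is part of the test suite.
At the healthy W_F it returns L_W identically for every k, so the
correction is inert exactly when tissue water is healthy. Because k is not
identifiable from these data, the corrected TMFF_MR is reported for the
sweep k ∈ {0, 0.2, 0.4, 0.6, 0.8, 1}.

## Parameters and defaults

| parameter | default | basis |
|---|---|---|
| ρ_F, ρ_W | 70.35, 111.11 mmol/l | literature proton densities |
| D_F, D_W | 0.9, 1.0 g/ml | literature mass densities |
| L_W (healthy) | 0.711 | literature healthy tissue water fraction |
| T1_free, T1_bound | 4000, 250 ms | **placeholders** — order-of-magnitude values only; no authoritative source is bundled. Set explicitly for quantitative T1 work. |
| L_B (healthy) | 0.08 | **placeholder**, same caveat |
| area→volume factor | 2/3 | sphere-in-cube (π/6) over circle-in-square (π/4) for spherical vacuoles; the alternative literal reading of the circle/square-to-sphere/cube expressions gives 4/3 and is selectable. 2/3 is the default because volume fractions below area fractions are the physically expected direction for this conversion. |
| white threshold | 0.85 | fixed (non-adaptive) on [0,1] grayscale |
| background threshold / min fragment | 0.15 / 200 px | outline detection; speckle suppression |
| T2 cap | 2000 ms | degenerate (non-decaying) series safety; arbitrary |
| k sweep | 0, 0.2, …, 1 | k is unidentifiable; full sweep reported |

Placeholder fields are listed in `ModelConstants.PLACEHOLDER_FIELDS`. All
internal fractions live on [0,1]; percent appears only in reports.

## Synthetic cohort

The generator emulates a 110-patient biopsy cohort: fibrosis stages F0–F4
with proportions 24/30/24/21/12, steatosis grades S0–S3 with 27/44/19/20,
inflammation none-mild/moderate/severe with 66/24/20, drawn independently.
The pathologist's visual percentage is uniform within the CRN band of the
assigned grade (S0 < 5%, S1 5–33%, S2 >33–66%, S3 >66–90%) and scaled by
0.25 to a vacuole area fraction, the regression slope observed between
morphometric and visual reads. The mass ratio R_M then follows from the
morphometry chain (area → ×2/3 → volume → density ratio → mass fraction)
inverted at the patient's own tissue water, so every forward measurement
is mutually consistent by construction.

Fibrosis raises free water by stage increments (0, 0, 0, 0.03, 0.06) plus
N(0, 0.01) individual variation, flat through F0–F2 and rising at F3/F4 —
the shape of the observed stage-wise T1 trend, which is near-constant over
F0–F2. The bound pool is held fixed, so the generator's world is exactly
the k = 1 scenario of the correction model; consequently the k = 1
correction is exact in the noise-free limit and the k sweep moves the
severe-group regression slope monotonically toward unity. Absolute T1
values depend on the placeholder pool T1s and are not meaningful; only the
monotone trend is.

Raw data per patient: fat/water peak areas at TE = 30/40/60/80 ms with
mono-exponential decay (T2_water ~ N(46, 4) ms, T2_fat ~ N(68, 6) ms,
plausible 1.5 T liver values) and additive Gaussian area noise (default
sd 2.0 against a shortest-TE water area of 100, i.e. water SNR 50); a
10-point magnitude inversion-recovery series (TI 100–5000 ms) with ideal
inversion (b = 2, configurable) and Rician noise (default sd 25 against
amplitude 1000, SNR 40); and a rendered grayscale biopsy — elliptical
fragments on a dark background with non-overlapping bright circular
vacuoles (radii log-uniform in [2, 12] px) planted until the white-pixel
share is within 0.5 percentage points of the target.

What the generator does **not** emulate: spectral lineshape/J-coupling
effects (areas are emitted post-quantification), B1/B0 inhomogeneity,
imperfect fat suppression in the IR measurement, H&E colour and staining
artifacts, and — importantly — non-fat white structures (sinusoids, tears,
unstained swollen vacuoles) that inflate real-slide DIAFF. Passing tests
therefore demonstrate internal consistency of the model chain and
estimator correctness at realistic SNR, not robustness to those real-data
confounds.

## Numerical choices

* **T2 fit**: nonlinear least squares on the linear scale (Gaussian area
  noise is non-Gaussian after log transform), initialised from the
  log-linear regression; series that fail to decay are fitted with T2
  capped at 2000 ms under a warning. Non-positive areas are rejected; in
  the pipeline, fat series at the noise floor fall back to the clipped
  series mean as a TE=0 estimate (no T2 correction is meaningful there).
* **IR fit**: magnitude data lose polarity, so the signed model is fitted
  for every plausible polarity split (candidate nulls adjacent to the
  magnitude minimum, plus the no-flip split) and the minimum-residual
  assignment wins; deterministic for fixed input. Inversion efficiency b
  is free in [1, 2] by default.
* **Precision floor**: with the fixed 4-echo design (TE ≥ 30 ms) and
  per-peak SNR 50 referenced to the shortest-TE area, the Cramér–Rao bound
  on the TE=0 amplitude gives a median relative PDFF error around 2.5%,
  and the estimator operates near that bound (~2.3% measured). Recovery
  requirements are therefore stated as: T2 and T1 within 5% relative
  (measured ~3.7% and ~1.7% medians), PDFF within 2 points on the percent
  scale (measured ~0.3 pp) — the percent scale being PDFF's reporting
  unit.
* **Clipping**: W_F from noisy T1 fits may exceed [0,1] and L_W† may
  exceed 1 at high k; both are clipped with warnings rather than raised,
  since both occur legitimately under measurement noise.
* **Quartiles**: linear interpolation of order statistics (numpy default),
  documented so the 1.5/3·IQR outlier fences are exactly reproducible.
* **Group test**: Mann–Whitney U by default (box-plot-style presentation
  suggests a nonparametric test; exact for small tie-free samples, normal
  approximation with tie correction otherwise); Welch's t selectable. No
  multiple-testing correction is applied.
* **Mass conversion**: implemented as the proper two-component mass
  fraction D_F·v/(D_F·v + D_W·(1−v)) rather than bare multiplication by
  0.9; the two agree to first order in v.

## Limitations

* T1_free/T1_bound and healthy L_B are placeholders; absolute tissue-water
  percentages and stage-wise T1 values are illustrative only. The
  correction's *structure* (healthy-point invariance, k-monotonicity) does
  not depend on them.
* k is unidentifiable from these measurements; results are reported as a
  sweep, not a point estimate.
* Iron/T2* confounding, PRESS-vs-STEAM localisation effects and
  MRS-voxel-vs-biopsy-site mismatch are out of scope.
* The grading boundary convention (5% and 33% → S1, 66% → S2) is fixed as
  stated; real-world grading is ordinal and subject to reader variation
  that is not modelled.
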