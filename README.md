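# liverfat

Quantitative comparison of **MR proton density fat fraction (PDFF)** with
**histological tissue mass fat fraction (TMFF)** in fibrotic livers, with a
T1-relaxometry-based tissue-water correction.

## The problem

MR spectroscopy and chemical-shift imaging measure PDFF — the fat share of
the MR-visible proton signal — while biopsy morphometry measures TMFF, the
fat share of tissue mass. In healthy liver the two nearly coincide, but
fibrosis raises MR-visible tissue water, which dilutes the water-referenced
fat signal and makes PDFF progressively *underestimate* TMFF. This package
implements the complete analysis chain connecting the two endpoints:

* **Signal model.** The fat-to-water signal ratio is proportional to the
  fat-to-water mass ratio, R<sub>s</sub> = f·R<sub>M</sub> with
  f = (ρ<sub>F</sub> D<sub>W</sub>)/(ρ<sub>W</sub> D<sub>F</sub>) ≈ 0.70
  (ρ<sub>F</sub> = 70.35 mmol/l, ρ<sub>W</sub> = 111.11 mmol/l,
  D<sub>F</sub> = 0.9 g/ml, D<sub>W</sub> = 1 g/ml), so
  PDFF = R<sub>s</sub>/(1 + R<sub>s</sub>) and
  TMFF = R<sub>M</sub>L<sub>W</sub>/(R<sub>M</sub>L<sub>W</sub> + 1),
  where L<sub>W</sub> is the free-water tissue fraction (0.711 in healthy
  liver).
* **MRS quantification.** Lorentzian peak integration, mono-exponential T2
  fits over TE = 30/40/60/80 ms, extrapolation to TE = 0, and
  PDFF = S<sub>F</sub>/(S<sub>F</sub> + S<sub>W</sub>).
* **T1 relaxometry.** Three-parameter |a(1 − b e<sup>−TI/T1</sup>)| fits to
  magnitude inversion-recovery series with exhaustive polarity restoration.
* **Tissue-water correction.** Fast-exchange two-pool inversion
  1/T<sub>1,O</sub> = W<sub>F</sub>/T<sub>1,F</sub> + (1 −
  W<sub>F</sub>)/T<sub>1,B</sub> gives the free water fraction; a
  three-compartment bookkeeping model
  L<sub>W</sub><sup>†</sup> = W<sub>F</sub><sup>†</sup>(L<sub>B</sub> +
  L<sub>W</sub> − kL<sub>W</sub>)/(1 − kW<sub>F</sub><sup>†</sup>)
  converts it to a patient-specific tissue water fraction for each k in
  {0, 0.2, 0.4, 0.6, 0.8, 1}, yielding the corrected TMFF<sub>MR</sub>.
* **Digital image analysis.** Biopsy outline segmentation, fixed-threshold
  white-pixel steatosis counting (DIAFF), area→volume (factor 2/3) and
  volume→mass (density ratio 0.9) conversion to TMFF<sub>DIA</sub>.
* **Cohort statistics.** CRN steatosis grading, F0–F2 vs F3–F4 fibrosis
  grouping, OLS method-comparison regressions with Pearson r, box-plot
  summaries with 1.5/3·IQR outlier fences, and the k-sweep slope table.

Because no patient data are distributable, everything runs on a fully
ground-truthed **synthetic cohort** (110 patients, study-matched grade and
stage proportions, fibrosis-dependent water elevation, simulated multi-echo
MRS, inversion-recovery and biopsy-image raw data).

## Worked example

```python
import liverfat as lf

c = lf.ModelConstants()
lf.signal_ratio_factor(c)          # 0.7035  -> the "0.7" in R_s = 0.7 R_M
lf.tmff_to_pdff(0.25, 1.0, c)      # 0.1900  -> TMFF 25% reads as PDFF 19%
lf.tmff_to_pdff(0.25, 0.711, c)    # 0.2480  -> near-identity at healthy water
```

A tissue mass fat fraction of 25% is reported by the scanner as a PDFF of
only 19% when tissue water is at its maximum (L<sub>W</sub> = 1), but at
the healthy water fraction 0.711 the two endpoints nearly coincide — the
core of the fibrosis confound.

Full pipeline from the shell:

```bash
liverfat run --seed 1 --out-dir out/
```

writes the cohort ground truth, per-patient quantification results, the
k-sweep table and the model curves. With the default study conditions the
k-sweep slopes of TMFF<sub>MR</sub> vs TMFF<sub>DIA</sub> are

| k   | F0–F2 | F3–F4 |
|-----|-------|-------|
| 0.0 | 1.00  | 0.77  |
| 0.4 | 1.00  | 0.77  |
| 0.8 | 1.02  | 0.78  |
| 1.0 | 1.06  | 0.81  |

i.e. the mild-fibrosis group sits at unity throughout, while the
severe-fibrosis group starts well below 1 (PDFF underestimates fat) and
moves toward unity as more of the water change is attributed to the
non-water compartment — the qualitative signature the analysis is built to
expose.

Other entry points: `simulate-cohort`, `quantify-mrs`, `fit-t1`,
`render-biopsy`, `analyze-biopsy`, `correct-pdff`, `cohort-stats`,
`model-curves` (see `liverfat --help`).

## Layout

```
src/liverfat/
  constants.py    physical constants, config loading
  water_model.py  signal model + two-pool T1 + tissue-water correction
  mrs.py          Lorentzian areas, T2 decay fits, PDFF
  relaxometry.py  magnitude inversion-recovery T1 fitting
  dia.py          biopsy segmentation, white-pixel morphometry, conversions
  cohort.py       synthetic cohort + raw-measurement simulators
  stats.py        grading, grouping, regressions, box summaries, k sweep
  pipeline.py     orchestration, CSV outputs, run manifest
  cli.py          command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
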