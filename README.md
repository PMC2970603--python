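# slicetex

**Does MRI slice thickness change what texture analysis can see?**
`slicetex` rebuilds, as a tested Python pipeline, a slice-thickness
texture-analysis experiment for brain MRI of multiple-sclerosis (MS)
patients: thick (3 mm) slices are *simulated* by intensity-averaging three
consecutive thin (1 mm) slices, a 264-parameter texture bank is computed on
four regions of interest (normal white matter WM, normal-appearing white
matter NAWM, an irregular plaque ROI MSi, and a fixed 10×10 plaque ROI MSr),
and tissue separability is quantified two ways: the proportion of texture
parameters with a significant paired Wilcoxon signed-ranks test, and the
median accuracy of repeated linear/nonlinear discriminant classification
with Fisher-coefficient feature selection — across all four train→test
thickness designs (1→1, 1→3, 3→1, 3→3 mm).

The clinical image data behind the original experiment are not public, so
the package ships a first-class **synthetic phantom cohort** whose
statistical structure mirrors the study: subjects × anatomical levels ×
sequences (T1, contrast-enhanced T1C), stacks of correlated thin slices with
integer intensities, WM/NAWM classes that are *nearly identical* by
construction, and a plaque class with clearly different mean and
second-order statistics. Every downstream stage is therefore runnable and
testable from a seed, with no downloads.

## The method in brief

- **Thick-slice simulation.** Per pixel, `round((a+b+c)/3)` over three
  consecutive thin slices (integer-exact accumulation, half-up rounding).
- **Per-ROI normalization.** Intensities are clipped to `[μ−3σ, μ+3σ]`
  (ROI mean and population SD) and mapped linearly onto Ng = 64 grey levels;
  this makes second-order statistics exactly invariant to positive affine
  intensity transforms.
- **Texture bank (264 parameters).** 11 histogram (4 moments + 7
  nearest-rank percentiles), 4 absolute-gradient moments, 220 grey-level
  co-occurrence features (11 Haralick-type statistics × 5 distances × 4
  directions, named `S(dx,dy)Feature`), 20 run-length features (5 statistics
  × 4 directions), 4 one-level Haar sub-band energies, and 5 causal
  autoregressive parameters (θ₁…θ₄, σ). Undefined values (degenerate ROIs,
  offsets with no pixel pair) are explicit NaN markers, never silent zeros.
- **Separability screening.** Per parameter, a two-sided Wilcoxon
  signed-ranks test on subject×level-paired values (exact null enumeration
  up to n = 25, tie-corrected normal approximation beyond); the share of
  parameters with p < 0.05 is the separability measure.
- **Feature selection.** Fisher coefficient `F = D/V` with `D` the
  between-class variance of the class means and `V` the mean within-class
  variance; the top three features are used per classification task.
- **Classification.** One hundred random train/test partitions at the
  (subject, level) key level — no key ever appears on both sides, which
  enforces the cross-thickness leakage constraint — with equal-prior
  pooled-covariance LDA and a quadratic discriminant as the nonlinear rule
  (NDA); the median accuracy over repetitions is reported.

## Worked example

```python
import slicetex as st

spec = st.CohortSpec(seed=1)            # 23 subjects, 2 levels, T1 + T1C
cohort = st.generate_cohort(spec)
table = st.build_feature_table(cohort)  # 736 ROIs x 264 parameters
print(st.separability_table(table).round(1))

s = st.run_design(table, ("WM", "MSi"), "T1", "1mm", "3mm",
                  classifier="lda", seed=1)
print(f"median {s.median_accuracy:.0f}% "
      f"[{s.interval[0]:.0f}, {s.interval[1]:.0f}]")
```

prints

```
               1mm         3mm
                T1   T1C    T1   T1C
WM vs. NAWM    6.1   8.0   6.4   1.9
WM vs. MSi    80.3  80.3  81.1  79.2
WM vs. MSr    78.8  75.8  81.1  76.9
NAWM vs. MSi  79.5  80.3  80.3  79.2
NAWM vs. MSr  78.8  75.0  82.6  77.3
MSi vs. MSr   83.7  84.1  82.6  84.5

median 100% [100, 100]
```

Reading: on the phantom, white matter and plaque ROIs differ in ~80% of the
264 texture parameters regardless of slice thickness or sequence, while the
deliberately similar WM/NAWM pair stays near the 5% false-positive floor —
and a classifier trained on 1 mm slices still separates plaque from white
matter perfectly when tested on simulated 3 mm slices. That is the study's
qualitative finding: thickening slices from 1 mm to 3 mm does not destroy
the texture information that separates plaques from white matter.

The same pipeline is scriptable from the shell:

```bash
slicetex reproduce --seed 1 --out-dir study_out       # full synthetic study
slicetex generate --seed 1 --out-dir cohort_dir       # NIfTI cohort + manifest
slicetex extract --manifest cohort_dir/manifest.tsv --out features.csv
```

## Layout

```
src/slicetex/
  cohort.py        phantom cohort generator (Gaussian random field / AR
                   textures, Rician noise, ROI geometry, NIfTI I/O)
  slices.py        slice containers, three-slice averaging
  roi.py           ROI masks, mu±3sigma normalization and quantization
  features/        the 264-parameter texture bank
  stats.py         Wilcoxon signed-ranks screening, Fisher ranking
  discriminant.py  equal-prior linear/quadratic Gaussian discriminants
  experiment.py    repeated split protocol with leakage guard
  pipeline.py      study tables (separability, thickness, accuracy)
  cli.py           `slicetex` command-line interface
docs/methods.md    model, parameters, design choices, limitations
```
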