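# piezobp

Cuffless, continuous blood-pressure estimation from a wearable dual-site
piezoelectric pulse sensor — the complete computational chain, plus the
synthetic physiology and device simulation needed to develop and test it
without hardware.

## The problem and the model

A pair of piezoelectric (PZT) sensors pressed over an artery 15 mm apart
converts the mechanical pulse of blood propagation into voltage. The
pipeline turns that voltage into beat-to-beat systolic and diastolic
pressure (SBP/DBP):

1. **Transduction.** The sensor's electromechanical coupling reduces, for
   thick PZT layers, to a lumped scalar model

   `F(t) = A·∫₀ᵗ V(τ) dτ − B·V(t) + C`

   with the integral term dominant, so the blood-propagation force
   waveform is recovered by integrating the voltage (`A`, `B`, `C` are
   calibration constants; force is carried in arbitrary units).
2. **Local pulse-wave velocity.** The pulse reaches the distal sensor a
   transit time Δt after the proximal one; local PWV = spacing / Δt.
   Arterial PWV of 2–20 m/s over 15 mm means Δt of 0.75–7.5 ms, so Δt is
   resolved at the full 2000 Hz/channel ADC rate by per-beat
   cross-correlation of systolic upstrokes with sub-sample (polyphase +
   parabolic) interpolation, *before* the waveform is down-rated to
   200 Hz for wireless transmission.
3. **Features.** The pulse is resampled to 1000 Hz, band-passed
   0.5–8 Hz with a 3rd-order zero-phase Butterworth, cut into
   1500-sample windows (30% overlap) and split into foot-to-foot beats.
   Per beat: foot, systolic peak, dicrotic notch and diastolic peak;
   systolic/diastolic time spans, peak heights, relative augmentation
   index, inflection-point area ratio; plus heart rate, age, sex, BMI
   and local PWV.
4. **Regression.** Two independent gradient-boosted-tree regressors
   (XGBoost; max depth 13, 437 trees, γ = 3.265, α = 0.006, learning
   rate 0.039 — Bayesian-optimised defaults) map feature vectors to SBP
   and DBP, trained with a shuffled 4:1 split and fivefold
   cross-validation. KNN, SVR and AdaBoost are available for comparison.
5. **Grading.** Accuracy is reported as mean error ± SD, MAE, RMSE,
   Pearson r, Bland–Altman limits of agreement, and the British
   Hypertension Society letter grade (A requires ≥ 60/85/95% of absolute
   errors under 5/10/15 mmHg).
6. **Pressure adaptation.** A micro-airbag presses the sensors to the
   skin; a closed-loop controller inflates it in 35 ms pumping phases
   (≥ 3.5 s apart, at most 5 phases, capping at 12 kPa ≈ 90 mmHg) when
   signal quality degrades, and asks the user to relocate the band once
   the phase budget is spent. The one-way valve's retention is an
   exponential leak calibrated to keep 30% of pressure after one hour.

The `simkit` module generates all of this synthetically with known
ground truth: three-component-wave pulse morphology with a dicrotic
notch, the characteristic piezo signature (strong positive spike,
negative valley, two weak peaks), per-sex cohort BP distributions, and
hand-grip/cold-pressor (HGCP) BP excursions peaking at 163/116 mmHg.

## Worked example

```python
from piezobp import PipelineConfig, end_to_end_benchmark

report = end_to_end_benchmark(PipelineConfig(seed=1), n_windows=2000, noise_sd=3.0)
print(report.summary().to_string(index=False))
```

```
target   me_mmhg  sd_mmhg  mae_mmhg  rmse_mmhg  pearson_r  pct_lt_5  pct_lt_10  pct_lt_15 bhs_grade
   SBP -0.096493 3.463084  2.782871   3.460098   0.977274     83.00      99.50      100.0         A
   DBP  0.130816 3.279437  2.612654   3.277946   0.954416     89.25      99.75      100.0         A
```

Here SBP/DBP are smooth functions of (PWV, systolic time span,
augmentation index) plus 3 mmHg of label noise, so the error SD of
~3.3–3.5 mmHg shows the regressors recovering the generative map almost
down to the noise floor; both targets reach BHS Grade A on the held-out
fifth of the 2000 windows.

The `examples/` directory walks through each capability (simulation and
voltage→force conversion, fiducials and PWV, training and grading,
closed-loop pressure control); each script prints what it computes and
what the numbers mean. A thin CLI covers the same ground from the
shell: `piezobp simulate | convert | features | train | predict | grade
| pump-demo | benchmark`.

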