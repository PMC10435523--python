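# Methods

This note records the models implemented in `piezobp`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that were genuinely open.

## Transduction model

The sensor model is the lumped scalar relation
`F(t) = A·∫V dτ − B·V(t) + C`. The constitutive tensors of the
piezoelectric stack are deliberately not represented individually: for
PZT layers thicker than a few micrometres the integral term dominates,
and no published calibration ties `A`/`B`/`C` to physical units, so the
defaults are `A = 1`, `B = 0`, `C = 0` (pure integration) and force is
an arbitrary-unit quantity. Integration is cumulative trapezoid
(second-order at the 2000 Hz ADC rate). No detrending happens inside
the transducer; integration drift is removed by the downstream
band-pass.

The inverse transform (used by the simulator to synthesize voltage from
a known force train) is a fourth-order finite-difference derivative for
`B = 0`. An exact discrete inverse of the trapezoid rule exists but has
a pole at the Nyquist frequency (`2/(1+z⁻¹)`), and the broadband ripple
it injects measurably biases sub-sample transit-time estimation — hence
the smooth derivative, whose round-trip error is the trapezoid
quadrature floor `(ω·Δt)²/12` (≈ 10⁻⁵–10⁻⁴ for pulse-band content at
2 kHz). For `B > 0` the inverse ODE `B·V' = A·V − F'` has a growing
mode `exp(A·t/B)`; the implicit trapezoid recursion is therefore run
*backward* in time, where that mode decays geometrically, and the
result reproduces `F` up to a constant force offset (an unobservable
static preload, removed by the band-pass).

## Synthetic physiology

**Beat morphology.** A beat is the sum of three positive asymmetric
Gaussian bumps — forward ejection wave plus two reflections — with
strictly decreasing amplitudes (1.0, 0.58, 0.30), centres at 0.13,
0.28 and 0.58 of the beat period, fall-side widths 58/75/90 ms at the
0.8 s reference period, and rise-side widths 0.6× the fall side
(sharper upstroke than decay). Widths scale with the beat period so the
morphology is heart-rate invariant in fraction-of-beat space. The
amplitudes and spacings were chosen once so that (a) exactly three
local maxima exist with decreasing heights, and (b) the dip before the
third wave — the dicrotic notch — is the most prominent post-systolic
minimum at every heart rate in the cohort range, which makes the
generator's analytic ground truth and the detector's definition agree.
Ground-truth fiducials are located numerically on a 10× oversampled
grid of the analytic sum; the waveform is affinely mapped so its
minimum is the subject's DBP and maximum the SBP.

**Dual-channel recording.** The distal channel is the proximal pulse
train evaluated at `t − spacing/PWV` (an analytic, genuinely
sub-sample delay) and damped by 0.85; both are forward-transduced to
voltage, yielding the characteristic piezo signature (strong positive
spike on the upstroke, negative valley on the decay, two weak
reflection peaks). Noise plumbing: white noise (fraction of
peak-to-peak), a slow respiration-like baseline sinusoid, and
motion-artifact bursts as damped 10 Hz sinusoids at Poisson times.

**Cohort.** Per-sex SBP/DBP normals (male 120.68 ± 11.86 /
79.58 ± 11.36 mmHg, female 108.27 ± 12.06 / 74.75 ± 8.12 mmHg), ages
9–62, BMI 17–32 kg/m², HR 55–95 bpm, PWV 2–20 m/s, all sampled
independently; an optional linear SBP–age trend defaults to slope 0.
Subjects must satisfy SBP > DBP + 10 mmHg. Enforcing that constraint by
redrawing the *pair* would bias the SBP marginal upward by ≈ 0.6 mmHg
(truncation of SBP−DBP at 10 with σ_diff ≈ 16 mmHg), so only DBP is
redrawn, from its exact conditional (truncated normal): the SBP
marginal stays calibrated to the population mean/SD and every subject
keeps a physiologic pulse pressure.

**HGCP trajectory.** Hand-grip ramps BP linearly to half the excursion
in 2 min, cold-pressor ramps steeper to the peak (163/116 mmHg
defaults) in 1 min, rest relaxes exponentially to baseline with
τ = 50 s.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no arterial fluid dynamics or vessel
mechanics, no beat-to-beat morphology variability within a subject, no
respiration-coupled amplitude modulation, no sensor drift or contact
impedance changes, and the feature→BP relation in the benchmark is a
chosen smooth map rather than physiology. Clinical-grade accuracy
claims require volunteer data; everything here validates the *pipeline
machinery* (recovery of known ground truth), not the physiological
model.

## Preprocessing

Butterworth was chosen for the 3rd-order 0.5–8 Hz IIR band-pass
(maximally flat; the filter family is otherwise unconstrained), applied
forward-backward so fiducial timing and Δt carry no phase bias — timing
fidelity was judged to outweigh the effective doubling of the order.
The 1500-sample window is counted at the 1000 Hz working rate (1.5 s),
hop = round(1500 × 0.7) = 1050 samples, full windows only, half-open
index ranges.

Beat delimitation: prominent maxima ≥ 0.3 s apart (prominence floor
30% of the robust 1st–99th-percentile span) are systolic candidates; a
second pass keeps only peaks with ≥ 45% of the maximum prominence so
prominent diastolic peaks cannot split a beat. Feet are the minima
between consecutive systolic peaks; a boundary minimum before the first
(or after the last) peak counts as a foot only when it is interior or
sits at foot level (within 7% of span of the window minimum) —
otherwise the edge beat is clipped and dropped. Beats are min–max
normalized to [0, 1] with the raw extrema retained as metadata.

Signal quality (for the pressure controller): `no_signal` when fewer
than two prominent peaks exist or less than half the non-DC power lies
in the 0.5–25 Hz pulse band (broadband noise); `distorted` when
inter-peak intervals are implausible (outside 0.3–2.0 s) or irregular
(CV ≥ 0.5) or peak prominences vary wildly (CV ≥ 0.5); `ok` otherwise.
These operational thresholds are invented constants, exposed as
arguments. In the full pipeline, quality is judged on the raw voltage
(as device firmware would), not the integrated force, because
integrated broadband noise masquerades as in-band signal.

## Fiducials, features, transit time

Systolic peak = global maximum; dicrotic notch = most prominent local
minimum after it, with the strongest positive curvature as fallback
when the notch does not dip to a minimum; diastolic peak = first local
maximum after the notch; foot = sample 0 by foot-to-foot construction.
Ordering is enforced; beats without the structure raise `DegenerateBeat`
and are excluded.

ST = foot→notch, DT = notch→next foot. Peak heights use
pre-normalization amplitudes (post-normalization every systolic height
would be identically 1 and carry no information). The relative
augmentation index is `(h_sys − h_dia)/h_sys` and the inflection-point
area ratio is the trapezoid area after the notch over the area before
it, both standard pulse-morphology definitions adopted because only the
feature names are fixed. Heart rate is 60 over the *median*
foot-to-foot interval (median, not mean, for missed-beat robustness);
per-beat Δt values are aggregated by median for the same reason.

Δt estimation: per detected beat, a ±0.15 s systolic-upstroke region of
the proximal channel is normalized-cross-correlated against the distal
channel over lags up to 40 ms, on a 10× polyphase-upsampled grid with
parabolic apex refinement. Upstroke correlation was preferred over
single-foot differencing (notch-region noise robustness); foot-to-foot
differencing would be a straightforward alternative estimator. Delays
below 0.1 ms or flat correlations raise `IndeterminateDelay`. PWV
outside (0.5, 30) m/s is flagged implausible. `decimate_for_transmission`
models the device strategy: Δt extracted at the full rate rides
unchanged alongside the 200 Hz anti-alias-decimated waveform.

## Regression and tuning

Two independent regressors (SBP, DBP) rather than a multi-output model,
since accuracy is reported per target. The 4:1 split shuffles windows
(mirroring the training protocol), not subjects; leave-subject-out
evaluation is possible by splitting on the subject column upstream but
is not the default. Sex is a 0/1 indicator recorded in the manifest.
XGBoost interprets γ as the per-split minimum loss reduction and α as
the L1 term on leaf weights; the printed defaults are used as-is.
Hyperparameter tuning is opt-in sequential model-based optimization: a
Matérn-5/2 Gaussian-process surrogate over the unit hypercube,
expected-improvement acquisition over a 256-point random pool, with the
incumbent default configuration always evaluated first so the tuned
result can never be worse than the default on the CV objective.
(A self-contained optimizer built on scikit-learn's GP regressor.)

Predictions are clamped to [30, 260] mmHg with a flag (never silently)
and flagged as extrapolated when more than 40 mmHg outside the training
label span.

## Grading

Errors are `pred − ref`. SD uses n−1; Pearson r is reported as
undefined (None) for zero-variance input. Bland–Altman limits are
bias ± 1.96 SD. BHS thresholds (A: 60/85/95, B: 50/75/90, C: 40/65/85
per cent under 5/10/15 mmHg) are encoded as a table so alternative
grading schemes can be added; the comparison is strict (`< 5 mmHg`),
with an inclusive variant switchable, since the boundary convention is
not fixed by the standard's common statement.

## Pressure controller

Per-phase increments default to equal steps (12 kPa / 5 = 2.4 kPa); the
true per-phase curve is not tabulated, so the schedule is configurable.
The leak is a single exponential calibrated to the one known retention
point: τ = 3600 / ln(1/0.30) ≈ 2990 s. The controller inflates only on
a distortion trigger (no spontaneous re-inflation after slow decay),
respects the 3.5 s inter-phase interval, and warns exactly once at
phase saturation. The coupled demo ties the controller to the
simulator with a monotone contact-gain step: below the threshold
pressure the pulse couples at 2% amplitude into a noise floor fixed at
15% of the full signal, above it at 100%, so quality flips to `ok`
after exactly the threshold number of phases (a 1% pressure tolerance
absorbs inter-step valve leakage at the threshold).

## Benchmark harness

`end_to_end_benchmark` draws subjects from the default cohort
(10 windows per subject), perturbs per-window features around
subject-level values, and sets
`SBP = 65 + 3.0·PWV − 40·(ST − 0.30) + 28·AIx + ε`,
`DBP = 45 + 2.0·PWV − 25·(ST − 0.30) + 16·AIx + ε` with
ε ~ N(0, 3 mmHg) by default — a feature-level harness with a known
noise floor, not a waveform-level simulation. The default problem size
(2000 windows, fivefold CV) runs in well under a minute per fit on one
CPU; the test suite uses 300–2000-window tables depending on what the
test demonstrates.

## Units and formats

kPa ↔ mmHg conversion uses 7.50062 mmHg/kPa (12 kPa ≈ 90 mmHg). Times
are seconds, sample indices 0-based, windows half-open. Waveforms and
feature tables are delimited text; recording metadata (sampling rate,
spacing, subject, seed, ground truth) lives in a YAML sidecar; only
trained model artifacts are binary (joblib).

## Known limitations

The Δt estimator assumes morphologically similar channels; strong
channel-specific distortion degrades it before the quality gate
catches it. The notch detector's curvature fallback can place the
notch a few samples early on heavily damped beats. The benchmark's
Grade A says the machinery recovers a known smooth map at a 3 mmHg
noise floor — it is not a clinical accuracy claim.
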