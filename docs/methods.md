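# Methods

This note documents the models, numerical choices, and open design
decisions behind `ppgmark`, in the order the pipeline runs.

## Synthetic cohort model

Each cardiac pulse is the sum of two Gaussians on a zero baseline — a
systolic wave (center `c_s`, width `σ_s`, height 1) and a dicrotic wave
(center `c_d`, width `σ_d`, relative height `r_d < 1`) — parameterized in
*phase units* (fractions of the beat period), so heart rate and sampling
rate factor out by construction. The chord through the pulse's endpoint
values is subtracted so every beat starts and ends at exactly zero;
consecutive beats therefore join continuously without any crossfade (an
overlap-add crossfade would shorten each beat and bias heart rate).
Records are assembled beat by beat with per-beat period jitter
(`Normal(60/HR, 2 %)`, truncated at ±30 %), then contaminated with:

| source | default | unit |
| --- | --- | --- |
| respiratory baseline wander | 0.15 amplitude at 0.25 | a.u., Hz |
| powerline interference | 0.02 at 50 | a.u., Hz |
| white sensor noise | 0.01 | a.u. (sd) |
| motion bursts (0.5-s triangular) | 0.5 per minute, 0.6 | events/min, a.u. |

Amplitudes are relative to the unit pulse height; values are in the range
reported for pulse-oximeter artefact studies and are deliberately moderate:
strong enough to exercise smoothing, baseline removal and quality
screening, weak enough that most segments stay usable.

### Class structure

The default cohort is 32 + 32 subjects, 60-s records, heart rate
75 ± 4 bpm, the non-anesthesia class sampled at 125 Hz and the anesthesia
class at 100 Hz — the same class/acquisition-rate confound the two source
databases have, which 2D normalization must absorb (a config switch
equalizes the rates).

*Non-anesthesia* subjects share one base morphology (early narrow systolic
wave, pronounced dicrotic wave) modulated by a common lognormal
"vascular-tone" factor (sd 0.15) that stretches the pulse's temporal layout
jointly — later peak *and* broader waves together. The factor is clamped so
the dicrotic wave stays distinct from the systolic one (`c_d` ∈
[0.58, 0.88]) and wide enough (`σ_d ≥ (1 − c_d)/3.2`) that the diastolic
decay still has nonzero slope at the beat boundary; without that clamp some
subjects have a dead-flat diastolic foot on which the onset position is
simply not identifiable from the waveform.

*Anesthesia* subjects sit on a continuum between two endpoint shapes,
emulating varying anesthetic depth: an early-but-wide pulse (vasodilation
dominating, with a broad low shoulder instead of a distinct dicrotic wave)
and a late-but-narrow one (delayed upstroke dominating, with a late
dicrotic wave). The systolic width follows a convex trade-off against
timing along the continuum, and the dicrotic load is rebalanced at every
point so that `σ_s + r_d·σ_d` — which controls the area under the
normalized pulse — is constant along the continuum and matched to the other
class (verified to < 2 % in class means). Consequences, by design:

- rising time and the upper width family (50–90 %) shift upward, the lower
  widths (20–30 %) shift downward (the anesthesia shapes lack the
  dicrotic extension that stretches low-level widths);
- total area carries no class signal and must *not* survive selection;
- the two class hulls interleave in the selected-marker space: the
  vascular-tone tail of the non-anesthesia class reaches into the gap
  between anesthesia morphologies. A single hyperplane or one Gaussian per
  class cannot follow that boundary, while local neighborhood voting can —
  which is what makes the classifier ranking (KNN ahead of quadratic
  discriminant and linear SVM) a structural property of the cohort rather
  than an artifact of tuning. At the default seed the ranking holds with a
  clear margin; across seeds it is typical but not universal, because with
  16 test subjects per class a single boundary subject moves accuracies by
  ±2–3 %.

The generator annotates ground truth per record: onset times (the
waveform's actual local minimum near each beat joint — with a strong late
dicrotic wave the chord tilt can displace the minimum a few samples past
the joint, and the waveform is what a detector can see), peak times, the
subject's realized shape parameters, and heart rate.

What the generator does **not** model: arrhythmia, SpO2/dual-wavelength
effects, slow drug-level dynamics within a record, sensor-site differences,
or any physiologically detailed hemodynamics. Passing tests on this cohort
show the *pipeline machinery* is correct and that the method recovers a
known class structure of realistic effect size under realistic noise; they
do not certify clinical performance on real recordings.

## Quality screening

Four deterministic rules replace a manual review; the first firing rule is
recorded. Thresholds live in `QualityRules`.

- **flatline** — sample variance below 1e-6 of the squared range.
- **clipping** — the longest *contiguous run* of samples within 0.1 % of a
  rail exceeds 5 % of the window. The total near-rail fraction is the more
  obvious statistic, but it fires on the flat diastolic foot of perfectly
  clean pulse trains; saturation is a dwell, not a count.
- **out_of_band** — more than 12 slope reversals per expected beat
  (2 Hz ceiling) *after* Savitzky–Golay smoothing. Counting on the raw
  segment would condemn every 125-Hz record, because 50-Hz mains ripple
  alone reverses the raw slope hundreds of times per window; what matters
  is the broadband noise that survives the denoising stage. Clean noisy
  segments show ≈ 40–90 reversals per 5-s window, white noise ≈ 170–250;
  the threshold (120) sits between the populations.
- **too_few_beats** — fewer than 3 delineated beats (applied after
  delineation).

## Preprocessing

**Smoothing.** Savitzky–Golay, polynomial order 4, 21-sample frame (the
frame must be odd; 21 is the nearest odd value to the nominal 20), edges
handled by polynomial fits on truncated windows (`mode="interp"`).

**Baseline removal.** A cubic spline anchored at provisional beat-onset
values is subtracted; onsets are morphological zeros of the pulse train, so
anchoring there flattens respiration-band drift without distorting pulse
shape. With fewer than 4 anchors the interpolant degenerates to linear;
with fewer than 2, mean subtraction.

**Delineation.** Extrema are slope sign-changes (plateaus attributed to
their first sample). Systolic-peak candidates must exceed 30 % of the
upper-quartile prominence — the *median* prominence fails when dicrotic
maxima are as numerous as systolic ones — and survive a refractory period
of 0.55× the beat period estimated from the segment's autocorrelation
(floored at 0.3 s): a deep-notch dicrotic wave can carry nearly full
prominence, and only its sub-period spacing gives it away. Onsets are the
minimum between consecutive accepted peaks, refined within ±5 samples on
the unsmoothed (detrended) signal because smoothing displaces the diastolic
corner by 2–3 samples. Edge-partial beats are dropped unless the boundary
minimum genuinely reaches onset level (within 10 % of the median pulse
amplitude). On noiseless default cohorts this recovers annotated landmarks
within ±2 samples for ≥ 99 % of beats.

**2D normalization.** Amplitude is affinely mapped so onset → 0 and
peak → 1 (values outside clip to [0, 1]; after resampling the beat is
rescaled by its grid maximum, since a uniform grid can narrowly miss the
peak sample). The time axis is linearly resampled to L = 100 samples over
onset → next onset; 100 is at least the native per-beat sample count at
both 100 and 125 Hz for heart rates up to ~75 bpm. Markers computed on the
normalized beat are dimensionless; the cross-rate agreement of all 13
markers is within 2 %, which is the operational point of the normalization.

## Markers

Widths use the first up-crossing before the peak and the last down-crossing
after it, with linear interpolation between samples — this convention makes
level sets nested, so `width_f` is non-increasing in `f` for every beat. A
normalized beat starts at exactly 0, so the rising-side crossing always
exists for genuine beats; a beat whose tail never returns below the level
counts its width to the beat end. A beat with any undefined marker is
excluded from all of its segment's marker means (jointly consistent
vectors), and segments with fewer than 3 usable beats are rejected.

## Selection

Point-biserial correlation is computed with the population-sd convention,
which is exactly the Pearson correlation with the 0/1-coded label (tested
to 1e-12 against an independent Pearson computation). The threshold applies
to |r| because markers may shift in either direction. Welch t-tests (with
Satterthwaite degrees of freedom) are reported per marker with **no
multiple-testing correction** — a deliberate mirroring of common practice
in this literature; with 13 markers, expect ~0.65 false positives at
α = 0.05 under the null. The default classifier feature set drops selected
markers that fail the t-test at p < 0.05 (`mode="significant"`); the
alternative (`mode="selected"`) trains on everything above the correlation
threshold.

## Classifiers

All three families standardize features with training-half mean/sd at fit
time; distances and margins are not scale-invariant, and the markers live
on different numeric ranges.

- **KNN** tie rules: with uniform weighting and a tied vote, the single
  nearest neighbor's class wins; with inverse-distance weighting an
  exact-match neighbor (d = 0) wins outright, as the limit of 1/d. The ROC
  score is the positive-class fraction of the vote weight.
- **Discriminant analysis**: Gaussian class-conditionals with empirical
  priors; pooled covariance for linear, per-class for quadratic. A ridge of
  1e-6·trace(Σ)/d is added and escalated tenfold until the condition number
  drops below 1e10 (degenerate synthetic features can make Σ singular).
  Prediction minimizes expected classification cost; with the default 0/1
  cost matrix this is the posterior argmax, and ties break to the lower
  class index. The ROC score is the positive-class posterior.
- **SVM**: the soft-margin dual is solved (via libsvm through scikit-learn)
  to a 1e-3 feasibility-gap tolerance. The "cubic" kernel is the polynomial
  kernel (x·x′ + 1)³ — the name alone does not pin down a formula, and this
  is the standard inhomogeneous cubic. For the linear kernel the primal
  normal β and bias b are exposed in original feature coordinates. The ROC
  score is the decision value.

Hyperparameter presets, by provenance: the tuned headline configuration is
KNN with k = 3, Euclidean metric, inverse-distance weighting; a documented
alternative is Minkowski (p = 2) with k = 6 and uniform voting. The
discriminant preset is quadratic. Three SVM presets exist: box 0.32 with
the cubic kernel, box 7.59 with the Gaussian kernel (the two tuned variants
differ between sources, so both are preserved), and a plain linear kernel
at C = 1.

## Evaluation

Subjects, never segments, are the unit of splitting: segments from one
subject are strongly correlated, and letting them straddle a train/test
boundary would leak identity information. The half split shuffles subjects
per class with a seeded generator (odd counts favor training); segment
counts per half then fall wherever subject membership puts them, so the
halves are generally unequal in segments. Grouped tenfold CV deals shuffled
subjects round-robin into folds, stratified by class.

The hyperparameter search is sequential model-based: 5 random warm-up
evaluations, then a Matérn-5/2 Gaussian-process surrogate with expected
improvement over a 256-candidate random pool, 30 iterations total,
all scored by grouped tenfold CV on the training half. The search's CV
score averages 3 independent fold assignments: with 32 training subjects a
fold holds ~3 subjects, and a single assignment is too noisy to rank
configurations (the plain single-assignment CV remains the
`grouped_kfold_cv` default). Purely categorical spaces smaller than the
budget are swept exhaustively; a random-search mode exists. Configurations
infeasible on a fold (k exceeding the fold's training size) score error
1.0 rather than aborting the search.

Metrics treat anesthesia as positive. Precision is reported as missing
(None), not 0, when no positive predictions exist. ROC points come from a
threshold sweep with ties moving simultaneously, so the trapezoid AUC
equals the normalized Mann–Whitney U with ½ credit for ties (tested to
1e-12).

## Problem sizes

The default experiment uses 32 + 32 subjects with 60-s records
(≈ 760 usable segments), 30 search iterations, tenfold CV × 3 assignments.
Unit and property tests use 4–8 subjects per class and 30–60-s records.
These sizes keep a full test run in tens of seconds while leaving every
stage with non-trivial work.

## Known limitations

- The onset of a pulse whose diastole decays to a flat foot is intrinsically
  ambiguous; the generator's clamps keep default cohorts away from that
  regime, but real recordings may not be.
- The classifier ranking on the synthetic default is a designed structural
  property; the absolute accuracies say nothing about real-data accuracy.
- SVM models serialize their support vectors and kernel parameters but are
  reconstructed through the underlying solver's data structures only at
  fit time; `load_model` supports KNN and discriminant models.
- No multiple-testing correction in selection (see above); the 4-vs-5
  feature ambiguity is exposed as `mode="significant"` vs
  `mode="selected"`.
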