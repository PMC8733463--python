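# Methods

`ictalprint` builds person-specific "ictal fingerprints" from
multimodal outpatient recordings: 2-channel bipolar subcutaneous EEG
(207 Hz, microvolts), a surface-EMG estimate derived from that EEG,
and 3-axis trunk accelerometry (10 or 20 Hz, units of g). This note
describes the analysis model, the synthetic cohort generator that
stands in for restricted clinical recordings, the numerical choices,
and what the tests do and do not establish.

## The analysis

**Cohort rule.** Seizures labeled FBTCS (focal to bilateral
tonic-clonic) are excluded first; persons with fewer than 10 remaining
electrographic seizures are then dropped entirely. The order matters
and is tested.

**Periods.** For a seizure with onset `o` and duration `d` (seconds):
ictal `[o+2, o+d−2]` (2 s trimmed at each end against transition
phenomena), pre-ictal `[o−60, o−2]` (58 s), baseline `[o−360, o−300]`
(a 1-min window ending 5 min before onset). A seizure with `d ≤ 6` has
no analyzable ictal period and is skipped; pre-ictal/baseline windows
that start before the recording or overlap another seizure's ictal
interval are skipped. Both rules are logged, configurable, and
decisions of this package (the minimum analyzable length equals the
shortest window the spectral estimator accepts). Sample indexing is
half-open with `index = floor(t·fs)`.

**Features (68).** Per EEG channel: absolute and relative power in six
bands (delta 0.5–4, low theta 4–6, high theta 6–8, alpha 8–12, beta
12–20, hf 20–48 Hz), total 0.5–48 Hz power, 95% spectral edge, peak
frequency, line length, and the three Hjorth parameters (19 × 2
channels). EMG estimate per channel: the electrode lead spans the
temporalis muscle, so EEG content above 20 Hz serves as an EMG
surrogate — absolute and relative >20 Hz power, mean and max of the
0.25-s RMS of the >20 Hz high-passed signal, zero-crossing rate
(5 × 2). Accelerometer: per-axis mean, sd, mean |first difference|/s
and dominant frequency; magnitude mean/sd/|Δ|/dominant frequency;
pitch and roll from the mean gravity projection; signal-magnitude
area; movement fraction (20). The catalog is data
(`features.default_catalog()`), serialized with every result. The
five canonical fingerprint features (`acc_x_mean`, `emg_power_prox`,
`eeg_relpow_delta`, `eeg_relpow_low_theta`, `eeg_relpow_high_theta`)
appear verbatim; the proximal channel carries the unsuffixed names.

**Spectral estimation.** Welch periodogram with 2-s Hamming windows,
50% overlap, per-window mean detrend, one-sided density scaling (the
integral over frequency approximates the variance; verified against
Parseval and sinusoid closed forms to 5%). Band powers are trapezoidal
integrals with linear interpolation at off-grid band edges; the
relative-power denominator is 0.5–48 Hz, chosen below mains frequency
and within Nyquist. The EMG band is 20 Hz up to min(100, fs/2 − 3) Hz,
the 3 Hz guard being an anti-alias margin.

**Selection.** A Random-Forest classifier separates ictal periods
between persons (one row per ictal period). 5-fold stratified CV over
the 3×3 grid {25, 50, 100} trees × {2, 4, 6} minimum samples to
split; remaining hyperparameters pinned (`criterion="gini"`,
`max_features="sqrt"`, `bootstrap=True`, fixed `random_state`). The
best grid point by mean fold accuracy (ties toward fewer trees, then
smaller min-split) is refit on all ictal rows and the top 5 features
by impurity (Gini) importance form the reduced space (importance ties
resolved by catalog order). Trees are scale-invariant, so no feature
scaling precedes the forest.

**Fingerprint.** Z-scoring is fit on the ictal rows of the reduced
table (sample sd, ddof = 1) and reused unchanged for pre-ictal and
baseline rows, anchoring all comparisons to ictal statistics. PCA is a
covariance eigendecomposition of the Z-scored ictal rows, components
sign-fixed so each component's largest-magnitude loading is positive.
Person centroids are arithmetic means over the first 3 component
scores (configurable to 5); each seizure is assigned to the nearest
centroid (Euclidean; exact ties go to the person with more seizures,
then lexicographic id). Centroids include the assigned seizure by
default, matching "average over all seizures"; a leave-one-out mode
recomputes the assigned person's centroid without the held-out seizure
and is the appropriate choice for negative controls, where the
self-inclusion pull alone lifts chance-level accuracy from 0.25 to
≈0.39 at 12 seizures/person. Radar fingerprints are per-person,
per-feature medians and interquartile ranges (linear-interpolated
percentiles) of the Z-scored ictal rows. Ictal vs pre-ictal/baseline
separation classifies each period by the nearer of the two
person-specific cluster averages in the Z-scored 5-dim reduced space
(ties count as ictal); metrics are pooled over persons with ictal as
the positive class and 95% Wald intervals on the pooled n (Wilson and
Clopper–Pearson available).

## The synthetic cohort generator

Raw clinical recordings of this kind are not publicly available, so
`ictalprint.simulate` produces desk-scale stand-ins: minutes-to-hours
recordings hosting 10–25 annotated seizures per person with
inter-seizure gaps (default 420–620 s) wide enough for the baseline
windows, instead of the months-scale originals. Four archetype
signatures mirror the clinically observed fingerprint types:

| person | archetype | signature |
|---|---|---|
| B | theta-dominant | low-theta ×5, high-theta ×3.5, delta ×1.5 |
| E | mixed theta + movement | low-theta ×3, high-theta ×2, posture shift 0.25 g |
| G | EMG-dominant | >20 Hz burst power ×7 on the proximal channel |
| I | movement-dominant | posture shift 0.45 g, delta ×3 |

Band gains are multiplicative power gains relative to the local
background band power; dominant gains are ≥3× background. Default
seizure counts are 25/15/12/22 with two FBTCS extras each for B and E
(78 planted, 74 electrographic non-FBTCS).

The background model deliberately includes the variability that makes
feature selection on real data hard; without it, dozens of catalog
features become noise-free monotone equivalents of the planted
signatures and impurity-based importance cannot order them:

- **1/f EEG** (exponent 1.0, flat below 0.5 Hz, sd 20 µV) with a
  shared log-normal amplitude drift (sd 0.3, 2-min control points) —
  impedance/vigilance drift; makes absolute powers unreliable exactly
  as on real electrodes.
- **Waxing/waning background rhythms**: alpha (2× base power), beta
  (1×) and infra-slow 0.05–0.45 Hz activity (4×; electrode/sweat slow
  potentials) with ~3-min log-normal envelopes per channel. The
  infra-slow component sits below every analysis band but inside the
  raw-signal variance, decoupling time-domain shape features (Hjorth,
  line length) from the band features.
- **Ictal EEG component**: band-passed noise added over the seizure
  interval (1-s cosine edge tapers), projected at 0.35 amplitude onto
  the distal channel (focal source nearer the proximal contact).
- **EMG bursts**: 20–100 Hz noise under an on/off burst envelope
  (~1 s bursts, smoothed), proximal channel only.
- **Ictal artifact**: every seizure of every person also receives a
  person-independent 20–100 Hz component with per-seizure power factor
  drawn uniform from 1.2–3.5 — muscle/movement artifact is
  near-universal in ictal EEG. Null cohorts disable it.
- **Per-seizure intensity jitter**: one LogNormal(0, 0.35) draw scales
  all of a seizure's planted excesses; seizures of one person vary in
  intensity.
- **Accelerometry**: gravity projection plus white noise (0.02 g),
  piecewise-constant posture epochs every 5–15 min (roll ±0.7 rad,
  pitch ±0.12 rad), and everyday-activity bouts (35% of 30–300 s
  segments, 1–4 Hz dynamic acceleration of 0.05–0.25 g on all axes).
  The ictal posture change is a magnitude-preserving rotation of
  gravity about the device y-axis (a real posture change re-orients
  gravity, it does not add to |a|), with 2-s cosine ramps that fall
  inside the trimmed-off transition seconds. An optional tremor
  oscillation (person-specific 2–3.5 Hz) is available but not part of
  the stock archetypes.

All per-person randomness flows from one seeded generator; seeds and
parameters are logged in the cohort manifest, and identical inputs
give bit-identical EDF/CSV outputs.

**Null cohorts** (`simulate.null_cohort`) zero every ictal signature
*and* the state-dependent background terms (drift, rhythms, posture,
activity, artifact), so that all analysis periods of all persons are
exchangeable. This is the correct negative control: person-specific
realizations of background states are genuine person-identifying
signal, but not ictal signal, and would confound a chance-level test.

## What the tests show — and do not show

The planted-signature recovery suite shows that the pipeline finds
fingerprints it should find (≥4 of the 5 planted signature families
selected; person clustering ≥0.80; pre-ictal separation ≥0.75 on five
generator seeds at study-scale counts) and the null suite shows it
does not invent them (chance-level clustering with leave-one-out
centroids; near-uniform importances). Recovery is asserted at the
level of *signature families* (`features.fingerprint_families()`), not
verbatim feature names: the catalog intentionally contains monotone
transforms of the canonical five (trunk pitch vs mean x-acceleration;
the 20–48 Hz EEG band vs >20 Hz EMG power; RMS vs power), and
tree-based importance is invariant to monotone transforms, so which
member of an equivalence class tops the ranking is not identifiable
even in principle. On pure-noise cohorts the maximum of 68 Gini
importances has a heavy tail driven by which grid point wins CV (a
25-tree refit gives few splits per feature), so single-seed maxima can
exceed 3× the uniform level without any planted signal; the
permutation-null test on a fixed table is the sharper tool for
selection-bias regressions.

None of this demonstrates performance on real recordings: the
generator has no spikes, sleep architecture, circadian structure,
artifacts beyond those listed, or gait models, and its ictal
signatures are stationary band-power shifts rather than evolving
seizure morphologies. Synthetic accuracies (≈0.93–1.0 clustering,
≈0.95–0.99 separations at the default gains) are upper bounds set by
the chosen signal-to-background ratios, not predictions; the clinical
anchor values (84.5% / 93.1% clustering, 83.8% / 88.1% separations)
are qualitative references only.

## Numerical and degenerate-input choices

- EDF encoding: 16-bit, 1-s records, symmetric physical ranges (EEG
  ±1000 µV, acc ±4 g — conventions, configurable); out-of-range
  samples raise rather than clip; round-trip error is bounded by one
  quantization step (range/2¹⁵).
- Relative power of an all-zero signal is 0 (denominator guard);
  Hjorth mobility/complexity of a constant signal are 0.
- PCA requires rows ≥ features; Z-scoring requires ≥2 rows and
  non-constant features (errors name the offending feature).
- Constant feature columns at selection are retained with zero
  importance and a warning (on synthetic cohorts the distal peak
  frequency is constant at 0.5 Hz — a 1/f spectrum peaks at the lowest
  band edge).
- Dominant accelerometer frequency searches above 0.25 Hz; signals
  shorter than one Welch window raise a length error naming the
  minimum.
- Report serialization uses fixed float formatting and sorted JSON
  keys; reruns with identical config and seed are byte-identical.

## Problem sizes

Default test and acceptance runs use the study-scale synthetic cohort
(74 electrographic seizures across 4 persons, ~2–4 h of multirate
signal per person); recovery and null suites repeat the full pipeline
on five seeds. These sizes keep a full run in a few minutes on one
core while leaving every stage's statistics (5-fold CV with ≥12 rows
per person, 148-period separations) well-posed.
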