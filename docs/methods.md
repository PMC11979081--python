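# Methods

## Signal model

A synthetic cardiac cycle of length T = 60/HR seconds is built from three
pieces, chosen so that every quantity the analysis reports has a closed
form:

* **Anacrotic limb** (foot → systolic peak, `upstroke_fraction`·T, default
  0.15): raised cosine from DBP to SBP. Its second time-derivative is
  maximal at onset, which makes the detection fiducial ("maximum of the
  second derivative on the rising limb") analytically well defined.
* **Systolic descent** (peak → dicrotic notch at `notch_fraction`·T,
  default 0.35): a cosine arc leaving the peak with zero slope and
  arriving at the notch pressure *steeper* than the diastolic decay that
  follows (target steepness 2× the initial decay slope, capped by the
  feasibility of the arc; the arc phase solves
  (1−cos φ)/(φ sin φ) = ΔP/(T_d·|m|) by bisection). The slope therefore
  jumps *up* at the notch — the end-systolic deceleration shoulder that a
  real incisura leaves on the waveform — giving notch detection a
  localized positive-curvature landmark.
* **Diastole** (notch → cycle end): exponential decay
  P(t) = P∞ + (P_notch − P∞)·e^(−t/τ), the two-element Windkessel relation
  with τ = R·C.

**Asymptote convention.** With the default `asymptote=None`, P∞ is derived
per beat so the exponential lands exactly on DBP at cycle end:
P∞ = (DBP − P_notch·E)/(1 − E), E = e^(−T_dia/τ). Consecutive cycles are
then continuous at every foot, the foot value equals the `dbp` parameter
(an unambiguous DBP truth label), and τ remains the exact decay constant.
The derived P∞ may be negative for fast decays; it is a mathematical
anchor — samples never fall below DBP. Passing an explicit numeric
asymptote (e.g. 0) instead truncates the exponential at cycle end and
resets the next foot to DBP, leaving a step at the foot whenever the decay
does not reach DBP within one diastole; that variant exists because the
zero-asymptote identity ∫P dt = τ(P₀ − P_end) is the textbook area-method
relation and is used directly in tests.

**Trace assembly.** Beats are concatenated for the requested duration
(default 60 s at 100 Hz). Additive white measurement noise (default SD
1 mmHg), a 0.05 Hz sinusoidal baseline drift (default amplitude 2 mmHg —
below the beat frequency, above DC, so it stresses foot detection), and
artifact beats: with probability `artifact_rate` (default 0.05) a cycle is
replaced by the time-reversed clean beat scaled by 0.6 about its mean
pressure. Time reversal guarantees a correlation with the clean template
far below the 0.95 retention gate (≈ −0.5; affine rescaling leaves the
correlation unchanged), and mean-anchored scaling keeps the artifact in
the physiological range without large steps at its boundaries. Ground
truth (every beat foot, notch index, artifact flag) is returned alongside
the trace; equal seeds give bitwise-identical output.

## Processing chain

Order is fixed: 10 Hz low-pass first, then Savitzky-Golay smoothing.

* **Low-pass**: 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`), i.e. zero phase — fiducial timing is not shifted.
  The filter family/order and zero-phase application are this package's
  choices; only the 10 Hz corner is externally prescribed.
* **Savitzky-Golay**: order 2, 50 ms window, converted to samples and
  rounded to the nearest odd count (≥ 5; exactly 5 samples at 100 Hz),
  with polynomial interpolation at the edges so quadratics are reproduced
  exactly everywhere.

Both stages are linear and length-preserving; mirror-type padding avoids
endpoint transients so the first and last beats of a 60-s trace remain
usable.

## Beat analysis

* **Feet**: local pressure minima preceding peaks of dP/dt. The peak
  threshold is half the median upstroke-peak slope, with the median taken
  over the strong-peak population (anchored at half the 90th percentile)
  so small noise-induced dP/dt peaks between beats cannot drag the
  threshold down. A 300 ms refractory period separates peaks; cycles
  outside 0.3–2.0 s are discarded. A trace with peak-to-peak excursion
  under 5 mmHg is treated as non-pulsatile (no beats, warning).
* **Fiducials**: maximum of the centered second difference between the
  segment start and the systolic peak, after edge-padded binomial
  smoothing ([1,2,1]/4) of the second difference for noise stability.
  Beats with a systolic rise below 1 mmHg are flagged and excluded from
  averaging. Note that the 10 Hz conditioning rounds the onset corner, so
  the detected fiducial sits a constant ~20–30 ms into the smoothed
  upstroke on every beat; this offset is identical across beats and
  cancels in alignment, and feet (used for all timing-sensitive outputs)
  are unaffected.
* **Two-step averaging**: beats aligned at fiducials with up to 100 ms of
  pre-fiducial context (beats lacking it, typically the first, are
  dropped); the common support ends at the shortest post-fiducial span
  among beats near the median cycle length (beats > 25% away from the
  median cycle length, or with outlier spans, are excluded from support —
  they are stubs cut around artifacts and would truncate everyone).
  Step 1 averages these windows into the raw average; step 2 Pearson
  correlates every usable beat against it over the available overlap and
  re-averages only full-support beats with r > 0.95 (exactly two passes,
  no iteration). Diagnostics (per-beat correlation, retention flag) are
  kept on the result. Minimum retained beats: 5 (configurable).

## Morphometrics

On the representative beat: foot = pressure minimum before the systolic
peak; cycle end = foot + median cycle length. SBP = cycle maximum, DBP =
foot value, PP = SBP − DBP, MBP = trapezoidal time-average over the cycle
(the integral mean, consistent with the area outputs, rather than the
(SBP+2·DBP)/3 cuff approximation). The dicrotic notch is searched from
50 ms after the peak to 80% of the cycle: primary rule, the most prominent
local pressure minimum (prominence at least 2% of the beat amplitude so
residual noise dips are ignored); fallback for shoulder-type incisurae,
the most prominent interior maximum of the second difference. A monotone
featureless decay yields "notch not found": durations, areas and τ are
reported missing while amplitude features remain.

**Decay constant (area method).** Over the diastolic window the
exponential satisfies ∫(P − P∞) dt = τ·(P_start − P_end), so
τ = A′/(P_start − P_end) once P∞ is fixed (default 0 mmHg; exact when the
true asymptote matches). `asymptote="fit"` estimates P∞ jointly by
regressing P on its own running integral and time (exact for any
asymptote on clean data) — but the joint (τ, P∞) problem is poorly
identified when τ exceeds the window length, so under noise this variant
is imprecise and the known-asymptote form is the default throughout. The
window opens 40 ms after the notch and closes 100 ms before cycle end:
the zero-phase conditioning filters ring over roughly 1/cutoff = 100 ms
around the notch shoulder and the next foot, and the guards keep that
ringing out of the integral and its endpoint pressures. Windows shorter
than 100 ms, or pressure drops under 0.5 mmHg, raise "tau undefined".

## Circle-of-Willis classification

Seven segments relative to the operated side: contralateral A1, A-com,
ipsilateral A1 (anterior semicircle); P1 and P-com on each side
(posterior). Normal ≥ 0.8 mm, hypoplastic < 0.8 mm, absent if not
visualized. Groups: 1 all normal; 2 anterior-only compromise; 3
posterior-only; 4 both semicircles compromised; 5 isolated MCA — an
ABSENT segment interrupts the (series) anterior chain *and* an ABSENT
segment interrupts the ipsilateral P1→P-com route, so the operated MCA
receives no primary collateral flow from the contralateral ICA or the
vertebrobasilar system. Group 5 takes precedence over 4. Declared
interpretations where the verbal rules are ambiguous: contralateral
posterior segments count toward semicircle compromise but not toward the
isolation test; multiple non-normal segments confined to one semicircle
stay in group 2/3 (flagged `multi_segment`); a both-compromised
configuration whose non-normal segments are all ABSENT without meeting
the isolation test is group 4, flagged `ambiguous_pair`. The classifier
is total and deterministic on all 3⁷ configurations and is verified
against an independently written rule table by exhaustive enumeration.

## Cohort simulator (the study conditions)

Group sizes (12, 12, 31, 18, 5) for CoW 1–5. Per-group ICA-stump DBP and
pulse pressure are truncated normals at the published group means and
between-subject SDs (DBP ≥ 15 mmHg; PP ≥ 2 mmHg — weak stump pulsation
can genuinely be a few mmHg); SBP = DBP + PP; the notch pressure sits
0.47 ± 0.03 of the way up the pulse (the fraction implied by the published
end-systolic means). Heart rate is drawn per subject from the group's
published level and shared between the ICA and radial channels. The radial
channel uses one pooled distribution (DBP 62 ± 15, PP 71 ± 19 mmHg, notch
fraction 0.37). τ is drawn from N(2.0, 0.3²) s truncated at 0.3 s in
*every* group — a true null mirroring the reported absence of a CoW effect
on diastolic decay. Backflow grade is drawn from a group-conditional
distribution that weakens with increasing CoW compromise (grade-3
probability 0.90/0.80/0.65/0.40/0.20 across groups 1–5), producing a
moderate negative Spearman correlation between backflow and CoW group
(≈ −0.43) of the same character as observed intraoperatively.
Contralateral stenosis is drawn independently of the waveform parameters
(normal 30 ± 25%, clipped to [0, 95]), so stenosis–waveform correlations
are null by construction, matching the weak observed associations.
Feature-mode cohorts fill the per-subject panels with the model's closed
forms; trace-mode additionally synthesizes the paired raw recordings.

What the generator does *not* emulate: beat-to-beat physiological
variability (respiration, arrhythmia), baroreflex dynamics, catheter-line
resonance, wave reflections, or any mechanistic link between CoW anatomy
and the waveform beyond the configured group means. Passing tests
demonstrate that the pipeline recovers known truth under this model, not
that it is robust to every artifact of real operating-room data.

## Statistics

One-way fixed-effects ANOVA per waveform variable with CoW group as the
factor (groups with < 2 observations excluded with a warning), pairwise
Tukey HSD (studentized-range adjusted p), Pearson for stenosis
associations, Spearman (mid-ranks) for backflow × CoW (both treated as
ordinal 1–5 / 1–3), chi-square for categorical tables when every expected
count exceeds 5, otherwise Fisher's exact for 2×2 (larger sparse tables
fall back to chi-square with a warning). α = 0.05; no correction across
features — each variable's ANOVA p is reported as-is, Tukey adjusts only
within its own family. Implementations are scipy-backed and cross-checked
in the tests against hand computations, the studentized-range
distribution, hypergeometric enumeration, and statsmodels.

## Numerical and design choices

* Problem sizes in tests and the acceptance script — 60-s traces, 3–6
  noise seeds per τ, 200 simulated cohorts, 1000 type-I replicates — were
  chosen as the smallest sizes at which the Monte-Carlo bands are
  meaningfully narrower than the properties they check.
* Pressure units are mmHg throughout; time is seconds from trace start;
  no unit-conversion layer.
* The recovery analyses pass the generator's derived asymptote to the τ
  estimator: generator and estimator share the asymptote convention, so
  they measure pipeline fidelity (filtering, segmentation, averaging,
  integration), not asymptote identifiability — which is poor over a
  single diastole and is reported as such (see above).
* Determinism: all randomness flows through `numpy.random.default_rng`
  seeds carried in the parameter objects.

## Known limitations

* The τ/asymptote pair is not jointly identifiable from one diastole when
  τ is comparable to or longer than the diastolic window; a convention
  (or external knowledge) for P∞ is required, and results under different
  conventions are not numerically comparable.
* The notch detector assumes either a dip or a single curvature shoulder;
  heavily damped recordings with neither will report the notch as missing.
* Fisher's exact test is 2×2 only; sparse larger tables get an asymptotic
  chi-square with a warning.
* The classifier encodes one reading of the verbal grouping rules (see
  flags above); borderline anatomies should be reviewed with the
  `classify_cow_detailed` flags.
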