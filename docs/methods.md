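# Methods

This note documents the models, defaults and design choices behind
`sigwhistle`, and what the validation experiments do and do not show.

## Classification rules

The unit of analysis is the *whistle unit*: a single- or multi-loop whistle.
Consecutive contours in a session whose end-to-start gap is strictly less
than 250 ms are merged into one unit (`merge_loops`); a gap of exactly
250 ms separates two units. All later gap windows are closed intervals
measured end-of-unit to start-of-next:

- **REWT**: a whistle type with ≥ 2 mutually matching units in one session
  whose gap lies within [0.25 s, 10 s].
- **SW (SIGID bout criterion)**: a REWT with, in some session, ≥ 4 units of
  which ≥ 75 % (equality qualifies: 3/4 counts) have their nearest same-type
  gap within [1 s, 10 s]. The criterion is evaluated per session; once a
  type qualifies anywhere, its SW-ID propagates to every matching unit in
  the study. The 75 % clause counts whistle units, not loops.

Expert visual contour matching is replaced by a deterministic shape
distance: contours are resampled to 64 points over their own time span,
z-normalised in frequency, and compared by RMS difference. The distance is
therefore invariant to time shifts, constant frequency offsets and overall
duration; what it compares is the frequency-modulation shape. Two units
match if their distance is ≤ 0.22. This threshold was calibrated once on
the generator: same-prototype pairs under the jitter conditions used in the
robustness experiments lie below ≈ 0.11, while the generator guarantees
distinct prototypes at least 0.45 apart, so the threshold sits in a wide
margin. A dynamic-time-warping metric is available (`MatchParams(metric=
"dtw")`) for data with local tempo variation. Catalogue construction is
two-pass — grow greedily, then re-inspect every unit against the completed
catalogue — mirroring the second inspection pass of catalogue-based field
protocols; ties go to the earliest-created entry.

## Contour extraction

Spectrograms use a Hann window with 50 % overlap and no edge padding;
512- and 1024-point transforms are supported (93.75 Hz bins at the 96 kHz
default rate, comparable to the ~135 Hz resolution typical of survey
analyses). Analyses are restricted to a 2–22 kHz band so sessions recorded
at 44 kHz remain comparable.

Ridge tracking is deterministic: per frame, spectral peaks at least 10 dB
above the in-band median noise floor are kept (peaks more than 25 dB below
the frame's strongest peak are discarded as Hann sidelobe leakage, which
sits ~31 dB down), refined by parabolic interpolation, and linked to active
tracks by nearest distance to the track's linearly extrapolated frequency.
The default association tolerance is 6 frequency bins per frame (~105 kHz/s
at the default grid) — wide enough for the steep sweep segments of highly
modulated whistles — growing linearly across dropout gaps of up to 3 frames;
tracks shorter than 0.1 s are dropped. Tolerances this loose are safe
because candidate peaks are sparse after thresholding and sidelobe
rejection.

Grades operationalise the three-level quality scale via contour SNR
(dB of the median ridge magnitude over the noise floor) and ridge coverage:
grade 3 at SNR > 20 dB and coverage ≥ 95 %, grade 2 at SNR > 10 dB and
coverage ≥ 90 %, else grade 1 (discarded). The published scale is
qualitative; these cut-offs are package defaults, configuration-exposed,
and chosen so the grade is monotone in rendered SNR on synthetic audio.

## Feature measurement

The seven parameters are measured over the whole unit: frequency extrema
across all loops, start/end from the first/last contour sample, duration
from first-loop start to last-loop end (silent inter-loop gaps included).
Inflection points are sign changes of the first difference of a 5-point
moving-average-smoothed trajectory, with zero-slope runs ignored (a plateau
is not an inflection) and counted within loops, then summed — the silent
gap between loops is not a slope change. Per-loop measurement is available
as an option.

## Statistical chain

- **Per-SW means → fourth root → Bray–Curtis.** d(x,y) = Σ|x′−y′|/Σ(x′+y′)
  with x′ = x^¼; an all-zero pair is defined as distance 0 with a warning.
- **nMDS**: non-metric MDS on the precomputed matrix, best of 50 random
  restarts (seeded), Kruskal stress-1 reported; coordinates are rotated to
  principal axes with pinned signs so seeded runs are reproducible up to
  the inherent rotation/reflection indeterminacy.
- **ANOSIM**: R = (r̄_between − r̄_within)/(M/2) on midranked pairwise
  distances, M = n(n−1)/2; one-sided p = (1 + #{R* ≥ R})/(1 + n_perm) with
  999 seeded permutations by default, or exact enumeration of all distinct
  label assignments for small n. Groups of size 1 are rejected by name.
- **PCA** on the correlation matrix (the seven parameters mix Hz, s and
  counts, so covariance PCA would be scale-dominated); components with
  eigenvalue ≥ 1 are retained (Kaiser). Eigenvector signs are pinned
  (largest-magnitude loading positive); `orient_components` re-pins them to
  any reporting convention, since eigenvector sign is arbitrary. Before
  PCA, rows with |robust z| > 3 (median/MAD) on any raw parameter are
  dropped and logged — a transparent default for the usual "outliers
  removed" step.
- **Mixed models**: `PC ~ factor + (1 | SW-ID)`, Gaussian, REML via
  statsmodels MixedLM (L-BFGS with Powell/CG fallbacks). Wald t-tests use
  containment denominator DF: a term constant within every SW-ID is tested
  with DF = Q − 1 − p_between (Q = number of SW-IDs); the intercept and any
  within-group term use DF = N − Q − p_within. This reproduces the DF
  pattern of nlme's `lme` for this design. A near-zero random-intercept
  variance is flagged as a boundary fit, not an error. Residual diagnostics
  (mean residual, Shapiro normality on a subsample, |residual|-vs-fitted
  rank correlation) are attached to each fit.
- **Site clustering**: sea bottom = Ward linkage on habitat-presence
  indicators plus depth; demography = complete linkage on the six
  demographic variables (mean and range of population size, mean and range
  of group size, residency, connection). Numeric columns are standardised
  and categorical ones encoded 0/1 before Euclidean distances; cluster
  labels are renumbered by first appearance so results are deterministic.
  On the bundled six-site metadata table the sea-bottom cut at three
  clusters and the demography cut at four reproduce the groupings the
  factors are meant to encode. Encoding population-size confidence bounds
  as separate columns instead of a single range changes the demography
  partition — the clustering is sensitive to this choice, which is why the
  six-variable encoding is the default.

## Synthetic-data generator

Prototypes are piecewise-quadratic frequency trajectories
f(u) = f₀ + (f₁−f₀)u + c·u(1−u) per segment, rising from their minimum to
their maximum through an even number (0/2/4) of slope sign changes, so
min ≡ start and max ≡ end — a deliberate simplification matching the
predominantly rising contour types of the study system that keeps all seven
parameters in closed form. Within each monotone run, two random interior
knots and free random timing give shape variety (slow–fast–slow rises,
plateaux, multi-humped contours); a per-segment duration floor caps the
sweep rate at 80 kHz/s (a physiological rate that also keeps ridges
traceable). Candidate prototypes closer than 0.45 in shape distance to an
accepted one are redrawn, so identities are mutually distinguishable —
signature whistles are distinctive by definition. This rejection step
biases the realised inflection-count mix slightly toward modulated
contours.

Baseline parameter distributions (chosen as field-realistic): minimum
frequency ~ N(5.5 kHz, 0.7 kHz), maximum ~ N(13.5 kHz, 0.9 kHz) (≥ 2 kHz
above the minimum), duration ~ N(0.9 s, 0.18 s) (≥ 0.3 s; duration floors
may lengthen extreme draws slightly), inflection counts {0, 2, 4} with
probabilities {0.30, 0.50, 0.20}, 1–3 loops with 0.08–0.22 s inter-loop
gaps (loop counts are a free generator parameter, not an empirical claim).
Factor effects are additive shifts applied through the generative
parameters — min/start shifts move the contour floor, max/end/range shifts
the ceiling — plus identity-level random intercepts and per-emission
residuals (whole-contour frequency offset, duration rescaling, optional
white per-sample roughness).

Sessions lay out per-identity emission blocks separated by > 10 s so one
identity's bout structure cannot affect another's classification. The
patterns are: "sw" (≥ 4 units, 1.5–8 s gaps — satisfies both rules), "rewt"
(either ≤ 3 units at 1.5–8 s, failing the minimum of four, or ≥ 4 units at
0.3–0.8 s, repeated but with 0 % in the 1–10 s window), "sparse"
(25–40 s gaps, failing the repeated-element rule) and one-off variant
whistles. Ground-truth labels are re-derived from the schedule alone by an
independent rule checker, never copied from the generator's intent.

Audio rendering sums frequency-modulated sine tones (phase = 2π∫f dt, 5 ms
cosine ramps) in white Gaussian noise scaled so that
20·log₁₀(tonal RMS / in-band noise RMS) equals the requested SNR, at a
96 kHz default rate.

What the generator does **not** emulate: harmonics, propagation and
attenuation physics, vessel noise, overlapping simultaneous whistlers,
graded intermediate contour types, introductory/terminal loops distinct
from the central pattern, and emitter movement. Passing the validation
suite therefore shows the algorithms implement the stated rules correctly
and recover known structure under realistic noise — not that extraction
would match expert annotation on sea recordings.

## Validation experiment sizes

Problem sizes were chosen to give the statistics useful resolution at desk
scale: 1000 random sessions (≤ 20 units) for the classifier/brute-force
sweep; 100 sessions for recovery (noise-free, and with 150 Hz emission
offsets, 0.04 s duration jitter, 60 Hz roughness); 1000 null datasets for
ANOSIM size (199 permutations each; nominal level exactly 10/200 = 0.05);
200 recovery and 800 null replicates of the 150-identity × 12-observation
mixed-model design; 50 replicates each for the end-to-end detection power
and false-positive experiments, at 30 identities per site so a one-SD
(700 Hz) shift on min/start frequency is detected with high power on the
min/start-aligned component.

## Known limitations

- The ridge tracker assumes at most a handful of concurrent tonal sources
  and no harmonic stacking; it selects fundamentals only by band limiting.
- The shape distance normalises away absolute frequency and duration, so
  two whistles differing *only* in register or tempo are treated as the
  same type; the generator's distinctness margin makes this unambiguous in
  simulation, but real catalogues may need the DTW metric or a lower
  threshold.
- Containment DF are exact for the balanced group-constant-factor designs
  used here; for heavily unbalanced designs a Satterthwaite/Kenward-Roger
  approximation would differ.
- The grade thresholds and the outlier rule are operational defaults, not
  estimates of any annotator's behaviour.
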