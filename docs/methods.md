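# Methods

## Scope and data model

`strainpost` post-processes time-sampled myocardial deformation curves; it
does not perform speckle tracking. A study is a set of `StrainTrace`s (one
per chamber/view; strain in %, strain rate in 1/s, time in ms with t = 0 at
the first QRS onset of the selected beat), an optional co-registered ECG,
and an `EventTiming` holding the four valve events and three ECG landmarks
of that beat. Left-ventricular analysis uses the AHA 18-segment model
(basal/mid/apical of two walls per apical view: inferoseptal + anterolateral
in the 4-chamber, anteroseptal + inferolateral in the 3-chamber, inferior +
anterior in the 2-chamber view).

## Trace dialect

Vendors' raw-data exports are plain text but not standardized, so the
package defines its own canonical dialect (tab-separated, header row,
`time_ms` first, `.` decimals, `#` metadata lines) and a tolerant reader for
the variations seen in practice (decimal commas, arbitrary whitespace,
reordered columns, `time_s`). Parsing is strict about data integrity: ragged
rows, non-numeric fields and non-monotone time are hard errors, not repairs.
The writer emits 10 significant digits, making read∘write value-exact.
Traces with exactly 18 or 6 segments are typed `AHA18`/`SIX`; other counts
are accepted as `FREE` for ad-hoc work, but GLS requires `AHA18`.

## View merging

Heart rate drifts between the three apical acquisitions, so their beats
differ in length. The 4-chamber recording is the time standard; each other
view's times are scaled by the ratio of cycle lengths (a pure linear
rescaling — the minimal defensible model absent beat-by-beat registration)
and its curves resampled onto the reference grid by linear interpolation. A
cycle-length ratio outside [0.5, 2] is rejected as a wrong-cycle selection.
When all cycle lengths are equal the merge is the identity up to
interpolation roundoff.

## Phase segmentation

The six phases are fixed by the named events in physiological order
(QRS₁ → MVC → AVO → AVC → MVO → P onset → QRS₂), with half-open intervals
[start, end) so every instant belongs to exactly one phase and durations sum
exactly to the RR interval. `qrs1 = mvc` is allowed as a degenerate
electromechanical-coupling phase; all later orderings are strict. The E/A
boundary is placed at P-wave onset — the only intra-diastolic ECG landmark
collected — so diastasis is merged into E. Landmark times come from a config
file or CLI flags rather than interactive clicks, for non-interactive
reproducibility; `validate_landmarks` checks ordering and that marks lie
inside the ECG span. A quality-control helper flags exams whose repeated
event registrations disagree by more than 10 ms (the exclusion rule used
when curating the packaged validation set).

## Peak detection and GLS

The systolic search window runs from the first QRS onset to aortic valve
closure, the sample nearest each boundary included (the boundary convention
is not standardized; nearest-sample inclusion makes the window well defined
on any grid). Peaks are taken on the sample grid — no sub-sample
interpolation and no smoothing or manual adjustment. `window_min` returns
the most negative sample (earliest tie wins; on exclusively positive curves
the least positive sample — the rule never switches sign). `echopac_75`
selects the positive extreme P when P > 0.75·|N| with N the negative
extreme, strict inequality, else N; windows with no negative samples yield
P. GLS is the unweighted arithmetic mean of the 18 segmental peaks;
excluding more than two segments sets a quality flag on the result rather
than silently proceeding. Strain rate is obtained by central divided
differences of fractional strain against time in seconds (one-sided at the
ends), exact for linear ramps and O(h²) on smooth curves; optional smoothing
is deliberately not applied by default.

## Agreement battery

Shapiro-Wilk (scipy's implementation of the standard approximation, valid
for 3 ≤ n ≤ 5000) and a Q-Q construction with plotting positions
(i − 0.5)/n and a reference line through the first/third-quartile points
(R's `qqnorm`/`qqline` convention, verified against R in the tests) assess
normality at α = 0.05. The correlation gate uses Pearson only when *both*
marginals pass; the location gate uses the paired t-test only when the
differences pass, else Wilcoxon signed-rank with zeros dropped, the exact
null for ≤ 25 nonzero differences and the continuity-corrected normal
approximation above (matching R's defaults when driven with the same
switches). Bland-Altman: bias = mean(a − b), SD with n − 1 denominator,
limits of agreement bias ± 1.96·SD. "Dispersion" is defined here as the
limits-of-agreement half-width 1.96·SD; the raw SD is also reported so
either reading can be checked. The equivalence verdict requires
r ≥ 0.95 (coefficient rounded to 2 decimals, full precision kept
internally), p > 0.05, |bias| ≤ 1 and dispersion ≤ 2 (absolute thresholds
in percentage points, since GLS is negative-signed). Identical series are
reported as equivalent with a degenerate-test warning (p = 1) rather than
an error.

## Packaged validation fixture

`load_gls_validation_pairs()` ships 48 paired GLS values (EchoPAC reference
vs. an open post-processing chain) transcribed from a published comparison.
One row (subject 19) is typographically garbled in the source: as printed it
implies a 2.8-point outlier under which the differences fail Shapiro-Wilk —
contradicting the source's own reported normality, paired-t p-value and
correlation. The default `"printed"` variant keeps the row verbatim; the
`"published"` variant applies the minimal one-digit repair (candidate value
−19.68 instead of −16.68; reading the reference as −16.50 gives identical
differences), under which the published statistics are reproduced (Spearman
r = 0.99 at 2 dp, differences normal, paired-t p = 0.674 vs. 0.6798
reported). Both variants satisfy all four equivalence criteria.

## Synthetic generator

`generate_strain_cycle` builds per-segment curves as chains of cosine-eased
segments joined at phase boundaries: zero at QRS₁, an optional positive
early-systolic bulge peaking at AVO (the dyssynchronous "stretch" pattern),
monotone descent to the prescribed peak at 75 % of ejection (snapped onto
the sample grid so the target is attained by a sample), recovery through
IVR/E, a small atrial deflection, return to 0 at QRS₂. Extrema of a cosine
chain sit exactly on its nodes, so with zero noise the window minimum equals
the prescribed peak for every segment. Defaults: an 850-ms resting cycle
(EMC 30, IVC 50, ejection 300, IVR 80, E 240, A 150 ms), healthy-range
peaks around −22 %, 10-ms sampling (speckle-tracking frame rates of 50–90 Hz
give 11–20 ms), additive white Gaussian noise with a fixed seed. The
schematic ECG has impulse-like QRS deflections at both onsets and a broad
P bump. `generate_paired_gls` draws a ~ N(μ, spread²), b = a − bias +
N(0, sd²), so the true Bland-Altman bias and dispersion are exactly `bias`
and 1.96·`sd`.

What the generator does *not* emulate: speckle-tracking drift and temporal
correlation of tracking noise, segment dropout, beat-to-beat variability,
pathological morphologies beyond the early-stretch bulge. Tests passing on
this material therefore establish the correctness of the arithmetic and the
gating logic, not clinical robustness.

### A note on peak detection under additive white noise

The window-minimum statistic is downward-biased on noisy curves: any smooth
curve has zero slope at its extremum, so with k window samples competing
within the noise the expected detected minimum is roughly the true peak
minus σ·√(2 ln k). At σ = 0.5 % and ~30 window samples this bias is
≈ 0.8 %, which the 18-segment average does not reduce (it removes variance,
not bias). Recovering the prescribed peak to better than ~0.5 % under such
noise would require pre-smoothing matched to the noise model; since real
exports are already smoothed by the tracking algorithm and the package
deliberately detects peaks on the raw samples, no such filter is applied,
and noisy-input recovery should be judged against this bias floor.

## Problem sizes

The shipped checks use 1000 random event sets for the partition property,
100 random curves per peak rule, 100 paired samples for the R cross-check,
50 seeds for noisy GLS recovery and n = 10 000 pairs for Bland-Altman
parameter recovery (Monte-Carlo SE of the bias 0.007 at sd 0.7) — sizes at
which every Monte-Carlo margin is a small fraction of the tolerance it
guards.

## Known limitations

Interactive landmark marking is intentionally replaced by config input; no
automatic QRS/P detection is attempted. Radial/circumferential/twist strain,
Doppler-derived parameters, post-systolic indices and atrial
reservoir/conduit/booster decomposition are out of scope. Confidence
intervals for the limits of agreement and proportional-bias (regression)
agreement are not computed.
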