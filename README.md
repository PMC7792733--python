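# strainpost

Post-processing of speckle-tracking echocardiography deformation curves:
cardiac-cycle phase segmentation, peak systolic strain, Global Longitudinal
Strain (GLS), and the paired method-agreement statistics used to validate one
measurement chain against another.

## Who this is for

Proprietary speckle-tracking packages (EchoPAC and peers) compute strain from
image loops but expose a fixed set of derived parameters. Research groups that
need more — phase-resolved analysis, cross-chamber comparisons, alternative
peak definitions — work instead from the *raw-data* trace exports those
packages write as plain text. `strainpost` is a library (plus a thin CLI) for
that post-processing step: it never touches images; time-sampled strain /
strain-rate curves per myocardial segment, with a co-registered ECG, are its
inputs.

## The science in brief

**Phase segmentation.** One beat runs from a QRS onset to the next. The four
valve events — mitral closure (MVC), aortic opening (AVO), aortic closure
(AVC), mitral opening (MVO) — and the P-wave onset split it into six
mechanical phases, in order: EMC (electromechanical coupling, QRS→MVC), IVC
(isovolumic contraction, MVC→AVO), Ejec (ejection, AVO→AVC), IVR (isovolumic
relaxation, AVC→MVO), E (early filling, MVO→P onset), A (atrial contraction,
P onset→QRS₂). Intervals are half-open, so the six durations always sum
exactly to the RR interval.

**Peak systolic strain, two rules.** For each segment the peak is sought in
the window from QRS onset to AVC:

* `window_min` — the most negative sample (the least positive one if the
  curve never goes negative);
* `echopac_75` — EchoPAC's rule: with N the most negative and P the most
  positive sample, P is selected when P > 0.75·|N|, otherwise N.

The rules disagree exactly on curves with a prominent positive systolic
peak — the early-stretch signature of left-bundle-branch-block dyssynchrony.

**GLS** is the arithmetic mean of the 18 segmental peaks of the left
ventricle (AHA 18-segment model, six segments per apical view; the 4-chamber
recording is the time standard and the other two views are linearly rescaled
onto its beat).

**Method agreement.** Two paired series a (reference) and b (candidate) are
compared with a normality-gated battery: Shapiro-Wilk + Q-Q on a, b and
d = a − b; Pearson correlation if both marginals are normal, else Spearman;
paired t-test if d is normal, else Wilcoxon signed-rank; Bland-Altman bias
= mean(d) and limits of agreement bias ± 1.96·SD(d). Equivalence requires
r ≥ 0.95, test p > 0.05, |bias| ≤ 1 % and dispersion (1.96·SD, the
limits-of-agreement half-width) ≤ 2 %.

The package ships a 48-subject paired GLS validation set (EchoPAC vs. an open
post-processing chain, transcribed from a published comparison) as
`load_gls_validation_pairs()`.

## Worked example

```bash
python examples/method_agreement.py
```

prints (abridged):

```
n: 48
normal_a: False (W=0.9281, p=0.005812)
normal_b: False (W=0.9314, p=0.007686)
correlation_method: spearman
r: 0.99
p_value: 0.3833
bias: -0.0979
dispersion: 1.3816
equivalent: True
```

Both marginals fail Shapiro-Wilk, so Spearman is used: r = 0.99 is a strong
monotone agreement. The location test keeps the null of zero mean difference
(p = 0.38 > 0.05). The candidate reads GLS 0.10 percentage points more
negative than the reference on average (bias), with 95 % of paired
differences inside ±1.38 points (dispersion) — within the 1 % / 2 % clinical
margins, so the two chains are equivalent for GLS.

Other narrative examples: `examples/segment_cycle_phases.py` (phase table),
`examples/peak_rules_dyssynchrony.py` (where the two peak rules diverge),
`examples/gls_from_study.py` (file round-trip → view merge → GLS).

## Command line

```bash
strainpost simulate --out study/ --with-rv          # synthetic study files
strainpost run --traces-dir study/ --events study/events.yaml \
    --landmarks study/landmarks.yaml --option 4 --rule min --out results/
strainpost validate --out figures/                  # packaged 48-pair battery
```

`run` mirrors the interactive tools' flow: read → merge views → validate
landmarks → segment phases → peaks/GLS → terminal report + figure with
MVC/AVO/AVC/MVO markers. View options 1-6 choose the displayed panels;
option 6 processes simulated model output that has no ECG (no phase
segmentation; peaks over the whole trace, flagged unphased).

## Trace file dialect

Tab-separated text, `#`-prefixed `key: value` metadata (chamber, view,
quantity), a `time_ms` column (t = 0 at the first QRS onset), one column per
segment (strain in %, strain rate in 1/s), optional `ecg` column. The
tolerant reader additionally accepts decimal commas, whitespace delimiters
and reordered columns. `write_trace_export` emits the dialect with enough
digits that a read/write round-trip is value-exact.

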