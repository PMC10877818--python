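# Methods

## Scope and data model

The package analyses daily LH measurements from two channels per menstrual
cycle: urine (analyte LH, normalizer creatinine) and vaginal discharge
(analyte LH, normalizer total extract protein). All day indices are 1-based
cycle days counted from the first day of menstruation; collection covers
days 10–19 by default. Inputs are already concentrations — standard-curve
fitting from raw absorbances is out of scope.

## Preprocessing

* **LOD.** Limit of detection per assay by the 3σ method:
  mean(blanks) + 3·SD(blanks), with the *sample* SD (n−1 denominator; the
  method's usual convention, configurable in `compute_lod` only through the
  blanks supplied). At least two blanks are required.
* **Censoring.** "Below the LOD" is strict (<): a value equal to the LOD
  passes unchanged. Censored values are replaced by the LOD itself, which
  keeps ratios positive and is idempotent.
* **QC.** A day is a *failed collection* iff **both** the analyte and its
  normalizer read below LOD; only the analyte below LOD is fine (it is
  substituted). Failed and absent days are unobserved downstream; nothing
  is imputed or interpolated.
* **Normalization.** value = censored analyte ÷ censored normalizer
  (mIU/mg). A zero normalizer is only possible with LOD = 0 and raises an
  error naming the day.

## Surge calling

* **Peak maximum**: observed day with the largest value; ties break to the
  earliest day (deterministic and reproducible; ties are knife-edge cases
  with no principled winner).
* **Baseline**: mean of the observed values among the four days
  {peak−2, peak−1, peak+1, peak+2}, excluding the peak day. At the window
  edge or with missing days the mean degrades gracefully to whichever of
  the four are observed; with none observed the cycle is uncallable and is
  reported as pattern `none` with flag `baseline_undetermined`.
* **Elevated day**: excess over baseline strictly greater than 30% of the
  peak's excess, and value strictly greater than twice the baseline.
  "Amplitude" is read as height above baseline (`excess` convention): the
  second rule already anchors to baseline, and amplitude conventionally
  means height above it. The alternative reading — 30% of the raw maximum
  value — is available via `amplitude_convention="raw"`.
* **Pattern**: runs of elevated days contiguous in the sequence of
  *observed* days (missing days do not split a run; splitting requires an
  observed, non-elevated day). One 1-day run → sharp single; one ≥2-day
  run → broad single; ≥2 runs → multiple.
* **Ovulation day** (urine only): day after the last elevated day across
  all runs. It may fall one day past the collection window (elevated on
  day 19 → ovulation day 20); this is allowed and flagged
  `ovulation_beyond_window`.
* **First surge day**: earliest elevated day across all runs — the day a
  daily home test would first read positive.
* **Fertile window**: the 6 days [ovulation−5, ovulation].

A known structural property of the literal baseline rule: a contiguous
elevated run of width ≥3 can never satisfy the 2×-baseline condition on all
its days, because two run members always fall among the four flanking days
of the peak and inflate the baseline beyond what either member can double.
The rule therefore caps recoverable plateaus at two days; this shapes the
generator defaults below. For broad peaks generally, elevated flanks
inflate the baseline; the rule is applied literally, with no iteration or
re-estimation.

## Evaluation

* **Concordance**: per-cycle offset = first vLH surge day − ovulation day,
  bucketed at −5…0 ("within the fertile window") plus `others` (anything
  earlier or later). Percentages are integer round-half-up; raw counts
  always sum exactly to the total, so the percentage column may differ from
  100 by at most one unit per row.
* **t-test**: classical pooled-variance Student's *t* (the package's
  default; Welch by flag), two-sided, df = n₁+n₂−2. Zero pooled variance
  maps to t=0, p=1 for equal means, ±∞ with p→0 and a warning otherwise.
* **ROC**: positivity at value ≥ threshold, thresholds swept over all
  observed values; AUC by trapezoid, which on this construction equals the
  Mann–Whitney exceedance probability (ties counted half) — an identity the
  tests verify against direct pair counting.
* **Youden cutoff**: maximizes J = sensitivity + specificity − 1; ties
  resolve to the *lower* cutoff (higher sensitivity, matching home-test
  intent). All five metrics (sensitivity, specificity, PPV, NPV, accuracy)
  derive from the single confusion matrix at that cutoff; an undefined
  metric (zero denominator) is reported as 0 with a warning.
* **Groups**: one baseline value and one first-surge value per eligible
  cycle, taken from the vaginal-discharge channel: the baseline from the
  cycle's own flank-mean, the surge value from the series at the first
  surge day.
* **Exclusion funnel**: cycles drop in order — no uLH surge, then no usable
  VD data (no observed VD day), then no vLH surge — mirroring the staged
  exclusions of a real cohort; every exclusion is logged with its reason.
* A note on the derived reference confusion matrix TP=25, FN=4, TN=24,
  FP=5 (n=29 per group): it reproduces sensitivity 86%, specificity 83%,
  PPV 83%, NPV 86% under round-half-up, but its accuracy is 49/58 = 84.5%,
  which rounds to 84% — one point below the 85% sometimes quoted alongside
  those four values. The package reports accuracy as computed from the
  matrix and does not force agreement.

## Synthetic-cohort generator

The generator emulates a daily-collection study: 35 participants, 55
cycles (20 participants contribute two cycles), cycle length normal with
mean 30 and SD 2.4 days clipped to 25–38, collection on days 10–19.
Per cycle it draws:

* a urinary baseline (lognormal, mean 1.0 mIU/mg, CV 0.2) and surge
  amplitude (lognormal, mean 8.0, CV 0.25) — illustrative values; real LH
  distributions for these channels are not published. The amplitude is
  floored at 5.5× the cycle's baseline so that every surge, including
  secondary peaks at 40–80% relative amplitude, satisfies both calling
  rules at zero noise (0.4 · 5.5 = 2.2 > 2): the generator's truth is then
  recoverable by construction. Real urinary surges are ~10-fold, so the
  floor is physiologically mild.
* a pattern: sharp single (0.6), broad single (0.2), multiple (0.2) —
  sharp is the common morphology; broad and multiple are recognised but
  uncommon variants. The broad plateau is 2 days by default (the widest
  plateau the calling rules can recover, per the structural property
  above) with a 0.1% per-day downward tilt so the peak-maximum day is not
  left to float rounding. Multiple-peak cycles place 1 weak secondary peak
  (40–80% amplitude) 2–4 days *before* the primary, as weak premonitory
  peaks are what the morphology describes; gaps are constrained to fit the
  window, so the drawn pattern is always realized.
* a vLH lag on −4…+4 days, weighted toward the vLH surge leading
  (probabilities 0.24/0.14/0.07/0.28/0.10 at −4…0; 0.17 spread over +1…+4),
  shaped to produce a mostly-within-window offset distribution; the vLH
  channel has its own baseline (mean 0.05 mIU/mg) and amplitude
  (mean 0.4 mIU/mg) so the Youden cutoff lands on the ~0.1 mIU/mg scale.
* per-day multiplicative lognormal noise (CV 0.1 — typical immunoassay
  precision), per-day normalizer draws (creatinine mean 1.0 mg/mL, protein
  mean 0.5 mg/mL, CV 0.3), missing days (p 0.02) and per-channel failed
  collections (p 0.02, emitted as sub-LOD analyte+normalizer pairs).

**Truth semantics.** Urinary truth is the template itself: elevated days,
ovulation = last elevated + 1, pattern. The zero-noise closure invariant —
the calling rules recover this truth exactly, cycle by cycle — is asserted
in the tests on both channels. Vaginal truth is what the rules recover from
the *noise-free shifted template*: a lag can push surge days out of the
collection window, and a broad run pressed against the window edge leaves
too few clean flanks to establish a baseline; both yield realistic
partially- or wholly-unrecoverable vLH cycles (flagged `truncated_v`),
mirroring real cohorts' "no discernible peak" exclusions.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no endocrine dynamics (no estrogen/FSH/
progesterone feedback, no luteinized unruptured follicles), no
within-participant correlation across cycles, no day-to-day autocorrelated
baseline drift, and baseline/surge separation far cleaner than real
discharge assays achieve (the synthetic default yields AUC ≈ 1.0, which no
real mucus-based assay would). Concordance and recovery results transfer as
*algorithm* checks, not as estimates of real-world diagnostic performance.

## Determinism and numerics

* All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical config + seed reproduces cohorts
  bit-identically, and the CLI's staged and all-in-one runs produce
  byte-identical CSV/JSON (CSV floats are re-read with round-trip parsing,
  as the default parser can be off by 1 ulp).
* All rule comparisons are strict, matching "greater than" readings;
  rounding of percentages is half-up.
* Problem sizes: the analysis scripts and acceptance runs use the 55-cycle
  study scale; recovery checks use 200-cycle cohorts (exact at zero noise,
  ≥95% within ±1 day at CV 0.1); identity checks (AUC vs Mann–Whitney,
  Youden vs exhaustive scan, rule calls vs brute force) use 1,000 random
  small instances each.

## Limitations

* Thresholds (30%, 2×) are taken as given, not re-optimized; no smoothing,
  detrending or model-based peak fitting.
* No confidence intervals on AUC or the derived metrics, and no
  cross-validation of the Youden cutoff.
* LOD values are user inputs (blank panels are assay-specific); the
  generator's LODs are illustrative.
* The fertile-window definition (5 days before ovulation + ovulation day)
  and the ovulation rule (day after last elevated day) are conventions;
  no ultrasound-style gold standard exists in the data model.
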