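# Methods

`gazesim` implements the analysis chain of a directed-forgetting
eye-tracking study: scanpath-similarity scoring, four similarity designs
back-sorted by subsequent memory, skin-conductance response (SCR)
extraction and reduction, and the repeated-measures statistics — plus a
synthetic-study generator with known ground truth so the whole chain can
be validated end to end without access to participant data.

## Scanpath similarity

A scanpath (the ordered fixation sequence of one viewing episode) is
recoded into a symbol string in two steps:

1. **Spatial binning.** The 1024 x 768 px stimulus is partitioned into a
   12 x 8 region-of-interest grid (bins ~85 x 96 px). Each fixation maps
   to the row-major index of its bin; off-stimulus fixations clip to the
   nearest edge bin rather than being dropped, preserving the sequence's
   temporal structure. Coordinates are stimulus-frame, origin top-left,
   after subtracting the configured screen offsets (default: a centered
   stimulus on a 1920 x 1080 display, offsets 448 / 156 px; the true
   placement is configurable because only the display geometry, not the
   placement, is fixed by the hardware).
2. **Temporal binning.** Each fixation contributes
   `max(1, round(duration / 50 ms))` repeats of its bin symbol. The
   `max(1, .)` floor keeps very short fixations represented. A cap of
   200 symbols (3000 ms viewing / 50 ms bin = 60 typical) bounds cost on
   pathological inputs.

Two encoded sequences are compared by Needleman–Wunsch global alignment
(score-only dynamic program, numba-jitted) under the substitution matrix

    s(a, b) = T − d(a, b),

where `d` is the Euclidean distance between bin centers in bin units and
`T = 4` is the substitution threshold: identical bins score `T`, bins
exactly `T` apart score 0, more distant bins score negatively, so the
aligner only profits from aligning regions at most 4 bins apart. The gap
penalty is 0. The threshold can alternatively be derived from the data as
twice the sample SD of saccade amplitudes expressed in horizontal-bin
units; the analysis default is the fixed value 4.

The similarity score is `raw / (T * max(|A|, |B|))`, clipped to [0, 1]:
the denominator is the best attainable score, so an identical pair scores
exactly 1, and with gap penalty 0 the raw score is never negative. The
exact substitution form and normalization are design choices (the
convention of the standard scanpath-comparison toolbox); both are
config-exposed rather than hard-coded assumptions.

## Similarity designs

Studied trials carry a motivation cue (remember / control / forget) and a
recognition outcome (hit / miss). Four measures are computed per trial
and reduced to unweighted per-participant cell means for the 3 x 2
within-subject design:

* `enc_test` — encoding scanpath vs. the same image's test scanpath.
* `enc_reg` — encoding scanpath vs. the immediately following blurred
  image's regulation scanpath.
* `global_enc_reg` / `global_enc_enc` — for each hit (miss), the mean
  similarity of its encoding scanpath to the regulation (encoding)
  scanpaths of all *other* hits (misses); the same-trial pair is always
  excluded, and an outcome class needs at least 2 trials.

Global comparisons pool partners across motivation cues, and each
per-trial global score is averaged into the cell of its own trial's cue:
this is the only reading that both honors "all other hits (misses)" and
fills all six design cells. A `global_within_motivation` switch restricts
partners to the same cue for sensitivity analyses. Per-trial global
scores are arithmetic means over comparisons, so every source trial
contributes equally to its cell. Empty cells are flagged, never imputed.

## Exclusion cascade

Applied in order, each removal logged once with a rule id:

1. any phase-record with fewer than 3 fixations is dropped (strict
   "less than"; each phase-record judged independently, so a trial's
   encoding record survives the loss of its regulation record);
2. participants losing more than 20% (strict) of their regulation-phase
   records are excluded entirely from gaze analyses;
3. per measure, participants with an empty motivation x outcome cell are
   excluded from that measure's ANOVA only.

The cascade is idempotent. Whether encoding records of
regulation-excluded trials feed the global measures is configurable
(default: they do, since the removal rule is tied specifically to the
regulation phase).

## SCR extraction and reduction

The per-trial amplitude is the maximal increase in conductance 1–5 s
after stimulus onset, implemented as the largest trough-to-peak rise in
the window: `max_t (s(t) − min_{t' ≤ t} s(t'))`. This is non-negative,
shift-invariant and robust to slow drift; because the window baseline is
not uniquely defined by "maximal increase", an alternative
(`onset_value`: window max minus the conductance at stimulus onset) is
config-exposed. Reduction is a single pass in fixed order:

1. z-score amplitudes within (participant, phase, block), blocks being
   the pre/post-break halves of the trial sequence (sample SD; a
   zero-variance block leaves z undefined and falls through to step 3);
2. drop trials with |z| > 5, and movement-annotated trials with z
   strictly > 0 (a movement trial with z ≤ 0 is kept);
3. nonresponder check on what remains: a block with amplitude SD below
   0.01 µS is dropped; if both blocks of a phase qualify, the
   participant's SCR data for that phase are dropped. A block with fewer
   than two retained trials has no defined SD and is treated as
   nonresponsive.

Raw amplitudes (never z-scores) enter the ANOVAs; the z-scores exist only
to identify removable trials, and no re-standardization follows
filtering. Movement flags are taken from the events annotation file; no
detection from the trace is attempted.

## Statistics

* **3 x 2 within-subject ANOVA** (pingouin backend) for each similarity
  measure and SCR phase; a one-way version for recognition rates.
  Mauchly's test is run for every effect with more than one numerator
  df (the 3-level factor on its marginals; the interaction on the
  hit−miss difference scores); when it rejects at .05 the
  Greenhouse–Geisser corrected p is reported with its epsilon
  (`gg_always` forces the correction).
* **Post hocs**: the three motivation contrasts as two-sided paired
  t-tests on marginal means, Bonferroni multiplier fixed at 3; the
  2-level accuracy factor needs none.
* **Effect sizes**: Cohen's `f = sqrt(df1·F/df2)` and `d = t/sqrt(n)`.
  Confidence intervals on effect sizes are not computed.
* **Power**: two-sided paired-t power from the noncentral t distribution
  (df = n−1, noncentrality d·sqrt(n)).
* **Bayes factors**: JZS BF10 for t-tests, i.e. the marginal likelihood
  of t under a Cauchy(0, sqrt(2)/2) prior on the standardized effect
  size over its point-null likelihood, by adaptive quadrature (relative
  tolerance 1e−8; an integration failure raises with diagnostics rather
  than returning a value). Model-averaged ANOVA-level Bayes factors
  (inclusion/exclusion) are out of scope; the report marks them "not
  computed".

## Synthetic-data generator

The generator emulates the study design: 36 participants, 90 studied
trials each (30 per cue) plus 90 foils, 3000 ms viewing per phase,
fixation durations ~ N(250, 80) ms truncated at 60 ms drawn as a renewal
sequence that fills the viewing time (~12 fixations per record), and
fixation locations from an isotropic central-bias Gaussian (SD 150 px)
clipped to the stimulus — a template + central-bias mixture rather than
any image-saliency model, since the analyses depend only on similarity
structure:

* **Interference**: with probability .4 a trial's encoding scanpath is
  the participant-level template (24 locations, cycled as needed) plus
  40 px jitter; template trials get a +2 log-odds push toward miss
  outcomes on top of per-cue base hit rates .70/.60/.59. Misses thus
  share gaze structure, so global encoding-encoding (and
  encoding-regulation) similarity is higher for misses — the
  across-stimulus interference pattern.
* **Reinstatement**: each regulation/test fixation is, with probability
  rho, a jittered copy of the positionally corresponding encoding
  fixation; regulation rho varies by cue (.55/.45/.35 for
  remember/control/forget) and test rho by outcome (.60 hits / .30
  misses), producing the motivational modulation of
  encoding-regulation similarity and the encoding-test memory benefit.
* **Degraded records**: 2.3% of phase-records are truncated below 3
  fixations to exercise the exclusion rules at their observed rate.
* **SCR**: 1000 Hz traces, one per participant-phase, as tonic level
  (2 µS) + slow sinusoidal drift (0.05 µS, 120 s period) + per-trial
  bi-exponential bumps (rise 0.75 s, decay 2 s, 1 s onset latency so
  the rise lands inside the 1–5 s scoring window) + white noise
  (SD 0.005 µS). Bump amplitudes are condition means (encoding
  .17/.14 µS for misses/hits; test .12/.09 µS for hits/misses;
  regulation flat .12 µS) plus trial-level jitter (SD 0.08 µS,
  truncated at 0) so ANOVA F statistics are finite and realistic.
  Movement annotations are injected at rate .05. Traces are regenerated
  on demand from per-(participant, phase) child seeds instead of being
  held in memory.

Everything is reproducible from a single seed. What the generator does
*not* emulate: image content and saliency, saccade kinematics, blinks,
pupil size, habituation of SCR amplitudes across blocks, and any
correlation between gaze and SCR beyond their shared outcome labels.
Tests passing on this generator therefore validate the *pipeline* —
encoding, alignment, reduction rules, statistics, and their calibration —
not claims about real gaze behavior.

## Numerical choices and problem sizes

* Alignment DP in float64; sequences as int64 bin indices; the inner
  loop is numba-jitted with a pure-Python fallback.
* Degenerate inputs: empty scanpaths, non-finite coordinates, empty
  sequences, non-positive thresholds and incomplete ANOVA cell tables
  all raise; zero-variance SCR blocks route to the nonresponder check.
* Validation suites use 500 simulated null datasets for ANOVA
  calibration and 100 seeded pipeline runs per condition for effect
  recovery at the full design size (36 participants x 90 trials);
  oracle checks of the aligner enumerate all alignments exhaustively for
  short sequences (all pairs to length 2; a seeded sample to length 4)
  on a 3 x 2 grid.

## Known limitations

* The substitution-score form and normalization mirror the standard
  toolbox defaults; datasets scored with other conventions will differ
  by a monotone rescaling.
* Recognition hit rates produced by the generator sit below the per-cue
  base rates whenever interference is active (template trials are
  pushed toward misses); the base rates describe the no-interference
  margin.
* The SCR model has no habituation, so block-wise standardization is
  exercised but its purpose (removing habituation trends) is not.
* ANOVA-level inclusion Bayes factors and item-level mixed models are
  deliberately out of scope.
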