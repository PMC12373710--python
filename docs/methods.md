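# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mgsms`. It is the place to look when a default needs to be
questioned or a design decision needs to be traced.

## The task and its analysis windows

Each memory-guided saccade (MGS) trial is fixation (1 s), stimulus (300 ms),
memory delay (uniform 1.5–2.5 s), response (1 s). Targets occupy 12
locations, six per eccentricity ring at 6° and 12° of visual angle, each
shown equally often (the generator therefore requires the trial count to be
a multiple of 12). EEG analysis uses a fixed epoch from 500 ms before
stimulus onset to 1.5 s after stimulus offset (2.3 s), tiled by three
half-open intervals: fixation [−0.5, 0), visual [0, 0.3), memory [0.3, 1.8)
relative to stimulus onset. The memory interval is always the *first* 1.5 s
of the delay even when the true delay was longer, so every epoch has the
same geometry. Sample windows are 0-based and half-open; an event time maps
to the first sample at or after it.

## Preprocessing

The order is fixed: band-pass → common average reference → per-channel
z-score → epoching, all at session level.

- **Filter**: Butterworth band-pass 1–30 Hz of final order 6 (scipy
  prototype order 3), applied forward–backward (`sosfiltfilt`). Zero-phase
  filtering is essential here — microstate analysis is about the *timing*
  of topographic switches, and a causal filter would delay them; the cost
  is a squared magnitude response (≈ −6 dB at the band edges).
- **Reference**: subtract the cross-channel mean at every sample. All maps
  downstream are therefore zero-mean across channels, which makes the
  spatial-correlation similarity equal to a Pearson correlation.
- **Normalisation**: per channel over the full session, population SD.
  Session-wide (rather than per-epoch) scoring keeps global field power
  comparable across trials. A zero-variance channel is an error, reported
  by name.

## Microstate segmentation

1. **GFP peaks.** Global field power is the per-sample population SD across
   channels. Peaks are samples with a strict rise and non-rise after
   (`g[i−1] < g[i] ≥ g[i+1]`); a plateau belongs to its first sample,
   endpoints are excluded. Peak maps are pooled across trials and subjects
   into one global map set per dataset.
2. **Outlier screening.** Maps whose L2 norm has robust z
   (|x − median| / (1.4826·MAD)) above 3 are dropped. The scale gets a tiny
   relative floor so ulp-level jitter in identical norms is not read as
   spread. The criterion is deliberately simple; it removes amplitude
   artifacts, not topographic ones.
3. **Clustering.** Plain (polarity-*sensitive*) k-means with K = 8, 50
   restarts, best within-cluster sum of squares kept, centers renormalised
   to unit norm. Clustering the signed maps and merging afterwards — rather
   than polarity-invariant modified k-means — is deliberate: the
   polarity-aware analyses need distinct ± prototypes per class.
4. **Polarity pairing.** The 8 centers are paired greedily by
   most-negative spatial correlation first. A matched pair correlating
   above −0.5 triggers a warning (weak polarity structure).
5. **Canonical labels.** The 4 pairs are assigned to classes A–D by
   Hungarian assignment maximizing mean |correlation| with four template
   maps (A: right-frontal → left-occipital gradient, B: mirrored,
   C: anterior–posterior axis, D: midline frontocentral maximum); within a
   pair, the member positively correlated with its template is "+". A best
   assignment with |corr| < 0.3 warns of ambiguity.
6. **Back-fitting.** Polarity-invariant mode: argmax over the four class
   ("+") maps of |spatial correlation|; polarity-aware mode: argmax of the
   signed correlation over all 8 prototypes. Ties resolve to the lowest
   state index (A < B < C < D, "+" before "−") — a measure-zero event on
   real data, fixed for reproducibility. A zero-norm sample has similarity
   0 to every state and falls to the first state by the same rule.
7. **Temporal smoothing (30 ms).** Iterative short-segment rejection:
   while any interior segment is shorter than the window, the shortest such
   segment (earliest on ties) is removed; its samples are split between the
   two neighbouring segments at the cut point maximizing total similarity,
   so each sample joins the better-fitting neighbour while labels stay
   contiguous. Edge segments are exempt. Each iteration reduces the
   segment count by at least one, so termination is guaranteed, and on exit
   every interior segment spans ≥ the window. The window and the method
   (rejection rather than a regularized fit) are configuration-exposed.

Whether smoothing should precede or follow interval slicing is not
determined by first principles; here it is applied to the whole epoch, so a
state bridging an interval boundary is preserved and then truncated by the
slicer.

## Microstate parameters

For state k inside a window of length T seconds, with n_k segments
totalling T_k seconds: coverage = T_k/T, occurrence = n_k/T, duration =
T_k/n_k (all three 0 when n_k = 0). With the occurrence denominator equal
to the window length, coverage = occurrence × duration holds *exactly* and
is asserted on every computed table. Segments truncated by a boundary count
toward coverage and duration, but transitions are only counted between
segment pairs adjacent *within* the window — a segment entering the window
does not create a boundary transition, since that transition is an artifact
of slicing. Transition probabilities are conditional (row-normalised);
rows with no outgoing transition are undefined (NaN), never imputed zero,
and are excluded from subject means. The joint normalisation (by total
transitions) was considered and rejected as the default because the
polarity-aware analyses compare specific conditional probabilities; the
counts matrix is carried alongside for sensitivity analyses.

## Gaze and behavior

Saccade error is the Euclidean target–landing distance in pixels divided by
pixels-per-degree. The landing point is detected by velocity thresholds —
onset when 2-D speed exceeds 30°/s inside the 1 s response window, offset
when it next falls below 5°/s, landing = median position over the following
100 ms. Positions are smoothed (21 ms moving average) before
differentiation so tracker tremor cannot trip the thresholds; the median
makes the landing robust to post-saccadic tremor. All thresholds are
parameters. Trials are rejected for (a) any blink-flagged sample, (b) gaze
leaving a 2 dva radius around fixation during the fixation/visual/memory
intervals, or (c) saccade error > 2 dva; the verdict is order-independent
and the reported reason follows the priority blink > fixation break >
error. Valid trials are grouped low (< 0.5 dva) / high (> 1.5 dva) / mid —
mid trials are kept in correlations but excluded from the two-group
contrast — and near (6°) / far (12°).

## Statistics

- **State × interval ANOVA**: each subject contributes one mean per
  (state, interval) cell, so the design is within-subjects. The default is
  a two-way repeated-measures ANOVA; sphericity-corrected
  (Greenhouse–Geisser) p-values are reported next to the uncorrected ones.
  Under an exchangeable (iid) null, sphericity holds and the uncorrected
  p-value is exactly calibrated, while the GG p is conservative because the
  estimated epsilon is biased below 1 — calibration checks therefore target
  the uncorrected p, and both are reported. A plain between-cells two-way
  ANOVA is available as an option. Tukey HSD runs over the 12 interaction
  cells and is reported restricted to within-state across-interval
  contrasts, the comparisons of scientific interest.
- **Polarity ANOVA**: one-way ANOVA across the 8 polarity states on
  memory-interval subject means, with the full Tukey table.
- **Paired contrasts**: two-sided Wilcoxon signed-rank on subject means,
  zero differences dropped (classical convention); an all-zero difference
  vector degenerates to p = 1 with a warning.
- **Error–TP correlation**: saccade errors and memory-interval TP(D+→D−)
  are averaged per subject × target position and pooled across subjects —
  no subject random effects, by design, so n ≈ subjects × 12 minus cells
  with undefined TP (dropped and counted).
- **Condition contrasts**: named TP entries (A−→D−, D−→C+) are tested
  far-vs-near with signed-rank; because several transitions are examined
  at once, a Benjamini–Hochberg adjusted column accompanies the unadjusted
  p-values.

## The synthetic generator

The generator's defaults are the study conditions every test and the
acceptance script run under.

| parameter | default | meaning |
| --- | --- | --- |
| n_subjects × n_trials | 17 × 120 | study design |
| fs_eeg / fs_gaze | 250 / 1000 Hz | EEG rate is a free choice; gaze rate matches the tracker class |
| px_per_deg | 40 | ≈ 19-inch 1366×768 display at 60 cm |
| dwell_mean | 80 ms | gamma (shape 2) holding time of the 8-state semi-Markov chain |
| chain | uniform off-diagonal | embedded transition matrix |
| snr | 8 | peak per-channel signal RMS / noise SD |
| blink_prob | 0.2 | per-trial blink probability (150 ms flagged interval) |
| error_sigma | 0.6 / 0.85 dva | isotropic landing-offset SD, near / far |
| coupling_beta | 0.2 dva per z | error-spread coupling to planted D+→D− count |
| far_tp_boost | 0.08 | added to chain(A−→D−) on far trials |

Design notes:

- **Templates.** The four base maps are built from schematic 10–20
  electrode positions and then projected (alternating projections) onto the
  set of quartets with *equal per-channel energy*. With near-uniform class
  occupancy, the per-channel variance of a session is then flat, so the
  per-channel session z-score is a uniform rescale and does not warp the
  planted topographies — without this property, topography recovery cannot
  be meaningfully measured against the planted templates. Post-projection
  pairwise |correlation| among A–D is ≤ 0.51.
- **Envelope.** Segment amplitude follows a raised half-sine (floor 0.5 of
  the peak) so GFP maxima fall mid-segment while signal persists at
  segment boundaries, as in continuous EEG. A full half-sine (signal → 0
  at boundaries) leaves boundary samples to filter ringing and measurably
  degrades label recovery.
- **Noise.** White Gaussian per channel, SD = peak signal RMS / snr.
- **Blinks** are flags plus a held position; no ocular artifact topography
  is simulated.
- **Coupling** acts on the *planted* (ground-truth) transition counts, not
  the measured ones, so recovering the error–TP correlation is a genuine
  end-to-end test. `coupling_beta = 0.2` was calibrated so that the
  *measured* pooled correlation averages ≈ 0.15 across seeds: the
  measurement chain attenuates the planted coupling (cell-mean measured TP
  correlates ≈ 0.73 with cell-mean planted count), and the per-seed
  measured r fluctuates by roughly ±0.07 at n ≈ 204 — the effect is
  intentionally weak and marginally detectable.
- The behavioral defaults give ≈ 90 valid ("correct") trials per subject
  and a far−near mean-error gap of ≈ 0.2–0.3 dva.

What the generator does **not** emulate: volume-conducted source dynamics,
1/f background spectra, alpha rhythms, ocular/muscle artifacts, electrode
drift, inter-subject topographic variability (all subjects share the
template maps), or oculomotor latency/main-sequence detail. Passing tests
demonstrate that the pipeline's algorithms are correct and mutually
consistent and that planted effects of realistic size are recoverable —
not that real recordings would yield the same parameter values.

## Numerical and size choices

- Determinism: all randomness descends from explicit seeds
  (`numpy.random.Generator` with spawned per-trial streams); identical
  configuration and seed reproduce byte-identical outputs, and the run
  manifest records SHA-256 checksums to prove it.
- Label-recovery experiments use 96 trials (8 per position — the balanced
  design closest to one hundred trials) at snr 8: recovered prototypes
  correlate > 0.99 with the planted templates and smoothed polarity-aware
  labels agree with the planted sequence on ≈ 91% of samples. The ≈ 9%
  disagreement is dominated by segment-boundary blur introduced by the
  1–30 Hz filter plus planted segments shorter than the 30 ms smoothing
  window, both irreducible given the analysis definition.
- Statistical calibration/power checks in the test suite use 1000 null
  replicates and 50 planted-effect replicates per test on synthetic
  subject-level tables (17 subjects), which keeps the whole suite within a
  few minutes while leaving Monte-Carlo error on rejection rates near 0.7%.

## Known limitations

- The outlier screen looks only at map norms; a topographic artifact with
  ordinary amplitude passes through to clustering.
- K is fixed at 8 (→ 4 classes); no meta-criterion for selecting the
  number of clusters is provided.
- The pooled error–TP correlation ignores subject-level clustering by
  design (mirroring the analysis it implements); a per-subject summary is
  the appropriate diagnostic when that assumption matters.
- EDF files can be read (via `mne`) but not written; the native format is
  CSV/TSV.
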