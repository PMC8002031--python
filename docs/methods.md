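# Methods

This note documents the models, conventions and numerical choices behind
`neurolex`, and what the synthetic-data validation does and does not show.

## Synthetic EEG generator

Each trial at each channel is background noise plus planted ERP components.

**Background noise** is synthesized in the frequency domain: amplitude
spectrum ∝ f^(−slope/2) with zero DC, independent uniform random phases per
trial and channel, inverse real FFT, then each trace rescaled to the target
SD (default 10 µV, a plausible broadband single-trial EEG amplitude). The
spectral exponent ("slope") is the regularity lever: the default per-session
slopes (1.0, 1.3, 1.3) make sessions 2–3 more regular than session 1, which
lowers fine-scale sample entropy — the planted analogue of the reduced
signal complexity after the first session. The per-trial rescaling removes
trial-to-trial amplitude variability; this is deliberate (it keeps the
entropy tolerance r comparable across trials) and is listed as a limitation
below. A linear fit of the log mean periodogram recovers the configured
slope to well within ±0.2 for 600-sample epochs averaged over 100 trials
(tested).

**Components** are Gaussian-windowed half-sine deflections, a standard ERP
simulation primitive: smooth, compactly supported (peak ± width/2) and with
peak amplitude equal to the configured µV value. Defaults plant the four
components of the lexical-decision literature on their classic electrode
groups, with session-dependent amplitudes reproducing the reported pattern
(N170 more negative after session 1; P200 and N400 more positive; LPC less
positive). Per-electrode effect magnitudes in µV are not published, so the
default amplitudes (≈1–2 µV session changes on ~5–8 electrodes) are free,
plausibility-chosen parameters — not estimates of any real dataset.

**Behaviour.** RTs are shifted-lognormal: rt = shift + LogNormal(m, σ) with
shift 200 ms and trial-level shape σ = 0.35, giving right-skewed, strictly
positive RTs. Participant heterogeneity enters through a standard-normal
draw u_p shared across cells: the participant's cell mean is the published
cell mean plus u_p × the published between-participant SD, so fast
participants are fast everywhere and the session factor stays strongly
within-subject. Calibration targets are the published condition table
(word 811.16/763.96/727.24 ms, nonword 924.97/824.87/778.75 ms; accuracies
0.86–0.94); the table's SDs are interpreted as between-participant SDs of
participant means (the table reports n = 20 summary statistics, making this
the natural reading). Accuracy is Bernoulli per trial at the cell
probability.

**Streams.** One `SeedSequence` child per participant, split into a
behaviour stream and an EEG stream, so any participant can be regenerated
bit-identically in isolation and behaviour-only generation agrees exactly
with a full simulation.

**What the generator does not emulate:** inter-channel correlation beyond
shared components (no volume conduction), subject-level ERP amplitude or
latency idiosyncrasy, non-stationarity within an epoch, ocular/muscle
artefacts, and any coupling between RT and the neural signal. Passing
recovery tests therefore demonstrates correctness of the analysis chain
under clean, exchangeable noise — not robustness to realistic EEG artefact
structure.

## Exclusion, segmentation, averaging

RT outliers are removed in a single pass: a trial is excluded iff its RT
deviates more than 2.5 SD from its participant × session × lexicality cell
mean, with mean and sample SD computed once on all trials of the cell.
Re-running the rule on the filtered output would remove more trials; the
implementation deliberately does not iterate (tested). Cells with fewer
than two trials are retained with a warning. Incorrect trials are removed
afterwards; the order is exposed as a configuration switch
(`outliers_before_accuracy`) because either reading is defensible, with the
documented default matching the "outliers from all data, incorrect
additionally" phrasing.

Segments are defined on the retained (correct, outlier-free) trials in
presentation order: base size ⌊n/k⌋, the first n mod k segments one larger
(950 → ten segments of 95; 1003 → 101,101,101,100,…).

Time is in milliseconds relative to stimulus onset; the baseline interval
is half-open [−200, 0) ms so the t = 0 sample belongs to the post-stimulus
period. Baseline means are subtracted per trial per channel before
averaging, which makes ERP averaging linear in trial sets (tested).

## Multiscale entropy

Coarse-graining averages non-overlapping windows of length τ, discarding
the trailing remainder (600 samples → 27 points at τ = 22). Sample entropy
uses Chebyshev template distance, ordered pairs i < j over start positions
0..N−m−1 (self-matches excluded), natural-log units. The tolerance
r = 0.5 × SD of the original scale-1 series (sample SD, ddof = 1) is
computed once per trial and channel and held fixed across scales, following
the classic multiscale-entropy convention: coarse-graining shrinks variance
relative to r, so white noise shows decreasing entropy across scales
(tested). The counting kernel is numba-compiled; its (A, B) counts match a
brute-force O(N²) oracle exactly on randomized instances, and on white
Gaussian noise the scale-1 entropy matches the analytic value
−ln(2Φ(r/σ√2) − 1) ≈ 1.286 for r = 0.5σ.

Undefined entropy (A = 0 or B = 0, most likely on 27-point coarse series)
is stored as NaN and excluded from condition averages, with per-cell valid
counts kept so that valid + undefined always equals the trial count.
Entropy is computed over the full epoch by default, maximizing coarse-scale
series length; a post-stimulus-only window is available
(`window="post"`), since the original analysis window is not documented.

## Task PLS

The condition-mean matrix (conditions × features, averaging subject rows
within condition) is grand-mean centered column-wise — the standard task-PLS
mean-centering — and decomposed by SVD. Singular values at numerical zero
(relative tolerance max(dim)·eps·s₁) are not reported as LVs; identical
condition means therefore yield no LVs, and two-condition designs yield
exactly one. Sign convention: the largest-magnitude feature salience of
each LV is made positive.

**Permutation test.** Each permutation independently re-assigns the
condition labels within every subject (subjects fixed) and refits;
p = #{s_perm,k ≥ s_obs,k}/n_perm per LV position. This is the "count out of
n" definition, so p can be exactly 0; it is also mildly liberal relative to
the (k+1)/(n+1) convention (measured null LV1 rejection ≈ 0.05–0.06 at
α = 0.05). The definition is kept because it is the one the analysis family
historically uses; calibration is verified by test at the binomial 95%
level.

**Bootstrap.** Subjects are resampled with replacement, each keeping its
full condition set. Every resample is refit and its first k feature-salience
vectors are rotated onto the original solution by orthogonal Procrustes on
the design-salience space — without alignment, sign/axis flips across
resamples would inflate the SEs. Bootstrap ratio = original feature salience
/ SD (ddof = 1) of its aligned bootstrap distribution. Zero-SD guards: ratio
0 when the salience is also 0 (no evidence, no instability), NaN otherwise.
Because saliences are unit-norm, bootstrap ratios are invariant to feature
scaling (tested).

**Stable windows** are maximal contiguous runs of |BSR| ≥ 2.0 per channel
with constant salience sign. Time-feature runs must span at least 10 ms
(5 samples at 500 Hz) — a minimum-run criterion is plainly needed to
suppress isolated suprathreshold samples but no published value exists, so
10 ms is the package's default and is configurable. Scale-feature runs may
be a single scale.

## Behavioural statistics

The two-way fully-within ANOVA is an explicit sums-of-squares partition
(SS_A, SS_B, SS_AB with error terms SS_{A×S}, SS_{B×S}, SS_{A×B×S}); SS
conservation is property-tested and F, η²_G match both a loop-computed
oracle and `pingouin` on constructed datasets. η²_G follows the
Olejnik–Algina/Bakeman convention: effect SS over effect SS plus all
subject-related SS. Sphericity uses Mauchly's W on orthonormal-contrast
scores with the standard chi-square approximation; Greenhouse–Geisser
ε = (Σλ)²/(d·Σλ²) is clipped to (1/d, 1]. GG-corrected p-values are
reported (and flagged) only when Mauchly's p < .05, mirroring common
reporting practice; both corrected and uncorrected values are always in the
output table. Paired follow-ups use d_z (mean difference over difference
SD) and a caller-supplied Bonferroni α (default .017 for three pairwise
session tests).

## Study orchestration

`run_study` executes the eight analysis families — {ERP, MSE} × {across
session (3 conditions), within-session segments (10 conditions) × 3
sessions} — with α = .05 across-session and α = .008 within-session, plus
the behavioural chain. Trial-level entropy is computed once per
participant-session and reused across the across-/within-session splits.
Per-family RNG streams are spawned from the master seed, so the full report
is bit-reproducible and families are insensitive to each other's settings.
MSE feature columns containing any undefined cell are dropped (with counts
logged) before PLS, which requires complete data. `n_perm = 0` switches a
family to descriptive-only output.

## Validation problem sizes

The test-suite and acceptance script validate at deliberately reduced
sizes: effect recovery uses 5 participants × 100 trials/session on a
16-electrode montage with 100 permutations/bootstraps, null calibrations
use 100–200 replicate datasets, and the behavioural detection check uses 25
cohorts of 20 participants. The recovery configuration plants a *strong*
Session-1-vs-(2,3) effect (N170 −2 → −8 µV, P200 +2 → +5 µV): at a small
fraction of a real study's subjects and trials, condition-mean noise is an
order of magnitude larger, so the planted signal-to-noise is scaled up to
keep recovery informative about pipeline correctness rather than about
statistical power. The study-scale generator defaults keep the smaller,
more realistic 1–2 µV session changes.

## Known limitations

- No inter-channel noise correlation or head-model structure; PLS spatial
  patterns on synthetic data are cleaner than on real EEG.
- Per-trial noise normalization removes amplitude variability across trials.
- Permutation p = k/n can be 0 and is mildly liberal (see above).
- The BrainVision reader is a thin optional convenience around `mne` and is
  not exercised by the test suite (no recordings ship with the package).
- Published F/t statistics, RT means and window boundaries are properties
  of the original 20-participant dataset; the package reproduces the
  *procedures* and verifies them on synthetic data, not those numbers.
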