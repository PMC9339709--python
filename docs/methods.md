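# Methods

`p300lab` re-implements, as a tested pipeline, the computational chain of a
crossover EEG study in which transcranial alternating current stimulation
(tACS) is phase-locked to the P300 evoked by a visual oddball task: the
individual stimulation parameters are extracted on-site from the
pre-intervention block, target stimuli during the intervention are delayed so
that each P300 lands on a positive peak of the stimulation sinusoid, and the
pre/post × actual/sham outcome measures feed a 2×2 within-subject analysis.
Because no raw recordings ship with the package, a synthetic generator with a
complete ground-truth ledger stands in for the data; everything the analysis
stages claim to measure can therefore be checked against what was injected.

## Signal model

The generator realizes the event-related-oscillation (ERO) account of the
P300: each stimulus adds to the continuous EEG a burst

  s(t) = A · cos(2πf₀(t − t₀)) · exp(−(t − t₀)² / 2σ²),  σ = 1/(4f₀),

whose largest positive half-wave peaks at the P300 latency t₀ with amplitude
A. With σ equal to a quarter period, the burst has exactly one dominant
positive half-cycle — the P300 — flanked by small negative lobes, and its
amplitude spectrum peaks at f₀ (the ERO frequency, constrained to 1–8 Hz).
Targets additionally receive a late negative Gaussian component centred at
800 ms (σ = 150 ms), mirroring the N700 family of late ERPs.

Key ground-truth parameters (defaults):

- `p300_latency` = 350 ms (subject-level SD 40 ms, clipped to 250–550 ms).
- `ero_frequency` = 4 Hz (subject SD 1.2 Hz, clipped to 1.5–7.5 Hz).
- `p300_amplitude` = 20 µV: the *peak* of the target burst at Pz. Because the
  burst is brief, this corresponds to a 200–550 ms window mean of ≈2.6 µV at
  4 Hz, matching published target-P300 window means of ≈3 µV. Standards are
  scaled down by `target_standard_ratio` = 2.5.
- `n700_amplitude` = −0.2 µV peak (late-window means near zero at baseline).

Scalp topography is a fixed per-channel weight vector, not a head model. The
default P300 topography is dipolar (centro-parietal positive, fronto-polar and
mastoid negative) and sums to exactly zero across the 22-channel montage, so
common-average re-referencing — which the offline ERP branch applies — leaves
the Pz amplitude unchanged. Real EEG lead fields are approximately zero-sum,
and an all-positive topography would make every injected amplitude
unrecoverable after re-referencing by construction.

Background activity: per-channel 1/f^1 noise (4 µV RMS), occipitally weighted
10 Hz alpha (5 µV at the strongest site, slowly amplitude-modulated), white
sensor noise (2 µV), and blink-like frontal transients (300 ms raised cosine,
250 µV at Fp1/Fp2) on a configurable fraction (5%) of trials. Together this is
deliberately the statistical texture of an *ICA-cleaned* mobile recording
(~5 µV RMS at Pz); the artifact transients give the statistical rejection and
trial-by-trial (TBT) stages realistic work.

### Intervention effects

Pre→post effects are injected into post-block recordings as DC-balanced
double Gaussians (narrow 80 ms lobe minus an equal-area 300 ms lobe) centred
in the respective measurement window and scaled so that the *window mean*
equals the requested δ in µV. The balanced shape is essential: a monophasic
bump loses ≈21% of its window mean to the offline 0.5 Hz high-pass (measured
on the filter chain in isolation), whereas the balanced component passes at
1.04 (P300 window) and 0.90 (late window). ERO power effects multiply the
burst amplitude by 10^(δ/2), i.e. a δ shift in log₁₀ power. Default effects
reproduce the reference findings qualitatively: no differential P300 change
(−0.28 µV in both arms), a late-component increase under actual stimulation
only (+0.80 vs +0.25 µV), a small ERO power decrease in both arms (−0.05),
and a block-wise omission-rate worsening (+9 percentage points in both arms).

Behavior: lognormal reaction times (median 0.45 s, σ_log 0.25), omissions
(no press or wrong key) at 18%, commissions at 14%, with subject-level random
effects on all of these.

A parallel *distributional* outcome model (`simulate_outcome_measures`) draws
the measured outcomes directly — subject random effect + cell noise + the
same effect structure — and is used where thousands of replicate studies are
needed at the statistics layer (power properties, family-wise error checks);
the EEG-rendered chain is used everywhere a criterion concerns the signal
path itself.

## Phase-locked scheduling

The stimulator emits a pulse at every ascending zero-crossing of its
sinusoid, so positive peaks occur at `pulse + T/4 + kT` with `T = 1/f`.
Showing a target at `pulse + d` places its P300 at `pulse + d + latency`; the
scheduler takes the smallest `d ≥ min_lead` with

  d + latency − T/4 ≡ 0 (mod T),

which always exists with `d < min_lead + T`. `min_lead` defaults to 0.2 s (a
floor so the fixation-to-stimulus change remains perceivable; no value is
prescribed by the protocol this mirrors). Pulses are emitted only during the
full-amplitude plateau, not during the 10 s linear fade ramps (configurable).
Only target onsets are gated; standards inherit the accumulated cascade shift
so the ISI structure is preserved. Scheduling works in continuous time; the
phase-lock tests read the waveform back analytically, and the residual phase
error is at float precision (circular SD ≪ 1°).

The sham waveform is fade-in (10 s), plateau (10 s), fade-out (10 s) — a 30 s
envelope — followed by silence for the rest of the block.

## Online parameter extraction

The pre-intervention block is band-limited to 0.1–40 Hz and detrended. Band
limiting everywhere in the package is zero-phase (forward–backward) Butterworth
filtering: order 4 for the high-pass (gentle, to preserve slow ERP
components) and order 8 for the low-pass (a 50 Hz line component passes at
<3% through the 40 Hz edge). The high-pass stage is padded over three filter
time constants; scipy's default pad length is far too short for sub-hertz
edges and otherwise leaks slow edge transients into the record.

Artifact-component removal is a contract: any invertible linear decomposition
(FastICA via scikit-learn is provided) plus any selector; the packaged
selector flags components whose time course correlates with a reference trace
(simulated EOG/ECG) above |r| = 0.7. Statistical epoch rejection z-scores,
across epochs, per-channel and pooled kurtosis and the Gaussian negative
log-likelihood of each epoch's samples (channel-wise Gaussian fitted across
epochs); |z| > 3 drops the epoch, with the triggering metric logged.

P300 latency is the maximum of the target-epoch average at Pz within
250–450 ms (ties → earliest sample; a flat or non-positive window is flagged
low-confidence). A wider 250–600 ms window is available
(`OnlineConfig.WIDE_LATENCY_WINDOW`) for subjects whose P300 peaks late, but
the default follows the 250–450 ms protocol.

The individual stimulation frequency is the argmax over 1–8 Hz of the
across-epoch average of zero-padded periodograms of the Pz segment
±200 ms around the latency (0.1 Hz grid; ties → lower frequency). Two
numerical choices matter here. First, the periodogram uses a boxcar window
and no mean subtraction: the burst has a nonzero mean, and either a Hann
window or constant detrending redistributes that mean into neighbouring bins,
shifting the noiseless peak by +0.3–0.4 Hz. Second, by default the averaged
spectrum of an equally long pre-stimulus segment is subtracted first
(event-related power); without it the 1/f background tilts the argmax toward
the band floor. Both are configurable.

## Offline ERP analysis

Pre and post blocks are resampled to 250 Hz, merged (post events shifted and
tagged), band-limited to 0.5–40 Hz, detrended, and named bad channels are
repaired by spherical-spline interpolation (montage positions and spline
matrix from MNE); more than three requested repairs warns but proceeds. The
ERP branch then re-references to the common average and low-passes below 6 Hz
(to exclude alpha) — this filter never touches the TFR branch — epochs
−0.5…1.5 s around targets with a −0.5…0 s baseline, and applies TBT artifact
handling in exactly three passes with strict inequalities:

1. per epoch, mark channels whose peak-to-peak amplitude exceeds 150 µV;
2. exclude channels marked in more than 15% of epochs from the set entirely;
3. drop epochs with more than 10 remaining marked channels; spline-repair the
   marked channels of retained epochs.

Condition averages are measured at Pz as the mean over the half-open
200–550 ms window, the maximum over 250–550 ms with its latency (ties →
earliest), and the late-window (700–1000 ms) mean. The text-vs-figure
discrepancy in the mean window (200–550 vs 250–550 ms) is handled by
configuration: 200–550 ms is the default, `p300_mean_window=(250, 550)` is
one keyword away.

## Time–frequency analysis

Target epochs (−0.5…+1.6 s, common-average reference, time-domain baseline
subtraction, ±2 SD statistical rejection, no 6 Hz filter) are decomposed with
a complex Morlet CWT on 47 log-spaced frequencies from 0.25 to 6 Hz. The
wavelet bandwidth constant is B = 0.125 (≈1.6 cycles), fixed so the
time-domain support (4σ_t) at 0.25 Hz stays within 4 s; with a 2.1 s epoch
the slowest wavelets are necessarily edge-contaminated, which the
cone-of-influence mask (2σ_t from either edge) makes explicit. Such a short
wavelet is spectrally broad (σ_f ≈ 0.64·f); a tone's power concentrates
within an e-fold of its frequency, not within three bins — no bandwidth
satisfies both a 4 s support and 3-bin concentration on this grid, and the
support constraint is the one the analysis needs.

The convolution is implemented directly (analytically sampled kernels over
±5σ_t, symmetric zero-padded FFT correlation): pywt's CWT shows a large
asymmetric left-edge artifact from its integrate–convolve–differentiate
scheme, and MNE's Morlet refuses kernels longer than the signal. Each
frequency row is divided by the family's own response to a unit sinusoid at
that frequency (computed once per grid/epoch-length and cached), so a pure
tone peaks at its own bin with power ≈ its squared amplitude and the
short-epoch edge attenuation is compensated consistently.

Power is logarithmized per epoch *before* averaging across epochs (the order
matters and is asserted by a property test). The ROI statistic is the
arithmetic mean of log-power over 0.5–5.5 Hz × 250–550 ms, reported both with
edge-masked cells included (the convention of the analysis this mirrors) and
excluded. No spectral-domain baseline is applied.

## Behavioral scoring

Oddball: omissions are target trials without a correct target-key response —
both no-press and wrong-key, with a switch (`count_no_press_as_omission`) to
count key presses only; commissions are target-key responses to standards.
d′ = z(HR) − z(FA) with rates clipped to [1/(2N), 1 − 1/(2N)] so extreme
blocks stay finite. RT mean and RT variability (SD — the convention adopted
here) use correct target responses only.

d2 test: sheets are 14 lines × 47 symbols from {d, p} × {1..4 strokes}
(targets: d with two strokes, ≈46% of cells as in the printed test). The
processed span of a line runs to its last crossed position; processing speed
is the summed span, omissions are uncrossed targets within the span,
commissions crossed non-targets, and concentration performance = hits −
(commissions + omissions), following the "all conducted errors" reading.
Outlier exclusion for group analyses is single-pass: values with
|v − mean| > k·SD (k = 3, strict) are masked, computed once per measure over
the analyzed sample, with no re-iteration.

## Crossover statistics

Each outcome enters a 2×2 repeated-measures ANOVA (Block × Intervention,
statsmodels `AnovaRM`) on complete cases (listwise deletion per measure, with
dropped subjects reported). Both factors have two levels, so sphericity
corrections are moot, each effect has df = (1, n−1), partial η² follows
η_p² = F·df₁/(F·df₁ + df₂), and each effect's F equals the squared paired t
of its contrast — an identity the tests verify numerically, and the follow-up
paired t-tests (with Cohen's d = mean difference / SD of differences) exploit.
Exploratory association analysis pools post-minus-pre change scores across
both interventions (two rows per subject), computes Pearson correlations for
every measure pair, and applies Holm's step-down correction over the whole
matrix as a single family; undefined correlations (constant vectors, fewer
than three complete pairs) are reported as missing.

## Validation studies and problem sizes

The validation suite re-derives every claim from scratch:

- Phase lock: eight frequencies spanning 1–8 Hz, ≈240 scheduled targets;
  worst amplitude deviation < 1%, circular SD ≪ 1°.
- Online recovery: 50 simulated subjects, full 400-trial blocks at default
  noise; median |latency error| ≤ 8 ms, median |frequency error| ≤ 0.3 Hz.
- ERP effect recovery: +1 µV actual-only change, 20 replicate studies of 20
  subjects at 60 trials/block on a 9-channel zero-sum sub-montage; the median
  interaction estimate recovers the injection within ±0.3 µV.
- Type-I calibration: 500 replicate 19-subject studies with null effects,
  EEG rendered at 12 trials/block; the interaction rejection rate is checked
  against 0.05 ± 0.02. The reduced block size changes the measurement noise,
  not the null distribution of the test statistic, which is what is being
  calibrated.

## What the generator does not emulate

No volume conduction or head-model forward simulation (topography is a weight
vector); no trial-to-trial latency jitter or habituation of the ERP; no
stimulation artifact in the EEG (the intervention block itself is not
analyzed, matching the protocol); no non-stationary noise beyond the alpha
amplitude modulation and discrete blink transients; behavioral responses are
independent across trials (no sequential effects or fatigue drift within a
block — block effects enter as probability shifts only). Passing recovery
tests therefore demonstrates correctness of the chain under the stated model,
not robustness to every pathology of real recordings.

## Known limitations

- The frequency estimator's accuracy degrades toward the band edges (broad
  burst spectra truncated at 1 and 8 Hz); the median-error criterion reflects
  typical, not worst-case, subjects.
- TBT interpolation quality depends on montage density; with the reduced
  9-channel montage used in replicate studies, spline repair is coarse (the
  studies are sized so it is rarely triggered).
- FIF is the only writable signal format in this environment; EDF and
  BrainVision are read-only.
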