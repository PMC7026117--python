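# Methods

This note documents the models and procedures `mesomotif` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Preprocessing

Raw fluorescence movies are converted to percent dF/F₀ with a per-pixel
baseline F₀. For spontaneous epochs F₀ is the per-pixel mean over all frames
(no sliding window); for evoked trials the baseline comes instead from the
frame-wise mean of stimulus-free ("blank") trials, so the exponential dye
bleaching common to stimulus and blank trials cancels exactly. `dff` refuses
movies already flagged as dF/F₀ rather than silently double-normalizing.

Temporal filtering is a Chebyshev type-I bandpass, order 4, 0.1 dB passband
ripple, 0.5–6 Hz at 150 Hz sampling, applied forward–backward
(`scipy.signal.sosfiltfilt`) for zero phase lag. Forward–backward
application squares the magnitude response, so a passband sinusoid is
attenuated by at most twice the ripple in dB (gain ≥ 10^(−0.2/20) ≈ 0.977)
and stopband attenuation doubles. The filter order, ripple and band edges
are parameters, not constants. Note for users of the synthetic generator:
the planted motif events last ~67 ms (10 frames at 150 Hz), with dominant
temporal frequency above the 6 Hz band edge; filtering real VSD data is
appropriate because physiological noise is broadband, but on synthetic
movies with white noise the bandpass smears the planted events and degrades
onset localization, so the recovery analyses run on unfiltered dF/F₀.

## Sensory templates

The evoked response is summarized by the mean dF/F₀ in a 5×5-pixel region of
interest (ROI) centred on the maximally responsive pixel, searched over the
first ten post-stimulus frames. The peak frame is smoothed with a 3×3 mean
before the argmax so a single noisy pixel cannot win (raw argmax available
by flag); an ROI that would cross the image boundary is shifted inward with
a warning. Response onset is the first post-stimulus frame whose ROI value
exceeds the 200 ms-baseline mean + 2 SD — the threshold is configurable
since "initial segment" admits several operationalizations. The template is
the five frames from onset, restricted to the hemisphere (vertical midline
split by default; user-supplied rasters accepted) containing the maximally
responsive pixel, flattened over in-mask pixels. Templates are built from
the mean of the session's stimulus trials rather than a single
representative trial.

## Motif detection

Index frame t of a spontaneous movie carries the Pearson correlation between
the template's flat vector and the flattened in-mask window [t, t+5)
(half-open, 0-indexed). Pearson is used because the resulting distributions
are symmetric and zero-centred. Zero-variance windows yield r = 0 with a
warning. The detection threshold is mean + 1.5 SD of the trace; a motif
event is a maximal run of **strictly** supra-threshold values lasting at
least five frames. Runs are not merged across sub-threshold gaps; matches
to different modality templates are counted independently. Motif frequency
is events per 10,000 index frames (n_frames − 4 windows).

The concordance sweep operationalizes the threshold choice: matches are
isolated at thresholds mean + k·SD for k in steps of 0.05, each match's
first frame is binarized at a modality-specific fraction of its maximum
(template 0.4; matches 0.5 whisker / 0.6 forelimb / 0.7 hindlimb — match
frames peak lower and need higher relative cuts), and the Jaccard index
(Dice by flag) of template vs match support is averaged per k. A plateau is
declared at the smallest k beyond which every per-step relative gain stays
below 1%. The returned threshold is mean + max(plateau k, 1.5)·SD, so the
sweep is a diagnostic and never lowers the conventional rule. Two
implementation notes discovered by simulation: (i) with left-aligned window
indexing the first crossing index leads the visible motif by about two
frames, so the "first frame of the match" is taken two frames after the
crossing (`match_frame_offset`, 0 restores the literal frame); (ii)
binarization against the frame maximum assumes no spatially uniform offset —
data should be bleach-free or bandpassed before the sweep.

Cross-modality consistency of motif expression is a one-way random-effects
ICC(1,1) (via pingouin) on the subjects × modalities frequency table, with
its F-test p-value; low ICC means idiosyncratic, non-uniform upregulation.

## Surrogate nulls

A surrogate frame multiplies the frame's 2-D FFT by a unit-modulus random
phase field with conjugate (Hermitian) symmetry and DC factor 1, then
inverts. This preserves the amplitude spectrum exactly — hence the frame's
mean, variance and spatial autocorrelation — while destroying the specific
spatial arrangement. A rank-remap onto the original sorted values
(`histogram_match`) additionally makes the grey-value histogram identical at
the cost of an only approximate spectrum; both behaviours are available. A
"literal" mode multiplying by the full spectrum of random grey values
(which does not preserve the amplitude spectrum) exists for comparison.

Two null designs are provided. **Surrogate templates** phase-shuffle the
five template frames; by default one phase field is shared by all five,
which preserves the whole inter-frame Gram matrix (⟨fᵢ, fⱼ⟩ is invariant
under a common unit-modulus spectral multiplication), and with it the
temporal autocorrelation of the null correlation trace. Independent
per-frame fields (by flag) whiten the null trace — such surrogates can never
sustain five-frame runs and systematically understate the null.
**Surrogate movies** phase-shuffle every movie frame independently, leaving
frame order intact (a 2-D, spatial-only transform).

Match counting under the null holds every surrogate trace to the *same
absolute threshold* derived from the real data (mean + 1.5 SD of the real
trace). Giving each surrogate its own threshold would hand the null a lower
bar whenever genuine matches inflate the real trace's SD. For run-count
comparisons the movie-shuffle null is the default recommendation: a smooth,
localized template has few effective spatial degrees of freedom, so a
phase-randomized *template* still correlates with a planted motif pattern
with a broad random coefficient (SD ≈ 0.2 at a 64×64 field), and when every
event shares the kernel this leaks coherent null matches; shuffling the
movie destroys the events' spatial pattern and temporal coherence instead,
and on featureless noise it is distribution-preserving, making real and
null counts exchangeable. The empirical CI of null counts uses
linear-interpolation percentiles (Hyndman–Fan type 7) and requires at least
1/(1−coverage) surrogates.

Distribution-level comparisons use the two-sample Kolmogorov–Smirnov test
on correlation values. KS assumes independent samples: overlapping windows
autocorrelate the trace (over-rejection), and whole-epoch dF/F₀
normalization ties all windows of one epoch together (under-rejection), so
the calibration analyses decimate traces to every fifth value
(non-overlapping windows) of movies that are already in dF/F₀ units.

## Trial-to-trial variability

Per-trial amplitude is the 5×5-ROI maximum over the first ten post-stimulus
frames; the corrected amplitude subtracts the mean ROI value of the three
frames (~20 ms) preceding the detected response onset (anchored at the
onset, not the stimulus frame; correction applied after peak detection —
equivalent for a constant baseline). The maximal baseline correlation uses
only windows lying entirely within the 200 ms pre-stimulus baseline; no
post-stimulus frame can contribute, and this is tested by scrambling
post-stimulus data. Per-subject evoked SD is the sample SD (n−1) of
corrected amplitudes. Outlier exclusion follows Tukey's fences applied to
the *upper* fence only (excess variability is one-sided; two-sided by
flag), or a fixed cutoff.

The mixed model `amplitude ~ baseline_max_r + (1 | subject)` is fitted by
maximum likelihood (not REML) so nested comparisons across simulated
cohorts are valid; the fixed slope is reported with a Wald 95% CI and a t
statistic referred to df = n_trials − 2 (the residual-like convention; the
random-intercept structure makes any single df convention approximate).
Interval-stimulation sessions are analyzed as per-subject SDs per interval
followed by a one-way repeated-measures ANOVA across intervals (balanced
designs only; a degenerate all-equal table returns F = 0). The 5×5-pixel
ROI convention replaces a physical-µm ROI throughout, since synthetic
movies carry no calibrated pixel size; a µm-per-pixel configuration can
convert where provided. Bonferroni correction over a user-declared family
of tests is left to the reporting layer rather than hard-coded.

## Synthetic data: what it emulates and what it does not

**Motif kernels.** A planted motif is a non-negative Gaussian blob, peaked
at a modality-specific locus (forelimb anterior-medial, hindlimb posterior,
whisker lateral; all in one hemisphere, ≥ 15 px apart at 64×64), whose width
grows 25% per frame, whose centroid drifts 0.04·field px/frame along
divergent per-modality directions, and whose amplitude rises over three
frames (cubic ramp) then decays (τ = 4 frames). A fixed fine-grained
multiplicative texture (±60%, deterministic per modality) stands in for the
patchwork micro-structure of real depolarizations and gives the pattern
many effective spatial degrees of freedom. This geometry was designed so
that the sliding correlation localizes event onsets to ±2 frames at the
mean + 1.5 SD threshold, cross-modality correlations stay below threshold,
and phase surrogates cannot lock onto events — i.e., for detectability
under the stated analysis, not for biophysical realism.

**Spontaneous epochs.** Percent signal = band-limited background + planted
kernels (homogeneous Poisson onsets per modality, 10⁻³/frame by default ≈ 10
events per modality per 10,001 frames, same-modality overlap rejected) +
white noise (SD 0.05%), with peak event amplitude 0.4%. Raw fluorescence =
100 · exp(−t/30,000) · (1 + signal/100). The background is a rank-16 field:
spatially smoothed random modes weighted by 0.5–6 Hz-filtered coefficients.
Its default SD is 0.002% — deliberately an order of magnitude below the
noise — because spatially coherent slow background at realistic amplitude
produces sustained correlation excursions that the fixed mean + 1.5 SD rule
detects as motifs; in real data those crossings *are* the motifs, but in a
generator they destroy the ground-truth separation every recovery analysis
depends on. The parameter is exposed for users who want to study exactly
that regime.

**Evoked sessions.** Each trial holds a ≥ 200 ms baseline (optionally with
a planted same-modality motif of random amplitude), then a stimulus-locked
response kernel whose ROI amplitude is mean + subject intercept +
β · baseline_max_r + noise, where baseline_max_r is *measured* on the
generated baseline with the same code the analysis uses — so slope recovery
is not attenuated by errors in variables. Bleaching and blank trials are
included so the correction path is exercised. Interval sessions draw
amplitudes with SD 0.06 + 0.22·exp(−interval/900 ms) (monotone decreasing,
~0.23 at 250 ms relaxing to 0.06); summary-level cohorts give subject i a
motif frequency fᵢ ~ U(0.5, 10) per 10⁴ frames and trial SD
0.03 + 0.005·fᵢ. Defaults were chosen so the respective effects are
detectable at field-typical sample sizes (4 subjects × 7 intervals × 30
trials; ~90 subjects × 10 trials).

Not emulated: hemodynamic and vascular artifacts, motion, awake-state
dynamics, bilateral symmetry, any biophysically calibrated amplitude
distribution. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under its stated assumptions, not its
sensitivity on real recordings.

## Problem sizes and determinism

The validation suite and `scripts/acceptance.py` use desk-scale sizes:
10,001-frame 64×64 epochs for motif recovery; 5,001-frame 32×32 planted
movies with 200 movie-shuffle surrogates (95% CI) for null separation, and
40 pure-noise seeds × 50 surrogates for null specificity; 500 repeats of
decimated white-noise traces for KS size and 20 planted-movie repeats for
KS power; 10 subjects × 30 trials for slope recovery and 100 six-subject
cohorts for β = 0 coverage; 20 cohorts/sessions for the regression and
interval trends. Every stochastic quantity derives from a single seed;
identical configuration + seed reproduce byte-identical result tables.

## Known limitations

- The mean + 1.5 SD rule is scale-free but not specificity-calibrated: its
  false-positive behaviour depends entirely on the temporal autocorrelation
  of the correlation trace (see the background discussion above).
- Template-shuffle nulls understate or overstate run counts depending on
  the phase-sharing convention; run-count inference should prefer the
  movie-shuffle null (distribution-level KS comparisons are less affected).
- The onset the detector reports is the first threshold crossing, which
  systematically leads the visible event by ~2 frames for smoothly rising
  events.
- Hemisphere restriction uses a vertical midline split unless masks are
  supplied; no registration to an atlas is attempted.
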