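# Methods

This note documents the models and procedures implemented in
`strfshift`, the parameter choices that matter, what the synthetic
experiment does and does not emulate, and the numerical conventions.

## Stimulus arm: modulation filtering and inversion

**Spectrogram.** A Gaussian-windowed short-time transform with window
σ = 7.1 ms, hop 2 ms, and FFT length chosen so the frequency step is
≈ 1/(2πσ) ≈ 22 Hz — the resolution trade-off standard for speech
modulation analysis.  Values are log-amplitude in dB, clipped 50 dB
below the maximum.  All four parameters are exposed.

**Modulation power spectrum (MPS).** The 2D FFT of the mean-removed
log-spectrogram, folded to non-negative spectral modulation
(cycles/kHz) with signed temporal modulation (Hz).  Parseval's identity
on the folded grid (with conjugate-pair weights) is exact and tested to
1e−9 relative error.

**Modulation filters.** Low-pass in either axis; the pass band keeps
complex values (amplitude *and* phase) untouched, the stop band is set
to zero, with a raised-cosine transition spanning 20% of the corner
(`transition_width`) to limit ringing in the inverted spectrogram.  A
brick wall (`transition_width=0`) is exactly idempotent; the default
soft edge is idempotent only to ≈ a few percent, the price of the
gentler edge.  The corners default to 0.5 cycles/kHz (spectral) and
3 Hz (temporal), the values that make speech unintelligible while
preserving its long-term spectrum.

**Spectral-profile restoration.** After filtering, each frequency row
of the spectrogram is rescaled (a per-row dB offset) so its
time-averaged linear power matches the original; the offsets are
demeaned so the (0,0) modulation component is bit-preserved, and the
single remaining scale factor is fixed at the waveform stage by RMS
matching.  Note a consequence: restoration deliberately reinstates
*static* spectral structure (the ωt = 0 line), because a sound's
long-term power spectrum *is* that line.  On a perfectly stationary
harmonic stack a spectral low-pass therefore appears to do nothing
unless restoration is disabled — which is how the filter mechanism
itself is verified.  Real and synthetic speech have time-varying
harmonic structure, which stays removed.

**Inversion.** Iterative phase retrieval (random seeded phase
initialization, alternating waveform reconstruction and magnitude
replacement; 30 iterations by default).  The best iterate by relative
magnitude error is returned, making the reported error non-increasing
in the iteration budget by construction; three consecutive error
increases trigger a divergence warning.  Round-trip spectrogram
correlation on the synthetic speech corpus exceeds 0.95.

## Auditory spectrogram

128 fourth-order gammatone filters on the Glasberg–Moore ERB-rate
scale, 180–7000 Hz.  Per band: half-wave rectification, cube-root
compression (the standard cochlear choice; exponent configurable),
first-difference spectral sharpening across bands clipped at zero (a
lateral-inhibition approximation; bypassable), and a one-pole leaky
integrator with τ = 8 ms.  The chain is a homogeneous function of the
input (power-law compression), so loudness scaling never decreases any
output — a tested invariant.  Bands are block-averaged 4→1 to 32 bands
(conserving the mean exactly; centres become geometric means) and
resampled to 50 Hz (model path) or 100 Hz (coherence path) behind an
anti-alias low-pass at the target Nyquist.

## HFB extraction and electrode screens

Raw signals are band-passed 0.5–200 Hz and notch-filtered at the line
frequency and two harmonics, all zero-phase; channels with variance
above 5× the median are flagged and excluded from the common average
(this amplitude screen replaces visual artifact inspection).  HFB is
the mean of 21 Hilbert-envelope sub-bands geometrically spaced
70–140 Hz (bandwidth 0.25 × centre), each z-normalized over time before
averaging so no sub-band dominates.  Epochs are z-scored against their
own −800…−100 ms baseline.

**Speech-R screen.** Per electrode, the across-trial mean of the
per-trial post-stimulus mean is bootstrapped (10 000 resamples); the
electrode is kept iff the 0.5th percentile exceeds 0 (a 99% CI lower
bound; strictly greater, so degenerate all-zero electrodes fail).
False-positive rate under the null is ≤ 1%, tested on 1000 simulated
electrodes.

**STRF-R screen.** Same construction applied to the per-fold held-out
R² of the clean-speech encoding model: keep iff the 0.5th percentile of
fold R² exceeds 0.  (A two-sided 99% interval is used; the lower bound
is the 0.5th percentile, mirroring the Speech-R construction.)

## eSTRF estimation

The encoding model is linear in the lagged auditory spectrogram with 21
causal lags, 0–400 ms inclusive at 20 ms (the 50 Hz grid), 32 bands:
672 coefficients.  Per jackknife fold (leave one trial out), design and
response are z-scored with training-fold statistics (applied unchanged
to the held-out trial) and ridge regression is solved over a 17-point
penalty grid, 1e−2…1e6, through one eigendecomposition of the Gram
matrix per fold (every penalty and electrode reuses it).  The held-out
R² argmax per fold, pooled over active electrodes and conditions, is
aggregated by mode (ties toward the larger penalty) into a single
global penalty; all folds of all conditions are then finalized at that
one value, so the coefficient prior is identical in BEFORE, MIDDLE and
AFTER.  The final gain is the fold mean; the t-map is fold mean/std;
fold R² at the global penalty feeds the STRF-R screen.

Coefficients live on the standardized scale.  `STRFFit.gain_raw`
unstandardizes each fold (divide by feature stds, multiply by the
response std), which is the scale a generative ground-truth filter is
directly comparable on: recovery correlation is exactly 1 in the
noiseless limit.  At finite noise the recovery criterion is evaluated
on the standardized scale (truth mapped by the feature stds), because
raw-scale comparison amplifies noise in weakly-excited features.

**Prediction convention.** Cross-condition predictions standardize the
*lagged features* of the prediction stimulus (its own statistics), the
same per-feature standardization used in fitting.  Z-scoring whole
bands instead misscales individual lagged copies by 10–20% and destroys
the cancellation between correlated coefficients — measurably wrecking
noiseless prediction (R² 0.67 vs 0.99 in development tests).

## Coherence → bits/s

Sliding 400 ms windows in 200 ms steps, from −0.5 s to the epoch end,
on 100 Hz HFB (400 ms at 50 Hz would give only 20 samples per window).
Per window, cross- and auto-spectra are pooled over trials and 3
Slepian tapers (time-bandwidth 2).  Debiasing is a leave-one-trial-out
jackknife on the variance-stabilized transform atanh(√γ²); the debiased
value keeps the sign of the bias-corrected transform
(γ̃² = tanh(z*)·|tanh(z*)|), so null coherence fluctuates around zero
instead of resting on its positive bias floor — values below zero are
expected and meaningful under the null.  The information rate is
mi = −∫ log₂(1 − γ²(f)) df (trapezoidal over the resolved frequencies,
γ² clipped to [0, 1−1e−6]); the adopted integrand is the standard
coherence-information form, reconstructed because the source text's
formula panel is an image.  Analytic anchors tested: γ² = 1 for
identical signals; γ² = s/(1+s) for additive white noise at SNR s;
constant γ² = 0.5 over a 10 Hz band ↦ exactly 10 bits/s.  The contrast
MI(AFTER/MIDDLE) − MI(BEFORE/MIDDLE) is computed with and without
subtraction of each electrode's across-trial mean response; the
subtracted variant isolates sentence-specific tracking and is the
headline number.

## Tuning-shift statistics

**MTF.** The STRF's band axis is interpolated onto a uniform
log-frequency grid (ERB spacing is close to, but not exactly, log),
zero-padded 4×, 2D-FFT'd; the spectral-modulation axis is converted to
cycles/kHz linearized at the 1 kHz reference (1 cycle/decade =
1/ln 10 cycles/kHz there) so MTFs overlay the stimulus MPS.

**Output power.** The eSTRF is z-scored (only its shape matters),
convolved with each standardized clean-speech spectrogram over the
sound period, and the RMS taken over the concatenated outputs
(averaging per sentence is a switch).  Spectrograms are restricted to
the sound window: z-scoring a silence-padded spectrogram turns silence
into a band-dependent constant whose projection onto the filter only
adds offset variance.

**Generalization.** Clean-speech (MIDDLE) coefficients predict the
filtered-condition responses; predicted and observed traces are both
z-scored per trial and scored by a single R² over the concatenation
(identical traces give exactly 1).

**Partial correlation.** Each condition's eSTRF enters as its t-map
(the z-score of every feature across jackknife folds), flattened
lag-major — the vectorization order is irrelevant and tested so.
Residualization uses least squares with an intercept.  Degenerate
(zero-variance) inputs raise; inputs perfectly collinear with the
conditioned variable return 0 (no linear relation remains).  The
headline statistic is Δρ = ρ(A,M|B) − ρ(B,M|A), antisymmetric under
condition swap by construction.

## Resampling inference

Sign-flip tests use the +1 Monte-Carlo convention,
p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), so p is never 0 and an
all-zero difference vector gives p = 1.  The cluster test thresholds
the per-timepoint one-sample t at the two-sided critical value
(cluster-forming α = 0.05), sums t within contiguous same-sign runs
(cluster mass), and compares against the permutation maximum |mass|;
sign flips leave Σd² per time point invariant, so the whole permuted
t-series follows from the permuted means in closed form (the
implementation exploits this).  For a length-1 series the cluster p
equals the sign-flip p exactly with matched seeds.  Bootstrap CIs are
percentile intervals of the resampled mean.

## The synthetic experiment

Each trial holds one unique speech-like sound (no sound reused): a
harmonic stack with drifting fundamental (90–250 Hz) shaped by 2–4
slowly drifting formant-like log-spectral peaks, gated by a 3–8 Hz
syllabic envelope, with brief broadband bursts; peak amplitude 0.9.
Its modulation power concentrates below 10 Hz / 3 cycles/kHz (≈ 85% of
non-DC power), matching the speech-like concentration the stimulus arm
assumes.  BEFORE and AFTER present the bit-identical modulation-filtered
version; MIDDLE the unfiltered version.

Ground-truth STRFs are standardized random 2D Gabors per electrode
(random centre band, best lag 50–250 ms, random sign; optional Gabor
mixtures).  The clean-speech (MIDDLE) truth draws its modulation
carriers from the low-modulation range where speech power lives
(temporal 0.5–2 Hz, spectral 0.01–0.05 cycles/band), the BEFORE truth
from a broader, higher range (2.5–6 Hz, 0.04–0.12 cycles/band) spanning
the 3 Hz stimulus-filter corner — so clean-speech tuning is
speech-matched, as in the modelled system, and shifting toward it
genuinely increases speech-feature overlap.  With exchangeable truth
distributions the output-power contrast would have zero expectation at
any shift, which is a property of the measure, not a bug.  The AFTER
truth is exactly (1−λ)·before + λ·middle, elementwise, with no
re-standardization, so the endpoint identities hold bit-exactly and λ
is the scale-free effect size.

Simulated HFB is the causal convolution of the truth with the auditory
spectrogram (truths interpolated along the lag axis for the 100 Hz
coherence path), plus an evoked component proportional to overall
stimulus energy — a flat zero-lag filter, hence inside the linear model
class — shared by all electrodes and conditions, mimicking the broad
evoked HFB rise of real speech-responsive electrodes and giving the
global-response subtraction something real to remove.  Noise is white
Gaussian (an AR(1) option with coefficient 0.7 reflects the temporal
correlation of real HFB noise) scaled so var(feature-driven
signal)/var(noise) equals the configured SNR; the default single-trial
SNR of 4 is a plausible guess, exposed as a knob, not a claim.  Seeds
derive from one master seed through fixed integer key tuples, so any
subset (one trial's sound, one electrode's noise) is reproducible in
isolation.

**What the generator does not emulate:** intelligible speech or
perception; spatially correlated noise across electrodes; non-linear
(for example gain-adaptive or onset-transient) response components;
electrode-to-electrode latency differences; artifacts.  Passing tests
therefore certify the analysis chain — that it recovers built-in
linear tuning shifts at realistic SNR and stays silent when none exist
— not that real cortex behaves this way.

## Study sizes

Desk-scale sizes chosen for the standard in-silico experiments: the
main-effect run uses 25 trials × 3 s × 30 electrodes at SNR 4 (the
modelled task used 50–60 trials of 2–5 s); the shift sweep reuses the
same stimulus set across λ ∈ {0, 0.25, 0.5, 0.75, 1} with two
truth/noise draws per value (stimuli are λ-independent by design); the
null calibration runs 20 λ=0 replicates as 5 stimulus sets × 4
truth/noise draws of a leaner 10-trial × 2 s configuration, since
false-positive behaviour does not depend on power.  Parameter-recovery
checks use 20 trials × 3 s.

## Behaviour of the partial-correlation contrast

Δρ rises very steeply with the true shift — a small built-in shift
already produces a large contrast — and its dose-response curve can
peak below λ = 1 rather than increase to the end.  The mechanism is a
suppression effect built into the construction: at intermediate λ the
AFTER estimate contains part of the BEFORE tuning, so conditioning on
it removes correlated structure from *both* other estimates and pushes
ρ(BEFORE, MIDDLE | AFTER) negative, which inflates the difference; as
λ → 1 that term returns to zero and the contrast settles back.  The
shared evoked component (present in every condition's fit) amplifies
the effect.  Δρ is therefore a sensitive detector of *whether* tuning
shifted toward the clean-speech fields, not a linear readout of *how
far*; the output-power, generalization and coherence contrasts track
the shift magnitude monotonically.

## Known limitations

* The raised-cosine filter edge trades exact idempotence for less
  ringing (see above).
* Griffin–Lim inversion is phase-blind: reconstructed audio matches the
  spectrogram magnitude, not the original phase; perceptual quality is
  out of scope.
* The gammatone stage fixes the exact compression/sharpening recipe by
  convention where the literature leaves it open; both are configurable.
* Electrode anatomy is out of scope; the anatomical inclusion criterion
  of the modelled study is represented by an explicit whitelist
  (synthetic mode whitelists all electrodes).
* The jackknife penalty search is per-fold with per-electrode
  aggregation; a per-electrode search before the mode is an equally
  defensible reading of the procedure.
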