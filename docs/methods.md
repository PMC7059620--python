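# Methods

This note documents the models, conventions and numerical choices behind
`surfspike`, and what the synthetic data can and cannot show.

## Signal conditioning (`preprocess`)

High-frequency activity is isolated with a 3rd-order Butterworth high-pass
at 300 Hz applied forward and backward (zero phase; the effective magnitude
response is the squared single-pass response). Edges use odd-reflection
padding of three filter orders; the forward–backward composition is
time-reversal symmetric away from edge transients, which decay within a few
hundred samples at 20–30 kHz.

Stimulus onsets come from a sync channel carrying a 1–5 kHz tone burst per
presentation: band-pass, analytic-signal magnitude, threshold at 0.5 × the
95th magnitude percentile (robust to absolute level), 1 s refractory between
detections. On clean synthetic sync the detected onsets are within 1 ms of
truth.

The stimulus amplitude envelope is |Hilbert|, zero-phase low-passed and
polyphase-resampled to 200 Hz so it shares the 5 ms grid of binned spike
counts. The low-pass cutoff is not dictated by the analysis itself beyond
being below the 100 Hz target Nyquist; the default is 50 Hz and it is an
explicit parameter.

## Unit characterization (`unit_metrics`)

Waveform convention: *peak* = global minimum (initial depolarization),
*trough* = maximum strictly after the peak (earliest on ties), duration =
peak-to-trough interval, amplitude = max − min, trough/peak = signed ratio
(≤ 0 for canonical biphasic spikes). *Symmetry* — only loosely constrained
by the field's usage ("similarity about the waveform centre") — is defined
here as the Pearson correlation between the mean-removed waveform and its
time reversal: 1 for even-symmetric shapes, negative for strongly biphasic
asymmetric ones, consistent with the negative group values this preparation
reports. A monotone waveform (no post-peak maximum) has undefined features
and raises.

Burst classification builds a histogram of log₁₀(ISI) over [−3.5, 1.5]
decades (10 bins/decade, 3-point boxcar, normalized to sum 1). The void
parameter is 1 − g(min)/√(g(p₁)g(p₂)) over the two most prominent local
maxima (prominence ≥ 5% of the density maximum; all knobs exposed). Fewer
than two qualifying peaks ⇒ undefined ⇒ non-bursting; fewer than 20 ISIs ⇒
non-bursting by convention. The bursting threshold is 0.7, the convention
of the ISI-characterization literature the void statistic comes from; it is
a parameter. At these settings homogeneous Poisson trains (1–5 Hz, 1000
spikes) classify non-bursting and the generator's burst process bursting in
40/40 seeds each.

## Pair analysis (`pair_analysis`)

Cross-correlograms count spike pairs by lag t_surface − t_depth in half-open
5 ms bins over [−100, 100) ms, so positive lags mean the surface unit fires
after the depth unit. Counts are raw co-occurrences (not rate-normalized).
Analysis periods are an argument: the default is the full session (baseline
plus stimulus); baseline-only is selected by passing the baseline intervals.
Peak-lag ties resolve to the smallest |lag|, negative first, making the
statistic deterministic.

SPIKE-distance follows the standard time-resolved definition: at each t the
preceding/following spikes of each train are compared against the nearest
spikes of the other train, weighted by position within the local ISI and
normalized by the squared local mean ISI; the profile is averaged over the
interval. Auxiliary spikes sit at the interval edges. Because the profile
is linear between consecutive spikes of either train, the implementation
integrates it exactly segment by segment (trapezoid on segment endpoints);
the test suite checks it against an independent pointwise dense-grid oracle
to 10⁻³. Edge conventions: both trains empty → 0, exactly one empty → 1
(boundedness and continuity).

Depth-site coordinates place the shank at the surface-grid centre with site
z = insertion depth + index × spacing; insertion depth defaults to 600 µm,
matching the observation that the closest surface–depth single-unit pairs
in this preparation are at least 600 µm apart.

## Evoked responses (`stim_response`)

Counts are binned at 5 ms over a window from 200 ms before onset to at least
the stimulus end, averaged over trials, and smoothed with a centred 5-tap
moving average (shrinking window at edges; a 6-tap reading of "5th order"
would shift results by at most one bin and can be passed via `taps`). The
neural lag is the argmax of |cross-correlation| between the smoothed average
and the envelope over [0, 200) ms on the 5 ms grid — absolute value, so
suppressed (inverted) responses are treated like excited ones — and the
envelope is then delayed by that lag.

The onset-window test is a Pearson correlation over the 100 samples of the
−200…+300 ms window between the trial-averaged counts and the shifted
envelope, with Bonferroni correction over the family (analyzed units ×
stimuli — the most conservative per-run family; configurable) at α = 0.01.
The correlation uses the **raw** trial average by default: under the null
hypothesis the raw 5 ms bins are independent, so the Pearson t-test is
calibrated; correlating the smoothed average (`use_smoothed=True`) induces
serial correlation across the window and makes the nominal p anticonservative.
With the default, 200 simulated null units yield a flagged fraction within
the corrected nominal rate, and planted default-gain units are detected in
essentially every session.

Effect size is (μ_peak − μ_base)/σ_base on 5 ms bins: μ_peak over ±50 ms
around the peak of the smoothed average within the onset window (earliest
bin on ties), baseline statistics over the 200 bins of the 1 s before
onset, σ with population (n) normalization — at n = 200 the n vs n−1
distinction is negligible but fixing it makes results bit-reproducible.
Zero baseline variance leaves the effect size undefined (raises).

## Synthetic sessions (`synthdata`)

The generator emulates the study conditions: 54 presentations per session
(configurable 30–60), inter-stimulus intervals uniform on 7–15 s, recordings
at 20/30 kHz, a 32-contact 8×4 surface grid at 200 µm pitch with a 16-site
depth shank (50 µm spacing) through its centre. The stimulus stand-in is a
song-like envelope: raised-cosine syllables (default five 120 ms syllables,
150 ms gaps, ±30% amplitude jitter).

Units are inhomogeneous Poisson processes, sampled by thinning against a
200 Hz intensity grid:

  λᵢ(t) = max(0, rᵢ (1 + c·dᵢ(t))) + gᵢ · env(t − ℓᵢ)

with baseline rate rᵢ (lognormal around group medians 1.95/1.52 Hz),
stimulus gain gᵢ (default 15 Hz per unit envelope — a strong auditory onset
response), and planted lag ℓᵢ (default 50 ms). Bursting units (group
fractions 14/23 and 34/46 planted exactly) instead emit Poisson burst
onsets at rᵢ/2 followed by geometric(0.5) extra spikes at a 4 ms
intra-burst ISI jittered ±20%, which yields the bimodal log-ISI density the
void parameter requires; their stimulus gain is scaled by the mean burst
size (≈3) to keep evoked spike counts comparable.

The shared drive dᵢ(t) couples units through unit-variance
Ornstein–Uhlenbeck processes (τ = 100 ms) attached to a 2×2×2 lattice of
cluster centres spanning the electrode bounding box; each unit mixes them
with weights exp(−d/300 µm) to its electrode, normalized to unit variance,
so pair coupling is the cosine similarity of weight vectors and decays
monotonically with electrode separation. The coupling strength (c = 1.5)
and timescale were set so that the planted synchrony gradient is actually
resolvable by SPIKE-distance at session scale — the generator's purpose —
giving pair correlations of synchrony vs. distance around 0.2–0.4 on
default sessions, the scale reported for this preparation. Weaker coupling
(c = 1, τ = 50 ms) leaves the gradient below the noise from the bursting
mix.

Waveform templates are difference-of-Gaussians (lobe width = duration/2.5)
parameterized by peak amplitude, trough amplitude and duration, sampled at
the session rate; group medians are lognormal around 0.167/0.5 ms duration,
53.4/107.3 µV amplitude and −0.65/−0.32 trough/peak. Rendered averages of
50 noisy snippets round-trip through feature extraction to within a few
percent (lobe overlap compresses amplitude by ~4%; sampling quantizes
duration to one sample period).

Reproducibility: one global seed; the schedule, the drive and each unit
draw from independent streams keyed by a stable hash of the unit id, so
sessions are bit-identical under a fixed seed and unrelated units are
unaffected by population edits.

**What the synthetic data does not capture.** Real recordings have
spike-sorting errors and drift, non-Poisson regularity, rate
nonstationarity, stimulus-specific temporal selectivity beyond the
envelope, and waveform diversity beyond a two-lobed template. Passing tests
therefore demonstrate the *correctness* of the statistics and the
*recoverability* of planted structure, not the biological conclusions of
any particular dataset.

## Problem sizes

Defaults used by the test suite and the acceptance script were chosen to
estimate each quantity with comfortable margins: 50-trial sessions for lag
recovery (10 seeds per planted lag), 200 null units for the type-I check,
20 seeds for the distance–synchrony sign check with 8 surface × 16 depth
units (128 pairs, the scale of the published pair analysis), 200 units per
group for feature-median recovery, and 40 seeds per class for burst
classification. The whole suite runs in well under a minute of simulation
time.

## Known limitations

* The Bonferroni family and the envelope low-pass cutoff are conventions,
  not derived quantities; both are parameters.
* Correlogram counts are raw; rate-normalized variants would be needed to
  compare across units with very different rates.
* The exact-rank-sum path is limited to tie-free samples with min(n, m) ≤ 8;
  elsewhere the continuity-corrected normal approximation is used, which
  agrees with exact enumeration only to about the discrete-null lattice
  spacing (~0.01–0.02 at n = m = 8).
* SPIKE-distance is computed for one interval at a time; very long sessions
  are O(total spikes) per pair, which is fast, but no windowed/profile
  output is exposed.
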