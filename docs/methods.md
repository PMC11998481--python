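# Methods

This note documents the models, estimators and design choices behind
`beatrack`, the assumptions they make, and what the synthetic-data tests
do and do not establish about real data.

## Synthetic stimuli

The tonal generator walks a first-order Markov chain over the seven
degrees of a fixed major scale. Transition probabilities factor into a
tonal weight per target degree (a Krumhansl-style profile restricted to
in-key degrees, defaults `(5, 2, 3.5, 2.5, 4.5, 2, 1.5)` so the tonic
triad dominates) and a proximity kernel `exp(-dist/τ)` (τ = 1.5 degrees)
favoring small melodic steps. Both are configuration, not constants. The
melody walks the chain in eighth notes one octave above the key root, the
bass in quarter notes one octave below; at 46 bpm in 4/4 this produces
the 92-bpm dominant eighth-note pulse with a 652-ms inter-beat interval.
Because the chain starts from its stationary law, the long-run
scale-degree histogram equals the stationary distribution of the
configured transition matrix — the test oracle computes that distribution
independently by eigendecomposition.

Atonalization shifts each note by k semitones, |k| uniform on 1..9 with
random sign (100–900 cents), re-drawing any shift that would leave the
MIDI range rather than clipping, so the shift law stays uniform away from
the range edges. Timing, voices, tempo and meter are untouched, which is
the point of the manipulation: identical rhythm, destroyed tonal
hierarchy.

The audio-free envelope render gives each note a percussive kernel — a
10-ms linear attack and an exponential decay with τ = duration/3 — summed
over notes. No synthesis recipe exists for the "true" stimuli; any
onset-locked kernel with energy at the note onsets serves the purpose,
and the kernel is documented configuration. It is linear in amplitude and
translation-equivariant, and carries no timbre, dynamics or expressive
timing: conclusions about envelope *extraction from audio* rest on the
filterbank tests with amplitude-modulated noise instead.

Simulated recordings place a standardized, lag-delayed mixture of
stimulus features (delay applied as a circular shift to preserve
stationarity) into a chosen set of channels at a controlled
signal/noise variance ratio, on top of spatially independent 1/f noise
(exponent 1). There is no volume conduction, no artifacts, no
non-stationarity: the simulation validates estimators and statistics, not
preprocessing. Tap sequences put taps on the beat grid starting at t = 0
with Gaussian jitter, each tap independently dropped at the lapse rate;
collisions are resolved by re-drawing.

All generators derive their streams from one top-level seed through
per-component child seeds (hash of the component name), so results are
bit-reproducible and components are insensitive to each other's draws.

## Stimulus features

The wideband envelope band-passes the audio into 8 bands equidistant on
the ERB-rate scale between 100 and 8000 Hz (order-3 Butterworth, forward
and reverse), takes analytic magnitudes, averages, and resamples to
150 Hz (polyphase, reflection padding of three filter time-constants).
Filtering happens at the native audio rate; a 100–8000 Hz filterbank is
not realizable after downsampling to 150 Hz, so only the envelope is
downsampled. The Greenwood map could substitute for the ERB map; the ERB
scale is the common realization of a "cochlear frequency map". The
envelope is clipped at zero after resampling (polyphase filters can
undershoot), which preserves homogeneity.

Modulation spectra use non-overlapping 6-s windows, demeaned and
Hann-tapered, amplitude (not power) spectra, mean ± SEM across windows,
restricted to 0–12 Hz. The amplitude units are internal — only
within-pipeline contrasts are meaningful. Beat-related averages read the
nearest bins to {0.5, 1, 2, 3, 4} × the beat frequency.

Roughness locates spectral peaks per 50-ms Hann frame (25-ms hop, the 20
largest peaks) and sums the Plomp–Levelt pairwise dissonance in the
Sethares parameterization, `a1·a2·(e^{-3.5 s d} − e^{-5.75 s d})` with
`s = 0.24/(0.0207 f_low + 18.96)`. This mirrors the standard
toolbox-family estimator without claiming bit-level equivalence to any
particular implementation; its unit is arbitrary and only ordinal
comparisons are used.

## Surprisal model

The predictor is a simplified PPM. Counts are kept for all context
lengths 0..max_order (default 3; unbounded-order PPM* is out of scope).
Prediction interpolates from short to long contexts with escape method C:
at each context, observed symbols get `c/(t+e)` and the escape mass
`e/(t+e)` (t = total count, e = distinct continuations) multiplies the
next-shorter distribution, bottoming out at uniform over the alphabet —
every symbol keeps strictly positive probability, which bounds IC above
by log2 of the effective alphabet size. The long-term model is trained on
a corpus; the short-term model accumulates the same statistics within the
piece being scored, updated after each note. The two distributions merge
by an entropy-weighted geometric mean (weights ∝ 1/(H+1)), the weighting
family used by entropy-based mixtures of experts; the rule is
configurable.

Scoring reduces polyphony to monophonic lines first: highest pitch per
onset is the melody, lowest is the bass. Viewpoints are `pitch` (MIDI
numbers) and `onset-interval` (inter-onset intervals in ms), the latter
covering timing-surprisal controls with the same machinery. The
continuous surprisal signal holds each note's IC over the note's duration
(gaps carry 0 by default, configurable to hold) and is smoothed by a
unit-area Gaussian kernel; σ is interpreted in SAMPLES at the 150-Hz
analysis rate (σ = 50 ≈ 333 ms) since no unit is standard. Smoothing with
`reflect` boundaries conserves constants and (to ~1%) the mean.

At desk scale the corpus is 60 generated melodies (~40 notes each) rather
than a 953-melody folk-song collection; the absolute IC values therefore
characterize this generator family, not Western folk music. On 100
simulated tonal/atonalized pairs the atonalized member receives the
higher median IC in ≥95% of pairs, and the mean ICs (about 2.7 vs 7.4
bits) sit in the same regime as published tonal/atonal contrasts — a
directional analog, not a reproduction.

## Gaussian-copula MI

Each variable is rank-transformed (stable ordinal ranks, ties broken by
occurrence) to uniform scores `(r − 0.5)/n` and mapped through the normal
quantile function. MI is then the Gaussian formula on covariances of the
transformed data, in bits, with the analytic digamma small-sample bias
correction (`ψ((n−i)/2)` terms); the correction is configurable off. By
construction the estimate is invariant to strictly monotone marginal
transforms, supports multivariate blocks (melody+bass IC jointly) and the
conditional form `CMI(x;y|z) = MI(x;[y z]) − MI(x;z)`, floored at zero by
default since the population quantity is non-negative. Argument order is
canonicalized internally so symmetry holds exactly in floating point.
The estimator captures dependence expressible after marginal
Gaussianization — like the parent framework, it is insensitive to
dependence structures with zero Gaussian correlation.

Tracking filters both sides (zero-phase order-3 Butterworth; 0.5–3 Hz for
envelope, 0.1–50 Hz for surprisal), advances the recording by the
stimulus–brain lag (brain lags stimulus), discards the first 500 ms, and
computes MI per channel. A fast path computes all channels against many
feature blocks via correlation matrices; it is exactly equal to the
per-pair estimator and is exercised by an equality test.

### Lag selection

The lag grid is 40–200 ms in 20-ms steps (all integer sample shifts at
150 Hz). Per 1-Hz-spaced band between 1 and 12 Hz, the instantaneous
phase difference between Cz and the lag-delayed feature is reduced to its
mean unit phasor; the phasors are averaged ACROSS bands and the magnitude
taken, and profiles are averaged across conditions before the argmax
(ties break toward the smaller lag). Averaging complex phasors across
bands — rather than averaging per-band phase-locking magnitudes — is
deliberate: for narrowband (and especially quasi-periodic) signals a
constant lag error only adds a constant per-band phase offset, which
leaves each band's phase-locking magnitude unchanged, so a
magnitude-averaged profile is flat in the lag. The cross-band phasor
average is phase-slope sensitive: at the true lag all band offsets sit
near zero and add coherently; away from it they fan out in proportion to
frequency and cancel. With this definition an injected 120-ms lag is
recovered in 20/20 simulated replicates at SNR 0.5 (240-s recordings).

## Cluster statistics

Permutation nulls shuffle whole 1-s segments of the feature (trailing
partial segment stays in place; the sample multiset is preserved) and
re-run the identical MI pipeline; 3000 permutations is the full-scale
default, 200 the desk-scale default. For the vs-chance test the group
mean MI per channel is compared to the per-channel 95th percentile of the
permutation group means (participants averaged at matched surrogate
indices); supra-threshold channels form clusters over the montage
adjacency graph (minimum two electrodes), the cluster statistic is the
SUM of the channel statistic, and each cluster's sum is referred to the
null distribution of per-permutation maximal cluster sums — the standard
max-statistic construction that controls the family-wise error at the
cluster level. Condition contrasts use the paired t per channel with the
Student-t criterion (2.09 ≈ 2.1 at n = 20), clusters formed by sign,
two-tailed against the null of maximal |t-sums| from surrogate datasets
paired across conditions. Brain–behavior correlations are Fisher-z
transformed (guarded at |r| = 1), thresholded at the two-sided 2.5/97.5
permutation percentiles per channel, with a Spearman variant for rank
sensitivity checks.

Adjacency is a Euclidean-distance threshold on the normalized template
montage (32-channel 10-20 layout from mne's standard definitions). The
default threshold is 0.6 of the head radius: on this template
nearest-neighbor chord distances span 0.31–0.55 of the radius, so
anything below ~0.56 leaves channels isolated and no two-electrode
cluster could ever form; 0.6 yields a sparse connected graph (mean ~3.3
neighbors; Cz borders FC1/FC2/CP1/CP2). The threshold is configuration.

Lateralization tests average left- and right-hemisphere members of
channel pairs per participant, run a two-sided paired t per test, and
correct across tests with Benjamini–Hochberg FDR at 5%. Regression models
are ordinary least squares with named predictor columns (an interaction
helper builds product terms); rank-deficient designs are rejected.

The validation studies in `beatrack.validation` share the surrogate set
across simulated participants within a replicate — the exact form of
"matched surrogate indices", valid because the simulated channel noise is
independent across participants — and measure: family-wise false-positive
rate over 100 pure-noise group replicates (binomially compatible with the
nominal 0.05 for both cluster tests), and ≥80% detection of a 6-channel
driven cluster at SNR 0.5 with 20 participants and 60-s signals.

### A limitation of the segment-shuffle null for periodic features

A randomization test is exact when the observed feature is exchangeable
with its surrogates. The synthetic envelope is a strictly periodic
deterministic kernel train, and 1-s segment shuffles of it are *not*
distributionally equivalent to it: against the intact envelope,
pure-noise MI has a higher chance-level mean and spread (fewer effective
degrees of freedom in the beat band) than against the shuffled
surrogates, which makes the one-sided vs-chance test anti-conservative —
empirically a family-wise rate around 0.10 instead of 0.05 under these
worst-case conditions. The cluster machinery itself is exact (53/1000
false positives on i.i.d. Gaussian maps), and the correlation cluster
test is immune (the null distribution of a correlation with an
independent behavior vector does not depend on the MI marginals).
Accordingly, `fwer_study` validates type-I error with the observed
feature drawn from the shuffle orbit (exchangeability holds by
construction; the rate is nominal), and additionally reports the
periodic-envelope stress case. Real music envelopes sit between these
poles — expressive timing, varying polyphony and decaying resonance all
break exact periodicity — but chance levels for strongly isochronous
stimuli should be interpreted with this caveat in mind.

## Tapping analysis

Cleaning follows fixed rules: taps before 981 ms are dropped (the first
two beats of a 652-ms pulse, letting the participant hear two eighth
notes); consecutive-tap intervals outside 50–3000 ms are removed
(intervals spanning a removed interval are not re-bridged); trials with
fewer than the minimum surviving intervals are excluded — 6 in the 16-tap
design and 15 in the 32-tap design, taken as literal configuration since
no exact 50%-rule derivation reproduces both; within participant ×
condition, trials containing an interval above the pooled mean + 3 SD are
excluded, and participants whose condition-mean MAD exceeds the group
mean + 3 SD are excluded. Variability is the unscaled median absolute
deviation in ms (no 1.4826 normal-consistency factor — it is reported as
a raw dispersion, not an SD estimate). The condition contrast is a
one-tailed Wilcoxon signed-rank test on per-participant condition means
(exact enumeration for ≤12 non-zero differences, normal-approximation Z
otherwise, zero differences excluded). With Gaussian jitter σ the
inter-tap intervals have MAD ≈ 0.6745·√2·σ, which the Monte-Carlo oracle
in the tests reproduces; simulated jitter of 30 vs 36 ms at n = 20
participants yields a decisive one-tailed contrast.

## Problem sizes and numerical choices

Desk-scale runs use ~60-s stimuli (12 bars at 46 bpm), 20 simulated
participants, 200 permutations, a 60-melody training corpus, and 240-s
recordings for lag recovery; these sizes are the package's validation
defaults and all are configurable up to full scale (300-s stimuli, 3000
permutations, 953-melody corpora). Permutation p-values use the
add-one estimator `(1 + #{null ≥ obs})/(1 + n_perm)`. Filters are
applied with reflection padding of three time-constants at the low band
edge. Degenerate inputs fail loudly: constant columns in the copula
transform, singular joint covariances, rank-deficient designs, empty
corpora and sequences, bands outside Nyquist, missing montage channels.

## Known limitations

- The synthetic recordings have no volume conduction, artifacts or
  autocorrelated inter-participant structure; passing FWER/power tests
  validates the statistics under the stated noise model only.
- The PPM here is a documented simplification (bounded order, single
  escape method, one merge rule); absolute IC values are not comparable
  to full IDyOM outputs.
- Roughness and modulation-spectrum amplitudes are internal units.
- MIDI import is minimal (type 0/1, note on/off, first tempo applied
  globally, monophonic-per-track assumption).
- Tapping accuracy/asynchrony relative to the beat is intentionally out
  of scope; only interval variability is analyzed.
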