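# Methods

This note documents the models, numerical choices and limitations behind
`amcascade`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and demodulation

A speech waveform is z-scored (population SD, divisor T) so absolute
intensity cannot leak into modulation features, and excerpts shorter than
10 s are excluded.  The demodulation model is

    y_t = m_t · c_t,    m_t = exp(x_t),    c_t ~ N(0, σc²) i.i.d.,

with `x` a stationary Gaussian process.  The estimate is the MAP pair:
`x̂` maximizes the log joint of the Gaussian-carrier likelihood and the GP
prior, and the carrier is the residual `y / m̂`, so the product
reconstructs the input exactly (machine precision; the cascade-level
tolerance is relative RMS 1e-3).

### Numerics

- `x` is parameterized by its Fourier coefficients at frequencies at or
  below the cutoff `fc` only, synthesized on the signal grid by
  zero-padded inverse FFT.  The timescale constraint is therefore
  structural: the modulator cannot contain content above `fc`.  An earlier
  scheme (latent grid + linear interpolation) was discarded because
  interpolation images aliased envelope power above the cutoff.
- The prior spectral density carries a super-Gaussian in-band shoulder
  `exp(-(f/fc)^6)` and is normalized so the latent's marginal variance
  equals `prior_variance` (default 4) regardless of how densely the grid
  samples the band; without that normalization the effective prior
  strength would scale with the sampling rate.
- MAP ascent uses L-BFGS-B with analytic gradients (`ftol` 1e-8, at most
  500 iterations).  Initialization is deterministic — the log of the
  low-passed absolute signal — so inference uses no random numbers, and
  the recorded log-posterior trace is non-decreasing.
- The carrier/modulator scale ambiguity is resolved by normalizing the
  carrier to unit variance.
- Signals longer than `chunk_s` (default 10 s) are processed in chunks
  with 1-s overlaps cross-faded in the log domain; a chunk with vanishing
  variance gets a flat modulator and a convergence flag.

### Cascade

Round 1 demodulates the waveform at the 40 Hz cutoff, yielding the broad
envelope and the >40 Hz carrier.  Rounds 2–4 re-demodulate the previous
round's *modulator* at 12, 4 and 1 Hz; because those inputs are positive
envelopes, the MAP fit runs in the log domain (Gaussian observation model
on the log-envelope), which keeps both daughters strictly positive.  The
per-round fast daughter (previous envelope / new modulator) is the band
envelope: beta/gamma from round 2, theta/alpha from round 3, delta from
round 4, low-delta the final modulator.  Band edges are fixed at
1/4/12/40 Hz.  An alternative recursion that peels bands slow-to-fast off
the fast daughter is available (`recursion="carrier"`), as is a
linear-domain envelope fit (`envelope_fit="envelope"`); the linear fit
factorizes products of band-limited envelopes more cleanly but is not
positivity-safe near deep envelope minima (amplitude intermodulation of
order `d_p·d_s/2` can drive the fit negative), so the log-domain fit is
the default.

Known systematic of the log-domain split: the log of a deeply modulated
envelope has harmonics above its own band (for depth 0.8 the second
harmonic is ~25% of the fundamental), so a few percent of a strong
prosodic rhythm's power is attributed to faster bands.  This is intrinsic
to frequency-splitting the log-envelope and is shared by any cascade of
this type; it is why group contrasts on the matched bands are evaluated
on cohorts with realistic between-speaker variance (below).

## Modulation spectra

"Frequency power" of a rhythm is the summed one-sided periodogram power
of that band's own envelope within the band — prosody (1, 4], syllable
(4, 12], phoneme (12, 40] Hz — after mean removal, with zero-padding to at
least 0.1 Hz resolution.  The normalization satisfies Parseval exactly:
total one-sided power equals the envelope variance (checked to 1e-6 on
every fixture).  Content below 1 Hz is excluded from all band summaries
(sentence-level rhythm, not phonology).  As a cross-check the band powers
of the broadband envelope (product of the three band envelopes) are also
reported.  No window taper is applied by default; envelopes are analysed
at the 160 Hz envelope grid so the 12–40 Hz band is fully resolved.
Scalograms use an analytic complex-Morlet CWT on log-spaced frequencies
0.1–40 Hz over a seeded random 4-s excerpt, in dB with the maximum at
0 dB.

## Transfer entropy

Plug-in estimator on equal-occupancy (quantile) symbols; ordinal ranks
break ties, and already-discrete data (≤ n_bins distinct values) keep one
bin per value so the estimator agrees with exact enumeration on discrete
chains (verified to 0.02 bits at n = 1e5).  Defaults: 4 bins, history
L = 1, envelopes polyphase-resampled to 120 Hz.  Units are bits; negative
finite-sample estimates are clipped at zero with the raw value retained.
Quantile binning makes the estimate invariant to strictly monotone
transforms of either series.  The plug-in bias is controlled by a
circular-shift surrogate null (≥19 seeded rotations of the source by at
least 1 s); estimates are reported with the null mean and sample SD.
Because binning, L and the envelope rate are free choices, absolute TE
values are comparable only within a fixed configuration; orderings and
group contrasts are the meaningful quantities.

## Synthetic cohorts

One sample is `[1 + d_p s_p][1 + d_s(t) s_s][1 + d_f(t) s_f] · carrier`
plus white noise at 20 dB SNR; the carrier is white noise (or >40 Hz
band-passed noise), and each `s` is a jittered oscillation — a phase
random walk whose instantaneous rate wanders with SD 10% of the nominal
rate — so envelopes have realistic bandwidth.  Rates default to 2/6/20 Hz
and depths to 0.8/0.6/0.4; ground-truth envelopes are stored on the
160 Hz envelope grid.

Slow→fast coupling gates the faster level's depth by the slower level's
phase: `d_s(t) = d_s · g(t)`, `g ∝ 1 − κ + κ(1 + s_p)/2`, RMS-normalized
so that coupling strength does not change the gated level's modulation
power (without the normalization κ alters mean depth, confounding the
coupling contrast with a band-power contrast).  Instantaneous depths are
clipped below 1 so envelopes stay strictly positive.

Cohorts draw, per speaker: prosody depth Beta(7,3) (mean 0.7) with
κ = 0.7 for the NT-like preset, Beta(2,8) (mean 0.2) with κ = 0.2 for the
AUT-like preset; syllable and phoneme depths N(0.6, 0.12) and
N(0.4, 0.08), clipped, identically distributed in every group — matched
rhythms vary across talkers, as in real cohorts, but carry no group
difference.  Durations are uniform on 10–30 s at 8 kHz; 8 dyads per group
by default, two questioners; each questioner's prosody depth is
`0.05 + 1.0 × respondent depth + N(0, 0.05)`, giving the dyadic
correlation the dyad statistics are designed to detect.  All randomness
flows from one seed per spec; cohort seeds are derived by seed-sequence
splitting.

What the generator does not emulate: formant structure, pitch contours,
pauses and turn-taking, mora timing, recording-channel effects.  Passing
tests therefore demonstrate that the pipeline recovers nested-AM structure
and group/dyad contrasts of the stated kind — not that real conversational
recordings satisfy the generative assumptions.

## Statistics

Primary inference is permutation-based: group labels are shuffled across
units with each unit's within-factor profile intact.  Units are per-dyad
means — samples within a conversational pair are not independent, and at
the default cohort size 30 samples per group come from 8 speakers, so
sample-level permutation would be anticonservative.  The interaction
statistic is the centered between-group difference profile (levels
standardized first); per-level contrasts are two-sided mean differences
with BH adjustment; p-values use the add-one convention
`(b + 1)/(B + 1)` with B = 1000 by default.  A Greenhouse–Geisser-
corrected mixed ANOVA (pingouin) is attached for comparability, never as
the primary test.  The dyadic association is a one-tailed (positive)
correlation, Pearson unless Shapiro–Wilk rejects normality of either
margin (then Spearman), with an exact pairing-permutation p for n ≤ 10
and the asymptotic p above.  α = 0.05 throughout.

Type-I calibration of the permutation contrast and the Shapiro–Wilk gate
(5% ± 2% over 500 null simulations) and the BH hand-checks are exercised
in the acceptance tests.  BH step-up is monotone and bounded but not
idempotent — re-adjusting adjusted values can raise them further — so only
monotonicity is asserted.

## Problem sizes

The validation suite uses 10-s samples at 8 kHz for cascade work, cohorts
of 30 samples per group for contrast and coupling checks, 1e5-point chains
for the TE oracle, and 100–500 replicate simulations for calibrations;
`scripts/acceptance.py` uses 10 recovery seeds, 50 calibration runs, two
30-sample coupling cohorts and one full demo cohort.  These sizes give
stable medians and rates while keeping a full run in the minutes range on
one CPU.

The group-contrast null (no syllabic/phonetic difference) is a stochastic
event: with 8 speakers per group drawn from matched distributions, a
single cohort can be imbalanced by chance, so the acceptance check runs
three independent cohorts and requires the null pattern in the majority.

## Known limitations

- MAP point estimates only; no posterior uncertainty over envelopes, and
  θ is set manually per band rather than learned.
- The Fourier parameterization is periodic over each chunk; envelopes
  with strongly mismatched ends incur a localized seam effect within
  ~1/fc of the boundaries.
- Log-domain band splitting attributes deep-modulation harmonics to
  faster bands (quantified above).
- The plug-in TE estimator is biased upward at small n; surrogate nulls,
  not absolute values, carry the inference.
- Group presets are qualitative stand-ins; real effect sizes for depth
  and coupling in autistic vs neurotypical speech are unknown.
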