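# Methods

`qeeg` implements a channel-wise entropy/complexity analysis of two-group
resting-state EEG: eight scalar features per channel per participant,
compared between a typically developing (TD) group and an autism (ASD)
group with two nonparametric tests under Bonferroni correction. Because no
public recordings accompany this kind of clinical cohort, the package
includes a synthetic-cohort generator so every stage runs end-to-end from a
single seed.

## Segmentation

Features are computed on one continuous artifact-free segment per
recording: the longest run of clean samples (per-sample boolean mask,
earliest run wins ties), trimmed across the cohort to the common minimum
length, keeping each segment's first samples. Indexing is 0-based with
half-open windows. At the reference conditions — 43 s minimum at 250 Hz —
each channel contributes 10,750 samples, 204,250 values per 19-channel
participant. Manual artifact review cannot be codified, so the mask is an
input; recordings without a mask are treated as fully clean (the synthetic
cohorts are clean by construction).

An optional preprocessing flag applies the recording-chain filters:
zero-phase 6th-order Butterworth 0.53–50 Hz band-pass plus 45–55 Hz
band-stop. Only the corner frequencies are externally specified; the order
is ours, chosen so a 60 Hz mains component is suppressed below 5 % RMS in
steady state. The flag defaults to off because the generator is already
band-limited.

## Spectral features

The PSD is Welch's estimate with 2-s Hann windows and 50 % overlap
(0.5 Hz grid; ≈42 windows over 43 s). Window length and overlap are
configurable; a plain periodogram over 43 s would be an unbiased but far
noisier choice.

Five bands, half-open so the shared edges are unambiguous: Delta
[0.5, 4), Theta [4, 8), Alpha [8, 12), SMR [12, 15), Beta [15, 20) Hz.
Relative band power divides each band's summed PSD by the total over the
five bands. The per-Hz variant uses 1-Hz bins [k, k+1) up to 20 Hz.

**Brain rate** is the power-weighted mean band frequency
BR = Σᵢ fᵢ Pᵢ / Σᵢ Pᵢ with fᵢ the band midpoints (2.25, 6, 10, 13.5,
17.5 Hz). A spectral-centroid variant (per-bin weighting) would shift all
values slightly but not the group contrast; the banded form is the default
because the band powers are already part of the feature set.

**Spectral entropy** is the Shannon entropy of the PSD normalized over
[0.5, 20) Hz, in nats, un-normalized (dividing by ln n would only rescale
a per-cohort constant since every channel shares the grid).

## Time-domain features

All logs are natural unless stated. Every estimator is deterministic and
pure; each has an independent brute-force oracle in the test suite
(naive pattern counting, O(n²) template loops, exhaustive substring
parsing, dense mixture integration) that it must match to 1e-9 relative
(exactly, for integer counts).

* **Permutation entropy** (D = 3, τ = 1): Shannon entropy of the ordinal
  pattern distribution, in [0, ln D!]. Ties inside a window are broken by
  order of appearance (stable argsort) — EEG amplitudes rarely tie, but the
  rule must be fixed for bit-reproducibility.
* **Sample entropy** (m = 2, r = 0.2 × per-channel SD): −ln(A/B) with
  Chebyshev distance and self-matches excluded. Matching is strict
  (distance < r). A constant series returns 0; A = 0 with B > 0 returns
  +inf (documented sentinel); B = 0 raises. The production path enumerates
  candidate pairs through a sorted window on the first template component —
  an exact reformulation, not an approximation.
* **Rényi entropy** (α = 2): differential entropy
  H₂ = −ln ∫ f(x)² dx of a Gaussian-kernel density estimate of the
  amplitude distribution; classic Silverman bandwidth
  0.9·min(SD, IQR/1.349)·n^(−1/5), 1024-point grid spanning the data range
  padded by ±3 bandwidths, trapezoid quadrature. Kernels are truncated at
  8 bandwidths (relative error ≲1e-13). Being differential, the value is
  translation-invariant, gains ln c under amplitude scaling by c, and can
  be negative for sharply concentrated signals — it is used here as a
  relative group measure, not an absolute information content.
* **Tsallis entropy** (q = 1.5): S_q = (1 − Σ pᵢ^q)/(q − 1) on a 100-bin
  equal-width amplitude histogram spanning [min, max]. With q > 1 the value
  saturates below 1/(q − 1) = 2 as the histogram flattens; the saturation
  point depends on the bin count, so `n_bins` is configurable. Note the
  [min, max] support makes this feature scale-invariant: group differences
  reflect the *shape* of the amplitude distribution, unlike Rényi above.
* **Higuchi fractal dimension** (k_max = 10): the canonical offset-averaged
  algorithm — normalized curve lengths L(k) for k = 1..k_max, dimension =
  least-squares slope of ln L(k) vs ln(1/k); ≈1 for smooth curves, ≈2 for
  white noise.
* **Lempel–Ziv complexity**: the signal is binarized at its mean (strictly
  above → 1; ties and constants → 0) and parsed with the LZ76
  exhaustive-history rule — a word closes when it stops being a substring
  of the prefix concatenated with the word minus its last symbol; a
  trailing reproducible word counts once. This parse gives 6 for
  `011001011110`. A length-normalized variant c(n)·log₂(n)/n is reported
  alongside the raw count (all cohort segments share one length, so the
  two are equivalent for the group tests).

## Group statistics

For each of the 8 features × 19 channels, the TD and ASD samples are
compared with the two-sample Kolmogorov–Smirnov test and the Mann–Whitney
U test (exact enumeration when both groups have ≤ 20 observations,
tie-corrected normal approximation otherwise), both two-sided. A channel is
flagged significant only when **both** p-values fall below the Bonferroni
threshold α/m with α = 0.05 and m = 19 channels per feature (0.05/19 ≈
0.0026, displayed to 4 decimals, full precision retained internally).
Correcting per feature family of 19 channels — not for all 152 tests — is
deliberate: each feature is interpreted as its own family of 19 hypotheses.

Normality screening (Shapiro–Wilk plus one-sample KS against a normal with
estimated parameters, Lilliefors-corrected since the parameters come from
the sample) motivates the nonparametric choice. Group summaries use
t-based 95 % confidence intervals of the mean; a prediction-interval
reading of "error bars" is also defensible, but mean CIs are the plotting
convention adopted.

The conjunction flag is conservative by construction: its null rate is
bounded by each test's own rate, but the two p-values are strongly
positively dependent (they test the same samples), so the conjunction rate
is roughly α_corr/2–α_corr — *not* α_corr² as an independence argument
would suggest. Null-cohort tests in the suite use bounds consistent with
the dependent behavior.

## Synthetic cohort

Defaults: 39 TD + 49 ASD participants, 19 channels (10/20 montage), 43 s
at 250 Hz, background SD 10 µV. Per channel, three ingredients:

1. **1/f^β background**: white Gaussian noise spectrally reshaped to
   PSD ∝ f^(−β) (flat below 0.5 Hz, no DC), normalized to zero mean and
   unit SD. TD β = 1.0, ASD β = 2.4.
2. **Alpha component**: narrowband Gaussian noise (Gaussian spectral
   window, SD 0.5 Hz, centered at 10.5 Hz), RMS = gain × background SD.
   TD gain 1.2, ASD 0.3.
3. **Spike transients** (ASD only): biphasic derivative-of-Gaussian sharp
   waves of ≈70 ms at quasi-periodic times (rate 2 Hz, period jittered
   ±10 %), amplitude 1.0 × background SD.

The ASD signal is finally scaled by 1.8. Within-group variance comes from
±15 % per-participant and ±10 % per-channel multiplicative jitter on gains
and scales; one integer seed spawns an independent stream per participant,
so cohorts are reproducible and order-independent.

The calibration was chosen once so that the generative mechanisms produce
the group contrasts this analysis is designed to detect, and each contrast
has an identifiable cause:

* **lower ASD brain rate** — the steep β shifts relative power into the
  slow bands;
* **higher ASD Rényi entropy** — the 1.8× amplitude scale (differential
  entropy gains ln 1.8), with the TD alpha adding back only part of it;
* **higher ASD Tsallis entropy** — a 43-s realization of strongly
  autocorrelated 1/f^2.4 noise is quasi-oscillatory, so its amplitude
  histogram is flatter-than-Gaussian, while the TD marginal stays Gaussian
  because the alpha component is itself Gaussian (narrowband noise, not a
  constant-amplitude sinusoid);
* **lower ASD Lempel–Ziv complexity** — the slow background produces few,
  regular mean crossings against the TD's fast irregular ones.

Two calibration cautions discovered while designing the generator, kept
here because they constrain reuse: a *constant-envelope* sinusoidal alpha
makes the TD marginal bimodal (arcsine-like) and flips the Tsallis
contrast; and large-amplitude spikes (≳2 × SD) inflate the ASD histogram
range, re-concentrating the bulk and again flipping Tsallis — which is why
the spike amplitude is moderate. On white-like backgrounds, strong regular
spikes *lower* LZC by replacing irregular crossings with repeating words
(the classic account of spike-driven LZC reduction); on slow backgrounds
they add crossings and raise it slightly. In this calibration the LZC
contrast is carried by the background, with spikes as a secondary,
physiologically motivated ingredient.

What the generator does **not** emulate: real electrode covariance (channels
are independent up to shared participant-level jitter), eye/movement
artifacts, age or severity covariates, non-stationarity beyond the alpha
envelope, and any quantitative effect size from a real cohort — the
literature reports directions and significance patterns, not effect
magnitudes, so only those are recoverable. Passing cohort-level tests
therefore demonstrates that the pipeline detects the modeled contrasts with
correct directionality and calibrated false-positive behavior, not that it
reproduces any particular clinical dataset. The synthetic effects are much
stronger than typical real-data effects (most features reach significance
on nearly all 19 channels).

## Problem sizes and numerics

The cohort-level tests run the full default cohort (88 participants ×
19 channels × 43 s, seed 0) once and share it across checks. The
null-calibration suite keeps the 39 + 49 group sizes (they determine the
tests' discreteness and asymptotics) but shortens signals to 4 s: signal
duration moves estimator noise, never null test validity. Oracle batteries
use ≥100 random inputs of length ≤ 500 per estimator.

Degenerate inputs are defined, not patched around: constant series → SampEn
0, all-zero binarization (LZC 2), single-bin histogram (Tsallis 0), density
estimation refuses zero variance, spectral normalizations refuse all-zero
power. p-values are written to CSV at full precision with display-rounded
companions (3 decimals). All CSV artifacts have stable column order and
'\n' line endings, so a rerun with the same config and seed is
byte-identical.

## Known limitations

* EDF support is asymmetric: reading goes through `mne`; writing uses a
  built-in minimal 16-bit EDF writer (1-s records, integer sampling rates,
  whole seconds). The delimited-text dialect is the primary interchange
  format.
* Rényi entropy inherits KDE boundary bias for compactly supported
  amplitude distributions (visible as ≈2 % error against the uniform
  closed form).
* The Higuchi slope is a finite-k regression; its "dimension" is only
  asymptotically in [1, 2] and can exceed the bounds by the fit tolerance.
* Exact MWU enumeration is used only up to group sizes of 20; beyond that
  the tie-corrected normal approximation applies (they agree to <0.02 at
  n = 15 per the suite).
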