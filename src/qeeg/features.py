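"""Time-domain entropy and complexity estimators, and the per-channel
feature vector.

Eight scalar features are computed per channel:

* brain rate and spectral entropy (frequency domain, see :mod:`qeeg.spectral`)
* permutation entropy — Shannon entropy (nats) of the ordinal-pattern
  distribution at embedding dimension D and delay τ
* sample entropy — −ln A/B where B (A) counts pairs of m-length
  ((m+1)-length) templates within Chebyshev tolerance r, self-matches
  excluded
* Rényi entropy of order α on a Gaussian-kernel density estimate of the
  amplitude distribution: H_α = ln(∫ f(x)^α dx) / (1 − α)
* Tsallis entropy of index q on an equal-width amplitude histogram:
  S_q = (1 − Σ p_i^q)/(q − 1), bounded by 1/(q − 1) as the histogram
  flattens
* Higuchi fractal dimension — slope of the log–log curve-length scaling,
  1 for smooth curves up to 2 for noise-like series
* Lempel–Ziv (1976) complexity of the mean-thresholded binary sequence —
  the number of new words in a left-to-right exhaustive-history parse;
  low counts mean repetitive threshold-crossing structure.

Defaults follow common quantitative-EEG practice: D=3, τ=1; m=2 with
r = 0.2 × signal SD; α=2; q=1.5; k_max=10; 100 histogram bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .spectral import (
    DEFAULT_BANDS, band_powers, brain_rate, compute_psd, spectral_centroid,
    spectral_entropy,
)

# ---------------------------------------------------------------------------
# parameter bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureParams:
    """Estimator parameters for the per-channel feature vector."""

    D: int = 3                 # permutation-entropy embedding dimension
    tau: int = 1               # permutation-entropy embedding delay
    m: int = 2                 # sample-entropy template length
    r_fraction: float = 0.2    # sample-entropy tolerance, fraction of SD
    alpha: float = 2.0         # Rényi order
    q: float = 1.5             # Tsallis index
    k_max: int = 10            # Higuchi maximum interval
    n_bins: int = 100          # amplitude-histogram bins for Tsallis
    se_f_lo: float = 0.5       # spectral-entropy band (Hz)
    se_f_hi: float = 20.0
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    bands: tuple = DEFAULT_BANDS
    brain_rate_method: str = "bands"  # "bands" (midpoint-weighted) | "centroid"


#: Feature columns in the order they appear in every output table.
FEATURE_NAMES = (
    "brain_rate", "spectral_entropy", "permutation_entropy", "sample_entropy",
    "renyi_entropy", "tsallis_entropy", "higuchi_fd", "lzc",
)


class FeatureExtractionError(RuntimeError):
    """An estimator failed; carries the channel and feature it failed on."""

    def __init__(self, channel: str, feature: str, cause: Exception):
        super().__init__(f"feature {feature!r} failed on channel {channel!r}: {cause}")
        self.channel = channel
        self.feature = feature


# ---------------------------------------------------------------------------
# permutation entropy
# ---------------------------------------------------------------------------

def permutation_entropy(x: np.ndarray, D: int = 3, tau: int = 1) -> float:
    """Shannon entropy (nats) of ordinal patterns in windows of length D.

    Each window of D samples (spaced ``tau`` apart) is mapped to the
    permutation that sorts it; ties are broken by order of appearance
    (stable sort), a fixed rule so results are reproducible. The entropy of
    the empirical pattern distribution lies in [0, ln D!].
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if D < 2 or tau < 1:
        raise ValueError("need D >= 2 and tau >= 1")
    n_win = n - (D - 1) * tau
    if n_win < 2:
        raise ValueError(f"series of length {n} too short for D={D}, tau={tau}")
    idx = np.arange(n_win)[:, None] + tau * np.arange(D)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (D ** np.arange(D))
    counts = np.bincount(codes)
    p = counts[counts > 0] / n_win
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    # Counts pairs of m- and (m+1)-templates within Chebyshev distance r
    # (strict). Template pairs are enumerated through a sorted sliding
    # window on the first component — only pairs with |x_i - x_j| < r can
    # match, so the remaining components are checked for those alone. The
    # counts are identical to the naive double loop over all pairs.
    n = x.shape[0]
    nt = n - m  # number of templates of length m and of length m+1
    order = np.argsort(x[:nt])
    xs = x[:nt][order]
    A = 0
    B = 0
    for a in range(nt - 1):
        i = order[a]
        b = a + 1
        while b < nt and xs[b] - xs[a] < r:
            j = order[b]
            ok = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) >= r:
                    ok = False
                    break
            if ok:
                B += 1
                if abs(x[i + m] - x[j + m]) < r:
                    A += 1
            b += 1
    return A, B


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None, r_fraction: float = 0.2
) -> float:
    """SampEn(m, r) = −ln(A/B) with Chebyshev distance, self-matches excluded.

    ``r`` is the match tolerance in signal units; when omitted it is resolved
    as ``r_fraction`` × the (population) standard deviation of ``x``.
    Matching is strict (distance < r). A constant series returns 0; if no
    (m+1)-template pair matches while some m-template pair does, +inf is
    returned; if no m-template pair matches at all a ``ValueError`` is
    raised (the statistic is undefined).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < m + 2:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = r_fraction * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    A, B = _sampen_counts(x, m, float(r))
    if B == 0:
        raise ValueError("no template matches at length m; SampEn undefined")
    if A == 0:
        return math.inf
    return float(-math.log(A / B))


# ---------------------------------------------------------------------------
# amplitude density / histogram and the generalized entropies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityEstimate:
    """Kernel density estimate of the amplitude distribution on a grid."""

    grid: np.ndarray
    f: np.ndarray
    bandwidth: float


def silverman_bandwidth(x: np.ndarray) -> float:
    """Classic Silverman rule-of-thumb: 0.9 · min(SD, IQR/1.349) · n^(−1/5)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * sigma * x.size ** (-0.2)


@njit(cache=True)
def _kde_on_grid(x, g0, dg, gridsize, h, trunc):  # pragma: no cover - jitted
    f = np.zeros(gridsize)
    w = trunc * h / dg  # kernel reach in grid steps
    for i in range(x.shape[0]):
        c = (x[i] - g0) / dg
        j0 = int(max(0.0, np.ceil(c - w)))
        j1 = int(min(gridsize - 1.0, np.floor(c + w)))
        for j in range(j0, j1 + 1):
            z = (g0 + j * dg - x[i]) / h
            f[j] += np.exp(-0.5 * z * z)
    return f


def estimate_density(
    x: np.ndarray, gridsize: int = 1024, cut: float = 3.0
) -> DensityEstimate:
    """Gaussian-kernel density estimate with Silverman bandwidth.

    Evaluated on a ``gridsize``-point grid spanning [min − cut·h, max + cut·h]
    by summation of the kernel mixture; kernels are truncated at 8
    bandwidths, which is exact to machine precision relative to the full
    sum. Requires at least 10 samples and nonzero variance.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < 10:
        raise ValueError("need at least 10 samples for density estimation")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance series has no density estimate")
    h = silverman_bandwidth(x)
    g0 = x.min() - cut * h
    g1 = x.max() + cut * h
    grid = np.linspace(g0, g1, gridsize)
    dg = (g1 - g0) / (gridsize - 1)
    f = _kde_on_grid(x, g0, dg, gridsize, h, 8.0)
    f /= x.size * h * math.sqrt(2 * math.pi)
    return DensityEstimate(grid, f, h)


def renyi_entropy(dens: DensityEstimate, alpha: float = 2.0) -> float:
    """Differential Rényi entropy H_α = ln(∫ f^α dx)/(1 − α), in nats.

    Computed by trapezoid quadrature on the KDE grid. Being differential, it
    is translation-invariant, shifts by ln c under amplitude scaling by c,
    and can be negative for sharply concentrated amplitude distributions.
    """
    if alpha <= 0 or alpha == 1:
        raise ValueError("need alpha > 0, alpha != 1")
    integral = float(np.trapezoid(dens.f ** alpha, dens.grid))
    if not np.isfinite(integral) or integral <= 0:
        raise ValueError("non-finite or non-positive Rényi integral")
    return float(math.log(integral) / (1.0 - alpha))


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probability vector over amplitude bins (or symbols); sums to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def n(self) -> int:
        return self.probs.size


def amplitude_histogram(x: np.ndarray, n_bins: int = 100) -> DiscreteDistribution:
    """Equal-width histogram over [min, max], normalized to probabilities.

    A constant series puts all mass in a single bin.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty series")
    if np.ptp(x) == 0:
        p = np.zeros(n_bins)
        p[0] = 1.0
        return DiscreteDistribution(p)
    counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    return DiscreteDistribution(counts / counts.sum())


def tsallis_entropy(p: DiscreteDistribution, q: float = 1.5) -> float:
    """Tsallis entropy S_q = (1 − Σ p_i^q)/(q − 1).

    For q > 1 this saturates below 1/(q − 1) (= 2 at q = 1.5) as the
    distribution approaches uniformity over many bins; 0 for a degenerate
    (single-bin) distribution.
    """
    if q <= 0 or q == 1:
        raise ValueError("need q > 0, q != 1")
    return float((1.0 - (p.probs ** q).sum()) / (q - 1.0))


# ---------------------------------------------------------------------------
# Higuchi fractal dimension
# ---------------------------------------------------------------------------

def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension via offset-averaged curve lengths.

    For each interval k = 1..k_max and offset m = 0..k−1, the normalized
    curve length of the decimated sub-series is

        L_m(k) = [ Σ_i |x(m + i k) − x(m + (i−1) k)| ] · (N−1)/(n_m k) / k ,

    with n_m = ⌊(N−1−m)/k⌋ steps; L(k) is the mean over offsets and the
    dimension is the least-squares slope of ln L(k) against ln(1/k).
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 10 * k_max:
        raise ValueError(f"series of length {N} too short for k_max={k_max}")
    ks = np.arange(1, k_max + 1)
    L = np.empty(k_max)
    for k in ks:
        lengths = []
        for m in range(k):
            n_m = (N - 1 - m) // k
            if n_m < 1:
                continue
            idx = m + np.arange(n_m + 1) * k
            total = np.abs(np.diff(x[idx])).sum()
            lengths.append(total * (N - 1) / (n_m * k) / k)
        L[k - 1] = np.mean(lengths)
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(L), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# Lempel–Ziv complexity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinarySequence:
    """A 0/1 sequence with the amplitude threshold that produced it."""

    bits: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.size == 0:
            raise ValueError("empty binary sequence")
        if not np.isin(b, (0, 1)).all():
            raise ValueError("bits must be 0 or 1")
        object.__setattr__(self, "bits", b)

    def __len__(self) -> int:
        return self.bits.size


def binarize_mean(x: np.ndarray) -> BinarySequence:
    """Threshold at the mean amplitude: 1 where x > mean, else 0.

    Strictly greater-than, so samples exactly at the mean (and a constant
    series) map to 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty series")
    thr = float(x.mean())
    return BinarySequence((x > thr).astype(np.uint8), thr)


def lz76_complexity(b: BinarySequence | np.ndarray) -> int:
    """LZ76 exhaustive-history word count of a binary sequence.

    Scanning left to right, the current candidate word closes as soon as it
    is no longer a substring of the previously parsed prefix concatenated
    with the candidate minus its last symbol; a trailing word still
    reproducible at the end of the stream counts as one word. Substring
    search runs on ``bytes`` so the scan is C-speed.
    """
    bits = b.bits if isinstance(b, BinarySequence) else np.asarray(b, dtype=np.uint8)
    s = bytes(bytearray(bits))
    n = len(s)
    if n == 0:
        raise ValueError("empty binary sequence")
    c = 0
    i = 0
    while i < n:
        k = 1
        # extend while s[i:i+k] occurs in s[:i+k-1]
        while i + k <= n and s.find(s[i:i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


def lzc_normalized(b: BinarySequence) -> float:
    """Length-normalized LZ76: c(n) · log2(n) / n, comparable across lengths."""
    n = len(b)
    if n < 2:
        raise ValueError("need at least 2 symbols to normalize")
    return lz76_complexity(b) * math.log2(n) / n


# ---------------------------------------------------------------------------
# per-channel feature vector
# ---------------------------------------------------------------------------

def extract_channel_features(
    x: np.ndarray, fs: float, params: FeatureParams = FeatureParams()
) -> dict[str, float]:
    """All eight features (plus normalized LZC) for one channel's samples."""
    ps = compute_psd(x, fs, params.welch_window_s, params.welch_overlap)
    bp = band_powers(ps, params.bands)
    if params.brain_rate_method == "centroid":
        br = spectral_centroid(ps, params.se_f_lo, params.se_f_hi)
    elif params.brain_rate_method == "bands":
        br = brain_rate(bp, params.bands)
    else:
        raise ValueError(f"unknown brain_rate_method {params.brain_rate_method!r}")
    out = {
        "brain_rate": br,
        "spectral_entropy": spectral_entropy(ps, params.se_f_lo, params.se_f_hi),
        "permutation_entropy": permutation_entropy(x, params.D, params.tau),
        "sample_entropy": sample_entropy(x, params.m, r_fraction=params.r_fraction),
        "renyi_entropy": renyi_entropy(estimate_density(x), params.alpha),
        "tsallis_entropy": tsallis_entropy(
            amplitude_histogram(x, params.n_bins), params.q
        ),
        "higuchi_fd": higuchi_fd(x, params.k_max),
    }
    binary = binarize_mean(x)
    c = lz76_complexity(binary)
    out["lzc"] = float(c)
    out["lzc_normalized"] = c * math.log2(len(binary)) / len(binary)
    return out


def extract_all_features(segment, params: FeatureParams = FeatureParams()):
    """Feature vector for every channel of a segment.

    Returns a :class:`pandas.DataFrame` with one row per channel and a
    column per feature (plus ``lzc_normalized``), deterministic given the
    segment. Estimator failures are re-raised tagged with the channel and
    feature that failed.
    """
    import pandas as pd

    rows = []
    for ch_i, label in enumerate(segment.recording.channels):
        x = segment.data[ch_i]
        try:
            feats = extract_channel_features(x, segment.fs, params)
        except FeatureExtractionError:
            raise
        except Exception as e:  # tag with context, per-channel
            raise FeatureExtractionError(label, _failing_feature(e), e) from e
        rows.append({"channel": label, **feats})
    return pd.DataFrame(rows)


def _failing_feature(e: Exception) -> str:
    tb = e.__traceback__
    while tb is not None:
        name = tb.tb_frame.f_code.co_name
        if name in FEATURE_NAMES or name in (
            "compute_psd", "estimate_density", "amplitude_histogram",
            "binarize_mean", "lz76_complexity", "lzc_normalized",
        ):
            return name
        tb = tb.tb_next
    return "unknown"


__all__ = [
    "FeatureParams", "FEATURE_NAMES", "FeatureExtractionError",
    "permutation_entropy", "sample_entropy", "DensityEstimate",
    "silverman_bandwidth", "estimate_density", "renyi_entropy",
    "DiscreteDistribution", "amplitude_histogram", "tsallis_entropy",
    "higuchi_fd", "BinarySequence", "binarize_mean", "lz76_complexity",
    "lzc_normalized", "extract_channel_features", "extract_all_features",
]
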