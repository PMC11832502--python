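"""Channel-wise two-group statistics with Bonferroni correction.

For every (feature, channel) pair the two diagnostic groups are compared
with two nonparametric tests — the two-sample Kolmogorov–Smirnov test and
the Mann–Whitney U test — and a difference is flagged as significant only
when *both* tests fall below the Bonferroni-corrected threshold
α / m, where m is the number of channels tested per feature (19 for the
full montage, giving 0.05/19 ≈ 0.0026). Normality screening (Shapiro–Wilk
and a Lilliefors-corrected one-sample KS) is provided to justify the
nonparametric choice; 95 % t-based confidence intervals of the group means
summarize each side for error-bar plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .features import FEATURE_NAMES


def normality_screen(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk and one-sample KS (Lilliefors) p-values for normality.

    The one-sample KS test compares against a normal with the sample's own
    mean and SD, using the Lilliefors correction since the parameters are
    estimated from the data.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 observations for normality screening")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality tests undefined")
    p_shapiro = float(sps.shapiro(v).pvalue)
    _, p_ks1 = lilliefors(v, dist="norm")
    return p_shapiro, float(p_ks1)


def two_sample_tests(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample KS and Mann–Whitney U p-values.

    The U test is computed by exact enumeration when both groups have at
    most 20 observations, and by the tie-corrected normal approximation
    (with continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    p_ks = float(sps.ks_2samp(a, b).pvalue)
    method = "exact" if (a.size <= 20 and b.size <= 20) else "asymptotic"
    p_mwu = float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return p_ks, p_mwu


def bonferroni_alpha(alpha: float, m_tests: int) -> float:
    """Bonferroni-corrected per-test threshold α / m (full precision)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def bonferroni_alpha_display(alpha: float, m_tests: int, decimals: int = 4) -> float:
    """The corrected threshold rounded for display (0.05/19 -> 0.0026)."""
    return round(bonferroni_alpha(alpha, m_tests), decimals)


def mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval of the mean: mean ± t_{n−1} · SD/√n."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations for a CI")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    m = v.mean()
    sem = v.std(ddof=1) / np.sqrt(v.size)
    t = sps.t.ppf(0.5 + level / 2, df=v.size - 1)
    return float(m - t * sem), float(m + t * sem)


def build_comparison_table(
    feature_table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_NAMES,
    alpha: float = 0.05,
    m_tests: int = 19,
) -> pd.DataFrame:
    """Per (feature, channel) comparison of the TD and ASD groups.

    ``feature_table`` must have columns ``participant_id``, ``group``,
    ``channel`` and one column per feature. Returns one row per
    feature × channel with both p-values, the conjunction significance flag
    at the Bonferroni-corrected level, the direction of the difference
    (sign of median_ASD − median_TD) and 95 % mean CIs per group.
    """
    required = {"group", "channel"} | set(features)
    missing = required - set(feature_table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    alpha_corr = bonferroni_alpha(alpha, m_tests)
    channels = list(dict.fromkeys(feature_table["channel"]))
    rows = []
    for feature in features:
        for channel in channels:
            sub = feature_table[feature_table["channel"] == channel]
            td = sub.loc[sub["group"] == "TD", feature].to_numpy(dtype=float)
            asd = sub.loc[sub["group"] == "ASD", feature].to_numpy(dtype=float)
            if td.size == 0 or asd.size == 0:
                raise ValueError(
                    f"missing group for feature {feature!r}, channel {channel!r}"
                )
            p_ks, p_mwu = two_sample_tests(td, asd)
            med_td, med_asd = float(np.median(td)), float(np.median(asd))
            ci_td = mean_ci(td)
            ci_asd = mean_ci(asd)
            rows.append({
                "feature": feature,
                "channel": channel,
                "p_ks": p_ks,
                "p_mwu": p_mwu,
                "significant_both": bool(p_ks < alpha_corr and p_mwu < alpha_corr),
                "direction": int(np.sign(med_asd - med_td)),
                "median_td": med_td,
                "median_asd": med_asd,
                "ci_td_lo": ci_td[0], "ci_td_hi": ci_td[1],
                "ci_asd_lo": ci_asd[0], "ci_asd_hi": ci_asd[1],
            })
    return pd.DataFrame(rows)


def significant_channel_counts(comparison: pd.DataFrame) -> pd.DataFrame:
    """Per feature: number of significant channels and the modal direction."""
    rows = []
    for feature, sub in comparison.groupby("feature", sort=False):
        sig = sub[sub["significant_both"]]
        direction = 0
        if len(sig):
            direction = int(np.sign(sig["direction"].sum()))
        rows.append({
            "feature": feature,
            "n_significant": int(len(sig)),
            "n_channels": int(len(sub)),
            "direction": direction,
        })
    return pd.DataFrame(rows)


__all__ = [
    "normality_screen", "two_sample_tests", "bonferroni_alpha",
    "bonferroni_alpha_display", "mean_ci", "build_comparison_table",
    "significant_channel_counts",
]
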