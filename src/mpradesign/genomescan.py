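"""Windowed genome characterization of predicted-positive density.

With positives defined as the top 5% of scores genome-wide, a region with
no regulatory structure would scatter them uniformly: the per-1-kb-window
positive count is then Binomial(1000, 0.05), whose central 95% interval is
37-64 positives (3.7%-6.4%).  Windows below the interval are called
inactive, above it active, within it neutral; a Kolmogorov-Smirnov test
against the binomial null quantifies departure from uniformity.  The module
also provides track smoothing for visualization and the per-annotation group
comparisons (equal-variance t-tests for quantitative annotations,
chi-square independence tests for qualitative ones, Bonferroni-corrected
within a test family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigError


def smooth_track(scores, width: int = 1) -> np.ndarray:
    """Centered moving average with edge truncation.

    The window shrinks near the boundaries (mean over the available
    positions), so width 1 is the identity and constant tracks are fixed
    points for any width.
    """
    if width < 1 or width % 2 == 0:
        raise ConfigError(f"smoothing width must be an odd positive integer, got {width}")
    x = np.asarray(scores, dtype=float)
    if width == 1:
        return x.copy()
    half = width // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def window_positive_proportion(score_track, positive_threshold: float, window: int = 1000) -> pd.DataFrame:
    """Per-window count and proportion of positions scoring >= threshold.

    Windows are non-overlapping, contiguous, 0-based half-open.  A trailing
    remainder shorter than ``window`` is dropped with a warning.  Returns a
    frame with columns window, start, end, n_positive, proportion.
    """
    x = np.asarray(score_track, dtype=float)
    if x.size == 0:
        raise ConfigError("empty score track")
    if window < 1:
        raise ConfigError("window must be >= 1")
    n_windows, rem = divmod(x.size, window)
    if n_windows == 0:
        raise ConfigError(f"track of length {x.size} shorter than one window ({window})")
    if rem:
        warnings.warn(f"dropping trailing {rem} positions (< one {window}-bp window)", stacklevel=2)
    counts = (x[: n_windows * window] >= positive_threshold).reshape(n_windows, window).sum(axis=1)
    starts = np.arange(n_windows) * window
    return pd.DataFrame({
        "window": np.arange(n_windows),
        "start": starts,
        "end": starts + window,
        "n_positive": counts,
        "proportion": counts / window,
    })


@dataclass
class NullInterval:
    """Central ``coverage`` interval of Binomial(window, rate)/window."""

    lower: float
    upper: float
    coverage: float = 0.95
    window_size: int = 1000
    rate: float = 0.05


def uniform_null_interval(window: int = 1000, rate: float = 0.05, coverage: float = 0.95) -> NullInterval:
    """Proportion interval containing ``coverage`` of uniform-score windows.

    Quantiles use the smallest-k-with-CDF>=p convention; at the defaults
    (window 1000, rate 0.05, coverage 0.95) the counts are 37 and 64, i.e.
    proportions 0.037 and 0.064.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"rate must lie in [0, 1], got {rate}")
    if not 0.0 < coverage < 1.0:
        raise ConfigError(f"coverage must lie in (0, 1), got {coverage}")
    if window < 1:
        raise ConfigError("window must be >= 1")
    if rate in (0.0, 1.0):
        return NullInterval(rate, rate, coverage, window, rate)
    alpha = (1.0 - coverage) / 2.0
    lo = int(stats.binom.ppf(alpha, window, rate))
    hi = int(stats.binom.ppf(1.0 - alpha, window, rate))
    return NullInterval(lo / window, hi / window, coverage, window, rate)


def classify_regions(summaries: pd.DataFrame, interval: NullInterval) -> tuple[pd.DataFrame, dict]:
    """Call each window active/inactive/neutral against the null interval.

    Proportions strictly below the interval are inactive, strictly above are
    active, within (inclusive) neutral.  Returns the annotated frame and the
    fractions of each call (summing to 1).
    """
    out = summaries.copy()
    p = out["proportion"].to_numpy()
    call = np.where(p < interval.lower, "inactive", np.where(p > interval.upper, "active", "neutral"))
    out["call"] = call
    n = len(out)
    fractions = {k: float((call == k).sum()) / n for k in ("active", "inactive", "neutral")}
    return out, fractions


def ks_goodness_of_fit(proportions, window: int = 1000, rate: float = 0.05) -> tuple[float, float]:
    """One-sample KS test of window proportions against Binomial(window, rate).

    The statistic is the exact sup-gap between the empirical CDF of window
    counts and the binomial CDF over the full support; the p-value uses the
    asymptotic Kolmogorov distribution, which is conservative for a discrete
    null.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ConfigError("no window proportions supplied")
    if p.size < 20:
        raise ConfigError("need at least 20 windows for the KS test")
    counts = np.rint(p * window).astype(int)
    support = np.arange(window + 1)
    null_cdf = stats.binom.cdf(support, window, rate)
    ecdf = np.searchsorted(np.sort(counts), support, side="right") / counts.size
    d = float(np.max(np.abs(ecdf - null_cdf)))
    pval = float(special.kolmogorov(np.sqrt(counts.size) * d))
    return d, pval


def compare_groups(
    annotation_table: pd.DataFrame,
    group_labels,
    kinds: dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-annotation two-group tests with Bonferroni family correction.

    Quantitative annotations get an equal-variance two-sample t-test;
    qualitative (binary/categorical) ones a chi-square test of independence
    on the 2 x k contingency table.  ``kinds`` maps column -> "quantitative"
    or "qualitative" (inferred from dtype/cardinality when omitted).  The
    family is the set of columns tested here: the significance threshold is
    ``alpha / n_columns``.  A LOW_EXPECTED flag marks chi-square tables with
    an expected cell below 1.
    """
    g = np.asarray(group_labels)
    groups = np.unique(g)
    if len(groups) != 2:
        raise ConfigError(f"need exactly 2 groups, got {len(groups)}")
    if annotation_table.shape[1] == 0:
        return pd.DataFrame(columns=["annotation", "kind", "statistic", "p", "significant", "low_expected"])
    n_family = annotation_table.shape[1]
    thr = alpha / n_family
    rows = []
    for col in annotation_table.columns:
        x = annotation_table[col]
        if kinds and col in kinds:
            kind = kinds[col]
        else:
            vals = x.dropna().unique()
            kind = "qualitative" if (x.dtype == object or x.dtype == bool or len(vals) <= 5) else "quantitative"
        low_expected = False
        if kind == "quantitative":
            a = x[g == groups[0]].to_numpy(float)
            b = x[g == groups[1]].to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                raise ConfigError(f"group with < 2 observations for t-test on {col}")
            if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
                stat, pval = 0.0, 1.0
            else:
                stat, pval = stats.ttest_ind(a, b, equal_var=True)
        else:
            tab = pd.crosstab(g, x)
            if tab.shape[1] < 2:
                stat, pval = 0.0, 1.0
            else:
                res = stats.chi2_contingency(tab.to_numpy(), correction=False)
                stat, pval = res.statistic, res.pvalue
                low_expected = bool((res.expected_freq < 1).any())
                if low_expected:
                    warnings.warn(f"chi-square table for {col} has an expected cell < 1", stacklevel=2)
        rows.append({
            "annotation": col, "kind": kind, "statistic": float(stat), "p": float(pval),
            "significant": bool(pval < thr), "low_expected": low_expected,
        })
    return pd.DataFrame(rows)
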