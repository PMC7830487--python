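"""Univariate statistics from summary data.

One-way ANOVA reconstructed from (mean, sd, n) summaries, Duncan's
multiple range test with compact-letter assignment, and the
Durbin-Watson statistic on ordered residuals.

Duncan's critical values are computed from studentized-range quantiles
at the protection level alpha_p = 1 - (1 - alpha)^(p-1) for a span of p
ranked means, rather than from embedded lookup tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    label: object
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DataError(f"group {self.label!r}: sd must be >= 0")
        if self.n < 2:
            raise DataError(f"group {self.label!r}: n must be >= 2")


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    ms_between: float


@dataclass
class DmrtResult:
    ranked_labels: list
    ranked_means: list[float]
    critical_ranges: dict[int, float]  # span p -> R_p
    letters: dict  # label -> letter string
    alpha: float


def summarize(label, values) -> GroupSummary:
    """Build a GroupSummary from raw replicate values (sample sd)."""
    v = np.asarray(values, dtype=float)
    return GroupSummary(label, float(v.mean()), float(v.std(ddof=1)), int(v.size))


def anova_oneway_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from (mean, sd, n) triplets.

    SSB = sum n_i (mean_i - grand)^2, SSW = sum (n_i - 1) sd_i^2;
    F = MSB / MSW; p from the F survival function.
    """
    if len(groups) < 2:
        raise DataError("ANOVA requires at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd for g in groups], dtype=float)
    grand = float(np.sum(n * m) / np.sum(n))
    ssb = float(np.sum(n * (m - grand) ** 2))
    ssw = float(np.sum((n - 1) * sd**2))
    df_b = len(groups) - 1
    df_w = int(np.sum(n - 1))
    msb = ssb / df_b
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, 0.0, msb)
    msw = ssw / df_w
    f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f, df_b, df_w, p, msw, msb)


def duncan_critical_range(alpha: float, span: int, df: int, mse: float, n: int) -> float:
    """Least significant range R_p for a span of p ranked means:
    q(alpha_p; p, df) * sqrt(MSE / n) with alpha_p = 1-(1-alpha)^(p-1)."""
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    q = float(sps.studentized_range.ppf(1.0 - alpha_p, span, df))
    return q * np.sqrt(mse / n)


def dmrt(groups: list[GroupSummary], alpha: float = 0.05) -> DmrtResult:
    """Duncan's multiple range test with compact letter display.

    Groups are ranked by mean; a pair spanning p ranked positions is
    declared non-significant when its mean difference does not exceed
    R_p, or when it lies inside a wider non-significant range
    (containment rule). Maximal non-significant runs each receive one
    letter; groups sharing any letter are pairwise non-significant.
    """
    anova = anova_oneway_from_summary(groups)
    if anova.ms_within == 0.0:
        raise DataError("DMRT undefined with zero within-group variance")
    ns = [g.n for g in groups]
    if len(set(ns)) > 1:
        n_eff = len(ns) / float(np.sum(1.0 / np.asarray(ns, dtype=float)))
        log.warning("unequal group sizes; using harmonic mean n = %.3f", n_eff)
    else:
        n_eff = float(ns[0])

    # ranked ascending so the compact letters start at 'a' for the
    # smallest mean, matching conventional table notation
    order = sorted(range(len(groups)), key=lambda i: groups[i].mean)
    labels = [groups[i].label for i in order]
    means = [groups[i].mean for i in order]
    k = len(groups)
    ranges = {
        p: duncan_critical_range(alpha, p, anova.df_within, anova.ms_within, n_eff)
        for p in range(2, k + 1)
    }
    # nonsig[i][j] for ranked i < j; widest spans first so the
    # containment rule can propagate inward
    nonsig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if means[j] - means[i] <= ranges[span] or (
                i > 0 and nonsig[i - 1][j]
            ) or (j < k - 1 and nonsig[i][j + 1]):
                nonsig[i][j] = True
    # compact letters from maximal non-significant runs
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i][j + 1]:
            j += 1
        if not any(a <= i and j <= b for a, b in runs):
            runs.append((i, j))
    letters: dict = {lab: "" for lab in labels}
    for r, (a, b) in enumerate(sorted(runs)):
        letter = _letter(r)
        for i in range(a, b + 1):
            letters[labels[i]] += letter
    return DmrtResult(labels, means, ranges, letters, alpha)


def _letter(i: int) -> str:
    s = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        s = chr(ord("a") + r) + s
    return s


def durbin_watson(residuals) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2 on ordered residuals."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise DataError("Durbin-Watson requires at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0.0:
        raise DataError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def linear_trend_residuals(y, x=None) -> np.ndarray:
    """Residuals from an ordinary least squares straight-line fit,
    for feeding durbin_watson."""
    y = np.asarray(y, dtype=float)
    x = np.arange(y.size, dtype=float) if x is None else np.asarray(x, dtype=float)
    if y.size < 3:
        raise ConfigError("need at least 3 points to fit a line with residuals")
    coef = np.polyfit(x, y, 1)
    return y - np.polyval(coef, x)
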