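"""Paired pre/post summaries, agreement and multiplicity control.

The statistical layer of the pipeline: percent-change summaries of
paired pre/post measurements, Bland-Altman limits of agreement between
two measures of the same quantity, Pearson/Spearman correlation, and
Holm-Bonferroni stepdown adjustment for families of tests.

Sign convention: a *percent decrease* is positive — "reduced by 24%"
means ``100 * (pre - post) / pre = 24`` — because pre/post contrasts in
this field are almost always reported as reductions. The raw signed
change is retained alongside.

Hypothesis tests themselves (paired t, Wilcoxon signed-rank,
Mann-Whitney) are delegated to scipy; this module only encodes the
choice rule (paired t when the paired differences look normal by
Shapiro-Wilk at alpha = 0.05, Wilcoxon otherwise) and the input
contract (matched, complete pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError

#: z-quantile defining the limits of agreement (95% of differences).
LOA_Z = 1.96

SHAPIRO_ALPHA = 0.05


@dataclass
class PairedSeries:
    """Matched pre/post values for a set of subjects.

    Pairs are matched positionally by subject id; missing pairs must be
    dropped before construction.
    """

    subject_ids: Sequence[str]
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if not (len(self.subject_ids) == self.pre.size == self.post.size):
            raise DomainError(
                "subject_ids, pre and post must have equal length "
                f"({len(self.subject_ids)}, {self.pre.size}, {self.post.size})"
            )
        if self.pre.size == 0:
            raise InsufficientDataError("paired series is empty")
        if not (np.all(np.isfinite(self.pre)) and np.all(np.isfinite(self.post))):
            raise DomainError("paired values must be finite (drop missing pairs first)")

    def __len__(self) -> int:
        return self.pre.size


def percent_decrease(pre: float, post: float) -> float:
    """Percent decrease from ``pre`` to ``post``; positive = decrease."""
    if pre <= 0:
        raise DomainError(f"pre must be > 0, got {pre}")
    return 100.0 * (pre - post) / pre


class PercentChangeSummary(NamedTuple):
    style: str
    center: float  # median or mean of per-subject decreases, or the group-mean decrease
    spread_low: Optional[float]  # IQR lower / mean - SD; None for group_mean
    spread_high: Optional[float]
    per_subject: Optional[np.ndarray]  # signed per-subject percent decreases


def paired_percent_change_summary(series: PairedSeries, style: str = "median_iqr") -> PercentChangeSummary:
    """Summarize per-subject percent decreases pre -> post.

    ``style``:
      * ``median_iqr`` — median of per-subject decreases with IQR bounds;
      * ``mean_sd`` — mean with mean-SD / mean+SD bounds;
      * ``group_mean`` — percent decrease of the group means,
        ``100 * (mean(pre) - mean(post)) / mean(pre)``.

    ``group_mean`` and the mean of individual changes differ in general
    (the former weights subjects by their pre level); both are available
    and labelled by ``style``.
    """
    if np.any(series.pre <= 0):
        raise DomainError("all pre values must be > 0 for percent change")
    changes = 100.0 * (series.pre - series.post) / series.pre

    if style == "group_mean":
        center = percent_decrease(float(series.pre.mean()), float(series.post.mean()))
        return PercentChangeSummary(style, center, None, None, changes)
    if len(series) < 2:
        raise InsufficientDataError("dispersion summaries need >= 2 pairs")
    if style == "median_iqr":
        q1, med, q3 = np.percentile(changes, [25, 50, 75])
        return PercentChangeSummary(style, float(med), float(q1), float(q3), changes)
    if style == "mean_sd":
        mean, sd = float(changes.mean()), float(changes.std(ddof=1))
        return PercentChangeSummary(style, mean, mean - sd, mean + sd, changes)
    raise DomainError(f"unknown style {style!r}")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two measures: bias and 95% limits of agreement."""

    bias: float
    loa_lower: float
    loa_upper: float
    proportion_within_loa: float
    sd_diff: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise DomainError("limits of agreement must bracket the bias")


def bland_altman(x: Sequence[float], y: Sequence[float], log_scale: bool = False) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements ``x`` and ``y``.

    Differences ``d = x - y`` (or ``log x - log y`` with
    ``log_scale=True`` for proportional error); bias is ``mean(d)``,
    limits of agreement ``bias +/- 1.96 * SD(d)``, and the observed
    proportion of differences within the limits is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError(f"series lengths differ ({x.size} vs {y.size})")
    if x.size < 3:
        raise InsufficientDataError(f"Bland-Altman needs n >= 3, got {x.size}")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise DomainError("log-scale Bland-Altman requires positive values")
        d = np.log(x) - np.log(y)
    else:
        d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    within = float(np.mean(np.abs(d - bias) <= LOA_Z * sd))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - LOA_Z * sd,
        loa_upper=bias + LOA_Z * sd,
        proportion_within_loa=within,
        sd_diff=sd,
        n=int(x.size),
    )


class CorrelationResult(NamedTuple):
    coefficient: float
    pvalue: float
    method: str
    n: int


def correlation(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman is computed on ranks with average ranks for ties. A series
    with zero variance has no defined coefficient and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError(f"series lengths differ ({x.size} vs {y.size})")
    if x.size < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("coefficient undefined for a zero-variance series")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise DomainError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return CorrelationResult(float(r), float(p), method, int(x.size))


class HolmResult(NamedTuple):
    adjusted: List[float]
    reject: List[bool]
    alpha: float


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm-Bonferroni stepdown adjustment.

    Sorted ascending, ``adj_(k) = max_{j<=k} min(1, (m - j + 1) p_(j))``,
    reported in the original order. Uniformly more powerful than plain
    Bonferroni while controlling the family-wise error rate.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InsufficientDataError("no p-values supplied")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return HolmResult(list(map(float, adjusted)), list(map(bool, reject)), alpha)


class PairedTestResult(NamedTuple):
    test: str  # "paired_t" | "wilcoxon"
    statistic: float
    pvalue: float
    shapiro_p: float


def paired_test(series: PairedSeries) -> PairedTestResult:
    """Pre/post comparison with the normality-based test choice.

    The paired differences are screened with Shapiro-Wilk; when the
    normality hypothesis survives at alpha = 0.05 a paired t-test is
    used, otherwise the Wilcoxon signed-rank test. Both are delegated
    to scipy.
    """
    if len(series) < 3:
        raise InsufficientDataError("paired test needs >= 3 pairs")
    d = series.pre - series.post
    if np.allclose(d, d[0]):
        shapiro_p = 1.0  # constant differences: normality screen is vacuous
    else:
        shapiro_p = float(sps.shapiro(d).pvalue)
    if shapiro_p >= SHAPIRO_ALPHA:
        res = sps.ttest_rel(series.pre, series.post)
        return PairedTestResult("paired_t", float(res.statistic), float(res.pvalue), shapiro_p)
    res = sps.wilcoxon(series.pre, series.post)
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), shapiro_p)
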