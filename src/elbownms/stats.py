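"""Model-agreement statistics: Pearson correlation and one-way ANOVA.

Two torque (or force, or length) time series from different models are
compared with (a) the Pearson product-moment correlation, banded into
conventional strength labels, and (b) a one-way ANOVA treating the two
series as independent groups, with the verdict "no significant
difference" (NSD) when F stays below the critical value at the chosen
alpha.  Treating autocorrelated time series as independent samples
inflates the effective degrees of freedom; the protocol is reproduced
as published, and the caveat is recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "pearson",
    "correlation_label",
    "one_way_anova",
    "compare_series",
]

_CAVEAT = (
    "ANOVA treats the two time series as independent groups; "
    "autocorrelation is ignored"
)

# conventional correlation-strength bands on |r|
_BANDS = [
    (0.8, "ESC"),  # extremely strong correlation
    (0.6, "strong"),
    (0.4, "moderate"),
    (0.2, "weak"),
    (0.0, "very weak"),
]


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between one pair of series."""

    name: str
    pearson_r: float
    correlation_label: str
    anova_F: float
    anova_p: float
    F_crit: float
    alpha: float
    verdict: str  # NSD (no significant difference) or ESD
    note: str = _CAVEAT


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(sps.pearsonr(x, y).statistic)


def correlation_label(r: float) -> str:
    """Band |r| into conventional strength labels (ESC at |r| >= 0.8)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    a = abs(r)
    for lo, label in _BANDS:
        if a >= lo:
            return label
    return "very weak"


def one_way_anova(
    *groups, alpha: float = 0.05
) -> tuple[float, float, float, str]:
    """One-way ANOVA across two or more groups.

    Returns ``(F, p, F_crit, verdict)`` with F the between/within
    mean-square ratio at df = (g - 1, N - g), p its upper-tail
    probability, F_crit the upper-alpha quantile, and verdict "NSD"
    when F < F_crit (equivalently p >= alpha), else "ESD".
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    F, p = sps.f_oneway(*arrays)
    g = len(arrays)
    N = sum(a.size for a in arrays)
    F_crit = float(sps.f.ppf(1.0 - alpha, g - 1, N - g))
    verdict = "NSD" if F < F_crit else "ESD"
    return float(F), float(p), F_crit, verdict


def compare_series(x, y, name: str = "series", alpha: float = 0.05) -> AgreementReport:
    """Full agreement report for one pair of aligned series."""
    r = pearson(x, y)
    F, p, F_crit, verdict = one_way_anova(x, y, alpha=alpha)
    return AgreementReport(
        name=name,
        pearson_r=r,
        correlation_label=correlation_label(r),
        anova_F=F,
        anova_p=p,
        F_crit=F_crit,
        alpha=alpha,
        verdict=verdict,
    )
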