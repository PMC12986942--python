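"""One-way repeated-measures ANOVA with partial eta-squared and
Bonferroni-corrected paired post-hoc comparisons.

The decomposition is the classic two-way (subject x condition) additive
model without interaction:

    SS_total = SS_subject + SS_effect + SS_error,

with ``F = (SS_effect / (k-1)) / (SS_error / ((k-1)(n-1)))`` and no
sphericity correction by default (a Greenhouse-Geisser variant is exposed
behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "MetricsTable",
    "AnovaResult",
    "PairwiseResult",
    "rm_anova",
    "rm_anova_wide",
    "partial_eta_squared",
    "bonferroni_alpha",
    "bonferroni_posthoc",
]


@dataclass
class MetricsTable:
    """Long-format (subject, filter, value) records for one outcome."""

    data: pd.DataFrame

    @classmethod
    def from_records(cls, records) -> "MetricsTable":
        """Build from an iterable of (subject_id, filter_name, value)."""
        df = pd.DataFrame(records, columns=["subject", "filter", "value"])
        return cls(df)

    def to_wide(self) -> pd.DataFrame:
        """Complete-case wide table: one row per subject, one column per filter.

        Subjects missing any filter level (or carrying non-finite values)
        are dropped.
        """
        wide = self.data.pivot_table(index="subject", columns="filter",
                                     values="value", aggfunc="first")
        wide = wide.replace([np.inf, -np.inf], np.nan).dropna(axis=0)
        return wide

    @property
    def levels(self) -> list[str]:
        return sorted(self.data["filter"].unique())


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float
    ss_subject: float
    n_subjects: int
    levels: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    t: float
    df: int
    p: float
    alpha_adj: float
    significant: bool


def rm_anova_wide(values: np.ndarray) -> tuple[float, int, int, float, float,
                                               float, float]:
    """Core decomposition on an ``(n_subjects, k_levels)`` array.

    Returns ``(F, df1, df2, p, ss_effect, ss_error, ss_subject)``.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 2 or k < 2:
        raise DataError(f"need >= 2 subjects and >= 2 levels, got {n} x {k}")
    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_subject = k * float(((subj_means - grand) ** 2).sum())
    ss_effect = n * float(((cond_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_effect, 0.0)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    # zero error variance: F degenerates to a sentinel, not an exception
    scale = max(ss_total, 1.0)
    if ss_error <= scale * 1e-14:
        if ss_effect <= scale * 1e-14:
            return 0.0, df1, df2, 1.0, ss_effect, ss_error, ss_subject
        return float("inf"), df1, df2, 0.0, ss_effect, ss_error, ss_subject
    F = (ss_effect / df1) / (ss_error / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p, ss_effect, ss_error, ss_subject


def rm_anova(table: MetricsTable, gg_correction: bool = False) -> AnovaResult:
    """Repeated-measures ANOVA with filter as the lone within-subject factor.

    ``gg_correction=True`` applies the Greenhouse-Geisser epsilon to the
    degrees of freedom for the p-value (the reported df stay uncorrected).
    """
    wide = table.to_wide()
    values = wide.to_numpy()
    F, df1, df2, p, ss_e, ss_err, ss_s = rm_anova_wide(values)
    if gg_correction and np.isfinite(F):
        eps = _gg_epsilon(values)
        p = float(stats.f.sf(F, df1 * eps, df2 * eps))
    eta = partial_eta_squared(ss_e, ss_err) if (ss_e > 0 or ss_err > 0) else 0.0
    return AnovaResult(F=F, df1=df1, df2=df2, p=p, eta_p2=eta,
                       ss_effect=ss_e, ss_error=ss_err, ss_subject=ss_s,
                       n_subjects=values.shape[0],
                       levels=tuple(wide.columns))


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = values.shape[1]
    cov = np.cov(values, rowvar=False)
    centered = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * np.sum(centered ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """``SS_effect / (SS_effect + SS_error)``."""
    if ss_effect < 0 or ss_error < 0:
        raise DataError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise DataError("effect size undefined when both SS are zero")
    return float(ss_effect / (ss_effect + ss_error))


def bonferroni_alpha(alpha_fw: float, k_levels: int) -> float:
    """Familywise alpha divided by the number of unordered pairs."""
    n_pairs = k_levels * (k_levels - 1) // 2
    return alpha_fw / n_pairs


def bonferroni_posthoc(table: MetricsTable,
                       alpha_fw: float = 0.05) -> list[PairwiseResult]:
    """Two-sided paired t-test per unordered pair of filter levels.

    The significance flag compares the raw p-value against
    ``alpha_fw / (k(k-1)/2)``.
    """
    wide = table.to_wide()
    n, k = wide.shape
    if n < 2 or k < 2:
        raise DataError(f"need >= 2 subjects and >= 2 levels, got {n} x {k}")
    alpha_adj = bonferroni_alpha(alpha_fw, k)
    results: list[PairwiseResult] = []
    for a, b in combinations(wide.columns, 2):
        diffs = wide[a].to_numpy() - wide[b].to_numpy()
        mean_diff = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        df = n - 1
        if sd == 0.0:
            if mean_diff == 0.0:
                t, p = 0.0, 1.0
            else:
                t = float("inf") if mean_diff > 0 else float("-inf")
                p = 0.0
        else:
            t = mean_diff / (sd / np.sqrt(n))
            p = float(2.0 * stats.t.sf(abs(t), df))
        results.append(PairwiseResult(pair=(a, b), mean_diff=mean_diff,
                                      t=float(t), df=df, p=p,
                                      alpha_adj=alpha_adj,
                                      significant=bool(p < alpha_adj)))
    return results
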