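"""Cohort statistics: one-way repeated-measures ANOVA with LSD post hoc.

Each phantom contributes one value per planning method, so methods are a
within-subject factor.  The classical decomposition is used:

    SS_total = SS_subjects + SS_methods + SS_error,
    F = MS_methods / MS_error with df (k-1, (k-1)(n-1)).

When the omnibus test is significant at the gating level (0.05), Least
Significant Difference pairwise comparisons are performed with the
pooled within-subject error mean square, flagged at the adjusted
threshold alpha = 0.05 / 3 (Bonferroni over the three pairwise
comparisons).  No sphericity correction is applied; the reports note
this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CohortTable", "RMAnovaResult", "rm_anova", "lsd_posthoc"]

#: Pairwise significance threshold after the one-third adjustment.
ADJUSTED_ALPHA = 0.05 / 3.0


@dataclass
class CohortTable:
    """Subjects x methods matrix of one metric (no missing cells)."""

    values: np.ndarray          # (n_subjects, k_methods)
    methods: list[str]
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("cohort table must be 2-D (subjects x methods)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 methods")
        if len(self.methods) != k:
            raise ValueError("method labels do not match table width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cohort table contains missing/non-finite cells")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric: str = "",
                       units: str = "") -> "CohortTable":
        """Wide DataFrame (index = subjects, columns = methods)."""
        return cls(df.to_numpy(), list(df.columns), metric=metric, units=units)


@dataclass
class RMAnovaResult:
    F: float
    p: float
    df_method: int
    df_error: int
    ss_subjects: float
    ss_methods: float
    ss_error: float
    ms_methods: float
    ms_error: float
    zero_error_variance: bool = False


def rm_anova(table: CohortTable) -> RMAnovaResult:
    """One-way repeated-measures ANOVA across methods."""
    y = table.values
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    meth_means = y.mean(axis=0)

    ss_subjects = k * float(((subj_means - grand) ** 2).sum())
    ss_methods = n * float(((meth_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_methods

    df_method = k - 1
    df_error = (k - 1) * (n - 1)
    ms_methods = ss_methods / df_method
    ms_error = ss_error / df_error

    if ms_error <= 0 or np.isclose(ms_error, 0.0, atol=1e-300):
        if ms_methods > 0:
            # method effect with no residual variance: p below machine floor
            return RMAnovaResult(np.inf, 0.0, df_method, df_error,
                                 ss_subjects, ss_methods, max(ss_error, 0.0),
                                 ms_methods, 0.0, zero_error_variance=True)
        return RMAnovaResult(0.0, 1.0, df_method, df_error,
                             ss_subjects, 0.0, 0.0, 0.0, 0.0,
                             zero_error_variance=True)

    F = ms_methods / ms_error
    p = float(sps.f.sf(F, df_method, df_error))
    return RMAnovaResult(F, p, df_method, df_error, ss_subjects, ss_methods,
                         ss_error, ms_methods, ms_error)


def lsd_posthoc(table: CohortTable, alpha: float = ADJUSTED_ALPHA,
                gate_alpha: float = 0.05) -> pd.DataFrame:
    """LSD pairwise comparisons using the pooled within-subject error MS.

    The omnibus repeated-measures ANOVA gates the procedure at
    ``gate_alpha``; when the gate is not met, p-values are still
    reported but significance flags are suppressed.
    """
    res = rm_anova(table)
    gate = res.p < gate_alpha
    y = table.values
    n, k = y.shape
    means = y.mean(axis=0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if res.ms_error > 0:
                se = np.sqrt(2.0 * res.ms_error / n)
                t = diff / se
                p = float(2.0 * sps.t.sf(abs(t), res.df_error))
            else:
                t = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            rows.append({
                "a": table.methods[i],
                "b": table.methods[j],
                "mean_diff": diff,
                "t": t,
                "p": p,
                "significant": bool(gate and p < alpha),
            })
    out = pd.DataFrame(rows)
    out.attrs["omnibus_F"] = res.F
    out.attrs["omnibus_p"] = res.p
    out.attrs["gate_passed"] = bool(gate)
    out.attrs["alpha"] = alpha
    return out
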