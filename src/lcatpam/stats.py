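"""One-way ANOVA and Dunnett many-to-one comparisons against a control.

Triplicate kinetic parameters (or per-well rates) for each LCAT+compound
condition are compared to the no-compound LCAT control: an omnibus one-way
ANOVA followed by a two-tailed Dunnett test, whose adjusted p-values control
the familywise error across the k treatment-vs-control contrasts.  The
Dunnett statistics are

    t_i = (mean_i - mean_control) / sqrt(MSW * (1/n_i + 1/n_control)),

with MSW the pooled within-group mean square over all groups (variance
homogeneity assumed; a warning is raised when group variances differ more
than 10-fold).  Adjusted p-values come from the equicorrelated multivariate
t distribution (correlation 0.5 for balanced designs), evaluated by the
numeric integrator in :func:`scipy.stats.dunnett`; the single-treatment case
collapses exactly to the pooled two-sample two-sided t-test and is computed
in closed form.

Significance labels use the strict thresholds *p < 0.05, **p < 0.01,
***p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GroupData",
    "AnovaResult",
    "DunnettResult",
    "anova_oneway",
    "dunnett_test",
    "significance_stars",
    "per_stratum_comparisons",
]


@dataclass
class GroupData:
    """Measurements for one condition (e.g. triplicate Vmax values)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 values")


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


@dataclass
class DunnettResult:
    """One treatment-vs-control contrast."""

    comparison: str
    mean_difference: float
    t_statistic: float
    adjusted_p: float
    stars: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.adjusted_p <= 1.0:
            raise ValueError("adjusted_p outside [0, 1]")


def _pooled_msw(groups: list[GroupData]) -> tuple[float, int]:
    ss = sum(float(np.sum((g.values - g.values.mean()) ** 2)) for g in groups)
    df = sum(len(g.values) - 1 for g in groups)
    return ss / df, df


def anova_oneway(groups: list[GroupData]) -> AnovaResult:
    """Standard one-way between/within decomposition."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(len(g.values) for g in groups)
    if n_total <= len(groups):
        raise ValueError("need more observations than groups")
    msw, df_within = _pooled_msw(groups)
    if msw == 0:
        raise ValueError("zero within-group variance in every group")
    F, p = scipy.stats.f_oneway(*(g.values for g in groups))
    return AnovaResult(
        F=float(F), p=float(p), df_between=len(groups) - 1, df_within=df_within
    )


def dunnett_test(
    groups: list[GroupData],
    control_label: str,
    alpha: float = 0.05,
    rng=None,
) -> list[DunnettResult]:
    """Two-tailed Dunnett comparisons of every treatment against the control.

    ``rng`` seeds the multivariate-t evaluation so adjusted p-values are
    reproducible.  Adjusted p-values are forced to be at least the
    unadjusted pooled two-sided t p-value of the same contrast (they can
    never be smaller; tiny integrator noise is clipped away).
    """
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ValueError(
            f"control {control_label!r} not among groups {labels}"
        )
    control = next(g for g in groups if g.label == control_label)
    treatments = [g for g in groups if g.label != control_label]
    if not treatments:
        raise ValueError("need at least one treatment group")

    msw, df_within = _pooled_msw(groups)
    if msw == 0:
        raise ValueError("zero within-group variance; Dunnett t undefined")

    variances = [float(np.var(g.values, ddof=1)) for g in groups]
    vmin = min(v for v in variances if v > 0) if any(v > 0 for v in variances) else 0
    if vmin > 0 and max(variances) / vmin > 10:
        warnings.warn(
            "group variances differ more than 10-fold; pooled-variance "
            "Dunnett may be unreliable",
            stacklevel=2,
        )

    n_c = len(control.values)
    mean_c = float(control.values.mean())
    t_stats, diffs, raw_ps = [], [], []
    for g in treatments:
        n_i = len(g.values)
        diff = float(g.values.mean()) - mean_c
        t = diff / np.sqrt(msw * (1.0 / n_i + 1.0 / n_c))
        t_stats.append(t)
        diffs.append(diff)
        raw_ps.append(2.0 * scipy.stats.t.sf(abs(t), df_within))

    if len(treatments) == 1:
        # k = 1: Dunnett is exactly the pooled two-sided t-test
        adj = [raw_ps[0]]
    else:
        res = scipy.stats.dunnett(
            *(g.values for g in treatments),
            control=control.values,
            alternative="two-sided",
            rng=rng if rng is not None else np.random.default_rng(0),
        )
        adj = [float(p) for p in res.pvalue]

    out = []
    for g, diff, t, p_adj, p_raw in zip(treatments, diffs, t_stats, adj, raw_ps):
        p_adj = min(1.0, max(p_adj, p_raw))
        out.append(
            DunnettResult(
                comparison=f"{g.label} vs {control_label}",
                mean_difference=diff,
                t_statistic=float(t),
                adjusted_p=p_adj,
                stars=significance_stars(p_adj),
            )
        )
    return out


def significance_stars(p: float) -> str:
    """Map a p-value to the printed star convention (strict inequalities)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def per_stratum_comparisons(
    table: pd.DataFrame,
    control_label: str,
    value_col: str = "value",
    condition_col: str = "condition_label",
    stratum_col: str | None = "substrate_conc",
    alpha: float = 0.05,
    rng=None,
) -> pd.DataFrame:
    """ANOVA + Dunnett run independently within each stratum.

    Each substrate-concentration point of a rate table (or each kinetic
    parameter) is tested on its own, mirroring per-concentration testing of
    replicate rates.  Returns a tidy frame with one row per
    (stratum, comparison).
    """
    if stratum_col is None or stratum_col not in table.columns:
        strata = [(None, table)]
    else:
        strata = list(table.groupby(stratum_col))
    rows = []
    for stratum, sub in strata:
        groups = [
            GroupData(label=str(label), values=vals[value_col].to_numpy())
            for label, vals in sub.groupby(condition_col)
        ]
        anova = anova_oneway(groups)
        results = dunnett_test(groups, control_label, alpha=alpha, rng=rng)
        for r in results:
            rows.append(
                {
                    "stratum": stratum,
                    "comparison": r.comparison,
                    "mean_difference": r.mean_difference,
                    "t_statistic": r.t_statistic,
                    "anova_F": anova.F,
                    "anova_p": anova.p,
                    "adjusted_p": r.adjusted_p,
                    "stars": r.stars,
                }
            )
    return pd.DataFrame(rows)
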