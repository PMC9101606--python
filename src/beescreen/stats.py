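"""Group statistics, ANOVA/Tukey comparisons and element correlations.

Group summaries are reported in each element's weekly-intake display
unit (µg or mg per week).  Five samples of the bundled survey belong to
two market groups at once; the default deduplication keeps them in the
royal-jelly (RG) and propolis (PR) groups and excludes them from the
honey (HO) group, so each sample enters a comparison exactly once.

Distributional diagnostics (Shapiro–Wilk per group, Levene across
groups) are attached to every comparison rather than gating it; the
omnibus test is a one-way ANOVA with all-pairs Tukey HSD at α = 0.05,
with no multiple-testing correction across elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ELEMENTS, GROUPS, Panel, SupplementSample
from .intake import DISPLAY_DECIMALS, WeeklyIntakeTable, display_unit

__all__ = [
    "DEFAULT_DEDUP",
    "GroupSummary",
    "ComparisonResult",
    "CorrelationMatrix",
    "group_members",
    "group_summary",
    "compare_groups",
    "correlation_matrix",
]

#: Paper-faithful defaults: shared samples count in RG and PR, not HO.
DEFAULT_DEDUP: dict[str, str] = {
    "RG": "include_shared",
    "PR": "include_shared",
    "HO": "exclude_shared",
}

ALPHA = 0.05
CORR_ALPHA = 0.001


@dataclass(frozen=True)
class GroupSummary:
    group: str
    element: str
    n: int
    mean: float
    sd: float
    units: str

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("empty group")


@dataclass(frozen=True)
class ComparisonResult:
    element: str
    anova_p: float
    tukey_p: dict[tuple[str, str], float]
    shapiro_p: dict[str, float]
    levene_p: float
    significant: dict[tuple[str, str], bool]
    degenerate: bool = False


@dataclass
class CorrelationMatrix:
    """Pearson coefficients over element pairs, with p < 0.001 flags."""

    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    basis: str
    undefined: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = self.coefficients
        if not np.allclose(c.values, c.values.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")


def group_members(
    samples: list[SupplementSample],
    group: str,
    dedup_policy: str = "include_shared",
) -> list[str]:
    """Sample codes belonging to a group under a deduplication policy."""
    if dedup_policy not in ("include_shared", "exclude_shared"):
        raise ValueError(f"unknown dedup policy: {dedup_policy!r}")
    if group not in GROUPS:
        raise ValueError(f"unknown group: {group!r}")
    out = []
    for s in samples:
        if group in s.groups and not (dedup_policy == "exclude_shared" and s.shared):
            out.append(s.code)
    return out


def group_summary(
    intakes: WeeklyIntakeTable,
    samples: list[SupplementSample],
    element: str,
    group: str,
    dedup_policy: str | None = None,
) -> GroupSummary:
    """Mean ± sample (n−1) standard deviation of a group's weekly intakes.

    Values are in the element's display unit.  A single-member group has
    sd 0 by convention.
    """
    policy = dedup_policy if dedup_policy is not None else DEFAULT_DEDUP[group]
    codes = group_members(samples, group, policy)
    if not codes:
        raise ValueError(f"group {group} is empty under policy {policy!r}")
    x = intakes.display_frame()[element].loc[codes]
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return GroupSummary(
        group=group,
        element=element,
        n=len(x),
        mean=float(x.mean()),
        sd=sd,
        units=display_unit(element),
    )


def _group_values(
    intakes: WeeklyIntakeTable,
    samples: list[SupplementSample],
    element: str,
    dedup: dict[str, str],
) -> dict[str, np.ndarray]:
    disp = intakes.display_frame()[element]
    return {
        g: disp.loc[group_members(samples, g, dedup[g])].to_numpy(dtype=float)
        for g in GROUPS
    }


def compare_groups(
    intakes: WeeklyIntakeTable,
    samples: list[SupplementSample],
    element: str,
    dedup: dict[str, str] | None = None,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """One-way ANOVA across RG/PR/HO with all-pairs Tukey HSD.

    Zero-variance (degenerate) input is flagged rather than raised.
    """
    dedup = dedup or DEFAULT_DEDUP
    groups = _group_values(intakes, samples, element, dedup)
    small = [g for g, v in groups.items() if len(v) < 2]
    if len(groups) - len(small) < 2:
        raise ValueError("need at least two groups with at least two members")
    data = np.concatenate(list(groups.values()))
    if np.ptp(data) == 0:
        pairs = [(a, b) for i, a in enumerate(GROUPS) for b in GROUPS[i + 1:]]
        return ComparisonResult(
            element=element,
            anova_p=1.0,
            tukey_p={p: 1.0 for p in pairs},
            shapiro_p={g: 1.0 for g in groups},
            levene_p=1.0,
            significant={p: False for p in pairs},
            degenerate=True,
        )

    shapiro = {}
    for g, v in groups.items():
        if len(v) >= 3 and np.ptp(v) > 0:
            shapiro[g] = float(sps.shapiro(v).pvalue)
        else:
            shapiro[g] = float("nan")
    levene_p = float(sps.levene(*groups.values()).pvalue)
    anova_p = float(sps.f_oneway(*groups.values()).pvalue)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
    tk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    tukey_p: dict[tuple[str, str], float] = {}
    for row, p in zip(tk.summary().data[1:], tk.pvalues):
        pair = (str(row[0]), str(row[1]))
        tukey_p[pair] = float(p)
    significant = {pair: p < alpha for pair, p in tukey_p.items()}
    return ComparisonResult(
        element=element,
        anova_p=anova_p,
        tukey_p=tukey_p,
        shapiro_p=shapiro,
        levene_p=levene_p,
        significant=significant,
    )


def correlation_matrix(
    data: Panel | WeeklyIntakeTable,
    basis: str = "intakes",
    policy: str = "loq",
) -> CorrelationMatrix:
    """Pearson correlation over all element pairs.

    ``basis`` selects the grid: per-person weekly intakes (the default —
    the convention under which the survey's published matrix was
    computed, verified by reproducing it) or censoring-resolved
    concentrations from a panel.  Pairs involving a constant column are
    undefined (NaN) and flagged via ``undefined``.
    """
    if basis == "concentrations":
        if not isinstance(data, Panel):
            raise TypeError("basis 'concentrations' requires a Panel")
        grid = data.resolve(policy)
    elif basis == "intakes":
        if not isinstance(data, WeeklyIntakeTable):
            raise TypeError("basis 'intakes' requires a WeeklyIntakeTable")
        grid = data.mg_per_week
    else:
        raise ValueError(f"unknown basis: {basis!r}")
    if len(grid) < 3:
        raise ValueError("need at least 3 observations")

    els = list(grid.columns)
    coef = pd.DataFrame(np.eye(len(els)), index=els, columns=els)
    pval = pd.DataFrame(np.zeros((len(els), len(els))), index=els, columns=els)
    constant = tuple(el for el in els if np.ptp(grid[el].to_numpy()) == 0)
    for i, a in enumerate(els):
        for b in els[i + 1:]:
            if a in constant or b in constant:
                r, p = float("nan"), float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = sps.pearsonr(grid[a], grid[b])
            coef.loc[a, b] = coef.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    sig = (pval < CORR_ALPHA) & pd.notna(coef)
    np.fill_diagonal(sig.values, False)
    return CorrelationMatrix(
        coefficients=coef, p_values=pval, significant=sig, basis=basis, undefined=constant
    )


def summary_frame(
    intakes: WeeklyIntakeTable,
    samples: list[SupplementSample],
    dedup: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per element per group: n, mean, sd (display units)."""
    dedup = dedup or DEFAULT_DEDUP
    rows = []
    for el in ELEMENTS:
        for g in GROUPS:
            s = group_summary(intakes, samples, el, g, dedup[g])
            rows.append(
                {
                    "element": el,
                    "group": g,
                    "n": s.n,
                    "mean": round(s.mean, DISPLAY_DECIMALS[el]),
                    "sd": round(s.sd, DISPLAY_DECIMALS[el]),
                    "units": s.units,
                }
            )
    return pd.DataFrame(rows)


def boxplot_frame(
    intakes: WeeklyIntakeTable,
    samples: list[SupplementSample],
    dedup: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format (code, group, element, value, units) export for plotting."""
    dedup = dedup or DEFAULT_DEDUP
    disp = intakes.display_frame()
    rows = []
    for g in GROUPS:
        for code in group_members(samples, g, dedup[g]):
            for el in ELEMENTS:
                rows.append(
                    {
                        "code": code,
                        "group": g,
                        "element": el,
                        "value": disp.at[code, el],
                        "units": display_unit(el),
                    }
                )
    return pd.DataFrame(rows)
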