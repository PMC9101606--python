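"""Min–max multi-criteria toxicological ranking of supplements.

Each of six criteria (BMDL01, NOAEL, BMDL10, BMDL05, LOAEL, DNEL)
carries per-element limits expressed as mg per 70-kg person per week.
For a "lower is better" quantity the min–max score of a sample is

    score = (limit − x) / (limit − x_min),  clamped to [0, 1],

where x is the sample's body-weight-scaled weekly intake
(70 × mg/week per person), x_min the across-sample minimum on the same
scale, and the limit plays the role of the worst anchor.  A sample at
the panel minimum scores 1; a sample at or beyond the limit scores 0.
A criterion's score is the equal-weight arithmetic mean over its
elements, and the per-sample standard score (SS) is the mean of plain
min–max ranks across all 11 elements.

``se_faithful`` (default on) evaluates the Se term of the DNEL
criterion on the µg magnitude of the weekly intake against the mg-scale
limit 2.107.  Every sample's Se intake then exceeds the limit and the
term saturates at 0 — the convention under which the published ranking
this package reproduces was computed.  With the switch off, Se is
scored in mg like every other element (and, all intakes being far below
2.107 mg, scores near 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

from .core import ELEMENTS
from .intake import UG_ELEMENTS, WeeklyIntakeTable

__all__ = [
    "CRITERIA",
    "CriterionLimit",
    "RankingConfig",
    "ScoreTable",
    "DegenerateNormalizationError",
    "default_criteria",
    "load_criteria",
    "minmax_score",
    "criterion_score",
    "standard_scores",
    "rank_table",
    "write_scores_csv",
]

#: Criterion columns in report order.
CRITERIA: tuple[str, ...] = ("BMDL01", "NOAEL", "BMDL10", "BMDL05", "LOAEL", "DNEL")


class DegenerateNormalizationError(ValueError):
    """Raised when limit ≤ panel minimum leaves no normalization range."""


@dataclass(frozen=True)
class CriterionLimit:
    """One element's limit under one criterion (mg per 70-kg person/week)."""

    criterion: str
    element: str
    limit: float

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion: {self.criterion!r}")
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element: {self.element!r}")
        if not self.limit > 0:
            raise ValueError(f"{self.criterion}/{self.element}: limit must be > 0")


@dataclass(frozen=True)
class RankingConfig:
    """Scoring conventions.

    bw_scale multiplies per-person mg/week intakes before comparison
    with the limits (70, matching their per-70-kg-person scale); clamp
    bounds every score to [0, 1]; polarity maps elements to "lower" or
    "higher" for the standard score (default: all lower-is-better).
    """

    bw_scale: float = 70.0
    clamp: bool = True
    se_faithful: bool = True
    quantize_ug: int | None = 2
    polarity: tuple[tuple[str, str], ...] = tuple((el, "lower") for el in ELEMENTS)

    def __post_init__(self) -> None:
        if not self.bw_scale > 0:
            raise ValueError("bw_scale must be > 0")
        if self.quantize_ug is not None and self.quantize_ug < 0:
            raise ValueError("quantize_ug must be >= 0 or None")
        bad = [(e, p) for e, p in self.polarity if p not in ("lower", "higher")]
        if bad:
            raise ValueError(f"polarity must be 'lower' or 'higher': {bad}")

    @property
    def polarity_map(self) -> dict[str, str]:
        return dict(self.polarity)

    def fingerprint(self) -> str:
        se = "se_faithful" if self.se_faithful else "se_mg"
        cl = "clamp" if self.clamp else "noclamp"
        q = "exact" if self.quantize_ug is None else f"q{self.quantize_ug}ug"
        return f"bw{self.bw_scale:g}-{cl}-{se}-{q}"


@dataclass
class ScoreTable:
    """Per-sample criterion scores plus the standard score (SS)."""

    scores: pd.DataFrame  # columns: CRITERIA + ("SS",)
    best: dict[str, str]  # criterion -> best sample code
    config: RankingConfig

    def __post_init__(self) -> None:
        if self.config.clamp:
            vals = self.scores[list(CRITERIA)]
            if ((vals < 0) | (vals > 1)).any().any():
                raise ValueError("clamped scores must lie in [0, 1]")


def load_criteria(path) -> list[CriterionLimit]:
    df = pd.read_csv(path)
    return [
        CriterionLimit(row["criterion"], row["element"], float(row["limit_mg_per_70kg_week"]))
        for _, row in df.iterrows()
    ]


def default_criteria() -> list[CriterionLimit]:
    """The bundled EFSA/ECHA-derived limit set (12 element–criterion pairs)."""
    return load_criteria(str(resources.files("beescreen") / "data" / "criteria.csv"))


def minmax_score(x: float, x_min: float, limit: float, clamp: bool = True) -> float:
    """Clamped lower-is-better min–max score of one scaled intake.

    When the limit does not exceed the panel minimum the normalization
    has no range; with clamping on, any intake at or beyond the limit
    still scores an unambiguous 0, otherwise the degenerate case raises.
    """
    if limit <= x_min:
        if clamp and x >= limit:
            return 0.0
        raise DegenerateNormalizationError(
            f"limit {limit} <= panel minimum {x_min}: no normalization range"
        )
    score = (limit - x) / (limit - x_min)
    if clamp:
        score = min(1.0, max(0.0, score))
    return score


def _half_up(value: float, decimals: int) -> float:
    # round(.., 12) first to strip binary-float noise so that e.g. a
    # computed 0.31499999999999995 µg quantizes to 0.32 like the tables print
    d = Decimal(repr(round(value, 12))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
    )
    return float(d)


def _scaled_series(
    intakes: WeeklyIntakeTable,
    element: str,
    criterion: str,
    config: RankingConfig,
) -> pd.Series:
    """Body-weight-scaled intakes entering a criterion's score.

    With ``quantize_ug`` set, intakes are first expressed in µg/week and
    rounded half-up to that many decimals — the working precision of
    the report tables this scoring reproduces.
    """
    ug = intakes.mg_per_week[element] * 1000.0
    if config.quantize_ug is not None:
        ug = ug.map(lambda v: _half_up(v, config.quantize_ug))
    x = (ug / 1000.0) * config.bw_scale
    if config.se_faithful and criterion == "DNEL" and element == "Se":
        x = x * 1000.0  # µg magnitude against the mg-scale limit
    return x


def criterion_score(
    code: str,
    criterion: str,
    intakes: WeeklyIntakeTable,
    limits: list[CriterionLimit] | None = None,
    config: RankingConfig | None = None,
) -> float:
    """Equal-weight mean of the element scores under one criterion."""
    limits = limits if limits is not None else default_criteria()
    config = config or RankingConfig()
    entries = [lm for lm in limits if lm.criterion == criterion]
    if not entries:
        raise ValueError(f"criterion {criterion!r} has no element limits")
    parts = []
    for lm in entries:
        series = _scaled_series(intakes, lm.element, criterion, config)
        if code not in series.index:
            raise KeyError(f"no intake cell for sample {code}, element {lm.element}")
        parts.append(minmax_score(float(series[code]), float(series.min()), lm.limit, config.clamp))
    return sum(parts) / len(parts)


def standard_scores(
    intakes: WeeklyIntakeTable | pd.DataFrame,
    config: RankingConfig | None = None,
) -> pd.Series:
    """Per-sample mean of element-wise min–max ranks.

    With the default all-lower-better polarity, the sample with the
    smallest value of an element ranks 1 for it.  A constant element
    column carries no ranking information; its rank is defined as 1 for
    every sample and a warning is emitted.
    """
    config = config or RankingConfig()
    grid = intakes.mg_per_week if isinstance(intakes, WeeklyIntakeTable) else intakes
    if len(grid) < 2:
        raise ValueError("need at least 2 samples to rank")
    pol = config.polarity_map
    ranks = pd.DataFrame(index=grid.index, columns=grid.columns, dtype=float)
    for el in grid.columns:
        x = grid[el].astype(float)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            warnings.warn(f"element {el} is constant; rank set to 1 for all samples")
            ranks[el] = 1.0
        elif pol.get(el, "lower") == "lower":
            ranks[el] = (hi - x) / (hi - lo)
        else:
            ranks[el] = (x - lo) / (hi - lo)
    return ranks.mean(axis=1)


def rank_table(
    intakes: WeeklyIntakeTable,
    limits: list[CriterionLimit] | None = None,
    config: RankingConfig | None = None,
) -> ScoreTable:
    """Full per-sample score table over all six criteria plus SS."""
    limits = limits if limits is not None else default_criteria()
    config = config or RankingConfig()
    present = {lm.criterion for lm in limits}
    missing = [c for c in CRITERIA if c not in present]
    if missing:
        raise ValueError(f"criteria without limits: {missing}")
    scores = pd.DataFrame(index=intakes.mg_per_week.index, columns=list(CRITERIA), dtype=float)
    for crit in CRITERIA:
        for code in scores.index:
            scores.at[code, crit] = criterion_score(code, crit, intakes, limits, config)
    scores["SS"] = standard_scores(intakes, config)
    best = {crit: scores[crit].idxmax() for crit in CRITERIA}
    return ScoreTable(scores=scores, best=best, config=config)


def write_scores_csv(table: ScoreTable, path) -> None:
    out = table.scores.round(3).copy()
    out["config"] = table.config.fingerprint()
    out.index.name = "code"
    out.to_csv(path)
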