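"""Weekly intake of each element through the recommended daily dose.

For a reference consumer taking the manufacturer's recommended daily
dose *d* (g/day) of a supplement with element concentration *c*
(mg/kg), the weekly intake per whole person is

    I = c [mg/kg] × d/1000 [kg/day] × 7 [day/week]   (mg/week).

All internal arithmetic is in mg/week per person; µg is purely a
display convention (Pb, Cd, As, Hg, Ni, Co, Se are conventionally
reported in µg/week, Cr, Fe, Cu, Zn in mg/week).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import CENSOR_POLICIES, ELEMENTS, Constants, Panel

__all__ = [
    "UG_ELEMENTS",
    "MG_ELEMENTS",
    "DISPLAY_DECIMALS",
    "WeeklyIntakeTable",
    "weekly_intake",
    "build_intake_table",
    "per_kg_bw",
    "display_unit",
    "write_intake_csv",
]

log = logging.getLogger(__name__)

#: Elements reported in µg/week.
UG_ELEMENTS: frozenset[str] = frozenset({"Pb", "Cd", "As", "Hg", "Ni", "Co", "Se"})
#: Elements reported in mg/week.
MG_ELEMENTS: frozenset[str] = frozenset({"Cr", "Fe", "Cu", "Zn"})

#: Decimals used when rendering display values (report convention).
DISPLAY_DECIMALS: dict[str, int] = {
    **{el: 2 for el in UG_ELEMENTS},
    "Cr": 3,
    "Fe": 3,
    "Zn": 3,
    "Cu": 4,
}


def display_unit(element: str) -> str:
    return "ug/week" if element in UG_ELEMENTS else "mg/week"


def weekly_intake(concentration: float, dose_g_per_day: float) -> float:
    """Weekly intake in mg/week per person; see module formula."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if not dose_g_per_day > 0:
        raise ValueError(f"dose must be > 0, got {dose_g_per_day}")
    return concentration * (dose_g_per_day / 1000.0) * 7.0


@dataclass
class WeeklyIntakeTable:
    """Per-sample, per-element weekly intake for a reference consumer.

    ``mg_per_week`` is the unrounded grid in mg/week per whole person;
    the constants and censoring policy used to build it are carried as
    provenance.
    """

    mg_per_week: pd.DataFrame
    constants: Constants = field(default_factory=Constants)
    policy: str = "loq"

    def __post_init__(self) -> None:
        if list(self.mg_per_week.columns) != list(ELEMENTS):
            raise ValueError(f"columns must be {list(ELEMENTS)}")
        if (self.mg_per_week < 0).any().any():
            raise ValueError("weekly intakes must be >= 0")
        if self.policy not in CENSOR_POLICIES:
            raise ValueError(f"unknown censoring policy: {self.policy!r}")

    @property
    def codes(self) -> list[str]:
        return list(self.mg_per_week.index)

    def display_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Grid in display units (µg/week or mg/week per element)."""
        out = self.mg_per_week.copy()
        for el in ELEMENTS:
            if el in UG_ELEMENTS:
                out[el] = out[el] * 1000.0
            if rounded:
                out[el] = out[el].round(DISPLAY_DECIMALS[el])
        return out

    def per_kg_bw(self) -> pd.DataFrame:
        """Grid in mg per kg body weight per week."""
        return per_kg_bw(self.mg_per_week, self.constants)


def build_intake_table(
    panel: Panel,
    constants: Constants | None = None,
    policy: str = "loq",
) -> WeeklyIntakeTable:
    """Weekly-intake grid from a panel: resolve censoring, then convert.

    Every cell equals ``weekly_intake(resolved concentration, dose)``.
    """
    constants = constants or Constants()
    resolved = panel.resolve(policy)  # validates the policy name
    doses = panel.doses()
    n_sub = int(panel.censored.to_numpy().sum())
    if n_sub:
        log.info("censoring policy %r applied to %d cells", policy, n_sub)
    try:
        grid = resolved.mul(doses / 1000.0, axis=0) * float(constants.days_per_week)
    except Exception as exc:  # pragma: no cover - defensive context wrapper
        raise ValueError(f"intake conversion failed: {exc}") from exc
    return WeeklyIntakeTable(mg_per_week=grid, constants=constants, policy=policy)


def per_kg_bw(mg_per_week: pd.DataFrame | pd.Series | float, constants: Constants) -> object:
    """Convert per-person mg/week to mg per kg body weight per week."""
    if not constants.body_weight > 0:
        raise ValueError("body_weight must be > 0")
    return mg_per_week / constants.body_weight


def write_intake_csv(table: WeeklyIntakeTable, path) -> None:
    """Long-format export: code, element, mass, display value and unit."""
    rows = []
    disp = table.display_frame(rounded=True)
    for code in table.codes:
        for el in ELEMENTS:
            rows.append(
                {
                    "code": code,
                    "element": el,
                    "mass_mg_per_week": table.mg_per_week.at[code, el],
                    "display_value": disp.at[code, el],
                    "display_unit": display_unit(el),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
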