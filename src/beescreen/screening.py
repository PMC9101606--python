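"""Exceedance screening against health-based weekly guidance values.

Each element carries one tolerable-weekly-intake style limit (PTWI,
TWI, PMTWI or MTWI), published per kg body weight per week.  Two
comparison modes are provided:

``faithful``
    Compares the *per-person* weekly mass, expressed in the guidance
    value's mass unit (µg or mg), against the guidance's numeric value.
    This is the convention used in the source survey this package
    reproduces (it treats e.g. "19.6 µg/kg bw/week" as a 19.6 µg/week
    cut-off) and is the mode that matches its published exceedance
    counts.

``strict``
    The dimensionally coherent comparison: weekly mass divided by body
    weight, in matching per-kg-bw units, against the guidance value.

A sample exceeds only on a strictly greater-than comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core import ELEMENTS, Constants
from .intake import WeeklyIntakeTable

__all__ = [
    "GUIDANCE_KINDS",
    "GuidanceValue",
    "ExceedanceReport",
    "default_registry",
    "load_registry",
    "screen",
    "write_exceedance_csv",
    "summarize",
]

GUIDANCE_KINDS: tuple[str, ...] = ("PTWI", "TWI", "PMTWI", "MTWI")


@dataclass(frozen=True)
class GuidanceValue:
    """A health-based weekly limit for one element, as published."""

    element: str
    kind: str
    value: float
    nominal_units: str  # "ug/kg bw/week" or "mg/kg bw/week"
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in GUIDANCE_KINDS:
            raise ValueError(f"unknown guidance kind: {self.kind!r}")
        if not self.value > 0:
            raise ValueError(f"{self.element}: guidance value must be > 0")
        if self.nominal_units not in ("ug/kg bw/week", "mg/kg bw/week"):
            raise ValueError(f"{self.element}: unsupported units {self.nominal_units!r}")

    @property
    def mass_unit(self) -> str:
        return self.nominal_units.split("/")[0]


@dataclass(frozen=True)
class ExceedanceReport:
    element: str
    mode: str
    kind: str
    threshold: float
    threshold_units: str
    codes: tuple[str, ...]
    count: int
    percentage: float

    def __post_init__(self) -> None:
        if self.count != len(self.codes):
            raise ValueError("count must equal the number of exceeding codes")


def load_registry(path) -> list[GuidanceValue]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            GuidanceValue(
                element=row["element"],
                kind=row["kind"],
                value=float(row["value"]),
                nominal_units=row["nominal_units"],
                source=str(row.get("source", "")),
            )
        )
    seen = [g.element for g in out]
    dup = sorted({e for e in seen if seen.count(e) > 1})
    if dup:
        raise ValueError(f"duplicate guidance entries for {dup}")
    return out


def default_registry() -> list[GuidanceValue]:
    """The 11-element registry bundled with the package."""
    return load_registry(str(resources.files("beescreen") / "data" / "guidance.csv"))


def screen(
    intakes: WeeklyIntakeTable,
    registry: list[GuidanceValue] | None = None,
    mode: str = "faithful",
    constants: Constants | None = None,
    elements: tuple[str, ...] = ELEMENTS,
) -> list[ExceedanceReport]:
    """Exceedance report per element; see the module notes on modes."""
    if mode not in ("faithful", "strict"):
        raise ValueError(f"unknown screening mode: {mode!r}")
    registry = registry if registry is not None else default_registry()
    constants = constants or intakes.constants
    by_el = {g.element: g for g in registry}
    n = len(intakes.codes)
    reports = []
    for el in elements:
        if el not in by_el:
            raise KeyError(f"no guidance value registered for element {el}")
        g = by_el[el]
        mass_mg = intakes.mg_per_week[el]
        if mode == "faithful":
            compared = mass_mg * 1000.0 if g.mass_unit == "ug" else mass_mg
            units = g.mass_unit + "/week (per person)"
        else:
            per_kg = mass_mg / constants.body_weight
            compared = per_kg * 1000.0 if g.mass_unit == "ug" else per_kg
            units = g.nominal_units
        exceed = compared > g.value
        codes = tuple(c for c in intakes.codes if bool(exceed[c]))
        reports.append(
            ExceedanceReport(
                element=el,
                mode=mode,
                kind=g.kind,
                threshold=g.value,
                threshold_units=units,
                codes=codes,
                count=len(codes),
                percentage=round(100.0 * len(codes) / n, 2) if n else 0.0,
            )
        )
    return reports


def write_exceedance_csv(reports: list[ExceedanceReport], path) -> None:
    pd.DataFrame(
        [
            {
                "element": r.element,
                "mode": r.mode,
                "kind": r.kind,
                "threshold": r.threshold,
                "threshold_units": r.threshold_units,
                "count": r.count,
                "percentage": r.percentage,
                "codes": ";".join(r.codes),
            }
            for r in reports
        ]
    ).to_csv(path, index=False)


def summarize(reports: list[ExceedanceReport], n_samples: int) -> str:
    """Human-readable screening summary, one line per element.

    Total As is screened against its guidance value as measured;
    speciation (organic vs inorganic As) is outside the data and the
    counts here refer to total As only.
    """
    lines = []
    for r in reports:
        if r.count:
            lines.append(
                f"{r.element}: {r.count} of {n_samples} samples ({r.percentage}%) exceed "
                f"{r.kind} {r.threshold:g} [{r.threshold_units}, {r.mode} mode]: "
                + ", ".join(r.codes)
            )
        else:
            lines.append(
                f"{r.element}: no sample exceeds {r.kind} {r.threshold:g} "
                f"[{r.threshold_units}, {r.mode} mode]"
            )
    return "\n".join(lines) + "\n"
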