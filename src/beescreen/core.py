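"""Domain model and I/O for elemental panels of food supplements.

The package works on a *panel*: a complete sample × element grid of
ICP-MS concentrations (mg/kg) for 11 elements — the toxic metals Pb, Cd,
As, Hg and the micronutrients Cr, Fe, Co, Ni, Cu, Zn, Se — measured in
food supplements based on beehive products (royal jelly, propolis,
honey).  Values below the limit of quantification (LOQ) are
left-censored and carried with an explicit flag; the default analysis
policy substitutes the LOQ itself, the most conservative choice for
intake screening.

A bundled 51-sample fixture ships with the package (three market
groups: RG royal-jelly, PR propolis, HO honey; five samples belong to
two groups at once).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ELEMENTS",
    "TOXIC_METALS",
    "MICRONUTRIENTS",
    "GROUPS",
    "CENSOR_POLICIES",
    "SchemaError",
    "DoseParseError",
    "Measurement",
    "DoseSpec",
    "SupplementSample",
    "Panel",
    "Constants",
    "element_class",
    "parse_dose",
    "resolve_censored",
    "load_panel",
    "write_panel",
    "fixture_paths",
    "load_fixture_panel",
]

#: Element columns in canonical (report) order.
ELEMENTS: tuple[str, ...] = ("Pb", "Cd", "As", "Hg", "Cr", "Fe", "Co", "Ni", "Cu", "Zn", "Se")

TOXIC_METALS: frozenset[str] = frozenset({"Pb", "Cd", "As", "Hg"})
MICRONUTRIENTS: frozenset[str] = frozenset(ELEMENTS) - TOXIC_METALS

GROUPS: tuple[str, ...] = ("RG", "PR", "HO")

#: Supported left-censoring substitution policies.
CENSOR_POLICIES: tuple[str, ...] = ("loq", "half_loq", "zero")

_GRAMS_PER_ML = 1.0
_GRAMS_PER_DROP = 0.03


class SchemaError(ValueError):
    """Raised when an input table violates the panel CSV schema."""


class DoseParseError(ValueError):
    """Raised when no daily-dose quantity can be read from a dose string."""


def element_class(symbol: str) -> str:
    """Return ``"toxic-metal"`` or ``"micronutrient"`` for an element symbol."""
    if symbol in TOXIC_METALS:
        return "toxic-metal"
    if symbol in MICRONUTRIENTS:
        return "micronutrient"
    raise KeyError(f"unknown element symbol: {symbol!r}")


@dataclass(frozen=True)
class Measurement:
    """One element's concentration in one sample, mg/kg.

    ``censored`` marks a value below the LOQ; the stored ``value`` then
    equals the LOQ itself (the raw table prints ``<LOQ``).
    """

    element: str
    value: float
    censored: bool = False
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise SchemaError(f"unknown element: {self.element!r}")
        if not self.value > 0:
            raise SchemaError(f"{self.element}: concentration must be > 0, got {self.value}")
        if self.censored:
            if self.loq is None:
                raise SchemaError(f"{self.element}: censored measurement requires an LOQ")
            if self.value != self.loq:
                raise SchemaError(
                    f"{self.element}: censored value {self.value} must equal LOQ {self.loq}"
                )


@dataclass(frozen=True)
class DoseSpec:
    """Recommended daily dose: the verbatim label text plus grams/day."""

    raw_text: str
    grams_per_day: float

    def __post_init__(self) -> None:
        if not self.grams_per_day > 0:
            raise SchemaError(f"grams_per_day must be > 0, got {self.grams_per_day}")

    def render(self) -> str:
        return f"{self.grams_per_day:g} g"


@dataclass(frozen=True)
class SupplementSample:
    code: str
    name: str
    form: str
    groups: tuple[str, ...]
    dose: DoseSpec

    def __post_init__(self) -> None:
        if not self.groups:
            raise SchemaError(f"{self.code}: sample must belong to at least one group")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise SchemaError(f"{self.code}: unknown group(s) {sorted(bad)}")
        if len(set(self.groups)) != len(self.groups):
            raise SchemaError(f"{self.code}: duplicated group membership")

    @property
    def shared(self) -> bool:
        """True iff the sample is listed under two market groups."""
        return len(self.groups) == 2


@dataclass(frozen=True)
class Constants:
    """Reference-consumer conventions: 70 kg body weight, 7 days/week."""

    body_weight: float = 70.0
    days_per_week: int = 7

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise SchemaError(f"body_weight must be > 0, got {self.body_weight}")


@dataclass
class Panel:
    """A complete sample × element grid of measurements.

    ``values`` holds concentrations in mg/kg (censored cells already at
    their LOQ), ``censored`` the boolean flags; both are indexed by
    sample code with one column per element, in canonical order.
    """

    samples: list[SupplementSample]
    values: pd.DataFrame
    censored: pd.DataFrame

    def __post_init__(self) -> None:
        codes = [s.code for s in self.samples]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise SchemaError(f"duplicate sample code(s): {dup}")
        for frame, label in ((self.values, "values"), (self.censored, "censored")):
            if list(frame.columns) != list(ELEMENTS):
                raise SchemaError(f"{label}: columns must be {list(ELEMENTS)}")
            if list(frame.index) != codes:
                raise SchemaError(f"{label}: row index must match the sample codes")
        if self.values.isna().any().any():
            cell = self.values.stack(future_stack=True)
            missing = cell[cell.isna()].index[0]
            raise SchemaError(f"missing concentration for sample {missing[0]}, element {missing[1]}")
        if (self.values <= 0).any().any():
            raise SchemaError("concentrations must be strictly positive")

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.samples]

    def sample(self, code: str) -> SupplementSample:
        for s in self.samples:
            if s.code == code:
                return s
        raise KeyError(code)

    def measurement(self, code: str, element: str) -> Measurement:
        cens = bool(self.censored.at[code, element])
        value = float(self.values.at[code, element])
        return Measurement(element, value, censored=cens, loq=value if cens else None)

    def doses(self) -> pd.Series:
        """Grams/day per sample, indexed by code."""
        return pd.Series({s.code: s.dose.grams_per_day for s in self.samples}).loc[self.codes]

    def resolve(self, policy: str = "loq") -> pd.DataFrame:
        """Concentration grid with the censoring policy applied (mg/kg)."""
        if policy not in CENSOR_POLICIES:
            raise ValueError(f"unknown censoring policy: {policy!r}")
        out = self.values.copy()
        if policy == "half_loq":
            out = out.where(~self.censored, out / 2.0)
        elif policy == "zero":
            out = out.where(~self.censored, 0.0)
        return out

    def n_censored(self) -> pd.Series:
        """Number of censored cells per element."""
        return self.censored.sum(axis=0)

    def loqs(self) -> dict[str, float]:
        """Per-element LOQ inferred from the censored cells (absent if never censored)."""
        out: dict[str, float] = {}
        for el in ELEMENTS:
            mask = self.censored[el]
            if mask.any():
                out[el] = float(self.values.loc[mask, el].iloc[0])
        return out


# -- dose grammar ------------------------------------------------------------

_NUM = r"(\d+(?:[.,]\d+)?)"
_RE_GRAMS = re.compile(rf"{_NUM}\s*g\b")
_RE_ML = re.compile(rf"{_NUM}\s*m[lL]\b")
_RE_DROPS = re.compile(rf"{_NUM}\s*drops?\b", re.IGNORECASE)


def parse_dose(raw_text: str) -> float:
    """Daily dose in grams from a label dose string.

    Precedence: an explicit gram amount (the last one stated, so
    ``"45 drops ≈ 1.35 mL ≈ 1.35 g"`` reads 1.35) beats a millilitre
    amount (1 mL ≡ 1 g for these matrices) beats a drop count
    (1 drop ≡ 0.03 g).
    """
    if not raw_text or not raw_text.strip():
        raise DoseParseError("empty dose string")
    grams = _RE_GRAMS.findall(raw_text)
    if grams:
        return float(grams[-1].replace(",", "."))
    ml = _RE_ML.findall(raw_text)
    if ml:
        return float(ml[-1].replace(",", ".")) * _GRAMS_PER_ML
    drops = _RE_DROPS.findall(raw_text)
    if drops:
        return float(drops[-1].replace(",", ".")) * _GRAMS_PER_DROP
    raise DoseParseError(f"no parsable dose quantity in {raw_text!r}")


def resolve_censored(m: Measurement, policy: str = "loq") -> float:
    """Concentration (mg/kg) after applying a censoring policy."""
    if policy not in CENSOR_POLICIES:
        raise ValueError(f"unknown censoring policy: {policy!r}")
    if not m.censored:
        return m.value
    assert m.loq is not None
    if policy == "loq":
        return m.loq
    if policy == "half_loq":
        return m.loq / 2.0
    return 0.0


# -- CSV I/O -----------------------------------------------------------------

def _read_register(path: str | Path) -> list[SupplementSample]:
    df = pd.read_csv(path, dtype=str)
    required = {"code", "name", "form", "groups", "dose_text"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing register column(s) {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        raw = row["dose_text"]
        g = row.get("grams_per_day")
        if g is not None and isinstance(g, str) and g.strip():
            grams = float(g)
        else:
            grams = parse_dose(raw)
        samples.append(
            SupplementSample(
                code=row["code"],
                name=row["name"],
                form=row["form"],
                groups=tuple(p for p in row["groups"].split(";") if p),
                dose=DoseSpec(raw_text=raw, grams_per_day=grams),
            )
        )
    return samples


def load_panel(register_path: str | Path, concentration_path: str | Path) -> Panel:
    """Read the sample register and the concentration grid into a Panel.

    Concentration cells prefixed ``<`` are parsed as left-censored at
    the stated LOQ.  Any missing cell, duplicated code, or non-positive
    concentration raises :class:`SchemaError` naming the offender.
    """
    samples = _read_register(register_path)
    raw = pd.read_csv(concentration_path, dtype=str)
    if "code" not in raw.columns:
        raise SchemaError(f"{concentration_path}: missing 'code' column")
    missing_cols = set(ELEMENTS) - set(raw.columns)
    if missing_cols:
        raise SchemaError(f"{concentration_path}: missing element column(s) {sorted(missing_cols)}")
    raw = raw.set_index("code")
    reg_codes = [s.code for s in samples]
    if sorted(raw.index) != sorted(reg_codes):
        extra = set(raw.index) - set(reg_codes)
        absent = set(reg_codes) - set(raw.index)
        raise SchemaError(
            f"register/concentration code mismatch: extra={sorted(extra)} missing={sorted(absent)}"
        )
    raw = raw.loc[reg_codes, list(ELEMENTS)]

    values = pd.DataFrame(index=raw.index, columns=list(ELEMENTS), dtype=float)
    censored = pd.DataFrame(False, index=raw.index, columns=list(ELEMENTS))
    for code in raw.index:
        for el in ELEMENTS:
            cell = raw.at[code, el]
            if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
                raise SchemaError(f"missing concentration for sample {code}, element {el}")
            text = str(cell).strip()
            cens = text.startswith("<")
            num = float(text.lstrip("<").strip())
            if num <= 0:
                raise SchemaError(f"non-positive concentration for sample {code}, element {el}")
            values.at[code, el] = num
            censored.at[code, el] = cens
    return Panel(samples=samples, values=values, censored=censored)


def write_panel(panel: Panel, register_path: str | Path, concentration_path: str | Path) -> None:
    """Write a panel back to the two CSV schemas (deterministic column order)."""
    reg = pd.DataFrame(
        {
            "code": [s.code for s in panel.samples],
            "name": [s.name for s in panel.samples],
            "form": [s.form for s in panel.samples],
            "groups": [";".join(s.groups) for s in panel.samples],
            "dose_text": [s.dose.raw_text for s in panel.samples],
            "grams_per_day": [f"{s.dose.grams_per_day:g}" for s in panel.samples],
        }
    )
    reg.to_csv(register_path, index=False)

    cells = panel.values.astype(object).copy()
    for code in panel.codes:
        for el in ELEMENTS:
            v = panel.values.at[code, el]
            text = f"{v:g}"
            if panel.censored.at[code, el]:
                text = "<" + text
            cells.at[code, el] = text
    cells.index.name = "code"
    cells.to_csv(concentration_path)


def fixture_paths() -> tuple[Path, Path]:
    """Paths of the bundled register and concentration CSVs."""
    base = resources.files("beescreen") / "data"
    return Path(str(base / "samples.csv")), Path(str(base / "concentrations.csv"))


def load_fixture_panel() -> Panel:
    """The bundled 51-sample market survey panel."""
    reg, conc = fixture_paths()
    return load_panel(reg, conc)
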