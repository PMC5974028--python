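"""Climate variables, units and scaling conventions.

The modelling set consists of 12 climate variables: four annual ones —
Hargreaves reference evaporation (``eref``, mm), degree-days above 5 °C
(``dd5``), degree-days below 18 °C (``dd_18``) and mean annual temperature
(``mat``, °C) — plus seasonal (spring/summer/autumn/winter) splits of DD5
and DD_18.

Degree-day and evaporation variables enter the growth model scaled down by
a factor of 100 so their coefficients are of order 1; MAT is never scaled.
:class:`ClimateVector` stores values in *model* (scaled) units; tabular
data keep original units and are scaled at model ingestion via
:func:`scale_climate`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

#: The 12 modelling variables, in canonical order.
CLIMATE_VARS: tuple[str, ...] = (
    "eref",
    "dd5",
    "dd_18",
    "mat",
    "dd5_sp",
    "dd5_sm",
    "dd5_at",
    "dd5_wt",
    "dd_18_sp",
    "dd_18_sm",
    "dd_18_at",
    "dd_18_wt",
)

#: Variables divided by 100 when converting original units to model units.
SCALED_VARS: frozenset[str] = frozenset(v for v in CLIMATE_VARS if v != "mat")

#: Scale divisor applied to every variable in SCALED_VARS.
SCALE_FACTOR = 100.0

#: Minimum annual DD5 (original units) for the growth model to apply.
DD5_APPLICABILITY_MIN = 100.0

#: Plausible Pacific-Northwest ranges (original units) used as generator
#: defaults: maritime coast through interior montane sites.
PNW_CLIMATE_RANGES: dict[str, tuple[float, float]] = {
    "eref": (450.0, 950.0),
    "dd5": (400.0, 2400.0),
    "dd_18": (3000.0, 4800.0),
    "mat": (0.0, 12.0),
    "dd5_sp": (50.0, 700.0),
    "dd5_sm": (150.0, 1500.0),
    "dd5_at": (50.0, 600.0),
    "dd5_wt": (0.0, 200.0),
    "dd_18_sp": (600.0, 1300.0),
    "dd_18_sm": (300.0, 900.0),
    "dd_18_at": (600.0, 1300.0),
    "dd_18_wt": (900.0, 1500.0),
}


class ApplicabilityError(ValueError):
    """Raised when the model is applied outside its climatic domain
    (annual DD5 at or below 100 degree-days in original units)."""


@dataclass(frozen=True)
class ClimateVector:
    """One site's 12 modelling variables in model (scaled) units."""

    eref: float
    dd5: float
    dd_18: float
    mat: float
    dd5_sp: float = 0.0
    dd5_sm: float = 0.0
    dd5_at: float = 0.0
    dd5_wt: float = 0.0
    dd_18_sp: float = 0.0
    dd_18_sm: float = 0.0
    dd_18_at: float = 0.0
    dd_18_wt: float = 0.0

    @classmethod
    def from_original(cls, **values: float) -> "ClimateVector":
        """Build from original-unit values, applying the /100 convention."""
        scaled = {
            k: (v / SCALE_FACTOR if k in SCALED_VARS else v)
            for k, v in values.items()
        }
        return cls(**scaled)

    def check_applicability(self) -> None:
        if self.dd5 * SCALE_FACTOR <= DD5_APPLICABILITY_MIN:
            raise ApplicabilityError(
                f"model requires DD5 > {DD5_APPLICABILITY_MIN:g} degree-days "
                f"(got {self.dd5 * SCALE_FACTOR:g})"
            )

    def __getitem__(self, name: str) -> float:
        if name not in CLIMATE_VARS:
            raise KeyError(f"unknown climate variable {name!r}")
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def validate_climate_names(names) -> tuple[str, ...]:
    """Check a list of variable names against the modelling set; reject
    unknowns and duplicates. Returns the names as a tuple (order kept)."""
    names = tuple(names)
    unknown = [n for n in names if n not in CLIMATE_VARS]
    if unknown:
        raise KeyError(f"unknown climate variable(s): {unknown}")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate climate variable in {names}")
    return names


def scale_climate(df: pd.DataFrame) -> pd.DataFrame:
    """Convert original-unit climate columns to model units (/100 for all
    degree-day and Eref variables; MAT unchanged). Non-climate columns pass
    through untouched."""
    out = df.copy()
    for col in out.columns:
        if col in SCALED_VARS:
            out[col] = out[col] / SCALE_FACTOR
    return out


def check_applicability_frame(df: pd.DataFrame) -> None:
    """Raise ApplicabilityError if any row's DD5 (original units) <= 100."""
    bad = np.asarray(df["dd5"]) <= DD5_APPLICABILITY_MIN
    if bad.any():
        idx = np.flatnonzero(bad)[:10]
        raise ApplicabilityError(
            f"{int(bad.sum())} record(s) have DD5 <= "
            f"{DD5_APPLICABILITY_MIN:g} (rows {idx.tolist()} ...)"
        )
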