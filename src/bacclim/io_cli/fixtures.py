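"""Packaged transcriptions of the published regional composite tables.

``table1`` holds region x scenario x variable composite means with spatial
standard errors and cell counts; ``table2`` holds the regional decomposition
terms (total change in free-living specific DOC uptake, DOC-control term,
temperature-control term) per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..composites import REGIONS

__all__ = ["PaperFixture", "load_fixture", "TABLE1_VARIABLES", "TABLE2_TERMS"]

TABLE1_VARIABLES = ("BB", "BB_DOC", "BB_POC", "BCD", "BR", "BP", "T", "POC", "DOC")
TABLE1_SCENARIOS = ("baseline", "ssp126", "ssp245", "ssp370", "ssp585")
TABLE2_TERMS = ("total", "doc", "temp")
TABLE2_SCENARIOS = ("ssp126", "ssp245", "ssp370", "ssp585")


@dataclass(frozen=True)
class PaperFixture:
    """One transcribed summary table with schema validation and accessors."""

    name: str
    frame: pd.DataFrame

    def value(self, region: str, scenario: str, key: str) -> float:
        """Composite mean for (region, scenario, variable-or-term)."""
        col = "variable" if self.name == "table1" else "term"
        sel = self.frame[
            (self.frame["region"] == region)
            & (self.frame["scenario"] == scenario)
            & (self.frame[col] == key)
        ]
        if len(sel) != 1:
            raise KeyError(f"{self.name}: no unique row for ({region}, {scenario}, {key})")
        return float(sel["mean"].iloc[0])

    def se(self, region: str, scenario: str, key: str) -> float:
        col = "variable" if self.name == "table1" else "term"
        sel = self.frame[
            (self.frame["region"] == region)
            & (self.frame["scenario"] == scenario)
            & (self.frame[col] == key)
        ]
        if len(sel) != 1:
            raise KeyError(f"{self.name}: no unique row for ({region}, {scenario}, {key})")
        return float(sel["se"].iloc[0])

    def n_cells(self, region: str) -> int:
        sel = self.frame[self.frame["region"] == region]
        return int(sel["n"].iloc[0])


def _validate_table1(df: pd.DataFrame) -> None:
    required = {"region", "scenario", "variable", "mean", "se", "n", "units"}
    if not required.issubset(df.columns):
        raise ValueError(f"table1 fixture missing columns {required - set(df.columns)}")
    for var in TABLE1_VARIABLES:
        for scen in TABLE1_SCENARIOS:
            sub = df[(df["variable"] == var) & (df["scenario"] == scen)]
            if sorted(sub["region"]) != sorted(REGIONS):
                raise ValueError(f"table1 fixture incomplete for {var}/{scen}")


def _validate_table2(df: pd.DataFrame) -> None:
    required = {"region", "scenario", "term", "mean", "se", "n", "units"}
    if not required.issubset(df.columns):
        raise ValueError(f"table2 fixture missing columns {required - set(df.columns)}")
    for term in TABLE2_TERMS:
        for scen in TABLE2_SCENARIOS:
            sub = df[(df["term"] == term) & (df["scenario"] == scen)]
            if sorted(sub["region"]) != sorted(REGIONS):
                raise ValueError(f"table2 fixture incomplete for {term}/{scen}")


def load_fixture(name: str) -> PaperFixture:
    """Load and validate a packaged fixture (``table1`` or ``table2``)."""
    if name not in ("table1", "table2"):
        raise ValueError(f"unknown fixture {name!r}; choose 'table1' or 'table2'")
    ref = resources.files("bacclim").joinpath("data", f"{name}.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if name == "table1":
        _validate_table1(df)
    else:
        _validate_table2(df)
    return PaperFixture(name=name, frame=df)
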