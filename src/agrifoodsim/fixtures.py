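"""Loader for the hand-encoded printed reference tables.

One CSV per table, shipped as package data, region labels as printed.
Empty cells printed as an en-dash ("–") load as missing values, never as
zero; sums skip missing.  Marginal rows that are true sums of printed
components reproduce after the table's printed rounding; some printed
sub-region rows include residual countries in the marginal only, and those
are stored but not asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

FIXTURE_FILES = {
    "table1": "table1_investment_landscape.csv",
    "table2": "table2_ssp2_macro.csv",
    "table3": "table3_comp_targets.csv",
    "table4": "table4_baseline_costs.csv",
    "table5": "table5_comp_costs.csv",
    "table6": "table6_income_scenarios.csv",
}

# printed precision: number of decimal places per table
TABLE_DECIMALS = {"table1": 0, "table2": 1, "table3": 0, "table4": 2,
                  "table5": 2, "table6": 1}

# Region-label aliases between fixture tables and model region codes.
FIXTURE_REGION_CODES = {
    "Africa": "AFR",
    "Northern Africa": "NAF",
    "South of the Sahara": "SSA",
    "South of Sahara": "SSA",
    "Africa South of the Sahara": "SSA",
    "Western Africa": "WAF",
    "Eastern Africa": "EAF",
    "Central Africa": "CAF",
    "Southern Africa": "SAF",
    "North Africa and West Asia": "NAWA",
    "Africa and West Asia": "AWA",
    "Other Developing Countries": "ODV",
    "Developing Countries": "DVG",
    "All Developing Countries": "DVG",
    "Developed Countries": "DEV",
    "World": "WLD",
}


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSet:
    investment_landscape: pd.DataFrame  # table 1, million USD
    macro: pd.DataFrame                 # table 2
    comp_targets: pd.DataFrame          # table 3, percent
    baseline_costs: pd.DataFrame        # table 4, billion USD/yr
    comp_costs: pd.DataFrame            # table 5, billion USD/yr
    income_scenarios: pd.DataFrame      # table 6, thousand USD/person

    def by_name(self, name: str) -> pd.DataFrame:
        return {
            "table1": self.investment_landscape,
            "table2": self.macro,
            "table3": self.comp_targets,
            "table4": self.baseline_costs,
            "table5": self.comp_costs,
            "table6": self.income_scenarios,
        }[name]


def _read(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, na_values=["–", "-", ""], index_col="region")
    except Exception as exc:  # surface the row if pandas reports one
        raise FixtureError(f"malformed fixture {path.name}: {exc}") from exc
    bad = [c for c in frame.columns if frame[c].dtype == object]
    if bad:
        for c in bad:
            for i, v in enumerate(frame[c]):
                if isinstance(v, str):
                    raise FixtureError(
                        f"malformed fixture {path.name}: non-numeric value "
                        f"{v!r} at row {i + 2}, column {c}")
    frame.index = [FIXTURE_REGION_CODES.get(r, r) for r in frame.index]
    return frame


def default_fixture_dir() -> Path:
    return Path(resources.files("agrifoodsim") / "data")


def load_paper_fixtures(path: Optional[Path] = None) -> FixtureSet:
    """Load every reference table from ``path`` (default: packaged data)."""
    base = Path(path) if path is not None else default_fixture_dir()
    frames = {}
    for key, fname in FIXTURE_FILES.items():
        fpath = base / fname
        if not fpath.exists():
            raise FixtureError(f"fixture file missing: {fpath}")
        frames[key] = _read(fpath)
    return FixtureSet(
        investment_landscape=frames["table1"],
        macro=frames["table2"],
        comp_targets=frames["table3"],
        baseline_costs=frames["table4"],
        comp_costs=frames["table5"],
        income_scenarios=frames["table6"],
    )


def sum_matches_printed(components: pd.Series, printed: float,
                        decimals: int) -> bool:
    """Does the printed marginal equal the component sum after printed
    rounding?  Each printed component carries up to half a ULP of rounding
    error, so the tolerance is half an ULP per non-missing component."""
    vals = components.dropna()
    tol = 0.5 * 10.0 ** (-decimals) * (len(vals) + 1)
    return abs(float(vals.sum()) - printed) <= tol
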