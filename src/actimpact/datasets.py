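"""Accessors for the small data tables shipped with the package.

* ``load_default_compendium`` — illustrative MET values for common
  recreational activities plus one average MET per non-recreation domain.
  Replace with a study-specific compendium table for real analyses.
* ``load_example_rr`` — an illustrative monotone relative-risk table for
  the five outcomes (breast cancer flagged women-only).  These are demo
  values, not estimates from any meta-analysis.
* ``load_brazil_2015_deaths`` — premature deaths (ages 30-69) in Brazil in
  2015 by outcome and sex, from the national Mortality Information System,
  with major-NCD and all-cause denominators.
"""

from __future__ import annotations

from pathlib import Path

from .attribution import DeathTable, read_deaths_csv
from .impact import RRSet, read_rr_csv
from .scoring import Compendium, read_compendium_csv

__all__ = [
    "load_default_compendium",
    "load_example_rr",
    "load_brazil_2015_deaths",
    "data_path",
]

_DATA_DIR = Path(__file__).parent / "data"


def data_path(name: str) -> Path:
    """Absolute path of a shipped data file."""
    path = _DATA_DIR / name
    if not path.exists():
        raise FileNotFoundError(f"no shipped data file {name!r}")
    return path


def load_default_compendium() -> Compendium:
    return read_compendium_csv(data_path("compendium.csv"))


def load_example_rr() -> dict[str, RRSet]:
    return read_rr_csv(data_path("rr_example.csv"))


def load_brazil_2015_deaths() -> DeathTable:
    return read_deaths_csv(data_path("deaths_brazil_2015.csv"))
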