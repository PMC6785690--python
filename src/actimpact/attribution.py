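"""From impact fractions to preventable premature deaths.

Applies each (scenario, outcome, stratum) impact fraction to the matching
count of premature deaths (ages 30-69), rounds to whole deaths, and
aggregates the five outcomes into totals expressed as shares of premature
deaths from major NCDs and from all causes.  The two denominators are
consumed as data — they cover a wider ICD set (all CVD, all cancers,
chronic respiratory disease) than the five modelled outcomes and can never
be derived from them.

Rounding happens at the cell level, half away from zero, and stratum totals
sum the rounded cells; this is the arithmetic that makes a published table
of integer cells internally consistent.

Structural NA cells (a women-only outcome in men, and its both-sex row) are
kept distinct from zeros: a zero means "no impact", NA means "not defined".
The women's count for such an outcome still enters the both-sex totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .impact import ImpactResult

__all__ = [
    "OUTCOMES",
    "STRATA",
    "DENOMINATORS",
    "DeathTable",
    "AttributionReport",
    "preventable_deaths",
    "aggregate_shares",
    "build_report",
    "read_deaths_csv",
    "write_deaths_csv",
]

#: The five modelled outcomes, in report order.
OUTCOMES: tuple[str, ...] = ("breast_cancer", "colon_cancer", "diabetes", "ihd", "stroke")

STRATA: tuple[str, ...] = ("both", "men", "women")

#: Special rows of the deaths table holding aggregate denominators.
DENOMINATORS: tuple[str, ...] = ("major_ncd", "all_cause")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class DeathTable:
    """Premature deaths (ages 30-69) by outcome and stratum, plus denominators.

    ``deaths`` maps (outcome, stratum) to a count, or to ``None`` for a
    structurally missing cell (breast cancer in men).  The both-sex count
    for an outcome need not equal men + women: deaths with missing sex
    information enter only the both-sex row.  ``denominators`` maps
    (denominator, stratum) to the major-NCD and all-cause counts.
    """

    deaths: Mapping[tuple[str, str], int | None]
    denominators: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for key, v in self.deaths.items():
            if v is not None and (v < 0 or v != int(v)):
                raise ValueError(f"death count for {key} must be a non-negative integer, got {v}")
        for key, v in self.denominators.items():
            if v <= 0:
                raise ValueError(f"denominator for {key} must be positive, got {v}")

    def count(self, outcome: str, stratum: str) -> int | None:
        return self.deaths.get((outcome, stratum))

    def denominator(self, which: str, stratum: str) -> int:
        try:
            return self.denominators[(which, stratum)]
        except KeyError:
            raise KeyError(f"no {which!r} denominator for stratum {stratum!r}") from None


def preventable_deaths(pif: float, deaths: int) -> int:
    """Whole-number preventable deaths: round(pif x deaths), half away from zero."""
    if deaths < 0:
        raise ValueError(f"deaths must be >= 0, got {deaths}")
    if pif > 1:
        raise ValueError(f"pif must be <= 1, got {pif}")
    return _round_half_away(pif * deaths)


def aggregate_shares(
    per_outcome: Sequence[int], denominators: tuple[int, int]
) -> tuple[int, float, float]:
    """Total preventable deaths and their % of the two denominators.

    ``denominators`` is (major-NCD deaths, all-cause deaths); shares are in
    percent at full precision.
    """
    major, all_cause = denominators
    if major <= 0 or all_cause <= 0:
        raise ValueError("denominators must be positive")
    total = int(sum(per_outcome))
    return total, 100.0 * total / major, 100.0 * total / all_cause


@dataclass(frozen=True)
class AttributionReport:
    """Preventable-death report: per-cell results and per-stratum aggregates.

    ``cells`` has one row per (scenario, outcome, stratum) with the death
    count, the impact fraction in percent and the rounded preventable
    count (NaN marks structurally undefined cells).  ``summary`` has one
    row per (scenario, stratum) with the five-outcome total and its share
    of major-NCD and all-cause premature deaths.
    """

    cells: pd.DataFrame
    summary: pd.DataFrame
    scenarios: tuple[str, ...] = field(default=())

    def write_csv(self, cells_path: str | Path, summary_path: str | Path) -> None:
        """Full-precision machine-readable output."""
        self.cells.to_csv(cells_path, index=False)
        self.summary.to_csv(summary_path, index=False)

    def to_text(self) -> str:
        """Aligned text table: one block per outcome, PIF at two decimals."""
        lines: list[str] = []
        header = f"{'outcome':<14}{'stratum':<8}{'deaths':>9}"
        for sc in self.scenarios:
            header += f"{sc + ' PIF%':>22}{'n prev':>8}"
        lines.append(header)
        for outcome in list(dict.fromkeys(self.cells["outcome"])):
            for stratum in STRATA:
                sub = self.cells[
                    (self.cells["outcome"] == outcome) & (self.cells["stratum"] == stratum)
                ]
                if sub.empty:
                    continue
                deaths = sub["deaths"].iloc[0]
                row = f"{outcome:<14}{stratum:<8}"
                row += f"{'NA':>9}" if pd.isna(deaths) else f"{int(deaths):>9}"
                for sc in self.scenarios:
                    cell = sub[sub["scenario"] == sc].iloc[0]
                    if pd.isna(cell["pif_pct"]):
                        row += f"{'NA':>22}{'NA':>8}"
                    else:
                        row += f"{cell['pif_pct']:>22.2f}{int(cell['preventable']):>8}"
                lines.append(row)
        lines.append("")
        lines.append(
            f"{'aggregate':<14}{'stratum':<8}"
            + "".join(f"{sc + ' total':>22}{'%NCD':>8}{'%all':>8}" for sc in self.scenarios)
        )
        for stratum in STRATA:
            row = f"{'':<14}{stratum:<8}"
            for sc in self.scenarios:
                cell = self.summary[
                    (self.summary["scenario"] == sc) & (self.summary["stratum"] == stratum)
                ].iloc[0]
                row += (
                    f"{int(cell['total_preventable']):>22}"
                    f"{cell['major_ncd_share_pct']:>8.2f}"
                    f"{cell['all_cause_share_pct']:>8.2f}"
                )
            lines.append(row)
        return "\n".join(lines)


def build_report(
    impacts: Iterable[ImpactResult],
    deaths: DeathTable,
    outcomes: Sequence[str] = OUTCOMES,
    strata: Sequence[str] = STRATA,
) -> AttributionReport:
    """Assemble the attribution report from impact fractions and death counts.

    Every (scenario, outcome, applicable stratum) must be covered by
    ``impacts``; anything absent raises with the missing combinations
    listed.  A not-applicable impact in men propagates NA to the men's and
    both-sex cells of that outcome, while the women's preventable count
    still enters both-sex totals.
    """
    by_key: dict[tuple[str, str, str], ImpactResult] = {}
    for imp in impacts:
        by_key[(imp.scenario, imp.outcome, imp.stratum)] = imp
    scenarios = tuple(dict.fromkeys(k[0] for k in by_key))

    # women-only outcomes: men's cell is NA by construction
    na_outcomes = {
        imp.outcome for imp in by_key.values() if not imp.applicable and imp.stratum == "men"
    }

    missing = [
        (sc, oc, st)
        for sc in scenarios
        for oc in outcomes
        for st in strata
        if (sc, oc, st) not in by_key and not (oc in na_outcomes and st == "both")
    ]
    if missing:
        raise ValueError(f"impacts missing for combinations: {missing}")

    cell_rows: list[dict] = []
    totals: dict[tuple[str, str], int] = {(sc, st): 0 for sc in scenarios for st in strata}
    for sc in scenarios:
        for oc in outcomes:
            for st in strata:
                death_count = deaths.count(oc, st)
                if oc in na_outcomes and st in ("men", "both"):
                    # structurally undefined cell; both-sex totals pick up the
                    # women's contribution below
                    cell_rows.append(
                        {
                            "scenario": sc,
                            "outcome": oc,
                            "stratum": st,
                            "deaths": math.nan,
                            "pif_pct": math.nan,
                            "preventable": math.nan,
                        }
                    )
                    continue
                imp = by_key[(sc, oc, st)]
                if death_count is None:
                    raise ValueError(f"no death count for ({oc!r}, {st!r})")
                n_prev = preventable_deaths(imp.pif, death_count)
                cell_rows.append(
                    {
                        "scenario": sc,
                        "outcome": oc,
                        "stratum": st,
                        "deaths": death_count,
                        "pif_pct": 100.0 * imp.pif,
                        "preventable": n_prev,
                    }
                )
                totals[(sc, st)] += n_prev
                if oc in na_outcomes and st == "women":
                    totals[(sc, "both")] += n_prev

    summary_rows = []
    for sc in scenarios:
        for st in strata:
            total = totals[(sc, st)]
            _, major_share, all_share = aggregate_shares(
                [total],
                (deaths.denominator("major_ncd", st), deaths.denominator("all_cause", st)),
            )
            summary_rows.append(
                {
                    "scenario": sc,
                    "stratum": st,
                    "total_preventable": total,
                    "major_ncd_share_pct": major_share,
                    "all_cause_share_pct": all_share,
                }
            )

    return AttributionReport(
        cells=pd.DataFrame(cell_rows),
        summary=pd.DataFrame(summary_rows),
        scenarios=scenarios,
    )


# ---------------------------------------------------------------------------
# Deaths table I/O
# ---------------------------------------------------------------------------

def read_deaths_csv(path: str | Path) -> DeathTable:
    """Read a deaths CSV with columns ``outcome, stratum, deaths``.

    Rows with outcome ``major_ncd`` or ``all_cause`` carry the aggregate
    denominators; an empty ``deaths`` cell marks a structural NA.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("outcome", "stratum", "deaths"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    deaths: dict[tuple[str, str], int | None] = {}
    denominators: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        stratum = str(row.stratum)
        if stratum not in STRATA:
            raise ValueError(
                f"{path}: row {i}, column 'stratum': expected one of {STRATA}, got {stratum!r}"
            )
        value = None if pd.isna(row.deaths) else int(row.deaths)
        if row.outcome in DENOMINATORS:
            if value is None:
                raise ValueError(f"{path}: row {i}: denominator cannot be empty")
            denominators[(str(row.outcome), stratum)] = value
        else:
            deaths[(str(row.outcome), stratum)] = value
    return DeathTable(deaths=deaths, denominators=denominators)


def write_deaths_csv(table: DeathTable, path: str | Path) -> None:
    rows = [
        {"outcome": oc, "stratum": st, "deaths": "" if v is None else v}
        for (oc, st), v in table.deaths.items()
    ]
    rows += [
        {"outcome": oc, "stratum": st, "deaths": v}
        for (oc, st), v in table.denominators.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
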