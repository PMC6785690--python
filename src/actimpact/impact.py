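"""Potential impact fractions and the attributable-fraction special case.

For a categorical exposure with current prevalence P_i, counterfactual
prevalence P'_i and category relative risks RR_i, the potential impact
fraction is

    PIF = (sum_i P_i RR_i - sum_i P'_i RR_i) / sum_i P_i RR_i,

the expected proportional reduction in deaths from shifting the exposure
distribution while everything else stays the same.  When the counterfactual
puts everyone in the reference (minimum-risk) category this is the
population attributable fraction (PAF), the Levin-type multi-category form
(sum P_i RR_i - 1) / sum P_i RR_i, since RR_ref = 1.

Relative risks are external inputs (typically from a dose-response
meta-analysis); the reference category (>=8000 MET-min/week) must carry RR
exactly 1 — an RR vector normalised to a different reference is rejected
rather than silently rescaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exposure import ExposureDistribution
from .scoring import CATEGORY_LABELS

__all__ = [
    "RRSet",
    "ImpactResult",
    "potential_impact_fraction",
    "population_attributable_fraction",
    "read_rr_csv",
    "write_rr_csv",
]


@dataclass(frozen=True)
class RRSet:
    """Relative risks per exposure category for one outcome.

    ``rr`` is ordered low-to-high activity; the last entry (>=8000, the
    theoretical minimum risk exposure level) must equal exactly 1.
    Confidence limits, when present, are carried through I/O but not
    propagated into impact-fraction intervals.  ``women_only`` flags
    outcomes (breast cancer) for which a men's impact fraction is
    structurally not applicable.
    """

    outcome: str
    rr: tuple[float, float, float, float]
    ci_low: tuple[float, ...] | None = None
    ci_high: tuple[float, ...] | None = None
    women_only: bool = False

    def __post_init__(self) -> None:
        rr = tuple(float(v) for v in self.rr)
        object.__setattr__(self, "rr", rr)
        if len(rr) != len(CATEGORY_LABELS):
            raise ValueError(f"expected {len(CATEGORY_LABELS)} RRs, got {len(rr)}")
        if any(v <= 0 for v in rr):
            raise ValueError(f"all RRs must be > 0, got {rr}")
        if rr[-1] != 1.0:
            raise ValueError(
                f"reference-category RR must be exactly 1, got {rr[-1]!r}; "
                "renormalise to the >=8000 MET-min/week reference before use"
            )


@dataclass(frozen=True)
class ImpactResult:
    """Impact fraction for one (scenario, outcome, stratum) cell.

    ``pif`` is a proportion (not %); ``is_paf`` marks the
    exposure-elimination (tmrel) special case.  ``applicable`` is False for
    structurally undefined cells (a women-only outcome in men), whose
    ``pif`` is NaN — never 0, which would mean "no impact".
    """

    scenario: str
    outcome: str
    stratum: str
    pif: float
    is_paf: bool = False
    applicable: bool = True

    @classmethod
    def not_applicable(cls, scenario: str, outcome: str, stratum: str) -> "ImpactResult":
        return cls(
            scenario=scenario,
            outcome=outcome,
            stratum=stratum,
            pif=math.nan,
            is_paf=scenario == "tmrel",
            applicable=False,
        )


def potential_impact_fraction(
    current: ExposureDistribution,
    counterfactual: ExposureDistribution,
    rr: RRSet,
    scenario: str = "custom",
) -> ImpactResult:
    """PIF for shifting ``current`` to ``counterfactual`` under ``rr``.

    Computed at full precision; rounding happens only in reports.  A
    women-only outcome evaluated for the "men" stratum yields a
    not-applicable result.
    """
    if rr.women_only and current.stratum == "men":
        return ImpactResult.not_applicable(scenario, rr.outcome, current.stratum)
    p = current.shares
    q = counterfactual.shares
    if len(p) != len(q):
        raise ValueError("current and counterfactual must share the category scheme")
    exp_cur = sum(pi * ri for pi, ri in zip(p, rr.rr))
    exp_cf = sum(qi * ri for qi, ri in zip(q, rr.rr))
    pif = (exp_cur - exp_cf) / exp_cur
    return ImpactResult(
        scenario=scenario,
        outcome=rr.outcome,
        stratum=current.stratum,
        pif=pif,
        is_paf=scenario == "tmrel",
    )


def population_attributable_fraction(
    current: ExposureDistribution, rr: RRSet
) -> ImpactResult:
    """PAF: the PIF with everyone moved to the reference category.

    Delegates to :func:`potential_impact_fraction` with the degenerate
    counterfactual (0, 0, 0, 1), so the two routes are bit-identical.
    """
    reference = ExposureDistribution(
        stratum=current.stratum,
        shares=(0.0, 0.0, 0.0, 1.0),
        population_weight=current.population_weight,
    )
    return potential_impact_fraction(current, reference, rr, scenario="tmrel")


# ---------------------------------------------------------------------------
# RR table I/O
# ---------------------------------------------------------------------------

def read_rr_csv(path: str | Path) -> dict[str, RRSet]:
    """Read an RR table CSV into per-outcome :class:`RRSet`s.

    Columns: ``outcome, category, rr`` with optional ``ci_low, ci_high,
    women_only``; ``category`` labels must be exactly the four band labels
    and every outcome must cover all four.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("outcome", "category", "rr"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: dict[str, RRSet] = {}
    for outcome, grp in df.groupby("outcome", sort=False):
        grp = grp.set_index("category")
        missing = [c for c in CATEGORY_LABELS if c not in grp.index]
        if missing:
            raise ValueError(
                f"{path}: outcome {outcome!r} missing categories {missing}"
            )
        grp = grp.loc[list(CATEGORY_LABELS)]
        has_ci = "ci_low" in grp.columns and grp["ci_low"].notna().all()
        women_only = bool(grp["women_only"].iloc[0]) if "women_only" in grp.columns else False
        out[str(outcome)] = RRSet(
            outcome=str(outcome),
            rr=tuple(grp["rr"].astype(float)),
            ci_low=tuple(grp["ci_low"].astype(float)) if has_ci else None,
            ci_high=tuple(grp["ci_high"].astype(float)) if has_ci else None,
            women_only=women_only,
        )
    return out


def write_rr_csv(rrsets: Iterable[RRSet], path: str | Path) -> None:
    rows = []
    for rs in rrsets:
        for i, label in enumerate(CATEGORY_LABELS):
            rows.append(
                {
                    "outcome": rs.outcome,
                    "category": label,
                    "rr": rs.rr[i],
                    "ci_low": rs.ci_low[i] if rs.ci_low else "",
                    "ci_high": rs.ci_high[i] if rs.ci_high else "",
                    "women_only": rs.women_only,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
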