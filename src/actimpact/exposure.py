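"""Survey-weighted exposure-category prevalence.

The prevalence vector over the four activity bands is the P_i of the
impact-fraction model.  Estimates are Horvitz-Thompson style point
estimates: each record contributes its expansion weight, and the share of a
category is the weighted mass in that category over the total weighted
mass.  No design-based variance is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import CATEGORY_LABELS, METProfile, category_index

__all__ = ["ExposureDistribution", "weighted_distribution", "combine_strata"]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ExposureDistribution:
    """Prevalence shares over the four exposure categories for one stratum.

    ``shares`` is ordered low-to-high activity (<600 first) and must sum to
    1; ``population_weight`` is the total survey weight behind the stratum,
    used when combining strata.
    """

    stratum: str
    shares: tuple[float, float, float, float]
    population_weight: float = 1.0

    def __post_init__(self) -> None:
        shares = tuple(float(s) for s in self.shares)
        object.__setattr__(self, "shares", shares)
        if len(shares) != len(CATEGORY_LABELS):
            raise ValueError(
                f"expected {len(CATEGORY_LABELS)} shares, got {len(shares)}"
            )
        if any(s < -_SUM_TOL or s > 1 + _SUM_TOL for s in shares):
            raise ValueError(f"shares must lie in [0, 1], got {shares}")
        if abs(sum(shares) - 1.0) > _SUM_TOL:
            raise ValueError(f"shares must sum to 1, got sum {sum(shares)!r}")
        if self.population_weight <= 0:
            raise ValueError("population_weight must be positive")

    @classmethod
    def from_percentages(
        cls, stratum: str, percentages: Sequence[float], population_weight: float = 1.0
    ) -> "ExposureDistribution":
        """Build from percentage points (e.g. a published prevalence row).

        Printed rows are rounded to one decimal and rarely sum to exactly
        100; the residual is absorbed proportionally so the shares are a
        valid distribution while each stays within rounding distance of its
        printed value.
        """
        arr = np.asarray(percentages, dtype=float)
        if arr.sum() <= 0:
            raise ValueError("percentages must have positive sum")
        shares = arr / arr.sum()
        return cls(stratum=stratum, shares=tuple(shares), population_weight=population_weight)

    def as_series(self) -> pd.Series:
        return pd.Series(self.shares, index=list(CATEGORY_LABELS), name=self.stratum)


def weighted_distribution(
    profiles: Iterable[METProfile], stratum: str = "both"
) -> ExposureDistribution:
    """Weighted category prevalence for a stratum.

    ``stratum`` selects records by sex ("men", "women") or takes everyone
    ("both").  Share of category i = (sum of weights of selected records in
    i) / (sum of weights of selected records).
    """
    if stratum not in ("both", "men", "women"):
        raise ValueError(f"stratum must be 'both', 'men' or 'women', got {stratum!r}")
    tallies = np.zeros(len(CATEGORY_LABELS))
    n_selected = 0
    for p in profiles:
        if stratum != "both" and p.sex != stratum:
            continue
        n_selected += 1
        tallies[category_index(p.category)] += p.weight
    if n_selected == 0:
        raise ValueError(f"no records selected for stratum {stratum!r}")
    total = tallies.sum()
    if total <= 0:
        raise ValueError(f"total survey weight is zero for stratum {stratum!r}")
    return ExposureDistribution(
        stratum=stratum, shares=tuple(tallies / total), population_weight=float(total)
    )


def combine_strata(dists: Sequence[ExposureDistribution], stratum: str = "both") -> ExposureDistribution:
    """Population-weight-weighted mean of stratum distributions.

    Used e.g. to form the both-sex row from per-sex rows after a scenario
    that acts differently on men and women.  Mass is conserved: the output
    shares sum to 1 whenever the inputs do.
    """
    if not dists:
        raise ValueError("need at least one distribution to combine")
    weights = np.array([d.population_weight for d in dists], dtype=float)
    shares = np.array([d.shares for d in dists], dtype=float)
    combined = weights @ shares / weights.sum()
    return ExposureDistribution(
        stratum=stratum, shares=tuple(combined), population_weight=float(weights.sum())
    )


def write_prevalence_csv(
    rows: Iterable[tuple[str, str, ExposureDistribution]], path: str | Path
) -> None:
    """Write (stratum, scenario, distribution) rows as a prevalence table.

    Percentages are rounded to one decimal only here, at the reporting
    layer; all computation upstream keeps full precision.
    """
    data = [
        {
            "stratum": stratum,
            "scenario": scenario,
            **{
                label: round(100 * share, 1)
                for label, share in zip(CATEGORY_LABELS, dist.shares)
            },
        }
        for stratum, scenario, dist in rows
    ]
    pd.DataFrame(data).to_csv(path, index=False)
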