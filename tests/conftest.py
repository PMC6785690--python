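"""Shared fixtures: published prevalence rows, a tiny compendium, and a
brute-force microdata oracle for the impact-fraction formula."""

from __future__ import annotations

import numpy as np
import pytest

from actimpact import Compendium, ExposureDistribution

# Published one-decimal prevalence rows (percent) over the four bands,
# Brazilian adults 18-69, 2013: both sexes, men, women.
BOTH_CURRENT_PCT = (44.6, 41.3, 7.6, 6.5)
MEN_CURRENT_PCT = (40.9, 38.7, 9.7, 10.6)
WOMEN_CURRENT_PCT = (47.9, 43.6, 5.7, 2.7)


@pytest.fixture
def both_current() -> ExposureDistribution:
    return ExposureDistribution.from_percentages("both", BOTH_CURRENT_PCT)


@pytest.fixture
def men_current() -> ExposureDistribution:
    return ExposureDistribution.from_percentages("men", MEN_CURRENT_PCT)


@pytest.fixture
def women_current() -> ExposureDistribution:
    return ExposureDistribution.from_percentages("women", WOMEN_CURRENT_PCT)


@pytest.fixture
def tiny_compendium() -> Compendium:
    return Compendium(
        activity_mets={"walking": 3.5, "running": 9.8, "soccer": 7.0},
        domain_mets={
            "recreation": 4.0,
            "occupation": 3.5,
            "commuting": 4.0,
            "household": 3.0,
        },
    )


def pif_microdata_oracle(p, q, rr, n: int = 1_000_000) -> float:
    """Independent check of the impact-fraction formula by enumeration.

    Instantiates ``n`` pseudo-individuals per distribution (category counts
    proportional to the shares), assigns each its category relative risk,
    and forms the ratio of mean-risk differences.  Shares the definition,
    not the code path, with the closed-form implementation.
    """
    rr = np.asarray(rr, dtype=float)
    counts_p = np.round(np.asarray(p, dtype=float) * n).astype(int)
    counts_q = np.round(np.asarray(q, dtype=float) * n).astype(int)
    mean_p = np.repeat(rr, counts_p).mean()
    mean_q = np.repeat(rr, counts_q).mean()
    return (mean_p - mean_q) / mean_p
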