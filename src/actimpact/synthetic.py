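"""Synthetic survey microdata with known ground truth.

Emulates the structure of a national health-survey activity questionnaire
(one row per respondent: sex, age, survey weight, and per-domain weekly
frequency, session duration and recreational activity type) with
controllable exposure-category marginals, so the whole scoring →
prevalence → scenario → impact pipeline can be exercised and validated
without any external download.

Generation works top-down: a category is sampled per the per-sex target
shares, a total MET-min/week is drawn uniformly within the category's
bounds (the open top band is capped at 16 000 for sampling — downstream
computations only ever use the category, so any finite cap serves), the
total is split across the four domains by the per-category domain mix, and
frequency x duration is back-solved from each domain's MET value.  Scoring
the generated diary therefore lands the respondent exactly in the sampled
category, which is what makes parameter recovery a meaningful test.

Default targets and domain mixes reflect a 2013 Brazilian adult survey:
women are the slight majority (53%), insufficient activity (<600
MET-min/week) sits near 41% in men and 48% in women, and the share at or
above 8000 MET-min/week — dominated by occupational activity — is about
four-fold higher in men.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import OUTCOMES, DeathTable
from .datasets import load_brazil_2015_deaths, load_default_compendium
from .impact import RRSet
from .scoring import CATEGORY_BOUNDS, CATEGORY_LABELS, DOMAINS, Compendium, DiaryRecord, DomainEntry

__all__ = [
    "GeneratorSpec",
    "DEFAULT_SEX_SHARES",
    "DEFAULT_CATEGORY_TARGETS",
    "DEFAULT_DOMAIN_MIX",
    "generate_survey",
    "generate_rr_table",
    "generate_death_table",
    "write_survey_csv",
]

#: Upper sampling bound for the open >=8000 band (MET-min/week).
TOP_CATEGORY_CAP = 16_000.0

_TOL = 1e-9


def _normalized(row: Sequence[float]) -> tuple[float, ...]:
    arr = np.asarray(row, dtype=float)
    return tuple(arr / arr.sum())


#: Population sex split (women the slight majority, as in the emulated survey).
DEFAULT_SEX_SHARES: dict[str, float] = {"men": 0.47, "women": 0.53}

#: Per-sex target shares over the four bands (printed one-decimal rows, normalised).
DEFAULT_CATEGORY_TARGETS: dict[str, tuple[float, ...]] = {
    "men": _normalized((40.9, 38.7, 9.7, 10.6)),
    "women": _normalized((47.9, 43.6, 5.7, 2.7)),
}

#: Mean share of total MET by domain (recreation, occupation, commuting,
#: household) within each band; occupational activity dominates the top band.
DEFAULT_DOMAIN_MIX: dict[str, tuple[float, ...]] = {
    "<600": _normalized((30, 4, 88, 10)),
    "600-3999": _normalized((612, 224, 536, 295)),
    "4000-7999": _normalized((1131, 2667, 1059, 747)),
    ">=8000": _normalized((937, 9182, 1049, 837)),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic survey.

    ``seed`` is mandatory: reproducibility is a contract, not an option.
    ``category_targets`` maps each sex to its target shares over the four
    bands; ``weight_mode`` is "constant" (all weights 1.0) or "gamma"
    (unit-mean gamma weights, to exercise the weighted-prevalence path).
    """

    n_respondents: int
    seed: int
    sex_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_SHARES)
    )
    category_targets: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_TARGETS)
    )
    domain_mix: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_MIX)
    )
    weight_mode: str = "constant"
    gamma_shape: float = 4.0

    def __post_init__(self) -> None:
        if not isinstance(self.n_respondents, (int, np.integer)) or self.n_respondents <= 0:
            raise ValueError(f"n_respondents must be a positive integer, got {self.n_respondents!r}")
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is required and must be an integer")
        if abs(sum(self.sex_shares.values()) - 1.0) > _TOL:
            raise ValueError(f"sex_shares must sum to 1, got {dict(self.sex_shares)}")
        if set(self.sex_shares) - {"men", "women"}:
            raise ValueError("sex_shares keys must be 'men' and/or 'women'")
        for sex, row in self.category_targets.items():
            if len(row) != len(CATEGORY_LABELS):
                raise ValueError(f"category_targets[{sex!r}] must have {len(CATEGORY_LABELS)} entries")
            if abs(sum(row) - 1.0) > _TOL:
                raise ValueError(f"category_targets[{sex!r}] must sum to 1, got {tuple(row)}")
        for sex in self.sex_shares:
            if self.sex_shares[sex] > 0 and sex not in self.category_targets:
                raise ValueError(f"no category_targets for sex {sex!r}")
        for cat, row in self.domain_mix.items():
            if cat not in CATEGORY_LABELS:
                raise ValueError(f"domain_mix key {cat!r} is not a category label")
            if abs(sum(row) - 1.0) > _TOL:
                raise ValueError(f"domain_mix[{cat!r}] must sum to 1")
        if self.weight_mode not in ("constant", "gamma"):
            raise ValueError(f"weight_mode must be 'constant' or 'gamma', got {self.weight_mode!r}")

    @classmethod
    def with_single_target(
        cls, n_respondents: int, seed: int, targets: Sequence[float], **kwargs
    ) -> "GeneratorSpec":
        """Same category targets for both sexes (an all-population marginal)."""
        return cls(
            n_respondents=n_respondents,
            seed=seed,
            category_targets={"men": tuple(targets), "women": tuple(targets)},
            **kwargs,
        )


def generate_survey(
    spec: GeneratorSpec, compendium: Compendium | None = None
) -> list[DiaryRecord]:
    """Generate diary records whose scored categories match the sampled targets.

    Deterministic for a fixed seed.  Ages are uniform on 18-69; weights are
    1.0 (or unit-mean gamma in "gamma" mode).  For each respondent the
    recreational activity type is drawn from the compendium, frequencies are
    uniform on 1-7 days, and durations are back-solved so that
    frequency x duration x MET reproduces the domain's assigned
    MET-min/week exactly.
    """
    if compendium is None:
        compendium = load_default_compendium()
    rng = np.random.default_rng(spec.seed)

    sexes = list(spec.sex_shares)
    sex_probs = np.array([spec.sex_shares[s] for s in sexes])
    activity_codes = sorted(compendium.activity_mets)

    # vectorised draws up front; back-solving is per record
    sex_idx = rng.choice(len(sexes), size=spec.n_respondents, p=sex_probs)
    ages = rng.uniform(18, 69, size=spec.n_respondents)
    if spec.weight_mode == "gamma":
        weights = rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_shape, size=spec.n_respondents)
    else:
        weights = np.ones(spec.n_respondents)

    records: list[DiaryRecord] = []
    lo = np.array(CATEGORY_BOUNDS[:-1])
    hi = np.array(CATEGORY_BOUNDS[1:-1] + (TOP_CATEGORY_CAP,))
    for i in range(spec.n_respondents):
        sex = sexes[sex_idx[i]]
        targets = np.asarray(spec.category_targets[sex], dtype=float)
        cat = rng.choice(len(CATEGORY_LABELS), p=targets / targets.sum())
        # keep clear of band edges so float round-trip cannot flip the category
        total = rng.uniform(lo[cat] + 1e-3, hi[cat] - 1e-3)
        mix = np.asarray(spec.domain_mix[CATEGORY_LABELS[cat]], dtype=float)
        entries: dict[str, DomainEntry] = {}
        rec_code = activity_codes[rng.integers(len(activity_codes))] if activity_codes else None
        for d, domain in enumerate(DOMAINS):
            met_min = total * mix[d]
            if met_min <= 0:
                entries[domain] = DomainEntry(frequency=0, duration=0.0)
                continue
            code = rec_code if domain == "recreation" else None
            met = compendium.met_for(domain, code)
            freq = int(rng.integers(1, 8))
            entries[domain] = DomainEntry(
                frequency=freq, duration=met_min / (freq * met), activity_code=code
            )
        records.append(
            DiaryRecord(
                id=f"r{i:06d}",
                sex=sex,
                age=float(ages[i]),
                weight=float(weights[i]),
                entries=entries,
            )
        )
    return records


def generate_rr_table(
    outcomes: Sequence[str] = OUTCOMES,
    monotone: bool = True,
    seed: int = 0,
    women_only: Sequence[str] = ("breast_cancer",),
) -> dict[str, RRSet]:
    """Random relative-risk tables with the reference band fixed at RR = 1.

    With ``monotone=True`` (the epidemiologically expected shape) RRs are
    non-increasing with activity, built by stacking uniform increments on
    top of the reference.
    """
    if not outcomes:
        raise ValueError("need at least one outcome")
    rng = np.random.default_rng(seed)
    out: dict[str, RRSet] = {}
    for outcome in outcomes:
        if monotone:
            increments = rng.uniform(0.05, 0.35, size=3)
            rr3 = 1.0 + increments[0]
            rr2 = rr3 + increments[1]
            rr1 = rr2 + increments[2]
            rr = (rr1, rr2, rr3, 1.0)
        else:
            vals = rng.uniform(0.8, 2.0, size=3)
            rr = (float(vals[0]), float(vals[1]), float(vals[2]), 1.0)
        out[outcome] = RRSet(outcome=outcome, rr=rr, women_only=outcome in women_only)
    return out


def generate_death_table(seed: int | None = None, mode: str = "fixture") -> DeathTable:
    """Death tables for testing the attribution stage.

    ``fixture`` mode returns the shipped Brazil 2015 premature-death counts
    unchanged (both-sex counts come from the register and need not equal
    men + women because of missing sex information).  ``random`` mode draws
    Poisson counts around the fixture values, deterministic per seed.
    """
    fixture = load_brazil_2015_deaths()
    if mode == "fixture":
        return fixture
    if mode != "random":
        raise ValueError(f"mode must be 'fixture' or 'random', got {mode!r}")
    if seed is None:
        raise ValueError("random mode requires a seed")
    rng = np.random.default_rng(seed)
    deaths = {
        key: (None if v is None else int(rng.poisson(v))) for key, v in fixture.deaths.items()
    }
    denominators = {
        key: max(1, int(rng.poisson(v))) for key, v in fixture.denominators.items()
    }
    return DeathTable(deaths=deaths, denominators=denominators)


def write_survey_csv(records: Sequence[DiaryRecord], path: str | Path) -> None:
    """Write diary records in the CSV dialect that :func:`~actimpact.scoring.read_survey_csv` reads."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id,
            "sex": r.sex,
            "age": r.age,
            "weight": r.weight,
        }
        for domain in DOMAINS:
            entry = r.entries.get(domain, DomainEntry(frequency=0, duration=0.0))
            row[f"{domain}_freq_days"] = entry.frequency
            row[f"{domain}_duration_min"] = entry.duration
            if domain == "recreation":
                row["recreation_activity"] = entry.activity_code or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
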