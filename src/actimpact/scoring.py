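"""Scoring of physical-activity diaries to MET-min/week.

Each respondent reports, for a typical week, the frequency (0--7 days) and
session duration of activity in four domains: recreation, occupation,
commuting and household.  A compendium assigns a MET value (multiple of
resting metabolic rate) to the reported recreational activity type; the
other domains carry one average MET value each.  Domain energy expenditure
is ``frequency x duration x MET`` in MET-min/week, and the total across the
four domains places the respondent in one of four exposure categories:

    <600, 600-3999, 4000-7999, >=8000  MET-min/week

The <600 band is "insufficient physical activity" (roughly <150 min/week of
moderate-to-vigorous activity); >=8000 is the theoretical minimum risk
exposure level used as the reference in the risk model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DOMAINS",
    "CATEGORY_LABELS",
    "CATEGORY_BOUNDS",
    "DomainEntry",
    "DiaryRecord",
    "Compendium",
    "METProfile",
    "categorize",
    "score_record",
    "score_records",
    "domain_restricted_total",
    "read_survey_csv",
    "read_compendium_csv",
]

#: The four activity domains, in canonical order.
DOMAINS: tuple[str, ...] = ("recreation", "occupation", "commuting", "household")

#: Exposure-category labels, lowest activity first.
CATEGORY_LABELS: tuple[str, ...] = ("<600", "600-3999", "4000-7999", ">=8000")

#: Half-open interval edges for the categories: [0,600), [600,4000), [4000,8000), [8000,inf).
CATEGORY_BOUNDS: tuple[float, ...] = (0.0, 600.0, 4000.0, 8000.0, math.inf)


def categorize(total: float) -> str:
    """Assign the exposure category for a total of ``total`` MET-min/week.

    Intervals are half-open on the left: [0,600), [600,4000), [4000,8000),
    [8000,inf), so every non-negative real total maps to exactly one band.

    Raises
    ------
    ValueError
        If ``total`` is negative or not finite... NaN totals are always a
        data error upstream, never a category.
    """
    if math.isnan(total) or total < 0:
        raise ValueError(f"total MET-min/week must be >= 0, got {total!r}")
    for label, hi in zip(CATEGORY_LABELS, CATEGORY_BOUNDS[1:]):
        if total < hi:
            return label
    return CATEGORY_LABELS[-1]


def category_index(label: str) -> int:
    """Position of a category label in the canonical low-to-high order."""
    try:
        return CATEGORY_LABELS.index(label)
    except ValueError:
        raise ValueError(
            f"unknown category {label!r}; expected one of {CATEGORY_LABELS}"
        ) from None


@dataclass(frozen=True)
class DomainEntry:
    """One domain's diary entry: days/week, minutes/session, optional activity code."""

    frequency: float  # days per week, 0-7
    duration: float  # minutes per session
    activity_code: str | None = None  # recreation only

    def __post_init__(self) -> None:
        if not 0 <= self.frequency <= 7:
            raise ValueError(f"frequency must be in [0, 7], got {self.frequency}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class DiaryRecord:
    """A single respondent's activity diary row.

    ``weight`` is the survey expansion weight (1.0 for an unweighted or
    self-weighting design).  ``entries`` maps each of the four domains to a
    :class:`DomainEntry`; missing domains count as zero activity.
    """

    id: str
    sex: str  # "men" | "women"
    age: float
    weight: float = 1.0
    entries: Mapping[str, DomainEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("men", "women"):
            raise ValueError(f"sex must be 'men' or 'women', got {self.sex!r}")
        if self.weight < 0:
            raise ValueError(f"survey weight must be >= 0, got {self.weight}")
        unknown = set(self.entries) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains in diary entries: {sorted(unknown)}")


@dataclass(frozen=True)
class Compendium:
    """MET lookup: activity-code values plus one average MET per non-recreation domain.

    MET values are dimensionless multiples of resting metabolic rate and must
    be positive.  The shipped default (``data/compendium.csv``) carries
    illustrative values and is meant to be replaced by a study-specific table.
    """

    activity_mets: Mapping[str, float]
    domain_mets: Mapping[str, float]

    def __post_init__(self) -> None:
        for code, met in self.activity_mets.items():
            if met <= 0:
                raise ValueError(f"MET for activity {code!r} must be > 0, got {met}")
        for domain, met in self.domain_mets.items():
            if met <= 0:
                raise ValueError(f"MET for domain {domain!r} must be > 0, got {met}")

    def met_for(self, domain: str, activity_code: str | None) -> float:
        """Resolve the MET value for a domain entry.

        A recreational activity code takes precedence; otherwise the
        domain-average MET applies.  An unresolvable code with no domain
        default is an explicit error naming the code.
        """
        if activity_code is not None:
            if activity_code in self.activity_mets:
                return self.activity_mets[activity_code]
            if domain not in self.domain_mets:
                raise KeyError(
                    f"activity code {activity_code!r} not in compendium and no "
                    f"default MET for domain {domain!r}"
                )
            return self.domain_mets[domain]
        if domain not in self.domain_mets:
            raise KeyError(f"no default MET for domain {domain!r}")
        return self.domain_mets[domain]


@dataclass(frozen=True)
class METProfile:
    """Scored diary: per-domain and total MET-min/week plus exposure category."""

    id: str
    sex: str
    weight: float
    domain_met: Mapping[str, float]
    total: float
    category: str


def score_record(record: DiaryRecord, compendium: Compendium) -> METProfile:
    """Score one diary record to a :class:`METProfile`.

    Domain MET-min/week = frequency (days/week) x duration (min/session) x
    MET; the total is the sum over the four domains and determines the
    exposure category.
    """
    domain_met: dict[str, float] = {}
    for domain in DOMAINS:
        entry = record.entries.get(domain)
        if entry is None:
            domain_met[domain] = 0.0
            continue
        met = compendium.met_for(domain, entry.activity_code)
        domain_met[domain] = entry.frequency * entry.duration * met
    total = sum(domain_met.values())
    return METProfile(
        id=record.id,
        sex=record.sex,
        weight=record.weight,
        domain_met=domain_met,
        total=total,
        category=categorize(total),
    )


def score_records(
    records: Iterable[DiaryRecord], compendium: Compendium
) -> list[METProfile]:
    """Score a collection of diary records."""
    return [score_record(r, compendium) for r in records]


def domain_restricted_total(
    profile: METProfile, domains: Sequence[str] | set[str]
) -> METProfile:
    """Recompute total and category from a subset of domains.

    Used for the sensitivity rerun restricted to recreational and commuting
    activity; unselected domains contribute zero.  Restricting to all four
    domains is the identity.
    """
    selected = set(domains)
    if not selected:
        raise ValueError("domain subset must be non-empty")
    unknown = selected - set(DOMAINS)
    if unknown:
        raise ValueError(f"unknown domains: {sorted(unknown)}")
    new_domain_met = {
        d: (profile.domain_met.get(d, 0.0) if d in selected else 0.0) for d in DOMAINS
    }
    total = sum(new_domain_met.values())
    return replace(
        profile, domain_met=new_domain_met, total=total, category=categorize(total)
    )


# ---------------------------------------------------------------------------
# CSV ingest
# ---------------------------------------------------------------------------

_SURVEY_BASE_COLUMNS = ("id", "sex", "age", "weight")


def read_survey_csv(path: str | Path) -> list[DiaryRecord]:
    """Read a survey microdata CSV into diary records.

    Expected columns: ``id, sex, age, weight`` then per domain
    ``<domain>_freq_days`` and ``<domain>_duration_min``, plus
    ``recreation_activity`` (the recreational activity code; empty for
    respondents with no recreational activity).  Schema violations raise
    with the file, row and column named.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _SURVEY_BASE_COLUMNS if c not in df.columns]
    for domain in DOMAINS:
        for suffix in ("freq_days", "duration_min"):
            col = f"{domain}_{suffix}"
            if col not in df.columns:
                missing.append(col)
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    records: list[DiaryRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        entries: dict[str, DomainEntry] = {}
        for domain in DOMAINS:
            freq = getattr(row, f"{domain}_freq_days")
            dur = getattr(row, f"{domain}_duration_min")
            code = None
            if domain == "recreation" and "recreation_activity" in df.columns:
                raw = getattr(row, "recreation_activity")
                if isinstance(raw, str) and raw:
                    code = raw
            try:
                entries[domain] = DomainEntry(
                    frequency=float(freq), duration=float(dur), activity_code=code
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {i}, domain {domain!r}: {exc}"
                ) from exc
        try:
            records.append(
                DiaryRecord(
                    id=str(row.id),
                    sex=str(row.sex),
                    age=float(row.age),
                    weight=float(row.weight),
                    entries=entries,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def read_compendium_csv(path: str | Path) -> Compendium:
    """Read a compendium CSV with columns ``kind, key, met``.

    ``kind`` is ``activity`` (recreational activity code) or ``domain``
    (average MET for a whole domain).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("kind", "key", "met"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    activity: dict[str, float] = {}
    domain: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.kind == "activity":
            activity[str(row.key)] = float(row.met)
        elif row.kind == "domain":
            domain[str(row.key)] = float(row.met)
        else:
            raise ValueError(
                f"{path}: row {i}, column 'kind': expected 'activity' or "
                f"'domain', got {row.kind!r}"
            )
    return Compendium(activity_mets=activity, domain_mets=domain)
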