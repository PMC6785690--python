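"""Counterfactual redistribution of the exposure distribution.

Four scenarios turn the current prevalence vector P into the counterfactual
P' of the impact-fraction model:

* ``tmrel`` — everyone reaches the theoretical minimum risk exposure level
  (>=8000 MET-min/week); the impact fraction under this scenario is the
  population attributable fraction.
* ``recommendation`` — everyone reaches at least 600 MET-min/week: the
  entire <600 share moves into the 600-3999 band.
* ``relative_reduction`` — the prevalence of insufficient activity (<600)
  shrinks by a given fraction (default 10%, the WHO 25x25 target); the
  freed mass moves into 600-3999.
* ``reference_stratum`` — gender equality: the target stratum (women)
  adopts the reference stratum's (men's) distribution; the reference
  stratum itself is unchanged.

Freed mass always lands in the 600-3999 band, the minimal shift consistent
with "reaches at least 600": people just past the recommendation threshold,
not redistributed proportionally upward.  Every scenario conserves
probability mass and never moves mass downward (the cumulative share below
any category boundary never increases).

Scenarios operate on distributions, not on microdata.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exposure import ExposureDistribution

__all__ = [
    "SCENARIO_KINDS",
    "ScenarioSpec",
    "apply_tmrel",
    "apply_recommendation",
    "apply_relative_reduction",
    "apply_reference_stratum",
    "apply_scenario",
]

SCENARIO_KINDS: tuple[str, ...] = (
    "tmrel",
    "recommendation",
    "relative_reduction",
    "reference_stratum",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named scenario with its parameters.

    ``reduction_fraction`` applies to ``relative_reduction`` only (default
    0.10); ``reference`` names the reference stratum for
    ``reference_stratum`` (default "men").
    """

    kind: str
    reduction_fraction: float = 0.10
    reference: str = "men"

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}"
            )
        if not 0.0 <= self.reduction_fraction <= 1.0:
            raise ValueError(
                f"reduction_fraction must be in [0, 1], got {self.reduction_fraction}"
            )


def apply_tmrel(dist: ExposureDistribution) -> ExposureDistribution:
    """Move everyone to the >=8000 MET-min/week reference category."""
    return ExposureDistribution(
        stratum=dist.stratum,
        shares=(0.0, 0.0, 0.0, 1.0),
        population_weight=dist.population_weight,
    )


def apply_recommendation(dist: ExposureDistribution) -> ExposureDistribution:
    """Everyone reaches at least 600 MET-min/week.

    The <600 share is moved entirely into 600-3999; the upper two
    categories are unchanged.
    """
    p = dist.shares
    return ExposureDistribution(
        stratum=dist.stratum,
        shares=(0.0, p[0] + p[1], p[2], p[3]),
        population_weight=dist.population_weight,
    )


def apply_relative_reduction(
    dist: ExposureDistribution, fraction: float = 0.10
) -> ExposureDistribution:
    """Shrink the insufficient-activity (<600) prevalence by ``fraction``.

    The new <600 share is (1 - fraction) x the old share; the freed mass is
    added to 600-3999.  ``fraction=0`` is the identity and ``fraction=1``
    coincides with :func:`apply_recommendation`.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    p = dist.shares
    moved = fraction * p[0]
    return ExposureDistribution(
        stratum=dist.stratum,
        shares=(p[0] - moved, p[1] + moved, p[2], p[3]),
        population_weight=dist.population_weight,
    )


def apply_reference_stratum(
    target: ExposureDistribution, reference: ExposureDistribution
) -> ExposureDistribution:
    """Give the target stratum the reference stratum's distribution.

    Gender-equality scenario: women adopt the men's distribution; applying
    it to the reference stratum itself is the identity, so the reference
    stratum's impact fraction is structurally zero.  Stratum label and
    population weight stay the target's.
    """
    return ExposureDistribution(
        stratum=target.stratum,
        shares=reference.shares,
        population_weight=target.population_weight,
    )


def apply_scenario(
    spec: ScenarioSpec,
    dist: ExposureDistribution,
    reference: ExposureDistribution | None = None,
) -> ExposureDistribution:
    """Dispatch a :class:`ScenarioSpec` onto a distribution.

    ``reference`` is required for the ``reference_stratum`` kind.
    """
    if spec.kind == "tmrel":
        return apply_tmrel(dist)
    if spec.kind == "recommendation":
        return apply_recommendation(dist)
    if spec.kind == "relative_reduction":
        return apply_relative_reduction(dist, spec.reduction_fraction)
    if spec.kind == "reference_stratum":
        if reference is None:
            raise ValueError("reference distribution required for reference_stratum")
        return apply_reference_stratum(dist, reference)
    raise AssertionError(f"unreachable: {spec.kind}")
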