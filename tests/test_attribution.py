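"""Attribution arithmetic: cell rounding, aggregation, NA handling."""

import math

import pandas as pd
import pytest

from actimpact import (
    ImpactResult,
    aggregate_shares,
    build_report,
    load_brazil_2015_deaths,
    preventable_deaths,
)
from actimpact.attribution import DeathTable, OUTCOMES, STRATA, read_deaths_csv, write_deaths_csv


class TestPreventableDeaths:
    @pytest.mark.parametrize(
        "pif,deaths,expected",
        [
            (0.1179, 10_480, 1_236),  # published breast-cancer women cell
            (0.1684, 17_048, 2_871),  # published IHD women cell
            (0.1618, 2_624, 425),  # published colon-cancer men cell
            (0.0, 123_456, 0),
        ],
    )
    def test_round_half_away_from_zero(self, pif, deaths, expected):
        assert preventable_deaths(pif, deaths) == expected

    def test_tie_rounds_away_from_zero(self):
        assert preventable_deaths(0.5, 1) == 1
        assert preventable_deaths(-0.5, 1) == -1

    def test_negative_deaths_rejected(self):
        with pytest.raises(ValueError):
            preventable_deaths(0.1, -5)

    def test_pif_above_one_rejected(self):
        with pytest.raises(ValueError):
            preventable_deaths(1.2, 100)

    def test_never_exceeds_cell_deaths(self):
        assert preventable_deaths(1.0, 321) == 321


class TestAggregateShares:
    def test_published_tmrel_aggregates(self):
        # five-outcome cells 1236+908+4548+8038+1984 = 16714; shares of the
        # major-NCD and all-cause denominators print as 5.75% and 3.23%
        total, major, all_cause = aggregate_shares(
            (1_236, 908, 4_548, 8_038, 1_984), (290_874, 517_134)
        )
        assert total == 16_714
        assert round(major, 2) == 5.75
        assert round(all_cause, 2) == 3.23

    def test_published_gender_equality_aggregates(self):
        total, major, _ = aggregate_shares((124, 58, 299, 375, 102), (290_874, 517_134))
        assert total == 958
        assert round(major, 2) == 0.33

    def test_all_zero_counts(self):
        total, major, all_cause = aggregate_shares((0, 0, 0, 0, 0), (1000, 2000))
        assert (total, major, all_cause) == (0, 0.0, 0.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            aggregate_shares((1, 2), (0, 100))


def impacts_for(pifs: dict, scenario: str = "tmrel") -> list[ImpactResult]:
    """Build ImpactResults from a {(outcome, stratum): pif} mapping;
    None marks the structurally-NA women-only cells in men."""
    out = []
    for (outcome, stratum), pif in pifs.items():
        if pif is None:
            out.append(ImpactResult.not_applicable(scenario, outcome, stratum))
        else:
            out.append(
                ImpactResult(
                    scenario=scenario, outcome=outcome, stratum=stratum, pif=pif,
                    is_paf=scenario == "tmrel",
                )
            )
    return out


# Published impact fractions (percent) for the exposure-elimination scenario.
TMREL_PIF_PCT = {
    ("breast_cancer", "men"): None,
    ("breast_cancer", "women"): 11.79,
    ("colon_cancer", "both"): 17.14,
    ("colon_cancer", "men"): 16.18,
    ("colon_cancer", "women"): 17.99,
    ("diabetes", "both"): 20.22,
    ("diabetes", "men"): 19.04,
    ("diabetes", "women"): 21.26,
    ("ihd", "both"): 15.96,
    ("ihd", "men"): 14.97,
    ("ihd", "women"): 16.84,
    ("stroke", "both"): 17.00,
    ("stroke", "men"): 16.07,
    ("stroke", "women"): 17.82,
}


class TestBuildReport:
    def _report(self):
        impacts = impacts_for(
            {k: (None if v is None else v / 100) for k, v in TMREL_PIF_PCT.items()}
        )
        return build_report(impacts, load_brazil_2015_deaths())

    def test_breast_cancer_men_and_both_are_na_not_zero(self):
        report = self._report()
        for stratum in ("men", "both"):
            cell = report.cells[
                (report.cells.outcome == "breast_cancer")
                & (report.cells.stratum == stratum)
            ].iloc[0]
            assert math.isnan(cell["pif_pct"])
            assert math.isnan(cell["preventable"])

    def test_womens_breast_count_enters_both_sex_total(self):
        report = self._report()
        both_total = report.summary[
            (report.summary.scenario == "tmrel") & (report.summary.stratum == "both")
        ].iloc[0]["total_preventable"]
        # both-sex cells from published PIFs: colon 911, diabetes 4573,
        # ihd 8230, stroke 2009 (recomputed at 2-dp PIF precision), plus
        # the women's breast-cancer 1236
        cells = report.cells
        non_breast = cells[
            (cells.stratum == "both") & (cells.outcome != "breast_cancer")
        ]["preventable"].sum()
        assert both_total == non_breast + 1_236

    def test_missing_combination_is_reported(self):
        impacts = impacts_for({("colon_cancer", "both"): 0.1714})
        with pytest.raises(ValueError, match="missing"):
            build_report(impacts, load_brazil_2015_deaths())

    def test_gender_equality_reference_stratum_prevents_nothing(self):
        pifs = {}
        for outcome in OUTCOMES:
            for stratum in STRATA:
                if outcome == "breast_cancer" and stratum in ("men", "both"):
                    pifs[(outcome, stratum)] = None
                elif stratum == "men":
                    pifs[(outcome, stratum)] = 0.0
                else:
                    pifs[(outcome, stratum)] = 0.02
        report = build_report(
            impacts_for(pifs, scenario="gender-equality"), load_brazil_2015_deaths()
        )
        men = report.summary[report.summary.stratum == "men"].iloc[0]
        assert men["total_preventable"] == 0
        men_cells = report.cells[
            (report.cells.stratum == "men") & (report.cells.outcome != "breast_cancer")
        ]
        assert (men_cells["preventable"] == 0).all()

    def test_text_table_renders_na_and_integers(self):
        text = self._report().to_text()
        assert "NA" in text
        assert "1236" in text


class TestDeathTableIO:
    def test_round_trip(self, tmp_path):
        table = load_brazil_2015_deaths()
        path = tmp_path / "deaths.csv"
        write_deaths_csv(table, path)
        back = read_deaths_csv(path)
        assert dict(back.deaths) == dict(table.deaths)
        assert dict(back.denominators) == dict(table.denominators)

    def test_bad_stratum_names_file_row_column(self, tmp_path):
        path = tmp_path / "deaths.csv"
        path.write_text("outcome,stratum,deaths\ncolon_cancer,children,5\n")
        with pytest.raises(ValueError, match=r"row 2.*stratum"):
            read_deaths_csv(path)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            DeathTable(deaths={("colon_cancer", "both"): -1}, denominators={})
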