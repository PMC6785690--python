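"""Diary scoring: MET-min/week arithmetic, band assignment, domain restriction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actimpact import (
    DiaryRecord,
    DomainEntry,
    categorize,
    domain_restricted_total,
    score_record,
)
from actimpact.scoring import CATEGORY_LABELS, Compendium, read_survey_csv


def make_record(entries, sex="men", weight=1.0):
    return DiaryRecord(id="x", sex=sex, age=40, weight=weight, entries=entries)


class TestCategorize:
    @pytest.mark.parametrize(
        "total,expected",
        [
            (0.0, "<600"),
            (599.9, "<600"),
            (600.0, "600-3999"),  # lower bound inclusive
            (3999.99, "600-3999"),
            (4000.0, "4000-7999"),
            (7999.5, "4000-7999"),
            (8000.0, ">=8000"),  # reference band includes its lower bound
            (50_000.0, ">=8000"),
        ],
    )
    def test_half_open_bands(self, total, expected):
        assert categorize(total) == expected

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            categorize(-1.0)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_total_function_on_nonnegative_reals(self, total):
        assert categorize(total) in CATEGORY_LABELS


class TestScoreRecord:
    def test_recreation_session_arithmetic(self, tiny_compendium):
        rec = make_record(
            {"recreation": DomainEntry(frequency=3, duration=60, activity_code="recreation_generic")}
        )
        comp = Compendium(activity_mets={"recreation_generic": 4.0}, domain_mets={})
        profile = score_record(rec, comp)
        assert profile.total == pytest.approx(720.0)  # 3 days x 60 min x MET 4
        assert profile.category == "600-3999"

    def test_all_zero_entries_is_inactive(self, tiny_compendium):
        profile = score_record(make_record({}), tiny_compendium)
        assert profile.total == 0.0
        assert profile.category == "<600"

    def test_heavy_occupation_reaches_reference_band(self, tiny_compendium):
        comp = Compendium(activity_mets={}, domain_mets={"occupation": 10.0})
        rec = make_record({"occupation": DomainEntry(frequency=7, duration=120)})
        profile = score_record(rec, comp)
        assert profile.total == pytest.approx(8400.0)  # 7 x 120 x 10
        assert profile.category == ">=8000"

    def test_unknown_activity_code_without_default_names_code(self):
        comp = Compendium(activity_mets={}, domain_mets={"occupation": 3.5})
        rec = make_record(
            {"recreation": DomainEntry(frequency=1, duration=30, activity_code="zumba")}
        )
        with pytest.raises(KeyError, match="zumba"):
            score_record(rec, comp)

    def test_total_is_sum_of_domains(self, tiny_compendium):
        rec = make_record(
            {
                "recreation": DomainEntry(frequency=2, duration=30, activity_code="walking"),
                "occupation": DomainEntry(frequency=5, duration=60),
                "commuting": DomainEntry(frequency=5, duration=20),
                "household": DomainEntry(frequency=3, duration=45),
            }
        )
        profile = score_record(rec, tiny_compendium)
        assert profile.total == pytest.approx(sum(profile.domain_met.values()))

    @given(
        freq=st.integers(min_value=0, max_value=6),
        dur=st.floats(min_value=0, max_value=300, allow_nan=False),
        bump_freq=st.booleans(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_more_activity_never_lowers_total_or_band(self, freq, dur, bump_freq):
        tiny_compendium = Compendium(activity_mets={}, domain_mets={"commuting": 4.0})
        base = make_record({"commuting": DomainEntry(frequency=freq, duration=dur)})
        more = make_record(
            {
                "commuting": DomainEntry(
                    frequency=freq + (1 if bump_freq else 0),
                    duration=dur + (0 if bump_freq else 30),
                )
            }
        )
        p0, p1 = score_record(base, tiny_compendium), score_record(more, tiny_compendium)
        assert p1.total >= p0.total
        assert CATEGORY_LABELS.index(p1.category) >= CATEGORY_LABELS.index(p0.category)


class TestDomainRestriction:
    def _profile(self, tiny_compendium):
        rec = make_record(
            {
                "recreation": DomainEntry(frequency=5, duration=25, activity_code="walking"),
                "commuting": DomainEntry(frequency=5, duration=10),
                "occupation": DomainEntry(frequency=5, duration=300),
            }
        )
        return score_record(rec, tiny_compendium)

    def test_restriction_drops_unselected_domains(self, tiny_compendium):
        profile = self._profile(tiny_compendium)
        restricted = domain_restricted_total(profile, {"recreation", "commuting"})
        assert restricted.total == pytest.approx(
            profile.domain_met["recreation"] + profile.domain_met["commuting"]
        )
        assert restricted.domain_met["occupation"] == 0.0

    def test_all_domains_is_identity(self, tiny_compendium):
        profile = self._profile(tiny_compendium)
        same = domain_restricted_total(
            profile, {"recreation", "occupation", "commuting", "household"}
        )
        assert same.total == pytest.approx(profile.total)
        assert same.category == profile.category

    def test_occupation_only_worker_becomes_inactive(self, tiny_compendium):
        rec = make_record({"occupation": DomainEntry(frequency=6, duration=240)})
        profile = score_record(rec, tiny_compendium)
        restricted = domain_restricted_total(profile, {"recreation", "commuting"})
        assert restricted.total == 0.0
        assert restricted.category == "<600"

    def test_empty_subset_rejected(self, tiny_compendium):
        with pytest.raises(ValueError):
            domain_restricted_total(self._profile(tiny_compendium), set())


class TestValidation:
    def test_frequency_above_seven_rejected(self):
        with pytest.raises(ValueError):
            DomainEntry(frequency=8, duration=30)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            DomainEntry(frequency=3, duration=-5)

    def test_survey_reader_names_file_and_row_on_bad_value(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,sex,age,weight,recreation_freq_days,recreation_duration_min,"
            "recreation_activity,occupation_freq_days,occupation_duration_min,"
            "commuting_freq_days,commuting_duration_min,household_freq_days,"
            "household_duration_min\n"
            "a,men,40,1.0,9,30,,0,0,0,0,0,0\n"
        )
        with pytest.raises(ValueError, match=r"bad\.csv.*row 2"):
            read_survey_csv(path)

    def test_survey_reader_reports_missing_columns(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("id,sex\n1,men\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_survey_csv(path)
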