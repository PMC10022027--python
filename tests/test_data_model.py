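"""Record validation and CSV round-trip behaviour."""

import string

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from sitecap import (
    AGE_BANDS,
    INFO_SOURCES,
    CapacityParams,
    DatasetValidationError,
    DuplicateRecordError,
    MonthlyRecord,
    SchemaError,
    read_dataset,
    write_dataset,
)
from sitecap.data_model import monthly_columns, validate_dataset

from conftest import make_profile, make_record


class TestRecordInvariants:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            make_record(beds=-1)

    def test_days_exceeding_month_rejected(self):
        with pytest.raises(ValidationError, match="days_of_operation"):
            make_record(month="2015-02", days_of_operation=29)

    def test_followup_cannot_exceed_performed(self):
        with pytest.raises(ValidationError, match="followup_48h"):
            make_record(performed=10, followup_48h=11)
        assert make_record(performed=10, followup_48h=10).followup_48h == 10

    def test_adverse_events_cannot_exceed_performed(self):
        with pytest.raises(ValidationError, match="ae_mild"):
            make_record(performed=5, ae_mild=6)

    def test_age_bands_consistent_across_maps(self):
        with pytest.raises(ValidationError, match="age-band keys"):
            make_record(performed=5,
                        reached_by_age={"15-19": 3})

    def test_absent_distinct_from_zero(self):
        r = make_record()
        assert r.performed is None
        assert r.vmmc_by_age is None
        z = make_record(performed=0)
        assert z.performed == 0

    def test_outreach_requires_parent(self):
        with pytest.raises(ValidationError, match="parent_fixed_site"):
            make_profile(mode="outreach", parent=None)
        with pytest.raises(ValidationError, match="parent_fixed_site"):
            make_profile(mode="fixed", parent="Somewhere")

    def test_enums_reject_unknown_values(self):
        for bad in (dict(urban_rural="suburban"), dict(ownership="church"),
                    dict(delivery_mode="van"), dict(pepfar_category="other"),
                    dict(vmmc_category="other")):
            with pytest.raises(ValidationError):
                make_profile(**bad)

    def test_month_format(self):
        with pytest.raises(ValidationError):
            make_record(month="2015-13")
        with pytest.raises(ValidationError):
            make_record(month="Jan 2015")


class TestDatasetInvariants:
    def test_duplicate_site_month_rejected(self):
        p = [make_profile("Site X")]
        r = [make_record(), make_record()]
        with pytest.raises(DuplicateRecordError, match="duplicate"):
            validate_dataset(p, r)

    def test_duplicate_site_name_rejected(self):
        with pytest.raises(DuplicateRecordError):
            validate_dataset([make_profile("A"), make_profile("A")], [])

    def test_parent_must_resolve_to_fixed_site(self):
        mobile = make_profile("M1", mode="mobile")
        orphan = make_profile("O1", mode="outreach", parent="Nowhere")
        with pytest.raises(DatasetValidationError, match="does not exist"):
            validate_dataset([orphan], [])
        bad_parent = make_profile("O2", mode="outreach", parent="M1")
        with pytest.raises(DatasetValidationError, match="not a .*fixed"):
            validate_dataset([mobile, bad_parent], [])

    def test_record_must_reference_profile(self):
        with pytest.raises(DatasetValidationError, match="no profile"):
            validate_dataset([make_profile("A")],
                             [make_record(site="B")])


class TestCsvRoundTrip:
    def test_tiny_dataset_round_trips(self, tiny_dataset, tmp_path):
        profiles, records = tiny_dataset
        write_dataset(profiles, records, tmp_path)
        p2, r2 = read_dataset(tmp_path)
        assert p2 == profiles
        assert r2 == records
        assert len(p2) == 2 and len(r2) == 6

    def test_synthetic_dataset_round_trips(self, synth_small, tmp_path):
        profiles, records = synth_small
        write_dataset(profiles, records, tmp_path)
        p2, r2 = read_dataset(tmp_path)
        assert p2 == profiles
        assert r2 == records

    def test_empty_dataset_writes_headers_only(self, tmp_path):
        write_dataset([], [], tmp_path)
        sites = (tmp_path / "sites.csv").read_text().strip().splitlines()
        monthly = (tmp_path / "monthly.csv").read_text().strip().splitlines()
        assert len(sites) == 1 and len(monthly) == 1
        p, r = read_dataset(tmp_path)
        assert p == [] and r == []

    def test_zero_counts_written_as_zeros_not_blanks(self, tmp_path):
        profiles = [make_profile()]
        records = [make_record(performed=0, followup_48h=0, ae_severe=0)]
        write_dataset(profiles, records, tmp_path)
        df = pd.read_csv(tmp_path / "monthly.csv", dtype=str,
                         keep_default_na=False)
        assert df.loc[0, "followup_48h"] == "0"
        assert df.loc[0, "ae_severe"] == "0"
        assert df.loc[0, f"vmmc_{AGE_BANDS[0]}"] == "0"
        # absent optionals stay blank, not zero
        assert df.loc[0, "hiv_tests"] == ""
        p2, r2 = read_dataset(tmp_path)
        assert r2[0].followup_48h == 0
        assert r2[0].hiv_tests is None


class TestCsvErrors:
    def test_missing_column_named_in_schema_error(self, tiny_dataset,
                                                  tmp_path):
        write_dataset(*tiny_dataset, tmp_path)
        df = pd.read_csv(tmp_path / "monthly.csv")
        df.drop(columns=["beds"]).to_csv(tmp_path / "monthly.csv",
                                         index=False)
        with pytest.raises(SchemaError, match="beds"):
            read_dataset(tmp_path)

    def test_extra_column_rejected(self, tiny_dataset, tmp_path):
        write_dataset(*tiny_dataset, tmp_path)
        df = pd.read_csv(tmp_path / "sites.csv")
        df["surprise"] = 1
        df.to_csv(tmp_path / "sites.csv", index=False)
        with pytest.raises(SchemaError, match="surprise"):
            read_dataset(tmp_path)

    def test_negative_bed_count_cites_row(self, tiny_dataset, tmp_path):
        write_dataset(*tiny_dataset, tmp_path)
        df = pd.read_csv(tmp_path / "monthly.csv")
        df.loc[2, "beds"] = -3
        df.to_csv(tmp_path / "monthly.csv", index=False)
        with pytest.raises(DatasetValidationError) as exc:
            read_dataset(tmp_path)
        assert any(row == 3 for row, _ in exc.value.errors)
        assert "beds" in str(exc.value)

    def test_outreach_without_parent_in_csv_rejected(self, tmp_path):
        profiles = [make_profile("F1"),
                    make_profile("O1", mode="outreach", parent="F1")]
        write_dataset(profiles, [], tmp_path)
        df = pd.read_csv(tmp_path / "sites.csv", dtype=str,
                         keep_default_na=False)
        df.loc[1, "parent_fixed_site"] = ""
        df.to_csv(tmp_path / "sites.csv", index=False)
        with pytest.raises(DatasetValidationError, match="parent_fixed_site"):
            read_dataset(tmp_path)

    def test_duplicate_site_month_in_csv_rejected(self, tiny_dataset,
                                                  tmp_path):
        write_dataset(*tiny_dataset, tmp_path)
        df = pd.read_csv(tmp_path / "monthly.csv", dtype=str,
                         keep_default_na=False)
        pd.concat([df, df.iloc[[0]]]).to_csv(tmp_path / "monthly.csv",
                                             index=False)
        with pytest.raises(DuplicateRecordError):
            read_dataset(tmp_path)

    def test_unsupported_schema_version(self, tiny_dataset, tmp_path):
        write_dataset(*tiny_dataset, tmp_path)
        with pytest.raises(SchemaError, match="schema_version"):
            read_dataset(tmp_path, schema_version="99")


class TestCapacityParams:
    def test_slots_derived_from_durations(self):
        p = CapacityParams(minutes_per_procedure=30,
                           operating_minutes_per_day=300)
        assert p.slots_per_station_per_day == 10

    def test_changing_one_recomputes_dependency(self):
        p = CapacityParams()
        assert p.slots_per_station_per_day == 15
        p.minutes_per_procedure = 45
        assert p.slots_per_station_per_day == 10
        p.slots_per_station_per_day = 8
        assert p.operating_minutes_per_day == 8 * 45
        assert p.slots_per_station_per_day == 8

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            CapacityParams(minutes_per_procedure=0)
        with pytest.raises(ValueError):
            CapacityParams(task_shifting_factor=-1)
        with pytest.raises(ValueError):
            CapacityParams(task_sharing_factor=0)


# --- property-based round trip ---------------------------------------------

_names = st.lists(
    st.text(alphabet=string.ascii_uppercase, min_size=1, max_size=6),
    min_size=1, max_size=4, unique=True)
_counts = st.integers(min_value=0, max_value=500)
_opt_counts = st.none() | st.integers(min_value=0, max_value=50)


@st.composite
def _dataset(draw):
    names = draw(_names)
    profiles = [make_profile(n, zone=f"Z{i % 2}",
                             province=f"P{i % 2}")
                for i, n in enumerate(names)]
    months = draw(st.lists(
        st.sampled_from(["2015-01", "2015-02", "2016-11"]),
        min_size=1, max_size=3, unique=True))
    records = []
    for n in names:
        for m in months:
            performed = draw(st.none() | st.integers(0, 300))
            kw = {}
            if performed is not None:
                kw["followup_48h"] = draw(
                    st.none() | st.integers(0, performed))
                kw["ae_mild"] = draw(st.none() | st.integers(0, performed))
                kw["reached_by_age"] = {
                    b: draw(_counts) for b in AGE_BANDS}
                kw["seeking_by_age"] = {
                    b: draw(_counts) for b in AGE_BANDS}
                if draw(st.booleans()):
                    kw["reached_by_source"] = {
                        s: draw(_counts) for s in INFO_SOURCES}
            records.append(make_record(
                site=n, month=m, performed=performed,
                target=draw(_counts), providers=draw(st.integers(0, 9)),
                beds=draw(st.integers(0, 9)),
                days_of_operation=draw(st.integers(0, 28)),
                hiv_tests=draw(_opt_counts), **kw))
    return profiles, records


@settings(max_examples=25, deadline=None, derandomize=True)
@given(_dataset())
def test_round_trip_identity_property(tmp_path_factory, dataset):
    """write -> read recovers every field exactly, absent included."""
    profiles, records = dataset
    path = tmp_path_factory.mktemp("rt")
    write_dataset(profiles, records, path)
    p2, r2 = read_dataset(path)
    assert p2 == profiles
    assert r2 == records
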