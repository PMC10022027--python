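import pytest

from sitecap import (
    AGE_BANDS,
    CapacityParams,
    MonthlyRecord,
    SiteProfile,
    SynthConfig,
    generate,
    worked_example_fixture,
)


def make_profile(name="Site X", province="Province A", zone="Zone 1",
                 mode="fixed", parent=None, **kw):
    defaults = dict(
        site_name=name,
        health_zone=zone,
        province=province,
        urban_rural="urban",
        ownership="public",
        delivery_mode=mode,
        pepfar_category="scale-up aggressive",
        vmmc_category="scale-up",
        opening_date="2014-10-01",
        parent_fixed_site=parent,
    )
    defaults.update(kw)
    return SiteProfile(**defaults)


def make_record(site="Site X", month="2015-01", performed=None, **kw):
    defaults = dict(
        site_name=site,
        month=month,
        target=100,
        providers=1,
        trained_assistants=1,
        other_nurses=1,
        mobilizers=1,
        counselors=1,
        beds=1,
        days_of_operation=20,
    )
    if performed is not None:
        vmmc = {b: 0 for b in AGE_BANDS}
        vmmc[AGE_BANDS[1]] = performed
        defaults["vmmc_by_age"] = vmmc
    defaults.update(kw)
    return MonthlyRecord(**defaults)


@pytest.fixture
def default_params():
    return CapacityParams()


@pytest.fixture
def tiny_dataset():
    """Two sites x three months, all valid."""
    profiles = [make_profile("Site X"), make_profile("Site Y")]
    records = [make_record(site=s, month=m, performed=10)
               for s in ("Site X", "Site Y")
               for m in ("2015-01", "2015-02", "2015-03")]
    return profiles, records


@pytest.fixture(scope="session")
def synth_small():
    """A compact synthetic dataset (12 months, ramp at month 6)."""
    cfg = SynthConfig(months=12, start_month="2016-04",
                      outreach_start_month="2016-10", seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def synth_default():
    """The default study-shaped dataset: 9 fixed sites, 36 months."""
    return generate(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def worked_fixture():
    return worked_example_fixture()
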