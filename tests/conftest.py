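import pytest

from dietpaf.published import published_risk_table
from dietpaf.strata import Factor, Race, Sex
from dietpaf.exposure import DietRecord


@pytest.fixture(scope="session")
def risk_table():
    return published_risk_table()


def make_record(pid, consumption, band="25-34", sex=Sex.men, race=Race.nh_white, weight=1.0):
    """Record with the given red-meat consumption (or a full factor map)."""
    if not isinstance(consumption, dict):
        consumption = {Factor.red_meat: consumption}
    return DietRecord(
        person_id=str(pid), age_band=band, sex=sex, race=race,
        weight=weight, consumption=consumption,
    )


@pytest.fixture()
def four_records():
    """The four-person red-meat example: 10, 50, 80, 120 g/day, unit weights."""
    return [make_record(i, c) for i, c in enumerate([10.0, 50.0, 80.0, 120.0])]
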