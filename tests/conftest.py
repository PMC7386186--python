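import datetime as dt

import pytest

from tbi_autoplan import (
    Prescription,
    build_plan,
    compute_mu,
    generate_fixture,
)


@pytest.fixture(scope="session")
def beam():
    return generate_fixture(seed=7, n_energies=2)


@pytest.fixture()
def rx():
    return Prescription(
        protocol="standard_adult",
        dose_per_field=150.0,
        num_fractions=6,
        separation=36.0,
        max_dose_rate=10.0,
        arrangement="AP/PA",
        patient_id="MRN-0001",
        patient_name="Doe^Jane",
    )


@pytest.fixture()
def calc(beam, rx):
    return compute_mu(beam, rx)


@pytest.fixture()
def plan(rx, calc):
    return build_plan(rx, calc, today=dt.date(2019, 7, 15))
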