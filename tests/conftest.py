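import pytest

from framen400 import (
    fixture_birthday_party,
    fixture_holiday_resort,
    fixture_prescription,
    fixture_seaside_caution,
)


@pytest.fixture(scope="session")
def resort():
    return fixture_holiday_resort()


@pytest.fixture(scope="session")
def birthday():
    return fixture_birthday_party()


@pytest.fixture(scope="session")
def seaside_hc():
    return fixture_seaside_caution("HC")


@pytest.fixture(scope="session")
def seaside_lc():
    return fixture_seaside_caution("LC")


@pytest.fixture(scope="session")
def prescription():
    return fixture_prescription()


@pytest.fixture(scope="session")
def resort_arg(resort):
    return resort.argument_concept()
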