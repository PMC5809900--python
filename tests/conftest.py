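import pytest

from vfscreen import load_parameter_set


@pytest.fixture(scope="session")
def women_base():
    return load_parameter_set(sex="female", scenario="base_case")


@pytest.fixture(scope="session")
def men_base():
    return load_parameter_set(sex="male", scenario="base_case")


@pytest.fixture(scope="session")
def women_subgroup():
    return load_parameter_set(sex="female", scenario="subgroup_old_age")


@pytest.fixture(scope="session")
def men_subgroup():
    return load_parameter_set(sex="male", scenario="subgroup_old_age")
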