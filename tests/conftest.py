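import numpy as np
import pytest

from collamat import charge, kinetics


@pytest.fixture(scope="session")
def base_composition():
    return charge.default_composition()


@pytest.fixture(scope="session")
def deamidated_composition(base_composition):
    return charge.deamidate(base_composition, 0.24)


@pytest.fixture(scope="session")
def ta_fickian_ref():
    return kinetics.reference_fit(
        kinetics.ReferenceCurve(1 / 1440, kinetics.Regime.FICKIAN)
    )


@pytest.fixture(scope="session")
def ta_case2_ref():
    return kinetics.reference_fit(
        kinetics.ReferenceCurve(1 / 1440, kinetics.Regime.CASE2)
    )
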