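import numpy as np
import pytest

import excea


@pytest.fixture(scope="session")
def registry():
    return excea.parse_parameter_table(excea.packaged_parameter_table())


@pytest.fixture(scope="session")
def life_table():
    return excea.generate_life_table()


@pytest.fixture(scope="session")
def utility_table():
    return excea.generate_utility_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230613)


@pytest.fixture(scope="session")
def base_draw(registry):
    return registry.point_estimates()


def zero_risk_draw(age=64.0, utility_flat=None):
    """A hand-built draw with every disease risk and cost switched off."""
    draw = {
        "age": age,
        "p_cvd_baseline": 0.0, "p_recurrence": 0.0,
        "share_stroke": 0.35, "share_chd": 0.31, "share_hf": 0.34,
        "p_fatal_stroke": 0.0, "p_fatal_chd_hf": 0.0,
        "surv5_post_stroke": 1.0, "surv5_post_chd": 1.0, "surv5_post_hf": 1.0,
        "surv5_post_recurrence": 1.0,
        "hr_cvd_exercise": 1.0, "hr_recurrence_exercise": 1.0,
        "du_recurrence": 0.0,
        "u_post_stroke": 1.0, "u_post_chd": 1.0, "u_post_hf": 1.0,
        "du_stroke_event": 0.0, "du_chd_event": 0.0, "du_hf_event": 0.0,
        "c_exercise": 0.0, "c_surveillance": 0.0,
        "c_stroke_treatment": 0.0, "c_chd_treatment": 0.0, "c_hf_treatment": 0.0,
        "c_post_stroke_fu": 0.0, "c_post_chd_fu": 0.0, "c_post_hf_fu": 0.0,
        "c_recurrence_treatment": 0.0, "c_post_cancer_fu": 0.0,
    }
    return draw
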