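import numpy as np
import pytest

from tfaban.inputs import AGES, SEXES, StratumRates
from tfaban.synthetic import SynthConfig, generate_bundle, published_scalars


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic input bundle, shared read-only across tests."""
    return generate_bundle()


@pytest.fixture(scope="session")
def scalars():
    return published_scalars()


@pytest.fixture(scope="session")
def flat_bundle():
    """A bundle with no subgroup gradients: all quintiles and remoteness
    groups share the total population's intake and rates."""
    cfg = SynthConfig(
        quintile_intake_offsets=(0.0,) * 5,
        remoteness_intake_offsets=(0.0,) * 3,
        mortality_ratios={k: 1.0 for k in SynthConfig().mortality_ratios},
        ihd_ratios={k: 1.0 for k in SynthConfig().ihd_ratios},
        subgroup_population_shares={
            k: (0.2 if k.startswith("seifa") else v)
            for k, v in SynthConfig().subgroup_population_shares.items()
        },
    )
    return generate_bundle(cfg)


def make_rates(
    sex="male",
    subgroup="total",
    acm=0.0,
    incidence=0.0,
    prevalence=0.0,
    case_fatality=0.0,
    yld=0.0,
    dw=0.0,
):
    """Constant-rate schedules for analytical life-table checks."""
    const = lambda v: np.full(AGES.size, float(v))  # noqa: E731
    return StratumRates(
        sex=sex, subgroup=subgroup,
        all_cause_mortality=const(acm),
        ihd_incidence=const(incidence),
        ihd_prevalence=const(prevalence),
        ihd_case_fatality=const(case_fatality),
        yld_all_cause=const(yld),
        ihd_disability_weight=float(dw),
    )
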