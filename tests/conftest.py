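import numpy as np
import pytest

from remisim import (
    ConstantHazard,
    CostParams,
    EligibleDwell,
    ModelParameters,
    WeibullParams,
    default_truth,
)


@pytest.fixture
def demo_params() -> ModelParameters:
    """The packaged demonstration parameters (with illustrative SEs)."""
    return default_truth()


@pytest.fixture
def demo_costs() -> CostParams:
    return CostParams()


def make_exponential_params(q1: float, q3: float, q5: float,
                            death: float = 0.0) -> ModelParameters:
    """All-exponential parameters (p = 1) with hourly exit probabilities
    q_k in states 1/3/5, eligible states skipped, death hazard ``death``.

    The Weibull rate reproducing a constant hourly probability q is
    L = -ln(1 - q).
    """
    def expo(q: float) -> WeibullParams:
        return WeibullParams(-np.log1p(-q), 1.0)

    tiny = WeibullParams(1e-12, 1.0)
    return ModelParameters(
        progression={"s1_CS": expo(q1), "s1_RS": expo(q1),
                     "s3_CS": expo(q3), "s3_RS": expo(q3), "s5": expo(q5)},
        eligible={k: EligibleDwell(1.0, None)
                  for k in ("s2_CS", "s2_RS", "s4_CS", "s4_RS", "s6")},
        death_s1=tiny if death == 0.0 else expo(death),
        death_s3=ConstantHazard(death),
        death_s5=ConstantHazard(death),
        switch_s1=tiny,
    )


@pytest.fixture
def exponential_params() -> ModelParameters:
    return make_exponential_params(0.02, 0.04, 0.05)
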