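import numpy as np
import pytest

import polyarm as pa


@pytest.fixture(scope="session")
def example_bernoulli_spec():
    """The three-arm myelodysplastic-syndrome-motivated design problem:
    two experimental arms vs control, binary outcome."""
    return pa.DesignSpec(
        K=2, alpha=0.15, beta=0.2, delta1=0.15, delta0=0.0,
        mcc="dunnett", power_type="marginal",
        outcome=pa.BernoulliOutcome(0.3), ratios=(1.0, 1.0))


@pytest.fixture(scope="session")
def example_bernoulli_result(example_bernoulli_spec):
    return pa.required_sample_size(example_bernoulli_spec)


@pytest.fixture(scope="session")
def example_normal_spec():
    """Normal-outcome variant of the example with unit SDs and integer n."""
    return pa.DesignSpec(
        K=2, alpha=0.15, beta=0.2, delta1=0.15, delta0=0.0,
        mcc="dunnett", power_type="marginal",
        outcome=pa.NormalOutcome((1.0, 1.0, 1.0)), ratios=(1.0, 1.0),
        integer_n=True)


@pytest.fixture(scope="session")
def example_normal_result(example_normal_spec):
    return pa.required_sample_size(example_normal_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
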