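import numpy as np
import pytest

from yonezawa import AdaptiveResponseParams


@pytest.fixture
def abstract_params() -> AdaptiveResponseParams:
    """The abstract-unit worked-example parameters (alpha0=1, alpha1=1, alpha2=0.7)."""
    return AdaptiveResponseParams(1.0, 1.0, 0.7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_params(rng: np.random.Generator) -> AdaptiveResponseParams:
    """Moderate random alphas for property tests (well away from over/underflow)."""
    return AdaptiveResponseParams(
        float(rng.uniform(0.05, 20.0)),
        float(rng.uniform(0.1, 5.0)),
        float(rng.uniform(0.05, 2.0)),
    )
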