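import pytest

import gspoisson as gp


@pytest.fixture(scope="session")
def osah_problem() -> gp.DesignProblem:
    """The packaged moderate-OSAH design problem (AHI endpoint)."""
    return gp.moderate_osah_trial()


@pytest.fixture(scope="session")
def tiny_problem() -> gp.DesignProblem:
    """A small point-hypothesis problem where exhaustive oracles are cheap."""
    return gp.DesignProblem(
        lambda_null=(2.0, 2.0),
        lambda_alt=(2.0, 2.0),
        delta=1.5,
        alpha=0.2,
        beta=0.3,
        lambda_ess=2.0,
    )


@pytest.fixture(scope="session")
def small_designs():
    """Small exact designs paired with rates, cheap enough for enumeration/MC."""
    designs = [
        (gp.GroupSequentialDesign(2, 5, (-2, 8), (6, 8), "exact"), gp.PoissonRates(2, 1)),
        (gp.GroupSequentialDesign(2, 4, (0, 6), (5, 6), "exact"), gp.PoissonRates(1.5, 1.5)),
        (gp.GroupSequentialDesign(2, 8, (-3, 5), (7, 5), "exact"), gp.PoissonRates(1, 1)),
        (gp.GroupSequentialDesign(3, 3, (-4, 0, 7), (6, 9, 7), "exact"), gp.PoissonRates(2, 1.2)),
        (gp.GroupSequentialDesign(3, 6, (-2, 2, 10), (8, 11, 10), "exact"), gp.PoissonRates(1.8, 1)),
        (gp.GroupSequentialDesign(3, 10, (-5, -1, 6), (6, 8, 6), "exact"), gp.PoissonRates(0.8, 0.8)),
    ]
    return designs
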