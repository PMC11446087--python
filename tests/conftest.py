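import numpy as np
import pytest

from tripilot import (
    AdjustmentInterval,
    ErrorConstraints,
    Hypotheses,
    PauseDecisionModel,
    Problem,
    validate_problem,
)


@pytest.fixture
def adherence_hypotheses():
    """Running example: poor adherence 0.5 vs promising 0.7."""
    return Hypotheses(0.5, 0.7)


@pytest.fixture
def adherence_problem(adherence_hypotheses):
    """The running example with the standard error-rate bounds."""
    return validate_problem(
        adherence_hypotheses,
        ErrorConstraints(alpha_star=0.05, beta_star=0.1),
        PauseDecisionModel(0.5, 0.5),
        AdjustmentInterval(0.0, 0.0),
    )


def random_problem(rng: np.random.Generator, allow_adjustment: bool = True) -> Problem:
    """Draw a random but well-posed binary design problem."""
    rho0 = rng.uniform(0.15, 0.6)
    rho1 = rho0 + rng.uniform(0.1, 0.3)
    eta = round(float(rng.uniform(0.0, 0.5)), 3)
    if allow_adjustment and rng.random() < 0.5:
        tau_min = round(float(rng.uniform(0.0, min(0.05, rho0 - 0.01))), 3)
        tau_max = tau_min + round(float(rng.uniform(0.0, 0.03)), 3)
    else:
        tau_min = tau_max = 0.0
    return validate_problem(
        Hypotheses(round(rho0, 3), round(rho1, 3)),
        ErrorConstraints(
            alpha_star=round(float(rng.uniform(0.03, 0.2)), 3),
            beta_star=round(float(rng.uniform(0.05, 0.25)), 3),
            gamma_star=round(float(rng.uniform(0.5, 1.0)), 3),
        ),
        PauseDecisionModel(eta, eta),
        AdjustmentInterval(tau_min, tau_max),
    )
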