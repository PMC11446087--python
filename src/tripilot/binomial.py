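"""Exact binomial operating characteristics for three-outcome designs.

With X ~ Binomial(n, rho) successes and integer thresholds x0 <= x1 the
decision rule is

    stop  iff X <= x0,    pause iff x0 < X <= x1,    go iff X > x1.

All tail probabilities are exact binomial CDF evaluations; no normal
approximation is used anywhere in this module.

The overall (reformulated) error rates account for the post-pause decision
process and an optional adjustment of effect tau in [tau_min, tau_max]:

    alpha = max[ P(X > x1 | rho0),
                 eta P(x0 < X <= x1 | rho0 - tau_min)
                   + P(X > x1 | rho0 - tau_min) ]
    beta  = P(X <= x0 | rho1 - tau_max)
              + eta P(x0 < X <= x1 | rho1 - tau_max)

which reduce, when tau_min = tau_max = 0, to

    alpha = alpha_a + eta0 * lambda,    beta = beta_a + eta1 * delta.

gamma = gamma_L + gamma_U is always evaluated at the unshifted midpoint
rho_m with no eta weighting: it measures the chance of any conclusive
decision when the truth is borderline.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.stats import binom

from .types import (
    AdjustmentInterval,
    Design,
    Hypotheses,
    OperatingCharacteristics,
    PauseDecisionModel,
    ValidationError,
)

__all__ = ["decision_probs", "oc_classic", "oc_reformulated"]


def cdf_table(n: int, p: float) -> np.ndarray:
    """Return F with F[k] = P(X <= k - 1) for k = 0..n+1, X ~ Bin(n, p).

    Index k corresponds to a threshold x = k - 1, so F[x + 1] = P(X <= x)
    and F[0] = 0 covers the x = -1 sentinel.
    """
    return np.concatenate(([0.0], binom.cdf(np.arange(n + 1), n, p)))


def _region_probs(n: int, x0: int, x1: int, rho: float) -> tuple[float, float, float]:
    F = lambda x: 0.0 if x < 0 else float(binom.cdf(x, n, rho))
    p_stop = F(x0)
    p_pause = F(x1) - F(x0)
    p_go = 1.0 - F(x1)
    return p_stop, p_pause, p_go


def decision_probs(design: Design, rho: float) -> tuple[float, float, float]:
    """Exact (p_stop, p_pause, p_go) of a binary-endpoint design at rho.

    The three probabilities sum to one exactly.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValidationError(f"rho must lie in [0, 1]; got {rho}")
    x0, x1 = design.require_integer_thresholds()
    return _region_probs(design.n, x0, x1, rho)


def oc_classic(design: Design, hypotheses: Hypotheses) -> OperatingCharacteristics:
    """Classic three-outcome operating characteristics at rho0, rho1, rho_m.

    Returns the two historical parameterisations of the same design: the
    Sargent-style (alpha_a, beta_a, lambda, delta) and the Storer-style
    (alpha_b, beta_b, gamma_L, gamma_U), plus gamma = gamma_L + gamma_U.
    The overall error rates alpha, beta are left unset; use
    :func:`oc_reformulated` for those.
    """
    x0, x1 = design.require_integer_thresholds()
    n = design.n
    s0, l0, a0 = _region_probs(n, x0, x1, hypotheses.rho0)
    s1, d1, g1 = _region_probs(n, x0, x1, hypotheses.rho1)
    sm, _, gm = _region_probs(n, x0, x1, hypotheses.rho_m)
    return OperatingCharacteristics(
        alpha_a=a0,
        beta_a=s1,
        lambda_=l0,
        delta=d1,
        alpha_b=l0 + a0,   # P(X > x0 | rho0)
        beta_b=s1 + d1,    # P(X <= x1 | rho1)
        gamma_L=sm,
        gamma_U=gm,
        gamma=sm + gm,
    )


def oc_reformulated(
    design: Design,
    hypotheses: Hypotheses,
    pause_model: Optional[PauseDecisionModel] = None,
    adjustment: Optional[AdjustmentInterval] = None,
) -> OperatingCharacteristics:
    """Overall error rates of a design, allowing post-pause decisions and
    adjustment.

    With no adjustment, alpha = alpha_a + eta0*lambda and
    beta = beta_a + eta1*delta (separate eta0, eta1 permitted).  With an
    adjustment interval the general formulas above apply and a common eta
    is required, since the shifted-maximum derivation assumes one.
    """
    pause_model = pause_model or PauseDecisionModel()
    adjustment = adjustment or AdjustmentInterval()
    x0, x1 = design.require_integer_thresholds()
    n = design.n

    classic = oc_classic(design, hypotheses)

    if adjustment.is_null:
        alpha = classic.alpha_a + pause_model.eta0 * classic.lambda_
        beta = classic.beta_a + pause_model.eta1 * classic.delta
    else:
        eta = pause_model.common_eta
        _, pause_lo, go_lo = _region_probs(
            n, x0, x1, hypotheses.rho0 - adjustment.tau_min
        )
        alpha = max(classic.alpha_a, eta * pause_lo + go_lo)
        stop_hi, pause_hi, _ = _region_probs(
            n, x0, x1, hypotheses.rho1 - adjustment.tau_max
        )
        beta = stop_hi + eta * pause_hi

    return dataclasses.replace(classic, alpha=alpha, beta=beta)
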