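"""Continuous-endpoint engine: normal sampling model with known sigma.

The pilot estimate is modelled as rho_hat ~ Normal(rho, sigma^2 / n) and
the thresholds x0 <= x1 live on the estimate (mean) scale.  The decision
rule and all error-rate definitions mirror the binomial engine; because
the sampling distribution is continuous, the lower threshold can be chosen
so the type I error rate hits alpha* exactly, by inverting

    P(rho_hat <= x0) = 1/eta + ((eta - 1)/eta) P(rho_hat <= x1) - alpha*/eta

evaluated at rho0 - tau_min.  The upper threshold is then the largest x1
keeping beta <= beta* (found by root-finding: beta is increasing in x1),
and n is the smallest integer whose resulting design satisfies
gamma <= gamma*.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .types import (
    AdjustmentInterval,
    Design,
    Hypotheses,
    OperatingCharacteristics,
    PauseDecisionModel,
    Problem,
    ValidationError,
)

__all__ = [
    "decision_probs_normal",
    "oc_reformulated_normal",
    "x0_from_alpha_normal",
    "find_three_outcome_normal",
]

logger = logging.getLogger(__name__)

#: Resolution of threshold root-finding on the estimate scale.
THRESHOLD_XTOL = 1e-8


def _se(sigma: float, n: int) -> float:
    if not (sigma > 0):
        raise ValidationError(f"sigma must be positive; got {sigma}")
    if n < 1:
        raise ValidationError(f"n must be >= 1; got {n}")
    return sigma / math.sqrt(n)


def decision_probs_normal(
    design: Design, rho: float, sigma: float
) -> tuple[float, float, float]:
    """(p_stop, p_pause, p_go) for rho_hat ~ Normal(rho, sigma^2/n).

    p_stop = Phi((x0 - rho) sqrt(n) / sigma), p_go = 1 - Phi((x1 - rho)
    sqrt(n) / sigma); the remainder is p_pause.  Infinite thresholds encode
    empty stop/go regions.
    """
    se = _se(sigma, design.n)
    p_stop = float(norm.cdf(design.x0, rho, se)) if np.isfinite(design.x0) else (
        0.0 if design.x0 < 0 else 1.0
    )
    F1 = float(norm.cdf(design.x1, rho, se)) if np.isfinite(design.x1) else (
        0.0 if design.x1 < 0 else 1.0
    )
    return p_stop, F1 - p_stop, 1.0 - F1


def oc_reformulated_normal(
    design: Design,
    hypotheses: Hypotheses,
    pause_model: Optional[PauseDecisionModel] = None,
    adjustment: Optional[AdjustmentInterval] = None,
    sigma: float = 1.0,
) -> OperatingCharacteristics:
    """Full operating characteristics of a continuous-endpoint design."""
    pause_model = pause_model or PauseDecisionModel()
    adjustment = adjustment or AdjustmentInterval()
    s0, l0, a0 = decision_probs_normal(design, hypotheses.rho0, sigma)
    s1, d1, g1 = decision_probs_normal(design, hypotheses.rho1, sigma)
    sm, _, gm = decision_probs_normal(design, hypotheses.rho_m, sigma)
    if adjustment.is_null:
        alpha = a0 + pause_model.eta0 * l0
        beta = s1 + pause_model.eta1 * d1
    else:
        eta = pause_model.common_eta
        _, pl, gl = decision_probs_normal(
            design, hypotheses.rho0 - adjustment.tau_min, sigma
        )
        alpha = max(a0, eta * pl + gl)
        sh, ph, _ = decision_probs_normal(
            design, hypotheses.rho1 - adjustment.tau_max, sigma
        )
        beta = sh + eta * ph
    return OperatingCharacteristics(
        alpha_a=a0, beta_a=s1, lambda_=l0, delta=d1,
        alpha_b=l0 + a0, beta_b=s1 + d1,
        gamma_L=sm, gamma_U=gm, gamma=sm + gm,
        alpha=alpha, beta=beta,
    )


def x0_from_alpha_normal(
    n: int,
    x1: float,
    hypotheses: Hypotheses,
    pause_model: PauseDecisionModel,
    adjustment: AdjustmentInterval,
    alpha_star: float,
    sigma: float,
) -> float:
    """Exact lower threshold giving alpha = alpha* for fixed n and x1.

    Inverts the post-pause type I error rate through the normal CDF at
    rho0 - tau_min.  Returns -inf when even an empty stop region keeps
    alpha below alpha*.
    """
    se = _se(sigma, n)
    eta = pause_model.common_eta if not adjustment.is_null else pause_model.eta0
    if 1.0 - norm.cdf(x1, hypotheses.rho0, se) > alpha_star + 1e-12:
        raise ValidationError(
            f"x1 too small for alpha_star: P(rho_hat > {x1} | rho0) > {alpha_star}"
        )
    mu = hypotheses.rho0 - adjustment.tau_min
    F1 = float(norm.cdf(x1, mu, se))
    if eta == 0.0:
        return -math.inf
    rhs = (1.0 - alpha_star + (eta - 1.0) * F1) / eta
    if rhs <= 0.0:
        return -math.inf
    if rhs >= 1.0:
        raise ValidationError(
            f"no finite x0 keeps alpha within {alpha_star} at n={n}, x1={x1}"
        )
    return float(norm.ppf(rhs, mu, se))


def _beta_of_x1(
    x1: float,
    n: int,
    hypotheses: Hypotheses,
    pause_model: PauseDecisionModel,
    adjustment: AdjustmentInterval,
    alpha_star: float,
    sigma: float,
) -> tuple[float, float]:
    """(beta, x0) for the alpha*-achieving x0 at this x1."""
    eta = pause_model.common_eta if not adjustment.is_null else pause_model.eta0
    x0 = x0_from_alpha_normal(
        n, x1, hypotheses, pause_model, adjustment, alpha_star, sigma
    )
    se = _se(sigma, n)
    mu = hypotheses.rho1 - adjustment.tau_max
    Fb0 = float(norm.cdf(x0, mu, se)) if math.isfinite(x0) else 0.0
    Fb1 = float(norm.cdf(x1, mu, se))
    return Fb0 + eta * (Fb1 - Fb0), x0


def find_three_outcome_normal(
    problem: Problem,
    settings=None,
) -> "SearchResult":
    """Minimum-sample-size three-outcome design for a continuous endpoint.

    Same nested procedure as the binary search, with the thresholds
    resolved exactly: x0 achieves alpha = alpha* through the CDF inversion
    and x1 is the largest value keeping beta <= beta* (found by Brent root
    finding to ``THRESHOLD_XTOL``).  Returns the smallest integer n whose
    design also satisfies gamma <= gamma*.
    """
    from .search import InfeasibleDesignError, SearchResult, SearchSettings

    settings = settings or SearchSettings()
    if problem.endpoint.kind != "continuous":
        raise ValidationError("find_three_outcome_normal needs a continuous endpoint")
    sigma = problem.endpoint.sigma
    h, c, adj, pm = (
        problem.hypotheses,
        problem.constraints,
        problem.adjustment,
        problem.pause_model,
    )
    best: Optional[tuple[float, SearchResult]] = None
    for n in range(settings.n_min, settings.n_max + 1):
        se = sigma / math.sqrt(n)
        x1_min = h.rho0 + norm.ppf(1.0 - c.alpha_star) * se
        beta_lo, _ = _beta_of_x1(x1_min, n, h, pm, adj, c.alpha_star, sigma)
        if beta_lo > c.beta_star + 1e-12:
            continue
        # beta is increasing in x1; expand an upper bracket then root-find
        hi = max(x1_min, h.rho1 - adj.tau_max) + se
        while _beta_of_x1(hi, n, h, pm, adj, c.alpha_star, sigma)[0] < c.beta_star \
                and hi < x1_min + 60 * se:
            hi += se
        if _beta_of_x1(hi, n, h, pm, adj, c.alpha_star, sigma)[0] < c.beta_star:
            x1 = hi  # beta never reaches beta*: cap the go threshold
        else:
            x1 = brentq(
                lambda x: _beta_of_x1(x, n, h, pm, adj, c.alpha_star, sigma)[0]
                - c.beta_star,
                x1_min, hi, xtol=THRESHOLD_XTOL,
            )
        beta, x0 = _beta_of_x1(x1, n, h, pm, adj, c.alpha_star, sigma)
        design = Design(n, x0, float(x1))
        oc = oc_reformulated_normal(design, h, pm, adj, sigma)
        logger.debug(
            "three-outcome normal: n=%d x0=%.5f x1=%.5f beta=%.5f gamma=%.5f",
            n, x0, x1, beta, oc.gamma,
        )
        if oc.gamma <= c.gamma_star + 1e-9:
            return SearchResult(design, oc)
        viol = oc.gamma - c.gamma_star
        if best is None or viol < best[0]:
            best = (viol, SearchResult(design, oc))
    raise InfeasibleDesignError(
        f"no continuous-endpoint design with n <= {settings.n_max} meets the constraints",
        best[1] if best else None,
        best[0] if best else float("inf"),
    )
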