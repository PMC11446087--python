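"""Minimum-sample-size searches for two- and three-outcome designs.

The central routine, :func:`find_three_outcome`, implements the nested
threshold-selection procedure for the reformulated three-outcome test:

  for each n ascending:
    1. candidate upper thresholds x1 are those with P(X > x1 | rho0) <= alpha*;
    2. for each x1, x0 is the smallest integer (down to the -1 sentinel)
       keeping the overall type I error rate alpha <= alpha* — i.e. the x0
       that maximises alpha subject to the constraint, obtained by
       inverting the CDF (alpha is non-increasing in x0);
    3. the selected x1 is the largest with x0 <= x1 and beta <= beta*;
    4. the first n whose selected design also satisfies gamma <= gamma*
       is returned.

Classic four-constraint searches (Sargent: alpha_a, beta_a, lambda, delta;
Storer: alpha_b, beta_b, gamma_L, gamma_U) and an exhaustive brute-force
oracle are provided alongside.

Feasibility comparisons use an absolute slack ``CONSTRAINT_TOL`` (1e-5):
an operating characteristic equal to its nominal level at that resolution
counts as feasible.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Optional

import numpy as np

from . import binomial
from .types import (
    CONSTRAINT_TOL,
    AdjustmentInterval,
    Design,
    ErrorConstraints,
    Hypotheses,
    OperatingCharacteristics,
    PauseDecisionModel,
    Problem,
    ValidationError,
)

__all__ = [
    "SearchSettings",
    "SearchResult",
    "InfeasibleDesignError",
    "find_two_outcome",
    "x0_from_alpha",
    "find_three_outcome",
    "find_sargent_original",
    "find_storer_original",
    "brute_force_min_n",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # guards CDF inversions against float ties, not a feasibility slack


@dataclass(frozen=True)
class SearchSettings:
    """Bounds on the sample-size search."""

    n_max: int = 2000
    n_min: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.n_min <= self.n_max):
            raise ValidationError(
                f"1 <= n_min <= n_max required; got [{self.n_min}, {self.n_max}]"
            )


@dataclass(frozen=True)
class SearchResult:
    """A design returned by a search, with its operating characteristics."""

    design: Design
    oc: OperatingCharacteristics

    def to_record(self, constraints: Optional[ErrorConstraints] = None) -> dict[str, Any]:
        """Flat JSON-serialisable record (thresholds, OCs, constraint slacks)."""
        rec: dict[str, Any] = {
            "n": self.design.n,
            "x0": self.design.x0,
            "x1": self.design.x1,
        }
        rec.update(self.oc.as_dict())
        if constraints is not None and self.oc.alpha is not None:
            rec["alpha_slack"] = constraints.alpha_star - self.oc.alpha
            rec["beta_slack"] = constraints.beta_star - self.oc.beta
            rec["gamma_slack"] = constraints.gamma_star - self.oc.gamma
        return rec


class InfeasibleDesignError(Exception):
    """No design within n_max satisfies the constraints.

    Attributes
    ----------
    best : Optional[SearchResult]
        The least-violating candidate encountered, for diagnosis.
    violation : float
        Its worst constraint excess.
    """

    def __init__(self, message: str, best: Optional[SearchResult] = None,
                 violation: float = float("inf")) -> None:
        if best is not None:
            message += (
                f" (best candidate: n={best.design.n}, x0={best.design.x0}, "
                f"x1={best.design.x1}, constraint excess {violation:.4g})"
            )
        super().__init__(message)
        self.best = best
        self.violation = violation


def _feasible(value: float, bound: float) -> bool:
    return value <= bound + CONSTRAINT_TOL


# ---------------------------------------------------------------------------
# Two-outcome (A'Hern-style) search
# ---------------------------------------------------------------------------

def find_two_outcome(
    hypotheses: Hypotheses,
    alpha_star: float,
    beta_star: float,
    settings: SearchSettings = SearchSettings(),
) -> SearchResult:
    """Smallest exact-binomial single-stage stop/go design.

    Finds the minimum n admitting an integer threshold x with
    P(X > x | rho0) <= alpha* and P(X <= x | rho1) <= beta*; among feasible
    x at that n the smallest (power-maximising) threshold is returned.
    """
    best: Optional[tuple[float, int, int]] = None
    for n in range(settings.n_min, settings.n_max + 1):
        F0 = binomial.cdf_table(n, hypotheses.rho0)
        F1 = binomial.cdf_table(n, hypotheses.rho1)
        alpha = 1.0 - F0
        beta = F1
        ok = (alpha <= alpha_star + CONSTRAINT_TOL) & (beta <= beta_star + CONSTRAINT_TOL)
        if ok.any():
            k = int(np.argmax(ok))  # smallest feasible threshold index
            x = k - 1
            design = Design(n, x, x)
            logger.debug("two-outcome: n=%d feasible at x=%d", n, x)
            return SearchResult(design, binomial.oc_reformulated(design, hypotheses))
        viol = np.maximum(alpha - alpha_star, beta - beta_star).min()
        if best is None or viol < best[0]:
            k = int(np.argmin(np.maximum(alpha - alpha_star, beta - beta_star)))
            best = (float(viol), n, k - 1)
    assert best is not None
    viol, n, x = best
    design = Design(n, x, x)
    raise InfeasibleDesignError(
        f"no two-outcome design with n <= {settings.n_max} meets "
        f"alpha* = {alpha_star}, beta* = {beta_star}",
        SearchResult(design, binomial.oc_reformulated(design, hypotheses)),
        viol,
    )


# ---------------------------------------------------------------------------
# Threshold inversion for the reformulated three-outcome test
# ---------------------------------------------------------------------------

def _x0_index_from_alpha(
    F0_shift: np.ndarray,
    k1: int,
    eta: float,
    alpha_star: float,
) -> Optional[int]:
    """Smallest CDF-table index k0 keeping the post-pause type I term
    eta*(F[k1]-F[k0]) + (1-F[k1]) within alpha*; None if impossible.

    Index k corresponds to threshold x = k - 1.
    """
    tail = 1.0 - F0_shift[k1]
    if eta == 0.0:
        return 0 if tail <= alpha_star + CONSTRAINT_TOL else None
    # eta*(F[k1] - F[k0]) + tail <= alpha*  <=>  F[k0] >= rhs
    rhs = F0_shift[k1] - (alpha_star + CONSTRAINT_TOL - tail) / eta
    if rhs <= 0.0:
        return 0
    k0 = int(np.searchsorted(F0_shift, rhs - _EPS, side="left"))
    if k0 >= len(F0_shift):
        return None
    return k0


def x0_from_alpha(
    n: int,
    x1: float,
    hypotheses: Hypotheses,
    pause_model: PauseDecisionModel,
    adjustment: AdjustmentInterval,
    alpha_star: float,
    endpoint=None,
) -> float:
    """Lower threshold achieving the largest type I error rate not
    exceeding alpha*, given n and x1.

    Binary endpoints return the smallest integer x0 in [-1, x1] with
    alpha(n, x0, x1) <= alpha* (alpha is non-increasing in x0); the -1
    sentinel denotes an empty stop region.  Continuous endpoints solve the
    CDF-inversion equation exactly so that alpha = alpha*.

    Requires P(X > x1 | rho0) <= alpha*; otherwise no x0 can rescue the
    design and a :class:`ValidationError` is raised.
    """
    if endpoint is not None and endpoint.kind == "continuous":
        from . import normal

        return normal.x0_from_alpha_normal(
            n, x1, hypotheses, pause_model, adjustment, alpha_star, endpoint.sigma
        )
    eta = pause_model.common_eta if not adjustment.is_null else pause_model.eta0
    x1 = int(x1)
    F0 = binomial.cdf_table(n, hypotheses.rho0)
    if 1.0 - F0[x1 + 1] > alpha_star + CONSTRAINT_TOL:
        raise ValidationError(
            f"x1 too small for alpha_star: P(X > {x1} | rho0) = "
            f"{1.0 - F0[x1 + 1]:.4g} > {alpha_star}"
        )
    F0s = (
        F0
        if adjustment.tau_min == 0.0
        else binomial.cdf_table(n, hypotheses.rho0 - adjustment.tau_min)
    )
    k0 = _x0_index_from_alpha(F0s, x1 + 1, eta, alpha_star)
    if k0 is None or k0 > x1 + 1:
        raise ValidationError(
            f"no x0 in [-1, {x1}] keeps alpha within {alpha_star} at n={n}"
        )
    return k0 - 1


# ---------------------------------------------------------------------------
# Reformulated three-outcome search (the main procedure)
# ---------------------------------------------------------------------------

def _select_thresholds_at_n(
    n: int,
    hypotheses: Hypotheses,
    constraints: ErrorConstraints,
    eta: float,
    adjustment: AdjustmentInterval,
) -> Optional[tuple[int, int, float]]:
    """Run steps 1-3 of the procedure at fixed n.

    Returns (x0, x1, beta) of the selected design — the largest x1 whose
    derived x0 satisfies x0 <= x1 and beta <= beta* — or None when no
    candidate survives.
    """
    F0 = binomial.cdf_table(n, hypotheses.rho0)
    F0s = (
        F0
        if adjustment.tau_min == 0.0
        else binomial.cdf_table(n, hypotheses.rho0 - adjustment.tau_min)
    )
    F1s = binomial.cdf_table(
        n,
        hypotheses.rho1 - adjustment.tau_max,
    )

    k1_all = np.arange(n + 2)
    direct_ok = (1.0 - F0) <= constraints.alpha_star + CONSTRAINT_TOL
    k1 = k1_all[direct_ok]
    if k1.size == 0:
        return None

    tail = 1.0 - F0s[k1]
    if eta == 0.0:
        k0 = np.zeros(k1.size, dtype=int)
        valid = tail <= constraints.alpha_star + CONSTRAINT_TOL
    else:
        rhs = F0s[k1] - (constraints.alpha_star + CONSTRAINT_TOL - tail) / eta
        k0 = np.searchsorted(F0s, np.maximum(rhs, 0.0) - _EPS, side="left")
        valid = k0 <= n + 1
    valid &= k0 <= k1
    beta = F1s[np.minimum(k0, n + 1)] + eta * (F1s[k1] - F1s[np.minimum(k0, n + 1)])
    valid &= beta <= constraints.beta_star + CONSTRAINT_TOL
    if not valid.any():
        return None
    i = int(np.max(np.nonzero(valid)[0]))  # largest feasible x1
    return int(k0[i]) - 1, int(k1[i]) - 1, float(beta[i])


def find_three_outcome(
    problem: Problem,
    settings: SearchSettings = SearchSettings(),
) -> SearchResult:
    """Minimum-sample-size reformulated three-outcome design (binary
    endpoint).

    Runs the nested procedure described in the module docstring and returns
    the first n whose selected (x0, x1) also satisfies gamma <= gamma*.
    Continuous-endpoint problems are delegated to the normal engine.
    """
    if problem.endpoint.kind == "continuous":
        from . import normal

        return normal.find_three_outcome_normal(problem, settings)

    h, c, adj = problem.hypotheses, problem.constraints, problem.adjustment
    eta = (
        problem.pause_model.common_eta
        if not adj.is_null
        else problem.pause_model.eta0
    )
    if adj.is_null and problem.pause_model.eta0 != problem.pause_model.eta1:
        # the procedure's threshold inversion is derived for a common eta;
        # distinct eta0/eta1 with tau = 0 is handled by the brute-force path
        return brute_force_min_n(problem, settings)

    best: Optional[tuple[float, SearchResult]] = None
    for n in range(settings.n_min, settings.n_max + 1):
        sel = _select_thresholds_at_n(n, h, c, eta, adj)
        if sel is None:
            continue
        x0, x1, beta = sel
        design = Design(n, x0, x1)
        oc = binomial.oc_reformulated(design, h, problem.pause_model, adj)
        logger.debug(
            "three-outcome: n=%d candidate x0=%d x1=%d alpha=%.4f beta=%.4f gamma=%.4f",
            n, x0, x1, oc.alpha, oc.beta, oc.gamma,
        )
        if _feasible(oc.gamma, c.gamma_star):
            return SearchResult(design, oc)
        viol = oc.gamma - c.gamma_star
        if best is None or viol < best[0]:
            best = (viol, SearchResult(design, oc))
    raise InfeasibleDesignError(
        f"no three-outcome design with n <= {settings.n_max} meets the constraints",
        best[1] if best else None,
        best[0] if best else float("inf"),
    )


# ---------------------------------------------------------------------------
# Original four-constraint phase II searches
# ---------------------------------------------------------------------------

def find_sargent_original(
    hypotheses: Hypotheses,
    alpha_a_star: float,
    beta_a_star: float,
    lambda_star: float,
    delta_star: float,
    settings: SearchSettings = SearchSettings(),
) -> SearchResult:
    """Smallest design with alpha_a, beta_a, lambda, delta all within their
    bounds (classic Sargent-style three-outcome design).

    Exhaustive over integer x0 <= x1 at each n; ties broken by the largest
    x1, then the largest x0.
    """
    for name, v in (("alpha_a_star", alpha_a_star), ("beta_a_star", beta_a_star),
                    ("lambda_star", lambda_star), ("delta_star", delta_star)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]; got {v}")
    for n in range(settings.n_min, settings.n_max + 1):
        F0 = binomial.cdf_table(n, hypotheses.rho0)
        F1 = binomial.cdf_table(n, hypotheses.rho1)
        # largest k0 with beta_a = F1[k0] within bound
        k0_beta_hi = int(np.searchsorted(F1, beta_a_star + CONSTRAINT_TOL + _EPS,
                                         side="right")) - 1
        if k0_beta_hi < 0:
            continue
        found: Optional[tuple[int, int]] = None
        for k1 in range(n + 1, -1, -1):  # prefer the largest x1
            if 1.0 - F0[k1] > alpha_a_star + CONSTRAINT_TOL:
                continue
            # lambda = F0[k1] - F0[k0] <= lambda*  =>  F0[k0] >= F0[k1] - lambda*
            k0_lam = int(np.searchsorted(
                F0, F0[k1] - lambda_star - CONSTRAINT_TOL - _EPS, side="left"))
            k0_del = int(np.searchsorted(
                F1, F1[k1] - delta_star - CONSTRAINT_TOL - _EPS, side="left"))
            lo = max(k0_lam, k0_del)
            hi = min(k0_beta_hi, k1)
            if lo <= hi:
                found = (hi - 1, k1 - 1)  # largest x0
                break
        if found is not None:
            design = Design(n, *found)
            return SearchResult(design, binomial.oc_classic(design, hypotheses))
    raise InfeasibleDesignError(
        f"no Sargent-style design with n <= {settings.n_max} meets the constraints"
    )


def find_storer_original(
    hypotheses: Hypotheses,
    alpha_b_star: float,
    beta_b_star: float,
    gamma_L_star: float,
    gamma_U_star: float,
    settings: SearchSettings = SearchSettings(),
) -> SearchResult:
    """Smallest design with alpha_b, beta_b (at rho0, rho1) and gamma_L,
    gamma_U (at rho_m) all within their bounds (classic Storer-style
    design).  Ties broken by the largest x1, then the largest x0.
    """
    for name, v in (("alpha_b_star", alpha_b_star), ("beta_b_star", beta_b_star),
                    ("gamma_L_star", gamma_L_star), ("gamma_U_star", gamma_U_star)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]; got {v}")
    for n in range(settings.n_min, settings.n_max + 1):
        F0 = binomial.cdf_table(n, hypotheses.rho0)
        F1 = binomial.cdf_table(n, hypotheses.rho1)
        Fm = binomial.cdf_table(n, hypotheses.rho_m)
        # alpha_b = 1 - F0[k0] <= alpha_b*  =>  F0[k0] >= 1 - alpha_b*
        k0_lo = int(np.searchsorted(F0, 1.0 - alpha_b_star - CONSTRAINT_TOL - _EPS,
                                    side="left"))
        # gamma_L = Fm[k0] <= gamma_L*
        k0_hi = int(np.searchsorted(Fm, gamma_L_star + CONSTRAINT_TOL + _EPS,
                                    side="right")) - 1
        # beta_b = F1[k1] <= beta_b*
        k1_hi = int(np.searchsorted(F1, beta_b_star + CONSTRAINT_TOL + _EPS,
                                    side="right")) - 1
        # gamma_U = 1 - Fm[k1] <= gamma_U*  =>  Fm[k1] >= 1 - gamma_U*
        k1_lo = int(np.searchsorted(Fm, 1.0 - gamma_U_star - CONSTRAINT_TOL - _EPS,
                                    side="left"))
        if k0_lo > k0_hi or k1_lo > k1_hi or k0_lo > k1_hi:
            continue
        k1 = k1_hi
        k0 = min(k0_hi, k1)
        design = Design(n, k0 - 1, k1 - 1)
        return SearchResult(design, binomial.oc_classic(design, hypotheses))
    raise InfeasibleDesignError(
        f"no Storer-style design with n <= {settings.n_max} meets the constraints"
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_min_n(
    problem: Problem,
    settings: SearchSettings = SearchSettings(),
) -> SearchResult:
    """Exhaustive search over all (n, x0, x1) with -1 <= x0 <= x1 <= n.

    Evaluates the reformulated error rates for every threshold pair and
    returns the smallest feasible n, breaking ties by the largest x1 and
    then the smallest (alpha-maximising) x0 — the same tie-break as
    :func:`find_three_outcome`, with which it must agree.  Intended as a
    verification oracle; n_max <= 1000 is recommended.
    """
    h, c, adj, pm = (
        problem.hypotheses,
        problem.constraints,
        problem.adjustment,
        problem.pause_model,
    )
    best: Optional[tuple[float, SearchResult]] = None
    for n in range(settings.n_min, settings.n_max + 1):
        F0 = binomial.cdf_table(n, h.rho0)
        Fm = binomial.cdf_table(n, h.rho_m)
        k = np.arange(n + 2)
        k0g, k1g = np.meshgrid(k, k, indexing="ij")  # k0 rows, k1 cols
        pair_ok = k0g <= k1g
        if adj.is_null:
            F1 = binomial.cdf_table(n, h.rho1)
            alpha = (1.0 - F0[k1g]) + pm.eta0 * (F0[k1g] - F0[k0g])
            beta = F1[k0g] + pm.eta1 * (F1[k1g] - F1[k0g])
        else:
            eta = pm.common_eta
            F0s = binomial.cdf_table(n, h.rho0 - adj.tau_min)
            F1s = binomial.cdf_table(n, h.rho1 - adj.tau_max)
            alpha = np.maximum(
                1.0 - F0[k1g],
                eta * (F0s[k1g] - F0s[k0g]) + (1.0 - F0s[k1g]),
            )
            beta = F1s[k0g] + eta * (F1s[k1g] - F1s[k0g])
        gamma = Fm[k0g] + (1.0 - Fm[k1g])
        viol = np.maximum.reduce([
            alpha - c.alpha_star, beta - c.beta_star, gamma - c.gamma_star,
            np.zeros_like(alpha),
        ])
        viol = np.where(pair_ok, viol, np.inf)
        feasible = viol <= CONSTRAINT_TOL
        if feasible.any():
            k1_best = int(np.max(np.nonzero(feasible.any(axis=0))[0]))
            k0_best = int(np.min(np.nonzero(feasible[:, k1_best])[0]))
            design = Design(n, k0_best - 1, k1_best - 1)
            return SearchResult(
                design, binomial.oc_reformulated(design, h, pm, adj)
            )
        i0, i1 = np.unravel_index(int(np.argmin(viol)), viol.shape)
        if best is None or viol[i0, i1] < best[0]:
            design = Design(n, int(i0) - 1, int(i1) - 1)
            best = (
                float(viol[i0, i1]),
                SearchResult(design, binomial.oc_reformulated(design, h, pm, adj)),
            )
    raise InfeasibleDesignError(
        f"no design with n <= {settings.n_max} meets the constraints",
        best[1] if best else None,
        best[0] if best else float("inf"),
    )
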