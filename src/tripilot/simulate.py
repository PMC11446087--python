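"""Monte Carlo validation of the analytic operating characteristics.

Each replicate draws a pilot outcome, classifies it as stop/pause/go, and
— on a pause — resolves the final decision with the eta abstraction: the
post-pause decision is a single Bernoulli event whose go-probability
depends on where the (adjusted) true parameter sits relative to the
hypotheses:

    rho' <= rho0 : go with probability eta0   (a wrong go)
    rho' >= rho1 : go with probability 1 - eta1  (stop would be wrong)
    otherwise    : go with probability 0.5    (no hypothesis is true;
                                               decision is a toss-up)

When an adjustment interval is supplied, tau is drawn uniformly on
[tau_min, tau_max] per pause (the analytic framework only ever uses the
interval endpoints; the uniform rule is this module's documented choice).

All randomness flows through one numpy Generator seeded from the spec, so
a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import binomial, normal
from .types import (
    AdjustmentInterval,
    Design,
    EndpointModel,
    Hypotheses,
    PauseDecisionModel,
    ValidationError,
)

__all__ = ["SimulationSpec", "SimulationResult", "simulate_oc"]


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: a design, a true parameter, and the decision model."""

    design: Design
    hypotheses: Hypotheses
    rho_true: float
    pause_model: PauseDecisionModel = PauseDecisionModel()
    adjustment: AdjustmentInterval = AdjustmentInterval()
    endpoint: EndpointModel = EndpointModel()
    n_reps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError(f"n_reps must be >= 1; got {self.n_reps}")


@dataclass(frozen=True)
class SimulationResult:
    """Empirical decision rates with Wald standard errors, next to the
    analytic values they estimate."""

    rates: dict[str, float]
    std_errors: dict[str, float]
    analytic: dict[str, float]
    n_reps: int
    seed: int

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "n_reps": self.n_reps,
                "seed": self.seed,
                "rates": self.rates,
                "std_errors": self.std_errors,
                "analytic": self.analytic,
            },
            indent=indent,
        )


def _post_pause_go_prob(rho_eff: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    h, pm = spec.hypotheses, spec.pause_model
    return np.where(
        rho_eff <= h.rho0 + 1e-12,
        pm.eta0,
        np.where(rho_eff >= h.rho1 - 1e-12, 1.0 - pm.eta1, 0.5),
    )


def _analytic_rates(spec: SimulationSpec) -> dict[str, float]:
    if spec.endpoint.kind == "binary":
        p_stop, p_pause, p_go = binomial.decision_probs(spec.design, spec.rho_true)
    else:
        p_stop, p_pause, p_go = normal.decision_probs_normal(
            spec.design, spec.rho_true, spec.endpoint.sigma
        )
    # expectation of the post-pause go probability over tau ~ U[min, max];
    # the go probability is piecewise constant in rho + tau, so integrate
    # each piece exactly
    adj, h, pm = spec.adjustment, spec.hypotheses, spec.pause_model
    lo, hi = spec.rho_true + adj.tau_min, spec.rho_true + adj.tau_max
    if hi == lo:
        go_prob = float(_post_pause_go_prob(np.array([lo]), spec)[0])
    else:
        width = hi - lo
        below = max(0.0, min(hi, h.rho0) - lo) / width
        above = max(0.0, hi - max(lo, h.rho1)) / width
        middle = max(0.0, 1.0 - below - above)
        go_prob = below * pm.eta0 + above * (1.0 - pm.eta1) + middle * 0.5
    return {
        "p_stop": p_stop,
        "p_pause": p_pause,
        "p_go": p_go,
        "overall_go": p_go + p_pause * go_prob,
        "overall_stop": p_stop + p_pause * (1.0 - go_prob),
    }


def simulate_oc(spec: SimulationSpec) -> SimulationResult:
    """Estimate the five decision rates of a design by simulation.

    Returns empirical frequencies over ``n_reps`` replicates with Wald
    standard errors sqrt(p(1-p)/n_reps), alongside the analytic values
    from the exact engines.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.design
    if spec.endpoint.kind == "binary":
        x0, x1 = d.require_integer_thresholds()
        est = rng.binomial(d.n, spec.rho_true, size=spec.n_reps)
    else:
        x0, x1 = d.x0, d.x1
        est = rng.normal(
            spec.rho_true, spec.endpoint.sigma / math.sqrt(d.n), size=spec.n_reps
        )
    stop = est <= x0
    go = est > x1
    pause = ~stop & ~go

    n_pause = int(pause.sum())
    post_go = np.zeros(spec.n_reps, dtype=bool)
    if n_pause:
        tau = (
            rng.uniform(spec.adjustment.tau_min, spec.adjustment.tau_max, n_pause)
            if spec.adjustment.tau_max > spec.adjustment.tau_min
            else np.full(n_pause, spec.adjustment.tau_min)
        )
        go_prob = _post_pause_go_prob(spec.rho_true + tau, spec)
        post_go[pause] = rng.random(n_pause) < go_prob

    rates = {
        "p_stop": stop.mean(),
        "p_pause": pause.mean(),
        "p_go": go.mean(),
        "overall_go": (go | post_go).mean(),
        "overall_stop": (stop | (pause & ~post_go)).mean(),
    }
    rates = {k: float(v) for k, v in rates.items()}
    ses = {
        k: math.sqrt(max(v * (1.0 - v), 0.0) / spec.n_reps) for k, v in rates.items()
    }
    return SimulationResult(rates, ses, _analytic_rates(spec), spec.n_reps, spec.seed)
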