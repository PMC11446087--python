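"""Sensitivity sweeps: optimal sample size as a function of the design
assumptions, and fixed-n trade-off tables.

Each sweep re-runs the minimum-sample-size search over a grid of one
assumption (post-pause error eta, conclusive-decision bound gamma*, or the
adjustment interval) and records the optimal design and its realised
operating characteristics in a tidy :class:`pandas.DataFrame`, one row per
grid point, sorted by the swept parameter.  Grid points that are
infeasible within n_max are recorded with missing values rather than
aborting the sweep.  Tables are written as RFC 4180 CSV so figures can be
regenerated externally.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import binomial
from .search import InfeasibleDesignError, SearchResult, SearchSettings, find_three_outcome
from .types import (
    AdjustmentInterval,
    Design,
    ErrorConstraints,
    Hypotheses,
    PauseDecisionModel,
    Problem,
)

__all__ = [
    "DEFAULT_ETA_GRID",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_TAU_MIN_GRID",
    "DEFAULT_TAU_WIDTH_GRID",
    "sweep_eta",
    "misspecified_eta_curve",
    "sweep_gamma",
    "sweep_tau",
    "fixed_n_tradeoff",
]

logger = logging.getLogger(__name__)

DEFAULT_ETA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.501, 0.05), 3))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.3, 1.001, 0.05), 3))
DEFAULT_TAU_MIN_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.101, 0.025), 4))
DEFAULT_TAU_WIDTH_GRID: tuple[float, ...] = (0.0, 0.025, 0.05)

_COLUMNS = ["n", "x0", "x1", "alpha", "beta", "gamma", "width"]


def _design_record(result: Optional[SearchResult]) -> dict:
    if result is None:
        return {c: np.nan for c in _COLUMNS}
    d, oc = result.design, result.oc
    return {
        "n": d.n, "x0": d.x0, "x1": d.x1,
        "alpha": oc.alpha, "beta": oc.beta, "gamma": oc.gamma,
        "width": d.x1 - d.x0,
    }


def _solve(problem: Problem, settings: SearchSettings) -> Optional[SearchResult]:
    try:
        return find_three_outcome(problem, settings)
    except InfeasibleDesignError as err:
        logger.warning("sweep point infeasible within n_max: %s", err)
        return None


def sweep_eta(
    problem: Problem,
    eta_grid: Sequence[float] = DEFAULT_ETA_GRID,
    settings: SearchSettings = SearchSettings(),
) -> pd.DataFrame:
    """Optimal design per post-pause error probability eta.

    The grid should stay within [0, 0.5]: eta > 0.5 models worse-than-
    random post-pause decisions, under which the two-outcome design is
    optimal anyway.
    """
    rows = []
    for eta in sorted(eta_grid):
        if not (0.0 <= eta <= 0.5):
            raise ValueError(f"eta grid values must lie in [0, 0.5]; got {eta}")
        p = dataclasses.replace(problem, pause_model=PauseDecisionModel(eta, eta))
        rows.append({"eta": eta, **_design_record(_solve(p, settings))})
    return pd.DataFrame(rows)


def misspecified_eta_curve(
    problem: Problem,
    eta_assumed_grid: Sequence[float] = DEFAULT_ETA_GRID,
    eta_true: float = 0.5,
    settings: SearchSettings = SearchSettings(),
) -> pd.DataFrame:
    """Realised error rates when the design stage assumes eta too small.

    For each assumed eta the optimal design is found, then its alpha and
    beta are re-evaluated under ``eta_true``.  A correctly specified row
    (assumed == true) shows no inflation.
    """
    true_model = PauseDecisionModel(eta_true, eta_true)
    rows = []
    for eta in sorted(eta_assumed_grid):
        p = dataclasses.replace(problem, pause_model=PauseDecisionModel(eta, eta))
        result = _solve(p, settings)
        rec = {"eta_assumed": eta, "eta_true": eta_true,
               "n": np.nan, "x0": np.nan, "x1": np.nan,
               "alpha": np.nan, "beta": np.nan}
        if result is not None:
            oc = binomial.oc_reformulated(
                result.design, problem.hypotheses, true_model, problem.adjustment
            )
            rec.update({"n": result.design.n, "x0": result.design.x0,
                        "x1": result.design.x1, "alpha": oc.alpha, "beta": oc.beta})
        rows.append(rec)
    return pd.DataFrame(rows)


def sweep_gamma(
    problem: Problem,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    settings: SearchSettings = SearchSettings(),
) -> pd.DataFrame:
    """Optimal design per conclusive-decision bound gamma*.

    gamma* = 1 imposes nothing and recovers the two-outcome optimum;
    tightening it forces a wider pause zone and a larger n.
    """
    rows = []
    for g in sorted(gamma_grid):
        c = dataclasses.replace(problem.constraints, gamma_star=g)
        p = dataclasses.replace(problem, constraints=c)
        rows.append({"gamma_star": g, **_design_record(_solve(p, settings))})
    return pd.DataFrame(rows)


def sweep_tau(
    problem: Problem,
    tau_min_grid: Sequence[float] = DEFAULT_TAU_MIN_GRID,
    width_grid: Sequence[float] = DEFAULT_TAU_WIDTH_GRID,
    settings: SearchSettings = SearchSettings(),
) -> pd.DataFrame:
    """Optimal design over a Cartesian grid of adjustment intervals.

    Sweeps the interval lower limit tau_min and the width
    tau_max - tau_min; the width-0 rows trace the known-adjustment-effect
    curve.
    """
    rows = []
    for tmin in sorted(tau_min_grid):
        for w in sorted(width_grid):
            adj = AdjustmentInterval(tmin, tmin + w)
            p = dataclasses.replace(problem, adjustment=adj)
            rows.append({
                "tau_min": tmin, "tau_width": w, "tau_max": tmin + w,
                **_design_record(_solve(p, settings)),
            })
    return pd.DataFrame(rows)


def fixed_n_tradeoff(
    n: int,
    hypotheses: Hypotheses,
    pause_model: PauseDecisionModel,
    design_list: Iterable[tuple[float, float] | Design],
    adjustment: Optional[AdjustmentInterval] = None,
) -> pd.DataFrame:
    """Operating characteristics of user-chosen threshold pairs at fixed n.

    Accepts (x0, x1) pairs or full :class:`Design` objects and tabulates
    both the classic and the reformulated error rates, to show the
    alpha/beta price of shrinking gamma at a pinned sample size.
    """
    adjustment = adjustment or AdjustmentInterval()
    rows = []
    for item in design_list:
        design = item if isinstance(item, Design) else Design(n, item[0], item[1])
        if design.n != n:
            raise ValueError(f"design {design} does not have n = {n}")
        oc = binomial.oc_reformulated(design, hypotheses, pause_model, adjustment)
        rows.append({
            "n": n, "x0": design.x0, "x1": design.x1,
            **oc.as_dict(), "width": design.x1 - design.x0,
        })
    return pd.DataFrame(rows)
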