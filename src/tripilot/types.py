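"""Domain types and validation for three-outcome pilot trial designs.

A pilot trial estimates a feasibility parameter rho (e.g. an adherence
probability) and maps the estimate to one of three outcomes via two
thresholds x0 <= x1 on the decision scale:

    stop  (red)    if  estimate <= x0
    pause (amber)  if  x0 < estimate <= x1
    go    (green)  if  estimate > x1

For binary endpoints the decision scale is the count of successes out of n
and the thresholds are integers; x0 = -1 encodes an empty stop region and
x1 = n an empty go region.  Setting x0 = x1 collapses the rule to the usual
two-outcome stop/go criterion.

A *pause* outcome is resolved later using other information; eta0 and eta1
are the probabilities that this final decision is wrong under the null and
alternative hypothesis respectively.  When an adjustment of effect
tau in [tau_min, tau_max] is made after a pause, the main-trial parameter
becomes rho + tau.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Optional

__all__ = [
    "ValidationError",
    "Hypotheses",
    "ErrorConstraints",
    "PauseDecisionModel",
    "AdjustmentInterval",
    "Design",
    "EndpointModel",
    "OperatingCharacteristics",
    "Problem",
    "validate_problem",
    "problem_from_dict",
    "problem_from_config",
    "parse_threshold",
    "reflect_hypotheses",
    "CONSTRAINT_TOL",
]

#: Absolute slack used whenever an operating characteristic is compared with
#: its nominal constraint.  Designs sitting exactly on a constraint boundary
#: are treated as feasible at this resolution; see docs/methods.md.
CONSTRAINT_TOL = 1e-5


class ValidationError(ValueError):
    """Raised when a design-problem input violates one of its invariants."""


def _check_prob(name: str, value: float, lo: float = 0.0, hi: float = 1.0,
                lo_open: bool = False, hi_open: bool = False) -> None:
    bad = (
        not math.isfinite(value)
        or value < lo or value > hi
        or (lo_open and value == lo)
        or (hi_open and value == hi)
    )
    if bad:
        lob = "(" if lo_open else "["
        hib = ")" if hi_open else "]"
        raise ValidationError(
            f"{name} must lie in {lob}{lo}, {hi}{hib}; got {value!r}"
        )


@dataclass(frozen=True)
class Hypotheses:
    """Null (poor), alternative (promising) and midpoint parameter values.

    ``rho_m`` is the borderline value at which a *pause* outcome is the
    desired result; it defaults to the midpoint (rho0 + rho1) / 2.
    """

    rho0: float
    rho1: float
    rho_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.rho0 < self.rho1):
            raise ValidationError(
                f"rho0 < rho1 required; got rho0={self.rho0}, rho1={self.rho1}"
            )
        if self.rho_m is None:
            object.__setattr__(self, "rho_m", (self.rho0 + self.rho1) / 2.0)
        if not (self.rho0 < self.rho_m < self.rho1):
            raise ValidationError(
                f"rho0 < rho_m < rho1 required; got rho_m={self.rho_m} "
                f"outside ({self.rho0}, {self.rho1})"
            )


@dataclass(frozen=True)
class ErrorConstraints:
    """Nominal bounds alpha*, beta*, gamma* on the three error rates.

    gamma* defaults to 1, the trivial constraint under which the framework
    reduces to controlling the overall type I and II error rates only.
    """

    alpha_star: float
    beta_star: float
    gamma_star: float = 1.0

    def __post_init__(self) -> None:
        _check_prob("alpha_star", self.alpha_star, lo_open=True)
        _check_prob("beta_star", self.beta_star, lo_open=True)
        _check_prob("gamma_star", self.gamma_star, lo_open=True)


@dataclass(frozen=True)
class PauseDecisionModel:
    """Probabilities of a wrong final decision after a *pause* outcome.

    eta0: probability of deciding *go* after a pause when rho' <= rho0.
    eta1: probability of deciding *stop* after a pause when rho' >= rho1.
    The conservative default eta0 = eta1 = 0.5 models a coin-flip decision.
    """

    eta0: float = 0.5
    eta1: float = 0.5

    def __post_init__(self) -> None:
        _check_prob("eta0", self.eta0)
        _check_prob("eta1", self.eta1)

    @property
    def common_eta(self) -> float:
        if self.eta0 != self.eta1:
            raise ValidationError(
                "a common eta is required here but eta0 != eta1 "
                f"({self.eta0} != {self.eta1})"
            )
        return self.eta0


@dataclass(frozen=True)
class AdjustmentInterval:
    """Bounds on the adjustment effect applied to rho after a pause."""

    tau_min: float = 0.0
    tau_max: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_min <= self.tau_max):
            raise ValidationError(
                f"0 <= tau_min <= tau_max required; got "
                f"[{self.tau_min}, {self.tau_max}]"
            )

    @property
    def is_null(self) -> bool:
        return self.tau_max == 0.0


@dataclass(frozen=True)
class Design:
    """A decision rule: sample size n and thresholds x0 <= x1.

    x0 = x1 denotes a two-outcome design (empty pause region).
    """

    n: int
    x0: float
    x1: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and self.n >= 1):
            raise ValidationError(f"n must be a positive integer; got {self.n!r}")
        if self.x0 > self.x1:
            raise ValidationError(
                f"x0 <= x1 required; got x0={self.x0}, x1={self.x1}"
            )

    def require_integer_thresholds(self) -> tuple[int, int]:
        """Return (x0, x1) as count-scale integers, validating bounds."""
        for name, x in (("x0", self.x0), ("x1", self.x1)):
            if x != int(x):
                raise ValidationError(
                    f"{name} must be an integer count for a binary endpoint; "
                    f"got {x!r}"
                )
        x0, x1 = int(self.x0), int(self.x1)
        if not (-1 <= x0 <= x1 <= self.n):
            raise ValidationError(
                f"-1 <= x0 <= x1 <= n required; got x0={x0}, x1={x1}, n={self.n}"
            )
        return x0, x1

    @property
    def is_two_outcome(self) -> bool:
        return self.x0 == self.x1


def parse_threshold(value: Any, n: int) -> int:
    """Convert a threshold given as a count, fraction string or proportion
    to the count scale.

    Accepts an integer count, a string like ``"9/15"``, or a float
    proportion p with n*p integral to within 1e-9.
    """
    if isinstance(value, str):
        if "/" in value:
            num, den = value.split("/", 1)
            value = float(num) / float(den)
        else:
            value = float(value)
    if isinstance(value, int):
        return value
    x = n * float(value)
    if abs(x - round(x)) > 1e-9:
        raise ValidationError(
            f"proportion-scale threshold {value!r} does not correspond to an "
            f"integer count for n={n} (n*p = {x})"
        )
    return int(round(x))


@dataclass(frozen=True)
class EndpointModel:
    """Sampling model for the pilot estimate.

    binary:     successes ~ Binomial(n, rho), thresholds on the count scale.
    continuous: estimate ~ Normal(rho, sigma^2 / n) with known sigma,
                thresholds on the estimate scale.

    The engines assume higher values of rho are better; lower-is-better
    problems should be reflected first (see :func:`reflect_problem`).
    """

    kind: str = "binary"
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValidationError(
                f"endpoint kind must be 'binary' or 'continuous'; got {self.kind!r}"
            )
        if self.kind == "continuous":
            if self.sigma is None or not (self.sigma > 0):
                raise ValidationError(
                    "a positive sigma is required for a continuous endpoint"
                )
        elif self.sigma is not None:
            raise ValidationError("sigma is only meaningful for a continuous endpoint")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """All decision probabilities of a design at the hypothesised values.

    Classic quantities (always at the unshifted rho0, rho1, rho_m):
      alpha_a  P(go | rho0)          beta_a  P(stop | rho1)
      lambda_  P(pause | rho0)       delta   P(pause | rho1)
      alpha_b  P(not stop | rho0)    beta_b  P(not go | rho1)
      gamma_L  P(stop | rho_m)       gamma_U P(go | rho_m)

    Reformulated overall error rates (None when not computed):
      alpha  probability of an eventual go when rho' <= rho0
      beta   probability of an eventual stop when rho' >= rho1
      gamma  gamma_L + gamma_U, chance of any conclusive decision at rho_m
    """

    alpha_a: float
    beta_a: float
    lambda_: float
    delta: float
    alpha_b: float
    beta_b: float
    gamma_L: float
    gamma_U: float
    gamma: float
    alpha: Optional[float] = None
    beta: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Problem:
    """A validated design problem: hypotheses, constraints and models."""

    hypotheses: Hypotheses
    constraints: ErrorConstraints
    pause_model: PauseDecisionModel = PauseDecisionModel()
    adjustment: AdjustmentInterval = AdjustmentInterval()
    endpoint: EndpointModel = EndpointModel()

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "rho0": self.hypotheses.rho0,
            "rho1": self.hypotheses.rho1,
            "rho_m": self.hypotheses.rho_m,
            "alpha_star": self.constraints.alpha_star,
            "beta_star": self.constraints.beta_star,
            "gamma_star": self.constraints.gamma_star,
            "eta0": self.pause_model.eta0,
            "eta1": self.pause_model.eta1,
            "tau_min": self.adjustment.tau_min,
            "tau_max": self.adjustment.tau_max,
            "kind": self.endpoint.kind,
        }
        if self.endpoint.sigma is not None:
            d["sigma"] = self.endpoint.sigma
        return d


def validate_problem(
    hypotheses: Hypotheses,
    constraints: ErrorConstraints,
    pause_model: Optional[PauseDecisionModel] = None,
    adjustment: Optional[AdjustmentInterval] = None,
    endpoint: Optional[EndpointModel] = None,
) -> Problem:
    """Cross-validate the components of a design problem and fill defaults.

    Component-level invariants are enforced by each dataclass; this checks
    the constraints that couple components:

    * binary endpoints need 0 < rho0 < rho1 < 1 and every shifted
      evaluation point (rho0 - tau_min, rho1 - tau_max) inside [0, 1];
    * adjustment-aware error rates are only derived for a common eta, so
      tau_max > 0 with eta0 != eta1 is rejected.
    """
    pause_model = pause_model or PauseDecisionModel()
    adjustment = adjustment or AdjustmentInterval()
    endpoint = endpoint or EndpointModel()

    if endpoint.kind == "binary":
        _check_prob("rho0", hypotheses.rho0, lo_open=True, hi_open=True)
        _check_prob("rho1", hypotheses.rho1, lo_open=True, hi_open=True)
        for name, point in (
            ("rho0 - tau_min", hypotheses.rho0 - adjustment.tau_min),
            ("rho1 - tau_max", hypotheses.rho1 - adjustment.tau_max),
        ):
            if not (0.0 <= point <= 1.0):
                raise ValidationError(
                    f"evaluation point {name} = {point} falls outside [0, 1]"
                )
    if not adjustment.is_null and pause_model.eta0 != pause_model.eta1:
        raise ValidationError(
            "adjustment-aware error rates require a common eta "
            f"(got eta0={pause_model.eta0}, eta1={pause_model.eta1} with "
            f"tau_max={adjustment.tau_max} > 0)"
        )
    return Problem(hypotheses, constraints, pause_model, adjustment, endpoint)


def problem_from_dict(d: dict[str, Any]) -> Problem:
    """Build a validated :class:`Problem` from a flat key/value mapping."""
    known = {
        "rho0", "rho1", "rho_m", "alpha_star", "beta_star", "gamma_star",
        "eta", "eta0", "eta1", "tau_min", "tau_max", "kind", "sigma",
    }
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown problem fields: {sorted(unknown)}")
    for req in ("rho0", "rho1", "alpha_star", "beta_star"):
        if req not in d:
            raise ValidationError(f"missing required field: {req}")
    if "eta" in d and ("eta0" in d or "eta1" in d):
        raise ValidationError("give either eta or (eta0, eta1), not both")
    eta0 = d.get("eta0", d.get("eta", 0.5))
    eta1 = d.get("eta1", d.get("eta", 0.5))
    return validate_problem(
        Hypotheses(d["rho0"], d["rho1"], d.get("rho_m")),
        ErrorConstraints(d["alpha_star"], d["beta_star"], d.get("gamma_star", 1.0)),
        PauseDecisionModel(eta0, eta1),
        AdjustmentInterval(d.get("tau_min", 0.0), d.get("tau_max", 0.0)),
        EndpointModel(d.get("kind", "binary"), d.get("sigma")),
    )


def problem_from_config(path: str) -> Problem:
    """Read a flat JSON or YAML configuration file into a Problem."""
    with open(path) as fh:
        text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path!r} must hold a flat mapping")
    return problem_from_dict(data)


def reflect_hypotheses(
    rho0: float,
    rho1: float,
    rho_m: Optional[float] = None,
    kind: str = "binary",
) -> Hypotheses:
    """Reflect a lower-is-better problem into the higher-is-better
    orientation the engines assume.

    For a lower-is-better parameter the promising value rho1 lies *below*
    the poor value rho0.  Binary endpoints map rho -> 1 - rho (an observed
    count x maps to n - x); continuous endpoints map rho -> -rho.  The
    reflected null is again the poor value and sits below the alternative.
    """
    if not (rho1 < rho0):
        raise ValidationError(
            "reflect_hypotheses expects a lower-is-better problem with "
            f"rho1 < rho0; got rho0={rho0}, rho1={rho1}"
        )
    if kind == "binary":
        return Hypotheses(1 - rho0, 1 - rho1,
                          None if rho_m is None else 1 - rho_m)
    return Hypotheses(-rho0, -rho1, None if rho_m is None else -rho_m)
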