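"""Minimum-sample-size searches, checked against exhaustive oracles.

Frozen expected values were computed with independent brute-force
enumerations (plain double loops over all thresholds, no CDF tables).
"""

import dataclasses

import numpy as np
import pytest

from tripilot import (
    AdjustmentInterval,
    CONSTRAINT_TOL,
    Design,
    ErrorConstraints,
    Hypotheses,
    InfeasibleDesignError,
    PauseDecisionModel,
    SearchSettings,
    brute_force_min_n,
    find_sargent_original,
    find_storer_original,
    find_three_outcome,
    find_two_outcome,
    oc_reformulated,
    validate_problem,
    x0_from_alpha,
)
from conftest import random_problem


class TestTwoOutcome:
    def test_running_example_needs_53(self, adherence_hypotheses):
        r = find_two_outcome(adherence_hypotheses, 0.05, 0.1)
        assert r.design.n == 53
        assert r.design.x0 == r.design.x1 == 32

    def test_relaxed_beta_matches_enumeration(self, adherence_hypotheses):
        # frozen from a double-loop enumeration over n <= 100, all x
        r = find_two_outcome(adherence_hypotheses, 0.05, 0.2)
        assert (r.design.n, r.design.x0) == (37, 23)

    def test_vacuous_constraints_return_n_min(self, adherence_hypotheses):
        r = find_two_outcome(adherence_hypotheses, 1.0, 1.0,
                             SearchSettings(n_min=4, n_max=50))
        assert r.design.n == 4

    def test_infeasible_reports_best_candidate(self, adherence_hypotheses):
        with pytest.raises(InfeasibleDesignError) as exc:
            find_two_outcome(adherence_hypotheses, 1e-4, 1e-4,
                             SearchSettings(n_max=20))
        assert exc.value.best is not None
        assert exc.value.violation > 0


class TestX0FromAlpha:
    def test_eta_zero_gives_sentinel(self, adherence_hypotheses):
        x0 = x0_from_alpha(
            30, 20, adherence_hypotheses, PauseDecisionModel(0.0, 0.0),
            AdjustmentInterval(), alpha_star=0.25,
        )
        assert x0 == -1

    def test_linear_scan_oracle_n30(self, adherence_hypotheses):
        # frozen: smallest x0 in {-1..20} with alpha <= 0.25 is 15
        x0 = x0_from_alpha(
            30, 20, adherence_hypotheses, PauseDecisionModel(0.5, 0.5),
            AdjustmentInterval(), alpha_star=0.25,
        )
        assert x0 == 15

    def test_n52_threshold_pair(self, adherence_hypotheses):
        # at n=52 the smallest direct-go-feasible x1 is 32; x0 sits just below
        x0 = x0_from_alpha(
            52, 32, adherence_hypotheses, PauseDecisionModel(0.5, 0.5),
            AdjustmentInterval(), alpha_star=0.05,
        )
        assert x0 == 31

    def test_precondition_violation_raises(self, adherence_hypotheses):
        with pytest.raises(Exception, match="x1 too small"):
            x0_from_alpha(
                30, 10, adherence_hypotheses, PauseDecisionModel(0.5, 0.5),
                AdjustmentInterval(), alpha_star=0.05,
            )


def _problem(hyp, alpha=0.05, beta=0.1, gamma=1.0, eta=0.5, tau=(0.0, 0.0)):
    return validate_problem(
        hyp, ErrorConstraints(alpha, beta, gamma),
        PauseDecisionModel(eta, eta), AdjustmentInterval(*tau),
    )


class TestThreeOutcome:
    def test_guessing_after_pause_needs_52(self, adherence_hypotheses):
        r = find_three_outcome(_problem(adherence_hypotheses))
        assert r.design.n == 52
        assert (r.design.x0, r.design.x1) == (31, 32)

    def test_informative_pause_decisions_shrink_n(self, adherence_hypotheses):
        r = find_three_outcome(_problem(adherence_hypotheses, eta=0.2))
        assert r.design.n == 41

    def test_conclusive_bound_inflates_n(self, adherence_hypotheses):
        r = find_three_outcome(_problem(adherence_hypotheses, gamma=0.4))
        assert r.design.n == 98

    def test_vacuous_constraints_return_n_min(self, adherence_hypotheses):
        r = find_three_outcome(
            _problem(adherence_hypotheses, alpha=1.0, beta=1.0),
            SearchSettings(n_min=3, n_max=40),
        )
        assert r.design.n == 3

    def test_returned_design_meets_constraints(self, adherence_hypotheses):
        for kwargs in (dict(), dict(eta=0.2), dict(gamma=0.4),
                       dict(tau=(0.0, 0.05)), dict(tau=(0.05, 0.05))):
            p = _problem(adherence_hypotheses, **kwargs)
            r = find_three_outcome(p)
            oc = oc_reformulated(r.design, p.hypotheses, p.pause_model, p.adjustment)
            assert oc.alpha <= p.constraints.alpha_star + CONSTRAINT_TOL
            assert oc.beta <= p.constraints.beta_star + CONSTRAINT_TOL
            assert oc.gamma <= p.constraints.gamma_star + CONSTRAINT_TOL

    def test_infeasible_within_n_max(self, adherence_hypotheses):
        with pytest.raises(InfeasibleDesignError):
            find_three_outcome(_problem(adherence_hypotheses),
                               SearchSettings(n_max=30))


class TestClassicSearches:
    def test_sargent_running_example_needs_42(self, adherence_hypotheses):
        r = find_sargent_original(adherence_hypotheses, 0.05, 0.1, 0.1, 0.1)
        assert r.design.n == 42
        oc = r.oc
        assert oc.alpha_a <= 0.05 + CONSTRAINT_TOL
        assert oc.beta_a <= 0.1 + CONSTRAINT_TOL
        assert oc.lambda_ <= 0.1 + CONSTRAINT_TOL
        assert oc.delta <= 0.1 + CONSTRAINT_TOL

    def test_sargent_enumeration_oracle(self):
        # frozen from exhaustive (n, x0, x1) enumeration to n = 200
        r = find_sargent_original(Hypotheses(0.2, 0.4), 0.15, 0.15, 0.15, 0.15)
        assert (r.design.n, r.design.x0, r.design.x1) == (17, 4, 5)

    def test_no_pause_allowed_reduces_to_two_outcome(self, adherence_hypotheses):
        r = find_sargent_original(adherence_hypotheses, 0.05, 0.1, 0.0, 0.0)
        two = find_two_outcome(adherence_hypotheses, 0.05, 0.1)
        assert r.design.n == two.design.n
        assert r.design.is_two_outcome

    def test_storer_near_vacuous_returns_n_min(self, adherence_hypotheses):
        r = find_storer_original(adherence_hypotheses, 1.0, 1.0, 0.5, 0.5,
                                 SearchSettings(n_min=1, n_max=20))
        assert r.design.n == 1

    def test_storer_enumeration_oracle(self, adherence_hypotheses):
        # frozen from exhaustive enumeration to n = 300
        r = find_storer_original(adherence_hypotheses, 0.3, 0.3, 0.2, 0.2)
        assert (r.design.n, r.design.x0, r.design.x1) == (49, 26, 32)

    def test_storer_two_outcome_is_always_conclusive(self, adherence_hypotheses):
        # gamma_L + gamma_U = 1 whenever x0 = x1, so bounds below 1/2 on both
        # tails force a genuine pause region
        r = find_storer_original(adherence_hypotheses, 0.3, 0.3, 0.2, 0.2)
        assert r.design.x1 > r.design.x0
        assert r.oc.gamma == pytest.approx(r.oc.gamma_L + r.oc.gamma_U)


class TestBruteForceOracle:
    def test_agrees_with_procedure_on_randomized_problems(self):
        rng = np.random.default_rng(20240917)
        settings = SearchSettings(n_max=80)
        checked = 0
        for _ in range(12):
            p = random_problem(rng)
            try:
                fast = find_three_outcome(p, settings)
            except InfeasibleDesignError:
                with pytest.raises(InfeasibleDesignError):
                    brute_force_min_n(p, settings)
                continue
            slow = brute_force_min_n(p, settings)
            assert slow.design == fast.design, p
            checked += 1
        assert checked >= 6

    def test_infeasible_at_tiny_n_max(self, adherence_hypotheses):
        with pytest.raises(InfeasibleDesignError):
            brute_force_min_n(_problem(adherence_hypotheses, alpha=1e-4, beta=1e-4),
                              SearchSettings(n_max=20))


class TestMonotonicity:
    def test_n_non_increasing_in_eta(self, adherence_hypotheses):
        ns = [find_three_outcome(_problem(adherence_hypotheses, eta=e)).design.n
              for e in (0.2, 0.35, 0.5)]
        assert ns == sorted(ns)

    def test_n_non_increasing_in_gamma_star(self, adherence_hypotheses):
        ns = [find_three_outcome(_problem(adherence_hypotheses, gamma=g)).design.n
              for g in (0.5, 0.7, 1.0)]
        assert ns == sorted(ns, reverse=True)

    def test_n_non_decreasing_in_tau_max(self, adherence_hypotheses):
        ns = [find_three_outcome(_problem(adherence_hypotheses, tau=(0.0, t))).design.n
              for t in (0.0, 0.025, 0.05)]
        assert ns == sorted(ns)

    def test_n_non_decreasing_in_interval_width(self, adherence_hypotheses):
        ns = [find_three_outcome(
            _problem(adherence_hypotheses, tau=(0.02, 0.02 + w))).design.n
            for w in (0.0, 0.02, 0.04)]
        assert ns == sorted(ns)

    def test_three_outcome_never_beats_two_outcome_at_eta_half(
        self, adherence_hypotheses
    ):
        three = find_three_outcome(_problem(adherence_hypotheses)).design.n
        two = find_two_outcome(adherence_hypotheses, 0.05, 0.1).design.n
        assert three <= two
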