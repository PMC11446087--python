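# Methods

## Model

A single-arm, single-stage pilot estimates a feasibility parameter ρ.
For a binary endpoint the number of successes is X ~ Binomial(n, ρ) and
decisions are made on the count scale; for a continuous endpoint the
estimate is ρ̂ ~ Normal(ρ, σ²/n) with σ treated as known.  The decision
rule is

    stop iff ρ̂ ≤ x0,   pause iff x0 < ρ̂ ≤ x1,   go iff ρ̂ > x1,

with the conventions x0 = −1 (binary) or −∞ (continuous) for an empty stop
region and x1 = n or the right-hand cap for an empty go region.  x0 = x1
is the two-outcome special case.  Note the boundary placement: the stop
region is closed on the right and the go region open on the left.  The
alternative display convention (go at ρ̂ ≥ x1) is an off-by-one relabeling
for binary endpoints and makes no difference to any optimal sample size;
we fix this one because it matches the probability definitions used
throughout the operating characteristics.

A *pause* is resolved afterwards by people and data outside the model.
This process is abstracted into two probabilities: η0, the chance of a
wrong *go* after a pause when the (possibly adjusted) parameter is at or
below ρ0, and η1, the chance of a wrong *stop* when it is at or above ρ1.
η0 = η1 = 0.5 — the default — models an uninformative coin flip and is the
conservative choice; values below 0.5 require a genuine auxiliary source
of information (e.g. a correlated secondary outcome) and should be
justified, because assuming them wrongly inflates the realised error
rates substantially (the misspecification sweep quantifies this).

An adjustment made after a pause (e.g. switching to phone follow-up)
shifts the main-trial parameter to ρ' = ρ + τ with τ known only up to
0 ≤ τmin ≤ τ ≤ τmax.  The overall error rates are then

    α = max[ P(ρ̂ > x1 | ρ0),
             η P(x0 < ρ̂ ≤ x1 | ρ0 − τmin) + P(ρ̂ > x1 | ρ0 − τmin) ],
    β = P(ρ̂ ≤ x0 | ρ1 − τmax) + η P(x0 < ρ̂ ≤ x1 | ρ1 − τmax),

the worst cases over ρ of the misleading-decision probabilities; the
maxima sit at the stated evaluation points by stochastic monotonicity of
the binomial/normal families, so the engines evaluate them there directly
rather than re-maximising numerically.  These formulas are derived for a
common η; the package rejects τmax > 0 combined with η0 ≠ η1.  With
τmin = τmax = 0 they reduce to α = αa + η0λ, β = βa + η1δ, where αa, βa,
λ, δ are the immediate-go, immediate-stop and pause probabilities at the
unshifted hypotheses.

The third operating characteristic, γ = γL + γU = P(stop | ρm) +
P(go | ρm), is the probability of any conclusive decision at a borderline
midpoint ρm (default (ρ0 + ρ1)/2).  γ is always computed at the unshifted
ρm with no η weighting: it describes the pilot's own verdict, not the
post-pause process.  Constraining γ ≤ γ* < 1 is what forces a design to
keep a wide amber zone; γ* = 1 disables the constraint.

## Search procedure

`find_three_outcome` minimises n subject to α ≤ α*, β ≤ β*, γ ≤ γ*.  For
each n ascending from n_min:

1. candidate upper thresholds are those with P(ρ̂ > x1 | ρ0) ≤ α*;
2. for each candidate, x0 is set to the value that maximises α while
   keeping α ≤ α*, found by inverting the CDF.  For binary endpoints this
   is the smallest integer x0 (α is non-increasing in x0); for continuous
   endpoints the inversion is exact and α = α* is achieved;
3. the selected design at this n is the largest x1 whose derived x0
   satisfies x0 ≤ x1 and β ≤ β*;
4. the first n whose selected design also has γ ≤ γ* is returned.

Step 3's choice also minimises γ among the (α, β)-feasible designs at that
n — raising x1 lowers both γU directly and γL through the relaxed x0 — so
the procedure and the exhaustive `brute_force_min_n` return the same
minimal n; the test suite verifies this equivalence on randomized
problems.  Ties among thresholds are broken toward the largest x1 and then
the α-maximising (smallest) x0; the classic Sargent-/Storer-style searches
break ties toward the largest x1 then the largest x0.  These tie-breaks
are this package's documented choices; optimal n does not depend on them.

The search ascends linearly with no approximation-based warm start;
exhaustive enumeration to n ≈ 600 costs well under a second with
vectorised CDF tables, and linear ascent makes minimality trivial to
argue.  Infeasibility within n_max raises an error carrying the
least-violating candidate found, for diagnosis.

## Numerical choices

- Binary tail probabilities come from exact binomial CDF evaluations; no
  normal approximation or continuity correction is used anywhere in the
  binary engine.
- **Constraint slack.** A design is deemed feasible when each operating
  characteristic is within 1e-5 of its nominal level.  Error rates of
  useful designs sit exactly on a constraint boundary by construction
  (step 2 pushes α to α*; step 3 pushes β toward β*), and reference
  designs in the literature for this framework are reported as feasible
  when an error rate equals its nominal level at about this resolution.
  The slack is far below the 2-decimal resolution at which error rates
  are specified and reported, and in every verified problem the nearest
  competing design violates its constraint by at least 1.5e-3, so the
  slack never admits a materially infeasible design.  It is fixed
  package-wide (`CONSTRAINT_TOL`) and is not user-tunable.
- Continuous thresholds are resolved by Brent root-finding to 1e-8 on the
  estimate scale; β(x1) is increasing in x1 (with x0 re-derived), which
  makes the largest feasible x1 a simple root.  When β never reaches β*
  (very small η), the go threshold is capped at the top of the bracket;
  the returned design still satisfies all constraints.
- Proportion-scale threshold input ("9/15") is converted to the count
  scale with an exactness check (n·p must be integral to 1e-9).
- Lower-is-better endpoints are reflected (ρ → 1−ρ binary, ρ → −ρ
  continuous) at the interface via `reflect_hypotheses`; the engines only
  ever see the higher-is-better orientation.

## Simulation model

`simulate_oc` draws pilot outcomes, classifies them, and resolves each
pause with a single Bernoulli event whose go-probability is η0 when
ρ + τ ≤ ρ0, 1 − η1 when ρ + τ ≥ ρ1, and 0.5 in between (no hypothesis is
true; the abstraction has nothing sharper to say there).  τ is drawn
uniformly on [τmin, τmax] per pause — the analytic framework uses only the
interval endpoints, so the uniform rule is a simulation-side choice.  This
deliberately simulates the η *abstraction*, not a mechanistic correlated
secondary endpoint: agreement validates the analytic algebra (the
decomposition of overall rates and the shifted evaluation points), not the
realism of η itself.  Randomness flows through one `numpy` Generator with
an explicit integer seed; runs are bit-for-bit reproducible.

Default problem sizes: 1e5 replicates per validation run, which puts the
Monte Carlo standard error near 1.5e-3 and makes the 3-standard-error
agreement checks sharp enough to catch any off-by-one threshold error.

## Limitations and scope

- One progression criterion at a time; multivariate criteria, Bayesian
  formulations, two-stage and multi-arm designs are out of scope.
- σ is a known input for continuous endpoints; no t-correction and no
  variance-targeting sample-size rules.
- The adjustment model is additive with a known interval; nothing is
  learned about τ within the model, and γ has no adjustment-aware
  variant.
- The η abstraction compresses the entire post-pause decision process
  into one number.  Passing Monte Carlo checks therefore says the
  arithmetic is right under that abstraction, not that η = 0.5 (or any
  value) describes a given trial team.
- Optimality is minimal n subject to error-rate constraints; expected-
  sample-size or admissible-design criteria are not considered.
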