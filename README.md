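# tripilot

Optimal stop/pause/go progression criteria and sample size for external
pilot trials.

External pilot trials assess whether a planned definitive RCT is feasible
— can we recruit, will participants adhere, will they stay in follow-up?
Progression is usually governed by pre-specified *progression criteria*,
very often a three-outcome "traffic light" rule on a feasibility estimate
ρ̂ with thresholds x0 ≤ x1:

- **red / stop** if ρ̂ ≤ x0,
- **amber / pause** if x0 < ρ̂ ≤ x1 — the decision is finished later, using
  other data, stakeholder discussion, or after adjusting the intervention,
- **green / go** if ρ̂ > x1.

`tripilot` treats such a rule as a three-outcome hypothesis test of a null
(poor) value ρ0 against an alternative (promising) value ρ1 and finds the
smallest sample size n, with thresholds, controlling the *overall*
frequentist error rates of the eventual decision:

```
α = P(eventually go  | ρ' ≤ ρ0) ≤ α*
β = P(eventually stop| ρ' ≥ ρ1) ≤ β*
γ = P(stop or go     | ρ = ρm ) ≤ γ*
```

Eventual decisions include those made after a pause, which are wrong with
probability η (η = 0.5 ≡ guessing, the conservative default), and ρ' = ρ + τ
allows for an adjustment with effect τ known up to an interval
[τmin, τmax] applied after a pause.  With no adjustment the rates decompose
as α = αa + η0·λ and β = βa + η1·δ, where (αa, βa, λ, δ) are the classic
immediate-go/stop and pause probabilities; with an adjustment,

```
α = max[ P(ρ̂ > x1 | ρ0),  η·P(x0 < ρ̂ ≤ x1 | ρ0 − τmin) + P(ρ̂ > x1 | ρ0 − τmin) ]
β = P(ρ̂ ≤ x0 | ρ1 − τmax) + η·P(x0 < ρ̂ ≤ x1 | ρ1 − τmax).
```

γ = γL + γU caps the chance of a *conclusive* decision when the truth sits
at the borderline midpoint ρm (default (ρ0+ρ1)/2), which is how a design is
forced to keep a genuine amber zone.  All binary-endpoint computations are
exact binomial; continuous endpoints use a normal model with known σ.  The
classic four-constraint phase II searches (Sargent-style and Storer-style)
are included for comparison, as are sensitivity sweeps, a brute-force
search oracle, and a Monte Carlo validator.

## Worked example

Adherence is feasible enough at ρ1 = 0.7 and inadequate at ρ0 = 0.5; we
want α ≤ 0.05, β ≤ 0.1, and a coin-flip model (η = 0.5) for decisions made
after an amber result:

```
$ tripilot design --rho0 0.5 --rho1 0.7 --alpha 0.05 --beta 0.1 --eta 0.5
design: n = 52, x0 = 31, x1 = 32
  red   (stop):  estimate <= 31
  amber (pause): 31 < estimate <= 32
  green (go):    estimate > 32
operating characteristics:
  alpha_a      0.035
  beta_a       0.072
  lambda_      0.028
  delta        0.049
  alpha_b      0.063
  beta_b       0.120
  gamma_L      0.530
  gamma_U      0.360
  gamma        0.890
  alpha        0.049
  beta         0.096
  alpha_slack  0.001
  beta_slack   0.004
  gamma_slack  0.110
```

Recruit 52 participants; stop at ≤ 31 adherers, go at ≥ 33, and pause on
exactly 32.  The realised overall error rates are α = 0.049 and β = 0.096,
inside the nominal levels.  (The plain two-outcome design needs n = 53 —
with η = 0.5 the amber zone buys almost nothing, which is the central
practical message: three-outcome criteria cost, rather than save, sample
size unless post-pause decisions are genuinely informative.)

Asking additionally for γ ≤ 0.4 at the midpoint ρm = 0.6 — so that a
borderline truth usually produces an amber result for stakeholders to
deliberate on — raises the price to n = 98:

```
$ tripilot sweep --sweep gamma --grid 0.4,1.0 --rho0 0.5 --rho1 0.7 \
      --alpha 0.05 --beta 0.1
gamma_star,n,x0,x1,alpha,beta,gamma,width
0.4,98,55,64,0.047611825004777786,0.0924169086041095,0.36633902251338124,9
1.0,52,31,32,0.04918532422024591,0.09593140272671888,0.8897466314945532,1
```

The same interface evaluates user-chosen designs (`tripilot evaluate`),
sweeps η or the adjustment interval, and cross-checks any design by
simulation (`tripilot simulate`).  Everything is also available as a
library: `find_three_outcome`, `find_two_outcome`, `find_sargent_original`,
`find_storer_original`, `oc_reformulated`, `sweep_*`, `simulate_oc`.

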