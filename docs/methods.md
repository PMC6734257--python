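# Methods

## Model and assumptions

The package implements a three-period decision model of adherence to a
prophylactic therapy. An individual in an asymptomatic state accepts a
treatment contract at t = 0 and learns their cost type c; decides at t = 1
to adhere (bearing c) or not; and at t = 2 transitions to "healthy" with
probability p_A (adherent) or p_NA (non-adherent), evaluated with
instantaneous utilities u_h > u_s. Discounting is quasi-hyperbolic: the
current period has weight 1 and periods k ahead have weight βδ^k, so β < 1
expresses present bias and produces time-inconsistent choices. Individuals
are otherwise fully rational expected-utility maximizers; the horizon is
fixed at three periods and no belief updating, heterogeneous preferences
within a scenario, or additional health states are modeled.

The decision reduces to threshold rules. Writing Δp = p_A − p_NA and
Δu = u_h − u_s, the planned (t = 0 perspective) and actual (t = 1
perspective) criteria are c ≤ δΔpΔu + p_D·b and c ≤ βδΔpΔu + p_D·b, where
b is a monetary bonus for adherence and p_D the probability that an
improper claim by a non-adherent is detected. Adherence probabilities are
the cost CDF at these thresholds; their difference is the self-control gap.
Ties at the threshold count as adherent, matching the weak inequality in
the criterion. Thresholds may be negative (large co-payments) or exceed the
support; probabilities clamp through the CDF rather than erroring.

Two deliberate conventions close gaps the model statement leaves open:

- **Units.** Monetary quantities (b, c, societal costs) and utilities share
  one linear dimensionless scale, i.e. the marginal utility of money is 1.
- **Co-payments.** b < 0 represents a co-payment with unchanged detection
  semantics: the non-adherent's period-1 receipt is (1 − p_D)·b whatever
  the sign of b, so the simulator draws one detection Bernoulli per
  non-adherent and pays (1 − detected)·b.
- **Sophistication.** Whether the t = 0 self anticipates its own present
  bias is not modeled; the two perspectives are computed as stated, without
  a sophistication parameter.

## Welfare

Both welfare components are expected net benefits of the contract relative
to rejection, from the t = 1 perspective (a rejector follows the
non-adherent health path and claims no bonus). Individual welfare is
W_I = −∫₀^θ c f dc + F(θ)·θ + (1 − p_D)·b with θ the actual threshold;
society's component nets therapy expenses C_A/C_NA, the follow-up cost C_F
of period-2 illness (discounted by δ; society applies no present bias — its
printed objective carries δ only, and the package follows that exactly,
adding no alternative long-run normative criterion), and the bonus payout
with administrative overhead λ per unit paid. The bonus itself is a pure
transfer: with λ = 0, total welfare W = W_I + W_S depends on b only through
the adherence response.

E[c | adherent] is defined as 0 when nobody adheres (the defining ratio is
0/0 there); W_I then correctly evaluates to (1 − p_D)·b.

Under uniform costs on [0, c_max] every quantity is piecewise closed-form;
the package evaluates uniform scenarios through those closed forms and any
other `CostModel` through its `partial_mean` contract, which defaults to
adaptive quadrature (absolute tolerance 1e-10, support truncated where the
CDF reaches 1 − 1e-12). `individual_welfare_quadrature` deliberately
bypasses all closed forms so tests can compare two independent routes.

## Optimal bonus

Under full observability (p_D = 1), uniform costs and an interior threshold
(θ < c_max), W is a concave quadratic in b and the first-order condition
gives b* = [δΔpC_F − (C_A − C_NA) − βδΔpΔu·λ]/(1 + 2λ), valid when the
overhead condition λ < [δΔpC_F − (C_A − C_NA)]/(βδΔpΔu) holds (strict, with
the β = 0 limit handled by requiring a positive numerator). Outside that
domain (partial observability, boundary solutions, negative closed-form
candidates) `optimal_bonus` maximizes W numerically: a 10,000-point grid on
[0, b_full + support width], where b_full is the bonus driving full
adherence (W is non-increasing beyond it), followed by bounded scalar
refinement to 1e-8. Boundary solutions are returned with `interior=False`
rather than truncated, since the model states no truncation intent; an
infeasible overhead raises a warning and still returns the maximizer
(typically b = 0), so callers get a structured answer rather than an
exception.

## Synthetic populations

`simulate_population` draws n cost types, applies the perspective-1
threshold rule, draws period-2 health Bernoullis, and, for non-adherents,
detection Bernoullis. All agents accept the contract (the adherence concept
presumes acceptance; rejection enters only as the welfare baseline). One
root seed is spawned into three independent child streams (costs, health,
detection), so enabling detection draws never perturbs the cost draws, and
results are bit-reproducible per seed.

Per-agent welfare contributions are computed against the analytic rejection
baseline. By default the period-2 payoff enters in expectation
(βδΔpΔu for adherents; Δp·δ·C_F of averted follow-up cost on the societal
side), a variance-reduction choice that leaves all estimators unbiased
because the health draw is independent of everything else conditional on
the decision; `realized_outcomes=True` switches to fully realized period-2
payoffs for stress testing. What the simulator emulates is therefore the
model's own data-generating process — it validates the algebra, not the
model: passing Monte Carlo checks say nothing about whether real cohorts
follow β–δ decision rules, have uniform cost types, or face constant
transition probabilities.

Default problem sizes: 100,000 agents per simulation check and 20 seeds ×
11 scenarios for the convergence suite, giving three-standard-error checks
with adherence SEs near 0.0016.

## Comparative statics

The closed-form derivatives dF/db = f(θ)·p_D and, for the no-incentive
model, dW_S/dβ = −f(βδΔpΔu)·δΔpΔu·(C_A − C_NA − Δp·δ·C_F) are verified
against central finite differences (step 1e-6, one-sided at domain
boundaries such as β = 1; relative tolerance 1e-4). The adherence
derivative raises an error when the threshold sits at a support boundary,
where F has a kink. Sweeps re-validate scenario invariants at every grid
point and skip invalid points with a warning instead of aborting (β = 0 is
allowed, per the welfare-limit convention above).

## Numerical choices and limitations

- Tolerances: closed form vs quadrature 1e-9; threshold/utility
  indifference identity 1e-12; optimal-bonus closed form vs independent
  grid maximization 1e-6; Monte Carlo checks at |z| ≤ 3.
- Serialized CLI output rounds to 12 significant digits; simulation seeds
  are mandatory (no wall-clock seeding).
- Only the uniform cost family ships as a concrete distribution; any
  non-negative distribution can be plugged in through the `CostModel`
  contract, at quadrature accuracy.
- Heterogeneity is confined to the cost type: one (β, δ) pair per scenario.
  Budget-constrained or type-targeted bonus schemes, repeated multi-period
  adherence decisions, and insurer-side contract design are out of scope.
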