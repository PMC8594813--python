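# Methods

## Model and assumptions

The package treats adverse evolution (resistance spread) as a regime shift:
a pristine state with annual profit Π(γ) under stewardship action γ, and an
evolved state with constant annual profit Π̄. The shift is a single
irreversible jump; once evolved, the manager stops stewarding. Evolutionary
uncertainty enters through κ(γ), the annual probability the shift does not
occur. Only the *excess* stream E(γ) = Π(γ) − Π̄ is valued (the baseline Π̄
is earned regardless), and its present value factorizes as E(γ)·L(γ) with
effective life span L(γ) = 1/(1 − δκ(γ)), δ = 1/(1+r). The model therefore
assumes: annual compounding; a stationary action repeated every pristine
year; constant Π̄; and max_γ Π(γ) > Π̄ (evolution is economically adverse —
validated at construction).

The "no stewardship" reference γ₀ is *defined* as the E-maximizer. The
constructor recomputes it from Π (ties break toward smaller γ); pinning a
different γ₀ produces a warning rather than an error, since users may want
to study a conventional reference. For continuous action sets γ₀ is located
on a 1001-point probe grid, which is exact for the monotone profit families
shipped here.

## Decision conventions

"Beneficial" uses the strict inequality B > C; an exact tie (relative
tolerance 1e-9 — all model quantities are O(1)–O(10³)) is flagged and
reported as not beneficial. When E(γ) ≤ 0 the percentage-cost form divides
by a non-positive number, so the decision falls back to the direct
comparison V(γ) > V(γ₀) with `percentage_form_valid=False`; the percentage
fields are NaN rather than misleading numbers. The expanded form
(in δ, κ, Π directly) requires Π(γ) > Π̄ and is algebraically identical —
the equivalence is property-tested against random scenarios.

Profit and persistence curves are supplied as named serializable families
(constant, linear, logistic, tabulated-with-linear-interpolation) so every
scenario round-trips through YAML/JSON; arbitrary callables are accepted
programmatically but refuse to serialize.

## Optimization

Continuous action sets are optimized by grid search (default 1001 points)
optionally refined by bounded scalar minimization around the best bracket to
1e-8 in γ. Grid-first is deliberate: tabulated inputs make V(γ) piecewise
linear and derivative-based methods unreliable. Argmax ties break toward
smaller γ (less stewardship), mirroring the strict-inequality convention.
The critical discount factor uses the closed form
δ* = c/(κ(γ) − κ(γ₀) + c·κ(γ)); feasibility requires
(κ(γ) − κ(γ₀))/(1 − κ(γ)) > c, otherwise even δ → 1 cannot pay for the
action and an explicit infeasible result (not an exception) is returned.

## Bt-refuge closed forms

With γ₀ = 0 and the farmer reverting to non-Bt corn after resistance, the
percentage cost reduces to γ/(1−γ) — independent of per-acre prices, which
is why optimal refuge sizes are insensitive to costs and revenues. The
calendar-year conversion models efficacy as a deterministic window (κ = 1
until the crop fails at year T, then 0), giving the finite-horizon life
span L_fin(T) = (1 − δ^T)/(1 − δ); the break-even duration solves
L_fin(M)/L_fin(N) = 1/(1−γ) in closed form and is reported both as a real
number and as its integer ceiling. The default rate for the canonical
26%/15-year comparison is r = 0.04/year, chosen as a standard agricultural
planning rate that places the break-even near 23.4 years; a 3–5% band moves
it between ~22.4 and ~24.8. Note the direction: the required calendar
duration *increases* with r, because heavier discounting shrinks the value
of the added years. The alternative-land-use variant replaces the
post-resistance baseline with an outside option Π_alt; the cost is
increasing in Π_alt and returns +inf once the outside option absorbs the
whole excess stream.

## Simulation

Profits accrue at the start of each year; the evolution draw happens at
year end, so every realization contains the leading undiscounted E and
shift years are ≥ 1 (geometric with success probability 1 − κ). The default
truncation horizon is the smallest T with (δκ)^T < 1e-10, and a smaller
user horizon triggers a warning carrying the analytic bias bound. One
seeded `numpy` generator per call, replicates drawn as a single vectorized
block — bit-identical results for a fixed seed. The reversible extension is
a generic two-state Markov chain (pristine→evolved with probability 1−κ,
evolved→pristine with probability ρ, zero excess while evolved); its exact
value solves the 2×2 linear system V_p = E + δ(κV_p + (1−κ)V_e),
V_e = δ(ρV_p + (1−ρ)V_e), which the simulator is validated against.

## Games, stability, dynamics

The manager game treats p, the stewarding fraction, as a continuum.
Interior Nash equilibria are roots of g(p) = B(p) − C(p), found by a
sign-change scan (default resolution 1e-3) polished with Brent's method to
1e-10; p = 0 is an equilibrium iff g(0) ≤ 0 and p = 1 iff g(1) ≥ 0.
Convergence stability is read from the sign pattern: an interior root with
g passing + → − is stable, a tangency (no sign change) is "marginal" and
excluded from the stable set, and strict boundary inequalities make corners
stable. A stretch of the scan with |g| < 1e-9 is reported as a continuum of
equilibria rather than an arbitrary point. Feedback classification is the
monotonicity of g on a grid (decreasing → negative/substitutes, increasing
→ positive/complements, otherwise mixed; a constant g is degenerate and
labeled weakly negative with a flat flag).

Best-response dynamics use the sign-smoothed update
p ← clip(p + step·tanh(g/ε), 0, 1) with ε = 1e-3, and halve the step each
time g changes sign. The halving is what makes the iteration contract onto
interior roots: with a fixed step the map's slope at a root is 1 + step·g′/ε,
far outside the unit circle for any sensible step, producing a permanent
limit cycle of amplitude ≈ step. Only the limit set matters here, and with
halving it provably coincides with the convergence-stable equilibria (and is
tested to, on random monotone games).

## Policy

A subsidy S is paid per stewarding year in the pristine state and enters
the steward's excess profit, so C_S(p) = (E_p(γ₀) − E_p(γ) − S)/(E_p(γ) + S);
B is untouched. Whether the subsidy should also be paid in the evolved
state is genuinely open; pristine-and-stewarding-only is the default as the
most literal reading of "paying those who engage in stewardship", and the
transformed game is an ordinary `PopulationGame`, so alternatives are easy
to construct. The minimum switching subsidy solves B(p) = C_S(p) for S
pointwise — S(p) = (E_p(γ₀) − E_p(γ) − B(p)E_p(γ))/(1 + B(p)) — and takes
the worst case over a 1001-point grid. A temporary subsidy is modeled as
one synchronous best response under the subsidized game (everyone stewards
if stewardship is dominant, i.e. the population jumps to p = 1), after
which the unsubsidized dynamics determine the long-run state; beliefs are
represented purely by that post-intervention state, with no explicit belief
model. The cartel analysis maximizes per-manager welfare
W(p) = p·E_p(γ)L_p(γ) + (1−p)·E_p(γ₀)L_p(γ₀) over p only (the action γ is
fixed, matching the binary-choice frame); joint optimization of a
continuous γ is an extension hook, not implemented.

## Synthetic scenarios — what they do and do not show

The fixture catalog carries the study conditions: `bt_binary` (a 20% refuge
costing 25% and buying a 30% life-span gain, baseline L = 8), `bt_continuous`
(linear profit and persistence in γ), `fig3a_substitutes`
(B = 0.5 − 0.3p, C = 0.2 + 0.2p: unique stable interior equilibrium at
p* = 0.6), `fig3b_complements` (B = 0.1 + 0.6p, C = 0.3 + 0.2p: stable
corners, unstable interior at 0.5), `hospital_tracing` (individual action
does not move L, so B ≡ 0), and `reversible_demo`. The two game fixtures
are qualitative stand-ins chosen for their equilibrium *structure*; their
numeric curve values are not estimates of any real system. Passing tests
therefore demonstrate the decision logic, equilibrium computation and
policy comparative statics — not the empirical calibration of κ or Π for
any actual crop or hospital, which is out of scope (the package takes these
as inputs).

## Problem sizes and numerical defaults

Monte Carlo validation uses 100,000 replicates per (δ, κ) cell, which puts
the standard error around 0.1–1% of the analytic value — small enough that
a 3-standard-error band is a sharp test. Scans default to 1001 points
(γ grids, subsidy grids), Nash scans to resolution 1e-3 with 1e-10 root
polish, finite differences to h = 1e-5 with a ±1e-9 zero band. Degenerate
inputs are handled explicitly rather than returning NaN: δκ = 1 raises a
non-finite-lifespan error, κ = 1 sampling returns an "infinite" shift-time
sentinel, γ = 1 refuges raise (no Bt planted, no stream), and infeasible
calendar conversions return a flagged result.

## Known limitations

Single repeated action per state (no time-varying policies); two states
only; homogeneous managers in the game; no estimation of κ or Π from data;
no societal welfare accounting beyond manager profit. The reversible chain
is a generic relaxation of irreversibility, not a calibrated model of
resistance reversion.
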