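# evomgmt

Decision analysis for the economics of managing adverse evolution.

Farmers planting Bt crops, hospitals rolling out antibiotic stewardship, and
fish farmers dosing antimicrobials all face the same trade-off: a costly
*stewardship* action (a non-Bt refuge, a partner drug, contact tracing)
lowers profit today but delays the evolution of resistance, protecting
profit tomorrow. `evomgmt` models this as a regime shift between a
*pristine* state (resistance has not spread) and an *evolved* state, and
answers: when is stewardship in the manager's own economic interest?

## The model

Time runs in years. Annual profit is Π(γ) in the pristine state under
action γ and a constant Π̄ once evolved; the excess profit is
E(γ) = Π(γ) − Π̄. With discount factor δ = 1/(1+r) and annual persistence
probability κ(γ) (the chance evolution does *not* occur this year), the
excess stream is worth

    V(γ) = E(γ) · L(γ),      L(γ) = 1 / (1 − δ·κ(γ)),

where L is the **effective life span** — economic and evolutionary
discounting compounded. Stewardship action γ beats the no-stewardship
choice γ₀ (the E-maximizer) exactly when the dimensionless **evolution
management inequality** holds:

    (L(γ) − L(γ₀)) / L(γ₀)  >  (E(γ₀) − E(γ)) / E(γ)

— the percentage gain in effective life span must exceed the percentage of
annual excess profit forgone. On top of this core the package provides:

- **Single managers** — optimal action over finite or continuous action
  sets, the critical discount factor δ* above which a given action pays,
  and monotone comparative statics (patience, management effectiveness,
  evolved-state profit).
- **Bt refuges in closed form** — the cost of a refuge of fraction γ
  collapses to γ/(1−γ), independent of per-acre prices; includes the
  calendar-year conversion and the alternative-land-use caveat.
- **Manager games** — when E and L depend on the fraction p of managers
  stewarding, percentage benefit/cost curves B(p), C(p), Nash equilibria
  with convergence stability, strategic substitutes vs complements, and
  best-response dynamics.
- **Policy** — permanent and temporary subsidies, the minimum subsidy
  making stewardship dominant, cartels (collective optima), and
  externality diagnostics.
- **Monte Carlo** — stochastic regime-shift simulation validating the
  analytic present values, plus a reversible-evolution two-state chain.

## Worked example: a 20% Bt refuge

```
$ evomgmt fixtures --name bt_binary --outdir demo
$ evomgmt evaluate --config demo/bt_binary.yaml --gamma 0.2
{
  "gamma": 0.2,
  "E": 32.0,
  "L": 10.4,
  "V": 332.8,
  "B": 0.30000000000000004,
  "C": 0.25,
  "beneficial": true,
  ...
}
```

Setting aside 20% of the farm costs C = 0.2/0.8 = 25% of annual excess
profit. In this scenario the refuge stretches the effective life span from
8 to 10.4 years — a 30% gain — so B > C and the refuge pays for itself
(V rises from 320 to 332.8). Equivalently: with an 8-effective-year
baseline the refuge must buy at least 0.25 × 8 = 2 effective years.

The calendar-year version of the same logic:

```
$ evomgmt refuge calendar --n 15 --gamma 0.26 --rate 0.04
{"feasible": true, "m_real": 23.4258..., "m_years": 24, ...}
```

A 26% refuge on a crop whose efficacy would otherwise last 15 years is
worth it (at 4%/year interest) once it extends efficacy to at least ~23.4
calendar years.

Games and policy from the command line:

```
$ evomgmt nash --game fig3b_complements.yaml
{"equilibria": [{"p": 0.0, ... "convergence_stable": true},
                {"p": 0.5, "kind": "interior", "convergence_stable": false},
                {"p": 1.0, ... "convergence_stable": true}],
 "feedback_class": "positive", ...}
```

Under positive strategic feedback the population is bistable: nobody
stewards or everybody does. A one-year subsidy large enough to make
stewardship dominant (`evomgmt policy switching-subsidy`) flips the
population permanently from p = 0 to p = 1; under negative feedback the
same subsidy has no lasting effect.

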