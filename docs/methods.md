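# Methods

## Model structure

The cohort is tracked over mutually exclusive health states — *No VF*,
*Prevalent VF*, *Post VF*, *New VF (absorbing exit)* and *VFA impossible*
(absorbing for screening; disease progression continues) — refined internally
by therapy status and by whether a patient has ever been diagnosed.  The
horizon is 10 years in cycles of 2 years (1 year in the `cycle_1y` scenario);
mortality, ageing within the horizon, BMD-based eligibility, adherence below
100 %, and adverse drug effects are outside the model, as in the source
analysis.

Each cycle starts with a screening event.  Classification is per true
fracture status: radiography is the gold standard (Se = Sp = 1); VFA
classifies readable scans with Se 0.82 / Sp 0.93 (0.88/0.99 in the old-age
subgroup); a scan is unreadable with probability 0.03 per patient.  In the
combined strategy a confirmatory radiograph is taken at a patient's *first*
positive VFA only; previously diagnosed patients restart therapy on a positive
VFA without re-confirmation.  This first-time-only confirmation is a design
decision back-calculated from the published per-capita radiation totals: the
published combined-strategy 10-year dose (747 μSv for women) is consistent
with roughly 5.7 VFA scans plus about one radiograph per capita, not with a
radiograph at every screen (≈ 3.5 mSv) nor with the flat "625 μSv per cycle"
reading.  Everyone still in the simulation is re-screened at every event;
re-tested positives restart therapy.

Patients found unreadable at the first screen enter the absorbing
VFA-impossible state: they are never screened again but keep fracturing and
accruing outcomes.  By default the combined strategy does *not* resolve
unreadables by radiography; unreadability is treated as a persistent patient
trait.  This choice preserves an identity the published base-case table
prints: X-ray-following-VFA and VFA-only have exactly equal effectiveness
(25.2/25.2 women, 10.1/10.1 men), which is only possible if the two
strategies treat exactly the same patients.  The alternative reading —
unreadables sent straight to radiography, per-patient treatment probability
[(1−u)·Se + u]·Se_xray = 0.8254 — is implemented behind the
`unreadable_confirmed_by_xray` switch.

## Disease dynamics

Per cycle, untreated fracture-free patients move to *Prevalent VF* with the
two-year first-fracture probability (0.12 women / 0.05 men); arrivals are not
at new-fracture risk until the next cycle.  Fracture carriers draw a new
fracture with the two-year probability 0.22, multiplied by RR (0.58 women /
0.38 men) while on therapy.  Therapy lasts one year; by default RR applies to
the whole cycle in which therapy starts (`rr_prorated` recomposes the cycle
from annual hazards with only the first year protected).

A new fracture on therapy is diagnosed and exits.  An untreated new fracture
exits only if clinically recognised — the symptomatic fraction
1/(1+2.8) ≈ 0.26, from the asymptomatic-to-symptomatic ratio of 2.8 —
otherwise the patient continues, undetected and at risk (`untreated_exit_all`
switches to exit-on-every-fracture).  A first fracture's asymptomatic
survivor faces one further same-cycle draw from the post-fracture pool:
two-year cycles are long relative to recurrence times, and this within-cycle
recurrence is required to reproduce the published no-screening incidences and
costs (without it they fall to 38.7 %/19.6 % against the selected
configuration's 43.1 %/21.8 %).  Effectiveness counts fracture *events* per
100 persons by default (`count_events=False` counts first fractures per
person); the event tally can exceed 100 in the high-risk subgroup, which is
why the trace invariant is monotone non-negativity rather than a [0, 100]
bound.

## Payoffs

Costs are 2013 euros, discounted at 5 %/year with half-cycle correction:
screening costs at the event time, disease costs at the cycle midpoint.
Doses and effectiveness are undiscounted.  Test costs (VFA €17, radiography
€24) include the physician visit.  The all-in "treatment of a VF patient"
cost (€1526 women / €1707 men; scenario-specific values in Table 2 analogues)
is charged **once at a patient's first positive test** — including a false
positive, which is exactly the unnecessary-treatment cost of imperfect VFA
specificity discussed in the source — and each incident new fracture is
charged one drug-year plus one visit (€189/€203).  `procedure_cost_added`
optionally adds the symptomatic-weighted procedure cost per fracture.  This
assignment is the package's design decision, selected because it reproduces
the published cost structure to the euro where the obvious alternative
(fracture events charged €1526, therapy starts charged €189) misses the
published no-screening costs by a factor of two and every incremental cost by
€200–400.  Re-detections at later screens are not re-charged.

## Replication search

Six binary switches — `six_screening_events` (screens at t = 0,2,…,10 vs
five events), `count_events`, `untreated_exit_all`, `rr_prorated`,
`unreadable_confirmed_by_xray`, `procedure_cost_added` — span 64
combinations.  `replication_search` scores each by the sum of relative
absolute errors against 22 published values: per-sex, per-strategy
effectiveness, ΔC and ΔRE of the base case, and the two subgroup
do-screening ΔE values.  Relative error was chosen once, a priori, to weight
the three outcome scales (%, €, μSv) symmetrically; ties break in documented
switch order.  The search is deterministic and reports a full residual table.
The selected configuration is `110010`: six screening events, event counting,
symptomatic-only exits, whole-cycle RR, radiography-resolved unreadables, no
separate procedure cost.  It differs from the package default (`110000`) only
on the unreadable switch: the argmin trades the printed exact equality of the
two VFA-based strategies for a closer fit to the published combined-strategy
dose and cost, while the default preserves the structural identity.  Both are
a single flag apart and the residual tables make the trade explicit.

### Known irreducible discrepancies

Two published figures cannot be reached anywhere in the convention space, and
the package reports them honestly rather than fitting to them:

* **Women's no-screening incidence (published 54.6 %).**  With the shared
  two-year new-fracture probability (0.22 for both sexes), the women:men
  ratio of cumulative incidence is a saturation-damped mixture of the
  prevalence ratio (0.22/0.11 = 2.0) and the first-fracture incidence ratio
  (0.12/0.05 = 2.4) — strictly below 2.43 for every counting/exit/schedule
  convention.  The published pair (54.6/22.5 = 2.43) therefore cannot be met
  jointly; configurations matching the women's value put men near 28 %.  The
  selected configuration gives 43.1 % women / 21.8 % men.
* **Old-age subgroup do-screening ΔE (published −41.0 women / −32.8 men).**
  Under event counting the subgroup's prevalence (0.43/0.46) and two-year
  new-fracture probability (0.32) drive the no-screening tally to ≈ 107
  events per 100 women and ΔE to −54.0/−48.7; person counting saturates
  instead (ΔE ≈ −15).  The published values lie between the two counting
  regimes and are not attainable at ±1 pp anywhere in the space.

A third, smaller deviation: the published claim that strategy rankings are
invariant across all one-way variants fails for the VFA-cost variant (€17 →
€40), where radiography-only becomes cheaper than the combined strategy.  The
published numbers imply the same flip (€881 + ≈€130 > €998), so the model is
taken to be right and the narrative claim approximate.

## Microsimulation oracle

The microsimulation draws individual trajectories under the identical
probabilities, payoffs and conventions: one `numpy.random.default_rng(seed)`
stream consumed cycle-synchronously over the patient vector in a fixed draw
order, so identical `(params, n, seed)` reproduce trajectories exactly.
State-changing branches are drawn; per-event screening costs and doses accrue
as conditional expectations, which leaves all means unchanged while tightening
the comparison.  Logged costs are present values, so trajectory summaries are
plain sums.  `validate_against_cohort` requires each outcome mean at
n = 100 000 to lie within three Monte-Carlo standard errors of the cohort
value; across seeds the z-scores are centred on zero, and with eight
strategy×sex runs per validation an occasional |z| slightly above 3 for one
outcome is expected roughly once per several seeds.

What the generator emulates: the study's claims-derived population as i.i.d.
patients with sex-specific prevalence and hazards.  What it does not: age
drift, secular trends, screening non-adherence, correlated fracture risks, or
any individual covariates beyond the scenario — so agreement validates the
engine's arithmetic, not the model's fidelity to any real population.

## Numerical notes

Mass conservation is asserted each cycle at 1e-12.  The two VFA-based
strategies agree in effectiveness to ≈ 1e-14 under the default conventions.
Probabilities for non-tabulated cycle lengths use the constant-hazard
conversion `1 − (1 − p)^(t'/t)`; published one- and two-year values are used
directly.  Ranks in the sensitivity report are dense ranks on values rounded
to 1e-9 so that exactly tied strategies share a rank.  The deterministic
engine runs a scenario in well under a millisecond; the full 64-point search
takes ≈ 0.1 s, and an eight-run oracle validation at n = 100 000 ≈ 0.5 s.
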