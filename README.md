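# vfscreen

A decision-analytic Markov cohort model comparing population screening
strategies for **prevalent vertebral fractures (VF)** in adults aged 50 and
older, with an individual-level microsimulation as a Monte-Carlo oracle.

Vertebral fracture is the most common osteoporotic fracture and most prevalent
fractures go unrecognised, yet detecting one and starting anti-osteoporotic
therapy substantially lowers the risk of the next fracture.  The package
compares three screening strategies against no screening, every one to two
years over a ten-year horizon:

1. **X-ray following VFA** — densitometric vertebral fracture assessment
   (VFA) for everyone, positives confirmed by spine radiography;
2. **VFA only** — therapy started directly on a positive VFA;
3. **X-ray only** — spine radiography for everyone (the gold standard,
   sensitivity = specificity = 1).

Outcomes per strategy: cumulative incidence of *new* VFs (%), discounted cost
(€ per capita, 5 %/year with half-cycle correction), and cumulative radiation
exposure (μSv per capita; 600 μSv per radiograph vs 25 μSv per VFA).

## Model

Health states: *No VF → Prevalent VF → Post VF → New VF (exit)*, plus an
absorbing *VFA-impossible* state for patients whose scans cannot be read.
Per two-year cycle, fracture-free patients acquire a first VF with probability
`vf_incidence`; fracture carriers suffer a new VF with `new_vf_incidence`,
multiplied by the treatment relative risk `RR` while on therapy.  Patients
testing positive (true or false) start one year of therapy; a diagnosed new VF
leaves the simulation.  Incremental outcomes versus no screening are

```
ΔE = Effect_index − Effect_no-screening      (percentage points)
ΔC = Cost_index  − Cost_no-screening         (€)
ΔRE = Dose_index − Dose_no-screening         (μSv)
```

and the "do screening" comparator is the unweighted mean of the three
strategies.  Several conventions of the original analysis are not fully
specified; they are exposed as six binary switches and an exhaustive
64-combination **replication search** picks the combination that best
reproduces the published result tables (see `docs/methods.md`).

## Worked example

```python
from vfscreen import load_parameter_set, run_base_case

women = load_parameter_set(sex="female", scenario="base_case")
men = load_parameter_set(sex="male", scenario="base_case")
print(run_base_case(women, men).round(1).to_string(index=False))
```

```
   sex       strategy  effectiveness_pct  delta_e  cost_eur  delta_c  delta_re
female   no-screening               43.1      0.0      62.5      0.0       0.0
female   do-screening               23.5    -19.6     936.0    873.4    1333.5
female xray-after-vfa               25.2    -17.9     832.5    770.0     599.6
female       vfa-only               25.2    -17.9    1071.2   1008.6     133.2
female      xray-only               20.1    -23.0     904.2    841.7    3267.8
  male   no-screening               21.8      0.0      33.8      0.0       0.0
  male   do-screening                9.4    -12.4     654.7    620.8    1375.7
  male xray-after-vfa               10.5    -11.3     516.2    482.3     500.6
  male       vfa-only               10.5    -11.3     876.3    842.4     141.0
  male      xray-only                7.1    -14.6     571.6    537.7    3485.6
 total   do-screening               16.9    -16.2     804.5    755.4    1353.2
```

Reading the women's block: without screening, 43 new fractures accrue per 100
women over ten years at €63 per capita.  Screening by any strategy roughly
halves that.  The combined strategy is the cheapest screening option (€833)
because confirmatory radiography eliminates false-positive therapy; VFA alone
is the most expensive despite the cheapest test, and radiography alone costs
an order of magnitude more radiation (3268 μSv vs 133 μSv for VFA).  The
`total` row weights the sexes by the 2013 registration population.

The same surface is available from a shell:

```sh
vfscreen table3              # base-case table above + manifest
vfscreen sensitivity         # one-way sensitivity analysis
vfscreen scenario --name subgroup_old_age
vfscreen microsim --strategy vfa-only --n 10000 --seed 7
vfscreen replicate           # convention search + residual report
vfscreen validate            # microsim-vs-cohort oracle check
```

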