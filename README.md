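# psmcea

A partitioned-survival cost-effectiveness model of first-line **nivolumab +
ipilimumab (NI)** versus **pemetrexed + cisplatin/carboplatin chemotherapy
(C)** for unresectable malignant pleural mesothelioma, from the perspective
of the Chinese healthcare system.

It is written for health economists and methodologists who want a fully
scripted, testable version of this kind of analysis: every stage — survival
curve handling, pseudo individual-patient-data (IPD) reconstruction,
parametric extrapolation, the economic engine, and the sensitivity
analyses — is a plain Python API with a thin command-line wrapper.

## The model

Three mutually exclusive health states are read directly off the
progression-free survival (PFS) and overall survival (OS) curves, with no
transition probabilities:

```
progression-free  PF(t) = min(S_PFS(t), S_OS(t))
progressed        PD(t) = S_OS(t) − PF(t)
dead               D(t) = 1 − S_OS(t)
```

The cohort runs in 1-month cycles over a 10-year horizon. Quality-adjusted
life-years (QALYs) accrue as `PF·u_PF + PD·u_PD` per cycle (u_PF = 0.706,
u_PD = 0.565 per year), discounted at 5%/year; one-off adverse-event
disutilities and management costs are charged undiscounted in the first
cycle. Costs cover first-line drug acquisition (by body-weight, body-surface
or Calvert AUC dosing), intravenous administration fees, follow-up visits,
and an expected full-course second-line lump sum charged at progression.
The decision statistic is the incremental cost-effectiveness ratio (ICER)

```
ICER = ΔCost / ΔQALY        vs. WTP = $33,819/QALY  (3 × per-capita GDP)
```

Survival curves are the six standard extrapolation families (exponential,
Weibull in proportional-hazards form, log-logistic, log-normal, Gompertz,
gamma), with right-censored maximum likelihood fitting and AIC/BIC
selection. When only published Kaplan-Meier figures are available,
pseudo-IPD is rebuilt from digitized coordinates plus the number-at-risk
table by the Guyot interval-matching algorithm. A synthetic-data module
simulates trial-like arms (303/302, 229/226 and 74/76 patients per
population; uniform accrual; administrative censoring) so the whole
pipeline is testable without any external data.

Sensitivity analyses: one-way (tornado) analysis over every parameter
range, threshold-price search by bisection on the ICER, and a
1000-iteration second-order Monte Carlo probabilistic sensitivity analysis
(beta for utilities/incidences, gamma for costs and prices, uniform for
mixture probabilities) summarized as cost-effectiveness acceptability
curves (CEAC).

## Worked example

```bash
psmcea base-case -o out/
```

prints (population A = all randomized, E = epithelioid, N = non-epithelioid):

```
population               strategy life_years total_cost qalys    icer
         A                     NI       2.01     56,741  1.30
         A                      C       1.74     20,543  1.10
         A incremental (NI vs. C)       0.28     36,198  0.20 184,129
         E                     NI       2.32     56,998  1.47
         E                      C       2.00     20,762  1.25
         E incremental (NI vs. C)       0.32     36,236  0.22 162,010
         N                     NI       1.87     56,625  1.22
         N                      C       1.05     19,976  0.71
         N incremental (NI vs. C)       0.82     36,649  0.50  72,625
```

Reading the A rows: the NI arm yields 2.01 discounted life-years and 1.30
QALYs at a total discounted cost of $56,741; chemotherapy yields 1.10 QALYs
at $20,543. NI therefore buys 0.20 extra QALYs for $36,198 — an ICER of
$184,129/QALY, far above the $33,819 willingness-to-pay threshold, so NI is
not cost-effective in any population (probability ≈ 0 in the PSA at that
threshold). Per-cycle audit traces and the summary are written to `out/`.

Other entry points:

```bash
psmcea owsa -p A -o out/          # tornado table + plot
psmcea psa -p N -n 1000 -o out/   # PSA scatter + CEAC
psmcea simulate -o fixture/       # synthetic digitized curves + risk tables
psmcea reconstruct fixture/curve_NI_A.tsv --risk-file fixture/risk_NI_A.tsv
psmcea export-config my_config.yaml
```

and the same operations as Python calls (`psmcea.run_cea`,
`psmcea.owsa`, `psmcea.psa_run`, `psmcea.reconstruct_ipd`, ...).

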