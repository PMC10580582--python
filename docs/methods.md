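# Methods

## Model structure and assumptions

The model is a pure partitioned survival model (PSM): state occupancies are
deterministic functionals of the two marginal survival curves, so there are
no transition probabilities, no tunnel states and no individual-level
simulation. The implied assumptions are the usual ones for a PSM:

- PFS and OS come from the same randomized cohort, and `S_PFS(t) ≤ S_OS(t)`
  is enforced by clamping (`PF = min(PFS, OS)`), so progression-free
  occupancy can never exceed the share alive.
- Post-progression survival is whatever the OS curve implies; it is not
  modelled causally.
- Progression is assumed to precede death within a cycle: the flow of "new
  progressors" used for second-line costing is the decrement of the raw PFS
  curve, `max(PFS(t−1) − PFS(t), 0)`.
- All patients enter progression-free at t = 0.

An optional constant background-mortality hazard can be multiplied into OS
(`OS·exp(−h·t)`), guaranteeing the all-cause hazard never falls below the
background rate. It is off in the base case: no life table is part of the
base-case inputs, and the three-year horizon of the underlying trial data
dominates the curve anyway.

## Survival curves

Six families, parameterized as is conventional in survival extrapolation
(time in months everywhere; conversions happen only at I/O):

| family | S(t) | parameters |
|---|---|---|
| exponential | `exp(−λt)` | rate λ |
| Weibull (PH) | `exp(−λt^γ)` | rate λ, shape γ |
| log-logistic | `1/(1+(t/λ)^γ)` | scale λ, shape γ |
| log-normal | `1−Φ((ln t − λ)/γ)` | log-location λ, log-sd γ |
| Gompertz | `exp(−(λ/γ)(e^{γt}−1))` | rate λ, shape γ |
| gamma | `1−P(γ, λt)` | rate λ, shape γ |

The Weibull is the proportional-hazards form (cumulative hazard `λt^γ`),
which is what the base-case rate/shape values assume. A Gompertz with
|γ| < 1e−8 falls back to the exponential to avoid overflow. The base-case
curves reproduce the trial's published medians and 3-year survival rates to
within rounding, which is the strongest available check that the
parameterizations are the intended ones.

One base-case value is typographically corrupted in its source table: the
shape of the non-epithelioid chemotherapy OS log-logistic. The default,
2.17796, is the least-edit reconstruction of the printed digits; it is an
ordinary config value (`survival.os.C.N`) and all non-epithelioid outputs
inherit its uncertainty.

Fitting is right-censored maximum likelihood: `Σ_events log f(t) +
Σ_censored log S(t)`, maximized by L-BFGS-B on log-transformed parameters
with moment-based multi-starts, making results deterministic for a given
data set. The exponential uses its closed form (events / total exposure)
exactly. Model selection ranks all six families by AIC, ties broken by BIC
then family name. Note that with ~3 years of follow-up, n ≈ 300 and shapes
near 1, the families are close to indistinguishable: the true family is not
reliably ranked first, it is merely never far behind (ΔAIC < 10), and
parameter-level recovery of a Weibull rate at this n has 20–40% sampling
error. Tests therefore check fitted curves, not raw parameter equality.

## Pseudo-IPD reconstruction

Published curves are only available as figures, so patient-level records
are rebuilt from digitized (time, survival) coordinates and the
number-at-risk table via the Guyot interval-matching algorithm: within each
risk-table interval, censoring is assumed uniform, events are allocated to
the digitized drops through the running product-limit identity, and the
interval's censoring count is adjusted (≤ 100 passes) until the implied
number at risk matches the table exactly. Conventions fixed here:

- The digitized point sitting exactly on a risk-table time carries the
  drops just before it, so it is processed before that boundary's at-risk
  comparison; at-risk counts are read as "still under observation just
  after the table time".
- Simultaneous digitized drops are allocated in time order.
- Beyond the last risk-table time no censoring is assumed; patients still
  at risk at the end of the curve are censored there.
- Without a risk table, the fall-back assumes no censoring before the last
  follow-up (initial arm size required, warning logged).

The synthetic digitizer samples the true Kaplan-Meier step function on a
monthly grid with a quarterly risk table — the resolution of the model's
cycles. This is coarser than pixel-level digitization of a real figure:
reconstructed event times are lattice-valued (mean half-month shift), which
leaves the reconstructed KM curve within ~0.01 of the original at grid
points but can move a refitted Weibull rate a long way along the rate/shape
likelihood ridge. Round-trip fidelity is therefore asserted on survival
curves (≤ 0.02 at the digitized grid; ≤ 0.04 between fits on original vs
reconstructed records), not on raw parameters.

## Economic engine

- **Cycles and discounting.** 120 monthly cycles; discount factor
  `(1+r)^(−t/12)` with r = 0.05 (range 0–0.08); each cycle contributes
  1/12 year.
- **Evaluation grid.** Occupancies are evaluated at cycle starts in the
  base case; half-cycle-corrected (midpoint) evaluation is a config switch.
  Cycle-start evaluation reproduces the published life-year totals of the
  immunotherapy arm exactly (2.01 vs 2.01), indicating the original model
  did not apply half-cycle correction, which is also the TreeAge default.
  With midpoint evaluation the trace agrees with fine-grid numerical
  integration of the OS curve to < 0.5%.
- **Utilities.** u_PF = 0.706, u_PD = 0.565, death 0 (per year). One-off
  adverse-event QALY losses (incidence × decrement × 1/12, for asthenia /
  anemia / neutropenia) are subtracted undiscounted in cycle 1, as are the
  corresponding management costs.
- **Dosing.** nivolumab 3 mg/kg q2w; ipilimumab 1 mg/kg q6w; pemetrexed
  500 mg/m² q3w; cisplatin 75 mg/m² q3w; carboplatin AUC 5 by the Calvert
  formula `dose = AUC × (CrCl + 25)` with GFR ≈ CrCl (the universal
  clinical convention); vinorelbine 25 mg/m² and gemcitabine 1000 mg/m² on
  days 1+8 q3w. Reference patient: 65 kg, 1.72 m², CrCl 60 mL/min, 69 y.
- **First-line cost accrual.** Continuous: doses per month =
  dosing-days-per-interval × 30.4375 / interval-days, charged against
  progression-free occupancy up to the median treatment duration (NI 6
  months, C 4 months). One first-hour IV fee ($7.83) per administration
  day, regardless of how many drugs share the visit (q6w nests in q2w;
  platinum is co-administered with pemetrexed).
- **Second line.** An expected full-course cost, charged as a lump sum to
  each newly progressed patient: NI arm → pemetrexed + platinum
  (cisplatin/carboplatin 50:50) for 5 months; C arm → with probability 0.5
  immunotherapy (nivolumab ± ipilimumab 50:50, 3 months), otherwise
  single-agent chemotherapy (vinorelbine/gemcitabine 50:50, 16 months).
  A PSM cannot track time since progression, so a lump sum is the
  convention that matches "all patients receive second-line therapy at
  progression"; its limitation is that patients who die soon after
  progression are still charged a full course.
- **Follow-up.** $69.13 per cycle for all alive occupancy, first- and
  second-line alike.

## Sensitivity analyses

- **One-way.** Each parameter in the range table is set to its printed low
  and high with everything else at base; rows are ordered by ICER spread.
  Price ranges are historical bid-price extremes, not ±x% of base.
- **Threshold search.** Bisection on a single price to |ICER − target| <
  $1/QALY, bracket [0, 4×base] doubled up to 64× until a sign change.
- **PSA.** 1000 second-order Monte Carlo iterations from one seeded RNG
  stream. Families: beta for utilities, disutility magnitudes, incidences
  (method of moments with sd = range/3.92); gamma for costs, prices, weight
  and body-surface area (same moment rule); uniform for the four mixture
  probabilities whose printed range is the whole unit interval; survival
  parameters and the discount rate are held fixed (no published ranges; a
  fixed discount rate in PSA is standard practice). Method-of-moments
  sampling preserves every base value as the sampled mean, so the PSA is
  centered on the deterministic case by construction.
- **CEAC.** At each willingness-to-pay λ on a $0–400,000 grid ($1,000
  steps), the probability is the fraction of iterations with positive
  incremental net monetary benefit `λΔQALY − ΔCost`.

## Synthetic data

The generator emulates the structure the analysis assumes: per-arm event
times drawn from the base-case curves by inverse transform, uniform accrual
over 18 months, administrative censoring at a 36-month data cut-off
(mirroring a phase-III readout after "at least 3 years"), arm sizes
303/302, 229/226 and 74/76. It does not emulate covariates, treatment
crossover, informative dropout, or inter-curve dependence between PFS and
OS — so passing round-trip tests demonstrates the pipeline's internal
consistency on clean administratively-censored data, not robustness to the
messiness of real digitized figures.

## Fidelity to the published analysis

The package reproduces the published analysis's *inputs* exactly, and its
published survival curves check out against the underlying trial's medians
and 3-year rates. The published *outputs*, however, are not jointly
derivable from those inputs under any documented convention of this engine,
and the published results table is internally inconsistent (its life-year
column repeats the all-randomized values across all three populations; its
QALY/life-year ratios are exactly constant per arm; one subgroup's QALY
exceeds u_PF × life-years). Concretely, with the published curves the
discounted incremental survival benefit is ≈ 0.20 QALYs for the
all-randomized population — about twice the published 0.10 — so this
model's ICERs come out near half the published ones (e.g. $184,129 vs
$375,656/QALY for all-randomized patients), on the same side of the
willingness-to-pay threshold and with the same qualitative conclusions:
immunotherapy is not cost-effective at 3× per-capita GDP in any population,
and the non-epithelioid subgroup has by far the lowest ICER. Incremental
costs agree within ~5%. Because this model's non-epithelioid ICER sits
lower, the ICER is *increasing* in the pemetrexed price here (the
immunotherapy arm's second-line pemetrexed exposure exceeds the chemo arm's
first-line exposure under the lump-sum convention), so no threshold price
equates the ICER to the willingness-to-pay threshold. The acceptance tests
state the published values verbatim and are left failing where the inputs
cannot meet them; the project's decision notes carry the quantitative
analysis.

## Known limitations

- Vial rounding/wastage, price-year inflation, indirect costs and currency
  conversion are out of scope (a fixed RMB:USD = 7.1831 applies only if a
  user supplies RMB prices externally).
- The second-line lump sum ignores post-progression mortality during the
  course (see above).
- Background mortality is a constant-hazard stub, not an age-specific life
  table.
- The PSA ignores parameter correlation and survival-curve uncertainty.
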