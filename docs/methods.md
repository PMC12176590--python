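# Methods

## Model structure

The economic model is a three-state partitioned survival model (PSM).
Unlike a Markov cohort model, a PSM does not specify transition
probabilities: the membership of each health state at time *t* is read
directly off the two marginal curves, progression-free survival S_PFS and
overall survival S_OS. The implicit assumptions are (i) progression and
death are adequately summarized by their marginals — no patient-level
coupling between PFS and OS is modeled — and (ii) the extrapolated curves
remain ordered. Where extrapolations cross (S_PFS > S_OS), the
progression-free membership is clamped to S_OS and the progressed state
empties; the engine counts clamped boundaries and reports the count as a
diagnostic rather than refitting the curves.

Everyone enters progression-free. The cycle length is 21 days (matching the
dosing interval of the regimen) and the horizon is 10 years, i.e.
`ceil(10 × 365.25 / 21) = 174` cycles, long enough that under every fitted
scenario more than 95% of the cohort has died.

## Survival inputs

Six parametric families are supported, in the parameterizations usual for
survival extrapolation (scale-like parameter first):

| family | S(t) | parameters |
|---|---|---|
| exponential | exp(−λt) | rate λ |
| Weibull | exp(−λt^γ) | rate λ, shape γ |
| log-logistic | [1+(t/θ)^k]⁻¹ | scale θ (= median), shape k |
| log-normal | 1−Φ((ln t−μ)/σ) | meanlog μ, sdlog σ |
| Gompertz | exp(−(b/a)(e^{at}−1)) | shape a (ℝ), rate b |
| gen. gamma | Prentice (μ, σ, Q) | log-normal at Q=0, Weibull at Q=1 |

Fitting is by maximum likelihood on right-censored records, with positive
parameters optimized on the log scale, several deterministic moment-based
starts per family, and a BFGS gradient criterion scaled by the likelihood
magnitude. Families are ranked by AIC with BIC and parameter count as tie
breaks. The generalized-gamma log-density is evaluated by a series around
the log-normal limit for |Q| < 1e−4: the direct expression cancels
catastrophically there and, left alone, manufactures a spurious likelihood
spike at Q ≈ 0 that traps the optimizer.

All fitted parameters in the shipped configuration are expressed in
21-day-cycle time units. That convention is fixed by internal consistency:
the whole-population experimental-arm PFS scale (9.06 cycles ≈ 6.2 months)
equals the trial's reported median PFS, and no other time unit reproduces
the published QALY totals.

The published parameter table for the CPS < 1 subgroup labels the
experimental-arm OS row "Weibull 0.01 / 1.32" with uninterpretable column
names; we read it as rate/shape by the scale-first convention. The
resulting subgroup output does not reproduce the published CPS < 1
increments (the only scenario that does not), so that subgroup is reported
but carries no reproduction test.

## Curve reconstruction

`reconstruct_ipd` inverts a digitized Kaplan–Meier curve plus
numbers-at-risk into pseudo individual-patient data by interval-wise
allocation: within each risk-table interval an integer censoring count is
chosen (censor times spread uniformly — the standard identifying
assumption) so that the reconstructed risk set matches the next reported
number at risk, and event counts at each curve step are rounded with a
cumulative-error carry so rounding never drifts. Round-trip accuracy on
simulated trials (n = 300, 200 digitized points, 3-cycle risk tables) stays
within 0.02 in sup-norm, and the full chain — simulate, estimate, digitize,
reconstruct, refit, run the PSM — moves discounted QALYs by well under 3%.

## Accumulation and discounting

Each cycle's occupancy is valued at its **opening boundary** and discounted
at the cycle start: `(1.05)^(−j·21/365.25)` for cycle j (start-of-cycle
accounting). The textbook trapezoid half-cycle correction is available as
`convention="midpoint"`, but start-of-cycle accounting is the default
because it is what reproduces the published totals: against the printed
whole-population QALYs (1.193 / 0.857) start-of-cycle lands within ±0.5%
while the trapezoid undershoots both arms by about 2%. QALYs accrue
utility-weighted occupancy (u_PFS = 0.75, u_PD = 0.60, death 0; no age
decrement), costs accrue per the state occupancies below, and both use the
same convention.

## Costing conventions

* **Dosing.** Reference patient 65 kg / 1.72 m². Per administration day,
  doses are scaled by body surface area where applicable and billed in
  whole vials (no sharing): sugemalimab 1200 mg = 2 × 600 mg vials;
  cisplatin 80 mg/m² → 137.6 mg → 5 × 30 mg vials; 5-FU 800 mg/m²/day on
  four days → 6 × 250 mg vials per day.
* **Treatment duration.** First-line drug cost is weighted by
  progression-free occupancy up to a per-component cycle cap: 4 cycles for
  the chemotherapy backbone (within the 4–6 cycle convention of Chinese
  practice guidelines) and 24 cycles for sugemalimab. The published
  analysis does not state its duration assumptions; these caps are the
  package's calibration — they are the treatment durations under which the
  model reproduces the published cost side (all reproduction checks land
  within ≤3%, versus 13–18% cost overshoot with uncapped
  treat-to-progression exposure).
* **Hospitalization** ($142.10/cycle) accrues in every alive cycle;
  **post-progression care** ($753.49/cycle, a lump second-line cost rather
  than re-derived irinotecan/S-1 dosing) accrues in every progressed cycle
  until death.
* **Adverse events** (grade ≥ 3, incidence ≥ 3%) are one-off expected costs
  at model entry — incidence × unit management cost, undiscounted — because
  the incidences are trial-level proportions, not per-cycle hazards.
* **Assistance program.** The tier schedule (2 purchased + 2 free,
  2 + 25, 1 + 3) marks treatment cycles 1, 2, 5, 6 and 32 as purchased;
  all later cycles are free (the remaining occupancy there is negligible).
  Only the antibody is tier-gated; the control arm is unaffected.

## Threshold search

`price_threshold` bisects the antibody's 600 mg package price on
[0, $1,732.50] (60 iterations max, $0.01 price tolerance) against the WTP
of $23,901.90/QALY, holding efficacy fixed across prices. The re-plugged
ICER at the returned price is within $1/QALY of the WTP. Non-bracketing
bounds return a boundary verdict (`already_cost_effective` /
`never_cost_effective`) instead of raising.

## Sensitivity analysis

Ranges are read as 95% intervals, SE = (high − low)/3.92. Costs draw from
method-of-moments gamma distributions (shape = base²/SE², scale =
SE²/base); utilities, incidences and the discount rate from beta
distributions solved from the same mean/SE. Draws are mean-preserving, so
the PSA centroid tracks the base case (verified to 5% at n = 10,000). The
hospitalization range is ±20% of baseline because the published lower/upper
bounds for that row are inconsistent with their own baseline. One-way
analysis re-evaluates the full two-arm model at each parameter's bounds,
one at a time; a parameter shipped without a range would default to ±20%.

Survival-curve parameters are **not** resampled in the PSA — the published
range table covers only cost/utility/incidence parameters — so the PSA
understates total decision uncertainty; the PSA seed and draw count
(default 1,000) are explicit arguments and results are reproducible
per seed. Sampling the utility parameters independently can occasionally
draw u_PD > u_PFS; such draws are kept as drawn (the accumulator accepts
raw utilities) rather than silently re-ordered.

## Synthetic trials

The generator emulates a two-arm randomized trial at the evidence level the
PSM consumes: per arm × endpoint, n event times by inverse-CDF from a
parametric truth (defaults: the whole-population fitted curves, n = 358 /
182 as in the source trial), censored at the minimum of an administrative
cutoff (35 cycles ≈ 24 months of follow-up) and, with probability 0.05, a
uniform dropout time. PFS and OS cohorts are independent — exactly the
marginal information a PSM uses — so the data are *not* suitable for
patient-level multistate analyses; nor are recruitment curves or
adverse-event times simulated. Passing tests therefore demonstrate that the
fitting/reconstruction/economic chain is self-consistent at trial-like
sample sizes, not that the parametric families are correct for any real
registry population.

## Numerical notes

* Occupancy rows sum to 1 within 1e−12 by construction; the death column is
  monotone by monotonicity of S_OS.
* The vectorized arm-cost accumulator is tested against an explicit
  per-cycle python loop to 1e−9.
* Vial counts use `ceil(dose/vial − 1e−12)` to absorb float noise at exact
  multiples.
* RMST uses trapezoid quadrature; at step 0.1 cycles it matches the
  exponential and log-logistic (k = 2, arctan) closed forms to 1e−3 cycles.
* Pipeline outputs are written with fixed float formatting and a config
  hash + seed header, and rerunning with the same config and seed is
  byte-identical.

## Known limitations

* The CPS < 1 subgroup inherits an apparently corrupted published
  parameter row (see above); its results are indicative only.
* Treatment-duration caps are calibrated, not protocol-documented (the
  source analysis does not state its assumption).
* AE disutilities, indirect/societal costs and multi-comparator league
  tables are out of scope, matching the source analysis's own exclusions.
* The alternative international utility sets explored in the source's
  scenario analysis are not shipped (values unavailable); any utility pair
  can be supplied via config overrides.
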