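# psmcea

A partitioned-survival cost-effectiveness model of first-line **sugemalimab
plus cisplatin/5-FU versus cisplatin/5-FU alone** for advanced esophageal
squamous cell carcinoma (ESCC), from the perspective of China's health
system. The package is aimed at health-economics analysts who want the full
pipeline — survival-curve reconstruction, parametric extrapolation, the
three-state cycle model, subgroup/assistance-program scenarios, price-cap
search, and one-way plus probabilistic sensitivity analysis — as tested,
scriptable Python rather than a spreadsheet.

## The model

A partitioned survival model (PSM) with three mutually exclusive states —
progression-free (PFS), progressive disease (PD), dead — reads state
occupancy directly off the two marginal survival curves at each cycle
boundary *t*:

```
p_PFS(t) = min(S_PFS(t), S_OS(t))
p_PD(t)  = max(0, S_OS(t) − S_PFS(t))
p_dead(t) = 1 − S_OS(t)
```

Curves are parametric fits (exponential, Weibull, log-logistic, log-normal,
Gompertz, generalized gamma; maximum likelihood on right-censored data,
ranked by AIC/BIC) in 21-day cycle time units, extrapolated over a 10-year
horizon (174 cycles). Each cycle accrues utility-weighted life time
(u_PFS = 0.75, u_PD = 0.60) and costs — dosing-based drug acquisition with
whole-vial billing, one-off adverse-event management, per-cycle
hospitalization and post-progression care — discounted at 5% per year. The
headline statistic is the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY against a willingness-to-pay threshold of
$23,901.90/QALY, with net monetary benefit NMB = WTP·ΔQALY − ΔCost as the
acceptability criterion. A patient-assistance-program scenario gates the
antibody's per-cycle payment through tiered purchased/free blocks
(2+2, 2+25, 1+3, free thereafter), and a bisection search finds the package
price at which the ICER meets the WTP.

Pseudo individual-patient data can be rebuilt from digitized Kaplan–Meier
coordinates plus numbers-at-risk (Guyot-type interval inversion), and a
synthetic-trial generator draws endpoint-level event/censoring times from
any parametric truth so the whole chain is testable offline.

## Worked example

```python
from psmcea import PartitionedSurvivalCEA, default_config

config = default_config()          # the shipped base-case inputs
model = PartitionedSurvivalCEA(config, "whole")
print(model.fit().summary())
```

```
Partitioned-survival CEA — scenario 'whole' (WTP $23,901.90/QALY)
arm                         cost ($)    QALYs     dCost ($)   dQALYs   ICER ($/QALY)
sugemalimab_chemo          58,605.73    1.189     42,928.81    0.328      130,955.43
chemo                      15,676.92    0.861             —        —               —
```

Adding sugemalimab buys 0.328 discounted QALYs for an extra $42,929 —
about $131,000 per QALY, more than five times the willingness-to-pay
threshold, so the combination is not cost-effective at list price. The
price-cap search quantifies the gap:

```python
print(model.price_threshold())
# {'price': 147.79, 'reduction_pct': 91.47, 'icer': 23901.92, ...}
```

i.e. the 600 mg package price would have to fall ~91% (from $1,732.50 to
about $148) before the whole-population ICER meets the threshold. The same
objects drive the sensitivity machinery:

```python
from psmcea import owsa, run_psa, ceac

tornado = owsa(model)                      # antibody price tops the ranking
psa = run_psa(model, n=1000, seed=1)       # all 1000 draws above the WTP
ceac(psa, [23901.90])                      # probability 0 of cost-effectiveness
```

The same pipeline is scriptable from the shell:

```bash
psmcea run --scenario whole --out results/
psmcea price-cap --scenario pap --out results/
```

## Layout

| module | contents |
|---|---|
| `psmcea.survival` | six parametric families, censored MLE, AIC/BIC selection, RMST |
| `psmcea.km` | product-limit estimation, pseudo-IPD reconstruction |
| `psmcea.simulate` | synthetic trial generator, risk tables, curve digitization |
| `psmcea.engine` | occupancy traces, discounting, QALY/life-year accumulation |
| `psmcea.costing` | dosing, vial billing, AE/hospitalization/PD costs, PAP tiers |
| `psmcea.cea` | the `PartitionedSurvivalCEA` model, ICER/NMB, price bisection |
| `psmcea.sensitivity` | OWSA tornado, gamma/beta PSA, CEAC |
| `psmcea.config` / `cli` / `pipeline` | validated YAML config, CLI, artifact pipeline |

See `docs/methods.md` for modeling conventions, calibration decisions and
limitations.
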