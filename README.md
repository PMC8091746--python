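# kinspec

Kinetic spectrophotometric assay calibration and validation for
colour-forming reporting chemistries, built around the triiodide system.

## The problem

Many drugs (the motivating case is clindamycin hydrochloride in capsules)
can be quantified without chromatography by letting them drive a slow
colour-forming reaction and reading absorbance over time. A hydrochloride
salt supplies the acid for

    IO3- + 8 I- + 6 H+  ->  3 I3- + 3 H2O,

so the yellow triiodide signal (~350 nm) grows at a rate and to a plateau
set by the analyte concentration. With the iodine reagents in excess the
kinetics are pseudo-first-order in the analyte:

    A(t) = A_inf(C) * (1 - e^{-k_obs t}),    A_inf(C) = s_inf * C,
    v0 = dA/dt|_0 = k' C^n   (log10 v0 = log10 k' + n log10 C).

`kinspec` is for analytical chemists developing or auditing such assays.
It turns long-format absorbance-time tables into calibration models by the
four classical kinetic methods — **initial rate** (tangent slope at t -> 0,
log-log calibration giving order `n` and rate constant `k'`), **rate
constant** (per-curve `k' = -2.303 * slope(log10 A vs t)` regressed on C),
**fixed absorbance** (1/t to reach a preset A vs C), and **fixed time**
(A at a preselected time vs C, with an r^2-driven time scan) — and runs the
validation battery: recovery/RSD per level, LOD = 3.3 sigma/m and
LOQ = 10 sigma/m, Beer-Lambert molar absorptivity, and pooled t / F
comparison against a reference method. A stoichiometry-grounded simulator
generates datasets with the study's design so the whole pipeline is
testable offline.

## Worked example

```python
from kinspec import (SimulationConfig, generate_kinetic_dataset,
                     select_fixed_time, build_fixed_time_calibration,
                     build_initial_rate_calibration, lod_loq,
                     generate_capsule_samples, assay_formulation)

series = generate_kinetic_dataset(SimulationConfig(seed=11))

chosen, table = select_fixed_time(series, [300, 600, 900, 1200, 1500, 1800, 2100, 2400])
print(table.to_string(index=False)); print("chosen:", chosen)
```

```
 time_s    slope  intercept       r2
  300.0 0.088145   0.000125 0.999998
  600.0 0.111018  -0.000276 0.999999
  900.0 0.116892   0.000351 0.999999
 ...
 2400.0 0.119039  -0.000193 0.999998
chosen: 600.0
```

The scan refits the calibration at every candidate read time; 600 s wins
on r^2 (ties break toward the earliest, i.e. fastest, assay). The slope is
the assay sensitivity in AU per ug/ml at that read time — 0.088 at 300 s
rising toward the 0.119 plateau as the reaction completes.

```python
model = build_fixed_time_calibration(series, 600.0)
_, law = build_initial_rate_calibration(series)
lod, loq = lod_loq(model.fit)
print(f"A = {model.fit.slope:.4f} C + {model.fit.intercept:.4f}  (r2 = {model.fit.r2:.6f})")
print(f"order n = {law.order_n:.4f}, LOD = {lod:.3f}, LOQ = {loq:.3f} ug/ml")
```

```
A = 0.1110 C + -0.0003  (r2 = 0.999999)
order n = 1.0004, LOD = 0.026, LOQ = 0.077 ug/ml
```

The log-log initial-rate fit recovers the first-order dependence on
concentration (n = 1); LOD/LOQ come from the calibration residual SD.
Finally, assay simulated 75 mg capsules against the model:

```python
caps, dilution = generate_capsule_samples(SimulationConfig(seed=12),
                                          label_claim=75.0, n_units=5)
res = assay_formulation(caps, model, 75.0, dilution)
print(f"recovery = {res.recovery_pct_mean:.2f}% +/- {res.sd:.2f} (n={res.n}), "
      f"{res.estimated_mg:.2f} mg/unit")
```

```
recovery = 100.07% +/- 0.08 (n=5), 75.05 mg/unit
```

i.e. the five work-ups (50 mg-equivalent dissolved in 50 ml, diluted
100-fold into the 1-20 ug/ml linear range) recover the label claim within
a tenth of a percent at the default noise level.

The same pipeline is scriptable from a shell:

```sh
kinspec simulate --seed 11 -o curves.csv
kinspec scan-times curves.csv --candidates 300,600,900,1200,1500,1800,2100,2400
kinspec calibrate curves.csv --method fixed-time --time 600 -o model.json
kinspec validate model.json curves.csv -o report.json
kinspec assay unknowns.csv --model model.json --claim-mg 75
kinspec compare ref.csv test.csv --confidence 95
```

Exit codes: 0 success, 2 input/schema error, 3 computational error.

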