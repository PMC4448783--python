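# thermperf

Analysis of thermal acclimation in locomotor performance curves for
repeated-measures fish swim-trial designs.

Ectotherm performance traits such as critical swimming speed (Ucrit) rise
with acute test temperature to an optimum and fall beyond it. Reversible
acclimation can shift that curve, and individuals differ both in curve shape
and in how much they shift. `thermperf` implements the full analysis chain
for a design in which every fish is acclimated consecutively to a cool
(20 °C) and a warm (28 °C) treatment and swum at three acute test
temperatures (20, 28, 32 °C):

1. **Reaction-norm mixed model.** Standardized performance is modelled as

   ```
   Ucrit_z(ij) = β0 + β1·sex + β2·TT + β3·TT² + β4·AT + β5·TT·AT
                 + β6·TT²·AT + u(j) + ε(ij)
   ```

   with test temperature TT centered at 28 °C, acclimation AT coded 0/1,
   and per-fish random effects `u(j)`. Eight nested random structures are
   compared — intercept only; plus acute slope TT, curvature TT², or both;
   plus the acclimation shift AT, optionally with acclimation-specific
   slope (AT:TT) and curvature (AT:TT²) changes — by REML likelihood-ratio
   tests and AIC; fixed effects are tested within the simplest structure by
   ML.
2. **Per-fish performance curves.** Each fish × acclimation series is
   fitted with a quadratic on the raw BL s⁻¹ scale; the optimum Topt comes
   from f′(T)=0, the 80% performance breadth B80 from the quadratic roots of
   `a·T² + b·T + (c − 0.8·Pmax)`, and fish whose optimum falls at or above
   32 °C (outside the test grid) are excluded.
3. **Acclimation capacity and trade-offs.** Capacity
   `= 1 − (P28 − P20)/((P28 + P20)/2)` compares each fish's performance at
   its two acclimation temperatures (1 = perfect compensation); OLS
   regressions of Pmax and B80 on capacity, and of B80 on Pmax, quantify
   the generalist–specialist trade-off within each treatment.

A seeded synthetic-data generator reproduces the study design (48 fish,
20 male / 28 female) with known coefficients and acclimation-dominated
individual variation, so the whole chain is testable without any data
download. An optional simulator of the stepped flume protocol
(`Ucrit = U_f + T_f/T_i·U_i`) converts "true" speeds into protocol-grid
measurements.

## Worked example

```python
import thermperf as tp

table = tp.simulate_dataset(tp.default_params(seed=1))

# per-fish curves and the inclusion filter
summaries = tp.curve_summaries(table)
included, report = tp.filter_individuals(summaries)
print(included.groupby("accl_temp_c")["t_opt"].mean().round(2))

# random-effect ladder on the standardized response
ladder, fits = tp.run_ladder(tp.standardize_response(table))
print(ladder[["model_id", "n_varcomp", "aic"]].round(1).to_string(index=False))
t = tp.lrt(fits[8], fits[5])
print(f"model 8 vs 5: chi2={t.chi2:.1f} df={t.df} p={t.p:.2g}")
```

prints

```
accl_temp_c
20.0    26.22
28.0    27.45
Name: t_opt, dtype: float64
 model_id  n_varcomp   aic
        1          2 749.4
        2          4 748.2
        3          4 742.5
        4          7 747.9
        5          4 725.3
        6          7 681.3
        7          7 656.8
        8         11 653.8
model 8 vs 5: chi2=85.5 df=7 p=1e-15
```

Included cold-acclimated fish peak near 26 °C and warm-acclimated fish over
a degree higher — the acclimation shift. In the ladder, every structure with
the per-fish acclimation shift (models 5–8) outranks the acute-slope
structures (2–4), and the full acclimation-response model 8 attains the best
AIC: individual differences are driven by variation in the acclimation
response, not in acute thermal sensitivity.

The same analyses run from the shell:

```sh
tpc simulate --seed 1 --out obs.csv
tpc ladder obs.csv --out ladder.csv
tpc run --seed 1 --out results/
```

`tpc run` writes the fixed-effect table, the random-effect ladder with its
likelihood-ratio tests, per-fish curve summaries, the capacity table, the
trade-off report and a manifest with checksums for bit-identical reruns.

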