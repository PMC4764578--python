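# thymokinetics

Compartmental kinetics of thymocyte β-selection: a linear four-compartment
model of the DN3 → DN4 → ISP → DP developmental cascade, with exact
closed-form solutions, independent numerical and stochastic verification
engines, a synthetic flow-count generator, and scikit-learn-style estimators
that recover the rate constants from per-mouse subset counts.

The package is aimed at immunologists and modelers who want to reason
quantitatively about how changes in per-cell differentiation rates reshape
thymocyte subset numbers — for example why loss of the inositol kinase Itpkb,
which more than doubles the DN3→DP differentiation rate constants, depletes
the intermediate DN4 and ISP pools while leaving DN3 and DP numbers nearly
unchanged.

## The model

Population sizes C₁–C₄ of DN3, DN4, ISP and DP cells obey

    dC₁/dt = K  − (K₁+K_d1) C₁
    dC₂/dt = K₁C₁ − (K₂+K_d2) C₂
    dC₃/dt = K₂C₂ − (K₃+K_d3) C₃
    dC₄/dt = K₃C₃ − K_d4 C₄

with constant progenitor influx K (cells/day), differentiation rates K₁–K₃
and net turnover rates K_d1–K_d4 (1/day). Two regimes matter:

* **Steady state** (unperturbed mice): the fixed point
  C₁ = K/(K₁+K_d1), C₂ = K·K₁/((K₁+K_d1)(K₂+K_d2)), …,
  C₄ = K·K₁K₂K₃/(K_d4·(K₁+K_d1)(K₂+K_d2)(K₃+K_d3)).
* **Transient** (Rag2⁻/⁻ mice after α-CD3 injection): all cells start
  arrested at DN3, influx is negligible (K = 0), and the cascade is solved in
  closed form as a sum of exponentials from C(0) = (3×10⁸, 0, 0, 0).

Both closed forms are verified against an adaptive ODE integrator and an
exact Gillespie simulation of the underlying cell-level jump process.
Built-in presets carry the published rate constants for four genotypes
(`WT`, `Itpkb-KO`, `Rag2-WT`, `Rag2-ItpkbKO`).

## Worked example

Predicted steady-state subset numbers for wild type vs. Itpkb-deficient mice:

```bash
$ thymokin steady-state -g WT -g Itpkb-KO
genotype subset        count
      WT    DN3 7.700000e+05
      WT    DN4 4.753086e+05
      WT    ISP 1.100000e+06
      WT     DP 1.327586e+08
Itpkb-KO    DN3 5.133333e+05
Itpkb-KO    DN4 2.112483e+05
Itpkb-KO    ISP 4.888889e+05
Itpkb-KO     DP 1.770115e+08
```

The knockout keeps DN3 (×2/3) and DP (×4/3) close to wild type but more than
halves DN4 and ISP (×4/9 each) — the counter-intuitive signature of *faster*
transit through β-selection.

Generate a synthetic α-CD3 cohort (20 virtual mice × 7 time points, 5%
log-normal noise) and re-estimate the rate constants from it:

```python
import thymokinetics as tk

truth = tk.preset_parameters("Rag2-ItpkbKO")
design = tk.ExperimentDesign("acd3_timecourse", (truth,), mice_per_group=20)
data = tk.generate_dataset(design, tk.NoiseModel(cv=0.05, seed=1))

fit = tk.TransientRateFitter(
    free=("K1", "Kd1", "K2", "K3"), fixed={"Kd4": 0.00058}
).fit(data)
print(fit.estimates_)
# {'K1': 0.19926, 'Kd1': 0.09776, 'K2': 0.48102, 'K3': 0.21270}
```

The generating values were K₁ = 0.2, K_d1 = 0.1, K₂ = 0.486, K₃ = 0.21 /day —
each differentiation rate is recovered to ~1%. `compare_genotype_fits` then
turns a wild-type and a knockout fit into a fold-change table, recovering the
≥2-fold rate increases that define the knockout phenotype.

The same pipeline runs from the shell (`thymokin generate`, `thymokin fit`,
`thymokin compare`); every artifact gets a JSON manifest so runs are exactly
reproducible under their recorded seeds.

## Documentation

See `docs/methods.md` for the modeling assumptions, noise model, estimator
definition, numerical tolerances and known limitations.
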