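# dictreg

Sparse, interpretable nonlinear regression for continuous tabular data —
built for biostatistical and epidemiological modelling settings where the
analyst needs a formula they can read (and defend physiologically), not a
black box.

Given predictors x₁ … x_p and a response y, `dictreg` automatically

1. constructs a dictionary **Z** of interpretable transformed terms —
   powers x_j^k (half-integer exponents k ∈ {−α…−1, −½, ½, 1…α}, so
   reciprocals and square roots included), log powers (log x_j)^k, and
   cross-variable products of up to M such atoms;
2. screens **Z** to **Z**^δ, keeping columns with |ρ(z, y)| ≥ δ
   (default δ = half the best univariate correlation in the dictionary);
3. prunes **Z**^δ to **Z**^r so no two survivors correlate above ς
   (default 0.80), keeping of each correlated pair the column more
   correlated with y;
4. exhaustively searches subsets of **Z**^r for the model maximizing
   adjusted R², subject to every variance inflation factor
   VIF_j = 1/(1 − R_j²) ≤ 10,

and returns an ordinary least-squares fit y = β₀ + Σ β_i z_i with
coefficients on the original term scale, p-values, VIFs and residual
diagnostics. A conventional best-subset search on the raw columns
(`baseline_best_subset`) is included for comparison, and seeded synthetic
generators make every stage testable without any external data.

See `docs/methods.md` for the model, the numerical conventions and the
limits of what the synthetic benchmarks demonstrate.

## Worked example

The first benchmark generator draws x₁, x₂, x₃ ~ iid U(0, 100) and sets
y = 120 + 80·x₁·x₃ exactly. From the shell:

```sh
dictreg simulate --example 1 --seed 11 -o ex1.csv
dictreg fit ex1.csv --varsigma 0.5
```

prints

```
y = 120 + 80*x1*x3

term                                  coef     p-value       VIF
x1*x3                                   80           0         1

n = 1000   R2 = 1   adj R2 = 1   RMSE = 7.45193e-11
Bland-Altman: mean diff 6.773e-11, limits of agreement [7.165e-12, 1.283e-10]
screening: dictionary 216 -> delta screen 47 (delta=0.5) -> redundancy 1 (sigma=0.5); subsets evaluated 1, rejected by VIF 0
```

Reading the output: of 216 generated dictionary columns, 47 pass the
output-correlation screen at the auto threshold δ = 0.5, redundancy
pruning at ς = 0.5 leaves a single candidate, and the search returns the
true interaction with its generative intercept (120) and coefficient (80)
recovered exactly; the residual RMSE at 1e-10 is floating-point rounding,
not misfit. The same pipeline is available in Python:

```python
import dictreg as dr

X, y = dr.gen_example1(n=1000, seed=11)
model = dr.run_parameter_selection(X, y, dr.Hyperparams(sigma=0.5))
print(model.formula())            # y = 120 + 80*x1*x3
print(dr.render_report(model).to_text())
```

The second benchmark (`--example 2`) derives all three predictors from a
single uniform variate — x₁ and x₂ are perfectly collinear — with
y = 120 + 1000/x₂; run with the default ς = 0.80, the pruner collapses the
duplication and the fit returns `y = 120 + 1000*x2^-1`. A plain best
subset on the raw columns (`dictreg baseline ex1.csv`) caps out near
adjusted R² ≈ 0.86 on the first benchmark with a strongly structured
residual plot — the comparison the dictionary approach is designed to win.

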