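# ratdyn

Identification of rational-form biochemical dynamics from time-series data
by SVD null-space extraction.

## The problem

Biochemical rate laws are rarely polynomial: enzyme turnover saturates
(Michaelis–Menten), regulation is sigmoidal (Hill), and quasi-steady-state
reductions put polynomials in the *denominator*:

    dx_k/dt = N(x) / D(x).

Sparse-regression methods that expand the right-hand side in a polynomial
library cannot represent such laws directly.  `ratdyn` uses the implicit
reformulation: clearing the denominator gives

    dx_k/dt * D(x) − N(x) = 0,

which is linear in the coefficients of N and D.  Stacking all candidate
monomials Θ(X) next to the derivative-weighted monomials ẋ_k Θ(X) yields
the observational library B; the implicit model is a null vector of B,
obtained from the right singular vector(s) at the bottom of B's spectrum,
sparsified with a fixed small threshold (λ = 10⁻⁷), and regrouped into an
explicit rational ODE with named parameters.  When the library is richer
than the law — so that every polynomial multiple of the minimal relation is
also a null vector — the pipeline isolates the minimal relation
deterministically from the null cluster (see `docs/methods.md`).

The package ships four classic benchmark systems as first-class simulators
(Michaelis–Menten kinetics, the *B. subtilis* competence circuit, batch
penicillin production, the seven-species yeast glycolysis oscillator),
noise-robust TV-regularised differentiation, edge truncation, and the
structural / parametric error metrics used to score identification.

## A worked example

```python
import ratdyn

result = ratdyn.run_benchmark("mm", seed=0)
print(result.rational_models[0].equation_string())
print(result.named_parameters)
print(result.report.structural_error, result.report.frobenius_error)
```

prints (up to round-off):

```
dx/dt = (+0.18 -0.9*x) / (+0.3 +1*x)
{'jx': 0.6000000000000001, 'Vmax': 1.5, 'Km': 0.2999999999999997}
0.0 1.8192708085380816e-16
```

Reading: from 42 samples of two substrate-decay curves, the pipeline
selected exactly the 4 true library terms out of 10 (structural error 0 —
the identified numerator 0.18 − 0.9 x over denominator 0.3 + x is
jx·Km + (jx − Vmax)x over Km + x), and the recovered (jx, Vmax, Km) agree
with the generating values (0.6, 1.5, 0.3) to relative error 2·10⁻¹⁶.

The `examples/` directory has one short script per capability:

| script | what it shows |
| --- | --- |
| `01_michaelis_menten.py` | single-state rational law, 4 of 10 terms |
| `02_competence_circuit.py` | two coupled equations, Hill terms, 12 & 10 of 56 terms |
| `03_penicillin_batch.py` | driven subsystem, substrate inhibition, 7 of 40 terms |
| `04_glycolysis_oscillator.py` | seven equations, 3432-column libraries |
| `05_noise_robustness.py` | TVRegDiff + truncation + minimal-complexity structure recovery |

A thin CLI wraps the same calls:

```bash
ratdyn run-benchmark competence --seed 0 --out results/
ratdyn noise-sweep --sigma 1e-4 0.01 0.1 --ics 200 --out results/
```

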