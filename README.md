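# resistmc

Numerical toolkit for the question every targeted cancer therapy eventually
faces: **when a growing tumour is first detected, how likely is it that
drug-resistant cells are already present?**

The tumour is modelled as a two-type birth–death–mutation Markov chain.
Drug-sensitive cells divide at rate λ and die at rate μ; each sensitive
division produces a resistant daughter with probability γ; resistant cells
divide at rate α and die at rate β. The state is the pair (m, n) of total and
resistant cell counts, started at a single sensitive cell (1, 0). The process
ends at extinction (m = 0) or when the population reaches the detection size
M. `resistmc` computes the distribution of n at that first-passage moment,
and in particular the *probability of resistance*
P(n ≥ 1 | detection), three ways:

1. **Exact** — the chain is level-structured (only m ± 1 jumps), so the
   first-arrival operator from level i to level i+1 satisfies
   F_i = P_i + Q_i F_{i−1} F_i, solved per level as
   (I − Q_i F_{i−1}) F_i = P_i with F_1 = P_1. Propagating the initial point
   mass through the F_i gives the detection distribution without ever forming
   the O(M²)-state fundamental matrix (which is retained as a small-instance
   test oracle).
2. **Aggregated** — all states of a level with n ≥ m resistant cells are
   lumped into one aggregate state under a uniform-occupancy assumption,
   capping every matrix at (m+1) × (m+1). A resistant clone that reaches
   size m goes extinct with the gambler's-ruin probability (β/α)^m — about
   7×10⁻⁵ at α/β = 1.1 for m = 100 — so the default m = 100 is accurate to
   ~10⁻⁵ relative while making M = 10⁴…10⁶ routine.
3. **Simulated** — a numba-compiled jump-chain Monte-Carlo with batch-means
   95% confidence intervals, for validation.

## Worked example

```python
from resistmc import ModelParameters, detection_distribution_approx

params = ModelParameters(lambda_div=2.0, mu_death=1.0,
                         alpha_div=2.0, beta_death=1.0, gamma_mut=1e-5)
result = detection_distribution_approx(params, M=10_000, m=100)
print(f"{result.p_resistance:.6e}")   # 1.294275e-01
print(f"{result.reach_probability:.4f}")  # 0.5000
```

At detection size 10⁴ with mutation probability 10⁻⁵ per division, roughly
13% of detected tumours already contain resistant cells, and the population
escapes early extinction with probability 1 − μ/λ = 0.5. The
`examples/` directory holds one short script per capability (exact engine,
aggregation, simulation cross-check, aggregation-size choice, parameter
sweeps), each printing the numbers it computes.

A thin CLI wraps the same functions:

```bash
resistmc approx --lambda 2 --mu 1 --alpha 2 --beta 1 --gamma 1e-5 -M 10000
resistmc simulate --lambda 2 --mu 1 --alpha 2 --beta 1 --gamma 1e-5 -M 1000 \
    --runs 100000 --batches 10 --seed 1
```

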