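"""Exact detection distribution for a small tumour.

Computes the distribution of resistant-cell counts at the moment a population
grown from a single sensitive cell first reaches 200 cells, using the exact
embedded first-passage recurrence.
"""

from resistmc import ModelParameters, detection_distribution_exact, expected_resistant_cells

params = ModelParameters(
    lambda_div=2.0, mu_death=1.0, alpha_div=2.0, beta_death=1.0, gamma_mut=1e-3
)
result = detection_distribution_exact(params, M=200)
summary = expected_resistant_cells(result)

print(f"P(reach 200 cells before extinction) = {result.reach_probability:.6f}")
print(f"P(>= 1 resistant cell at detection)  = {result.p_resistance:.6e}")
print(f"mean resistant cells at detection    = {summary.mean:.4f}")
for n in range(4):
    print(f"  P(n = {n} | detected) = {result.conditional[n]:.6e}")

# The reach probability is close to the mutation-free gambler's-ruin value
# 1 - mu/lambda = 0.5; the resistance probability is of order
# M * gamma * (number of divisions inflation), here about 25% at gamma = 1e-3.
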