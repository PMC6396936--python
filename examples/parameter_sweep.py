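"""Parameter dependence of the resistance probability.

Regenerates the rate-ratio and mutation-rate tables at nominal detection size
10^4 (aggregation size 100).  Slower net growth of the bulk means more
divisions before detection and hence more resistance; a fitter resistant
clone or a higher mutation rate also raises it.
"""

from resistmc import division_death_table, mutation_rate_table

print("p_resistance vs lambda/mu (columns) and alpha/beta (rows), gamma = 1e-5:")
print(division_death_table().to_string(float_format=lambda v: f"{v:.6e}"))

print("\np_resistance vs mutation rate (columns) for four (lambda, alpha) pairs:")
print(mutation_rate_table().to_string(float_format=lambda v: f"{v:.6e}"))
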