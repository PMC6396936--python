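# Methods

## Model

A tumour grows from a single drug-sensitive cell as a continuous-time Markov
chain on states (m, n), m = total cells, n = resistant cells. Four events are
possible from (m, n):

| event | jump | rate |
|---|---|---|
| sensitive division, no mutation | (m+1, n) | λ(1−γ)(m−n) |
| division adding a resistant cell | (m+1, n+1) | λγ(m−n) + αn |
| sensitive death | (m−1, n) | μ(m−n) |
| resistant death | (m−1, n−1) | βn |

λ, α > 0 are division rates, μ, β ≥ 0 death rates, γ ∈ [0, 1] the mutation
probability per sensitive division. Levels 0 (extinction) and M (detection)
are absorbing. All quantities of interest — the probability of reaching M
before 0 and the distribution of n at first arrival to M — depend only on
the embedded jump chain, whose transition probabilities are the rates above
divided by Γ(m,n) = (m−n)(λ+μ) + n(α+β). Holding times never enter, which is
also why the simulator samples the jump chain directly.

Assumptions: density-independent exponential growth (no carrying capacity,
no spatial structure), a single resistant type, no back-mutation, constant
rates (no therapy modulation), and mutation only at division.

## Exact first-passage engine

States of level i are ordered n = 0…i. The blocks P_i ((i+1)×(i+2)) and Q_i
((i+1)×i) hold the up/down jump probabilities; each row of [P_i | Q_i] sums
to 1 to machine precision because both entries share the denominator Γ.

The first-arrival operator F_i (level i → i+1) satisfies
F_i = P_i + Q_i F_{i−1} F_i: a trajectory either jumps straight up or visits
level i−1 first, returns, and then goes up. Each F_i is obtained by LU
solve of (I − Q_i F_{i−1}) F_i = P_i rather than by explicit inversion
(accuracy and cost), with F_1 = P_1. The detection distribution is the
initial point mass pushed through F_1 … F_{M−1}. F-products are
sub-stochastic (extinction leaks mass), so the level distribution is
renormalized at every level and the log-normalizers accumulated; the
conditional distribution is invariant to this (verified in tests at M = 100
with renormalization on and off) and the reach probability is recovered as
exp(Σ log s_i). The exact engine accepts M ≤ 2000 and warns above M = 500,
where the O(M⁴) total solve cost starts to bite (M = 500 ≈ 3.5 s on one
core).

The classical absorbing-chain route — assemble the full transient block T of
all (M−1)(M+2)/2 states and solve (I − T) X = R for the absorption
probabilities — is implemented as `fundamental_matrix_oracle` (guarded to
M ≤ 60) purely as an independent correctness oracle; tests require
agreement with the recurrence to 1e−10 componentwise over random parameter
draws at M = 2…8.

## Aggregation (lumped tail)

For levels ℓ = m + k ≥ m, the states with n ≥ m are lumped into one
aggregate state m\*. Under a uniform-occupancy assumption across the k+1
lumped states, the aggregate's outgoing rates have closed forms

- up (stay aggregated): R_A(k) = [½k(k+1)λ + ((k+1)m + ½k(k+1))α]/(k+1)
- down, stay aggregated: R_B(k) = [½k(k+1)μ + (km + ½k(k+1))β]/(k+1)
- down, exit to n = m−1: R_C(k) = mβ/(k+1)

verified in tests against direct uniform-weight enumeration of the unlumped
rates. Ordinary rows n < m keep their exact probabilities; the
resistant-gain flux out of row m−1 feeds the aggregate column. At k = 0 the
aggregate is the single corner state (m, m) and the lumped row is exact, so
choosing m ≥ M−1 reproduces the exact engine identically (tested). All
blocks and operators are then (m+1)×(m+1) and the cost is linear in M:
M = 10⁴ at m = 100 runs in ~5 s.

The error of the lumping is governed by the chance that a resistant clone of
size m dies back below the boundary: ignoring mutation replenishment, the
clone is a birth–death walk whose ruin probability from m (walls 0 and M) is
((β/α)^M − (β/α)^m)/((β/α)^M − 1) → (β/α)^m for large M. At α/β = 1.1 this
is 3.9×10⁻¹ for m = 10 but 7.3×10⁻⁵ for m = 100, the rationale for the
default m = 100. Tests confirm the resistance probability moves by < 10⁻⁴
relative when m doubles from 50 to 100 at M = 1000, and agrees with the
exact engine to better than 10⁻⁵ relative at M = 500 for the four reference
rate pairs (λ, α) ∈ {(2,2), (4,4), (2,3), (3,5)}, μ = β = 1, γ = 10⁻⁵.

Because the lumped tail has no within-tail detail, the mean resistant count
of an aggregated distribution is reported as an explicit lower bound (tail
mass counted at m) together with the tail mass itself; the tail is never
redistributed.

## Detection-size convention for tabulated values

Two conventions coexist for "detected at size M": stop at first arrival to
level M, or declare detection once the population has *exceeded* the nominal
size, i.e. run the recurrence through level M and read the distribution one
level higher. The engines (`detection_distribution_exact` / `_approx`) use
strict first arrival at M — this is what makes the closed-form anchors exact
(at M = 2, p_resistance = γ; at γ = 0 the reach probability is the
gambler's-ruin value (1−μ/λ)/(1−(μ/λ)^M)). Published tabulations of this
model follow the exceed convention; the difference is one extra growth
level, a relative shift of order 1/M damped by saturation in γ·M. The table
drivers (`division_death_table`, `mutation_rate_table`) and
`scripts/acceptance.py` therefore evaluate the first-passage distribution at
level M+1 for a nominal size M (documented flag `convention="exceed"`,
`"arrival"` available).

## Monte-Carlo simulator

The simulator draws one uniform variate per event and walks the jump chain
until absorption; the numba-compiled kernel does ~10⁸ events/s. The estimate
of p_resistance is the batch-means construction: per batch, the fraction of
detected runs carrying ≥ 1 resistant cell; the point estimate is the batch
mean and the interval mean ± 1.96·sd(batches)/√B. The default layout is
10⁶ × 10 runs; tests scale this down (10⁵ × 10 at M = 1000 for the
cross-validation, and 2000 × 50 per repetition for the coverage check — 50
batches so that the normal quantile is an adequate stand-in for the t
quantile). Per-batch seeds are spawned from the master seed via
`numpy.random.SeedSequence`, so estimates are reproducible bit for bit and
batches are independent.

## Synthetic-data / fixture battery

There is no external data; the model's inputs are the five rates and the
sizes. `generate_fixtures(seed)` emits a deterministic battery of tiny
configurations — random valid parameter draws at M = 2…8 (where the
fundamental-matrix oracle applies), mutation-free gambler's-ruin cases, and
small-aggregation cases — used by the tests. Parameter defaults throughout
(λ/μ and α/β in 1.5…5, γ in 10⁻⁶…10⁻⁴, M = 10⁴, m = 100) are the regimes in
which this model family is normally studied: net growth ratios of order 2,
point-mutation rates per division, and a detection size of order 10⁴ cells.
What the tests at these sizes do *not* establish is behaviour under
density-dependent growth, multiple resistant types, or therapy-modulated
rates, none of which the model represents.

## Numerical choices and limitations

- Linear systems: dense LAPACK `solve` per level; the (I − Q F) systems are
  diagonally dominant in practice and never near-singular for valid rates
  (λ > 0 guarantees Γ > 0 everywhere). A singular solve is treated as a bug
  signal, not handled.
- Tolerances: row-stochasticity asserted at 1e−12 relative (entries are
  ratios of exact rate sums); recurrence-vs-oracle agreement at 1e−10;
  fixed-point residuals at 1e−10. No claim is made that these match any
  original implementation.
- Degenerate inputs: μ = β = 0 (pure birth) is allowed — extinction then has
  probability 0 and every trajectory is detected after exactly M−1 net
  divisions. γ = 0 gives p_resistance = 0 exactly (no mutation flux ever
  enters the n ≥ 1 states).
- The α = β extinction formula degenerates; the symmetric-walk value
  (M−m)/M is available behind an explicit opt-in flag.
- Serialization rounds probabilities to 9 significant digits (preserves the
  6–8 digits of tabulated references); CSV labels the aggregate row
  `m_star`.
- Exact mode memory: operators are streamed, never stored, so memory is
  O(M²) at the largest level rather than O(M³) for the whole sequence.
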