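"""State-aggregation (lumping) approximation of the first-passage analysis.

Once a level carries at least ``m`` resistant cells, extinction of the
resistant clone is so unlikely (a gambler's-ruin tail, see
:func:`resistmc.diagnostics.extinction_probability`) that the detailed tail of
the distribution carries little information.  All states of level ``m + k``
with resistant count >= ``m`` are therefore lumped into a single aggregate
state ``(m+k, m*)``, capping every transition block and first-passage
operator at ``(m+1) x (m+1)`` regardless of the detection size.

Transitions out of the aggregate assume its members are occupied uniformly
(each of the ``k + 1`` lumped states with weight ``1/(k+1)``), which yields
closed-form lumped rates:

``R_A(k)`` (up, stay aggregated)   = [k(k+1)/2 * lambda + ((k+1)m + k(k+1)/2) * alpha] / (k+1)
``R_B(k)`` (down, stay aggregated) = [k(k+1)/2 * mu     + (km     + k(k+1)/2) * beta ] / (k+1)
``R_C(k)`` (down, exit to n = m-1) = m * beta / (k+1)

At ``k = 0`` the aggregate is the single corner state ``(m, m)`` and the
lumped row coincides with the exact one, so the approximation is exact for
any aggregation size >= the detection size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exact import DetectionResult, _propagate, detection_distribution_exact
from .model import (
    CellState,
    LevelMatrices,
    ModelParameters,
    ValidationError,
    build_down_matrix,
    build_up_matrix,
    validate_parameters,
)

__all__ = [
    "AggregatedRates",
    "aggregated_rates",
    "aggregated_transition_probabilities",
    "build_aggregated_level_matrices",
    "detection_distribution_approx",
    "DEFAULT_AGGREGATION_SIZE",
]

#: Default aggregation size; chosen so the resistant clone's extinction
#: probability from the aggregate boundary is negligible (< 1e-4 for growth
#: ratios alpha/beta >= 1.1) while keeping matrices at 101 x 101.
DEFAULT_AGGREGATION_SIZE = 100


@dataclass(frozen=True)
class AggregatedRates:
    """Lumped transition rates of aggregate state ``(m + k, m*)``."""

    k: int
    m: int
    up_rate: float  # R_A: to (m+k+1, m*)
    down_stay_rate: float  # R_B: to (m+k-1, m*)
    down_exit_rate: float  # R_C: to (m+k-1, m-1)

    @property
    def total(self) -> float:
        return self.up_rate + self.down_stay_rate + self.down_exit_rate


def aggregated_rates(k: int, m: int, params: ModelParameters) -> AggregatedRates:
    """Closed-form lumped rates of the aggregate at excess level ``k``.

    Uniform occupancy over the ``k + 1`` lumped states
    ``(m+k, m), ..., (m+k, m+k)`` is assumed.  At ``k = 0`` this reduces to
    the exact rates of the corner state: ``(m alpha, 0, m beta)``.
    """
    if k < 0 or m < 1:
        raise ValidationError(f"need k >= 0 and m >= 1, got (k={k}, m={m})")
    lam, mu = params.lambda_div, params.mu_death
    alpha, beta = params.alpha_div, params.beta_death
    half = 0.5 * k * (k + 1)
    up = (half * lam + ((k + 1) * m + half) * alpha) / (k + 1)
    down_stay = (half * mu + (k * m + half) * beta) / (k + 1)
    down_exit = m * beta / (k + 1)
    return AggregatedRates(k=k, m=m, up_rate=up, down_stay_rate=down_stay, down_exit_rate=down_exit)


def aggregated_transition_probabilities(
    k: int, m: int, params: ModelParameters
) -> tuple[float, float, float]:
    """Jump probabilities of the aggregate: (up, down-stay, down-exit).

    These are the lumped rates divided by their sum; algebraically the up
    probability equals ``[k lambda + (2m+k) alpha] / [k(lambda+mu) +
    (2m+k)(alpha+beta)]`` and analogously for the two down moves.
    """
    rates = aggregated_rates(k, m, params)
    total = rates.total
    return (rates.up_rate / total, rates.down_stay_rate / total, rates.down_exit_rate / total)


def build_aggregated_level_matrices(
    level: int, m: int, params: ModelParameters, M: int | None = None
) -> LevelMatrices:
    """Lumped blocks of level ``level`` (>= ``m``), state order ``0..m-1, m*``.

    Ordinary rows ``j = 0..m-1`` keep the exact jump probabilities of a level
    with ``level`` total cells; the resistant-gain flux out of row ``m - 1``
    is directed into the aggregate column.  The aggregate row uses the lumped
    rates for ``k = level - m``.  Shapes are ``(m+1) x (m+1)``, except the
    down block of the boundary level ``level = m``, which maps into the
    unaggregated level ``m - 1`` and is ``(m+1) x m``.
    """
    if m < 1:
        raise ValidationError(f"aggregation size must be >= 1, got {m}")
    if level < m:
        raise ValidationError(f"level {level} is below the aggregation boundary {m}")
    if M is not None and not level <= M - 1:
        raise ValidationError(f"level {level} is not transient for detection size {M}")
    k = level - m
    lam, mu = params.lambda_div, params.mu_death
    alpha, beta = params.alpha_div, params.beta_death

    up = np.zeros((m + 1, m + 1))
    down = np.zeros((m + 1, m if k == 0 else m + 1))
    j = np.arange(m)
    g = (level - j) * (lam + mu) + j * (alpha + beta)
    up[j, j] = (level - j) * lam * (1.0 - params.gamma_mut) / g
    up[j, np.minimum(j + 1, m)] = ((level - j) * lam * params.gamma_mut + j * alpha) / g
    down[j, j] = (level - j) * mu / g
    jj = j[1:]
    down[jj, jj - 1] = jj * beta / g[1:]

    rates = aggregated_rates(k, m, params)
    total = rates.total
    up[m, m] = rates.up_rate / total
    down[m, m - 1] = rates.down_exit_rate / total
    if k >= 1:
        down[m, m] = rates.down_stay_rate / total  # R_B(0) = 0: column absent at k = 0
    return LevelMatrices(level=level, up=up, down=down)


def _mixed_blocks(params: ModelParameters, M: int, m: int):
    for i in range(1, min(m, M)):
        yield i, build_up_matrix(i, params), build_down_matrix(i, params)
    for i in range(m, M):
        lumped = build_aggregated_level_matrices(i, m, params, M)
        yield i, lumped.up, lumped.down


def detection_distribution_approx(
    params: ModelParameters,
    M: int,
    m: int = DEFAULT_AGGREGATION_SIZE,
    initial: CellState = CellState(1, 0),
    renormalize: bool = True,
) -> DetectionResult:
    """Approximate first-arrival distribution at level ``M`` with lumped tail.

    Levels below the aggregation size ``m`` use the exact blocks; levels at or
    above it use the lumped ``(m+1) x (m+1)`` blocks, so cost grows linearly
    in ``M``.  The returned distribution has ``m + 1`` entries: resistant
    counts ``0 .. m-1`` plus the aggregate mass (>= ``m`` resistant cells).
    With ``m >= M`` the computation falls back to the exact engine.
    """
    if m >= M:
        return detection_distribution_exact(params, M, initial, renormalize)
    validate_parameters(params, M, m)
    if not 1 <= initial.total < M:
        raise ValidationError(f"initial total must be in [1, M-1], got {initial.total}")
    initial_index = initial.resistant if initial.total < m else min(initial.resistant, m)
    conditional, reach = _propagate(
        _mixed_blocks(params, M, m), initial.total, initial_index, renormalize
    )
    return DetectionResult(
        detection_size=M,
        raw=conditional * reach,
        reach_probability=reach,
        conditional=conditional,
        p_resistance=1.0 - float(conditional[0]),
        aggregated=True,
        agg_size=m,
    )
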