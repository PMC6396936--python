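"""Two-type birth-death-mutation model of an expanding cancer cell population.

A tumour is modelled as a mixture of drug-sensitive cells (division rate
``lambda``, death rate ``mu``) and drug-resistant cells (division rate
``alpha``, death rate ``beta``).  When a sensitive cell divides, one daughter
acquires resistance with probability ``gamma``.  The population state is the
pair ``(m, n)`` of total and resistant cell counts; jumps change ``m`` by one,
so the chain is level-structured (quasi-birth-death): level ``i`` is the set
of states with ``i`` total cells, ordered by resistant count ``n = 0..i``.

This module defines the parameters, the elementary four-outcome jump
distribution of the embedded (jump) chain, and the per-level transition
probability blocks ``P_i`` (level ``i`` -> ``i+1``) and ``Q_i``
(level ``i`` -> ``i-1``) from which everything else is built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ValidationError",
    "ModelParameters",
    "CellState",
    "LevelMatrices",
    "TransitionProbabilities",
    "rate_sum",
    "transition_probabilities",
    "build_up_matrix",
    "build_down_matrix",
    "validate_parameters",
]


class ValidationError(ValueError):
    """A model parameter or configuration violates its validity constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the two-type birth-death-mutation process.

    Parameters
    ----------
    lambda_div : float
        Division rate of sensitive cells (per cell per unit time), > 0.
    mu_death : float
        Death rate of sensitive cells, >= 0.
    alpha_div : float
        Division rate of resistant cells, > 0.
    beta_death : float
        Death rate of resistant cells, >= 0.
    gamma_mut : float
        Probability that a sensitive division produces one resistant
        daughter, in [0, 1].
    """

    lambda_div: float
    mu_death: float
    alpha_div: float
    beta_death: float
    gamma_mut: float

    def __post_init__(self) -> None:
        if not self.lambda_div > 0:
            raise ValidationError(f"lambda_div must be > 0, got {self.lambda_div}")
        if not self.alpha_div > 0:
            raise ValidationError(f"alpha_div must be > 0, got {self.alpha_div}")
        if self.mu_death < 0:
            raise ValidationError(f"mu_death must be >= 0, got {self.mu_death}")
        if self.beta_death < 0:
            raise ValidationError(f"beta_death must be >= 0, got {self.beta_death}")
        if not 0.0 <= self.gamma_mut <= 1.0:
            raise ValidationError(f"gamma_mut must be in [0, 1], got {self.gamma_mut}")


@dataclass(frozen=True)
class CellState:
    """Population state: ``total`` cells of which ``resistant`` are resistant."""

    total: int
    resistant: int

    def __post_init__(self) -> None:
        if not 0 <= self.resistant <= self.total:
            raise ValidationError(
                f"resistant count must satisfy 0 <= n <= m, got ({self.total}, {self.resistant})"
            )


@dataclass(frozen=True)
class LevelMatrices:
    """Per-level transition probability blocks of the jump chain.

    ``up[j, k]`` is the one-step probability of moving from the ``j``-th state
    of ``level`` to the ``k``-th state of ``level + 1``; ``down`` likewise for
    ``level - 1``.  For the exact chain the shapes are ``(i+1, i+2)`` and
    ``(i+1, i)``; aggregated levels reuse this container with capped shapes.
    """

    level: int
    up: np.ndarray
    down: np.ndarray


class TransitionProbabilities(NamedTuple):
    """One-jump distribution from ``(m, n)``, in the order
    ``(m+1, n)``, ``(m+1, n+1)``, ``(m-1, n)``, ``(m-1, n-1)``."""

    grow_sensitive: float
    grow_resistant: float
    shrink_sensitive: float
    shrink_resistant: float


def rate_sum(i: int, j: int, params: ModelParameters) -> float:
    """Total event rate ``Gamma_{i,j} = (i-j)(lambda+mu) + j(alpha+beta)``
    of a state with ``i`` cells, ``j`` of them resistant."""
    if i < 1 or not 0 <= j <= i:
        raise ValidationError(f"rate_sum requires 1 <= i and 0 <= j <= i, got (i={i}, j={j})")
    total = (i - j) * (params.lambda_div + params.mu_death) + j * (
        params.alpha_div + params.beta_death
    )
    if not total > 0:
        raise ValidationError(f"zero total rate at (i={i}, j={j})")
    return total


def transition_probabilities(
    state: CellState, params: ModelParameters, detection_size: int | None = None
) -> TransitionProbabilities:
    """Jump-chain distribution over the four successor states of ``state``.

    The sensitive sub-population of size ``m - n`` divides without mutation at
    rate ``lambda (1-gamma) (m-n)`` and with mutation at ``lambda gamma (m-n)``;
    resistant cells divide at ``alpha n`` and die at ``beta n``.  Dividing each
    rate by their sum ``Gamma_{m,n}`` gives the embedded-chain probabilities.

    Raises if ``state`` sits on an absorbing level (``m = 0``, or
    ``m >= detection_size`` when a detection size is supplied).
    """
    m, n = state.total, state.resistant
    if m == 0:
        raise ValidationError("state (0, 0) is absorbing (extinction)")
    if detection_size is not None and m >= detection_size:
        raise ValidationError(f"level {m} is at/beyond the absorbing detection level {detection_size}")
    total = rate_sum(m, n, params)
    s = m - n
    return TransitionProbabilities(
        grow_sensitive=params.lambda_div * (1.0 - params.gamma_mut) * s / total,
        grow_resistant=(params.lambda_div * params.gamma_mut * s + params.alpha_div * n) / total,
        shrink_sensitive=params.mu_death * s / total,
        shrink_resistant=params.beta_death * n / total,
    )


def _gammas(i: int, j: np.ndarray, params: ModelParameters) -> np.ndarray:
    return (i - j) * (params.lambda_div + params.mu_death) + j * (
        params.alpha_div + params.beta_death
    )


def build_up_matrix(i: int, params: ModelParameters) -> np.ndarray:
    """Exact block ``P_i`` (shape ``(i+1, i+2)``), level ``i`` -> ``i+1``.

    Row ``j`` holds ``(i-j) lambda (1-gamma) / Gamma_{i,j}`` in column ``j``
    (sensitive division, no mutation) and
    ``{(i-j) lambda gamma + j alpha} / Gamma_{i,j}`` in column ``j+1``
    (any division that adds a resistant cell).
    """
    if i < 1:
        raise ValidationError(f"level index must be >= 1, got {i}")
    j = np.arange(i + 1)
    g = _gammas(i, j, params)
    up = np.zeros((i + 1, i + 2))
    up[j, j] = (i - j) * params.lambda_div * (1.0 - params.gamma_mut) / g
    up[j, j + 1] = ((i - j) * params.lambda_div * params.gamma_mut + j * params.alpha_div) / g
    return up


def build_down_matrix(i: int, params: ModelParameters) -> np.ndarray:
    """Exact block ``Q_i`` (shape ``(i+1, i)``), level ``i`` -> ``i-1``.

    Row ``j`` holds ``j beta / Gamma_{i,j}`` in column ``j-1`` (resistant
    death) and ``(i-j) mu / Gamma_{i,j}`` in column ``j`` (sensitive death).
    """
    if i < 1:
        raise ValidationError(f"level index must be >= 1, got {i}")
    j = np.arange(i + 1)
    g = _gammas(i, j, params)
    down = np.zeros((i + 1, i))
    jj = j[:-1]  # j = i has no sensitive cells left
    down[jj, jj] = (i - jj) * params.mu_death / g[:-1]
    jj = j[1:]
    down[jj, jj - 1] += jj * params.beta_death / g[1:]
    return down


def level_matrices(i: int, params: ModelParameters) -> LevelMatrices:
    """Both exact blocks of level ``i`` bundled together."""
    return LevelMatrices(level=i, up=build_up_matrix(i, params), down=build_down_matrix(i, params))


def validate_parameters(
    params: ModelParameters, M: int, m_agg: int | None = None
) -> tuple[ModelParameters, int, int | None]:
    """Check a full run configuration; returns it unchanged if valid.

    ``M`` is the detection size (absorbing level), ``m_agg`` the aggregation
    size capping matrix dimensions in the approximate engine.
    """
    # ModelParameters re-validates its own invariants on construction.
    ModelParameters(
        params.lambda_div, params.mu_death, params.alpha_div, params.beta_death, params.gamma_mut
    )
    if int(M) != M or M < 2:
        raise ValidationError(f"detection size M must be an integer >= 2, got {M}")
    if m_agg is not None:
        if int(m_agg) != m_agg or m_agg < 1:
            raise ValidationError(f"aggregation size must be an integer >= 1, got {m_agg}")
        if m_agg > M:
            raise ValidationError(f"aggregation size {m_agg} exceeds detection size {M}")
    return params, int(M), None if m_agg is None else int(m_agg)
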