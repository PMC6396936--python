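"""Exact first-passage analysis of the level-structured chain.

The quantity of interest is the distribution of the resistant-cell count at
the moment the total population first reaches the detection size ``M``
(before going extinct).  Instead of inverting the full transient block of the
absorbing chain -- feasible only for tiny ``M`` -- the computation runs level
by level through the embedded chain of first arrivals:

``F_i`` is the matrix of first-arrival probabilities from the states of level
``i`` to those of level ``i+1``.  A path either jumps up directly or first
drops to level ``i-1``, returns, and then goes up, which gives the fixed
point ``F_i = P_i + Q_i F_{i-1} F_i``, solved per level as the linear system
``(I - Q_i F_{i-1}) F_i = P_i`` with ``F_1 = P_1``.  Propagating the initial
point mass through the ``F_i`` yields the (sub-stochastic) first-arrival
distribution at level ``M``; its total mass is the probability of ever
reaching ``M``, and renormalizing gives the conditional distribution.

The brute-force fundamental-matrix route over the full two-dimensional state
space is retained as an independent oracle for small ``M``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .model import (
    CellState,
    ModelParameters,
    ValidationError,
    build_down_matrix,
    build_up_matrix,
    validate_parameters,
)

__all__ = [
    "FirstPassageOperator",
    "DetectionResult",
    "OracleAbsorption",
    "first_passage_operators",
    "detection_distribution_exact",
    "fundamental_matrix_oracle",
    "EXACT_SIZE_LIMIT",
    "EXACT_SIZE_WARNING",
]

logger = logging.getLogger("resistmc")

#: Largest detection size accepted by the exact engine; beyond this the
#: per-level solves (O(M^4) total work) stop being practical and the
#: aggregation engine should be used instead.
EXACT_SIZE_LIMIT = 2000
#: Size above which a cost warning is emitted.
EXACT_SIZE_WARNING = 500


@dataclass(frozen=True)
class FirstPassageOperator:
    """First-arrival probabilities from level ``level`` to ``level + 1``.

    ``matrix[j, k]`` is the probability that, starting from the ``j``-th state
    of the level, the chain ever reaches the next level and does so first in
    its ``k``-th state.  Row sums are <= 1 because extinction is possible.
    """

    level: int
    matrix: np.ndarray


@dataclass(frozen=True)
class DetectionResult:
    """First-arrival distribution of resistant-cell counts at detection.

    Attributes
    ----------
    detection_size : int
        The absorbing level ``M``.
    raw : numpy.ndarray
        Unnormalized first-arrival weights; sums to ``reach_probability``.
        Length ``M + 1`` for the exact engine, ``m_agg + 1`` when aggregated
        (last entry = aggregate mass of >= ``m_agg`` resistant cells).
    reach_probability : float
        Probability of hitting level ``M`` before extinction.
    conditional : numpy.ndarray
        ``raw`` normalized to total mass 1.
    p_resistance : float
        ``1 - conditional[0]``: probability that at least one resistant cell
        is present at detection, given detection happens.
    aggregated : bool
        Whether the tail of the distribution is lumped.
    agg_size : int or None
        Aggregation size used, if any.
    """

    detection_size: int
    raw: np.ndarray
    reach_probability: float
    conditional: np.ndarray
    p_resistance: float
    aggregated: bool = False
    agg_size: int | None = None


@dataclass(frozen=True)
class OracleAbsorption:
    """Absorption distribution computed from the fundamental matrix."""

    detection_size: int
    extinction_probability: float
    arrival: np.ndarray  # unnormalized mass into states (M, j), j = 0..M
    conditional: np.ndarray
    p_resistance: float


def _exact_blocks(params: ModelParameters, M: int) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    for i in range(1, M):
        yield i, build_up_matrix(i, params), build_down_matrix(i, params)


def _first_passage(
    blocks: Iterable[tuple[int, np.ndarray, np.ndarray]],
) -> Iterator[tuple[int, np.ndarray]]:
    """Stream ``(i, F_i)`` over a stream of ``(i, P_i, Q_i)`` blocks."""
    F: np.ndarray | None = None
    for i, up, down in blocks:
        if F is None:
            F = up
        else:
            system = -down @ F
            system[np.diag_indices_from(system)] += 1.0
            F = np.linalg.solve(system, up)
        yield i, F


def first_passage_operators(params: ModelParameters, M: int) -> Iterator[FirstPassageOperator]:
    """Yield ``F_i`` for ``i = 1 .. M-1`` (lazily; only ``F_{i-1}`` is kept).

    Materializing the whole sequence is only sensible for small ``M``.
    """
    validate_parameters(params, M)
    for i, F in _first_passage(_exact_blocks(params, M)):
        yield FirstPassageOperator(level=i, matrix=F)


def _propagate(
    blocks: Iterable[tuple[int, np.ndarray, np.ndarray]],
    initial_level: int,
    initial_index: int,
    renormalize: bool = True,
) -> tuple[np.ndarray, float]:
    """Push a point mass at (``initial_level``, ``initial_index``) through the
    first-passage operators; returns (conditional distribution at the level
    past the last block, reach probability).

    With ``renormalize`` the level distribution is rescaled to total mass 1
    after every step and the log of the running normalizer is accumulated, so
    the conditional distribution never underflows; the reach probability is
    recovered as the exponential of the accumulated log.
    """
    pi: np.ndarray | None = None
    log_reach = 0.0
    for i, F in _first_passage(blocks):
        if pi is None:
            if i < initial_level:
                continue
            if i != initial_level:
                raise ValidationError(
                    f"initial level {initial_level} not visited by the block stream"
                )
            pi = np.zeros(F.shape[0])
            pi[initial_index] = 1.0
        pi = pi @ F
        if renormalize:
            s = pi.sum()
            pi /= s
            log_reach += math.log(s)
        if i % 100 == 0:
            logger.info("first-passage propagation through level %d", i)
    if pi is None:
        raise ValidationError("empty block stream")
    if renormalize:
        # one last normalization guards the 1e-10 sum invariant
        s = pi.sum()
        conditional = pi / s
        reach = math.exp(log_reach + math.log(s))
    else:
        reach = float(pi.sum())
        conditional = pi / reach
    return conditional, reach


def detection_distribution_exact(
    params: ModelParameters,
    M: int,
    initial: CellState = CellState(1, 0),
    renormalize: bool = True,
) -> DetectionResult:
    """Exact first-arrival distribution of resistant counts at level ``M``.

    Parameters
    ----------
    params : ModelParameters
    M : int
        Detection size (absorbing level), ``2 <= M <= EXACT_SIZE_LIMIT``.
    initial : CellState
        Starting state; default a single sensitive cell ``(1, 0)``.
    renormalize : bool
        Keep the per-level renormalization on (default).  Off is supported
        only to demonstrate that the conditional distribution is invariant
        to it; at large ``M`` the raw products may underflow without it.
    """
    validate_parameters(params, M)
    if not 1 <= initial.total < M:
        raise ValidationError(f"initial total must be in [1, M-1], got {initial.total}")
    if M > EXACT_SIZE_LIMIT:
        raise ValidationError(
            f"exact engine supports M <= {EXACT_SIZE_LIMIT}; use the aggregation engine"
        )
    if M > EXACT_SIZE_WARNING:
        warnings.warn(
            f"exact analysis at M={M} is O(M^4); the aggregation engine is much cheaper",
            RuntimeWarning,
            stacklevel=2,
        )
    conditional, reach = _propagate(
        _exact_blocks(params, M), initial.total, initial.resistant, renormalize
    )
    return DetectionResult(
        detection_size=M,
        raw=conditional * reach,
        reach_probability=reach,
        conditional=conditional,
        p_resistance=1.0 - float(conditional[0]),
    )


#: Guard for the brute-force oracle; the dense transient block has
#: (M-1)(M+2)/2 states and is meant for cross-checking only.
ORACLE_SIZE_LIMIT = 60


def fundamental_matrix_oracle(
    params: ModelParameters, M: int, initial: CellState = CellState(1, 0)
) -> OracleAbsorption:
    """Absorption distribution via the fundamental matrix ``(I - T)^{-1}``.

    Assembles the full transient block ``T`` over states
    ``{(i, j) : 1 <= i <= M-1, 0 <= j <= i}`` and solves for the absorption
    probabilities into extinction ``(0, 0)`` and into each detection state
    ``(M, j)``.  Independent of the first-passage recurrence; used as a
    small-instance oracle in tests.
    """
    validate_parameters(params, M)
    if M > ORACLE_SIZE_LIMIT:
        raise ValidationError(f"fundamental-matrix oracle is limited to M <= {ORACLE_SIZE_LIMIT}")
    if not 1 <= initial.total < M:
        raise ValidationError(f"initial total must be in [1, M-1], got {initial.total}")

    offsets = np.concatenate([[0], np.cumsum([i + 1 for i in range(1, M)])])
    n_transient = int(offsets[-1])
    T = np.zeros((n_transient, n_transient))
    absorbing = np.zeros((n_transient, M + 2))  # col 0: (0,0); cols 1..M+1: (M, j)
    for i in range(1, M):
        rows = slice(offsets[i - 1], offsets[i - 1] + i + 1)
        up = build_up_matrix(i, params)
        down = build_down_matrix(i, params)
        if i + 1 <= M - 1:
            T[rows, offsets[i] : offsets[i] + i + 2] = up
        else:
            absorbing[rows, 1:] = up
        if i - 1 >= 1:
            T[rows, offsets[i - 2] : offsets[i - 2] + i] = down
        else:
            absorbing[rows, 0] = down[:, 0]

    system = np.eye(n_transient) - T
    absorption = np.linalg.solve(system, absorbing)
    start = offsets[initial.total - 1] + initial.resistant
    p_extinct = float(absorption[start, 0])
    arrival = absorption[start, 1:].copy()
    conditional = arrival / arrival.sum()
    return OracleAbsorption(
        detection_size=M,
        extinction_probability=p_extinct,
        arrival=arrival,
        conditional=conditional,
        p_resistance=1.0 - float(conditional[0]),
    )
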