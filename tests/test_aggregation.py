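"""Lumped-tail approximation: rates, blocks, and detection distributions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from resistmc import (
    ModelParameters,
    ValidationError,
    aggregated_rates,
    aggregated_transition_probabilities,
    build_aggregated_level_matrices,
    build_down_matrix,
    build_up_matrix,
    detection_distribution_approx,
    detection_distribution_exact,
)
from conftest import RATE_PAIRS, pair_params, random_valid_params

rates_st = st.floats(0.1, 5.0)
params_st = st.builds(ModelParameters, rates_st, st.floats(0.0, 3.0), rates_st, st.floats(0.0, 3.0), st.floats(0.0, 0.5))


def enumerated_rates(k, m, params):
    """Oracle: average the unlumped state rates uniformly over the aggregate.

    The aggregate at excess level k contains states (m+k, m+x), x = 0..k; with
    uniform occupancy the lumped up-rate is the mean of the per-state division
    rates, the down-stay rate the mean of the death rates that keep the
    resistant count >= m, and the down-exit rate the mean of the flux to
    n = m - 1 (a resistant death in a state with exactly m resistant cells).
    """
    lam, mu = params.lambda_div, params.mu_death
    alpha, beta = params.alpha_div, params.beta_death
    up = np.mean([(k - x) * lam + (m + x) * alpha for x in range(k + 1)])
    down_stay = np.mean(
        [(k - x) * mu for x in range(k + 1)]
    ) + np.mean([(m + x) * beta if x >= 1 else 0.0 for x in range(k + 1)])
    down_exit = np.mean([m * beta if x == 0 else 0.0 for x in range(k + 1)])
    return up, down_stay, down_exit


def test_aggregate_rates_at_boundary_level():
    """At k = 0 the aggregate is the single corner state (m, m)."""
    r = aggregated_rates(0, 100, ModelParameters(2, 1, 2, 1, 0.0))
    assert (r.up_rate, r.down_stay_rate, r.down_exit_rate) == (200.0, 0.0, 100.0)


@pytest.mark.parametrize("k, m", [(1, 1), (2, 10), (5, 3), (17, 40)])
def test_aggregate_rates_match_uniform_enumeration(k, m):
    params = ModelParameters(3, 1, 2, 1, 0.05)
    r = aggregated_rates(k, m, params)
    up, down_stay, down_exit = enumerated_rates(k, m, params)
    assert r.up_rate == pytest.approx(up, rel=1e-12)
    assert r.down_stay_rate == pytest.approx(down_stay, rel=1e-12)
    assert r.down_exit_rate == pytest.approx(down_exit, rel=1e-12)


def test_aggregate_probabilities_closed_forms():
    """The probability ratios admit closed forms in k, m and the rates."""
    k, m = 2, 10
    params = ModelParameters(3, 1, 2, 1, 0.0)
    up, down_stay, down_exit = aggregated_transition_probabilities(k, m, params)
    assert up == pytest.approx(50 / 74, rel=1e-14)
    lam, mu, alpha, beta = 3, 1, 2, 1
    denom = k * (lam + mu) + (2 * m + k) * (alpha + beta)
    assert up == pytest.approx((k * lam + (2 * m + k) * alpha) / denom, rel=1e-12)
    assert down_stay == pytest.approx(
        (k * (k + 1) * mu + (2 * k * m + k * (k + 1)) * beta) / ((k + 1) * denom), rel=1e-12
    )
    assert down_exit == pytest.approx(2 * m * beta / ((k + 1) * denom), rel=1e-12)


def test_boundary_aggregate_probabilities():
    up, down_stay, down_exit = aggregated_transition_probabilities(
        0, 7, ModelParameters(2, 1, 3, 1, 0.1)
    )
    assert up == pytest.approx(3 / 4, rel=1e-14)
    assert down_stay == 0.0
    assert down_exit == pytest.approx(1 / 4, rel=1e-14)


@given(k=st.integers(0, 60), m=st.integers(1, 200), params=params_st)
def test_aggregate_outcomes_normalize(k, m, params):
    probs = aggregated_transition_probabilities(k, m, params)
    assert all(p >= 0 for p in probs)
    assert sum(probs) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("offset", range(0, 51, 10))
def test_aggregated_blocks_are_row_stochastic(offset):
    m = 7
    params = ModelParameters(2.5, 1, 2, 0.8, 0.01)
    block = build_aggregated_level_matrices(m + offset, m, params)
    totals = block.up.sum(axis=1) + block.down.sum(axis=1)
    np.testing.assert_allclose(totals, 1.0, rtol=1e-12)
    assert np.all(block.up >= 0) and np.all(block.down >= 0)


def test_boundary_block_equals_exact_block_with_merged_columns():
    """At level m the lumped block is the exact one with the two up-columns
    that enter the next level's aggregate summed."""
    m = 6
    params = ModelParameters(2, 1, 3, 1, 0.2)
    block = build_aggregated_level_matrices(m, m, params)
    up_exact = build_up_matrix(m, params)
    down_exact = build_down_matrix(m, params)
    merged = np.column_stack([up_exact[:, : m], up_exact[:, m] + up_exact[:, m + 1]])
    np.testing.assert_allclose(block.up, merged, atol=1e-15)
    np.testing.assert_allclose(block.down, down_exact, atol=1e-15)


def test_aggregated_block_shape_guards():
    params = ModelParameters(2, 1, 2, 1, 0.0)
    with pytest.raises(ValidationError):
        build_aggregated_level_matrices(3, 5, params)
    with pytest.raises(ValidationError):
        build_aggregated_level_matrices(10, 5, params, M=10)


def test_lumping_only_last_two_states_is_exact():
    """m = M - 1 lumps just the two top detection states, so every probability
    it can express matches the exact engine."""
    M = 60
    params = ModelParameters(2, 1, 2, 1, 1e-3)
    exact = detection_distribution_exact(params, M)
    approx = detection_distribution_approx(params, M, M - 1)
    assert approx.aggregated and approx.conditional.size == M
    np.testing.assert_allclose(approx.conditional[: M - 1], exact.conditional[: M - 1], atol=1e-12)
    assert approx.conditional[-1] == pytest.approx(
        exact.conditional[M - 1] + exact.conditional[M], abs=1e-12
    )
    assert approx.p_resistance == pytest.approx(exact.p_resistance, abs=1e-12)
    assert approx.reach_probability == pytest.approx(exact.reach_probability, rel=1e-12)


def test_aggregation_size_at_detection_size_falls_back_to_exact():
    params = ModelParameters(2, 1, 2, 1, 1e-3)
    exact = detection_distribution_exact(params, 50)
    approx = detection_distribution_approx(params, 50, 50)
    np.testing.assert_allclose(approx.conditional, exact.conditional, atol=1e-10)
    assert not approx.aggregated


def test_small_aggregation_size_still_accurate():
    """Even m = 10 keeps the resistance probability within a few times the
    resistant clone's extinction tail of the exact value."""
    params = ModelParameters(2, 1, 2, 1, 1e-3)
    exact = detection_distribution_exact(params, 200).p_resistance
    approx = detection_distribution_approx(params, 200, 10).p_resistance
    assert approx == pytest.approx(exact, rel=1e-2)


def test_resistance_probability_insensitive_to_aggregation_size(approx_m500):
    """Doubling m from 50 to 100 moves the answer by < 1e-4 relative."""
    for lam, alpha in RATE_PAIRS.values():
        params = pair_params(lam, alpha)
        p100 = detection_distribution_approx(params, 1000, 100).p_resistance
        p50 = detection_distribution_approx(params, 1000, 50).p_resistance
        assert abs(p50 - p100) / p100 <= 1e-4


def test_no_mutation_means_no_resistance():
    result = detection_distribution_approx(ModelParameters(2, 1, 2, 1, 0.0), 400, 20)
    assert result.p_resistance == 0.0


def test_conditional_sums_to_one_when_aggregated():
    result = detection_distribution_approx(ModelParameters(2, 1, 3, 1, 1e-4), 600, 30)
    assert result.conditional.sum() == pytest.approx(1.0, abs=1e-10)
    assert result.conditional.size == 31
    assert result.agg_size == 30
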