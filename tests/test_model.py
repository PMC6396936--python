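"""Elementary transition structure of the two-type birth-death-mutation chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from resistmc import (
    CellState,
    ModelParameters,
    ValidationError,
    build_down_matrix,
    build_up_matrix,
    rate_sum,
    transition_probabilities,
    validate_parameters,
)

rates = st.floats(0.1, 5.0, allow_nan=False)
deaths = st.floats(0.0, 3.0, allow_nan=False)
gammas = st.floats(0.0, 1.0, allow_nan=False)
params_strategy = st.builds(ModelParameters, rates, deaths, rates, deaths, gammas)


@pytest.mark.parametrize(
    "i, j, params, expected",
    [
        (1, 0, ModelParameters(2, 1, 2, 1, 0.0), 3.0),
        (2, 1, ModelParameters(2, 1, 2, 1, 0.0), 6.0),
        (5, 5, ModelParameters(2, 1, 3, 1, 0.0), 20.0),
    ],
)
def test_rate_sum_examples(i, j, params, expected):
    assert rate_sum(i, j, params) == pytest.approx(expected, abs=0)


@pytest.mark.parametrize("i, j", [(0, 0), (3, 4), (2, -1)])
def test_rate_sum_rejects_invalid_state(i, j):
    with pytest.raises(ValidationError):
        rate_sum(i, j, ModelParameters(2, 1, 2, 1, 0.0))


def test_transition_probabilities_by_direct_substitution():
    probs = transition_probabilities(CellState(2, 1), ModelParameters(2, 1, 2, 1, 0.01))
    assert probs.grow_sensitive == pytest.approx(0.33, abs=1e-15)
    assert probs.grow_resistant == pytest.approx(2.02 / 6, abs=1e-15)
    assert probs.shrink_sensitive == pytest.approx(1 / 6, abs=1e-15)
    assert probs.shrink_resistant == pytest.approx(1 / 6, abs=1e-15)
    assert sum(probs) == pytest.approx(1.0, abs=1e-12)


def test_no_resistant_gain_without_mutation_from_sensitive_state():
    probs = transition_probabilities(CellState(1, 0), ModelParameters(3, 0.5, 2, 1, 0.0))
    assert probs.grow_resistant == 0.0
    assert probs.shrink_resistant == 0.0


def test_all_resistant_state_has_pure_resistant_dynamics():
    probs = transition_probabilities(CellState(3, 3), ModelParameters(5, 1, 2, 1, 0.2))
    assert probs.grow_sensitive == 0.0
    assert probs.shrink_sensitive == 0.0
    assert probs.grow_resistant == pytest.approx(2 / 3, abs=1e-15)
    assert probs.shrink_resistant == pytest.approx(1 / 3, abs=1e-15)


def test_transition_probabilities_rejects_absorbing_levels():
    params = ModelParameters(2, 1, 2, 1, 0.1)
    with pytest.raises(ValidationError):
        transition_probabilities(CellState(0, 0), params)
    with pytest.raises(ValidationError):
        transition_probabilities(CellState(10, 3), params, detection_size=10)


def test_up_matrix_entries_level_one():
    up = build_up_matrix(1, ModelParameters(2, 1, 2, 1, 0.0))
    assert np.allclose(up[0], [2 / 3, 0, 0], atol=1e-15)
    # state (1, 1): resistant division with probability alpha/(alpha+beta)
    assert np.allclose(up[1], [0, 0, 2 / 3], atol=1e-15)


def test_up_matrix_last_row_is_pure_resistant_division():
    params = ModelParameters(2, 1, 3, 1, 0.2)
    up = build_up_matrix(3, params)
    expected = 3 * params.alpha_div / rate_sum(3, 3, params)
    assert up[3, 4] == pytest.approx(expected, abs=1e-15)
    assert np.count_nonzero(up[3]) == 1


def test_down_matrix_entries():
    params = ModelParameters(2, 1, 2, 1, 0.0)
    down = build_down_matrix(1, params)
    assert down.shape == (2, 1)
    assert down[0, 0] == pytest.approx(1 / 3, abs=1e-15)
    down2 = build_down_matrix(2, ModelParameters(2, 1, 2, 1, 0.3))
    # all-resistant row: only the resistant-death column is populated
    assert down2[2, 1] == pytest.approx(2 * 1 / rate_sum(2, 2, ModelParameters(2, 1, 2, 1, 0.3)))
    assert down2[2, 0] == 0.0


@given(params=params_strategy, i=st.integers(1, 40))
def test_level_blocks_are_row_stochastic_sparse_and_bounded(params, i):
    """Every level's [up | down] block is row-stochastic with banded support."""
    up = build_up_matrix(i, params)
    down = build_down_matrix(i, params)
    assert up.shape == (i + 1, i + 2) and down.shape == (i + 1, i)
    assert np.all(up >= 0) and np.all(up <= 1)
    assert np.all(down >= 0) and np.all(down <= 1)
    np.testing.assert_allclose(up.sum(axis=1) + down.sum(axis=1), 1.0, rtol=1e-12)
    for j in range(i + 1):
        off_band_up = np.delete(up[j], [j, j + 1])
        assert np.all(off_band_up == 0)
        off_band_down = np.delete(down[j], [c for c in (j - 1, j) if 0 <= c < i])
        assert np.all(off_band_down == 0)


@given(params=params_strategy, i=st.integers(1, 30))
def test_up_row_sums_match_division_share(params, i):
    """Row j of P_i carries exactly the division share of the total rate."""
    up = build_up_matrix(i, params)
    j = np.arange(i + 1)
    expected = ((i - j) * params.lambda_div + j * params.alpha_div) / np.array(
        [rate_sum(i, jj, params) for jj in j]
    )
    np.testing.assert_allclose(up.sum(axis=1), expected, rtol=1e-12)


@pytest.mark.parametrize("i", [1, 4, 9])
def test_sensitive_and_resistant_roles_symmetric_without_mutation(i):
    """With gamma = 0 and equal rate pairs, the n = 0 and n = m boundaries of
    a level behave identically (relabelling sensitive <-> resistant)."""
    params = ModelParameters(2.0, 0.7, 2.0, 0.7, 0.0)
    up = build_up_matrix(i, params)
    down = build_down_matrix(i, params)
    assert up[0, 0] == pytest.approx(up[i, i + 1], abs=1e-15)
    if i >= 1:
        assert down[0, 0] == pytest.approx(down[i, i - 1], abs=1e-15)


def test_validate_parameters_accepts_reference_configuration():
    params = ModelParameters(2, 1, 2, 1, 1e-5)
    assert validate_parameters(params, 10_000, 100) == (params, 10_000, 100)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(lambda_div=0.0, mu_death=1, alpha_div=2, beta_death=1, gamma_mut=0.1),
        dict(lambda_div=2, mu_death=-1, alpha_div=2, beta_death=1, gamma_mut=0.1),
        dict(lambda_div=2, mu_death=1, alpha_div=2, beta_death=1, gamma_mut=-0.1),
        dict(lambda_div=2, mu_death=1, alpha_div=2, beta_death=1, gamma_mut=1.5),
    ],
)
def test_invalid_kinetic_parameters_are_rejected(kwargs):
    with pytest.raises(ValidationError):
        ModelParameters(**kwargs)


@pytest.mark.parametrize("M, m_agg", [(1, 100), (100, 0), (100, 101)])
def test_invalid_sizes_are_rejected(M, m_agg):
    with pytest.raises(ValidationError):
        validate_parameters(ModelParameters(2, 1, 2, 1, 0.1), M, m_agg)


def test_cell_state_bounds():
    with pytest.raises(ValidationError):
        CellState(2, 3)
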