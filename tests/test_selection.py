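"""Lifelong adaptive data selection: probabilities, history, exclusions."""

import numpy as np
import pytest

from lmlpot.selection import (
    SelectionError,
    SelectionHyperparameters,
    SelectionState,
    bad_probabilities,
    choose_subsample,
    good_probabilities,
    per_conformation_loss,
    update_history,
    update_p_good,
)

HP = SelectionHyperparameters


def make_state(n=3, **hp_kwargs):
    return SelectionState(ids=[f"c{i}" for i in range(n)], hp=HP(**hp_kwargs))


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------


def test_bad_probabilities_fresh_dataset_is_uniform():
    state = make_state(4)
    np.testing.assert_allclose(bad_probabilities(state), 0.25)


def test_bad_probabilities_uniform_for_equal_losses():
    state = make_state(4)
    state.l_old[:] = 2.0
    np.testing.assert_allclose(bad_probabilities(state), 0.25)


def test_bad_probabilities_hand_computed_example():
    # unnormalized weights (L/L_max)*S_hist = (0.25, 0.5, 2) with ratios
    # 1:2:8; dividing by L_max cancels under normalization
    state = make_state(3)
    state.l_old[:] = [1.0, 2.0, 4.0]
    state.s_hist[:] = [1.0, 1.0, 2.0]
    np.testing.assert_allclose(bad_probabilities(state), [1 / 11, 2 / 11, 8 / 11])


def test_bad_probabilities_excluded_get_zero():
    state = make_state(3)
    state.l_old[:] = [1.0, 2.0, 4.0]
    state.s_hist[1] = 0.0
    p = bad_probabilities(state)
    assert p[1] == 0.0 and p.sum() == pytest.approx(1.0)


def test_all_excluded_raises():
    state = make_state(2)
    state.s_hist[:] = 0.0
    with pytest.raises(SelectionError):
        bad_probabilities(state)


def test_good_probabilities_hand_computed_example():
    state = make_state(3, eps_prime=1e-6)
    state.l_old[:] = [1.0, 2.0, 4.0]
    raw = np.array([0.75, 0.5, 1e-6 * 0.5])  # max-loss entry gets eps' * min nonzero
    np.testing.assert_allclose(good_probabilities(state, np.arange(3)), raw / raw.sum())


def test_good_probabilities_all_equal_losses_become_uniform():
    state = make_state(4)
    state.l_old[:] = 3.0
    np.testing.assert_allclose(good_probabilities(state, np.arange(4)), 0.25)


def test_probability_vectors_normalized_and_nonnegative():
    rng = np.random.default_rng(0)
    for _ in range(20):
        state = make_state(10)
        state.l_old[:] = rng.uniform(0, 5, 10)
        state.l_old[rng.integers(0, 10)] = np.nan
        state.s_hist[:] = rng.uniform(0.1, 3.0, 10)
        state.s_hist[rng.integers(0, 10)] = 0.0
        for p in (bad_probabilities(state), good_probabilities(state, np.arange(10))):
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p[state.s_hist == 0] == 0)


# ---------------------------------------------------------------------------
# subsample choice
# ---------------------------------------------------------------------------


def test_choose_subsample_initial_p_good_zero_draws_only_bad():
    state = make_state(10)
    choice = choose_subsample(state, 4, np.random.default_rng(0))
    assert choice.n_bad == 4 and choice.n_good == 0 and len(choice.fit_ids) == 4
    assert len(set(choice.fit_ids)) == 4  # no duplicates


def test_choose_subsample_full_pool_returns_everything():
    state = make_state(5)
    choice = choose_subsample(state, 5, np.random.default_rng(1))
    assert sorted(choice.fit_ids) == sorted(state.ids)


def test_choose_subsample_is_deterministic_under_fixed_seed():
    state = make_state(20)
    state.l_old[:] = np.arange(20) + 1.0
    state.p_good = 0.4
    a = choose_subsample(state, 10, np.random.default_rng(123))
    b = choose_subsample(state, 10, np.random.default_rng(123))
    assert a.fit_ids == b.fit_ids and a.n_good == 4


def test_choose_subsample_rejects_oversized_requests():
    state = make_state(3)
    state.s_hist[0] = 0.0
    with pytest.raises(SelectionError):
        choose_subsample(state, 3, np.random.default_rng(0))


def test_empirical_frequencies_match_probabilities():
    """10^5 single draws against the bad/good distributions, 3-sigma bound."""
    state = make_state(6)
    state.l_old[:] = [0.5, 1.0, 1.5, 2.0, 3.0, 4.0]
    state.s_hist[:] = [1.0, 2.0, 0.5, 1.0, 1.0, 1.0]
    rng = np.random.default_rng(7)
    n = 100_000
    for p in (bad_probabilities(state), good_probabilities(state, np.arange(6))):
        counts = np.bincount(rng.choice(6, size=n, p=p), minlength=6)
        sigma = np.sqrt(n * p * (1 - p))
        big = p > 1e-4  # skip the eps'-floored entries (tiny expected counts)
        assert np.all(np.abs(counts[big] - n * p[big]) <= 3 * sigma[big])


# ---------------------------------------------------------------------------
# per-conformation loss
# ---------------------------------------------------------------------------


def test_per_conformation_loss_basics():
    assert per_conformation_loss(0.0, 0.0, 10.9, 5) == 0.0
    assert per_conformation_loss(4.0, 9.0, 0.0, 2) == pytest.approx(4.0 / 4)  # q=0: energy only
    base = per_conformation_loss(0.0, 1.0, 2.0, 3)
    assert per_conformation_loss(0.0, 4.0, 2.0, 3) == pytest.approx(4 * base)  # doubling residuals


# ---------------------------------------------------------------------------
# history updates
# ---------------------------------------------------------------------------


def test_strike_counter_excludes_outlier_at_n_x():
    state = make_state(2, n_x=5)
    for k in range(5):
        # conformation 0 is always a >T_X outlier relative to the mean loss
        update_history(state, ["c0", "c1"], [100.0, 1.0], total_loss=1.0)
        if k < 4:
            assert state.s_hist[0] > 0 and state.strikes[0] == k + 1
    assert state.s_hist[0] == 0.0  # excluded at the fifth strike
    assert state.s_hist[1] == 1.0


def test_strike_counter_resets_on_normal_evaluation():
    state = make_state(1, n_x=5)
    update_history(state, ["c0"], [100.0], 1.0)
    update_history(state, ["c0"], [1.0], 1.0)
    assert state.strikes[0] == 0


def test_redundant_decay_follows_closed_form_and_excludes():
    hp = HP(s_min=0.1, n_f_minus_minus=30)
    assert hp.f_minus_minus == pytest.approx(0.1 ** (1 / 30))
    assert hp.f_minus_minus == pytest.approx(0.92612, abs=1e-5)
    state = SelectionState(ids=["r"], hp=hp)
    # first evaluation establishes history; factors apply from the second on
    update_history(state, ["r"], [0.01], total_loss=1.0)
    n_decays = 0
    while state.s_hist[0] > 0:
        expected = hp.f_minus_minus**n_decays
        assert state.s_hist[0] == pytest.approx(expected)
        update_history(state, ["r"], [0.01], total_loss=1.0)  # non-increasing loss
        n_decays += 1
        assert n_decays < 40
    assert n_decays == 30  # S_min reached after exactly N_F-- applications


def test_reset_to_one_inside_band():
    state = make_state(1)
    state.s_hist[0] = 0.5
    state.l_old[0] = 1.0
    update_history(state, ["c0"], [1.0], total_loss=1.0)  # T_F1 <= L_rel <= T_F2
    assert state.s_hist[0] == 1.0
    state.s_hist[0] = 3.0
    update_history(state, ["c0"], [1.0], total_loss=1.0)
    assert state.s_hist[0] == 1.0


def test_growth_factors_applied_on_increased_loss():
    hp = HP()
    state = SelectionState(ids=["g"], hp=hp)
    update_history(state, ["g"], [3.0], total_loss=1.0)  # first eval, between T_F2,T_F3
    assert state.s_hist[0] == 1.0  # no factor on first evaluation
    update_history(state, ["g"], [3.5], total_loss=1.0)  # increased, T_F2 <= L_rel < T_F3
    assert state.s_hist[0] == pytest.approx(hp.f_plus)
    update_history(state, ["g"], [6.0], total_loss=1.0)  # increased, L_rel >= T_F3
    assert state.s_hist[0] == pytest.approx(hp.f_plus * hp.f_plus_plus)


def test_inconsistent_growth_above_s_max_excludes():
    hp = HP(s_max=100.0, n_f_plus_plus=150)
    state = SelectionState(ids=["x"], hp=hp)
    state.s_hist[0] = 99.9
    state.l_old[0] = 5.0
    update_history(state, ["x"], [6.0], total_loss=1.0)  # L_rel 6 >= T_F3, increased
    # 99.9 * F++ > 100 -> excluded as inconsistent
    assert state.s_hist[0] == 0.0


def test_exclusion_is_absorbing():
    state = make_state(1)
    state.s_hist[0] = 0.0
    update_history(state, ["c0"], [1.0], total_loss=1.0)
    assert state.s_hist[0] == 0.0


def test_unknown_ids_rejected():
    state = make_state(1)
    with pytest.raises(SelectionError):
        update_history(state, ["nope"], [1.0], 1.0)


# ---------------------------------------------------------------------------
# p_good
# ---------------------------------------------------------------------------


def test_p_good_stays_zero_on_first_decrease():
    state = make_state(1)
    update_p_good(state, 5.0)  # initial total is +inf: counts as a decrease
    assert state.p_good == 0.0
    assert state.l_old_total == 5.0


def test_p_good_reaches_maximum_after_n_p_increases():
    state = make_state(1, n_p=20, p_good_max=0.5)
    update_p_good(state, 1.0)
    total = 1.0
    for _ in range(20):
        total *= 1.1
        update_p_good(state, total)
    assert state.p_good == pytest.approx(0.5)
    update_p_good(state, total * 1.1)  # clamped at the maximum
    assert state.p_good == pytest.approx(0.5)


def test_p_good_oscillates_on_alternating_loss_and_stays_quantized():
    state = make_state(1, n_p=20, p_good_max=0.5)
    hp = state.hp
    update_p_good(state, 1.0)
    values = []
    for k in range(15):
        update_p_good(state, 2.0 if k % 2 == 0 else 1.0)
        values.append(state.p_good)
    quantum = hp.p_quantum
    assert all(v >= 0 for v in values)
    for v in values:
        assert (v / quantum) == pytest.approx(round(v / quantum), abs=1e-12)
    assert values[:4] == [quantum, 0.0, quantum, 0.0]


# ---------------------------------------------------------------------------
# planted-data stream simulations
# ---------------------------------------------------------------------------


def test_planted_outliers_are_excluded_by_strike_counter():
    """5 planted incorrect conformations whose relative loss exceeds T_X
    every epoch leave the pool after exactly N_X qualifying epochs.

    With 5 outliers among 100 conformations, a 25x-inlier-mean loss puts
    L_rel = loss / mean(all) at about 11.4 > T_X = 10.
    """
    n, n_out = 100, 5
    state = make_state(n)
    rng = np.random.default_rng(5)
    for epoch in range(state.hp.n_x):
        losses = rng.uniform(0.8, 1.2, n)
        losses[:n_out] = 25.0 * losses[n_out:].mean()
        total = float(losses.mean())
        assert losses[0] / total > state.hp.t_x  # the epochs do qualify
        update_history(state, state.ids, losses, total)
    assert np.all(state.s_hist[:n_out] == 0.0)
    assert np.all(state.s_hist[n_out:] > 0.0)


def test_planted_redundant_data_decay_out_of_the_pool():
    """50 near-zero-loss conformations are mostly excluded within
    N_F-- + 50 evaluations."""
    n, n_red = 200, 50
    hp = HP()
    state = SelectionState(ids=[f"c{i}" for i in range(n)], hp=hp)
    rng = np.random.default_rng(6)
    for epoch in range(hp.n_f_minus_minus + 50):
        losses = rng.uniform(0.9, 1.1, n)
        losses[:n_red] = rng.uniform(0.0, 1e-4, n_red)  # trivially represented
        total = float(losses.mean())
        update_history(state, state.ids, losses, total)
    excluded = np.count_nonzero(state.s_hist[:n_red] == 0)
    assert excluded >= int(0.9 * n_red)
    assert np.all(state.s_hist[n_red:] > 0)
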