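"""Model family: update rules, choice probabilities, likelihoods, simulators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valbandit.data import SubjectData
from valbandit.rlmodels import (
    MODELS,
    SubjectParams,
    batch_log_likelihood,
    choice_probs,
    get_model,
    init_state,
    log_likelihood,
    simulate_subject,
    stack_dataset,
    update_state,
)

M4 = get_model("banditNarm_4par")


def params_4par(Arew=0.5, Apun=0.3, R=5.0, P=4.0):
    return SubjectParams(M4, dict(Arew=Arew, Apun=Apun, R=R, P=P))


def _random_params(model, rng):
    return SubjectParams(
        model, {s: float(rng.uniform(lo, min(hi, 10))) for s, lo, hi in model.params}
    )


def test_registry_parameter_sets():
    expect = {
        "banditNarm_4par": ("Arew", "Apun", "R", "P"),
        "banditNarm_lapse": ("Arew", "Apun", "R", "P", "xi"),
        "banditNarm_lapse_decay": ("Arew", "Apun", "R", "P", "xi", "d"),
        "banditNarm_2par_lapse": ("Arew", "Apun", "xi"),
        "banditNarm_singleA_lapse": ("A", "R", "P", "xi"),
        "banditNarm_delta": ("A", "tau"),
        "banditNarm_kalman_filter": ("lam", "theta", "s0", "sD", "beta"),
    }
    assert {n: m.param_names for n, m in MODELS.items()} == expect
    for sym in ("Arew", "Apun"):
        assert M4.bounds(sym) == (0, 1)
    for sym in ("R", "P"):
        assert M4.bounds(sym) == (0, 30)


def test_out_of_bounds_params_rejected():
    with pytest.raises(ValueError):
        params_4par(Arew=1.2)
    with pytest.raises(ValueError):
        params_4par(R=31)


def test_softmax_choice_probabilities():
    p = params_4par()
    state = init_state(M4, 3)
    np.testing.assert_allclose(choice_probs(state, p), [1 / 3] * 3)
    state.Qr[:] = [1.0, 0.0, 0.0]
    e = math.e
    np.testing.assert_allclose(
        choice_probs(state, p), [e / (e + 2), 1 / (e + 2), 1 / (e + 2)], atol=1e-12
    )


def test_full_lapse_gives_uniform_probabilities_regardless_of_values():
    m = get_model("banditNarm_lapse")
    p = SubjectParams(m, dict(Arew=0.5, Apun=0.3, R=5, P=4, xi=1.0))
    state = init_state(m, 3)
    state.Qr[:] = [9.0, -2.0, 0.5]
    np.testing.assert_allclose(choice_probs(state, p), [1 / 3] * 3, atol=1e-15)


def test_chosen_arm_update_hand_computed():
    # delta_r = R*r - Qr = 2*1 - 0 = 2; Qr <- 0 + 0.5*2 = 1.0
    p = params_4par(Arew=0.5, R=2.0)
    state = init_state(M4, 3)
    new = update_state(state, 0, win=1, loss=0, params=p)
    assert new.Qr[0] == pytest.approx(1.0)
    assert state.Qr[0] == 0.0  # input untouched


def test_fictive_update_decays_unchosen_value():
    p = params_4par(Arew=0.5)
    state = init_state(M4, 3)
    state.Qr[1] = 1.0
    new = update_state(state, 0, win=0, loss=0, params=p)
    assert new.Qr[1] == pytest.approx(0.5)


def test_zero_state_zero_outcome_is_fixed_point():
    p = params_4par()
    state = init_state(M4, 3)
    new = update_state(state, 1, win=0, loss=0, params=p)
    np.testing.assert_array_equal(new.Qr, 0.0)
    np.testing.assert_array_equal(new.Qp, 0.0)


def test_punishment_drives_Qp_negative_within_bounds():
    p = params_4par(Apun=0.8, P=6.0)
    state = init_state(M4, 3)
    for _ in range(50):
        state = update_state(state, 0, win=0, loss=1, params=p)
    assert -6.0 <= state.Qp[0] < 0.0


def test_single_trial_loglik_is_uniform():
    sub = SubjectData("s", [0], [1], [0])
    assert log_likelihood(sub, params_4par()) == pytest.approx(math.log(1 / 3))


def test_full_lapse_loglik_counts_valid_trials_only():
    m = get_model("banditNarm_lapse")
    p = SubjectParams(m, dict(Arew=0.5, Apun=0.3, R=5, P=4, xi=1.0))
    sub = SubjectData("s", [0, 1, -1, 2, 0], [1, 0, 0, 1, 0], [0, 1, 0, 0, 1])
    assert log_likelihood(sub, p) == pytest.approx(4 * math.log(1 / 3))


def test_empty_data_rejected():
    with pytest.raises(ValueError):
        log_likelihood(SubjectData("s", [], [], []), params_4par())


def _oracle_loglik_4par(choices, wins, losses, Arew, Apun, R, P, n_arms=3):
    """Independent trial-by-trial re-walk of the update and softmax equations."""
    Qr = [0.0] * n_arms
    Qp = [0.0] * n_arms
    ll = 0.0
    for c, w, l in zip(choices, wins, losses):
        if c < 0:
            continue
        qsum = [Qr[a] + Qp[a] for a in range(n_arms)]
        z = sum(math.exp(q) for q in qsum)
        ll += math.log(math.exp(qsum[c]) / z)
        for a in range(n_arms):
            if a == c:
                Qr[a] = Qr[a] + Arew * (R * w - Qr[a])
                Qp[a] = Qp[a] + Apun * (P * (-l) - Qp[a])
            else:
                Qr[a] = Qr[a] + Arew * (-Qr[a])
                Qp[a] = Qp[a] + Apun * (-Qp[a])
    return ll


def test_loglik_matches_independent_oracle(small_schedule):
    p = params_4par(Arew=0.62, Apun=0.21, R=7.5, P=2.8)
    sub = simulate_subject(p, small_schedule, seed=5)
    sub.choices[7] = -1  # inject a missed trial
    sub.wins[7] = sub.losses[7] = 0
    oracle = _oracle_loglik_4par(sub.choices, sub.wins, sub.losses, 0.62, 0.21, 7.5, 2.8)
    assert log_likelihood(sub, p) == pytest.approx(oracle, abs=1e-10)


@pytest.mark.parametrize("name", sorted(MODELS))
def test_batch_loglik_matches_scalar_path(name, small_schedule):
    model = get_model(name)
    rng = np.random.default_rng(17)
    subs, values = [], []
    for i in range(4):
        p = _random_params(model, rng)
        s = simulate_subject(p, small_schedule, seed=100 + i)
        if i == 0:
            s.choices[3] = -1
            s.wins[3] = s.losses[3] = 0
        subs.append((s, p))
        values.append([p[k] for k in model.param_names])
    choices, wins, losses = stack_dataset([s for s, _ in subs])
    batch = batch_log_likelihood(np.array(values), choices, wins, losses, 3, model)
    scalar = [log_likelihood(s, p) for s, p in subs]
    np.testing.assert_allclose(batch, scalar, atol=1e-10)
    pw = batch_log_likelihood(np.array(values), choices, wins, losses, 3, model, pointwise=True)
    np.testing.assert_allclose(np.nansum(pw, axis=1), scalar, atol=1e-10)
    assert np.isnan(pw[0, 3])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_choice_probs_sum_to_one_for_random_states(seed):
    rng = np.random.default_rng(seed)
    name = list(MODELS)[seed % len(MODELS)]
    model = get_model(name)
    p = _random_params(model, rng)
    state = init_state(model, 3, p)
    state.Qr[:] = rng.normal(0, 5, 3)
    state.Qp[:] = -np.abs(rng.normal(0, 5, 3))
    if state.m is not None:
        state.m[:] = rng.normal(0, 2, 3)
    probs = choice_probs(state, p)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(probs >= 0)


def test_lapse_probabilities_bounded_by_mixture():
    m = get_model("banditNarm_lapse")
    xi = 0.4
    p = SubjectParams(m, dict(Arew=0.5, Apun=0.5, R=20, P=20, xi=xi))
    state = init_state(m, 3)
    state.Qr[:] = [30.0, 0.0, 0.0]
    probs = choice_probs(state, p)
    assert probs.min() >= xi / 3 - 1e-12
    assert probs.max() <= 1 - xi * 2 / 3 + 1e-12


def test_Q_values_stay_within_sensitivity_bounds(small_schedule):
    p = params_4par(Arew=0.9, Apun=0.9, R=8.0, P=6.0)
    state = init_state(M4, 3)
    rng = np.random.default_rng(3)
    for _ in range(300):
        state = update_state(
            state, int(rng.integers(3)), int(rng.integers(2)), int(rng.integers(2)), p
        )
        assert np.all(state.Qr >= 0) and np.all(state.Qr <= 8.0)
        assert np.all(state.Qp <= 0) and np.all(state.Qp >= -6.0)


def test_delta_model_equals_rescaled_4par(small_schedule):
    """With shared A and R = P = tau, scaling outcomes (4par) and scaling the
    softmax (delta) give identical likelihoods."""
    A, tau = 0.4, 2.5
    p4 = params_4par(Arew=A, Apun=A, R=tau, P=tau)
    pd_ = SubjectParams(get_model("banditNarm_delta"), dict(A=A, tau=tau))
    sub = simulate_subject(p4, small_schedule, seed=21)
    assert log_likelihood(sub, p4) == pytest.approx(log_likelihood(sub, pd_), abs=1e-10)


def test_indifferent_policy_chooses_uniformly(static_schedule):
    p = params_4par(R=0.0, P=0.0)
    counts = np.zeros(3)
    for seed in range(50):
        sub = simulate_subject(p, static_schedule, seed=seed)
        counts += np.bincount(sub.choices, minlength=3)
    freqs = counts / counts.sum()
    np.testing.assert_allclose(freqs, 1 / 3, atol=3 * np.sqrt((1 / 3) * (2 / 3) / counts.sum()))


def test_greedy_learner_exploits_the_rewarding_arm(static_schedule):
    """High sensitivity + a value-retaining learning rate approach the greedy
    limit: the only rewarding arm dominates choices once learned.  (With a
    learning rate of exactly 1 a single unrewarded trial resets the value, so
    the greedy limit needs partial retention.)"""
    p = params_4par(Arew=0.3, Apun=0.1, R=30.0, P=1.0)
    sub = simulate_subject(p, static_schedule, seed=2)
    late = sub.choices[20:]
    assert np.mean(late == 0) > 0.9


def test_simulation_is_deterministic_under_seed(small_schedule):
    a = simulate_subject(params_4par(), small_schedule, seed=9)
    b = simulate_subject(params_4par(), small_schedule, seed=9)
    np.testing.assert_array_equal(a.choices, b.choices)
    np.testing.assert_array_equal(a.wins, b.wins)
    np.testing.assert_array_equal(a.losses, b.losses)


def test_loglik_peaks_near_generating_parameters(small_schedule):
    """Average likelihood at the generating parameters beats perturbed ones."""
    from valbandit import schedules

    sched = schedules.generate_schedule(n_trials=200, n_arms=3, seed=77)
    p = params_4par(Arew=0.5, Apun=0.3, R=5, P=4)
    subs = [simulate_subject(p, sched, seed=1000 + i) for i in range(200)]
    choices, wins, losses = stack_dataset(subs)
    base = np.array([[0.5, 0.3, 5, 4]])
    ll_true = batch_log_likelihood(np.repeat(base, 200, axis=0), choices, wins, losses, 3, M4)
    for shift in ([0.25, 0, 0, 0], [0, 0.2, 0, 0], [0, 0, 4, 3]):
        pert = np.repeat(base + np.array(shift), 200, axis=0)
        ll_pert = batch_log_likelihood(pert, choices, wins, losses, 3, M4)
        assert ll_true.mean() > ll_pert.mean()
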