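"""Behavioural layer: exclusions, RT cleaning, strategies, prediction accuracy."""

import numpy as np
import pytest

from valbandit.behaviour import (
    apply_exclusions,
    clean_rts,
    ppc_strategy_check,
    predict_choices,
    win_stay_lose_shift,
)
from valbandit.data import SubjectData
from valbandit.rlmodels import SubjectParams, get_model, simulate_subject
from valbandit.synthcohort import make_exclusion_fixtures


def _subject(choices, wins=None, losses=None, rt=None, **kw):
    n = len(choices)
    return SubjectData(
        kw.pop("subject_id", "s"),
        choices,
        wins if wins is not None else [0] * n,
        losses if losses is not None else [0] * n,
        rt_ms=rt,
        **kw,
    )


def test_exclusion_rule_boundaries():
    retained, reports = apply_exclusions(make_exclusion_fixtures())
    by_id = {r.subject_id: r for r in reports}
    assert by_id["run20"].excluded and "consecutive_key" in by_id["run20"].reasons
    assert not by_id["run19"].excluded
    assert by_id["miss20"].excluded and "missing_trials" in by_id["miss20"].reasons
    assert not by_id["miss19"].excluded
    assert not by_id["clean"].excluded
    assert {s.subject_id for s in retained} == {"run19", "miss19", "clean"}


def test_attention_check_failure_excludes():
    s = _subject([0, 1, 0, 1], attention_fail=True)
    _, reports = apply_exclusions([s])
    assert reports[0].excluded and reports[0].reasons == ("attention_check",)


def test_missed_trial_breaks_a_key_run():
    # 10 + miss + 10 of the same key: two runs of 10, not one of 20
    choices = [1] * 10 + [-1] + [1] * 10 + [0, 2, 0, 2]
    _, reports = apply_exclusions([_subject(choices)])
    assert not reports[0].excluded


def test_exclusions_are_idempotent():
    dataset = make_exclusion_fixtures()
    once, _ = apply_exclusions(dataset)
    twice, reports = apply_exclusions(once)
    assert [s.subject_id for s in twice] == [s.subject_id for s in once]
    assert not any(r.excluded for r in reports)


def test_rt_cleaning_boundaries():
    rt = [150.0, 200.0, 1000.0, 3000.0, 3001.0, 500.0]
    choices = [0, 1, 2, 0, 1, -1]  # last trial missed
    got = clean_rts(_subject(choices, rt=rt))
    np.testing.assert_array_equal(got, [200.0, 1000.0, 3000.0])


def test_negative_rt_raises():
    with pytest.raises(ValueError):
        clean_rts(_subject([0, 1], rt=[-5.0, 300.0]))


def test_win_stay_lose_shift_hand_counted():
    # wins on trials 1 and 3 -> both following trials stayed; losses on
    # trials 2 and 4 -> both following trials shifted
    s = _subject([0, 0, 1, 1, 2], wins=[1, 0, 1, 0, 0], losses=[0, 1, 0, 1, 0])
    rates = win_stay_lose_shift(s)
    assert rates.ws_opportunities == 2 and rates.win_stay_pct == pytest.approx(100.0)
    assert rates.ls_opportunities == 2 and rates.lose_shift_pct == pytest.approx(100.0)


def test_no_reward_means_undefined_win_stay():
    s = _subject([0, 1, 2], wins=[0, 0, 0], losses=[1, 0, 0])
    rates = win_stay_lose_shift(s)
    assert rates.ws_opportunities == 0 and np.isnan(rates.win_stay_pct)
    assert rates.ls_opportunities == 1


def test_perseverator_win_stays_always():
    s = _subject([1] * 10, wins=[1] * 10, losses=[0] * 10)
    assert win_stay_lose_shift(s).win_stay_pct == pytest.approx(100.0)


def test_both_outcome_counts_for_both_strategies():
    s = _subject([0, 0], wins=[1, 0], losses=[1, 0])
    rates = win_stay_lose_shift(s)
    assert rates.ws_opportunities == 1 and rates.ls_opportunities == 1
    assert rates.win_stay_pct == pytest.approx(100.0)
    assert rates.lose_shift_pct == pytest.approx(0.0)


def test_missed_trials_break_strategy_adjacency():
    s = _subject([0, -1, 0, 0], wins=[1, 0, 1, 0], losses=[0, 0, 0, 0])
    rates = win_stay_lose_shift(s)
    assert rates.ws_opportunities == 1  # only the t3->t4 transition counts


def test_uniform_policy_strategy_rates_converge_to_chance(mixed_schedule):
    """With R = P = 0 choices are uniform: stay probability 1/3, shift 2/3."""
    m = get_model("banditNarm_4par")
    p = SubjectParams(m, dict(Arew=0.5, Apun=0.5, R=0.0, P=0.0))
    ws, ls, wn, ln = 0.0, 0.0, 0, 0
    for seed in range(60):
        rates = win_stay_lose_shift(simulate_subject(p, mixed_schedule, seed=seed))
        ws += rates.win_stay_pct * rates.ws_opportunities
        wn += rates.ws_opportunities
        ls += rates.lose_shift_pct * rates.ls_opportunities
        ln += rates.ls_opportunities
    assert ws / wn == pytest.approx(100 / 3, abs=2.0)
    assert ls / ln == pytest.approx(200 / 3, abs=2.0)


def test_prediction_accuracy_perfect_when_model_matches():
    m = get_model("banditNarm_4par")
    p = SubjectParams(m, dict(Arew=1.0, Apun=0.0, R=30.0, P=0.0))
    # after a win on arm a, the model's argmax is a; feed it a confirming run
    s = _subject([0] + [0] * 9, wins=[1] * 10, losses=[0] * 10)
    _, acc = predict_choices(s, p)
    assert acc == pytest.approx(100.0)


def test_uniform_probabilities_tie_break_to_lowest_arm():
    m = get_model("banditNarm_lapse")
    p = SubjectParams(m, dict(Arew=0.5, Apun=0.5, R=5, P=4, xi=1.0))
    s = _subject([0] * 8, wins=[0] * 8, losses=[0] * 8)
    probs, acc = predict_choices(s, p)
    np.testing.assert_allclose(probs, 1 / 3)
    assert acc == pytest.approx(100.0)  # argmax tie -> arm 0, matches choices


def test_chance_level_accuracy_for_random_choices():
    rng = np.random.default_rng(0)
    m = get_model("banditNarm_lapse")
    p = SubjectParams(m, dict(Arew=0.5, Apun=0.5, R=5, P=4, xi=1.0))
    n = 30_000
    s = _subject(rng.integers(0, 3, n), wins=[0] * n, losses=[0] * n)
    _, acc = predict_choices(s, p)
    se = 100 * np.sqrt((1 / 3) * (2 / 3) / n)
    assert acc == pytest.approx(100 / 3, abs=3 * se)


def test_accuracy_invariant_to_consistent_arm_relabelling(small_schedule):
    m = get_model("banditNarm_4par")
    p = SubjectParams(m, dict(Arew=0.6, Apun=0.3, R=6, P=3))
    s = simulate_subject(p, small_schedule, seed=4)
    perm = np.array([2, 0, 1])
    s2 = SubjectData("s2", perm[s.choices], s.wins, s.losses)
    probs1, _ = predict_choices(s, p)
    probs2, _ = predict_choices(s2, p)
    # probabilities permute exactly; matches agree wherever the argmax is
    # unique (the uniform first trial is a tie, where the lowest-index rule
    # is deliberately not permutation-invariant)
    np.testing.assert_allclose(probs2[:, perm], probs1, atol=1e-12)
    srt = np.sort(probs1, axis=1)
    unique_top = srt[:, -1] - srt[:, -2] > 1e-12
    assert unique_top.sum() > 10
    m1 = np.argmax(probs1[unique_top], axis=1) == s.choices[unique_top]
    m2 = np.argmax(probs2[unique_top], axis=1) == s2.choices[unique_top]
    np.testing.assert_array_equal(m1, m2)


def test_ppc_identity_gives_zero_delta_unit_r(small_cohort):
    table = ppc_strategy_check(small_cohort, small_cohort)
    assert list(table.columns) == ["group", "metric", "delta", "t", "df", "p", "dz", "ci_low", "ci_high", "r"]
    assert np.allclose(table["delta"], 0.0)
    assert np.allclose(table["r"], 1.0)


def test_ppc_detects_planted_lose_shift_deficit(mixed_schedule):
    m = get_model("banditNarm_4par")
    real, sim = [], []
    for i in range(12):
        p = SubjectParams(m, dict(Arew=0.5, Apun=0.5, R=0.0, P=0.0))
        s = simulate_subject(p, mixed_schedule, seed=200 + i)
        s.subject_id = f"s{i}"
        s.group = "anhedonic"
        real.append(s)
        # simulated twin: identical except half the lose-shifts undone
        twin = SubjectData(s.subject_id, s.choices.copy(), s.wins, s.losses, group=s.group)
        prev_loss = np.roll(s.losses, 1).astype(bool)
        prev_loss[0] = False
        shifts = prev_loss & (s.choices != np.roll(s.choices, 1))
        idx = np.where(shifts)[0]
        for t in idx[:: 2]:
            twin.choices[t] = twin.choices[t - 1]  # undo the shift
        sim.append(twin)
    table = ppc_strategy_check(real, sim)
    row = table[(table.metric == "lose_shift")].iloc[0]
    assert row.delta < 0 and row.p < 0.05


def test_ppc_requires_matched_ids(small_cohort):
    renamed = [SubjectData("x" + s.subject_id, s.choices, s.wins, s.losses) for s in small_cohort]
    with pytest.raises(ValueError):
        ppc_strategy_check(small_cohort, renamed)
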