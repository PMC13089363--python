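"""Model-agnostic behavioural layer.

Exclusion rules, reaction-time cleaning, win-stay/lose-shift strategy rates,
model prediction accuracy, and real-vs-simulated posterior predictive checks
on the strategy rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import SubjectData
from .rlmodels import SubjectParams, choice_probs, init_state, update_state

__all__ = [
    "StrategyRates",
    "ExclusionReport",
    "apply_exclusions",
    "clean_rts",
    "win_stay_lose_shift",
    "predict_choices",
    "ppc_strategy_check",
]

RT_MIN_MS = 200.0
RT_MAX_MS = 3000.0
RUN_THRESHOLD = 20
MISSING_THRESHOLD = 20


@dataclass(frozen=True)
class StrategyRates:
    """Win-stay / lose-shift percentages and their opportunity counts.

    A rate is NaN when its opportunity count is zero.
    """

    win_stay_pct: float
    lose_shift_pct: float
    ws_opportunities: int
    ls_opportunities: int


@dataclass(frozen=True)
class ExclusionReport:
    subject_id: str
    excluded: bool
    reasons: tuple[str, ...]


def _longest_run(choices: np.ndarray) -> int:
    """Longest run of identical responded choices; a missed trial breaks runs."""
    best = cur = 0
    prev = None
    for c in choices:
        if c < 0:
            cur, prev = 0, None
            continue
        cur = cur + 1 if c == prev else 1
        prev = c
        best = max(best, cur)
    return best


def apply_exclusions(
    dataset: list[SubjectData],
) -> tuple[list[SubjectData], list[ExclusionReport]]:
    """Flag subjects with a >=20-trial same-key run, >=20 missed trials, or a
    failed attention check; return (retained subjects, full report).

    Idempotent: re-applying to the retained set excludes nobody further.
    """
    retained, reports = [], []
    for s in dataset:
        reasons = []
        if _longest_run(s.choices) >= RUN_THRESHOLD:
            reasons.append("consecutive_key")
        if int((~s.valid).sum()) >= MISSING_THRESHOLD:
            reasons.append("missing_trials")
        if s.attention_fail:
            reasons.append("attention_check")
        excluded = bool(reasons)
        reports.append(ExclusionReport(s.subject_id, excluded, tuple(reasons)))
        if not excluded:
            retained.append(s)
    return retained, reports


def clean_rts(subject: SubjectData) -> np.ndarray:
    """Valid reaction times: responded trials with 200 <= RT <= 3000 ms.

    The exclusion rule is strict (< 200 or > 3000 removed), so the boundary
    values themselves are retained.  Used only for RT summaries, never for
    likelihood fitting.
    """
    rt = subject.rt_ms
    if np.any(rt[~np.isnan(rt)] < 0):
        raise ValueError("negative reaction time")
    mask = subject.valid & ~np.isnan(rt) & (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)
    return rt[mask]


def win_stay_lose_shift(subject: SubjectData) -> StrategyRates:
    """Win-stay and lose-shift percentages per the standard definitions.

    A win-stay opportunity is a responded trial whose previous responded
    neighbour was rewarded; the instance counts if the same arm was repeated.
    A lose-shift opportunity is the analogue for punished trials and
    switching.  A trial carrying both a win and a loss is an opportunity for
    both strategies.  Any missed trial breaks adjacency: neither the missed
    trial nor its successor contributes an opportunity.
    """
    c, w, l = subject.choices, subject.wins, subject.losses
    ws_opp = ws_hit = ls_opp = ls_hit = 0
    for t in range(1, subject.n_trials):
        if c[t] < 0 or c[t - 1] < 0:
            continue
        stayed = c[t] == c[t - 1]
        if w[t - 1] == 1:
            ws_opp += 1
            ws_hit += int(stayed)
        if l[t - 1] == 1:
            ls_opp += 1
            ls_hit += int(not stayed)
    return StrategyRates(
        win_stay_pct=100.0 * ws_hit / ws_opp if ws_opp else float("nan"),
        lose_shift_pct=100.0 * ls_hit / ls_opp if ls_opp else float("nan"),
        ws_opportunities=ws_opp,
        ls_opportunities=ls_opp,
    )


def predict_choices(
    subject: SubjectData,
    params: SubjectParams,
    n_arms: int = 3,
) -> tuple[np.ndarray, float]:
    """Replay a subject under fitted parameters and score top-1 accuracy.

    For every trial the model's choice probabilities are computed *before*
    seeing the observed choice; the predicted choice is the argmax with ties
    broken toward the lowest arm index.  Accuracy is
    ``100 * matches / responded trials``.  Missed trials get a NaN probability
    row and leave the state untouched.
    """
    state = init_state(params.model, n_arms, params)
    probs = np.full((subject.n_trials, n_arms), np.nan)
    matches = 0
    n_valid = 0
    for t in range(subject.n_trials):
        c = subject.choices[t]
        if c < 0:
            continue
        p = choice_probs(state, params)
        probs[t] = p
        if int(np.argmax(p)) == c:
            matches += 1
        n_valid += 1
        state = update_state(state, int(c), int(subject.wins[t]), int(subject.losses[t]), params)
    accuracy = 100.0 * matches / n_valid if n_valid else float("nan")
    return probs, accuracy


def _paired_stats(real: np.ndarray, sim: np.ndarray) -> dict:
    d = sim - real
    n = len(d)
    t, p = stats.ttest_rel(sim, real)
    sd = d.std(ddof=1)
    dz = d.mean() / sd if sd > 0 else float("nan")
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    r = stats.pearsonr(real, sim).statistic if n > 2 else float("nan")
    return {
        "delta": float(d.mean()),
        "t": float(t),
        "df": n - 1,
        "p": float(p),
        "dz": float(dz),
        "ci_low": float(d.mean() - tcrit * se),
        "ci_high": float(d.mean() + tcrit * se),
        "r": float(r),
    }


def ppc_strategy_check(
    real: list[SubjectData], simulated: list[SubjectData]
) -> pd.DataFrame:
    """Paired real-vs-simulated comparison of strategy rates, per group.

    ``simulated`` must contain one record per real subject with the same
    subject id (generated from that subject's fitted parameters).  Returns a
    tidy table with columns {group, metric, delta, t, df, p, dz, ci_low,
    ci_high, r}; delta is Sim - Real in percentage points.
    """
    sim_by_id = {s.subject_id: s for s in simulated}
    missing = [s.subject_id for s in real if s.subject_id not in sim_by_id]
    if missing:
        raise ValueError(f"simulated dataset missing subject ids: {missing[:5]}")
    rows = []
    groups = sorted({s.group or "all" for s in real})
    for g in groups:
        members = [s for s in real if (s.group or "all") == g]
        for metric, attr in (("win_stay", "win_stay_pct"), ("lose_shift", "lose_shift_pct")):
            rv, sv = [], []
            for s in members:
                r_rate = getattr(win_stay_lose_shift(s), attr)
                s_rate = getattr(win_stay_lose_shift(sim_by_id[s.subject_id]), attr)
                if not (np.isnan(r_rate) or np.isnan(s_rate)):
                    rv.append(r_rate)
                    sv.append(s_rate)
            st = _paired_stats(np.array(rv), np.array(sv))
            rows.append({"group": g, "metric": metric, **st})
    return pd.DataFrame(rows, columns=["group", "metric", "delta", "t", "df", "p", "dz", "ci_low", "ci_high", "r"])
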