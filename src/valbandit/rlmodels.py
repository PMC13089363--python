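"""The seven-model family of valence-specific reinforcement-learning models.

All Rescorla-Wagner variants track separate reward and punishment values Qr
and Qp per arm.  Outcomes are coded r = +1 for a win token (else 0) and
l = -1 for a loss token (else 0), so the punishment sensitivity P stays
positive while driving Qp negative.  Prediction errors scale the outcome by
the sensitivity (delta_r = R*r - Qr, delta_p = P*l - Qp) and each valence has
its own learning rate; unchosen arms receive fictive updates toward zero
(delta = -Q) with the same learning rates, i.e. gradual decay of unchosen
values.  Choices come from a softmax over Qsum = Qr + Qp; the four-parameter
model uses unit temperature because the sensitivities already set the value
scale.  Lapse variants mix the softmax policy with a uniform random policy
with probability xi.  The Kalman-filter variant instead tracks a single
posterior mean and variance per arm with mean reversion and diffusion.

Model names follow the bandit-family convention (``banditNarm_*``); the ``N``
is literal — every model works for any number of arms >= 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data import SubjectData
from .schedules import ProbabilitySchedule

__all__ = [
    "ModelSpec",
    "SubjectParams",
    "ValueState",
    "MODELS",
    "get_model",
    "init_state",
    "choice_probs",
    "update_state",
    "log_likelihood",
    "simulate_subject",
    "batch_log_likelihood",
    "stack_dataset",
    "export_bounds_json",
]


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: its name and ordered (symbol, lower, upper) parameters."""

    name: str
    params: tuple[tuple[str, float, float], ...]

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.params)

    def bounds(self, symbol: str) -> tuple[float, float]:
        for s, lo, hi in self.params:
            if s == symbol:
                return lo, hi
        raise KeyError(symbol)


MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        ModelSpec("banditNarm_4par", (("Arew", 0, 1), ("Apun", 0, 1), ("R", 0, 30), ("P", 0, 30))),
        ModelSpec(
            "banditNarm_lapse",
            (("Arew", 0, 1), ("Apun", 0, 1), ("R", 0, 30), ("P", 0, 30), ("xi", 0, 1)),
        ),
        ModelSpec(
            "banditNarm_lapse_decay",
            (("Arew", 0, 1), ("Apun", 0, 1), ("R", 0, 30), ("P", 0, 30), ("xi", 0, 1), ("d", 0, 1)),
        ),
        ModelSpec("banditNarm_2par_lapse", (("Arew", 0, 1), ("Apun", 0, 1), ("xi", 0, 1))),
        ModelSpec(
            "banditNarm_singleA_lapse",
            (("A", 0, 1), ("R", 0, 30), ("P", 0, 30), ("xi", 0, 1)),
        ),
        ModelSpec("banditNarm_delta", (("A", 0, 1), ("tau", 0, 5))),
        ModelSpec(
            "banditNarm_kalman_filter",
            (("lam", 0, 1), ("theta", 0, 1), ("s0", 0, 5), ("sD", 0, 5), ("beta", 0, 10)),
        ),
    ]
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; registered: {sorted(MODELS)}") from None


@dataclass(frozen=True)
class SubjectParams:
    """One subject's parameter values for a given model, validated against bounds."""

    model: ModelSpec
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.model.param_names) - set(self.values)
        if missing:
            raise ValueError(f"missing parameters for {self.model.name}: {sorted(missing)}")
        for sym, lo, hi in self.model.params:
            v = self.values[sym]
            if not (lo <= v <= hi):
                raise ValueError(f"{sym}={v} outside [{lo}, {hi}]")

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]


@dataclass
class ValueState:
    """Per-arm value state.  Qp is always <= 0; Kalman models use m and s2."""

    Qr: np.ndarray
    Qp: np.ndarray
    m: np.ndarray | None = None
    s2: np.ndarray | None = None

    @property
    def Qsum(self) -> np.ndarray:
        return self.Qr + self.Qp

    def copy(self) -> "ValueState":
        return ValueState(
            Qr=self.Qr.copy(),
            Qp=self.Qp.copy(),
            m=None if self.m is None else self.m.copy(),
            s2=None if self.s2 is None else self.s2.copy(),
        )


def init_state(model: ModelSpec, n_arms: int, params: SubjectParams | None = None) -> ValueState:
    """Fresh trial-1 state: all values zero (Kalman: m = 0, s2 = s0**2)."""
    state = ValueState(Qr=np.zeros(n_arms), Qp=np.zeros(n_arms))
    if model.name == "banditNarm_kalman_filter":
        if params is None:
            raise ValueError("Kalman state initialisation needs params (s0)")
        state.m = np.zeros(n_arms)
        state.s2 = np.full(n_arms, params["s0"] ** 2)
    return state


def _effective(params: SubjectParams) -> tuple[float, float, float, float, float, float | None, float]:
    """Map any Rescorla-Wagner variant onto (arew, apun, rscale, pscale, xi, decay, temp)."""
    name = params.model.name
    v = params.values
    if name == "banditNarm_4par":
        return v["Arew"], v["Apun"], v["R"], v["P"], 0.0, None, 1.0
    if name == "banditNarm_lapse":
        return v["Arew"], v["Apun"], v["R"], v["P"], v["xi"], None, 1.0
    if name == "banditNarm_lapse_decay":
        return v["Arew"], v["Apun"], v["R"], v["P"], v["xi"], v["d"], 1.0
    if name == "banditNarm_2par_lapse":
        return v["Arew"], v["Apun"], 1.0, 1.0, v["xi"], None, 1.0
    if name == "banditNarm_singleA_lapse":
        return v["A"], v["A"], v["R"], v["P"], v["xi"], None, 1.0
    if name == "banditNarm_delta":
        return v["A"], v["A"], 1.0, 1.0, 0.0, None, v["tau"]
    raise ValueError(f"not a Rescorla-Wagner variant: {name}")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def choice_probs(state: ValueState, params: SubjectParams) -> np.ndarray:
    """Choice-probability vector over arms for the current value state.

    Softmax over Qsum (scaled by tau for the delta model, by beta over the
    Kalman posterior means), mixed with a uniform policy for lapse variants.
    Output sums to 1.
    """
    if params.model.name == "banditNarm_kalman_filter":
        return _softmax(params["beta"] * state.m)
    _, _, _, _, xi, _, temp = _effective(params)
    p = _softmax(temp * state.Qsum)
    if xi > 0:
        p = (1.0 - xi) * p + xi / len(p)
    return p


def update_state(
    state: ValueState, choice: int, win: int, loss: int, params: SubjectParams
) -> ValueState:
    """One trial's value update; returns a new state (input left untouched).

    Chosen arm: delta_r = R*r - Qr, delta_p = P*l - Qp with r = win and
    l = -loss.  Unchosen arms: fictive updates toward zero with the same
    valence learning rates (lapse_decay instead multiplies unchosen values by
    1 - d; the Kalman model applies a Bayesian observation update to the
    chosen arm followed by a mean-reverting diffusion predict step).
    """
    if win not in (0, 1) or loss not in (0, 1):
        raise ValueError("win and loss must be 0/1 indicators")
    new = state.copy()
    if params.model.name == "banditNarm_kalman_filter":
        o = float(win) - float(loss)
        k = new.s2[choice] / (new.s2[choice] + 1.0)  # observation variance fixed at 1
        new.m[choice] += k * (o - new.m[choice])
        new.s2[choice] *= 1.0 - k
        lam, theta, sD = params["lam"], params["theta"], params["sD"]
        new.m = lam * new.m + (1.0 - lam) * theta
        new.s2 = lam**2 * new.s2 + sD**2
        return new
    arew, apun, rscale, pscale, _, decay, _ = _effective(params)
    r = float(win)
    l = -float(loss)
    if decay is None:
        # single affine step: chosen arm targets the scaled outcome, unchosen
        # arms target zero (the fictive update)
        target_r = np.zeros_like(new.Qr)
        target_p = np.zeros_like(new.Qp)
        target_r[choice] = rscale * r
        target_p[choice] = pscale * l
        new.Qr += arew * (target_r - new.Qr)
        new.Qp += apun * (target_p - new.Qp)
    else:
        unchosen = np.ones_like(new.Qr, dtype=bool)
        unchosen[choice] = False
        new.Qr[choice] += arew * (rscale * r - new.Qr[choice])
        new.Qp[choice] += apun * (pscale * l - new.Qp[choice])
        new.Qr[unchosen] *= 1.0 - decay
        new.Qp[unchosen] *= 1.0 - decay
    return new


def log_likelihood(data: SubjectData, params: SubjectParams, n_arms: int | None = None) -> float:
    """Summed log choice probability over responded trials.

    Missed trials contribute nothing and leave the value state unchanged.
    """
    if data.n_trials == 0:
        raise ValueError("empty data")
    if n_arms is None:
        n_arms = int(max(3, data.choices.max() + 1))
    state = init_state(params.model, n_arms, params)
    ll = 0.0
    for t in range(data.n_trials):
        c = data.choices[t]
        if c < 0:
            continue
        p = choice_probs(state, params)
        ll += float(np.log(p[c]))
        state = update_state(state, c, int(data.wins[t]), int(data.losses[t]), params)
    return ll


def simulate_subject(
    params: SubjectParams,
    schedule: ProbabilitySchedule,
    seed: int,
    subject_id: str = "sim",
) -> SubjectData:
    """Generate one subject's choices on a schedule under the generative model.

    On each trial a choice is sampled from the current policy, win/loss are
    realised from the schedule's probabilities, and the state is updated with
    the same counterfactual (zero-outcome) updates used when fitting.
    """
    rng = np.random.default_rng(seed)
    n_arms = schedule.n_arms
    state = init_state(params.model, n_arms, params)
    T = schedule.n_trials
    choices = np.empty(T, dtype=int)
    wins = np.empty(T, dtype=int)
    losses = np.empty(T, dtype=int)
    for t in range(T):
        p = choice_probs(state, params)
        c = int(rng.choice(n_arms, p=p))
        win = int(rng.random() < schedule.reward_p[t, c])
        loss = int(rng.random() < schedule.punish_p[t, c])
        choices[t], wins[t], losses[t] = c, win, loss
        state = update_state(state, c, win, loss, params)
    return SubjectData(
        subject_id=subject_id,
        choices=choices,
        wins=wins,
        losses=losses,
        true_params=dict(params.values),
    )


# ---------------------------------------------------------------------------
# Vectorised likelihood across subjects (used by the hierarchical fitter).
# ---------------------------------------------------------------------------


def _effective_batch(values: np.ndarray, model: ModelSpec):
    """Columns of `values` (n_subj, K) mapped to per-subject effective arrays."""
    idx = {s: i for i, s in enumerate(model.param_names)}
    n = values.shape[0]
    ones = np.ones(n)
    zeros = np.zeros(n)

    def col(sym):
        return values[:, idx[sym]]

    name = model.name
    if name == "banditNarm_4par":
        return col("Arew"), col("Apun"), col("R"), col("P"), zeros, None, ones
    if name == "banditNarm_lapse":
        return col("Arew"), col("Apun"), col("R"), col("P"), col("xi"), None, ones
    if name == "banditNarm_lapse_decay":
        return col("Arew"), col("Apun"), col("R"), col("P"), col("xi"), col("d"), ones
    if name == "banditNarm_2par_lapse":
        return col("Arew"), col("Apun"), ones, ones, col("xi"), None, ones
    if name == "banditNarm_singleA_lapse":
        return col("A"), col("A"), col("R"), col("P"), col("xi"), None, ones
    if name == "banditNarm_delta":
        return col("A"), col("A"), ones, ones, zeros, None, col("tau")
    raise ValueError(name)


def batch_log_likelihood(
    values: np.ndarray,
    choices: np.ndarray,
    wins: np.ndarray,
    losses: np.ndarray,
    n_arms: int,
    model: ModelSpec,
    pointwise: bool = False,
) -> np.ndarray:
    """Log-likelihood for many subjects at once.

    Parameters
    ----------
    values : (n_subj, K) parameter matrix in model parameter order.
    choices, wins, losses : (n_subj, T) arrays; choices 0-based, -1 = missing.
    pointwise : if True return the (n_subj, T) per-trial log-probabilities
        (NaN on missing trials) instead of per-subject sums.

    Matches :func:`log_likelihood` trial-by-trial to machine precision.
    """
    n, T = choices.shape
    valid = choices >= 0
    safe_choice = np.where(valid, choices, 0)
    rows = np.arange(n)
    lp = np.full((n, T), np.nan) if pointwise else None
    total = np.zeros(n)

    if model.name == "banditNarm_kalman_filter":
        idx = {s: i for i, s in enumerate(model.param_names)}
        lam = values[:, idx["lam"]][:, None]
        theta = values[:, idx["theta"]][:, None]
        s0 = values[:, idx["s0"]]
        sD = values[:, idx["sD"]][:, None]
        beta = values[:, idx["beta"]][:, None]
        m = np.zeros((n, n_arms))
        s2 = np.tile((s0**2)[:, None], (1, n_arms))
        for t in range(T):
            logits = beta * m
            logits = logits - logits.max(axis=1, keepdims=True)
            logz = np.log(np.exp(logits).sum(axis=1))
            lpt = logits[rows, safe_choice[:, t]] - logz
            v = valid[:, t]
            total += np.where(v, lpt, 0.0)
            if pointwise:
                lp[v, t] = lpt[v]
            o = wins[:, t] - losses[:, t]
            s2c = s2[rows, safe_choice[:, t]]
            k = s2c / (s2c + 1.0)
            mc = m[rows, safe_choice[:, t]]
            upd_m = mc + k * (o - mc)
            upd_s2 = (1.0 - k) * s2c
            m[rows, safe_choice[:, t]] = np.where(v, upd_m, mc)
            s2[rows, safe_choice[:, t]] = np.where(v, upd_s2, s2c)
            mask = v[:, None]
            m = np.where(mask, lam * m + (1.0 - lam) * theta, m)
            s2 = np.where(mask, lam**2 * s2 + sD**2, s2)
        return lp if pointwise else total

    arew, apun, rscale, pscale, xi, decay, temp = _effective_batch(values, model)
    arew = arew[:, None]
    apun = apun[:, None]
    xi_c = xi[:, None]
    temp_c = temp[:, None]
    Qr = np.zeros((n, n_arms))
    Qp = np.zeros((n, n_arms))
    onehot_eye = np.eye(n_arms, dtype=bool)
    use_lapse = bool(np.any(xi > 0))
    for t in range(T):
        logits = temp_c * (Qr + Qp)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        z = e.sum(axis=1)
        if use_lapse:
            p = (1.0 - xi_c) * (e / z[:, None]) + xi_c / n_arms
            lpt = np.log(p[rows, safe_choice[:, t]])
        else:
            lpt = logits[rows, safe_choice[:, t]] - np.log(z)
        v = valid[:, t]
        total += np.where(v, lpt, 0.0)
        if pointwise:
            lp[v, t] = lpt[v]
        onehot = onehot_eye[safe_choice[:, t]]  # (n, n_arms)
        target_r = onehot * (rscale * wins[:, t])[:, None]
        target_p = onehot * (-pscale * losses[:, t])[:, None]
        mask = v[:, None]
        if decay is None:
            Qr = np.where(mask, Qr + arew * (target_r - Qr), Qr)
            Qp = np.where(mask, Qp + apun * (target_p - Qp), Qp)
        else:
            dec = 1.0 - decay[:, None]
            Qr_new = np.where(onehot, Qr + arew * (target_r - Qr), dec * Qr)
            Qp_new = np.where(onehot, Qp + apun * (target_p - Qp), dec * Qp)
            Qr = np.where(mask, Qr_new, Qr)
            Qp = np.where(mask, Qp_new, Qp)
    return lp if pointwise else total


def stack_dataset(subjects: list[SubjectData]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a cohort into (choices, wins, losses) matrices for batch evaluation."""
    T = {s.n_trials for s in subjects}
    if len(T) != 1:
        raise ValueError("subjects must share a trial count")
    choices = np.stack([s.choices for s in subjects])
    wins = np.stack([s.wins for s in subjects])
    losses = np.stack([s.losses for s in subjects])
    return choices, wins, losses


def export_bounds_json(path) -> None:
    """Export every registered model's parameter bounds for the fitting layer."""
    out = {
        name: {sym: [lo, hi] for sym, lo, hi in spec.params} for name, spec in MODELS.items()
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
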