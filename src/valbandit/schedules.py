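"""Restless N-arm bandit environments.

Each arm carries two independently drifting outcome probabilities — one for
reward (win token) and one for punishment (loss token) — bounded between 0 and
a ceiling.  The default environment is the 3-arm / 200-trial / 0.75-ceiling
task; a 4-arm, 0.5-ceiling configuration reproduces the shape of the classic
4-arm variant.  Probability sequences are pre-generated from a seed and held
constant across subjects; only the stochastic outcome realisations differ
between subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbabilitySchedule",
    "TrialOutcome",
    "generate_schedule",
    "realize_outcome",
    "display_class",
    "write_schedule",
    "read_schedule",
]


@dataclass(frozen=True)
class ProbabilitySchedule:
    """Per-trial, per-arm reward and punishment probabilities.

    Attributes
    ----------
    n_trials, n_arms : int
        Task dimensions (trials x arms).
    reward_p, punish_p : ndarray, shape (n_trials, n_arms)
        Probability of a win / loss token for choosing each arm on each trial.
        All entries lie in ``[0, ceiling]``.
    ceiling : float
        Upper bound of the drifting probabilities (0.75 for the 3-arm task).
    seed : int
        Seed the walks were generated from.
    """

    n_trials: int
    n_arms: int
    reward_p: np.ndarray
    punish_p: np.ndarray
    ceiling: float = 0.75
    seed: int = 0
    step_sd: float = field(default=0.03, compare=False)

    def __post_init__(self) -> None:
        for name in ("reward_p", "punish_p"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (self.n_trials, self.n_arms):
                raise ValueError(
                    f"{name} must have shape (n_trials, n_arms)="
                    f"{(self.n_trials, self.n_arms)}, got {m.shape}"
                )
            if np.any(m < 0) or np.any(m > self.ceiling):
                raise ValueError(f"{name} escapes [0, ceiling={self.ceiling}]")
            object.__setattr__(self, name, m)


@dataclass(frozen=True)
class TrialOutcome:
    """A single realised trial outcome: win/loss indicators and display class."""

    win: int
    loss: int

    @property
    def display_class(self) -> str:
        return display_class(self.win, self.loss)


def display_class(win: int, loss: int) -> str:
    """Map (win, loss) indicators to the four token-display classes."""
    return {
        (0, 0): "none",
        (1, 0): "win_only",
        (0, 1): "loss_only",
        (1, 1): "both",
    }[(int(win), int(loss))]


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (folded boundary, applied repeatedly)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def generate_schedule(
    n_trials: int = 200,
    n_arms: int = 3,
    ceiling: float = 0.75,
    step_sd: float = 0.03,
    seed: int = 0,
) -> ProbabilitySchedule:
    """Generate bounded Gaussian random walks for every (arm, outcome-type).

    Walks start uniformly in ``[0.2*ceiling, 0.8*ceiling]``, take N(0, step_sd)
    steps and reflect at 0 and the ceiling, so every probability stays inside
    ``[0, ceiling]`` for any seed.  Identical (seed, settings) give a
    bit-identical schedule, matching the held-constant-across-subjects design.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_arms < 2:
        raise ValueError("n_arms must be >= 2")
    if not (0 < ceiling <= 1):
        raise ValueError("ceiling must lie in (0, 1]")
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")

    rng = np.random.default_rng(seed)
    mats = []
    for _outcome in ("reward", "punish"):
        start = rng.uniform(0.2 * ceiling, 0.8 * ceiling, size=n_arms)
        steps = rng.normal(0.0, step_sd, size=(n_trials - 1, n_arms)) if n_trials > 1 else np.empty((0, n_arms))
        raw = start[None, :] + np.vstack([np.zeros((1, n_arms)), np.cumsum(steps, axis=0)])
        mats.append(_reflect(raw, 0.0, ceiling))
    reward_p, punish_p = mats
    return ProbabilitySchedule(
        n_trials=n_trials,
        n_arms=n_arms,
        reward_p=reward_p,
        punish_p=punish_p,
        ceiling=ceiling,
        seed=seed,
        step_sd=step_sd,
    )


def realize_outcome(
    schedule: ProbabilitySchedule,
    trial: int,
    arm: int,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Draw win ~ Bernoulli(reward_p) and loss ~ Bernoulli(punish_p), independently.

    ``trial`` and ``arm`` are 0-based indices into the schedule.
    """
    if not (0 <= trial < schedule.n_trials):
        raise IndexError(f"trial {trial} out of range [0, {schedule.n_trials})")
    if not (0 <= arm < schedule.n_arms):
        raise IndexError(f"arm {arm} out of range [0, {schedule.n_arms})")
    win = int(rng.random() < schedule.reward_p[trial, arm])
    loss = int(rng.random() < schedule.punish_p[trial, arm])
    return TrialOutcome(win=win, loss=loss)


def write_schedule(schedule: ProbabilitySchedule, csv_path: str | Path) -> None:
    """Serialise as tidy CSV (1-based trial/arm) plus a JSON settings sidecar."""
    csv_path = Path(csv_path)
    t, a = np.meshgrid(
        np.arange(1, schedule.n_trials + 1), np.arange(1, schedule.n_arms + 1), indexing="ij"
    )
    pd.DataFrame(
        {
            "trial": t.ravel(),
            "arm": a.ravel(),
            "reward_p": schedule.reward_p.ravel(),
            "punish_p": schedule.punish_p.ravel(),
        }
    ).to_csv(csv_path, index=False)
    sidecar = {
        "n_trials": schedule.n_trials,
        "n_arms": schedule.n_arms,
        "ceiling": schedule.ceiling,
        "step_sd": schedule.step_sd,
        "seed": schedule.seed,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_schedule(csv_path: str | Path) -> ProbabilitySchedule:
    """Read a schedule written by :func:`write_schedule`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    n_trials, n_arms = meta["n_trials"], meta["n_arms"]
    df = df.sort_values(["trial", "arm"])
    reward_p = df["reward_p"].to_numpy().reshape(n_trials, n_arms)
    punish_p = df["punish_p"].to_numpy().reshape(n_trials, n_arms)
    return ProbabilitySchedule(
        n_trials=n_trials,
        n_arms=n_arms,
        reward_p=reward_p,
        punish_p=punish_p,
        ceiling=meta["ceiling"],
        seed=meta["seed"],
        step_sd=meta.get("step_sd", 0.03),
    )
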