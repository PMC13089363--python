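"""Trial-level data containers and tidy CSV I/O.

The on-disk trial format is a tidy CSV with columns
``subject_id, trial, choice, win, loss, rt_ms`` where ``trial`` and ``choice``
are 1-based and a missed trial has an empty ``choice`` (never 0).  Subject
metadata (group label, questionnaire totals, attention-check flag) live in a
separate subjects CSV.  In memory, choices are 0-based with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SubjectData", "write_trials", "read_trials", "write_subjects", "read_subjects"]

MISSING = -1


@dataclass
class SubjectData:
    """One subject's choice sequence, outcomes and metadata.

    ``choices`` are 0-based arm indices with ``-1`` marking a missed trial
    (no response within the 3 s window); ``wins``/``losses`` are 0/1 indicators
    of the realised outcome (0 on missed trials); ``rt_ms`` is NaN on missed
    trials.
    """

    subject_id: str
    choices: np.ndarray
    wins: np.ndarray
    losses: np.ndarray
    rt_ms: np.ndarray | None = None
    group: str | None = None
    shaps: int | None = None
    dars: int | None = None
    gad: int | None = None
    zung: int | None = None
    attention_fail: bool = False
    true_params: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.wins = np.asarray(self.wins, dtype=int)
        self.losses = np.asarray(self.losses, dtype=int)
        n = len(self.choices)
        if len(self.wins) != n or len(self.losses) != n:
            raise ValueError("choices, wins and losses must have equal length")
        if self.rt_ms is None:
            self.rt_ms = np.full(n, np.nan)
        else:
            self.rt_ms = np.asarray(self.rt_ms, dtype=float)
            if len(self.rt_ms) != n:
                raise ValueError("rt_ms length mismatch")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of responded trials."""
        return self.choices >= 0


def write_trials(subjects: list[SubjectData], path: str | Path) -> None:
    frames = []
    for s in subjects:
        t = np.arange(1, s.n_trials + 1)
        choice = np.where(s.valid, s.choices + 1, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "trial": t,
                    "choice": choice,
                    "win": s.wins,
                    "loss": s.losses,
                    "rt_ms": s.rt_ms,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["choice"] = df["choice"].astype("Int64")  # keeps missing as empty field
    df.to_csv(path, index=False)


def read_trials(
    path: str | Path, subjects_meta: pd.DataFrame | None = None
) -> list[SubjectData]:
    """Read a tidy trial CSV back into :class:`SubjectData` records.

    ``subjects_meta`` (optional) is the subjects table from
    :func:`read_subjects`, indexed by ``subject_id``.
    """
    df = pd.read_csv(path)
    out = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("trial")
        choice = g["choice"].to_numpy(dtype=float)
        choices = np.where(np.isnan(choice), MISSING, choice - 1).astype(int)
        meta: dict = {}
        if subjects_meta is not None and sid in subjects_meta.index:
            row = subjects_meta.loc[sid]
            meta = {
                "group": row.get("group"),
                "shaps": int(row["shaps"]) if "shaps" in row and pd.notna(row["shaps"]) else None,
                "dars": int(row["dars"]) if "dars" in row and pd.notna(row["dars"]) else None,
                "gad": int(row["gad"]) if "gad" in row and pd.notna(row["gad"]) else None,
                "zung": int(row["zung"]) if "zung" in row and pd.notna(row["zung"]) else None,
                "attention_fail": bool(row.get("attention_fail", False)),
            }
        out.append(
            SubjectData(
                subject_id=str(sid),
                choices=choices,
                wins=g["win"].to_numpy(dtype=int),
                losses=g["loss"].to_numpy(dtype=int),
                rt_ms=g["rt_ms"].to_numpy(dtype=float),
                **meta,
            )
        )
    return out


def write_subjects(subjects: list[SubjectData], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "shaps": [s.shaps for s in subjects],
            "dars": [s.dars for s in subjects],
            "gad": [s.gad for s in subjects],
            "zung": [s.zung for s in subjects],
            "attention_fail": [s.attention_fail for s in subjects],
        }
    ).to_csv(path, index=False)


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("subject_id")
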