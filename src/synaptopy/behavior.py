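"""Complex sensory learning task (CSLT) scheduling and scoring.

Each daily testing session holds 4 unscored "free" trials followed by up to
30 scored "closed" trials. The learning criterion for a stage is 8 correct
choices within 8-10 consecutive closed trials of a single session; a run of
closed trials never carries over a session boundary (the consecutive-correct
count resets each day). Omissions (no bowl choice within 120 s) count as
errors. Per stage the readouts are total closed trials to criterion, total
errors (incorrect + omission) among those, and the median choice latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "Trial",
    "TrialConfig",
    "StageSchedule",
    "StageScore",
    "make_schedule",
    "detect_criterion",
    "score_stage",
    "trials_table",
    "trials_from_table",
]

#: Test stages: simple discrimination, compound discrimination, CD reversal,
#: intra-dimensional shift.
STAGES = ("SD", "CD", "CDR", "IDS")
OUTCOMES = ("correct", "incorrect", "omission")
SIDES = ("left", "right")

#: Criterion window: >= MIN_CORRECT correct within a window of length
#: MIN_CORRECT..MAX_WINDOW consecutive closed trials of one session.
MIN_CORRECT = 8
MAX_WINDOW = 10
CLOSED_PER_SESSION = 30
FREE_PER_SESSION = 4


@dataclass(frozen=True)
class Trial:
    """One CSLT trial of one mouse."""

    stage: str
    trial_type: str  # "free" | "closed"
    session: int  # day index, 1-based
    index: int  # trial index within session and type, 1-based
    outcome: str
    latency_s: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.trial_type not in ("free", "closed"):
            raise ValueError(f"trial_type must be free/closed, got {self.trial_type!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if self.trial_type == "closed" and not 1 <= self.index <= CLOSED_PER_SESSION:
            raise ValueError(
                f"closed-trial index must be 1..{CLOSED_PER_SESSION}, got {self.index}"
            )
        if self.latency_s is not None and self.latency_s < 0:
            raise ValueError("latency must be >= 0 seconds")


@dataclass(frozen=True)
class TrialConfig:
    """One scheduled trial: which exemplar is rewarded, how the distractor
    dimension is paired with it, and which side holds the baited bowl."""

    trial_type: str
    rewarded_exemplar: str
    distractor_pairing: str
    rewarded_side: str

    def __post_init__(self) -> None:
        if self.trial_type not in ("free", "closed"):
            raise ValueError(f"invalid trial_type {self.trial_type!r}")
        if self.rewarded_side not in SIDES:
            raise ValueError(f"side must be left/right, got {self.rewarded_side!r}")


@dataclass(frozen=True)
class StageSchedule:
    """The pre-set pseudo-random trial order for one stage session:
    4 free trials (each distractor-pairing x side combination once) then
    ``n_closed`` closed trials with exact side balance and a capped side
    run length."""

    stage: str
    trials: tuple[TrialConfig, ...]
    seed: int
    max_run: int

    @property
    def free(self) -> tuple[TrialConfig, ...]:
        return tuple(t for t in self.trials if t.trial_type == "free")

    @property
    def closed(self) -> tuple[TrialConfig, ...]:
        return tuple(t for t in self.trials if t.trial_type == "closed")


@dataclass(frozen=True)
class StageScore:
    """Trials/errors-to-criterion readouts for one mouse x stage."""

    stage: str
    total_trials: int
    total_errors: int
    median_latency_s: float
    criterion_session: int | None
    criterion_trial: int | None

    def __post_init__(self) -> None:
        if self.total_errors > self.total_trials:
            raise ValueError("errors cannot exceed trials")
        if self.reached and self.total_trials < MIN_CORRECT:
            raise ValueError(
                f"criterion cannot be reached before trial {MIN_CORRECT}"
            )

    @property
    def reached(self) -> bool:
        return self.criterion_session is not None


# ---------------------------------------------------------------------------
# Schedule construction

_DISTRACTOR_PAIRINGS = ("pairing_a", "pairing_b")


def make_schedule(
    stage: str,
    n_closed: int = CLOSED_PER_SESSION,
    seed: int = 0,
    max_run: int = 3,
) -> StageSchedule:
    """Build one session's pseudo-randomised schedule.

    Free block: the 4 distinct (distractor pairing x rewarded side)
    combinations in seeded random order, each exactly once. Closed block:
    ``n_closed`` trials with exactly ``n_closed/2`` rewarded on each side and
    no run of more than ``max_run`` consecutive same-side trials; distractor
    pairings balanced and shuffled independently. Deterministic given seed.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    if n_closed % 2:
        raise ValueError(f"n_closed must be even, got {n_closed}")
    if max_run < 2:
        raise ValueError("max_run must be >= 2")
    rng = np.random.default_rng(seed)
    half = n_closed // 2
    # feasibility: with max_run = r, sides can be arranged iff half <= r*(half+1)
    if half > max_run * (half + 1):
        raise ValueError("infeasible side-run constraint")

    free_combos = [(p, s) for p in _DISTRACTOR_PAIRINGS for s in SIDES]
    rng.shuffle(free_combos)
    free = [
        TrialConfig("free", _rewarded_exemplar(stage), p, s) for p, s in free_combos
    ]

    sides = _balanced_sides(half, max_run, rng)
    pairings = [_DISTRACTOR_PAIRINGS[i % 2] for i in range(n_closed)]
    rng.shuffle(pairings)
    closed = [
        TrialConfig("closed", _rewarded_exemplar(stage), p, s)
        for p, s in zip(pairings, sides)
    ]
    return StageSchedule(
        stage=stage, trials=tuple(free + closed), seed=seed, max_run=max_run
    )


def _rewarded_exemplar(stage: str) -> str:
    # SD/CD/CDR use the first stimulus pair, IDS introduces novel exemplars;
    # CDR rewards the previously unrewarded exemplar.
    return {
        "SD": "white",
        "CD": "white",
        "CDR": "dark-blue",
        "IDS": "light-blue",
    }[stage]


def _balanced_sides(half: int, max_run: int, rng: np.random.Generator) -> list[str]:
    """Random side sequence with exact balance and capped run length."""
    for _ in range(10_000):
        seq: list[str] = []
        remaining = {"left": half, "right": half}
        ok = True
        while seq or remaining["left"] or remaining["right"]:
            if not remaining["left"] and not remaining["right"]:
                break
            run_side = seq[-1] if seq else None
            run_len = 0
            for s in reversed(seq):
                if s == run_side:
                    run_len += 1
                else:
                    break
            choices = [
                s
                for s in SIDES
                if remaining[s] > 0 and not (s == run_side and run_len >= max_run)
            ]
            if not choices:
                ok = False
                break
            weights = np.array([remaining[s] for s in choices], dtype=float)
            pick = rng.choice(len(choices), p=weights / weights.sum())
            side = choices[pick]
            seq.append(side)
            remaining[side] -= 1
        if ok and len(seq) == 2 * half:
            return seq
    raise ValueError("could not satisfy side-run constraint after bounded retries")


# ---------------------------------------------------------------------------
# Criterion detection and scoring


def detect_criterion(
    outcomes_by_session: Sequence[Sequence[str]],
    strict_run: bool = False,
) -> tuple[int, int] | None:
    """Earliest closed trial at which the learning criterion is met.

    Parameters
    ----------
    outcomes_by_session
        Closed-trial outcome strings grouped by session, in order.
    strict_run
        Default (window) reading: some window of 8-10 consecutive trials
        ending at trial t, wholly inside one session, contains >= 8 correct.
        Strict-run variant: 8 consecutive correct trials (a single error
        resets the run), still within one session.

    Returns
    -------
    (session_index, trial_index) both 1-based, or None if never satisfied.
    Windows never span sessions; omissions count as non-correct.
    """
    for s_idx, outcomes in enumerate(outcomes_by_session, start=1):
        correct = [o == "correct" for o in outcomes]
        n = len(correct)
        if strict_run:
            run = 0
            for t in range(n):
                run = run + 1 if correct[t] else 0
                if run >= MIN_CORRECT:
                    return (s_idx, t + 1)
        else:
            prefix = np.concatenate([[0], np.cumsum(correct)])
            for t in range(MIN_CORRECT - 1, n):
                if not correct[t]:
                    # a criterion window must end on a correct choice: with
                    # >=8-of-<=10 this is implied (dropping a trailing error
                    # gives a shorter window with the same correct count)
                    continue
                for w in range(MIN_CORRECT, MAX_WINDOW + 1):
                    if w > t + 1:
                        break
                    if prefix[t + 1] - prefix[t + 1 - w] >= MIN_CORRECT:
                        return (s_idx, t + 1)
    return None


def score_stage(
    trials: Iterable[Trial],
    strict_run: bool = False,
) -> StageScore:
    """Score one mouse's trials for one stage.

    Free trials are excluded. Total trials = closed trials up to and
    including the criterion trial, summed over sessions; total errors =
    incorrect + omission among those; median latency over the same trials
    (omissions' missing latencies excluded). If the criterion is never
    reached, totals cover all closed trials.
    """
    trials = list(trials)
    stages = {t.stage for t in trials}
    if len(stages) > 1:
        raise ValueError(f"score_stage requires a single stage, got {sorted(stages)}")
    closed = [t for t in trials if t.trial_type == "closed"]
    keys = [(t.session, t.index) for t in closed]
    if keys != sorted(keys):
        raise ValueError("trials must be sorted by (session, index)")
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (session, index) closed trials")
    stage = trials[0].stage if trials else "SD"

    sessions = sorted({t.session for t in closed})
    by_session = [[t for t in closed if t.session == s] for s in sessions]
    hit = detect_criterion(
        [[t.outcome for t in sess] for sess in by_session], strict_run=strict_run
    )

    if hit is None:
        scored = closed
        crit_session = crit_trial = None
    else:
        s_pos, t_pos = hit
        scored = [t for sess in by_session[: s_pos - 1] for t in sess]
        scored += by_session[s_pos - 1][:t_pos]
        crit_session = sessions[s_pos - 1]
        crit_trial = by_session[s_pos - 1][t_pos - 1].index

    errors = sum(1 for t in scored if t.outcome in ("incorrect", "omission"))
    latencies = [t.latency_s for t in scored if t.latency_s is not None]
    median_latency = float(np.median(latencies)) if latencies else float("nan")
    return StageScore(
        stage=stage,
        total_trials=len(scored),
        total_errors=errors,
        median_latency_s=median_latency,
        criterion_session=crit_session,
        criterion_trial=crit_trial,
    )


# ---------------------------------------------------------------------------
# Session-log tables

LOG_COLUMNS = [
    "mouse",
    "group",
    "stage",
    "session",
    "trial_index",
    "trial_type",
    "outcome",
    "latency_s",
]


def trials_table(
    trials: Sequence[Trial], mouse: str = "", group: str = ""
) -> pd.DataFrame:
    """Trials as the session-log CSV schema."""
    rows = [
        {
            "mouse": mouse,
            "group": group,
            "stage": t.stage,
            "session": t.session,
            "trial_index": t.index,
            "trial_type": t.trial_type,
            "outcome": t.outcome,
            "latency_s": t.latency_s if t.latency_s is not None else np.nan,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def trials_from_table(table: pd.DataFrame) -> dict[tuple[str, str, str], list[Trial]]:
    """Parse a session-log table into trials keyed by (mouse, group, stage)."""
    missing = set(LOG_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"session log missing columns: {sorted(missing)}")
    out: dict[tuple[str, str, str], list[Trial]] = {}
    for row in table.itertuples(index=False):
        lat = getattr(row, "latency_s")
        lat = None if pd.isna(lat) else float(lat)
        t = Trial(
            stage=str(row.stage),
            trial_type=str(row.trial_type),
            session=int(row.session),
            index=int(row.trial_index),
            outcome=str(row.outcome),
            latency_s=lat,
        )
        out.setdefault((str(row.mouse), str(row.group), str(row.stage)), []).append(t)
    for trials in out.values():
        trials.sort(key=lambda t: (t.session, 0 if t.trial_type == "free" else 1, t.index))
    return out
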