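"""Motor-gamble task structure: trials, schedules, sessions and success-rate tables.

The task is a go/no-go motor gamble. On each trial the player either skips
(keeping a small certain payoff, +10 points on reward trials or -10 on
punishment trials) or gambles on executing a tapping action. A successful
gamble pays 20/60/100 points on reward trials (or avoids the loss on
punishment trials); failure pays 0 (reward) or -20/-60/-100 (punishment).
A session is 42 trials: 6 value combinations x 7 target-size levels, with
the three easiest levels confined to the first three blocks, levels 4-6 to
blocks 4-6 and the hardest level to block 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

REWARD_MAGNITUDES = (20, 60, 100)
PUNISHMENT_MAGNITUDES = (-20, -60, -100)
CERTAIN_REWARD = 10
CERTAIN_PUNISHMENT = -10
N_TARGET_LEVELS = 7
N_TRIALS = 42
STARTING_POINTS = 250

SCREEN_BINS = (4, 6, 8, 10)

AGE_GROUP_LABELS = {
    1: "18-24",
    2: "25-29",
    3: "30-39",
    4: "40-49",
    5: "50-59",
    6: "60+",
}

#: Column order of the flat trial-by-trial CSV schema.
TRIAL_CSV_COLUMNS = [
    "participant_id",
    "age_group",
    "gender",
    "education",
    "screen_inches",
    "block",
    "target_level",
    "domain",
    "certain_value",
    "success_value",
    "fail_value",
    "choice",
    "motor_success",
    "points_delta",
]

#: Per-trial columns stored on a session (superset of the CSV trial fields).
SESSION_TRIAL_COLUMNS = [
    "block",
    "target_level",
    "domain",
    "certain_value",
    "success_value",
    "fail_value",
    "angle",
    "choice",
    "motor_success",
    "points_delta",
]


@dataclass(frozen=True)
class TrialSpec:
    """One decision problem before any choice is made."""

    domain: Literal["reward", "punishment"]
    certain_value: int
    gamble_success_value: int
    gamble_fail_value: int
    target_level: int
    block_index: int
    trajectory_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.domain == "reward":
            if self.certain_value != CERTAIN_REWARD or self.gamble_fail_value != 0:
                raise ValueError(
                    "reward trials have certain_value=+10 and gamble_fail_value=0"
                )
            if self.gamble_success_value not in REWARD_MAGNITUDES:
                raise ValueError(f"invalid reward magnitude {self.gamble_success_value}")
        elif self.domain == "punishment":
            if self.certain_value != CERTAIN_PUNISHMENT or self.gamble_success_value != 0:
                raise ValueError(
                    "punishment trials have certain_value=-10 and gamble_success_value=0"
                )
            if self.gamble_fail_value not in PUNISHMENT_MAGNITUDES:
                raise ValueError(f"invalid punishment magnitude {self.gamble_fail_value}")
        else:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not 1 <= self.target_level <= N_TARGET_LEVELS:
            raise ValueError("target_level must be in 1..7")
        if not 0.0 <= self.trajectory_angle <= 360.0:
            raise ValueError("trajectory_angle must be in [0, 360]")


@dataclass(frozen=True)
class GambleOffer:
    """A resolved offer: certain payoff versus a two-outcome motor gamble.

    ``o_success`` / ``o_fail`` are the gamble outcomes received with
    probability ``p_success`` / ``1 - p_success``; ``o_certain`` is the
    payoff for skipping.
    """

    p_success: float
    o_success: float
    o_fail: float
    o_certain: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_success <= 1.0:
            raise ValueError("p_success must be in [0, 1]")


def value_combinations() -> list[tuple[str, int, int, int]]:
    """The six (domain, certain, success, fail) payoff combinations."""
    combos = [("reward", CERTAIN_REWARD, m, 0) for m in REWARD_MAGNITUDES]
    combos += [("punishment", CERTAIN_PUNISHMENT, 0, m) for m in PUNISHMENT_MAGNITUDES]
    return combos


def build_schedule(seed: int | np.random.Generator) -> list[TrialSpec]:
    """Build the 42-trial schedule for one session.

    Blocks 1-3 present target levels 1-3 (one level per block, randomly
    permuted across those blocks), blocks 4-6 present levels 4-6 likewise,
    and block 7 presents level 7. Within each block the six value
    combinations appear once, in random order. Trajectory angles are drawn
    uniformly in [0, 360].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = list(rng.permutation([1, 2, 3])) + list(rng.permutation([4, 5, 6])) + [7]
    trials: list[TrialSpec] = []
    combos = value_combinations()
    for block, level in enumerate(levels, start=1):
        order = rng.permutation(len(combos))
        angles = rng.uniform(0.0, 360.0, size=len(combos))
        for angle, j in zip(angles, order):
            domain, oc, osucc, ofail = combos[j]
            trials.append(
                TrialSpec(
                    domain=domain,
                    certain_value=oc,
                    gamble_success_value=osucc,
                    gamble_fail_value=ofail,
                    target_level=int(level),
                    block_index=block,
                    trajectory_angle=float(angle),
                )
            )
    return trials


def expected_values(offer: GambleOffer) -> tuple[float, float]:
    """Expected value of the gamble (p*O1 + (1-p)*O2) and of the certain option."""
    ev_gamble = offer.p_success * offer.o_success + (1.0 - offer.p_success) * offer.o_fail
    return ev_gamble, offer.o_certain


def bin_screen(inches: float) -> int:
    """Map a device screen size to the nearest bin centre in {4, 6, 8, 10} inches.

    Ties (e.g. 5.0) break toward the smaller bin.
    """
    if not np.isfinite(inches) or inches <= 0:
        raise ValueError(f"invalid screen size {inches!r}")
    edges = np.array([5.0, 7.0, 9.0])
    idx = int(np.searchsorted(edges, inches, side="left"))
    return SCREEN_BINS[idx]


@dataclass
class ParticipantSession:
    """One participant's complete record: demographics plus 42 trials.

    ``trials`` is a DataFrame with columns :data:`SESSION_TRIAL_COLUMNS`;
    ``choice`` is 1 (gamble) / 0 (skip), ``motor_success`` is 1/0 on gambled
    trials and NaN on skipped trials (the outcome is unobservable), and
    ``points_delta`` is the signed points change. The running score starts
    at :data:`STARTING_POINTS`.
    """

    participant_id: str
    age_group: int
    gender: str
    education: str
    screen_inches: float
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not 1 <= int(self.age_group) <= 6:
            raise ValueError("age_group must be in 1..6")
        missing = [c for c in SESSION_TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"session trials missing columns {missing}")

    @property
    def screen_bin(self) -> int:
        return bin_screen(self.screen_inches)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def final_points(self) -> float:
        return STARTING_POINTS + float(self.trials["points_delta"].sum())

    def offers(self, success_table: "SuccessRateTable") -> pd.DataFrame:
        """Trial table augmented with the resolved success probability ``p``."""
        out = self.trials.copy()
        out["p"] = success_table.rates_for_session(self)
        return out


def session_from_schedule(
    schedule: Sequence[TrialSpec],
    participant_id: str,
    age_group: int,
    gender: str = "unknown",
    education: str = "school",
    screen_inches: float = 6.0,
) -> ParticipantSession:
    """Wrap a schedule into a session with empty choice/outcome columns."""
    rows = [
        {
            "block": t.block_index,
            "target_level": t.target_level,
            "domain": t.domain,
            "certain_value": t.certain_value,
            "success_value": t.gamble_success_value,
            "fail_value": t.gamble_fail_value,
            "angle": t.trajectory_angle,
            "choice": np.nan,
            "motor_success": np.nan,
            "points_delta": np.nan,
        }
        for t in schedule
    ]
    return ParticipantSession(
        participant_id=participant_id,
        age_group=age_group,
        gender=gender,
        education=education,
        screen_inches=screen_inches,
        trials=pd.DataFrame(rows, columns=SESSION_TRIAL_COLUMNS),
    )


@dataclass
class SuccessRateTable:
    """Empirical motor-success probabilities.

    ``mode='group'`` keys cells by (age_group, screen_bin, target_level) —
    the probability of success for a trial is the average success rate of
    all gambled trials from participants of the same age group, on the same
    screen-size bin, facing the same target level. ``mode='individual'``
    keys by (participant_id, target_level) using only that participant's
    own gambled trials. Cells with no gambled trials are *missing* (absent
    from the table), never zero; lookups return NaN for them.
    """

    mode: Literal["group", "individual"]
    table: pd.DataFrame  # indexed by the key columns; columns: rate, n

    GROUP_KEY = ["age_group", "screen_bin", "target_level"]
    INDIVIDUAL_KEY = ["participant_id", "target_level"]

    def __post_init__(self) -> None:
        rates = self.table["rate"].to_numpy(dtype=float)
        if len(rates) and (np.nanmin(rates) < 0 or np.nanmax(rates) > 1):
            raise ValueError("success rates must lie in [0, 1]")
        if len(self.table) and (self.table["n"].to_numpy() < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def key_columns(self) -> list[str]:
        return self.GROUP_KEY if self.mode == "group" else self.INDIVIDUAL_KEY

    def rate(self, *key) -> float:
        """Rate for one cell; NaN if the cell is missing."""
        try:
            return float(self.table.loc[tuple(key), "rate"])
        except KeyError:
            return float("nan")

    def rates_for_session(self, session: ParticipantSession) -> np.ndarray:
        """Per-trial success probabilities for a session (NaN where missing)."""
        levels = session.trials["target_level"].to_numpy()
        if self.mode == "group":
            keys = [(session.age_group, session.screen_bin, int(l)) for l in levels]
        else:
            keys = [(session.participant_id, int(l)) for l in levels]
        lookup = self.table["rate"].to_dict()
        return np.array([lookup.get(k, np.nan) for k in keys], dtype=float)

    def to_csv(self, path_or_buf) -> None:
        self.table.reset_index().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, mode: str = "group") -> "SuccessRateTable":
        df = pd.read_csv(path_or_buf)
        key = cls.GROUP_KEY if mode == "group" else cls.INDIVIDUAL_KEY
        return cls(mode=mode, table=df.set_index(key)[["rate", "n"]])


def estimate_success_table(
    sessions: Iterable[ParticipantSession], mode: str = "group"
) -> SuccessRateTable:
    """Estimate motor-success probabilities from gambled trials.

    Only trials that were actually gambled (choice == 1) carry an observed
    motor outcome and enter the averages. Cells with no observations are
    omitted (missing), not stored as zero.
    """
    if mode not in ("group", "individual"):
        raise ValueError(f"unknown mode {mode!r}")
    frames = []
    for s in sessions:
        t = s.trials
        gambled = t[t["choice"] == 1]
        if gambled.empty:
            continue
        df = pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "age_group": s.age_group,
                "screen_bin": s.screen_bin,
                "target_level": gambled["target_level"].to_numpy(),
                "motor_success": gambled["motor_success"].to_numpy(dtype=float),
            }
        )
        frames.append(df)
    key = SuccessRateTable.GROUP_KEY if mode == "group" else SuccessRateTable.INDIVIDUAL_KEY
    if not frames:
        empty = pd.DataFrame(columns=key + ["rate", "n"]).set_index(key)
        return SuccessRateTable(mode=mode, table=empty)
    data = pd.concat(frames, ignore_index=True)
    data = data.dropna(subset=["motor_success"])
    grouped = data.groupby(key)["motor_success"].agg(rate="mean", n="count")
    grouped["n"] = grouped["n"].astype(int)
    return SuccessRateTable(mode=mode, table=grouped)


def sessions_to_frame(sessions: Iterable[ParticipantSession]) -> pd.DataFrame:
    """Flatten sessions into the trial-by-trial CSV schema (one row per trial)."""
    frames = []
    for s in sessions:
        df = s.trials[
            [
                "block",
                "target_level",
                "domain",
                "certain_value",
                "success_value",
                "fail_value",
                "choice",
                "motor_success",
                "points_delta",
            ]
        ].copy()
        df.insert(0, "screen_inches", s.screen_inches)
        df.insert(0, "education", s.education)
        df.insert(0, "gender", s.gender)
        df.insert(0, "age_group", s.age_group)
        df.insert(0, "participant_id", s.participant_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=TRIAL_CSV_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRIAL_CSV_COLUMNS]


def sessions_from_frame(df: pd.DataFrame) -> list[ParticipantSession]:
    """Reassemble sessions from a flat trial table (inverse of sessions_to_frame)."""
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    sessions = []
    for pid, grp in df.groupby("participant_id", sort=False):
        trials = grp[
            [
                "block",
                "target_level",
                "domain",
                "certain_value",
                "success_value",
                "fail_value",
                "choice",
                "motor_success",
                "points_delta",
            ]
        ].reset_index(drop=True)
        trials["angle"] = np.nan
        trials = trials[SESSION_TRIAL_COLUMNS]
        first = grp.iloc[0]
        sessions.append(
            ParticipantSession(
                participant_id=str(pid),
                age_group=int(first["age_group"]),
                gender=str(first["gender"]),
                education=str(first["education"]),
                screen_inches=float(first["screen_inches"]),
                trials=trials,
            )
        )
    return sessions


def write_trials_csv(sessions: Iterable[ParticipantSession], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_trials_csv(path) -> list[ParticipantSession]:
    return sessions_from_frame(pd.read_csv(path))
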