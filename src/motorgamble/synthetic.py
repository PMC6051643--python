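"""Synthetic cohorts with the statistical structure of the app study.

The generator emulates the data the analysis pipeline expects: six age
groups, device screen sizes binned at {4, 6, 8, 10} inches (older groups
tending to larger screens), a motor-success surface that falls with
target-size level and is steeper for older groups and smaller screens,
and choices generated trial-by-trial from the winning approach-avoidance
model [alpha, mu, delta+, delta-] with age-graded parameter profiles:
the Pavlovian approach offset delta+ declines steeply from young to old,
delta- (avoidance) grows mildly more negative, alpha declines mildly and
mu is flat. Per-participant heterogeneity is truncated-normal around the
group medians, truncated at the model bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .models import (
    AA_WINNER,
    ALPHA_BOUNDS,
    DELTA_BOUNDS,
    MU_BOUNDS,
    ParameterVector,
    gamble_prob_arrays,
)
from .task import (
    AGE_GROUP_LABELS,
    SCREEN_BINS,
    SESSION_TRIAL_COLUMNS,
    N_TARGET_LEVELS,
    ParticipantSession,
    SuccessRateTable,
    build_schedule,
    session_from_schedule,
    sessions_to_frame,
)

N_AGE_GROUPS = 6


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Parameter profiles are linear interpolations between a youngest-group
    and an oldest-group anchor; per-participant values are truncated-normal
    draws around the group median. The success surface is logit-linear in
    target level with age and screen-size interaction strengths; setting
    both interactions to zero makes every (age, screen) cell identical.
    """

    n_per_age_group: tuple[int, ...] = (10, 10, 10, 10, 10, 10)
    # (youngest, oldest) anchors for the group medians
    alpha_anchors: tuple[float, float] = (0.85, 0.65)
    mu_anchors: tuple[float, float] = (0.6, 0.6)
    delta_plus_anchors: tuple[float, float] = (0.35, 0.05)
    delta_minus_anchors: tuple[float, float] = (-0.10, -0.25)
    # per-participant spread (sd of the truncated-normal draws)
    alpha_sd: float = 0.08
    mu_sd: float = 0.20
    delta_sd: float = 0.08
    # success surface: rate at level 1, drop per level (logit), interactions
    base_rate: float = 0.95
    level_slope: float = 0.55
    age_effect: float = 0.35
    screen_effect: float = 0.30
    # older participants tend toward larger screens (0 = uniform)
    screen_age_trend: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_age_group) != N_AGE_GROUPS:
            raise ValueError("need one count per age group")
        if any(n < 0 for n in self.n_per_age_group):
            raise ValueError("group counts must be non-negative")
        if self.level_slope < 0 or self.age_effect < 0 or self.screen_effect < 0:
            raise ValueError("surface slopes/interactions must be non-negative")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["n_per_age_group"] = list(d["n_per_age_group"])
        for k in ("alpha_anchors", "mu_anchors", "delta_plus_anchors", "delta_minus_anchors"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for k in (
            "n_per_age_group", "alpha_anchors", "mu_anchors",
            "delta_plus_anchors", "delta_minus_anchors",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def group_profiles(config: CohortConfig) -> pd.DataFrame:
    """Median generating parameters per age group (linear between anchors)."""
    w = np.linspace(0.0, 1.0, N_AGE_GROUPS)
    rows = {}
    for name, (young, old) in (
        ("alpha", config.alpha_anchors),
        ("mu", config.mu_anchors),
        ("delta_plus", config.delta_plus_anchors),
        ("delta_minus", config.delta_minus_anchors),
    ):
        rows[name] = young + w * (old - young)
    df = pd.DataFrame(rows, index=pd.RangeIndex(1, N_AGE_GROUPS + 1, name="age_group"))
    return df


def sample_success_surface(config: CohortConfig) -> SuccessRateTable:
    """Deterministic motor-success surface over age x screen bin x target level.

    logit(rate) falls linearly with target level; the fall is steeper for
    older groups (``age_effect``) and for smaller screens
    (``screen_effect``). Rates are clipped to [0.02, 0.98]. Monotone
    non-increasing in level and non-decreasing in screen bin by
    construction.
    """
    ages = np.arange(1, N_AGE_GROUPS + 1)
    screens = np.arange(len(SCREEN_BINS))
    levels = np.arange(1, N_TARGET_LEVELS + 1)
    a, s, l = np.meshgrid(ages, screens, levels, indexing="ij")
    steep = (
        config.level_slope
        * (1.0 + config.age_effect * (a - 1) / (N_AGE_GROUPS - 1))
        * (1.0 + config.screen_effect * (len(SCREEN_BINS) - 1 - s) / (len(SCREEN_BINS) - 1))
    )
    rate = expit(logit(config.base_rate) - steep * (l - 1))
    rate = np.clip(rate, 0.02, 0.98)
    table = pd.DataFrame(
        {
            "age_group": a.ravel(),
            "screen_bin": np.asarray(SCREEN_BINS)[s.ravel()],
            "target_level": l.ravel(),
            "rate": rate.ravel(),
            "n": 0,
        }
    ).set_index(SuccessRateTable.GROUP_KEY)
    return SuccessRateTable(mode="group", table=table)


def _truncnorm_draw(rng, loc, scale, lo, hi):
    if scale <= 0:
        return float(np.clip(loc, lo, hi))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return float(truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))


def _screen_probs(config: CohortConfig, age_group: int) -> np.ndarray:
    idx = np.arange(len(SCREEN_BINS)) - (len(SCREEN_BINS) - 1) / 2.0
    w = np.exp(config.screen_age_trend * (age_group - 3.5) * idx)
    return w / w.sum()


def draw_participant_parameters(
    config: CohortConfig, age_group: int, rng: np.random.Generator
) -> ParameterVector:
    med = group_profiles(config).loc[age_group]
    return ParameterVector(
        alpha=_truncnorm_draw(rng, med["alpha"], config.alpha_sd, *ALPHA_BOUNDS),
        mu=_truncnorm_draw(rng, med["mu"], config.mu_sd, *MU_BOUNDS),
        delta_plus=_truncnorm_draw(rng, med["delta_plus"], config.delta_sd, *DELTA_BOUNDS),
        delta_minus=_truncnorm_draw(rng, med["delta_minus"], config.delta_sd, *DELTA_BOUNDS),
    )


def simulate_session_choices(
    session: ParticipantSession,
    theta: ParameterVector,
    surface: SuccessRateTable,
    rng: np.random.Generator,
    spec=AA_WINNER,
) -> ParticipantSession:
    """Fill choices, motor outcomes and points for a session in place.

    Choices are Bernoulli draws from the gamble probability under ``spec``
    (default: the winning approach-avoidance model); motor success is drawn
    only on gambled trials (it is unobservable on skips).
    """
    t = session.trials
    p = surface.rates_for_session(session)
    sign = np.where(t["domain"].to_numpy() == "reward", 1.0, -1.0)
    f = gamble_prob_arrays(
        p,
        t["success_value"].to_numpy(dtype=float),
        t["fail_value"].to_numpy(dtype=float),
        t["certain_value"].to_numpy(dtype=float),
        sign,
        theta,
        spec,
    )
    y = (rng.random(len(f)) < f).astype(float)
    success = np.where(y == 1, (rng.random(len(f)) < p).astype(float), np.nan)
    points = np.where(
        y == 0,
        t["certain_value"].to_numpy(dtype=float),
        np.where(success == 1, t["success_value"], t["fail_value"]),
    )
    t["choice"] = y
    t["motor_success"] = success
    t["points_delta"] = points
    return session


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[list[ParticipantSession], pd.DataFrame, SuccessRateTable]:
    """Generate a full synthetic cohort.

    Returns (sessions, ground-truth parameter table, true success surface).
    Deterministic given the seed (defaulting to ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    surface = sample_success_surface(config)
    sessions: list[ParticipantSession] = []
    truth_rows = []
    idx = 0
    for age_group, count in enumerate(config.n_per_age_group, start=1):
        for _ in range(count):
            pid = f"P{idx:05d}"
            idx += 1
            gender = "male" if rng.random() < 0.6 else "female"
            education = rng.choice(["school", "university", "advanced"], p=[0.35, 0.42, 0.23])
            screen_bin = int(rng.choice(SCREEN_BINS, p=_screen_probs(config, age_group)))
            screen_inches = screen_bin + float(rng.uniform(-0.9, 0.9))
            theta = draw_participant_parameters(config, age_group, rng)
            session = session_from_schedule(
                build_schedule(rng),
                participant_id=pid,
                age_group=age_group,
                gender=gender,
                education=str(education),
                screen_inches=screen_inches,
            )
            simulate_session_choices(session, theta, surface, rng)
            sessions.append(session)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "age_group": age_group,
                    "screen_bin": screen_bin,
                    **theta.as_dict(),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return sessions, truth, surface


def generate_estimation_study(
    config: CohortConfig,
    n_per_group: int = 20,
    miscalibration: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic control study of verbal success-probability estimates.

    Each participant sees 42 trials; the verbal estimate is the true
    surface probability (in percent) plus a constant ``miscalibration``
    bias and Gaussian noise, rounded to the 0..100 grid in steps of 10;
    motor success is a Bernoulli draw from the true probability.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    surface = sample_success_surface(config)
    rows = []
    idx = 0
    for age_group in range(1, N_AGE_GROUPS + 1):
        for _ in range(n_per_group):
            pid = f"E{idx:04d}"
            idx += 1
            screen_bin = int(rng.choice(SCREEN_BINS, p=_screen_probs(config, age_group)))
            for t in build_schedule(rng):
                p = surface.rate(age_group, screen_bin, t.target_level)
                raw = 100.0 * p + miscalibration + rng.normal(0.0, noise_sd)
                estimate = float(np.clip(np.round(raw / 10.0) * 10.0, 0.0, 100.0))
                success = int(rng.random() < p)
                rows.append(
                    {
                        "participant_id": pid,
                        "age_group": age_group,
                        "screen_bin": screen_bin,
                        "target_level": t.target_level,
                        "p_true": p,
                        "estimate": estimate,
                        "motor_success": success,
                    }
                )
    return pd.DataFrame(rows)
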