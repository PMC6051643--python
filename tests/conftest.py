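import numpy as np
import pandas as pd
import pytest

from motorgamble import (
    CohortConfig,
    ParticipantSession,
    SuccessRateTable,
    build_schedule,
    generate_cohort,
    sample_success_surface,
)
from motorgamble.task import SESSION_TRIAL_COLUMNS, session_from_schedule


@pytest.fixture(scope="session")
def surface() -> SuccessRateTable:
    """True success surface under default study conditions."""
    return sample_success_surface(CohortConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """24-participant synthetic cohort (4 per age group), with truth and surface."""
    cfg = CohortConfig(n_per_age_group=(4,) * 6)
    return generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def template_session(surface) -> ParticipantSession:
    """An empty 42-trial session (age group 2, 6-inch screen)."""
    return session_from_schedule(
        build_schedule(11), "T0", age_group=2, screen_inches=6.0
    )


def make_session(trials: list[dict], participant_id="X0", age_group=1,
                 screen_inches=6.0, **kw) -> ParticipantSession:
    """Hand-build a session from partial trial dicts (missing fields defaulted)."""
    rows = []
    for i, t in enumerate(trials):
        row = {
            "block": 1,
            "target_level": 1,
            "domain": "reward",
            "certain_value": 10,
            "success_value": 20,
            "fail_value": 0,
            "angle": 0.0,
            "choice": np.nan,
            "motor_success": np.nan,
            "points_delta": np.nan,
        }
        row.update(t)
        rows.append(row)
    return ParticipantSession(
        participant_id=participant_id,
        age_group=age_group,
        screen_inches=screen_inches,
        gender=kw.get("gender", "female"),
        education=kw.get("education", "school"),
        trials=pd.DataFrame(rows, columns=SESSION_TRIAL_COLUMNS),
    )


def flat_success_table(rate: float = 0.5) -> SuccessRateTable:
    """Group table assigning the same success probability to every cell."""
    cells = [
        {"age_group": a, "screen_bin": s, "target_level": l, "rate": rate, "n": 10}
        for a in range(1, 7)
        for s in (4, 6, 8, 10)
        for l in range(1, 8)
    ]
    table = pd.DataFrame(cells).set_index(SuccessRateTable.GROUP_KEY)
    return SuccessRateTable(mode="group", table=table)
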