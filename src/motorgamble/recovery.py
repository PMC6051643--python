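"""Recovery diagnostics: parameter recovery, model recovery, predicted curves.

Parameter recovery simulates choices from known "typical participant"
parameter sets on a real trial schedule, refits the model, and checks that
the recovered estimates cluster around the generating values. Model
recovery simulates whole cohorts under each of two candidate generating
models and checks that summed-BIC model selection identifies the
generator. Predicted curves average the fitted models' trial-wise gamble
probabilities within expected-value-difference bins, the model-falsification
overlay: only models with separate Pavlovian offsets can produce a
reward > punishment gamble-rate gap where the options have equal expected
value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import FitResult, fit_mle
from .models import (
    AA_WINNER,
    PT_WINNER,
    ModelSpec,
    ParameterVector,
    gamble_prob_arrays,
    param_bounds,
)
from .stats import assign_bin
from .synthetic import (
    CohortConfig,
    sample_success_surface,
    simulate_session_choices,
)
from .task import (
    ParticipantSession,
    SuccessRateTable,
    build_schedule,
    session_from_schedule,
)

#: Default "typical participant" generating sets for the winning
#: approach-avoidance model, placed in the region where fitted participants
#: cluster (risk-averse alpha, shallow softmax, approach delta+ > 0 > delta-).
TYPICAL_AA_SETS = (
    ParameterVector(alpha=0.8, mu=0.5, delta_plus=0.3, delta_minus=-0.2),
    ParameterVector(alpha=0.7, mu=1.0, delta_plus=0.2, delta_minus=-0.1),
    ParameterVector(alpha=0.9, mu=0.3, delta_plus=0.1, delta_minus=-0.3),
)

#: Typical sets for the winning prospect-theory model.
TYPICAL_PT_SETS = (
    ParameterVector(alpha_plus=0.8, alpha_minus=0.7, mu_plus=0.6, mu_minus=0.4),
    ParameterVector(alpha_plus=0.7, alpha_minus=0.9, mu_plus=1.0, mu_minus=0.8),
)


def _copy_template(template: ParticipantSession, pid: str) -> ParticipantSession:
    return ParticipantSession(
        participant_id=pid,
        age_group=template.age_group,
        gender=template.gender,
        education=template.education,
        screen_inches=template.screen_inches,
        trials=template.trials.copy(),
    )


@dataclass
class RecoveryReport:
    """Parameter-recovery simulation results."""

    spec: ModelSpec
    draws: pd.DataFrame  # one row per (set, sim): recovered parameters + logL
    summary: pd.DataFrame  # per (set, parameter): truth, median, q10, q90, covered
    n_sims: int

    @property
    def all_covered(self) -> bool:
        """True if every generating value lies in its central 80% interval."""
        return bool(self.summary["covered"].all())


def parameter_recovery(
    param_sets: Sequence[ParameterVector],
    spec: ModelSpec,
    n_sims: int,
    session_template: ParticipantSession,
    success_table: SuccessRateTable,
    seed: int = 0,
    n_restarts: int = 20,
) -> RecoveryReport:
    """Simulate-and-refit check of parameter estimability.

    For each generating set, ``n_sims`` choice sequences are simulated on
    the template session's offers and refitted with the multi-start MLE.
    The summary reports, per parameter, the median and central 80% interval
    of the recovered values and whether the generating value is covered.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for set_idx, theta in enumerate(param_sets):
        for sim in range(n_sims):
            pid = f"R{set_idx}_{sim}"
            session = _copy_template(session_template, pid)
            simulate_session_choices(session, theta, success_table, rng, spec=spec)
            fit = fit_mle(session, spec, success_table, n_restarts=n_restarts, seed=seed)
            rows.append({"set": set_idx, "sim": sim, "logL": fit.log_likelihood,
                         **fit.theta.as_dict()})
    draws = pd.DataFrame(rows)

    summary_rows = []
    for set_idx, theta in enumerate(param_sets):
        sub = draws[draws["set"] == set_idx]
        for name in spec.param_names:
            vals = sub[name].to_numpy(dtype=float)
            q10, med, q90 = np.percentile(vals, [10, 50, 90])
            truth = theta.get(name)
            summary_rows.append(
                {
                    "set": set_idx,
                    "parameter": name,
                    "truth": truth,
                    "median": float(med),
                    "q10": float(q10),
                    "q90": float(q90),
                    "mad": float(np.median(np.abs(vals - truth))),
                    "covered": bool(q10 <= truth <= q90),
                }
            )
    return RecoveryReport(
        spec=spec, draws=draws, summary=pd.DataFrame(summary_rows), n_sims=n_sims
    )


def _jitter(theta: ParameterVector, spec: ModelSpec, sd: float, rng) -> ParameterVector:
    vals = {}
    for name in spec.param_names:
        lo, hi = param_bounds(name)
        vals[name] = float(np.clip(theta.get(name) + rng.normal(0.0, sd), lo, hi))
    return ParameterVector(**vals)


def model_recovery(
    generators: Mapping[str, tuple[ModelSpec, ParameterVector]] | None = None,
    n_cohorts: int = 1,
    cohort_size: int = 200,
    seed: int = 0,
    candidates: Mapping[str, ModelSpec] | None = None,
    success_table: SuccessRateTable | None = None,
    param_jitter: float = 0.05,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Confusion counts for summed-BIC model selection on simulated cohorts.

    For each generating model, ``n_cohorts`` cohorts of ``cohort_size``
    42-trial participants are simulated (with truncated-Gaussian
    participant-level jitter of the generating parameters) and each
    candidate model is fitted to every participant; the cohort is credited
    to the candidate with the smallest summed BIC. Rows of the returned
    frame (one per generator) sum to ``n_cohorts``.
    """
    if generators is None:
        generators = {
            "PT": (PT_WINNER, TYPICAL_PT_SETS[0]),
            "AA": (AA_WINNER, TYPICAL_AA_SETS[0]),
        }
    if candidates is None:
        candidates = {"PT": PT_WINNER, "AA": AA_WINNER}
    if success_table is None:
        success_table = sample_success_surface(CohortConfig())
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        0, index=pd.Index(generators.keys(), name="generator"), columns=list(candidates)
    )
    for gen_name, (gen_spec, gen_theta) in generators.items():
        for cohort in range(n_cohorts):
            summed_bic = {name: 0.0 for name in candidates}
            for i in range(cohort_size):
                pid = f"M{gen_name}_{cohort}_{i}"
                age_group = (i % 6) + 1
                session = session_from_schedule(
                    build_schedule(rng), pid, age_group=age_group,
                    screen_inches=float(rng.choice([4, 6, 8, 10])) + 0.1,
                )
                theta = _jitter(gen_theta, gen_spec, param_jitter, rng)
                simulate_session_choices(session, theta, success_table, rng, spec=gen_spec)
                for cand_name, cand_spec in candidates.items():
                    fit = fit_mle(
                        session, cand_spec, success_table, n_restarts=n_restarts, seed=seed
                    )
                    summed_bic[cand_name] += fit.bic
            winner = min(summed_bic, key=summed_bic.get)
            counts.loc[gen_name, winner] += 1
    return counts


def predicted_curves(
    fits: Mapping[str, FitResult] | Iterable[FitResult],
    sessions: Iterable[ParticipantSession],
    success_table: SuccessRateTable,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Model-predicted gamble probability per (age group, domain, EV-difference bin).

    For every trial of every fitted session the fitted model's gamble
    probability is computed and averaged within half-open EV-difference
    bins anchored at 0 — the overlay used to compare model predictions with
    the observed curves.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not isinstance(fits, Mapping):
        fits = {f.participant_id: f for f in fits}
    frames = []
    for s in sessions:
        fit = fits.get(s.participant_id)
        if fit is None:
            continue
        t = s.trials
        p = success_table.rates_for_session(s)
        ok = np.isfinite(p)
        sign = np.where(t["domain"].to_numpy() == "reward", 1.0, -1.0)
        o1 = t["success_value"].to_numpy(dtype=float)
        o2 = t["fail_value"].to_numpy(dtype=float)
        oc = t["certain_value"].to_numpy(dtype=float)
        f = gamble_prob_arrays(p[ok], o1[ok], o2[ok], oc[ok], sign[ok], fit.theta, fit.spec)
        ev_diff = p[ok] * o1[ok] + (1 - p[ok]) * o2[ok] - oc[ok]
        frames.append(
            pd.DataFrame(
                {
                    "age_group": s.age_group,
                    "domain": t["domain"].to_numpy()[ok],
                    "bin_center": assign_bin(ev_diff, bin_width),
                    "predicted": f,
                }
            )
        )
    if not frames:
        raise ValueError("no session matched a fit")
    data = pd.concat(frames, ignore_index=True)
    out = (
        data.groupby(["age_group", "domain", "bin_center"])["predicted"]
        .agg(predicted_rate="mean", n_trials="count")
        .reset_index()
    )
    return out
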