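"""Model-free behavioural statistics.

Covers four analyses: (1) the optimality discrepancy — how far observed
gamble/skip choices deviate from the expected-value-maximising choice;
(2) observed gamble-rate curves over binned expected-value differences,
with an exponential fit y = a*exp(-b*x) + c; (3) partial Spearman
correlations with age (controlling for gender/education) with BCa
bootstrap confidence intervals and permutation p-values; and (4) the
calibration error of verbal success-probability estimates from the
control study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task import ParticipantSession, SuccessRateTable


def _session_ev_diff(session: ParticipantSession, success_table: SuccessRateTable) -> np.ndarray:
    t = session.trials
    p = success_table.rates_for_session(session)
    ev_gamble = p * t["success_value"].to_numpy(dtype=float) + (1.0 - p) * t[
        "fail_value"
    ].to_numpy(dtype=float)
    return ev_gamble - t["certain_value"].to_numpy(dtype=float)


def optimality_discrepancy(
    session: ParticipantSession, success_table: SuccessRateTable
) -> tuple[float, float]:
    """Mean |choice - optimal_choice| per domain, in [0, 1].

    The optimal choice is to gamble when EV_gamble - EV_certain > 0 and to
    skip when it is < 0; trials with EV difference exactly 0 (either action
    optimal) or with unresolvable success probability are excluded. Returns
    (reward_score, punishment_score); a domain with no usable trials gets
    NaN. 0 marks an optimal decision-maker.
    """
    ev_diff = _session_ev_diff(session, success_table)
    y = session.trials["choice"].to_numpy(dtype=float)
    domain = session.trials["domain"].to_numpy()
    # |diff| below rounding noise counts as an exact EV tie and is excluded
    usable = np.isfinite(ev_diff) & np.isfinite(y) & (np.abs(ev_diff) > 1e-9)
    optimal = (ev_diff > 0).astype(float)
    scores = []
    for dom in ("reward", "punishment"):
        m = usable & (domain == dom)
        scores.append(float(np.mean(np.abs(y[m] - optimal[m]))) if m.any() else float("nan"))
    return scores[0], scores[1]


def assign_bin(ev_diff, bin_width: float = 10.0) -> np.ndarray:
    """Centre of the half-open EV-difference bin [lo, lo + width), anchored at 0."""
    ev_diff = np.asarray(ev_diff, dtype=float)
    lo = np.floor(ev_diff / bin_width) * bin_width
    return lo + bin_width / 2.0


def binned_gamble_rate(
    sessions: Iterable[ParticipantSession],
    success_table: SuccessRateTable,
    bin_width: float = 10.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed gamble proportion per (age group, domain, EV-difference bin).

    Bins are half-open [lo, lo + width) anchored at 0; rows carry the bin
    centre, the proportion, the trial count, and a bootstrap 95% CI for the
    proportion. Empty bins are simply absent.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for s in sessions:
        ev_diff = _session_ev_diff(s, success_table)
        y = s.trials["choice"].to_numpy(dtype=float)
        ok = np.isfinite(ev_diff) & np.isfinite(y)
        frames.append(
            pd.DataFrame(
                {
                    "age_group": s.age_group,
                    "domain": s.trials["domain"].to_numpy()[ok],
                    "bin_center": assign_bin(ev_diff[ok], bin_width),
                    "choice": y[ok],
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    rows = []
    for (age, dom, center), grp in data.groupby(["age_group", "domain", "bin_center"]):
        n = len(grp)
        rate = float(grp["choice"].mean())
        # bootstrap of a binary sample == binomial resampling of the mean
        boot = rng.binomial(n, rate, size=n_boot) / n
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append(
            {
                "age_group": age,
                "domain": dom,
                "bin_center": center,
                "rate": rate,
                "n": n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows).sort_values(["age_group", "domain", "bin_center"]).reset_index(
        drop=True
    )


@dataclass
class ExponentialFit:
    """Least-squares fit of y = a*exp(-b*x) + c to a binned curve."""

    a: float
    b: float
    c: float
    r_squared: float
    converged: bool


def fit_exponential(x: Sequence[float], y: Sequence[float]) -> ExponentialFit:
    """Nonlinear least squares of y = a*exp(-b*x) + c (b constrained >= 0).

    Initialised with c at the mean of the last two points, a at the
    first-point residual and b = 0.01. A flat input (zero variance in y)
    is degenerate: R2 is NaN. Non-convergence returns NaN parameters with
    ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")

    def f(x, a, b, c):
        return a * np.exp(-b * x) + c

    c0 = float(np.mean(y[-2:]))
    p0 = [float(y[0] - c0), 0.01, c0]
    try:
        popt, _ = optimize.curve_fit(
            f, x, y, p0=p0, bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return ExponentialFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    resid = y - f(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return ExponentialFit(float(popt[0]), float(popt[1]), float(popt[2]), r2, converged=True)


@dataclass
class PartialCorrResult:
    """Partial Spearman correlation with resampling-based uncertainty."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_boot: int
    n_perm: int


def _rank_residual_corr(x: np.ndarray, age: np.ndarray, z: np.ndarray | None) -> float:
    """Spearman partial correlation via residualised ranks.

    Ranks x, age and each covariate; regresses the ranks of x and of age on
    the covariate ranks (with intercept) by least squares; returns the
    Pearson correlation of the two residual vectors. With no covariates
    this reduces to the plain Spearman correlation.
    """
    rx = stats.rankdata(x)
    ra = stats.rankdata(age)
    if z is None or z.size == 0:
        ex, ea = rx - rx.mean(), ra - ra.mean()
    else:
        rz = np.column_stack([stats.rankdata(col) for col in z.T])
        design = np.column_stack([np.ones(len(rx)), rz])
        q, _ = np.linalg.qr(design)
        ex = rx - q @ (q.T @ rx)
        ea = ra - q @ (q.T @ ra)
    sx, sa = np.linalg.norm(ex), np.linalg.norm(ea)
    if sx == 0 or sa == 0:
        raise ValueError("constant variable after residualisation; correlation undefined")
    return float(ex @ ea / (sx * sa))


def partial_spearman(
    x,
    age,
    covars=None,
    n_boot: int = 10000,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PartialCorrResult:
    """Partial Spearman correlation of ``x`` with ``age`` given covariates.

    The point estimate correlates the residuals of the rank-transformed
    variables after regressing out the rank-transformed covariates. The 95%
    CI is a bias-corrected and accelerated (BCa) bootstrap over participants
    and the two-sided p-value comes from permuting the age labels, with the
    add-one correction p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    """
    x = np.asarray(x, dtype=float)
    age = np.asarray(age, dtype=float)
    if covars is None:
        z = None
    else:
        z = np.asarray(covars, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if len(z) != len(x):
            raise ValueError("covariates must have one row per observation")
    if len(x) != len(age):
        raise ValueError("x and age must have equal length")
    if n_boot < 1 or n_perm < 1:
        raise ValueError("n_boot and n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    r_obs = _rank_residual_corr(x, age, z)

    # --- permutation p-value: shuffle age labels only -----------------------
    # ranking a permuted vector permutes its ranks, so ranks are precomputed
    # and only the residualisation of the permuted age ranks is redone
    n = len(x)
    rx = stats.rankdata(x)
    ra = stats.rankdata(age)
    if z is None or z.size == 0:
        q = np.ones((n, 1)) / np.sqrt(n)  # projection onto the intercept
    else:
        rz = np.column_stack([stats.rankdata(col) for col in z.T])
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), rz]))
    ex = rx - q @ (q.T @ rx)
    ex_unit = ex / np.linalg.norm(ex)
    count = 0
    chunk = max(1, min(int(n_perm), 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, int(n_perm) - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        a_perm = ra[perms]  # (m, n)
        ea = a_perm - (a_perm @ q) @ q.T
        norms = np.linalg.norm(ea, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_perm = np.where(norms > 0, (ea @ ex_unit) / norms, 0.0)
        count += int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        done += m
    p = (1 + count) / (1 + n_perm)

    # --- BCa bootstrap CI over participants ---------------------------------
    samples = [x, age] + ([col for col in z.T] if z is not None else [])

    def statistic(*cols):
        xs, as_ = cols[0], cols[1]
        zs = np.column_stack(cols[2:]) if len(cols) > 2 else None
        try:
            return _rank_residual_corr(np.asarray(xs), np.asarray(as_), zs)
        except ValueError:
            return 0.0

    res = stats.bootstrap(
        samples,
        statistic,
        paired=True,
        vectorized=False,
        method="BCa",
        confidence_level=0.95,
        n_resamples=int(n_boot),
        rng=rng,
    )
    return PartialCorrResult(
        r=r_obs,
        ci_low=float(res.confidence_interval.low),
        ci_high=float(res.confidence_interval.high),
        p=float(p),
        n=len(x),
        n_boot=int(n_boot),
        n_perm=int(n_perm),
    )


def estimation_error(trials: Sequence[tuple[float, int]]) -> float:
    """Mean verbal-estimate error over control-study trials.

    Each trial is (estimate in percent on the 0..100 grid, motor success
    0/1); the per-trial error is estimate - 100 on successes and
    estimate - 0 on failures. Returns NaN on empty input; 0 marks perfect
    calibration on average.
    """
    if len(trials) == 0:
        return float("nan")
    est = np.asarray([t[0] for t in trials], dtype=float)
    succ = np.asarray([t[1] for t in trials], dtype=float)
    return float(np.mean(est - 100.0 * succ))
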