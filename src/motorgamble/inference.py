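"""Per-participant maximum-likelihood estimation of the choice models.

The central object is :class:`GambleChoiceModel`, a scikit-learn style
estimator over a fixed 5-column offer matrix. Each row is one trial::

    [p_success, o_success, o_fail, o_certain, domain_sign]

with ``domain_sign`` +1 on reward trials and -1 on punishment trials, and
the target ``y`` the observed choice (1 = gamble, 0 = skip). Fitting
maximises the Bernoulli log-likelihood

    L = sum_i  y_i ln F_i + (1 - y_i) ln(1 - F_i)

over the bounded parameter box by multi-start local optimisation
(L-BFGS-B from uniform-random starting points). Because the clamped
approach-avoidance choice rule can reach F of exactly 0 or 1, F is clamped
into [eps, 1 - eps] inside the logarithms only.

``fit_mle`` / ``log_likelihood`` / ``grid_oracle`` are thin functional
wrappers that work directly on :class:`~motorgamble.task.ParticipantSession`
objects plus a success-rate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .models import ModelSpec, ParameterVector, gamble_prob_arrays
from .selection import aic as _aic, bic as _bic, pseudo_r2 as _pseudo_r2
from .task import ParticipantSession, SuccessRateTable

#: clamp applied to F inside the logarithms only
LOG_EPS = 1e-9

#: default number of random restarts used by the functional wrapper
#: (matches the study protocol; the estimator default is smaller for speed)
DEFAULT_RESTARTS = 200

OFFER_COLUMNS = ["p", "o_success", "o_fail", "o_certain", "domain_sign"]


def session_design(
    session: ParticipantSession, success_table: SuccessRateTable
) -> tuple[np.ndarray, np.ndarray, int]:
    """Build (X, y, n_dropped) for a session.

    Trials whose success probability cannot be resolved from the table are
    excluded and counted in ``n_dropped``; trials without a recorded choice
    are likewise excluded.
    """
    t = session.trials
    p = success_table.rates_for_session(session)
    sign = np.where(t["domain"].to_numpy() == "reward", 1.0, -1.0)
    o1 = t["success_value"].to_numpy(dtype=float)
    o2 = t["fail_value"].to_numpy(dtype=float)
    oc = t["certain_value"].to_numpy(dtype=float)
    y = t["choice"].to_numpy(dtype=float)
    ok = np.isfinite(p) & np.isfinite(y)
    n_dropped = int(np.sum(np.isfinite(y) & ~np.isfinite(p)))
    if not ok.any():
        raise ValueError(
            f"session {session.participant_id}: no trial has a resolvable "
            "success probability"
        )
    X = np.column_stack([p[ok], o1[ok], o2[ok], oc[ok], sign[ok]])
    return X, y[ok].astype(int), n_dropped


def _split_X(X: np.ndarray):
    return X[:, 0], X[:, 1], X[:, 2], X[:, 3], X[:, 4]


def _validate_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValueError(
            "X must be (n_trials, 5): [p, o_success, o_fail, o_certain, domain_sign]"
        )
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    p = X[:, 0]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("success probabilities must lie in [0, 1]")
    if not np.isin(X[:, 4], (-1.0, 1.0)).all():
        raise ValueError("domain_sign must be +1 (reward) or -1 (punishment)")
    return X


def _bernoulli_loglik(f: np.ndarray, y: np.ndarray, eps: float = LOG_EPS) -> float:
    fc = np.clip(f, eps, 1.0 - eps)
    return float(np.sum(y * np.log(fc) + (1.0 - y) * np.log(1.0 - fc)))


def _make_nll(spec: ModelSpec, p, o1, o2, oc, sign, y, eps: float):
    """Negative log-likelihood closure over raw parameter arrays.

    Equivalent to evaluating :func:`~motorgamble.models.gamble_prob_arrays`
    through a ParameterVector, but without per-call dataclass construction —
    this is the optimiser's hot path.
    """
    names = spec.param_names
    idx = {n: i for i, n in enumerate(names)}
    pos = np.asarray(sign) > 0

    def pick(base: str):
        if f"{base}_plus" in idx:
            return idx[f"{base}_plus"], idx[f"{base}_minus"]
        return idx[base], idx[base]

    ia_p, ia_m = pick("alpha")
    im_p, im_m = pick("mu")
    abs_o1, abs_o2, abs_oc = np.abs(o1), np.abs(o2), np.abs(oc)
    s1, s2, sc = np.sign(o1), np.sign(o2), np.sign(oc)
    if spec.delta_mode == "split":
        id_p, id_m = idx["delta_plus"], idx["delta_minus"]
    elif spec.delta_mode == "joint":
        id_p = id_m = idx["delta"]
    weighted = spec.weighting == "weighted"
    neg_log_p = None
    if weighted:
        with np.errstate(divide="ignore"):
            neg_log_p = -np.log(np.maximum(p, 1e-300))
    y = np.asarray(y, dtype=float)

    def nll(x: np.ndarray) -> float:
        alpha = np.where(pos, x[ia_p], x[ia_m])
        mu = np.where(pos, x[im_p], x[im_m])
        v1 = s1 * abs_o1**alpha
        v2 = s2 * abs_o2**alpha
        vc = sc * abs_oc**alpha
        if weighted:
            wp = np.where(p > 0, np.exp(-(neg_log_p ** x[idx["gamma"]])), 0.0)
        else:
            wp = p
        with np.errstate(over="ignore"):
            f = 1.0 / (1.0 + np.exp(-mu * (wp * v1 + (1.0 - wp) * v2 - vc)))
        if spec.delta_mode != "none":
            f = np.clip(f + np.where(pos, x[id_p], x[id_m]), 0.0, 1.0)
        fc = np.clip(f, eps, 1.0 - eps)
        return -float(np.sum(y * np.log(fc) + (1.0 - y) * np.log(1.0 - fc)))

    return nll


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one participant."""

    spec: ModelSpec
    theta: ParameterVector
    log_likelihood: float
    n_trials: int
    n_dropped: int
    aic: float
    bic: float
    pseudo_r2: float
    n_restarts: int
    best_restart: int
    converged: bool
    participant_id: str | None = None

    def as_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "spec": self.spec.code,
            "k": self.spec.k,
            "n": self.n_trials,
            "n_dropped": self.n_dropped,
            "logL": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
        }
        row.update(self.theta.as_dict())
        return row


class GambleChoiceModel(BaseEstimator):
    """Scikit-learn style estimator for one choice-model variant.

    Parameters
    ----------
    spec : str or ModelSpec, default 'a1m1d2w0'
        Which member of the 24-model family to fit (the default is the
        winning approach-avoidance variant [alpha, mu, delta+, delta-]).
    n_restarts : int, default 20
        Number of uniform-random starting points for the bounded local
        optimiser; the best restart is kept.
    random_state : int or numpy Generator, optional
        Seeds the restart locations; fits are deterministic given it.
    eps : float, default 1e-9
        Clamp applied to predicted probabilities inside the log-likelihood.

    Attributes
    ----------
    theta_ : ParameterVector
        Maximum-likelihood parameters.
    log_likelihood_, aic_, bic_, pseudo_r2_ : float
        Fit quality; the pseudo-R2 null model predicts F = 0.5 everywhere.
    converged_ : bool
        Whether any restart reported optimiser convergence.
    """

    def __init__(self, spec="a1m1d2w0", n_restarts: int = 20, random_state=None,
                 eps: float = LOG_EPS):
        self.spec = spec
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.eps = eps

    def _resolved_spec(self) -> ModelSpec:
        return self.spec if isinstance(self.spec, ModelSpec) else ModelSpec.from_code(self.spec)

    def fit(self, X, y):
        X = _validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be one choice per trial")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("choices must be 0 (skip) or 1 (gamble)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        spec = self._resolved_spec()
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        p, o1, o2, oc, sign = _split_X(X)
        bounds = spec.bounds
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        nll = _make_nll(spec, p, o1, o2, oc, sign, y, self.eps)

        best_fun, best_x, best_restart, converged = np.inf, None, -1, False
        for r in range(int(self.n_restarts)):
            x0 = rng.uniform(lo, hi)
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            fun, x = (res.fun, res.x) if np.isfinite(res.fun) else (nll(x0), x0)
            converged = converged or bool(res.success)
            if fun < best_fun:
                best_fun, best_x, best_restart = fun, x, r

        self.spec_ = spec
        self.theta_ = ParameterVector.from_array(spec, np.clip(best_x, lo, hi))
        self.log_likelihood_ = -best_fun
        self.n_trials_ = int(X.shape[0])
        self.aic_ = _aic(self.log_likelihood_, spec.k)
        self.bic_ = _bic(self.log_likelihood_, spec.k, self.n_trials_)
        self.pseudo_r2_ = _pseudo_r2(self.log_likelihood_, self.n_trials_)
        self.best_restart_ = int(best_restart)
        self.converged_ = converged
        self.n_features_in_ = 5
        return self

    def predict_proba(self, X):
        """Probability of [skip, gamble] for each trial."""
        check_is_fitted(self, "theta_")
        X = _validate_X(X)
        p, o1, o2, oc, sign = _split_X(X)
        f = gamble_prob_arrays(p, o1, o2, oc, sign, self.theta_, self.spec_)
        return np.column_stack([1.0 - f, f])

    def predict(self, X):
        """Most likely choice (1 = gamble) for each trial."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        """Mean per-trial log-likelihood of the observed choices."""
        check_is_fitted(self, "theta_")
        X = _validate_X(X)
        y = np.asarray(y, dtype=float)
        f = self.predict_proba(X)[:, 1]
        return _bernoulli_loglik(f, y, self.eps) / len(y)

    def to_result(self, n_dropped: int = 0, participant_id: str | None = None) -> FitResult:
        check_is_fitted(self, "theta_")
        return FitResult(
            spec=self.spec_,
            theta=self.theta_,
            log_likelihood=self.log_likelihood_,
            n_trials=self.n_trials_,
            n_dropped=n_dropped,
            aic=self.aic_,
            bic=self.bic_,
            pseudo_r2=self.pseudo_r2_,
            n_restarts=int(self.n_restarts),
            best_restart=self.best_restart_,
            converged=self.converged_,
            participant_id=participant_id,
        )


def log_likelihood(
    theta: ParameterVector,
    spec: ModelSpec,
    session: ParticipantSession,
    success_table: SuccessRateTable,
    eps: float = LOG_EPS,
) -> float:
    """Choice log-likelihood of ``theta`` for one session.

    Trials with unresolvable success probability are excluded (their count
    is available through :func:`session_design`).
    """
    X, y, _ = session_design(session, success_table)
    p, o1, o2, oc, sign = _split_X(X)
    f = gamble_prob_arrays(p, o1, o2, oc, sign, theta, spec)
    return _bernoulli_loglik(f, y, eps)


def participant_seed(seed: int, participant_id: str) -> np.random.Generator:
    """Deterministic per-participant RNG stream derived from (seed, id)."""
    ss = np.random.SeedSequence([seed, *participant_id.encode()])
    return np.random.default_rng(ss)


def fit_mle(
    session: ParticipantSession,
    spec: ModelSpec,
    success_table: SuccessRateTable,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> FitResult:
    """Multi-start bounded MLE for one session; deterministic given ``seed``.

    The restart stream is derived from (seed, participant_id) so cohorts can
    be fitted in any order or in parallel with identical results.
    """
    X, y, n_dropped = session_design(session, success_table)
    est = GambleChoiceModel(
        spec=spec,
        n_restarts=n_restarts,
        random_state=participant_seed(seed, session.participant_id),
    )
    est.fit(X, y)
    return est.to_result(n_dropped=n_dropped, participant_id=session.participant_id)


MAX_GRID_EVALS = int(1e7)


def grid_oracle(
    session: ParticipantSession,
    spec: ModelSpec,
    success_table: SuccessRateTable,
    grid_step: float = 0.05,
    chunk: int = 20000,
) -> ParameterVector:
    """Exhaustive grid search over the bounded parameter box.

    ``grid_step`` is the spacing on each parameter rescaled to [0, 1], so a
    step of 0.05 places 21 points along every dimension regardless of its
    natural range. Intended as an independent check on :func:`fit_mle`, not
    as a fitting routine; more than 4 free parameters or ~1e7 grid points
    is rejected as misuse.
    """
    if spec.k > 4:
        raise ValueError("grid oracle supports at most 4 free parameters")
    if not 0 < grid_step <= 1:
        raise ValueError("grid_step must be in (0, 1]")
    n_pts = int(np.floor(1.0 / grid_step)) + 1
    if n_pts**spec.k > MAX_GRID_EVALS:
        raise ValueError("grid too dense; reduce grid_step")
    axes = [np.linspace(lo, hi, n_pts) for lo, hi in spec.bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([m.ravel() for m in mesh])  # (m, k)

    X, y, _ = session_design(session, success_table)
    p, o1, o2, oc, sign = _split_X(X)
    best_ll, best_x = -np.inf, grid[0]
    for start in range(0, len(grid), chunk):
        block = grid[start : start + chunk]
        ll = _grid_loglik_block(block, spec, p, o1, o2, oc, sign, y)
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best_x = float(ll[i]), block[i]
    return ParameterVector.from_array(spec, best_x)


def _grid_loglik_block(block, spec, p, o1, o2, oc, sign, y):
    """Log-likelihood of every candidate row in ``block``, vectorised over trials."""
    names = spec.param_names
    cols = {n: block[:, i][:, None] for i, n in enumerate(names)}  # (m, 1)
    pos = sign > 0  # (n,)

    def dom(base):
        if f"{base}_plus" in cols:
            return np.where(pos, cols[f"{base}_plus"], cols[f"{base}_minus"])
        return cols[base]

    alpha, mu = dom("alpha"), dom("mu")
    v1 = np.where(o1 >= 0, np.abs(o1) ** alpha, -np.abs(o1) ** alpha)
    v2 = np.where(o2 >= 0, np.abs(o2) ** alpha, -np.abs(o2) ** alpha)
    vc = np.where(oc >= 0, np.abs(oc) ** alpha, -np.abs(oc) ** alpha)
    if spec.weighting == "weighted":
        with np.errstate(divide="ignore"):
            wp = np.where(p > 0, np.exp(-((-np.log(np.maximum(p, 1e-300))) ** cols["gamma"])), 0.0)
    else:
        wp = p
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(-mu * (wp * v1 + (1.0 - wp) * v2 - vc)))
    if spec.delta_mode == "joint":
        f = np.clip(f + cols["delta"], 0.0, 1.0)
    elif spec.delta_mode == "split":
        f = np.clip(f + np.where(pos, cols["delta_plus"], cols["delta_minus"]), 0.0, 1.0)
    fc = np.clip(f, LOG_EPS, 1.0 - LOG_EPS)
    return np.sum(y * np.log(fc) + (1.0 - y) * np.log(1.0 - fc), axis=1)
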