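"""Prospect-theory and approach-avoidance choice models.

The family has four factors, fully crossed into 24 variants:

* risk preference ``alpha`` — joint, or separate for reward/punishment;
* softmax inverse temperature ``mu`` — joint or separate;
* Pavlovian offset ``delta`` — absent (pure prospect theory), joint, or
  separate for reward (approach) and punishment (avoidance);
* probability treatment — linear (w(p) = p) or the one-parameter
  weighting w(p) = exp(-(-ln p)^gamma).

Subjective value follows the two-part power law v(O) = O^alpha for gains
and -lambda * (-O)^alpha for losses, with the loss-aversion coefficient
lambda fixed at 1 (the task never mixes gains and losses in one gamble).
The gamble probability is the softmax of the utility difference; in the
approach-avoidance variants a value-independent offset delta is added
*after* the softmax and the result clamped to [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy.special import expit

from .task import GambleOffer

ALPHA_BOUNDS = (0.0, 1.0)
#: mu's interval is open at 0; the implementation lower bound is 1e-6.
MU_BOUNDS = (1e-6, 10.0)
DELTA_BOUNDS = (-1.0, 1.0)
GAMMA_BOUNDS = (1e-6, 5.0)
LAMBDA_FIXED = 1.0

_BOUNDS_BY_KIND = {
    "alpha": ALPHA_BOUNDS,
    "mu": MU_BOUNDS,
    "delta": DELTA_BOUNDS,
    "gamma": GAMMA_BOUNDS,
}


def _kind(name: str) -> str:
    return name.split("_")[0]


def param_bounds(name: str) -> tuple[float, float]:
    """Bounds of a parameter by name (split variants share the base bounds)."""
    return _BOUNDS_BY_KIND[_kind(name)]


@dataclass(frozen=True)
class ModelSpec:
    """One member of the 24-model family."""

    alpha_split: bool = False
    mu_split: bool = False
    delta_mode: Literal["none", "joint", "split"] = "none"
    weighting: Literal["linear", "weighted"] = "linear"

    def __post_init__(self) -> None:
        if self.delta_mode not in ("none", "joint", "split"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")
        if self.weighting not in ("linear", "weighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        names += ["alpha_plus", "alpha_minus"] if self.alpha_split else ["alpha"]
        names += ["mu_plus", "mu_minus"] if self.mu_split else ["mu"]
        if self.delta_mode == "joint":
            names += ["delta"]
        elif self.delta_mode == "split":
            names += ["delta_plus", "delta_minus"]
        if self.weighting == "weighted":
            names += ["gamma"]
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [_BOUNDS_BY_KIND[_kind(n)] for n in self.param_names]

    @property
    def code(self) -> str:
        """Short string code, e.g. 'a1m1d2w0' for [alpha, mu, delta+, delta-]."""
        d = {"none": 0, "joint": 1, "split": 2}[self.delta_mode]
        w = {"linear": 0, "weighted": 1}[self.weighting]
        return f"a{2 if self.alpha_split else 1}m{2 if self.mu_split else 1}d{d}w{w}"

    @classmethod
    def from_code(cls, code: str) -> "ModelSpec":
        m = re.fullmatch(r"a([12])m([12])d([012])w([01])", code)
        if not m:
            raise ValueError(f"malformed model code {code!r}")
        a, mu, d, w = (int(g) for g in m.groups())
        return cls(
            alpha_split=a == 2,
            mu_split=mu == 2,
            delta_mode=("none", "joint", "split")[d],
            weighting=("linear", "weighted")[w],
        )

    def __str__(self) -> str:  # human-readable parameter list
        pretty = {
            "alpha": "α", "alpha_plus": "α+", "alpha_minus": "α−",
            "mu": "μ", "mu_plus": "μ+", "mu_minus": "μ−",
            "delta": "δ", "delta_plus": "δ+", "delta_minus": "δ−",
            "gamma": "γ",
        }
        return "[" + ", ".join(pretty[n] for n in self.param_names) + "]"


#: The winning prospect-theory variant: separate alpha and mu, no delta, linear.
PT_WINNER = ModelSpec(alpha_split=True, mu_split=True, delta_mode="none", weighting="linear")
#: The overall winning approach-avoidance variant: joint alpha and mu, split delta, linear.
AA_WINNER = ModelSpec(alpha_split=False, mu_split=False, delta_mode="split", weighting="linear")


def enumerate_models() -> tuple[ModelSpec, ...]:
    """All 24 model variants in a stable order.

    Ordered by delta mode (none, joint, split), then weighting (linear,
    weighted), then alpha/mu splitting. Prospect-theory variants therefore
    come first and approach-avoidance variants after.
    """
    specs = []
    for delta_mode in ("none", "joint", "split"):
        for weighting in ("linear", "weighted"):
            for alpha_split in (False, True):
                for mu_split in (False, True):
                    specs.append(
                        ModelSpec(
                            alpha_split=alpha_split,
                            mu_split=mu_split,
                            delta_mode=delta_mode,
                            weighting=weighting,
                        )
                    )
    return tuple(specs)


@dataclass(frozen=True)
class ParameterVector:
    """Parameter values for some ModelSpec; absent parameters are None.

    Joint parameters are stored under the plain name (``alpha``); split
    variants under ``*_plus`` (reward domain) and ``*_minus`` (punishment).
    The loss-aversion coefficient ``lam`` is fixed at 1.
    """

    alpha: float | None = None
    alpha_plus: float | None = None
    alpha_minus: float | None = None
    mu: float | None = None
    mu_plus: float | None = None
    mu_minus: float | None = None
    delta: float | None = None
    delta_plus: float | None = None
    delta_minus: float | None = None
    gamma: float | None = None
    lam: float = LAMBDA_FIXED

    def __post_init__(self) -> None:
        if self.lam != LAMBDA_FIXED:
            raise ValueError("loss aversion lambda is fixed at 1")
        for name in (
            "alpha", "alpha_plus", "alpha_minus",
            "mu", "mu_plus", "mu_minus",
            "delta", "delta_plus", "delta_minus",
            "gamma",
        ):
            v = getattr(self, name)
            if v is None:
                continue
            lo, hi = _BOUNDS_BY_KIND[_kind(name)]
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def for_domain(self, sign: int) -> tuple[float, float, float | None, float | None]:
        """(alpha, mu, delta, gamma) effective on a reward (+1) or punishment (-1) trial.

        Split parameters take precedence over joint ones when both are set.
        """
        suffix = "plus" if sign > 0 else "minus"

        def pick(base: str) -> float | None:
            split = getattr(self, f"{base}_{suffix}")
            return split if split is not None else getattr(self, base)

        alpha, mu = pick("alpha"), pick("mu")
        if alpha is None or mu is None:
            raise ValueError("alpha and mu must be set for both domains")
        return alpha, mu, pick("delta"), self.gamma

    def to_array(self, spec: ModelSpec) -> np.ndarray:
        vals = []
        for name in spec.param_names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"parameter {name} required by {spec.code} is unset")
            vals.append(v)
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, spec: ModelSpec, x: Iterable[float]) -> "ParameterVector":
        x = np.asarray(list(x), dtype=float)
        if x.shape != (spec.k,):
            raise ValueError(f"expected {spec.k} values for {spec.code}, got {x.shape}")
        return cls(**dict(zip(spec.param_names, (float(v) for v in x))))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ParameterVector":
        return cls(**{k: float(v) for k, v in mapping.items()})

    def as_dict(self) -> dict[str, float]:
        out = {}
        for name in (
            "alpha", "alpha_plus", "alpha_minus",
            "mu", "mu_plus", "mu_minus",
            "delta", "delta_plus", "delta_minus",
            "gamma",
        ):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


def value_fn(o, alpha: float, lam: float = LAMBDA_FIXED):
    """Two-part power value function: O^alpha for gains, -lam*(-O)^alpha for losses."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    o = np.asarray(o, dtype=float)
    v = np.where(o >= 0, np.abs(o) ** alpha, -lam * np.abs(o) ** alpha)
    return float(v) if v.ndim == 0 else v


def weight_prob(p, gamma: float | None = None):
    """Probability weighting w(p) = exp(-(-ln p)^gamma); identity when gamma is None.

    w(0) = 0 by continuity and w(1) = 1 exactly.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if gamma is None:
        out = p.copy()
    else:
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        with np.errstate(divide="ignore"):
            out = np.where(p > 0, np.exp(-((-np.log(np.maximum(p, 1e-300))) ** gamma)), 0.0)
    return float(out) if out.ndim == 0 else out


def gamble_utilities(
    p, o1, o2, oc, alpha, gamma=None, lam: float = LAMBDA_FIXED
) -> tuple[np.ndarray, np.ndarray]:
    """Utility of the gamble, w(p)*v(O1) + (1-w(p))*v(O2), and of the certain option."""
    wp = weight_prob(p, gamma)
    u_gamble = wp * value_fn(o1, alpha, lam) + (1.0 - wp) * value_fn(o2, alpha, lam)
    u_certain = value_fn(oc, alpha, lam)
    return u_gamble, u_certain


def gamble_prob_arrays(
    p: np.ndarray,
    o1: np.ndarray,
    o2: np.ndarray,
    oc: np.ndarray,
    sign: np.ndarray,
    theta: ParameterVector,
    spec: ModelSpec,
) -> np.ndarray:
    """Vectorised gamble probability over trials.

    ``sign`` is +1 for reward trials and -1 for punishment trials and
    selects the domain-specific parameters in split models. The Pavlovian
    offset, where present, is added after the softmax and the result
    clamped to [0, 1] — never the offset itself.
    """
    a_p, m_p, d_p, g = theta.for_domain(+1)
    a_m, m_m, d_m, _ = theta.for_domain(-1)
    pos = np.asarray(sign) > 0
    alpha = np.where(pos, a_p, a_m)
    mu = np.where(pos, m_p, m_m)
    gamma = g if spec.weighting == "weighted" else None

    # value function with per-trial alpha
    o1 = np.asarray(o1, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    oc = np.asarray(oc, dtype=float)
    v1 = np.where(o1 >= 0, np.abs(o1) ** alpha, -np.abs(o1) ** alpha)
    v2 = np.where(o2 >= 0, np.abs(o2) ** alpha, -np.abs(o2) ** alpha)
    vc = np.where(oc >= 0, np.abs(oc) ** alpha, -np.abs(oc) ** alpha)
    wp = weight_prob(p, gamma)
    f = expit(mu * (wp * v1 + (1.0 - wp) * v2 - vc))
    if spec.delta_mode != "none":
        if d_p is None or d_m is None:
            raise ValueError(f"spec {spec.code} requires delta parameters")
        f = np.clip(f + np.where(pos, d_p, d_m), 0.0, 1.0)
    return f


def gamble_prob(
    offer: GambleOffer,
    theta: ParameterVector,
    spec: ModelSpec,
    domain: str | None = None,
) -> float:
    """Probability of choosing the gamble for one offer.

    ``domain`` selects the reward/punishment parameters in split models; if
    omitted it is inferred from the sign of the certain payoff.
    """
    if domain is None:
        domain = "reward" if offer.o_certain >= 0 else "punishment"
    sign = np.array([1 if domain == "reward" else -1])
    f = gamble_prob_arrays(
        np.array([offer.p_success]),
        np.array([offer.o_success]),
        np.array([offer.o_fail]),
        np.array([offer.o_certain]),
        sign,
        theta,
        spec,
    )
    return float(f[0])
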