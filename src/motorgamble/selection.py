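"""Model comparison: information criteria, pseudo-R2, winner tallies, LR tests.

Model comparison is subject-level: every participant is fitted under every
candidate model, criteria are summed over participants, and the winning
model (smallest summed BIC) is additionally compared against each
alternative by the percentage of participants it fits better and by paired
two-sided t-tests on the per-subject criterion values with Bonferroni
correction over the alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelSpec

LN_HALF = math.log(0.5)


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion: -2 logL + 2k."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return -2.0 * log_likelihood + 2.0 * k


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2 logL + k ln N."""
    if k < 0 or n < 1:
        raise ValueError("require k >= 0 and N >= 1")
    return -2.0 * log_likelihood + k * math.log(n)


def null_log_likelihood(n: int) -> float:
    """Log-likelihood of the null model (alpha = mu = delta = 0 => F = 0.5)."""
    return n * LN_HALF


def pseudo_r2(log_likelihood: float, n: int) -> float:
    """McFadden-style pseudo-R2 against the chance (F = 0.5) null model."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return 1.0 - log_likelihood / null_log_likelihood(n)


def lr_test(logL_null: float, logL_alt: float, df: int, tol: float = 1e-3) -> float:
    """Likelihood-ratio test of nested fits; upper-tail chi-square p-value.

    A slightly negative statistic (optimiser noise up to ``tol``) is clipped
    to 0; anything more negative indicates the models were not nested (or a
    failed fit) and is rejected.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (logL_alt - logL_null)
    if stat < -tol:
        raise ValueError(
            f"alternative log-likelihood below null by {-stat / 2:.4g}; models "
            "not nested or fit failed"
        )
    return float(stats.chi2.sf(max(stat, 0.0), df))


def fits_to_frame(fits: Iterable) -> pd.DataFrame:
    """Tidy (participant x model) table from FitResult objects."""
    rows = [f.as_row() for f in fits]
    return pd.DataFrame(rows)


def _tie_break_order(codes: Iterable[str]) -> list[str]:
    """Stable order for criterion ties: smaller k first, then code."""
    return sorted(codes, key=lambda c: (ModelSpec.from_code(c).k, c))


@dataclass
class ComparisonReport:
    """Cohort-level model comparison."""

    summed: pd.DataFrame  # index spec code; columns aic, bic, k
    winner_bic: str
    winner_aic: str
    winners: pd.DataFrame  # per alternative: % participants won, adjusted p-values
    n_participants: int
    lr_tallies: dict[str, int] | None = None

    def to_json_dict(self) -> dict:
        return {
            "winner_bic": self.winner_bic,
            "winner_aic": self.winner_aic,
            "n_participants": self.n_participants,
            "summed_bic": self.summed["bic"].to_dict(),
            "summed_aic": self.summed["aic"].to_dict(),
            "lr_tallies": self.lr_tallies,
        }


def compare_models(fits: pd.DataFrame | Iterable) -> ComparisonReport:
    """Identify the winning model and tally subject-level evidence.

    ``fits`` is either a tidy DataFrame (columns participant_id, spec, k,
    logL, aic, bic) or an iterable of FitResult. Participants missing a fit
    under some model are excluded pairwise from that comparison with a
    warning. Winner percentages treat exact criterion ties as half a win
    for each side.
    """
    df = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    required = {"participant_id", "spec", "aic", "bic"}
    if not required.issubset(df.columns):
        raise ValueError(f"fits table needs columns {sorted(required)}")

    bic_w = df.pivot_table(index="participant_id", columns="spec", values="bic")
    aic_w = df.pivot_table(index="participant_id", columns="spec", values="aic")
    if bic_w.isna().any().any():
        import warnings

        n_missing = int(bic_w.isna().sum().sum())
        warnings.warn(f"{n_missing} missing (participant, model) fits excluded pairwise")

    summed = pd.DataFrame(
        {
            "aic": aic_w.sum(axis=0, skipna=True),
            "bic": bic_w.sum(axis=0, skipna=True),
            "k": [ModelSpec.from_code(c).k for c in bic_w.columns],
        }
    )

    def winner(col: str) -> str:
        best = summed[col].min()
        tied = summed.index[np.isclose(summed[col], best)]
        return _tie_break_order(tied)[0]

    winner_bic, winner_aic = winner("bic"), winner("aic")

    rows = []
    alternatives = [c for c in bic_w.columns if c != winner_bic]
    n_alt = max(len(alternatives), 1)
    for alt in alternatives:
        rec: dict = {"spec": alt}
        for name, wide, win in (("bic", bic_w, winner_bic), ("aic", aic_w, winner_aic)):
            if alt == win:
                rec[f"pct_winner_{name}"] = 50.0
                rec[f"p_{name}"] = 1.0
                continue
            pair = wide[[win, alt]].dropna()
            diff = pair[win] - pair[alt]
            wins = float(np.sum(diff < 0) + 0.5 * np.sum(diff == 0))
            rec[f"pct_winner_{name}"] = 100.0 * wins / len(pair) if len(pair) else np.nan
            if len(pair) > 1 and np.ptp(diff) > 0:
                p = stats.ttest_rel(pair[win], pair[alt]).pvalue
            else:
                p = 1.0
            rec[f"p_{name}"] = min(1.0, float(p) * n_alt)  # Bonferroni
        rows.append(rec)
    winners = pd.DataFrame(rows).set_index("spec") if rows else pd.DataFrame()

    return ComparisonReport(
        summed=summed.sort_values("bic"),
        winner_bic=winner_bic,
        winner_aic=winner_aic,
        winners=winners,
        n_participants=int(bic_w.shape[0]),
    )


#: The three joint-vs-separate likelihood-ratio contrasts (df = 1 each):
#: split delta on top of the joint-delta base, then split alpha and split mu
#: on top of the winning split-delta model.
LR_CONTRASTS = {
    "delta": ("a1m1d1w0", "a1m1d2w0"),
    "alpha": ("a1m1d2w0", "a2m1d2w0"),
    "mu": ("a1m1d2w0", "a1m2d2w0"),
}


def lr_split_counts(
    fits: pd.DataFrame, alpha_level: float = 0.05
) -> dict[str, int]:
    """Per-individual LR tests of separate vs joint parameters.

    For each contrast in :data:`LR_CONTRASTS`, counts the participants for
    whom the separate-parameter model significantly improves on the joint
    one (p < ``alpha_level``, df = 1). The winning model here is the split
    model of the delta contrast; negative statistics within optimiser
    tolerance count as non-significant.
    """
    ll = fits.pivot_table(index="participant_id", columns="spec", values="logL")
    out: dict[str, int] = {}
    for name, (null_code, alt_code) in LR_CONTRASTS.items():
        if null_code not in ll.columns or alt_code not in ll.columns:
            continue
        pair = ll[[null_code, alt_code]].dropna()
        stat = 2.0 * (pair[alt_code] - pair[null_code]).clip(lower=0.0)
        pvals = stats.chi2.sf(stat, df=1)
        out[name] = int(np.sum(pvals < alpha_level))
    return out
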