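"""Inference helpers: frequency-by-boundary regression and Beta intervals.

The segmentation-decision regression models correctness as
``correct ~ log(freq) * bound``, where ``bound`` indicates whether a
word boundary is truly present at the gap and ``log(freq)`` is the
natural log of the governing word's token frequency.  With only a
handful of simulated participants, the maximal crossed random-effects
structure is deliberately replaced by participant fixed effects in the
pooled fit plus fully independent per-participant fits; significance
uses the z-approximation.  Both a logistic family (natural for the
binary outcome) and a linear-probability family are offered.

Binomial uncertainty intervals are equal-tailed Beta posteriors with a
non-informative prior — Jeffreys (1/2, 1/2) by default, uniform (1, 1)
by option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .segeval import LocationDecision

__all__ = [
    "BetaInterval",
    "FreqBoundModel",
    "beta_binomial_interval",
    "fit_freq_bound_model",
    "moving_average_smoother",
]

JEFFREYS = (0.5, 0.5)
UNIFORM = (1.0, 1.0)


@dataclass(frozen=True)
class BetaInterval:
    successes: int
    trials: int
    prior: tuple[float, float]
    low: float
    high: float
    prior_only: bool = False  # True when trials == 0


def beta_binomial_interval(successes: int, trials: int,
                           prior: tuple[float, float] = JEFFREYS,
                           level: float = 0.95) -> BetaInterval:
    """Equal-tailed Beta-posterior interval for a binomial proportion.

    The posterior is Beta(successes + a, trials - successes + b); the
    interval is its (1-level)/2 and 1-(1-level)/2 quantiles, strictly
    inside (0, 1) even at 0 or n successes.  With zero trials the
    interval is the prior's own quantiles, flagged ``prior_only``.
    """
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    a, b = prior
    post = scipy.stats.beta(successes + a, trials - successes + b)
    alpha = (1.0 - level) / 2.0
    low, high = post.ppf(alpha), post.ppf(1.0 - alpha)
    return BetaInterval(successes=successes, trials=trials, prior=prior,
                        low=float(low), high=float(high),
                        prior_only=(trials == 0))


@dataclass(frozen=True)
class FreqBoundModel:
    """Pooled and per-participant fits of correct ~ log(freq) * bound."""

    family: str
    pooled: pd.DataFrame                      # coef, se, z, p per term
    per_participant: dict[str, pd.DataFrame]
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.pooled.loc[term, "coef"])

    def z(self, term: str) -> float:
        return float(self.pooled.loc[term, "z"])

    def p_value(self, term: str) -> float:
        return float(self.pooled.loc[term, "p"])


def _decisions_frame(decisions, participant: str) -> pd.DataFrame:
    return pd.DataFrame({
        "correct": [int(d.correct) for d in decisions],
        "log_freq": [d.log_freq for d in decisions],
        "bound": [int(d.is_boundary) for d in decisions],
        "participant": participant,
    })


def _summary_table(fit) -> pd.DataFrame:
    return pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "z": fit.params / fit.bse,
        "p": 2 * scipy.stats.norm.sf(np.abs(fit.params / fit.bse)),
    })


def _fit_formula(df: pd.DataFrame, formula: str, family: str):
    if family == "logistic":
        return smf.glm(formula, data=df, family=sm.families.Binomial()).fit()
    return smf.ols(formula, data=df).fit()


def fit_freq_bound_model(
    decisions_by_participant: dict[str, list[LocationDecision]],
    family: str = "logistic",
) -> FreqBoundModel:
    """Fit the frequency-by-boundary decision model.

    Parameters
    ----------
    decisions_by_participant
        Mapping of participant id to that participant's location
        decisions (one per gap, from ``classify_locations``).
    family
        ``"logistic"`` (default) or ``"linear"`` (linear-probability).

    The pooled fit is ``correct ~ log_freq * bound`` plus participant
    fixed effects (when more than one participant is present); each
    participant also receives an independent fit of the same two-factor
    model.  Coefficient z statistics and two-sided z-approximation
    p-values are reported.
    """
    if family not in ("logistic", "linear"):
        raise ValueError(f"unknown family {family!r}")
    if not decisions_by_participant:
        raise ValueError("need decisions from at least one participant")
    frames = [
        _decisions_frame(decs, pid)
        for pid, decs in decisions_by_participant.items()
    ]
    df = pd.concat(frames, ignore_index=True)
    if df.bound.nunique() < 2:
        raise ValueError("need both boundary and word-internal gaps")
    if df.log_freq.nunique() < 2:
        raise ValueError("singular design: only one frequency value present")

    formula = "correct ~ log_freq * bound"
    pooled_formula = formula
    if df.participant.nunique() > 1:
        pooled_formula += " + C(participant)"
    pooled = _summary_table(_fit_formula(df, pooled_formula, family))

    per = {}
    for pid, grp in df.groupby("participant", sort=True):
        per[str(pid)] = _summary_table(_fit_formula(grp, formula, family))
    return FreqBoundModel(family=family, pooled=pooled, per_participant=per,
                          n_obs=len(df))


def moving_average_smoother(x: np.ndarray, y: np.ndarray,
                            window: float = 1.0,
                            grid: np.ndarray | None = None) -> pd.DataFrame:
    """Windowed moving average of y over x (plot aid for binned accuracy).

    For each grid point g the smoothed value is the mean of y over
    points with |x - g| <= window / 2; empty windows yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    half = window / 2.0
    smoothed = np.array([
        y[np.abs(x - g) <= half].mean() if np.any(np.abs(x - g) <= half) else np.nan
        for g in grid
    ])
    return pd.DataFrame({"x": grid, "y_smooth": smoothed})
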