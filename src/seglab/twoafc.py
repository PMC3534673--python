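"""Two-alternative forced choice: trial construction, scoring, half-logit fits.

The long-term retention test pairs each target word (from the trained
language) with a distractor from a *different* language's lexicon,
matched for syllable length and token frequency and composed only of
syllables shared by both languages.  Accuracy as a function of target
frequency is modelled by the half-logit psychometric law

    p(correct | f) = 0.5 + 0.5 * logistic(beta0 + beta1 * ln f),

the standard chance-floored form for a 2AFC task (accuracy can never
fall below the 50% guessing floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import expit

from .langgen import Lexicon
from .util import substream

__all__ = [
    "TwoAFCTrial",
    "HalfLogitFit",
    "build_twoafc_trials",
    "score_twoafc",
    "fit_half_logit",
    "half_logit_accuracy",
]

LOG_FREQ_MATCH_TOL = 0.25  # preferred |log f_target - log f_distractor|
PARAM_BOUND = 25.0         # |beta| beyond this is treated as a boundary fit


@dataclass(frozen=True)
class TwoAFCTrial:
    index: int
    target_form: tuple[str, ...]
    target_freq: int
    distractor_form: tuple[str, ...]
    distractor_freq: int

    def __post_init__(self) -> None:
        if len(self.target_form) != len(self.distractor_form):
            raise ValueError("target and distractor must be length-matched")


def _eligible_distractors(target, lexB: Lexicon, shared: set[str],
                          forbidden_forms: set) -> list:
    return [
        e for e in lexB.entries
        if e.length == target.length
        and all(s in shared for s in e.form)
        and e.form not in forbidden_forms
    ]


def build_twoafc_trials(lexA: Lexicon, lexB: Lexicon, n_trials: int = 64,
                        freq_cutoff: int = 1000, seed: int = 0) -> list[TwoAFCTrial]:
    """Construct the 2AFC trial list for language A against distractor language B.

    Every lexA word with token frequency above ``freq_cutoff`` is an
    obligatory target; the remaining slots are filled by sampling
    targets uniformly on the log-frequency range spanned by the lexicon
    (nearest available frequency to each uniform draw, without
    replacement).  Each target is paired with the length-matched lexB
    word, composed entirely of syllables present in both inventories,
    whose log frequency is closest to the target's (ties broken by
    closest raw frequency, then by seeded random draw).  Distractors are
    used without replacement and may not be forms of language A.
    """
    rng = substream(seed, "twoafc-trials")
    shared = set(lexA.inventory.syllables) & set(lexB.inventory.syllables)
    if not shared:
        raise ValueError("languages share no syllables; no distractors possible")

    obligatory = [e for e in lexA.entries if e.frequency > freq_cutoff]
    if len(obligatory) > n_trials:
        raise ValueError(
            f"{len(obligatory)} obligatory targets exceed n_trials={n_trials}"
        )

    # lengths for which any shared-syllable distractor exists in lexB at all
    forms_A = set(lexA.forms)
    matchable_lengths = {
        e.length for e in lexB.entries
        if all(s in shared for s in e.form) and e.form not in forms_A
    }

    # fill remaining slots uniformly on the log-frequency range
    freqs = np.array([e.frequency for e in lexA.entries], dtype=float)
    log_f = np.log(freqs)
    chosen = {e.rank for e in obligatory}
    targets = list(obligatory)
    lo, hi = log_f.min(), log_f.max()
    guard = 0
    while len(targets) < n_trials:
        guard += 1
        if guard > 100 * n_trials:
            raise RuntimeError("could not fill trial slots with distinct targets")
        draw = rng.uniform(lo, hi)
        order = np.argsort(np.abs(log_f - draw), kind="stable")
        for idx in order:
            e = lexA.entries[int(idx)]
            if e.rank not in chosen and e.length in matchable_lengths:
                chosen.add(e.rank)
                targets.append(e)
                break
        else:
            raise ValueError("no length-matchable targets remain in language A")

    used_distractors: set = set()
    trials = []
    for i, target in enumerate(targets):
        candidates = _eligible_distractors(target, lexB, shared,
                                           forms_A | used_distractors)
        if not candidates:
            # allow distractor reuse before giving up
            candidates = _eligible_distractors(target, lexB, shared, forms_A)
        if not candidates:
            raise ValueError(
                f"no eligible distractor for target {''.join(target.form)} "
                f"(rank {target.rank}, length {target.length})"
            )
        lf_t = np.log(target.frequency)
        keyed = sorted(
            candidates,
            key=lambda e: (abs(np.log(e.frequency) - lf_t),
                           abs(e.frequency - target.frequency)),
        )
        best_key = (abs(np.log(keyed[0].frequency) - lf_t),
                    abs(keyed[0].frequency - target.frequency))
        ties = [e for e in keyed
                if (abs(np.log(e.frequency) - lf_t),
                    abs(e.frequency - target.frequency)) == best_key]
        distractor = ties[int(rng.integers(0, len(ties)))]
        if abs(np.log(distractor.frequency) - lf_t) > LOG_FREQ_MATCH_TOL:
            warnings.warn(
                f"distractor for rank {target.rank} matched only to "
                f"|dlogf|={abs(np.log(distractor.frequency) - lf_t):.2f}",
                stacklevel=2)
        used_distractors.add(distractor.form)
        trials.append(TwoAFCTrial(
            index=i, target_form=target.form, target_freq=target.frequency,
            distractor_form=distractor.form, distractor_freq=distractor.frequency))
    return trials


def score_twoafc(trials: list[TwoAFCTrial], choices: np.ndarray,
                 n_freq_bins: int = 4) -> pd.DataFrame:
    """Join per-trial correctness with log target frequency.

    ``choices`` is a boolean array, True where the target was chosen.
    The result carries ``correct``, ``log_freq`` and an equal-width
    ``freq_bin`` grouping on the log-frequency axis for plotting.
    """
    if len(choices) != len(trials):
        raise ValueError(f"{len(trials)} trials but {len(choices)} choices")
    log_f = np.array([np.log(t.target_freq) for t in trials])
    df = pd.DataFrame({
        "trial": [t.index for t in trials],
        "target_freq": [t.target_freq for t in trials],
        "log_freq": log_f,
        "correct": np.asarray(choices, dtype=bool),
    })
    edges = np.linspace(log_f.min(), log_f.max() + 1e-9, n_freq_bins + 1)
    df["freq_bin"] = pd.cut(df.log_freq, edges, labels=False, include_lowest=True)
    return df


def half_logit_accuracy(beta0: float, beta1: float, log_freq) -> np.ndarray:
    """The half-logit psychometric curve, floored at chance (0.5)."""
    return 0.5 + 0.5 * expit(beta0 + beta1 * np.asarray(log_freq, dtype=float))


@dataclass(frozen=True)
class HalfLogitFit:
    beta0: float
    beta1: float
    log_likelihood: float
    se_beta0: float
    se_beta1: float
    ci_beta0: tuple[float, float]
    ci_beta1: tuple[float, float]
    boundary: bool   # True when the optimum sits at/near the parameter bound

    def predict(self, log_freq) -> np.ndarray:
        return half_logit_accuracy(self.beta0, self.beta1, log_freq)


def _negloglik(params: np.ndarray, log_f: np.ndarray, correct: np.ndarray) -> float:
    p = 0.5 + 0.5 * expit(params[0] + params[1] * log_f)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(np.where(correct, np.log(p), np.log1p(-p))))


def fit_half_logit(results: pd.DataFrame) -> HalfLogitFit:
    """Maximum-likelihood half-logit fit of accuracy on log frequency.

    ``results`` needs ``log_freq`` and boolean ``correct`` columns (as
    produced by :func:`score_twoafc`).  The optimizer is deterministic
    (L-BFGS-B from (0, 0), box-bounded); Wald standard errors and 95%
    CIs come from the numerical Hessian at the optimum.  Under complete
    separation (e.g. all choices correct) the fit sits at the parameter
    bound and is flagged ``boundary`` with infinite standard errors.
    """
    log_f = results["log_freq"].to_numpy(dtype=float)
    correct = results["correct"].to_numpy(dtype=bool)
    if len(np.unique(log_f)) < 2:
        raise ValueError("need responses at >= 2 distinct frequencies")

    bounds = [(-PARAM_BOUND, PARAM_BOUND)] * 2
    opt = scipy.optimize.minimize(
        _negloglik, x0=np.zeros(2), args=(log_f, correct),
        method="L-BFGS-B", bounds=bounds)
    b0, b1 = opt.x
    boundary = bool(np.any(np.abs(opt.x) >= PARAM_BOUND - 1e-6))
    if boundary:
        warnings.warn("half-logit fit hit the parameter bound "
                      "(complete or quasi-complete separation)", stacklevel=2)

    # numerical Hessian of the negative log-likelihood at the optimum
    eps = 1e-4
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            x = opt.x.copy()
            def f(xi, xj):
                y = x.copy()
                y[i] += xi
                y[j] += xj
                return _negloglik(y, log_f, correct)
            H[i, j] = (f(eps, eps) - f(eps, -eps) - f(-eps, eps) + f(-eps, -eps)) / (4 * eps ** 2)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.array([np.inf, np.inf])
    if boundary:
        ses = np.array([np.inf, np.inf])
    zcrit = scipy.stats.norm.ppf(0.975)
    return HalfLogitFit(
        beta0=float(b0), beta1=float(b1),
        log_likelihood=-float(opt.fun),
        se_beta0=float(ses[0]), se_beta1=float(ses[1]),
        ci_beta0=(float(b0 - zcrit * ses[0]), float(b0 + zcrit * ses[0])),
        ci_beta1=(float(b1 - zcrit * ses[1]), float(b1 + zcrit * ses[1])),
        boundary=boundary)
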