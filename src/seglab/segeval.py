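"""Segmentation scoring: precision/recall/F, permutation nulls, location analysis.

Scoring is strict gap matching.  A *hit* is a marked gap where a word
boundary truly lies, a *false alarm* a marked gap inside a word, a
*miss* an unmarked boundary.  Precision = hits/(hits + false alarms),
recall = hits/(hits + misses), and F is their harmonic mean.  Corpus
scores pool counts over sentences (micro-average) before the ratios are
taken.

The chance baseline re-randomizes the responder's own marks: each
replicate independently re-draws every sentence's m marked gaps
uniformly without replacement from its G candidate gaps, preserving the
per-sentence mark count, and the corpus F of each replicate forms the
empirical null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .langgen import Corpus, Lexicon
from .learners import SegmentationResponse
from .util import substream

__all__ = [
    "ScoreReport",
    "LocationDecision",
    "PermutationBaseline",
    "score_segmentation",
    "classify_locations",
    "bin_by_log_frequency",
    "permutation_baseline",
    "detect_degenerate_strategy",
]


@dataclass(frozen=True)
class ScoreReport:
    hits: int
    misses: int
    false_alarms: int
    level: str = "corpus"        # "corpus" or "sentence"

    @property
    def precision(self) -> float:
        denom = self.hits + self.false_alarms
        return self.hits / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.hits + self.misses
        return self.hits / denom if denom else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _validate_alignment(response: SegmentationResponse, gold: Corpus) -> None:
    if len(response.gaps) != len(gold.sentences):
        raise ValueError(
            f"response covers {len(response.gaps)} sentences, gold has "
            f"{len(gold.sentences)}"
        )
    for i, (marks, s) in enumerate(zip(response.gaps, gold.sentences)):
        bad = [g for g in marks if not 1 <= g <= s.n_gaps]
        if bad:
            raise ValueError(
                f"sentence {i}: marked gaps {bad} outside 1..{s.n_gaps}"
            )


def score_segmentation(response: SegmentationResponse, gold: Corpus,
                       per_sentence: bool = False):
    """Score a response against the gold segmentation.

    Returns a corpus-level :class:`ScoreReport` (counts pooled over all
    sentences), or a list of per-sentence reports when ``per_sentence``
    is set.  0/0 precision or recall is defined as 0.
    """
    _validate_alignment(response, gold)
    reports = []
    H = M = FA = 0
    for marks, s in zip(response.gaps, gold.sentences):
        h = len(marks & s.gold_gaps)
        m = len(s.gold_gaps - marks)
        fa = len(marks - s.gold_gaps)
        H, M, FA = H + h, M + m, FA + fa
        if per_sentence:
            reports.append(ScoreReport(h, m, fa, level="sentence"))
    return reports if per_sentence else ScoreReport(H, M, FA, level="corpus")


@dataclass(frozen=True)
class LocationDecision:
    """One segmentation decision at one gap of one sentence.

    ``freq_label`` carries the token frequency of the word governing the
    gap: at a true boundary, the higher frequency of the two adjacent
    words; inside a word, the containing word's frequency.
    """

    sentence: int
    gap: int
    is_boundary: bool
    marked: bool
    freq_label: int

    @property
    def correct(self) -> bool:
        return self.marked == self.is_boundary

    @property
    def log_freq(self) -> float:
        return float(np.log(self.freq_label))


def classify_locations(response: SegmentationResponse, gold: Corpus,
                       lexicon: Lexicon) -> list[LocationDecision]:
    """Emit one labelled decision record per gap per sentence."""
    _validate_alignment(response, gold)
    decisions = []
    for idx, (marks, s) in enumerate(zip(response.gaps, gold.sentences)):
        # map every gap to its governing word(s)
        word_freqs = [lexicon.frequency_of(r) for r in s.words]
        word_of_gap: dict[int, int] = {}      # word-internal gap -> word index
        boundary_after: dict[int, int] = {}   # boundary gap -> left word index
        pos = 0
        for w, rank in enumerate(s.words):
            length = len(lexicon.form_of(rank))
            for g in range(pos + 1, pos + length):
                word_of_gap[g] = w
            pos += length
            if w < len(s.words) - 1:
                boundary_after[pos] = w
        for g in range(1, s.n_syllables):
            if g in s.gold_gaps:
                w = boundary_after[g]
                freq = max(word_freqs[w], word_freqs[w + 1])
                is_boundary = True
            else:
                freq = word_freqs[word_of_gap[g]]
                is_boundary = False
            decisions.append(LocationDecision(
                sentence=idx, gap=g, is_boundary=is_boundary,
                marked=g in marks, freq_label=freq))
    return decisions


def bin_by_log_frequency(decisions: list[LocationDecision], n_bins: int = 8,
                         prior: tuple[float, float] = (0.5, 0.5)) -> pd.DataFrame:
    """Accuracy by log-frequency bin and boundary status.

    Equal-width bins on the natural log of ``freq_label``; each
    (bin, boundary-status) cell reports the proportion of correct
    decisions with an equal-tailed 95% Beta-posterior interval
    (Jeffreys prior by default).
    """
    from .stats import beta_binomial_interval

    if not decisions:
        raise ValueError("no decisions to bin")
    df = pd.DataFrame({
        "log_freq": [d.log_freq for d in decisions],
        "is_boundary": [d.is_boundary for d in decisions],
        "correct": [d.correct for d in decisions],
    })
    edges = np.linspace(df.log_freq.min(), df.log_freq.max() + 1e-9, n_bins + 1)
    df["bin"] = pd.cut(df.log_freq, edges, labels=False, include_lowest=True)
    rows = []
    for (b, bound), grp in df.groupby(["bin", "is_boundary"], sort=True):
        n, k = len(grp), int(grp.correct.sum())
        interval = beta_binomial_interval(k, n, prior=prior)
        rows.append({
            "bin": int(b), "is_boundary": bool(bound),
            "log_freq_mid": (edges[int(b)] + edges[int(b) + 1]) / 2,
            "n": n, "correct": k, "prop_correct": k / n,
            "ci_low": interval.low, "ci_high": interval.high,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PermutationBaseline:
    n_reps: int
    f_samples: np.ndarray
    observed_f: float
    ci_low: float
    ci_high: float
    p_value: float


def permutation_baseline(response: SegmentationResponse, gold: Corpus,
                         n_reps: int = 10_000, seed: int = 0) -> PermutationBaseline:
    """Empirical chance distribution of F under within-sentence mark shuffling.

    For each of ``n_reps`` replicates, every sentence's m marked gaps
    are independently re-drawn uniformly without replacement from its
    G = L-1 gaps (preserving m per sentence), and the corpus-level F is
    computed.  Reports the 2.5/97.5 empirical percentiles and the
    one-sided p-value for the observed F with the add-one correction
    (b + 1)/(n + 1).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _validate_alignment(response, gold)
    rng = substream(seed, "permutation")

    observed = score_segmentation(response, gold)
    total_k = observed.hits + observed.misses          # gold boundaries
    total_m = observed.hits + observed.false_alarms    # placed marks

    hits = np.zeros(n_reps, dtype=np.int64)
    for marks, s in zip(response.gaps, gold.sentences):
        G, m = s.n_gaps, len(marks)
        if m > G:
            raise ValueError(f"sentence with {G} gaps carries {m} marks")
        if m == 0 or len(s.gold_gaps) == 0:
            continue
        gold_mask = np.zeros(G, dtype=bool)
        gold_mask[[g - 1 for g in s.gold_gaps]] = True
        # uniform m-subsets of the G gaps: first m slots of a random permutation
        order = np.argsort(rng.random((n_reps, G)), axis=1)[:, :m]
        assert order.shape[1] == m
        hits += gold_mask[order].sum(axis=1)

    fa = total_m - hits
    miss = total_k - hits
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(hits + fa > 0, hits / np.maximum(hits + fa, 1), 0.0)
        rec = np.where(hits + miss > 0, hits / np.maximum(hits + miss, 1), 0.0)
        f = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)

    ci_low, ci_high = np.percentile(f, [2.5, 97.5])
    b = int(np.sum(f >= observed.f_score))
    p = (b + 1) / (n_reps + 1)
    return PermutationBaseline(n_reps=n_reps, f_samples=f,
                               observed_f=observed.f_score,
                               ci_low=float(ci_low), ci_high=float(ci_high),
                               p_value=float(p))


def detect_degenerate_strategy(response: SegmentationResponse) -> tuple[bool, dict]:
    """Flag responses that are an exact fixed-period boundary lattice.

    A response is degenerate when there is a single period p such that
    in *every* sentence the marked gaps are exactly {p, 2p, ...} up to
    the sentence's last gap — the content-free strategy that warrants
    exclusion.  An all-empty response (no marks anywhere) is degenerate
    with period None (a lattice whose period exceeds every sentence).
    """
    if len(response.gaps) == 0:
        raise ValueError("empty response list")
    max_gap = max((s and max(s)) or 0 for s in response.gaps)
    if response.n_marks == 0:
        return True, {"period": None, "reason": "no boundary marks in any sentence"}

    # a period-p lattice marks exactly the consecutive multiples of p up to
    # the sentence's last gap; sentences shorter than p are legitimately empty
    for p in range(1, max_gap + 1):
        ok = True
        for marks in response.gaps:
            if not marks:
                continue
            if set(marks) != set(range(p, max(marks) + 1, p)):
                ok = False
                break
        if ok:
            return True, {"period": p, "reason": f"exact period-{p} lattice"}
    return False, {"period": None, "reason": "no constant period fits"}
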