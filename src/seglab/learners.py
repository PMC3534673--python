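"""Synthetic participants: segmentation and forced-choice response generators.

Human response data are not part of this package; instead, learners with
known generative parameters stand in for participants so every scoring
and inference stage can be validated by parameter recovery.

* :func:`oracle_noisy_segmenter` — the canonical test harness: marks true
  boundaries with probability ``hit_rate`` and word-internal gaps with
  probability ``false_alarm_rate``, independently per gap.
* :func:`tp_segmenter` — a transitional-probability learner: places a
  boundary wherever P(next syllable | previous syllable), estimated from
  a training corpus, falls below a threshold.
* :func:`yoked_control_segmenter` — a TP learner trained on the test
  block alone, modelling a control participant who saw no training.
* :func:`periodic_segmenter` — the degenerate fixed-period strategy
  (boundary every k syllables regardless of content).
* :func:`chunk_segmenter` — a frequency-chunk learner: greedy
  leftmost-longest parse against a lexicon of the most frequent attested
  syllable n-grams.
* :func:`twoafc_responder` — a 2AFC chooser whose accuracy follows the
  half-logit law 0.5 + 0.5*logistic(beta0 + beta1*ln target frequency).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .langgen import Corpus
from .util import substream

__all__ = [
    "ResponderParams",
    "SegmentationResponse",
    "TPTable",
    "oracle_noisy_segmenter",
    "estimate_tp",
    "tp_segmenter",
    "yoked_control_segmenter",
    "periodic_segmenter",
    "chunk_segmenter",
    "twoafc_responder",
]


@dataclass(frozen=True)
class ResponderParams:
    """Generative parameters of the synthetic participants.

    hit_rate / false_alarm_rate drive the noisy oracle; tp_threshold the
    TP segmenter; (beta0, beta1) the 2AFC responder's accuracy as a
    function of log word frequency.
    """

    hit_rate: float = 0.55
    false_alarm_rate: float = 0.08
    tp_threshold: float = 0.1
    beta0: float = -4.0
    beta1: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hit_rate", "false_alarm_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SegmentationResponse:
    """Per-sentence predicted boundary gap sets for one participant."""

    gaps: tuple[frozenset[int], ...]
    participant_id: str = "sim"
    condition: str = "trained"          # trained / yoked-control / degenerate

    def __len__(self) -> int:
        return len(self.gaps)

    @property
    def n_marks(self) -> int:
        return sum(len(g) for g in self.gaps)


def _check_gaps(gaps: frozenset[int], sentence) -> frozenset[int]:
    bad = [g for g in gaps if not 1 <= g <= sentence.n_gaps]
    if bad:
        raise ValueError(f"gap indices {bad} outside 1..{sentence.n_gaps}")
    return gaps


def oracle_noisy_segmenter(test: Corpus, params: ResponderParams,
                           participant_id: str = "oracle") -> SegmentationResponse:
    """Mark boundaries by flipping independent coins at every gap.

    True boundary gaps are marked with probability ``hit_rate``,
    word-internal gaps with probability ``false_alarm_rate``.
    """
    rng = substream(params.seed, f"oracle-{participant_id}")
    out = []
    for s in test.sentences:
        marked = set()
        for g in range(1, s.n_syllables):
            p = params.hit_rate if g in s.gold_gaps else params.false_alarm_rate
            if rng.random() < p:
                marked.add(g)
        out.append(frozenset(marked))
    return SegmentationResponse(gaps=tuple(out), participant_id=participant_id,
                                condition="trained")


@dataclass(frozen=True)
class TPTable:
    """Forward transitional probabilities P(s2 | s1) over syllable bigrams.

    Bigram counts are accumulated within sentences only — the silence
    between sentences breaks the bigram chain.  ``unigram_counts`` holds
    counts of each syllable as a bigram *context* (non-final positions),
    so each nonzero row of the conditional table sums to 1.
    """

    bigram_counts: dict[tuple[str, str], int]
    unigram_counts: dict[str, int]

    def prob(self, s1: str, s2: str) -> float:
        """P(s2 | s1); unseen contexts and unseen bigrams give 0."""
        denom = self.unigram_counts.get(s1, 0)
        if denom == 0:
            return 0.0
        return self.bigram_counts.get((s1, s2), 0) / denom


def estimate_tp(corpus: Corpus) -> TPTable:
    """Count syllable bigrams within sentences and normalize per context."""
    if len(corpus.sentences) == 0:
        raise ValueError("cannot estimate transitional probabilities from an empty corpus")
    bigrams: Counter = Counter()
    contexts: Counter = Counter()
    for s in corpus.sentences:
        stream = s.syllable_stream
        for a, b in zip(stream[:-1], stream[1:]):
            bigrams[(a, b)] += 1
            contexts[a] += 1
    return TPTable(bigram_counts=dict(bigrams), unigram_counts=dict(contexts))


def tp_segmenter(test: Corpus, table: TPTable, params: ResponderParams,
                 participant_id: str = "tp") -> SegmentationResponse:
    """Place a boundary at every gap whose transitional probability is low.

    Gap g is marked when P(syllable g+1 | syllable g) < ``tp_threshold``.
    Bigrams never seen in training have probability 0 and are therefore
    marked — novel junctures favour boundary insertion.
    """
    out = []
    for s in test.sentences:
        stream = s.syllable_stream
        marked = frozenset(
            g for g in range(1, len(stream))
            if table.prob(stream[g - 1], stream[g]) < params.tp_threshold
        )
        out.append(marked)
    return SegmentationResponse(gaps=tuple(out), participant_id=participant_id,
                                condition="trained")


def yoked_control_segmenter(test: Corpus, params: ResponderParams,
                            participant_id: str = "yoked") -> SegmentationResponse:
    """A TP segmenter whose only exposure is the test block itself.

    Models a yoked control: statistics are estimated from the ~400-token
    test block rather than the 60,000-token training corpus, so word
    knowledge is limited to what the test session alone can teach.
    """
    if len(test.sentences) == 0:
        return SegmentationResponse(gaps=(), participant_id=participant_id,
                                    condition="yoked-control")
    table = estimate_tp(test)
    resp = tp_segmenter(test, table, params, participant_id=participant_id)
    return SegmentationResponse(gaps=resp.gaps, participant_id=participant_id,
                                condition="yoked-control")


def periodic_segmenter(test: Corpus, period: int,
                       participant_id: str = "periodic") -> SegmentationResponse:
    """The degenerate strategy: a boundary every ``period`` syllables.

    Marks every gap g with g mod period == 0, in every sentence, with no
    variation — the response pattern that renders segmentation data
    uninterpretable and triggers exclusion.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    out = []
    for s in test.sentences:
        out.append(frozenset(g for g in range(period, s.n_syllables, period)))
    return SegmentationResponse(gaps=tuple(out), participant_id=participant_id,
                                condition="degenerate")


def chunk_segmenter(test: Corpus, training: Corpus, k_chunks: int = 500,
                    max_len: int = 6,
                    participant_id: str = "chunk") -> SegmentationResponse:
    """Frequency-chunk learner: greedy parse with a lexicon of frequent n-grams.

    The chunk lexicon is the ``k_chunks`` most frequent syllable n-grams
    (lengths 1..max_len) attested within training sentences.  Each test
    sentence is parsed greedily left to right, always taking the longest
    chunk in the lexicon that matches at the current position
    (leftmost-longest tie-break); chunk edges become boundary marks.
    """
    counts: Counter = Counter()
    for s in training.sentences:
        stream = s.syllable_stream
        for n in range(1, max_len + 1):
            for i in range(len(stream) - n + 1):
                counts[stream[i:i + n]] += 1
    # single syllables always available as a fallback parse unit
    chunks = {gram for gram, _ in counts.most_common(k_chunks)}
    chunks.update(gram for gram in counts if len(gram) == 1)

    out = []
    for s in test.sentences:
        stream = s.syllable_stream
        marks = set()
        pos = 0
        while pos < len(stream):
            for n in range(min(max_len, len(stream) - pos), 0, -1):
                if stream[pos:pos + n] in chunks:
                    pos += n
                    break
            else:
                pos += 1
            if pos < len(stream):
                marks.add(pos)
        out.append(frozenset(marks))
    return SegmentationResponse(gaps=tuple(out), participant_id=participant_id,
                                condition="trained")


def twoafc_responder(trials, params: ResponderParams,
                     participant_id: str = "sim") -> np.ndarray:
    """Simulate 2AFC choices under the half-logit accuracy law.

    The probability of choosing the target on a trial with target token
    frequency f is 0.5 + 0.5 * logistic(beta0 + beta1 * ln f),
    independent across trials.  Returns a boolean array, True where the
    target was chosen.
    """
    rng = substream(params.seed, f"twoafc-{participant_id}")
    log_f = np.array([np.log(t.target_freq) for t in trials])
    p_correct = 0.5 + 0.5 * expit(params.beta0 + params.beta1 * log_f)
    return rng.random(len(trials)) < p_correct
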