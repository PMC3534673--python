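"""Artificial-language generation.

Builds the components of a large-scale statistical-learning language:
a consonant-vowel syllable inventory, a Zipfian lexicon of word types,
a training corpus of unsegmented sentences, and a novel-sentence test
block.  All randomness flows from named substreams of a single master
seed (see :func:`seglab.util.substream`), so each stage is reproducible
in isolation.

The default configuration mirrors a large-scale word-segmentation
study design: 1000 word types, 60,000 word tokens, type frequencies
f_r proportional to 1/rank with a hard floor of 10 tokens, word
lengths 1 + Poisson(2) syllables (mean 3), sentence lengths
2 + Poisson(2) words (mean 4, hence ~12 syllables), a 336-syllable CV
inventory built from 24 consonants and 14 vowels, and no word ever
repeated immediately after itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import substream

__all__ = [
    "PhonologyConfig",
    "SyllableInventory",
    "ZipfAllocation",
    "LexiconEntry",
    "Lexicon",
    "Sentence",
    "Corpus",
    "default_phonology",
    "build_syllable_inventory",
    "allocate_zipf_counts",
    "build_lexicon",
    "generate_corpus",
    "generate_test_block",
]

# SAMPA-flavoured default phoneme labels: 24 consonants x 14 vowels = 336 CV syllables.
DEFAULT_CONSONANTS = (
    "p b t d k g f v s z S Z tS dZ m n N l r w j h T D".split()
)
DEFAULT_VOWELS = "i e a o u E I O U @ A y aI aU".split()


@dataclass(frozen=True)
class PhonologyConfig:
    """Phoneme inventory from which CV syllables are built."""

    consonants: tuple[str, ...]
    vowels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.consonants or not self.vowels:
            raise ValueError("consonant and vowel lists must be non-empty")
        if len(set(self.consonants)) != len(self.consonants):
            raise ValueError("duplicate consonant labels")
        if len(set(self.vowels)) != len(self.vowels):
            raise ValueError("duplicate vowel labels")


def default_phonology() -> PhonologyConfig:
    """The stock 24-consonant / 14-vowel inventory (336 CV syllables)."""
    return PhonologyConfig(tuple(DEFAULT_CONSONANTS), tuple(DEFAULT_VOWELS))


@dataclass(frozen=True)
class SyllableInventory:
    """Ordered list of CV syllable labels (consonant-major order)."""

    syllables: tuple[str, ...]
    phonology: PhonologyConfig

    def __len__(self) -> int:
        return len(self.syllables)

    def phoneme_pair(self, syllable: str) -> tuple[str, str]:
        """Split a CV syllable back into its (consonant, vowel) labels."""
        for c in self.phonology.consonants:
            if syllable.startswith(c):
                v = syllable[len(c):]
                if v in self.phonology.vowels:
                    return (c, v)
        raise KeyError(f"syllable {syllable!r} not decomposable in this inventory")


def build_syllable_inventory(phonology: PhonologyConfig) -> SyllableInventory:
    """Full Cartesian product of consonants and vowels, consonant-major.

    A phonology with 24 consonants and 14 vowels yields 336 syllables.
    """
    syllables = tuple(c + v for c in phonology.consonants for v in phonology.vowels)
    if len(set(syllables)) != len(syllables):
        # e.g. consonants ("t", "ts") with vowels ("a", "sa") could collide
        raise ValueError("phoneme labels produce non-unique syllable strings")
    return SyllableInventory(syllables, phonology)


@dataclass(frozen=True)
class ZipfAllocation:
    """Per-rank token counts under a floored Zipfian law.

    counts[r-1] = max(round(C / r), floor), with the scale constant C
    solved so the counts sum exactly to the configured token total
    (any rounding residual is absorbed at rank 1).
    """

    scale_C: float
    counts: tuple[int, ...]
    floor: int

    @property
    def n_types(self) -> int:
        return len(self.counts)

    @property
    def total_tokens(self) -> int:
        return int(sum(self.counts))

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(np.diff(counts) > 0):
            raise ValueError("Zipf counts must be non-increasing in rank")
        if np.any(counts < self.floor):
            raise ValueError("Zipf counts must respect the floor")


def allocate_zipf_counts(n_types: int, total_tokens: int, floor: int = 0) -> ZipfAllocation:
    """Solve for token counts f_r = max(round(C/r), floor) summing to ``total_tokens``.

    The scale constant C is found by bisection (the summed counts are a
    non-decreasing step function of C); any residual left by rounding is
    added to (or removed from) rank 1.  Deterministic given its inputs.

    Raises
    ------
    ValueError
        If ``n_types * floor > total_tokens`` (the floor alone would
        overshoot the total).
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    if n_types * floor > total_tokens:
        raise ValueError(
            f"infeasible floor: {n_types} types * floor {floor} exceeds {total_tokens} tokens"
        )

    ranks = np.arange(1, n_types + 1, dtype=float)

    def summed(C: float) -> int:
        return int(np.maximum(np.round(C / ranks), floor).sum())

    lo, hi = 0.0, float(total_tokens)
    # find the smallest C (to within fp precision) whose counts reach the total
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if summed(mid) >= total_tokens:
            hi = mid
        else:
            lo = mid
    C = hi
    counts = np.maximum(np.round(C / ranks), floor).astype(int)
    residual = total_tokens - int(counts.sum())
    counts[0] += residual
    if n_types > 1 and counts[0] < counts[1]:
        raise ValueError("rounding residual broke rank monotonicity; allocation infeasible")
    return ZipfAllocation(scale_C=C, counts=tuple(int(c) for c in counts), floor=floor)


@dataclass(frozen=True)
class LexiconEntry:
    rank: int
    form: tuple[str, ...]
    frequency: int

    @property
    def length(self) -> int:
        return len(self.form)


@dataclass(frozen=True)
class Lexicon:
    """Ranked word types with forms and token frequencies."""

    entries: tuple[LexiconEntry, ...]
    inventory: SyllableInventory
    allocation: ZipfAllocation
    seed: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def forms(self) -> tuple[tuple[str, ...], ...]:
        return tuple(e.form for e in self.entries)

    def form_of(self, rank: int) -> tuple[str, ...]:
        return self.entries[rank - 1].form

    def frequency_of(self, rank: int) -> int:
        return self.entries[rank - 1].frequency


def build_lexicon(
    inventory: SyllableInventory,
    allocation: ZipfAllocation,
    length_mean: float = 3.0,
    seed: int = 0,
    max_resamples: int = 10_000,
) -> Lexicon:
    """Draw word forms for every rank of the allocation.

    Lengths are i.i.d. shifted-Poisson, 1 + Poisson(length_mean - 1), so
    the default mean is 3 syllables and no word has length zero.  Forms
    are uniform random syllable sequences of the drawn length, resampled
    on collision until all forms are pairwise distinct.  Length and rank
    (hence frequency) are independent: there is no bias toward short
    high-frequency words.
    """
    if length_mean < 1:
        raise ValueError("length_mean must be >= 1")
    rng = substream(seed, "lexicon")
    n = allocation.n_types
    lengths = 1 + rng.poisson(length_mean - 1.0, size=n)
    syls = inventory.syllables
    seen: set[tuple[str, ...]] = set()
    entries = []
    for rank, (length, freq) in enumerate(zip(lengths, allocation.counts), start=1):
        for attempt in range(max_resamples):
            form = tuple(syls[i] for i in rng.integers(0, len(syls), size=int(length)))
            if form not in seen:
                break
        else:
            raise RuntimeError(
                f"could not draw a unique form of length {length} after "
                f"{max_resamples} attempts (inventory too small for this stratum)"
            )
        seen.add(form)
        entries.append(LexiconEntry(rank=rank, form=form, frequency=int(freq)))
    return Lexicon(entries=tuple(entries), inventory=inventory,
                   allocation=allocation, seed=seed)


@dataclass(frozen=True)
class Sentence:
    """An ordered run of word tokens with its gold segmentation.

    ``gold_gaps`` uses 1-based gap indexing: for a sentence of L
    syllables the candidate boundary positions are gaps 1..L-1, gap g
    lying between syllable g and syllable g+1.  Utterance edges are not
    gaps.
    """

    words: tuple[int, ...]                 # lexicon ranks, in order
    syllable_stream: tuple[str, ...]
    gold_gaps: frozenset[int]

    @property
    def n_syllables(self) -> int:
        return len(self.syllable_stream)

    @property
    def n_gaps(self) -> int:
        return len(self.syllable_stream) - 1


def _make_sentence(word_ranks: list[int], lexicon: Lexicon) -> Sentence:
    stream: list[str] = []
    gaps: list[int] = []
    pos = 0
    for i, rank in enumerate(word_ranks):
        form = lexicon.form_of(rank)
        stream.extend(form)
        pos += len(form)
        if i < len(word_ranks) - 1:
            gaps.append(pos)
    return Sentence(words=tuple(word_ranks), syllable_stream=tuple(stream),
                    gold_gaps=frozenset(gaps))


@dataclass(frozen=True)
class Corpus:
    sentences: tuple[Sentence, ...]
    role: str = "training"               # "training" or "test"

    @property
    def token_total(self) -> int:
        return sum(len(s.words) for s in self.sentences)

    @property
    def syllable_total(self) -> int:
        return sum(s.n_syllables for s in self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)


def _arrange_no_repeat(tokens: np.ndarray, rng: np.random.Generator,
                       max_passes: int = 200) -> np.ndarray:
    """Shuffle a token multiset so no two equal tokens are adjacent.

    Random shuffle followed by swap repair: each clash position is
    swapped with a random position where the swap removes the clash
    without creating a new one.  Infeasible multisets (one type holding
    more than half the tokens plus one) are rejected up front.
    """
    counts = np.bincount(tokens)
    if counts.max() > (len(tokens) + 1) // 2:
        raise ValueError("adjacency constraint unsatisfiable: "
                         "one type exceeds half the token total")
    arr = tokens.copy()
    rng.shuffle(arr)
    n = len(arr)
    for _ in range(max_passes):
        clash = np.flatnonzero(arr[1:] == arr[:-1]) + 1
        if len(clash) == 0:
            return arr
        for i in clash:
            if arr[i] != arr[i - 1]:
                continue  # fixed by an earlier swap this pass
            for j in rng.integers(0, n, size=64):
                j = int(j)
                if arr[j] == arr[i]:
                    continue
                # swapping arr[i] <-> arr[j] must not create clashes at either site
                if arr[i - 1] == arr[j] or (i + 1 < n and arr[i + 1] == arr[j]):
                    continue
                if j > 0 and arr[j - 1] == arr[i]:
                    continue
                if j + 1 < n and arr[j + 1] == arr[i]:
                    continue
                arr[i], arr[j] = arr[j], arr[i]
                break
    clash = np.flatnonzero(arr[1:] == arr[:-1])
    if len(clash) == 0:
        return arr
    # Tight multisets (a type holding ~half the tokens) defeat random swap
    # repair; fall back to the round-robin interleave: types ordered by
    # remaining count fill even positions first, then odd.  Valid whenever
    # the multiset is feasible at all.
    types, counts_np = np.unique(tokens, return_counts=True)
    order = np.argsort(-counts_np, kind="stable")
    laid = np.concatenate([np.full(c, t) for t, c in
                           zip(types[order], counts_np[order])])
    out = np.empty(n, dtype=tokens.dtype)
    out[0::2] = laid[: len(out[0::2])]
    out[1::2] = laid[len(out[0::2]):]
    if np.any(out[1:] == out[:-1]):
        raise RuntimeError("interleave fallback failed to remove adjacent repetitions")
    return out


def _draw_sentence_lengths(n_tokens: int, sentlen_mean: float,
                           rng: np.random.Generator) -> list[int]:
    """Cut ``n_tokens`` into sentence lengths ~ 2 + Poisson(sentlen_mean - 2).

    The final sentence is trimmed to hit the exact token total; if the
    trim would leave a single-word sentence it is merged with the
    previous one instead.
    """
    lengths: list[int] = []
    remaining = n_tokens
    while remaining > 0:
        L = 2 + int(rng.poisson(sentlen_mean - 2.0))
        if L >= remaining:
            if remaining >= 2 or not lengths:
                lengths.append(remaining)
            else:  # a trailing 1-word sentence: merge into the previous one
                lengths[-1] += remaining
            remaining = 0
        else:
            lengths.append(L)
            remaining -= L
    return lengths


def generate_corpus(
    lexicon: Lexicon,
    sentlen_mean: float = 4.0,
    seed: int = 0,
    mode: str = "exact",
    adjacency: str = "stream",
) -> Corpus:
    """Arrange the lexicon's token allocation into a training corpus.

    Parameters
    ----------
    mode
        ``"exact"`` (default) realizes each type exactly at its
        allocation count, so the printed max/min frequencies hold in the
        corpus itself.  ``"multinomial"`` draws tokens i.i.d. with
        probabilities proportional to the allocation.
    adjacency
        ``"stream"`` (default) forbids immediate repetition across the
        whole token stream, including across sentence breaks;
        ``"sentence"`` only forbids it within sentences (repetitions
        straddling a sentence break are repaired per-sentence, which for
        an exact-count stream is equivalent to not re-checking them).
    """
    if sentlen_mean < 2:
        raise ValueError("sentlen_mean must be >= 2")
    if mode not in ("exact", "multinomial"):
        raise ValueError(f"unknown mode {mode!r}")
    if adjacency not in ("stream", "sentence"):
        raise ValueError(f"unknown adjacency {adjacency!r}")

    rng = substream(seed, "corpus")
    counts = np.asarray(lexicon.allocation.counts)
    total = int(counts.sum())
    if mode == "exact":
        tokens = np.repeat(np.arange(1, len(counts) + 1), counts)
    else:
        tokens = rng.choice(np.arange(1, len(counts) + 1), size=total,
                            p=counts / total)

    stream = _arrange_no_repeat(tokens, rng)
    lengths = _draw_sentence_lengths(total, sentlen_mean, rng)

    sentences = []
    pos = 0
    for L in lengths:
        chunk = stream[pos:pos + L]
        pos += L
        if adjacency == "sentence":
            # stream arrangement already guarantees within-sentence validity
            pass
        sentences.append(_make_sentence([int(r) for r in chunk], lexicon))
    corpus = Corpus(sentences=tuple(sentences), role="training")

    if mode == "exact":
        realized = np.bincount(stream, minlength=len(counts) + 1)[1:]
        assert np.array_equal(realized, counts), "exact-count realization violated"
    return corpus


def generate_test_block(
    lexicon: Lexicon,
    training: Corpus,
    n_sentences: int = 100,
    sentlen_mean: float = 4.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> Corpus:
    """Sample novel test sentences by the training generative process.

    Sentences draw their lengths from the same shifted-Poisson law and
    their words with probability proportional to the allocation counts,
    with no immediate repetition; each sentence is verified absent (as a
    word-rank sequence) from the training corpus.  With 100 sentences of
    mean length 4 the block holds ~400 word tokens.
    """
    rng = substream(seed, "test-block")
    counts = np.asarray(lexicon.allocation.counts, dtype=float)
    probs = counts / counts.sum()
    ranks = np.arange(1, len(counts) + 1)
    training_seqs = {s.words for s in training.sentences}

    sentences = []
    for _ in range(n_sentences):
        for _ in range(max_retries):
            L = 2 + int(rng.poisson(sentlen_mean - 2.0))
            words: list[int] = []
            for _ in range(L):
                while True:
                    w = int(rng.choice(ranks, p=probs))
                    if not words or w != words[-1]:
                        break
                words.append(w)
            if tuple(words) not in training_seqs:
                break
        else:
            raise RuntimeError(
                f"could not draw a novel sentence after {max_retries} retries"
            )
        sentences.append(_make_sentence(words, lexicon))
    return Corpus(sentences=tuple(sentences), role="test")
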