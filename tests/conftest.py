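import pytest

from seglab.langgen import (
    Corpus,
    Lexicon,
    LexiconEntry,
    PhonologyConfig,
    Sentence,
    ZipfAllocation,
    allocate_zipf_counts,
    build_lexicon,
    build_syllable_inventory,
    default_phonology,
    generate_corpus,
    generate_test_block,
)


@pytest.fixture(scope="session")
def inventory():
    return build_syllable_inventory(default_phonology())


@pytest.fixture(scope="session")
def tiny_inventory():
    return build_syllable_inventory(
        PhonologyConfig(("b", "d", "g", "t", "k", "p"), ("a", "i", "u", "o")))


@pytest.fixture(scope="session")
def paper_allocation():
    return allocate_zipf_counts(1000, 60_000, floor=10)


@pytest.fixture(scope="session")
def paper_language(inventory, paper_allocation):
    """One full-scale language: lexicon, training corpus, 100-sentence test."""
    lexicon = build_lexicon(inventory, paper_allocation, seed=11)
    training = generate_corpus(lexicon, seed=11)
    test = generate_test_block(lexicon, training, n_sentences=100, seed=11)
    return lexicon, training, test


@pytest.fixture(scope="session")
def small_language(tiny_inventory):
    """A 50-type, 2000-token language — fast, still Zipfian."""
    allocation = allocate_zipf_counts(50, 2000, floor=5)
    lexicon = build_lexicon(tiny_inventory, allocation, seed=7)
    training = generate_corpus(lexicon, seed=7)
    test = generate_test_block(lexicon, training, n_sentences=40, seed=7)
    return lexicon, training, test


def make_sentence(lexicon: Lexicon, ranks: list[int]) -> Sentence:
    """Assemble a Sentence by hand from lexicon ranks."""
    stream: list[str] = []
    gaps: list[int] = []
    pos = 0
    for i, r in enumerate(ranks):
        form = lexicon.form_of(r)
        stream.extend(form)
        pos += len(form)
        if i < len(ranks) - 1:
            gaps.append(pos)
    return Sentence(words=tuple(ranks), syllable_stream=tuple(stream),
                    gold_gaps=frozenset(gaps))


def toy_four_word_language():
    """Four 2-syllable words over distinct syllables, equal frequency.

    Within-word TP is exactly 1; across-word TPs are ~1/3, so any
    threshold in between separates boundaries perfectly.
    """
    phon = PhonologyConfig(("b", "d", "g", "t", "k", "p", "s", "m"),
                           ("a", "i"))
    inventory = build_syllable_inventory(phon)
    allocation = ZipfAllocation(scale_C=40.0, counts=(40, 40, 40, 40), floor=0)
    entries = tuple(
        LexiconEntry(rank=r, form=form, frequency=40)
        for r, form in enumerate(
            [("ba", "di"), ("ga", "ti"), ("ka", "pi"), ("sa", "mi")], start=1)
    )
    return Lexicon(entries=entries, inventory=inventory,
                   allocation=allocation, seed=0)


def toy_two_word_language():
    """Two 2-syllable words A=ba di, B=gu to, equal frequency."""
    phon = PhonologyConfig(("b", "d", "g", "t"), ("a", "i", "u", "o"))
    inventory = build_syllable_inventory(phon)
    allocation = ZipfAllocation(scale_C=10.0, counts=(10, 10), floor=0)
    entries = (
        LexiconEntry(rank=1, form=("ba", "di"), frequency=10),
        LexiconEntry(rank=2, form=("gu", "to"), frequency=10),
    )
    return Lexicon(entries=entries, inventory=inventory,
                   allocation=allocation, seed=0)
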