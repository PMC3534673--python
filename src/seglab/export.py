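"""Serialization: synthesis timing files, orthographic glosses, language bundles.

The timing export writes MBROLA-style ``.pho`` text: one event per line,
``label duration [position pitch]``, with the pause label ``_``.  Each CV
syllable occupies 250 ms (split 125/125 ms over its two phonemes) at a
constant 100 Hz pitch, and sentences are separated by a 200 ms silence —
the stimulus timing of the study design this package simulates.  Audio
rendering itself is out of scope; only the timing text is produced.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .langgen import (
    Corpus,
    Lexicon,
    LexiconEntry,
    Sentence,
    SyllableInventory,
)

__all__ = [
    "corpus_to_pho",
    "corpus_to_gloss",
    "parse_gloss",
    "write_language_bundle",
    "read_language_bundle",
]

SYLLABLE_MS = 250
PHONEME_MS = 125          # 250 ms syllable split evenly over C and V
PAUSE_MS = 200
PITCH_HZ = 100
BATCH_MS = 5 * 60 * 1000  # ~5-minute batches, mirroring the WAV-file chunking


def _sentence_events(sentence: Sentence, inventory: SyllableInventory) -> list[str]:
    lines = []
    for syl in sentence.syllable_stream:
        c, v = inventory.phoneme_pair(syl)
        lines.append(f"{c} {PHONEME_MS} 50 {PITCH_HZ}")
        lines.append(f"{v} {PHONEME_MS} 50 {PITCH_HZ}")
    return lines


def corpus_to_pho(corpus: Corpus, inventory: SyllableInventory,
                  batch_ms: int = BATCH_MS) -> list[str]:
    """Render a corpus as one or more ``.pho`` batch strings.

    Batches are cut at ~``batch_ms`` of audio; a sentence is never split
    across batches.  Every sentence is followed by a 200 ms pause line,
    so total voiced duration is 250 ms x syllables and total duration is
    voiced + 200 ms x sentences per batch.
    """
    batches: list[str] = []
    current: list[str] = []
    current_ms = 0
    for sentence in corpus.sentences:
        dur = SYLLABLE_MS * sentence.n_syllables + PAUSE_MS
        if current and current_ms + dur > batch_ms:
            batches.append("\n".join(current) + "\n")
            current, current_ms = [], 0
        current.extend(_sentence_events(sentence, inventory))
        current.append(f"_ {PAUSE_MS}")
        current_ms += dur
    if current:
        batches.append("\n".join(current) + "\n")
    return batches or [""]


def corpus_to_gloss(corpus: Corpus, reveal_boundaries: bool = False,
                    delimiter: str = "|") -> str:
    """Orthographic gloss: one sentence per line, syllables space-separated.

    With ``reveal_boundaries`` the word boundaries are marked with
    ``delimiter`` (debugging / gold export only — test stimuli carry no
    boundary marks).
    """
    lines = []
    for s in corpus.sentences:
        if reveal_boundaries:
            parts = []
            for i, syl in enumerate(s.syllable_stream, start=1):
                parts.append(syl)
                if i in s.gold_gaps:
                    parts.append(delimiter)
            lines.append(" ".join(parts))
        else:
            lines.append(" ".join(s.syllable_stream))
    return "\n".join(lines) + ("\n" if lines else "")


def _gold_lines(corpus: Corpus) -> str:
    lines = [",".join(str(g) for g in sorted(s.gold_gaps)) for s in corpus.sentences]
    return "\n".join(lines) + ("\n" if lines else "")


def parse_gloss(gloss_text: str, gold_text: str,
                lexicon: Lexicon | None = None, role: str = "test") -> Corpus:
    """Rebuild a Corpus from a gloss file plus its gold gap file.

    Word-rank sequences are recovered via the lexicon's form table when a
    lexicon is given; otherwise ranks are left as 0 placeholders (forms
    and boundaries are still exact).
    """
    form_to_rank = (
        {e.form: e.rank for e in lexicon.entries} if lexicon is not None else {}
    )
    sentences = []
    gloss_lines = [ln for ln in gloss_text.splitlines() if ln.strip()]
    gold_lines = gold_text.splitlines()
    if len(gloss_lines) != len([ln for ln in gold_lines]):
        raise ValueError("gloss and gold files disagree on sentence count")
    for gloss_line, gold_line in zip(gloss_lines, gold_lines):
        syllables = tuple(gloss_line.split())
        gaps = frozenset(int(g) for g in gold_line.split(",") if g.strip())
        # split the stream at the gold gaps to recover word forms
        cuts = sorted(gaps)
        words = []
        start = 0
        for cut in [*cuts, len(syllables)]:
            form = syllables[start:cut]
            words.append(form_to_rank.get(form, 0))
            start = cut
        sentences.append(Sentence(words=tuple(words), syllable_stream=syllables,
                                  gold_gaps=gaps))
    return Corpus(sentences=tuple(sentences), role=role)


def write_language_bundle(out_dir: str | Path, lexicon: Lexicon,
                          training: Corpus, test: Corpus,
                          config: dict | None = None) -> Path:
    """Write a language bundle directory.

    Contents: ``lexicon.json`` (rank, form, length, frequency),
    ``train.txt`` / ``test.txt`` glosses (no boundary marks),
    ``train.gold`` / ``test.gold`` gap files, ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lex_records = [
        {"rank": e.rank, "form": list(e.form), "length": e.length,
         "frequency": e.frequency}
        for e in lexicon.entries
    ]
    (out / "lexicon.json").write_text(json.dumps(
        {"seed": lexicon.seed,
         "scale_C": lexicon.allocation.scale_C,
         "floor": lexicon.allocation.floor,
         "consonants": list(lexicon.inventory.phonology.consonants),
         "vowels": list(lexicon.inventory.phonology.vowels),
         "entries": lex_records}, indent=1))
    (out / "train.txt").write_text(corpus_to_gloss(training))
    (out / "train.gold").write_text(_gold_lines(training))
    (out / "test.txt").write_text(corpus_to_gloss(test))
    (out / "test.gold").write_text(_gold_lines(test))
    if config is not None:
        (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return out


def read_language_bundle(bundle_dir: str | Path) -> tuple[Lexicon, Corpus, Corpus]:
    """Load a bundle written by :func:`write_language_bundle`."""
    from .langgen import (
        PhonologyConfig,
        ZipfAllocation,
        build_syllable_inventory,
    )

    bundle = Path(bundle_dir)
    blob = json.loads((bundle / "lexicon.json").read_text())
    phonology = PhonologyConfig(tuple(blob["consonants"]), tuple(blob["vowels"]))
    inventory = build_syllable_inventory(phonology)
    counts = tuple(rec["frequency"] for rec in blob["entries"])
    allocation = ZipfAllocation(scale_C=blob["scale_C"], counts=counts,
                                floor=blob["floor"])
    entries = tuple(
        LexiconEntry(rank=rec["rank"], form=tuple(rec["form"]),
                     frequency=rec["frequency"])
        for rec in blob["entries"]
    )
    lexicon = Lexicon(entries=entries, inventory=inventory,
                      allocation=allocation, seed=blob["seed"])
    training = parse_gloss((bundle / "train.txt").read_text(),
                           (bundle / "train.gold").read_text(),
                           lexicon, role="training")
    test = parse_gloss((bundle / "test.txt").read_text(),
                       (bundle / "test.gold").read_text(),
                       lexicon, role="test")
    return lexicon, training, test
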