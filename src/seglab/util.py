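"""Seed-substream plumbing shared across the pipeline stages."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a stage name."""
    tag = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % (2**31))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A named, independent random stream hanging off one master seed.

    Every stochastic stage (lexicon draw, corpus arrangement, learner
    responses, permutation engine, ...) pulls its own named stream, so a
    single artifact can be regenerated without replaying earlier stages.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag]))
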