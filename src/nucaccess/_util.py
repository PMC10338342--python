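"""Shared helpers: DNA string utilities and seeded random substreams."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtnYRyr", "TGCANtgcanRYry")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC Y/R aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return s


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG.

    The stream for a given (seed, name) pair is independent of every other
    named stream, so adding a new generator never perturbs existing fixtures.
    """
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
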