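"""Small shared helpers: sequence normalization and report rounding."""

from __future__ import annotations

import math

from .errors import InputError

_DNA = frozenset("ACGT")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T.

    Reads and gene sequences are stored internally in the DNA alphabet
    because the binding-element patterns are written over sequenced
    (reverse-transcribed) reads. Characters outside {A, C, G, T, U}
    are rejected.
    """
    s = seq.upper().replace("U", "T")
    if not set(s) <= _DNA:
        bad = sorted(set(s) - _DNA)
        raise InputError(f"non-nucleotide characters in sequence: {bad}")
    return s


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (used for report tables)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
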