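"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pufselect import BUILTIN_PATTERNS

_AMBIGUITY = {"R": set("AG"), "N": set("ACGT")}


def naive_match(read: str, pattern_string: str) -> bool:
    """Independent sliding-window matcher (character-by-character)."""
    read = read.upper().replace("U", "T")
    pat = pattern_string.upper().replace(".", "N").replace("U", "T")
    for i in range(len(read) - len(pat) + 1):
        if all(read[i + j] in _AMBIGUITY.get(c, {c})
               for j, c in enumerate(pat)):
            return True
    return False


def random_reads(n: int, length: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return ["".join(row) for row in bases[rng.integers(0, 4, (n, length))]]


@pytest.fixture(scope="session")
def all_builtin_patterns():
    return list(BUILTIN_PATTERNS.values())
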