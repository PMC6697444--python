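"""Binding-element patterns, matching, counting, and motif summaries.

PUF-family binding elements are anchored on a UGU trinucleotide. By
convention the first U of UGU is position +1 and the obligatory upstream
cytosine is position -1 (there is no position 0). A *compact* element has
one degenerate base between the +4 purine and the terminal AU (core
CUGURnAU, terminal U at +7); an *extended* element has two (CUGURnnAU,
terminal U at +8). Patterns are written in the DNA alphabet over sequenced
reads, with R = A/G and N (or '.') = any base.

The per-+4-base ratio of compact to extended read counts is the summary
statistic that links element length to the identity of base +4: A4 favors
extended elements, G4 favors compact ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, UndefinedRatioError
from .util import normalize_sequence, round_sig

_PATTERN_REGEX = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "N": "[ACGT]"}

COMPACT = "compact"
EXTENDED = "extended"


@dataclass(frozen=True)
class ElementPattern:
    """A degenerate binding-element pattern anchored at the UGU motif.

    Parameters
    ----------
    name : str
        Label used as the element-class key throughout the package.
    pattern : str
        Pattern over {A, C, G, T, R, N}; '.' is accepted as a synonym of N.
        Must begin with the upstream C (-1) followed by TGT (+1..+3).
    element_class : str
        ``"compact"`` (one N between +4 and the terminal AU) or
        ``"extended"`` (two).
    """

    name: str
    pattern: str
    element_class: str
    base4: str = field(init=False)
    terminal_AU_position: int = field(init=False)

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace(".", "N").replace("U", "T")
        object.__setattr__(self, "pattern", pat)
        if not set(pat) <= set("ACGTRN"):
            raise InputError(f"invalid pattern characters in {pat!r}")
        if not pat.startswith("CTGT"):
            raise InputError(
                f"pattern {pat!r} must start with the -1 C followed by TGT (+1..+3)"
            )
        if self.element_class not in (COMPACT, EXTENDED):
            raise InputError(f"unknown element class {self.element_class!r}")
        if not pat.endswith("AT"):
            raise InputError(f"pattern {pat!r} must end with the terminal AU/AT")
        n_degenerate = pat[5:-2].count("N")  # between +4 and the terminal AU
        expected = 1 if self.element_class == COMPACT else 2
        if n_degenerate != expected or len(pat) != 7 + expected:
            raise InputError(
                f"{self.element_class} pattern must have exactly {expected} "
                f"degenerate base(s) between +4 and the terminal AU: {pat!r}"
            )
        # -1 occupies index 0, so +k sits at index k; terminal U/T at +len-1
        object.__setattr__(self, "base4", pat[4])
        object.__setattr__(self, "terminal_AU_position", len(pat) - 1)

    @property
    def regex(self) -> re.Pattern:
        return re.compile("".join(_PATTERN_REGEX[c] for c in self.pattern))


# The generic compact/extended pair plus the four +4-resolved patterns used
# for the per-base-4 ratio table.
BUILTIN_PATTERNS: dict[str, ElementPattern] = {
    p.name: p
    for p in (
        ElementPattern("compact", "CTGTRNAT", COMPACT),
        ElementPattern("extended", "CTGTRNNAT", EXTENDED),
        ElementPattern("compact_A4", "CTGTANAT", COMPACT),
        ElementPattern("extended_A4", "CTGTANNAT", EXTENDED),
        ElementPattern("compact_G4", "CTGTGNAT", COMPACT),
        ElementPattern("extended_G4", "CTGTGNNAT", EXTENDED),
    )
}


def match_pattern(read: str, pattern: ElementPattern) -> bool:
    """True iff any window of `read` matches `pattern` (grep line semantics)."""
    return pattern.regex.search(normalize_sequence(read)) is not None


def find_first_match(read: str, pattern: ElementPattern) -> int | None:
    """0-based offset of the first pattern match in `read`, or None."""
    m = pattern.regex.search(normalize_sequence(read))
    return None if m is None else m.start()


class PatternCountTable:
    """Per-pattern read counts per dataset, with compact:extended ratios.

    Counts are read-level by default: each read contributes at most one to
    each pattern's count, and a read matching several patterns increments
    each of them (independent queries, mirroring separate grep runs).
    """

    COLUMNS = ["dataset", "pattern_name", "pattern", "element_class",
               "base4", "terminal_AU", "count"]

    def __init__(self, rows: pd.DataFrame | None = None):
        self.table = (
            rows.reset_index(drop=True)
            if rows is not None
            else pd.DataFrame(columns=self.COLUMNS)
        )

    @classmethod
    def from_counts(
        cls, counts: dict[tuple[str, str], int],
        patterns: dict[str, ElementPattern] | None = None,
    ) -> "PatternCountTable":
        """Build a table from {(dataset, pattern_name): count} pairs."""
        patterns = patterns or BUILTIN_PATTERNS
        rows = []
        for (dataset, name), count in counts.items():
            p = patterns[name]
            rows.append((dataset, p.name, p.pattern, p.element_class,
                         p.base4, p.terminal_AU_position, int(count)))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def add(self, dataset: str, pattern: ElementPattern, count: int) -> None:
        self.table.loc[len(self.table)] = (
            dataset, pattern.name, pattern.pattern, pattern.element_class,
            pattern.base4, pattern.terminal_AU_position, int(count),
        )

    def count(self, dataset: str, pattern_name: str) -> int:
        t = self.table
        sel = t[(t.dataset == dataset) & (t.pattern_name == pattern_name)]
        if sel.empty:
            raise KeyError((dataset, pattern_name))
        return int(sel["count"].iloc[0])

    def _class_count(self, dataset: str, base4: str, element_class: str) -> int:
        t = self.table
        sel = t[(t.dataset == dataset) & (t.base4 == base4)
                & (t.element_class == element_class)]
        if sel.empty:
            raise KeyError(
                f"no {element_class} count for dataset={dataset!r} base4={base4!r}"
            )
        return int(sel["count"].sum())

    def to_frame(self, with_ratios: bool = True) -> pd.DataFrame:
        """Report table; the ratio column shows '.' where undefined."""
        out = self.table.copy()
        if with_ratios:
            ratios = []
            for _, row in out.iterrows():
                if row.element_class != COMPACT:
                    ratios.append(".")
                    continue
                try:
                    r = compact_extended_ratio(self, row.dataset, row.base4)
                    ratios.append(f"{round_sig(r, 2):g}")
                except (KeyError, UndefinedRatioError):
                    ratios.append(".")
            out["ratio_compact_extended"] = ratios
        return out


def count_patterns(
    reads: Sequence[str],
    patterns: Iterable[ElementPattern],
    dataset_label: str,
    dedup: bool = False,
    occurrences: bool = False,
) -> PatternCountTable:
    """Count reads matching each pattern.

    With ``occurrences=True`` each non-overlapping occurrence counts instead
    of each read (grep -o rather than grep -c semantics); the default is
    read-level presence. ``dedup`` collapses identical sequences first.
    """
    patterns = list(patterns)
    if not patterns:
        raise InputError("empty pattern list")
    if len(reads) == 0:
        raise InputError("empty read set")
    seqs = [normalize_sequence(r) for r in reads]
    if dedup:
        seqs = list(dict.fromkeys(seqs))
    out = PatternCountTable()
    for p in patterns:
        rx = p.regex
        if occurrences:
            n = sum(len(rx.findall(s)) for s in seqs)
        else:
            n = sum(1 for s in seqs if rx.search(s))
        out.add(dataset_label, p, n)
    return out


def compact_extended_ratio(
    table: PatternCountTable, dataset_label: str, base4: str
) -> float:
    """Compact:extended read-count ratio for one dataset and +4 base.

    Raises UndefinedRatioError when the extended count is zero; callers
    report the value rounded to two significant figures.
    """
    compact = table._class_count(dataset_label, base4, COMPACT)
    extended = table._class_count(dataset_label, base4, EXTENDED)
    if extended == 0:
        raise UndefinedRatioError(
            f"extended count is 0 for dataset={dataset_label!r} base4={base4!r}"
        )
    return compact / extended


@dataclass
class PositionFrequencyMatrix:
    """Base probabilities and information content over a window around UGU.

    `positions` uses the biological convention (-2, -1, +1, ... +9; no 0).
    `probs` has one row per position and columns A, C, G, T summing to 1.
    Information content per column is 2 + sum_b p log2 p bits, i.e. relative
    to a uniform background, in [0, 2].
    """

    positions: list[int]
    probs: pd.DataFrame
    information_content: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        out = self.probs.copy()
        out.insert(0, "position", self.positions)
        out["information_bits"] = self.information_content
        return out


def _window_positions(window: tuple[int, int]) -> list[int]:
    lo, hi = window
    return [p for p in range(lo, hi + 1) if p != 0]


def build_pfm(
    reads: Sequence[str],
    anchor_pattern: ElementPattern,
    window: tuple[int, int] = (-2, 9),
    pseudocount: float = 0.0,
) -> PositionFrequencyMatrix:
    """Align reads on their first anchor-pattern match and tally bases.

    Only reads whose alignment places the whole window inside the read are
    used; the first match per read contributes. This is a desk-scale motif
    summary: a position frequency matrix with per-column information
    content, standing in for a full motif-discovery logo.
    """
    positions = _window_positions(window)
    bases = list("ACGT")
    counts = np.full((len(positions), 4), float(pseudocount))
    n_sites = 0
    for read in reads:
        seq = normalize_sequence(read)
        m = anchor_pattern.regex.search(seq)
        if m is None:
            continue
        # pattern starts at -1, so +1 sits at match start + 1
        i1 = m.start() + 1
        idx = [i1 + p - 1 if p > 0 else i1 + p for p in positions]
        if idx[0] < 0 or idx[-1] >= len(seq):
            continue
        for row, i in enumerate(idx):
            counts[row, bases.index(seq[i])] += 1
        n_sites += 1
    if n_sites == 0:
        raise InputError("no reads could be anchored with the full window in range")
    probs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return PositionFrequencyMatrix(
        positions=positions,
        probs=pd.DataFrame(probs, columns=bases),
        information_content=ic,
        n_sites=n_sites,
    )


def classify_patterns_by_kd(
    patterns: Iterable[ElementPattern], class_kd: dict[str, float]
) -> list[tuple[ElementPattern, float]]:
    """Pair each pattern with its class Kd, sorted tightest first."""
    pairs = []
    for p in patterns:
        if p.name not in class_kd:
            raise ConfigurationError(f"no Kd configured for element class {p.name!r}")
        pairs.append((p, float(class_kd[p.name])))
    return sorted(pairs, key=lambda t: t[1])
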