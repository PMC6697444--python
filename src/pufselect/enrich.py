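"""Motif-stratified gene sets and hypergeometric term enrichment.

Genes are stratified by whether their (3'UTR-like) sequence contains a
compact and/or extended binding element. For a target set of n genes drawn
from a universe of N, a term annotating K universe genes and k target
genes is tested for over-representation with the upper-tail hypergeometric
probability P(X >= k); p-values across terms are converted to q-values
with the Benjamini-Hochberg step-up procedure. One-sided (enrichment only),
flat term sets, sense strand only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .motif import COMPACT, EXTENDED, ElementPattern, match_pattern
from .util import normalize_sequence

logger = logging.getLogger(__name__)


@dataclass
class GeneRecord:
    """A gene with a UTR-like sequence and a set of annotated terms."""

    gene_id: str
    sequence: str
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"gene {self.gene_id!r} has an empty sequence")
        self.sequence = normalize_sequence(self.sequence)
        self.terms = frozenset(self.terms)


@dataclass
class EnrichmentResult:
    term: str
    k: int   # term genes in the target set
    K: int   # term genes in the universe
    n: int   # target-set size
    N: int   # universe size
    p_value: float
    q_value: float


def stratify_targets(
    universe: Sequence[GeneRecord], patterns: Iterable[ElementPattern]
) -> dict[str, set[str]]:
    """Split a gene universe by element content.

    Returns gene-id sets keyed 'compact', 'extended', 'either', and
    'compact_only'; a gene may belong to several sets.
    """
    if not universe:
        raise InputError("empty gene universe")
    ids = [g.gene_id for g in universe]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate gene_id in universe")
    patterns = list(patterns)
    compact_pats = [p for p in patterns if p.element_class == COMPACT]
    extended_pats = [p for p in patterns if p.element_class == EXTENDED]
    compact, extended = set(), set()
    for g in universe:
        if any(match_pattern(g.sequence, p) for p in compact_pats):
            compact.add(g.gene_id)
        if any(match_pattern(g.sequence, p) for p in extended_pats):
            extended.add(g.gene_id)
    return {
        "compact": compact,
        "extended": extended,
        "either": compact | extended,
        "compact_only": compact - extended,
    }


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    target: set[str],
    universe: Sequence[GeneRecord],
    terms: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in a target set.

    Terms annotating no universe gene are skipped with a warning. Results
    are sorted by p-value; q-values are BH-adjusted over the tested terms.
    """
    ids = {g.gene_id for g in universe}
    if not target <= ids:
        raise InputError("target contains gene ids absent from the universe")
    N, n = len(ids), len(target)
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in g.terms:
            term_genes.setdefault(t, set()).add(g.gene_id)
    tested = list(terms) if terms is not None else sorted(term_genes)
    rows = []
    for t in tested:
        genes = term_genes.get(t, set())
        K = len(genes)
        if K == 0:
            logger.warning("term %r annotates no universe gene; skipped", t)
            continue
        k = len(genes & target)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((t, k, K, p))
    q = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term=t, k=k, K=K, n=n, N=N,
                         p_value=p, q_value=float(qv))
        for (t, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a report table (term, k, K, n, N, p, q), sorted by p."""
    return pd.DataFrame(
        [(r.term, r.k, r.K, r.n, r.N, r.p_value, r.q_value) for r in results],
        columns=["term", "k", "K", "n", "N", "p_value", "q_value"],
    )
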