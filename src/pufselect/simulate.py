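"""Synthetic data generators for every pipeline input.

Four generators emulate the study's experiments so the whole analysis is
testable without any external download:

* ``simulate_library`` — the starting in vitro selection pool: reads with a
  random 20-nt core between constant flanks.
* ``simulate_selection`` — rounds of affinity-driven enrichment. Each read
  is retained with weight w = theta + b, where theta = P/(P + Kd) is the
  equilibrium fractional occupancy of the read's tightest matching element
  class at protein concentration P, theta = 0 for non-matching reads, and
  b is a concentration-independent background retention (carrier tRNA /
  plastic binding). The next round is a multinomial resample of the pool
  with probabilities proportional to w.
* ``simulate_titration`` — replicate EMSA curves from the one-site model
  with additive Gaussian noise, truncated at zero signal.
* ``generate_gene_fixtures`` — gene/term universes with elements of a
  chosen class planted into the genes of designated terms.

All generators take an explicit integer seed and are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .binding import BindingTitration, one_site
from .enrich import GeneRecord
from .errors import ConfigurationError, InputError
from .motif import BUILTIN_PATTERNS, ElementPattern, classify_patterns_by_kd
from .reference import DEFAULT_CLASS_KD_NM, EMSA_CONCENTRATIONS_NM
from .util import normalize_sequence

_BASES = np.array(list("ACGT"))


@dataclass
class LibrarySpec:
    """Random-core selection library: core_length nt flanked by constants.

    The default 5' flank "GG" mirrors the guanosines with which T7
    transcripts initiate; the 3' flank defaults to empty. Primer/adapter
    sequences of the real library are not modeled.
    """

    n_reads: int
    core_length: int = 20
    flank_5p: str = "GG"
    flank_3p: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_length <= 0:
            raise InputError("core_length must be positive")
        if self.n_reads < 0:
            raise InputError("n_reads must be nonnegative")
        self.flank_5p = normalize_sequence(self.flank_5p) if self.flank_5p else ""
        self.flank_3p = normalize_sequence(self.flank_3p) if self.flank_3p else ""


@dataclass
class SelectionModel:
    """Affinity-driven selection parameters.

    class_kd maps element-class labels (pattern names) to dissociation
    constants in nM; defaults are the measured affinities of representative
    RNAs for each of the four +4-resolved element classes. The default
    protein concentration (100 nM) sits between the tightest and weakest
    class Kds so occupancy differences drive enrichment.
    """

    protein_concentration: float = 100.0
    class_kd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_KD_NM))
    background_retention: float = 0.005
    rounds: int = 5
    reads_per_round: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_concentration <= 0:
            raise InputError("protein concentration must be positive")
        if any(kd <= 0 for kd in self.class_kd.values()):
            raise InputError("all class Kd values must be strictly positive")
        if not 0 <= self.background_retention <= 1:
            raise InputError("background_retention must lie in [0, 1]")
        if self.rounds < 1:
            raise InputError("rounds must be >= 1")
        if self.reads_per_round < 1:
            raise InputError("reads_per_round must be >= 1")


@dataclass
class TitrationSpec:
    """Replicate EMSA titrations from the one-site model plus noise.

    noise_sd is the Gaussian noise standard deviation as a fraction of
    Bmax; the default concentration series is the 15-point protein
    dilution series used in the study's EMSAs.
    """

    true_kd: float
    bmax: float = 1.0
    concentrations: tuple[float, ...] = EMSA_CONCENTRATIONS_NM
    noise_sd: float = 0.05
    n_replicates: int = 3
    rna_label: str = "synthetic"
    protein_label: str = "FBF-2"
    partner_present: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kd <= 0 or self.bmax <= 0:
            raise InputError("true_kd and bmax must be positive")
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c < 0) or 0 not in c:
            raise InputError("concentrations must be nonnegative and include 0")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")


def simulate_library(spec: LibrarySpec) -> list[str]:
    """Draw n_reads sequences with i.i.d. uniform core bases."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_reads == 0:
        return []
    cores = _BASES[rng.integers(0, 4, size=(spec.n_reads, spec.core_length))]
    return [spec.flank_5p + "".join(row) + spec.flank_3p for row in cores]


def _best_occupancy(
    seq: str,
    pattern_kds: Sequence[tuple[ElementPattern, float]],
    protein: float,
) -> float:
    """Occupancy of the tightest matching class; 0 if nothing matches.

    pattern_kds is sorted tightest-first, so the first hit wins.
    """
    for pattern, kd in pattern_kds:
        if pattern.regex.search(seq):
            return protein / (protein + kd)
    return 0.0


def simulate_selection(
    library: Sequence[str],
    model: SelectionModel,
    patterns: Iterable[ElementPattern] | None = None,
) -> list[list[str]]:
    """Run `model.rounds` rounds of selection; returns one pool per round.

    Retention weight per read is theta + background_retention with theta
    the occupancy of the read's lowest-Kd matching class (best-match rule:
    equilibrium capture is dominated by the tightest site). PCR is modeled
    as neutral resampling.
    """
    if len(library) == 0:
        raise InputError("empty starting library")
    if patterns is None:
        patterns = [BUILTIN_PATTERNS[name] for name in model.class_kd]
    pattern_kds = classify_patterns_by_kd(patterns, model.class_kd)

    rng = np.random.default_rng(model.seed)
    theta_cache: dict[str, float] = {}
    pool = [normalize_sequence(r) for r in library]
    rounds_out: list[list[str]] = []
    for _ in range(model.rounds):
        uniq, counts = np.unique(np.asarray(pool, dtype=object), return_counts=True)
        thetas = np.empty(len(uniq))
        for i, seq in enumerate(uniq):
            if seq not in theta_cache:
                theta_cache[seq] = _best_occupancy(
                    seq, pattern_kds, model.protein_concentration)
            thetas[i] = theta_cache[seq]
        weights = counts * (thetas + model.background_retention)
        total = weights.sum()
        if total <= 0:
            raise ConfigurationError(
                "all retention weights are zero; increase background_retention")
        drawn = rng.multinomial(model.reads_per_round, weights / total)
        pool = [s for s, c in zip(uniq, drawn) for s in [s] * int(c)]
        rounds_out.append(pool)
    return rounds_out


def simulate_titration(spec: TitrationSpec) -> list[BindingTitration]:
    """Generate n_replicates noisy one-site titration curves."""
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.concentrations, dtype=float)
    out = []
    for rep in range(1, spec.n_replicates + 1):
        y = one_site(x, spec.true_kd, spec.bmax)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd * spec.bmax, size=x.shape)
        y = np.maximum(y, 0.0)
        out.append(BindingTitration(
            rna_label=spec.rna_label,
            protein_label=spec.protein_label,
            partner_present=spec.partner_present,
            replicate_id=rep,
            concentrations_nM=x.copy(),
            signals=y,
        ))
    return out


def _realize_element(pattern: ElementPattern, rng: np.random.Generator) -> str:
    """A concrete sequence matching `pattern` (R and N drawn uniformly)."""
    out = []
    for c in pattern.pattern:
        if c == "R":
            out.append(str(rng.choice(["A", "G"])))
        elif c == "N":
            out.append(str(rng.choice(_BASES)))
        else:
            out.append(c)
    return "".join(out)


def generate_gene_fixtures(
    n_genes: int,
    terms: Sequence[str],
    planted: dict[str, str] | None = None,
    seed: int = 0,
    utr_length: int = 200,
    penetrance: float = 1.0,
) -> tuple[list[GeneRecord], "pd.DataFrame"]:
    """Random UTR-like genes with term annotations and planted elements.

    Each gene receives one term drawn uniformly from `terms` (none if the
    list is empty). For every term in `planted` (term -> element-class
    name, e.g. "compact_G4"), annotated genes carry an embedded concrete
    element of that class at a uniform random position, with probability
    `penetrance`. Returns the gene records and a (gene_id, term)
    annotation table.
    """
    import pandas as pd

    if n_genes <= 0:
        raise InputError("n_genes must be positive")
    planted = planted or {}
    for term in planted:
        if term not in terms:
            raise InputError(f"planted term {term!r} not in the term list")
        if planted[term] not in BUILTIN_PATTERNS:
            raise InputError(f"unknown element class {planted[term]!r}")
    rng = np.random.default_rng(seed)
    genes, rows = [], []
    for i in range(n_genes):
        gene_id = f"gene_{i+1:05d}"
        seq = "".join(_BASES[rng.integers(0, 4, size=utr_length)])
        gene_terms: frozenset[str] = frozenset()
        if terms:
            term = str(terms[int(rng.integers(0, len(terms)))])
            gene_terms = frozenset({term})
            rows.append((gene_id, term))
            if term in planted and rng.random() < penetrance:
                element = _realize_element(BUILTIN_PATTERNS[planted[term]], rng)
                pos = int(rng.integers(0, utr_length - len(element) + 1))
                seq = seq[:pos] + element + seq[pos + len(element):]
        genes.append(GeneRecord(gene_id=gene_id, sequence=seq, terms=gene_terms))
    annotations = pd.DataFrame(rows, columns=["gene_id", "term"])
    return genes, annotations
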