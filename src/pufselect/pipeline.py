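"""End-to-end orchestration: simulate, count, fit, enrich, and report.

``run_full_pipeline`` executes the configured stages in order — library
generation, selection rounds, pattern counting with compact:extended
ratios, motif summary (PFM), EMSA fitting, and term enrichment — writing
every output as TSV/JSON/FASTA under one directory together with a run
manifest (seeds, parameters, package version) sufficient to regenerate
every file byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import fit_emsa_table
from .enrich import enrichment_frame, hypergeom_enrich, stratify_targets
from .errors import PufselectError, UndefinedRatioError
from .io import write_gene_fixtures, write_reads, write_titrations, write_tsv
from .motif import (BUILTIN_PATTERNS, build_pfm, compact_extended_ratio,
                    count_patterns)
from .simulate import (LibrarySpec, SelectionModel, TitrationSpec,
                       generate_gene_fixtures, simulate_library,
                       simulate_selection, simulate_titration)
from .util import round_sig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-data run.

    Every stochastic stage carries its own explicit seed. Optional stages
    (EMSA fitting, enrichment) run only when their spec/flag is set.
    """

    library: LibrarySpec = field(
        default_factory=lambda: LibrarySpec(n_reads=100_000, seed=101))
    selection: SelectionModel = field(
        default_factory=lambda: SelectionModel(seed=202))
    pattern_names: tuple[str, ...] = tuple(BUILTIN_PATTERNS)
    count_round: int = -1  # index into the selection rounds; -1 = final
    dataset_label: str = "synthetic"
    titrations: tuple[TitrationSpec, ...] = ()
    reference_rna: str = "cFBE"
    enrichment: bool = False
    n_genes: int = 300
    terms: tuple[str, ...] = ()
    planted: dict[str, str] = field(default_factory=dict)
    gene_seed: int = 303
    enrich_class: str = "compact_only"
    read_format: str = "fasta"

    @classmethod
    def demo(cls) -> "PipelineConfig":
        """A small configuration exercising every stage in seconds."""
        return cls(
            library=LibrarySpec(n_reads=20_000, seed=11),
            selection=SelectionModel(rounds=5, reads_per_round=20_000, seed=22),
            titrations=(
                TitrationSpec(true_kd=10.3, rna_label="cFBE", seed=33),
                TitrationSpec(true_kd=56.8, rna_label="PBE", seed=44),
            ),
            enrichment=True,
            n_genes=200,
            terms=("utr_binding", "kinase", "chromatin", "transport"),
            planted={"utr_binding": "compact_G4"},
            gene_seed=55,
        )


def run_full_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all configured stages; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "pufselect",
        "version": __version__,
        "config": _config_dict(config),
        "outputs": [],
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return outdir / name

    patterns = [BUILTIN_PATTERNS[n] for n in config.pattern_names]

    logger.info("[library] generating %d reads", config.library.n_reads)
    library = simulate_library(config.library)
    write_reads(library, emit(f"round_0.{config.read_format}"),
                fmt=config.read_format)

    logger.info("[selection] %d rounds", config.selection.rounds)
    class_patterns = [BUILTIN_PATTERNS[n] for n in config.selection.class_kd]
    rounds = simulate_selection(library, config.selection, class_patterns)
    for k, pool in enumerate(rounds, start=1):
        write_reads(pool, emit(f"round_{k}.{config.read_format}"),
                    fmt=config.read_format)

    logger.info("[counting] round %s", config.count_round)
    counted = rounds[config.count_round]
    table = count_patterns(counted, patterns, config.dataset_label)
    write_tsv(table.to_frame(), emit("pattern_counts.tsv"))

    ratios = []
    for base4 in ("A", "G"):
        try:
            r = compact_extended_ratio(table, config.dataset_label, base4)
            ratios.append((config.dataset_label, base4, round_sig(r, 2)))
        except (KeyError, UndefinedRatioError):
            ratios.append((config.dataset_label, base4, np.nan))
    write_tsv(pd.DataFrame(
        ratios, columns=["dataset", "base4", "ratio_compact_extended"]),
        emit("ratios.tsv"))

    logger.info("[pfm] motif summary on the final round")
    try:
        pfm = build_pfm(counted, BUILTIN_PATTERNS["compact"])
        write_tsv(pfm.to_frame(), emit("pfm.tsv"))
        (outdir / "pfm.json").write_text(json.dumps(
            {"n_sites": pfm.n_sites, "window": [-2, 9],
             "anchor": BUILTIN_PATTERNS["compact"].pattern}, indent=2))
        manifest["outputs"].append("pfm.json")
    except PufselectError as exc:
        logger.warning("[pfm] skipped: %s", exc)

    if config.titrations:
        logger.info("[emsa] fitting %d titration specs", len(config.titrations))
        titrations = []
        for spec in config.titrations:
            titrations.extend(simulate_titration(spec))
        write_titrations(titrations, emit("titrations.tsv"))
        fits = fit_emsa_table(titrations, reference_rna=config.reference_rna)
        write_tsv(fits, emit("emsa_fits.tsv"))

    if config.enrichment:
        logger.info("[enrich] %d genes, %d terms",
                    config.n_genes, len(config.terms))
        genes, annotations = generate_gene_fixtures(
            config.n_genes, list(config.terms), dict(config.planted),
            seed=config.gene_seed)
        write_gene_fixtures(genes, annotations,
                            emit("genes.fasta"), emit("annotations.tsv"))
        strata = stratify_targets(genes, patterns)
        results = hypergeom_enrich(strata[config.enrich_class], genes)
        write_tsv(enrichment_frame(results), emit("enrichment.tsv"))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote %d outputs to %s", len(manifest["outputs"]), outdir)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj

    return {f.name: convert(getattr(config, f.name))
            for f in dataclasses.fields(config)}
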