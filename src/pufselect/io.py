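"""File I/O for the standard formats: FASTA/FASTQ reads, TSV tables.

All sequence parsing goes through Bio.SeqIO. Reads are validated to the
{A, C, G, T, U} alphabet and stored as DNA (U mapped to T). TSV tables are
tab-separated, UTF-8, with a header row; undefined ratios print as ".".
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import BindingTitration
from .enrich import GeneRecord
from .errors import InputError
from .util import normalize_sequence

logger = logging.getLogger(__name__)

_FASTQ_SUFFIXES = {".fastq", ".fq"}


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _format_for(path: Path) -> str:
    suffixes = [s for s in path.suffixes if s != ".gz"]
    if suffixes and suffixes[-1] in _FASTQ_SUFFIXES:
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path) -> list[str]:
    """Read a FASTA/FASTQ file (plain or gzip) into a list of sequences."""
    path = Path(path)
    fmt = _format_for(path)
    reads: list[str] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, fmt):
                reads.append(normalize_sequence(str(rec.seq)))
        except ValueError as exc:  # malformed record
            raise InputError(f"malformed {fmt} record in {path}: {exc}") from exc
    if not reads:
        logger.warning("no records found in %s", path)
    logger.info("read %d sequences from %s", len(reads), path)
    return reads


def write_reads(
    reads: Sequence[str], path: str | Path, fmt: str = "fasta",
    id_prefix: str = "read",
) -> None:
    """Write reads as FASTA (default) or FASTQ with constant quality 'I'."""
    if fmt not in ("fasta", "fastq"):
        raise InputError(f"unsupported format {fmt!r}")
    records = []
    for i, seq in enumerate(reads, start=1):
        rec = SeqRecord(Seq(normalize_sequence(seq)),
                        id=f"{id_prefix}_{i}", description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, fmt)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


TITRATION_COLUMNS = ["rna_label", "protein_label", "partner_present",
                     "replicate_id", "concentration_nM", "signal"]


def write_titrations(
    titrations: Sequence[BindingTitration], path: str | Path
) -> None:
    rows = []
    for t in titrations:
        for x, y in zip(t.concentrations_nM, t.signals):
            rows.append((t.rna_label, t.protein_label, bool(t.partner_present),
                         t.replicate_id, float(x), float(y)))
    write_tsv(pd.DataFrame(rows, columns=TITRATION_COLUMNS), path)


def read_titrations(path: str | Path) -> list[BindingTitration]:
    frame = read_tsv(path)
    missing = set(TITRATION_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"titration table missing columns: {sorted(missing)}")
    out = []
    keys = ["rna_label", "protein_label", "partner_present", "replicate_id"]
    for (rna, prot, partner, rep), grp in frame.groupby(keys, sort=True):
        out.append(BindingTitration(
            rna_label=str(rna), protein_label=str(prot),
            partner_present=bool(partner), replicate_id=int(rep),
            concentrations_nM=grp["concentration_nM"].to_numpy(float),
            signals=grp["signal"].to_numpy(float),
        ))
    return out


def write_gene_fixtures(
    genes: Sequence[GeneRecord], annotations: pd.DataFrame,
    fasta_path: str | Path, tsv_path: str | Path,
) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
               for g in genes]
    with open(fasta_path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    write_tsv(annotations, tsv_path)


def read_gene_fixtures(
    fasta_path: str | Path, tsv_path: str | Path | None = None
) -> list[GeneRecord]:
    """Load genes from FASTA plus an optional (gene_id, term) TSV."""
    term_map: dict[str, set[str]] = {}
    if tsv_path is not None:
        ann = read_tsv(tsv_path)
        for _, row in ann.iterrows():
            term_map.setdefault(str(row["gene_id"]), set()).add(str(row["term"]))
    genes = []
    with _open_text(Path(fasta_path)) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            genes.append(GeneRecord(
                gene_id=rec.id,
                sequence=normalize_sequence(str(rec.seq)),
                terms=frozenset(term_map.get(rec.id, set())),
            ))
    return genes


def read_gene_list(path: str | Path) -> set[str]:
    """A pre-made gene list: one id per line, blanks ignored."""
    with _open_text(Path(path)) as handle:
        return {line.strip() for line in handle if line.strip()}
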