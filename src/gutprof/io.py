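"""File readers/writers shared by the CLI and the library surface."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .ssu import RANKS, Read, ReferenceTaxon, TaxonomicAssignment


def read_reads_fasta(path: str | Path) -> list[Read]:
    return [Read(id=rec.id, bases=str(rec.seq)) for rec in
            SeqIO.parse(str(path), "fasta")]


def read_reference_fasta(path: str | Path) -> list[ReferenceTaxon]:
    """Reference FASTA whose headers carry ``id domain;phylum;...;genus``."""
    taxa = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(maxsplit=1)
        if len(parts) < 2:
            raise ValueError(f"{path}: {rec.id}: header lacks a taxonomy path")
        path_labels = tuple(p.strip() for p in parts[1].split(";"))
        if len(path_labels) != len(RANKS):
            raise ValueError(
                f"{path}: {rec.id}: expected {len(RANKS)} semicolon-separated ranks"
            )
        taxa.append(ReferenceTaxon(taxon_id=rec.id, path=path_labels,
                                   sequence=str(rec.seq).upper()))
    return taxa


def write_assignments_tsv(
    assignments: Iterable[TaxonomicAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tpath\tidentity\tcoverage\tcomposite\n")
        for a in assignments:
            fh.write(
                f"{a.query_id}\t{a.status}\t{';'.join(a.path)}\t"
                f"{a.pct_identity:.2f}\t{a.pct_coverage:.2f}\t"
                f"{a.composite_score:.2f}\n"
            )
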