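"""Assembly and read-set summary statistics (N50, GC content, singletons).

N50 follows the cumulative-sum-from-longest convention: the largest contig
length L such that contigs of length >= L together contain at least half
the total assembly length.  GC content pools G+C over unambiguous bases
across all sequences; "longer than" cut-offs are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .profiles import round_half_up

_GC = frozenset("GC")
_ACGT = frozenset("ACGT")


@dataclass
class ContigSet:
    """Contig lengths, with sequences optionally attached for GC stats."""

    lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.lengths.values()):
            raise ValueError("contig lengths must be >= 1")
        if self.sequences is not None:
            for cid, seq in self.sequences.items():
                if len(seq) != self.lengths.get(cid):
                    raise ValueError(f"contig {cid!r}: sequence/length mismatch")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ContigSet":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(lengths={cid: len(s) for cid, s in seqs.items()}, sequences=seqs)


def n50(lengths: Iterable[int]) -> int:
    """Largest L with sum(lengths >= L) >= total/2.

    Always an element of the input multiset, between min and max.
    """
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("empty length list")
    if any(l < 1 for l in ls):
        raise ValueError("lengths must be >= 1")
    half = sum(ls) / 2.0
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def gc_content(sequences: Iterable[str] | str) -> float:
    """Percent G+C over unambiguous bases, pooled across sequences (2 dp).

    Ambiguity codes are excluded from the denominator; a sequence with no
    unambiguous base is skipped with a warning.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = 0
    total = 0
    for seq in sequences:
        s = seq.upper()
        unamb = sum(1 for b in s if b in _ACGT)
        if unamb == 0:
            warnings.warn("sequence with no unambiguous bases excluded from GC",
                          stacklevel=2)
            continue
        gc += sum(1 for b in s if b in _GC)
        total += unamb
    if total == 0:
        raise ValueError("no unambiguous bases in input")
    return round_half_up(100.0 * gc / total, 2)


def readset_summary(
    n_reads: int,
    n_singletons: int,
    total_bases: int,
    singleton_min_len_count: int | None = None,
) -> dict[str, float | int | None]:
    """Read-set report: singleton percentage and mean read length.

    ``singleton_min_len_count`` optionally gives the number of singletons
    above a length cut-off, reported as a percentage of all reads too.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if n_singletons > n_reads or n_singletons < 0:
        raise ValueError("singletons must be between 0 and n_reads")
    out: dict[str, float | int | None] = {
        "n_reads": n_reads,
        "n_singletons": n_singletons,
        "singleton_pct": round_half_up(100.0 * n_singletons / n_reads, 2),
        "mean_read_length": round_half_up(total_bases / n_reads, 1),
    }
    if singleton_min_len_count is not None:
        if singleton_min_len_count > n_singletons:
            raise ValueError("filtered singleton count exceeds singleton count")
        out["singleton_min_len_count"] = singleton_min_len_count
        out["singleton_min_len_pct"] = round_half_up(
            100.0 * singleton_min_len_count / n_reads, 2)
    return out


def contig_summary(
    contigs: ContigSet, length_cutoff: int = 500
) -> dict[str, float | int | None]:
    """Assembly report: counts, total length, longest contig, N50, mean GC.

    ``count_over_cutoff`` counts contigs strictly longer than the cut-off.
    """
    lengths = list(contigs.lengths.values())
    if not lengths:
        raise ValueError("empty contig set")
    report: dict[str, float | int | None] = {
        "n_contigs": len(lengths),
        "total_length": sum(lengths),
        "count_over_cutoff": sum(1 for l in lengths if l > length_cutoff),
        "length_cutoff": length_cutoff,
        "longest": max(lengths),
        "n50": n50(lengths),
        "mean_gc": (gc_content(contigs.sequences.values())
                    if contigs.sequences else None),
    }
    return report
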