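"""Pairwise local alignment with identity and query-coverage percentages.

Classification of SSU rRNA reads uses a BLAST-like local alignment.  Rather
than reproducing BLAST bit scores, alignments are computed with a
Smith-Waterman scoring scheme close to megablast defaults (match +1,
mismatch -2, gap open -5, gap extend -2) and summarised as

* ``pct_identity``   = 100 * matches / alignment columns (gaps included)
* ``pct_coverage``   = 100 * aligned query span / query length

Reads are unoriented: the reverse complement of the query is also aligned
and the better-scoring orientation kept (forward wins ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Seq import reverse_complement

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -5
GAP_EXTEND = -2


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local")
    al.match_score = MATCH_SCORE
    al.mismatch_score = MISMATCH_SCORE
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


@dataclass(frozen=True)
class LocalAlignment:
    """Summary of one local alignment of a query against a target."""

    score: float
    matches: int
    columns: int          # aligned columns including internal gaps
    query_start: int      # 0-based half-open span on the (oriented) query
    query_end: int
    reverse: bool         # True when the reverse complement of the query aligned

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    def pct_coverage(self, query_length: int) -> float:
        return 100.0 * (self.query_end - self.query_start) / query_length


_EMPTY = LocalAlignment(score=0.0, matches=0, columns=0,
                        query_start=0, query_end=0, reverse=False)


def _align_one(query: str, target: str, reverse: bool) -> LocalAlignment:
    alignments = _aligner().align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        return _EMPTY
    aln = alignments[0]
    counts = aln.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    qspan = aln.aligned[0]
    qstart = int(qspan[0][0])
    qend = int(qspan[-1][1])
    return LocalAlignment(score=float(aln.score), matches=int(matches),
                          columns=int(columns), query_start=qstart,
                          query_end=qend, reverse=reverse)


def local_align(query: str, target: str, *, both_strands: bool = True) -> LocalAlignment:
    """Best local alignment of ``query`` (optionally either strand) vs ``target``."""
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    fwd = _align_one(query, target, reverse=False)
    if not both_strands:
        return fwd
    rev = _align_one(reverse_complement(query), target, reverse=True)
    return rev if rev.score > fwd.score else fwd


def pairwise_identity_coverage(query: str, target: str, *,
                               both_strands: bool = True) -> tuple[float, float]:
    """Percent identity and query-relative percent coverage of the best
    local alignment.

    Returns ``(pct_identity, pct_coverage)``, each in [0, 100].  Coverage is
    the aligned span on the query divided by the full query length; identity
    is computed over alignment columns (internal gaps count as columns).
    """
    aln = local_align(query, target, both_strands=both_strands)
    return aln.pct_identity, aln.pct_coverage(len(query))


def identity_over_shorter(a: str, b: str) -> float:
    """Fractional identity with the shorter sequence's length as denominator.

    This is the cd-hit-style identity used for read clustering: the number
    of matched bases in the best local alignment divided by the length of
    the shorter of the two sequences.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = local_align(a, b, both_strands=False)
    return aln.matches / min(len(a), len(b))


def kmer_set(seq: str, k: int) -> set[str]:
    """All distinct k-mers of ``seq`` (empty set when shorter than ``k``)."""
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def sampled_kmers(seq: str, k: int, stride: int) -> list[str]:
    """k-mers at every ``stride`` positions, always including the last one."""
    if len(seq) < k:
        return []
    starts = list(range(0, len(seq) - k + 1, stride))
    last = len(seq) - k
    if starts[-1] != last:
        starts.append(last)
    return [seq[i:i + k] for i in starts]
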