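"""SSU rRNA read pipeline: quality filtering, dereplication, greedy
clustering, composite-score taxonomic classification and profiling.

The pipeline mirrors the standard amplicon-free SSU workflow for
pyrosequencing read sets:

1. remove reads shorter than 200 nt, with more than 2% ambiguous bases or
   more than 2% of their bases inside long homopolymer runs;
2. dereplicate (collapse reads identical over the shorter read's full
   length) at identity 1.00, word size 8;
3. cluster the dereplication representatives greedily at identity 0.98
   (identity computed over the shorter sequence, cd-hit-est style);
4. classify the longest read of each cluster against a reference SSU
   database, accepting the best hit when the composite score
   ``(% identity + % query coverage) / 2`` is at least 93.0;
5. propagate each cluster reference's taxonomic path to the cluster's
   members and their dereplication replicates, then count reads per
   taxonomic label to obtain semi-quantitative profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import edlib
from Bio.Seq import reverse_complement

from .alignment import (
    kmer_set,
    local_align,
    pairwise_identity_coverage,
    sampled_kmers,
)
from .exceptions import InconsistencyError
from .profiles import AbundanceProfile

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Read:
    """A sequence read: opaque id plus uppercase IUPAC nucleotide string."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QualityCriteria:
    """Read quality filter thresholds.

    ``min_length`` is strict below ("shorter than 200" removes 199-nt
    reads but keeps 200-nt reads); the two fraction thresholds are strict
    above (a read with exactly 2% ambiguities passes).
    """

    min_length: int = 200
    max_ambiguity_frac: float = 0.02
    max_homopolymer_frac: float = 0.02
    homopolymer_min_run: int = 6

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for frac in (self.max_ambiguity_frac, self.max_homopolymer_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction thresholds must be in [0, 1]")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")


@dataclass(frozen=True)
class ClusteringParams:
    identity_threshold: float = 0.98
    word_size: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")


DEREPLICATION_PARAMS = ClusteringParams(identity_threshold=1.00, word_size=8)
CLUSTERING_PARAMS = ClusteringParams(identity_threshold=0.98, word_size=8)


@dataclass(frozen=True)
class ClassificationParams:
    min_composite_score: float = 93.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_composite_score <= 100.0:
            raise ValueError("min_composite_score must be in [0, 100]")


@dataclass
class ReadCluster:
    """A cluster of reads represented by its longest member.

    ``member_ids`` includes the reference; ``replicate_ids`` holds
    dereplication duplicates attached to members.  Across the clusters of
    one clustering pass, members + replicates partition the input reads.
    """

    reference_read_id: str
    member_ids: list[str]
    replicate_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids) + len(self.replicate_ids)


@dataclass(frozen=True)
class TaxonomicAssignment:
    """Outcome of classifying one read against the reference database."""

    query_id: str
    path: tuple[str, ...]
    pct_identity: float
    pct_coverage: float
    status: str  # "assigned" | "unclassified"

    @property
    def composite_score(self) -> float:
        return (self.pct_identity + self.pct_coverage) / 2.0

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


# ---------------------------------------------------------------------------
# quality filtering


def ambiguity_fraction(read: Read) -> float:
    """Fraction of bases that are not unambiguous A/C/G/T."""
    n = sum(1 for b in read.bases if b not in _ACGT)
    return n / len(read)


def homopolymer_fraction(read: Read, min_run: int = 6) -> float:
    """Fraction of bases inside single-nucleotide runs of length >= min_run.

    Long homopolymers are the characteristic pyrosequencing error mode;
    the filter removes reads dominated by them.
    """
    if not read.bases:
        raise ValueError("empty sequence")
    seq = read.bases
    in_runs = 0
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            in_runs += j - i
        i = j
    return in_runs / n


def filter_reads(
    reads: Iterable[Read], criteria: QualityCriteria = QualityCriteria()
) -> tuple[list[Read], list[tuple[str, str]]]:
    """Apply the quality criteria; returns (kept reads, rejection log).

    The rejection log records ``(read_id, rule)`` with the first rule that
    fired, in the order length, ambiguity, homopolymer.
    """
    kept: list[Read] = []
    rejected: list[tuple[str, str]] = []
    for read in reads:
        if len(read) < criteria.min_length:
            rejected.append((read.id, "length"))
        elif ambiguity_fraction(read) > criteria.max_ambiguity_frac:
            rejected.append((read.id, "ambiguity"))
        elif homopolymer_fraction(read, criteria.homopolymer_min_run) \
                > criteria.max_homopolymer_frac:
            rejected.append((read.id, "homopolymer"))
        else:
            kept.append(read)
    return kept, rejected


# ---------------------------------------------------------------------------
# dereplication and clustering

def _greedy_order(reads: Sequence[Read]) -> list[Read]:
    # length descending, ties lexicographic by id: deterministic greedy order
    return sorted(reads, key=lambda r: (-len(r), r.id))


def dereplicate(
    reads: Sequence[Read], params: ClusteringParams = DEREPLICATION_PARAMS
) -> list[ReadCluster]:
    """Collapse identical reads (identity 1.00 over the shorter read).

    A shorter read identical over its whole length to a longer one (exact
    containment) collapses into the longer read's cluster; the longest
    read is the representative.  The output clusters partition the input.
    """
    if params.identity_threshold != 1.0:
        raise ValueError("dereplication requires identity_threshold == 1.0")
    k = params.word_size
    clusters: list[ReadCluster] = []
    rep_seqs: list[str] = []
    index: dict[str, list[int]] = {}  # k-mer -> cluster indices whose rep contains it
    for read in _greedy_order(reads):
        seq = read.bases
        placed = False
        if len(seq) >= k:
            probe = seq[:k]
            # exact containment implies every query k-mer occurs in the rep
            for ci in index.get(probe, ()):
                if seq in rep_seqs[ci]:
                    clusters[ci].member_ids.append(read.id)
                    placed = True
                    break
        else:  # reads shorter than the word size: linear scan
            for ci, rep in enumerate(rep_seqs):
                if seq in rep:
                    clusters[ci].member_ids.append(read.id)
                    placed = True
                    break
        if not placed:
            ci = len(clusters)
            clusters.append(ReadCluster(reference_read_id=read.id,
                                        member_ids=[read.id]))
            rep_seqs.append(seq)
            for mer in kmer_set(seq, k):
                index.setdefault(mer, []).append(ci)
    return clusters


def _word_count_bound(n_query_kmers: int, length_shorter: int,
                      identity: float) -> int:
    # a pair meeting the identity threshold has at most
    # floor((1 - t) * Ls) unmatched query bases, each of which can remove
    # at most word_size distinct query k-mers from the target; one extra
    # word of slack absorbs boundary effects
    budget = math.floor((1.0 - identity) * length_shorter) + 1
    return n_query_kmers - 8 * budget


def cluster(
    reads: Sequence[Read], params: ClusteringParams = CLUSTERING_PARAMS
) -> list[ReadCluster]:
    """Greedy incremental clustering of dereplication representatives.

    Sequences are processed longest first; each joins the first existing
    cluster whose reference shares at least one exact word (k-mer) with it
    and aligns at fractional identity >= the threshold, where identity is
    matches over the shorter sequence's length.  Otherwise it founds a new
    cluster, so references are always founders and longest by construction.

    For long reads a word-counting prescreen (shared distinct k-mers must
    reach the combinatorial minimum implied by the identity threshold)
    avoids aligning hopeless candidate pairs; on short sequences every
    word-sharing candidate is aligned.
    """
    k = params.word_size
    t = params.identity_threshold
    clusters: list[ReadCluster] = []
    rep_reads: list[Read] = []
    rep_kmers: list[set[str]] = []
    index: dict[str, list[int]] = {}
    for read in _greedy_order(reads):
        seq = read.bases
        qkmers = kmer_set(seq, k)
        # stride chosen so that any pair passing the identity threshold
        # still shares a probed word (the longest exact run between
        # mismatches is >= (Ls - m)/(m + 1) - 7 word starts long)
        use_prescreen = len(seq) >= 100
        stride = 16 if use_prescreen else 1
        candidates: set[int] = set()
        for mer in sampled_kmers(seq, k, stride):
            candidates.update(index.get(mer, ()))
        placed = False
        for ci in sorted(candidates):
            shorter = min(len(seq), len(rep_reads[ci]))
            if use_prescreen:
                shared = len(qkmers & rep_kmers[ci])
                if shared < _word_count_bound(len(qkmers), shorter, t):
                    continue
            aln = local_align(seq, rep_reads[ci].bases, both_strands=False)
            if aln.matches / shorter >= t:
                clusters[ci].member_ids.append(read.id)
                placed = True
                break
        if not placed:
            ci = len(clusters)
            clusters.append(ReadCluster(reference_read_id=read.id,
                                        member_ids=[read.id]))
            rep_reads.append(read)
            rep_kmers.append(qkmers)
            for mer in qkmers:
                index.setdefault(mer, []).append(ci)
    return clusters


def attach_replicates(
    clusters: Sequence[ReadCluster], derep: Sequence[ReadCluster]
) -> list[ReadCluster]:
    """Attach dereplication duplicates to the clusters of their representatives.

    ``clusters`` is the 0.98 clustering of the dereplication representatives;
    each duplicate collapsed during dereplication becomes a replicate of the
    cluster holding its representative.
    """
    dup_of: dict[str, list[str]] = {}
    for dc in derep:
        dups = [m for m in dc.member_ids if m != dc.reference_read_id]
        if dups:
            dup_of[dc.reference_read_id] = dups
    out = []
    for cl in clusters:
        reps = list(cl.member_ids)
        replicates = list(cl.replicate_ids)
        for rid in reps:
            replicates.extend(dup_of.get(rid, ()))
        out.append(ReadCluster(reference_read_id=cl.reference_read_id,
                               member_ids=reps, replicate_ids=replicates))
    return out


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ReferenceTaxon:
    """A reference SSU sequence with its six-rank taxonomic path."""

    taxon_id: str
    path: tuple[str, ...]
    sequence: str

    def __post_init__(self) -> None:
        if len(self.path) != len(RANKS) or any(not p for p in self.path):
            raise ValueError(
                f"taxon {self.taxon_id!r}: path must have {len(RANKS)} "
                "non-empty ranks"
            )
        if not self.sequence or set(self.sequence) - _ACGT:
            raise ValueError(f"taxon {self.taxon_id!r}: sequence must be ACGT only")


def _edlib_prescreen(
    query: str, refdb: Sequence[ReferenceTaxon], margin: int
) -> list[ReferenceTaxon]:
    """Rank references by banded edit distance on either strand; keep all
    references within ``margin`` of the best.  Pure performance device: the
    retained candidates are re-scored with the exact local aligner."""
    rc = reverse_complement(query)
    dists = []
    for ref in refdb:
        d = min(
            edlib.align(query, ref.sequence, mode="HW", task="distance")["editDistance"],
            edlib.align(rc, ref.sequence, mode="HW", task="distance")["editDistance"],
        )
        dists.append(d)
    best = min(dists)
    return [ref for ref, d in zip(refdb, dists) if d <= best + margin]


def classify(
    reference_read: Read,
    refdb: Sequence[ReferenceTaxon],
    params: ClassificationParams = ClassificationParams(),
    *,
    prescreen: bool = True,
) -> TaxonomicAssignment:
    """Best-hit classification of a cluster reference read.

    The best hit maximises the composite score (mean of percent identity
    and percent query coverage); ties break on higher identity, then on the
    lexicographically smallest taxon id.  The full taxonomic path of the
    best hit is assigned when the composite score is at least the threshold
    (inclusive); otherwise the read is unclassified with an empty path.
    """
    if not refdb:
        raise ValueError("reference database is empty")
    candidates: Sequence[ReferenceTaxon] = refdb
    if prescreen and len(refdb) > 4:
        margin = max(4, math.ceil(0.05 * len(reference_read)))
        candidates = _edlib_prescreen(reference_read.bases, refdb, margin)
    best: tuple[float, float, str] | None = None
    best_ref: ReferenceTaxon | None = None
    best_idcov = (0.0, 0.0)
    for ref in candidates:
        ident, cov = pairwise_identity_coverage(reference_read.bases, ref.sequence)
        composite = (ident + cov) / 2.0
        key = (-composite, -ident, ref.taxon_id)
        if best is None or key < best:
            best = key
            best_ref = ref
            best_idcov = (ident, cov)
    assert best_ref is not None
    ident, cov = best_idcov
    composite = (ident + cov) / 2.0
    if composite >= params.min_composite_score:
        return TaxonomicAssignment(
            query_id=reference_read.id, path=best_ref.path,
            pct_identity=ident, pct_coverage=cov, status="assigned",
        )
    return TaxonomicAssignment(
        query_id=reference_read.id, path=(),
        pct_identity=ident, pct_coverage=cov, status="unclassified",
    )


def propagate(
    clusters: Sequence[ReadCluster],
    assignments: Mapping[str, TaxonomicAssignment],
) -> list[TaxonomicAssignment]:
    """Map each cluster reference's assignment onto members and replicates.

    Every read of every cluster receives its reference's path and status,
    so the read count is conserved: the output has exactly one record per
    member plus replicate.
    """
    out: list[TaxonomicAssignment] = []
    for cl in clusters:
        try:
            ref_assign = assignments[cl.reference_read_id]
        except KeyError:
            raise InconsistencyError(
                f"cluster reference {cl.reference_read_id!r} has no assignment"
            ) from None
        for rid in list(cl.member_ids) + list(cl.replicate_ids):
            out.append(replace(ref_assign, query_id=rid))
    return out


def taxonomic_profile(
    per_read_assignments: Iterable[TaxonomicAssignment], rank: str
) -> AbundanceProfile:
    """Read counts and percentages per taxonomic label at one rank.

    Only assigned reads contribute; percentages are relative to the total
    number of contributing reads, rounded half-up to two decimals.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    idx = RANKS.index(rank)
    labels = [
        a.path[idx]
        for a in per_read_assignments
        if a.assigned and len(a.path) > idx
    ]
    return AbundanceProfile.from_labels(rank, labels, ndigits=2)


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class PipelineResult:
    kept_reads: list[Read]
    rejections: list[tuple[str, str]]
    derep_clusters: list[ReadCluster]
    clusters: list[ReadCluster]
    reference_assignments: dict[str, TaxonomicAssignment]
    per_read_assignments: list[TaxonomicAssignment]

    def profile(self, rank: str) -> AbundanceProfile:
        return taxonomic_profile(self.per_read_assignments, rank)


def run_pipeline(
    reads: Sequence[Read],
    refdb: Sequence[ReferenceTaxon],
    *,
    quality: QualityCriteria = QualityCriteria(),
    derep_params: ClusteringParams = DEREPLICATION_PARAMS,
    cluster_params: ClusteringParams = CLUSTERING_PARAMS,
    class_params: ClassificationParams = ClassificationParams(),
) -> PipelineResult:
    """Filter, dereplicate, cluster, classify and propagate in one call."""
    kept, rejections = filter_reads(reads, quality)
    derep = dereplicate(kept, derep_params)
    by_id = {r.id: r for r in kept}
    reps = [by_id[c.reference_read_id] for c in derep]
    clusters_ = attach_replicates(cluster(reps, cluster_params), derep)
    assignments = {
        c.reference_read_id: classify(by_id[c.reference_read_id], refdb, class_params)
        for c in clusters_
    }
    per_read = propagate(clusters_, assignments)
    return PipelineResult(
        kept_reads=kept, rejections=rejections, derep_clusters=derep,
        clusters=clusters_, reference_assignments=assignments,
        per_read_assignments=per_read,
    )
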