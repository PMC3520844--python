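"""SSU read pipeline: filtering, clustering, classification, profiling."""

import random

import pytest

from gutprof.exceptions import InconsistencyError
from gutprof.ssu import (
    ClassificationParams,
    ClusteringParams,
    QualityCriteria,
    Read,
    TaxonomicAssignment,
    attach_replicates,
    classify,
    cluster,
    dereplicate,
    filter_reads,
    homopolymer_fraction,
    propagate,
    run_pipeline,
    taxonomic_profile,
)

from conftest import make_taxon, random_dna


# -- homopolymer and quality filtering --------------------------------------


@pytest.mark.parametrize(
    "seq,min_run,expected",
    [
        ("ACGTACGT", 6, 0.0),          # no runs at all
        ("AAAAAA", 6, 1.0),            # the whole sequence is one run
        ("AAAAAATTTT", 6, 0.6),        # 6 of 10 bases inside a >=6 run
        ("AAAAATTTTT", 6, 0.0),        # two runs of 5, below the cut
        ("AAAAATTTTT", 5, 1.0),
    ],
)
def test_homopolymer_fraction(seq, min_run, expected):
    assert homopolymer_fraction(Read("r", seq), min_run) == pytest.approx(expected)


def test_filter_boundaries():
    base200 = "ACGT" * 50                           # no homopolymer runs
    clean199 = Read("a", base200[:199])
    with_4n = Read("b", "N" * 4 + base200[4:])     # exactly 2.0% ambiguous
    with_5n = Read("c", "N" * 5 + base200[5:])     # 2.5% ambiguous
    homopoly = Read("d", "A" * 20 + base200[20:])  # 10% in a long run
    kept, rejected = filter_reads([clean199, with_4n, with_5n, homopoly],
                                  QualityCriteria())
    assert [r.id for r in kept] == ["b"]           # exactly-2% passes
    assert dict(rejected) == {"a": "length", "c": "ambiguity", "d": "homopolymer"}


def test_filter_empty_input():
    kept, rejected = filter_reads([], QualityCriteria())
    assert kept == [] and rejected == []


# -- dereplication ----------------------------------------------------------


def test_dereplicate_identical_and_contained():
    rng = random.Random(2)
    long = random_dna(rng, 60)
    reads = [
        Read("long", long),
        Read("dup", long),              # byte-identical
        Read("prefix", long[:40]),      # exact prefix: contained
        Read("other", random_dna(rng, 50)),
    ]
    clusters = dereplicate(reads)
    by_ref = {c.reference_read_id: sorted(c.member_ids) for c in clusters}
    # equal-length ties break lexicographically by id, so "dup" represents
    assert by_ref["dup"] == ["dup", "long", "prefix"]
    assert by_ref["other"] == ["other"]


def test_dereplicate_single_substitution_splits():
    seq = "ACGT" * 15
    mutated = seq[:30] + "A" + seq[31:] if seq[30] != "A" else seq[:30] + "C" + seq[31:]
    clusters = dereplicate([Read("a", seq), Read("b", mutated)])
    assert len(clusters) == 2


# -- greedy clustering ------------------------------------------------------


def test_cluster_identical_inputs_single_cluster():
    seq = random_dna(random.Random(3), 120)
    clusters = cluster([Read(f"r{i}", seq) for i in range(4)])
    assert len(clusters) == 1
    assert clusters[0].size == 4


def test_cluster_99pct_identity_merges():
    rng = random.Random(4)
    a = random_dna(rng, 400)
    positions = rng.sample(range(400), 4)
    b = list(a)
    for p in positions:
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    clusters = cluster([Read("a", a), Read("b", "".join(b))])
    assert len(clusters) == 1


def test_cluster_no_shared_word_never_merges():
    # identical 7-mers have no 8-mer at all, so the word filter keeps them apart
    clusters = cluster([Read("a", "ACGTACG"), Read("b", "ACGTACG")])
    assert len(clusters) == 2


def test_cluster_reference_is_longest_founder():
    rng = random.Random(5)
    seq = random_dna(rng, 300)
    reads = [Read("short", seq[:250]), Read("full", seq)]
    clusters = cluster(reads)
    assert len(clusters) == 1
    assert clusters[0].reference_read_id == "full"


# -- classification ---------------------------------------------------------


def _act_only_dna(rng, n):  # no G: lets a poly-G tail stay unalignable
    return "".join(rng.choice("ACT") for _ in range(n))


def test_classify_perfect_hit_assigned():
    rng = random.Random(6)
    ref = make_taxon("T1", random_dna(rng, 400))
    read = Read("q", ref.sequence[100:300])
    a = classify(read, [ref])
    assert a.assigned and a.path == ref.path
    assert a.pct_identity == 100.0 and a.pct_coverage == 100.0


def test_classify_composite_exactly_93_is_assigned():
    rng = random.Random(7)
    core = _act_only_dna(rng, 200)
    ref = make_taxon("T1", core)
    # 86 aligned bases + 14-base poly-G tail: identity 100, coverage 86
    read = Read("q", core[:86] + "G" * 14)
    a = classify(read, [ref])
    assert a.pct_identity == 100.0
    assert a.pct_coverage == pytest.approx(86.0)
    assert a.composite_score == pytest.approx(93.0)
    assert a.assigned


def test_classify_below_threshold_unclassified():
    rng = random.Random(8)
    ref = make_taxon("T1", _act_only_dna(rng, 300))
    read = Read("q", ref.sequence[:100] + "G" * 100)  # coverage ~50
    a = classify(read, [ref])
    assert not a.assigned
    assert a.path == ()
    assert a.composite_score < 93.0


def test_classify_tie_breaks_on_smallest_taxon_id():
    rng = random.Random(9)
    seq = random_dna(rng, 300)
    refs = [make_taxon(tid, seq, genus=f"G_{tid}") for tid in ("T9", "T2", "T5")]
    read = Read("q", seq[50:250])
    a = classify(read, refs)
    assert a.path[-1] == "G_T2"


def test_classify_empty_refdb_rejected():
    with pytest.raises(ValueError):
        classify(Read("q", "ACGTACGT"), [])


def test_threshold_monotonicity(ten_taxa, clean_community):
    reads, _truth, _spec = clean_community
    result = run_pipeline(reads[:300], ten_taxa)
    composites = [a.composite_score
                  for a in result.reference_assignments.values()]
    counts = [sum(c >= th for c in composites) for th in (80, 90, 93, 97, 100)]
    assert counts == sorted(counts, reverse=True)


# -- propagation and profiles -----------------------------------------------


def _assignment(qid, path, status="assigned"):
    return TaxonomicAssignment(query_id=qid, path=path, pct_identity=99.0,
                               pct_coverage=99.0, status=status)


def test_propagate_conserves_read_count():
    from gutprof.ssu import ReadCluster

    path = ("Bacteria", "P", "C", "O", "F", "G")
    clusters = [
        ReadCluster("a", ["a", "b"]),
        ReadCluster("c", ["c", "d"], replicate_ids=["e"]),
        ReadCluster("f", ["f", "g", "h", "i", "j"]),
    ]
    assignments = {rid: _assignment(rid, path) for rid in "acf"}
    per_read = propagate(clusters, assignments)
    assert sorted(a.query_id for a in per_read) == list("abcdefghij")
    assert all(a.path == path for a in per_read)


def test_propagate_unclassified_reference_spreads():
    from gutprof.ssu import ReadCluster

    clusters = [ReadCluster("a", ["a", "b", "c"])]
    assignments = {"a": _assignment("a", (), status="unclassified")}
    per_read = propagate(clusters, assignments)
    assert all(not a.assigned for a in per_read)


def test_propagate_missing_reference_raises():
    from gutprof.ssu import ReadCluster

    with pytest.raises(InconsistencyError):
        propagate([ReadCluster("a", ["a"])], {})


def test_profile_counts_and_percentages():
    path_a = ("Bacteria", "PhyA", "C", "O", "F", "G1")
    path_b = ("Bacteria", "PhyB", "C", "O", "F", "G2")
    per_read = [_assignment(f"a{i}", path_a) for i in range(2)] + \
               [_assignment(f"b{i}", path_b) for i in range(2)] + \
               [_assignment("u", (), status="unclassified")]
    prof = taxonomic_profile(per_read, "phylum")
    assert prof.counts == {"PhyA": 2, "PhyB": 2}
    assert prof.percentages == {"PhyA": 50.0, "PhyB": 50.0}
    assert prof.total == 4  # unclassified reads do not contribute


def test_profile_empty_when_nothing_assigned():
    prof = taxonomic_profile([_assignment("u", (), status="unclassified")],
                             "phylum")
    assert prof.total == 0 and prof.percentages == {}


def test_profile_unknown_rank_rejected():
    with pytest.raises(ValueError):
        taxonomic_profile([], "species")


# -- pipeline invariants ----------------------------------------------------


def test_partition_invariant(ten_taxa, clean_community):
    """Members plus replicates across clusters cover every kept read once."""
    reads, _truth, _spec = clean_community
    kept, _ = filter_reads(reads)
    derep = dereplicate(kept)
    by_id = {r.id: r for r in kept}
    reps = [by_id[c.reference_read_id] for c in derep]
    clusters = attach_replicates(cluster(reps), derep)
    seen = [rid for c in clusters for rid in c.member_ids + c.replicate_ids]
    assert sorted(seen) == sorted(r.id for r in kept)


def test_pipeline_zero_error_reads_classified_to_true_genus(
    ten_taxa, clean_community
):
    reads, truth, _spec = clean_community
    result = run_pipeline(reads, ten_taxa)
    genus_of = {t.taxon_id: t.path[-1] for t in ten_taxa}
    assert result.per_read_assignments
    for a in result.per_read_assignments:
        assert a.assigned
        assert a.path[-1] == genus_of[truth[a.query_id]]
    prof = result.profile("phylum")
    total_pct = sum(100.0 * c / prof.total for c in prof.counts.values())
    assert total_pct == pytest.approx(100.0, abs=1e-9)
    assert sum(prof.percentages.values()) == pytest.approx(100.0, abs=0.05)
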