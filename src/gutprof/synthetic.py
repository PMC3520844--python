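"""Synthetic communities with known ground truth.

Every input the pipeline consumes can be generated here: a rank-structured
reference SSU database, pyrosequencing-style read sets (substitutions,
ambiguous bases, homopolymer indels), ORF annotation tables whose E-value
and homology distributions straddle the validity cut-offs, and linear pNP
kinetics.  All randomness flows from a single integer seed, so identical
seeds give byte-identical outputs and every generated dataset carries its
ground truth alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import KineticsSeries
from .ssu import RANKS, Read, ReferenceTaxon

_BASES = "ACGT"

#: Per-rank substitution divergence injected below each ancestor sequence
#: (phylum ... genus).  SSU genes are strongly conserved, so the doses are
#: small: two sibling genera accumulate two genus-level doses (~8% expected
#: divergence), keeping best-local-alignment identity between distinct
#: genera below 0.95, while the deepest split stays under ~25% divergence so
#: that local alignments remain gene-length rather than collapsing onto
#: short perfect repeats.
RANK_DIVERGENCE = (0.06, 0.03, 0.02, 0.02, 0.04)

_RANK_TAGS = ("phy", "cls", "ord", "fam", "gen")

#: Probability that a new taxon reuses an existing group at each rank
#: (phylum ... family); genus is always new.
_REUSE_PROB = (0.6, 0.6, 0.6, 0.6)


@dataclass(frozen=True)
class CommunitySpec:
    """Composition and error model of a simulated read set.

    ``weights`` maps taxon id to its relative abundance (sums to 1).  Read
    lengths are drawn from a normal distribution; error rates are per-base
    probabilities.  The defaults emulate a long-read pyrosequencing run:
    mean read length 367 nt and low residual error dominated by
    homopolymer artefacts.
    """

    weights: Mapping[str, float]
    n_reads: int
    read_length_mean: float = 367.0
    read_length_sd: float = 60.0
    substitution_rate: float = 0.005
    ambiguity_rate: float = 0.002
    homopolymer_indel_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 (within 1e-9)")
        for name in ("substitution_rate", "ambiguity_rate",
                     "homopolymer_indel_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def generate_reference(
    n_taxa: int,
    seed: int,
    *,
    length_range: tuple[int, int] = (1200, 1600),
) -> list[ReferenceTaxon]:
    """A rank-structured reference database of ``n_taxa`` SSU sequences.

    Taxonomic paths form a tree: each new taxon either reuses an existing
    group or founds a new one at every rank below the shared domain, and
    sequences evolve along that tree with per-rank substitution doses
    (:data:`RANK_DIVERGENCE`), so sequence similarity mirrors taxonomic
    relatedness and distinct genera stay clearly divergent.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    root_len = int(rng.integers(length_range[0], length_range[1] + 1))
    root_seq = "".join(_BASES[i] for i in rng.integers(0, 4, root_len))

    # nodes per rank: key = group label, value = (ancestor sequence)
    group_seq: dict[str, str] = {"Bacteria": root_seq}
    group_children: dict[str, list[str]] = {}
    taxa: list[ReferenceTaxon] = []
    counter = 0

    def new_label(parent: str, rank_i: int) -> str:
        nonlocal counter
        counter += 1
        return f"{_RANK_TAGS[rank_i]}{counter:03d}"

    for t in range(n_taxa):
        path = ["Bacteria"]
        parent = "Bacteria"
        for rank_i in range(5):
            children = group_children.setdefault(parent, [])
            reuse = (
                rank_i < 4
                and children
                and rng.random() < _REUSE_PROB[rank_i]
            )
            if reuse:
                label = children[int(rng.integers(len(children)))]
            else:
                label = new_label(parent, rank_i)
                children.append(label)
                group_seq[label] = _mutate(
                    group_seq[parent], RANK_DIVERGENCE[rank_i], rng
                )
            path.append(label)
            parent = label
        taxa.append(ReferenceTaxon(
            taxon_id=f"T{t + 1:04d}",
            path=tuple(path),
            sequence=group_seq[path[-1]],
        ))
    return taxa


def _apply_homopolymer_indels(seq: str, rate: float,
                              rng: np.random.Generator) -> str:
    """Expand or contract homopolymer runs of length >= 3, the
    characteristic pyrosequencing error; one indel per affected run."""
    if rate <= 0:
        return seq
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.random() < rate * (j - i):
            if rng.random() < 0.5:
                run = run + seq[i]      # over-call: insert one base
            else:
                run = run[:-1]          # under-call: delete one base
        out.append(run)
        i = j
    return "".join(out)


def simulate_reads(
    reference: Sequence[ReferenceTaxon], spec: CommunitySpec
) -> tuple[list[Read], dict[str, str]]:
    """Draw reads from the reference community; returns (reads, truth).

    Each read is a fragment of its source taxon's sequence with
    homopolymer indels, substitutions and ambiguous bases applied at the
    per-base rates of the spec; ``truth`` maps read id to source taxon id.
    """
    if not reference:
        raise ValueError("reference is empty")
    by_id = {t.taxon_id: t for t in reference}
    unknown = set(spec.weights) - set(by_id)
    if unknown:
        raise ValueError(f"weights refer to unknown taxa: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    taxon_ids = sorted(spec.weights)
    probs = np.array([spec.weights[t] for t in taxon_ids], dtype=float)
    probs = probs / probs.sum()
    picks = rng.choice(len(taxon_ids), size=spec.n_reads, p=probs)
    reads: list[Read] = []
    truth: dict[str, str] = {}
    width = max(6, len(str(spec.n_reads)))
    for i, pick in enumerate(picks):
        taxon = by_id[taxon_ids[int(pick)]]
        source = taxon.sequence
        length = int(round(rng.normal(spec.read_length_mean,
                                      spec.read_length_sd)))
        length = max(30, min(length, len(source)))
        start = int(rng.integers(0, len(source) - length + 1))
        frag = source[start:start + length]
        frag = _apply_homopolymer_indels(frag, spec.homopolymer_indel_rate, rng)
        frag = _mutate(frag, spec.substitution_rate, rng)
        if spec.ambiguity_rate > 0:
            chars = list(frag)
            for j in np.flatnonzero(rng.random(len(chars)) < spec.ambiguity_rate):
                chars[j] = "N"
            frag = "".join(chars)
        rid = f"read{i + 1:0{width}d}"
        reads.append(Read(id=rid, bases=frag))
        truth[rid] = taxon.taxon_id
    return reads, truth


# ---------------------------------------------------------------------------
# annotation tables


@dataclass
class AnnotationTruth:
    """Seed-determined ground truth of a simulated annotation table."""

    valid_counts: dict[str, int]          # database -> rows passing the cut-offs
    category_counts: dict[str, int]


def simulate_annotations(
    n_orfs: int,
    category_fracs: Sequence[float],
    ko_pool: Sequence[str],
    gh_pool: Sequence[str],
    seed: int,
    *,
    cog_pool: Sequence[str] | None = None,
    cazy_frac: float = 0.03,
    pass_prob: float = 0.8,
) -> tuple[pd.DataFrame, AnnotationTruth]:
    """An ORF annotation table with E-values and homology percentages
    drawn from mixtures straddling the validity cut-offs (1e-5, 50%).

    ``category_fracs`` are the (hypothetical, conserved hypothetical,
    functional) fractions.  Only functional ORFs carry KEGG/COG labels and,
    with probability ``cazy_frac``, a CAZy family.  Each labelled row
    independently passes its cut-offs with probability ``pass_prob``; the
    exact surviving row counts are recorded in the returned truth object.
    """
    fracs = [float(f) for f in category_fracs]
    if len(fracs) != 3 or any(f < 0 for f in fracs):
        raise ValueError("category_fracs must be 3 nonnegative fractions")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("category_fracs must sum to 1")
    if n_orfs < 0:
        raise ValueError("n_orfs must be >= 0")
    rng = np.random.default_rng(seed)
    cog_pool = list(cog_pool) if cog_pool is not None else \
        [f"COG{i:04d}" for i in range(1, 201)]
    categories = ("hypothetical", "conserved_hypothetical", "functional")
    rows: list[dict[str, object]] = []
    valid = {"KEGG": 0, "COG": 0, "CAZy": 0}
    cat_counts = dict.fromkeys(categories, 0)

    def draw_evalue(passing: bool) -> float:
        if passing:
            return float(10.0 ** rng.uniform(-30.0, -5.5))
        return float(10.0 ** rng.uniform(-5.0, -1.0))

    def draw_homology(passing: bool) -> float:
        if passing:
            return float(np.round(rng.uniform(50.0, 100.0), 1))
        return float(np.round(rng.uniform(20.0, 49.9), 1))

    cat_draw = rng.choice(3, size=n_orfs, p=np.array(fracs) / sum(fracs))
    for i in range(n_orfs):
        orf = f"orf{i + 1:06d}"
        cat = categories[int(cat_draw[i])]
        cat_counts[cat] += 1
        row: dict[str, object] = {
            "orf_id": orf, "category": cat, "ko_id": "", "cog_id": "",
            "cazy_family": "", "evalue": "", "homology_pct": "",
        }
        if cat == "functional":
            ok = rng.random() < pass_prob
            row["ko_id"] = ko_pool[int(rng.integers(len(ko_pool)))]
            row["cog_id"] = cog_pool[int(rng.integers(len(cog_pool)))]
            row["evalue"] = draw_evalue(ok)
            if ok:
                valid["KEGG"] += 1
                valid["COG"] += 1
            if rng.random() < cazy_frac:
                cazy_ok = ok and rng.random() < pass_prob
                row["cazy_family"] = gh_pool[int(rng.integers(len(gh_pool)))]
                row["homology_pct"] = draw_homology(cazy_ok)
                if cazy_ok:
                    valid["CAZy"] += 1
        rows.append(row)
    columns = ["orf_id", "category", "ko_id", "cog_id", "cazy_family",
               "evalue", "homology_pct"]
    table = pd.DataFrame(rows, columns=columns)
    return table, AnnotationTruth(valid_counts=valid, category_counts=cat_counts)


def annotation_hits(table: pd.DataFrame) -> list["AnnotationHit"]:
    """Flatten an annotation table into per-database hits."""
    from .functional import AnnotationHit

    hits: list[AnnotationHit] = []
    for row in table.itertuples(index=False):
        if row.ko_id:
            hits.append(AnnotationHit(row.orf_id, "KEGG", row.ko_id,
                                      float(row.evalue)))
        if row.cog_id:
            hits.append(AnnotationHit(row.orf_id, "COG", row.cog_id,
                                      float(row.evalue)))
        if row.cazy_family:
            hits.append(AnnotationHit(row.orf_id, "CAZy", row.cazy_family,
                                      float(row.evalue),
                                      float(row.homology_pct)))
    return hits


# ---------------------------------------------------------------------------
# kinetics


def simulate_kinetics(
    true_activity: float,
    protein_mass_g: float,
    volume_l: float,
    epsilon: float,
    path_cm: float,
    n_points: int,
    noise_sd: float,
    seed: int,
    *,
    duration_min: float = 60.0,
    baseline_au: float = 0.05,
) -> KineticsSeries:
    """Absorbance time course implied by a known specific activity.

    Inverse of the activity computation: the slope in AU/min is
    ``activity * protein / 1e6 / volume * epsilon * path``; Gaussian noise
    of ``noise_sd`` AU is added per point.
    """
    for name, v in (("protein_mass_g", protein_mass_g), ("volume_l", volume_l),
                    ("epsilon", epsilon), ("path_cm", path_cm),
                    ("n_points", n_points), ("duration_min", duration_min)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if true_activity < 0 or noise_sd < 0:
        raise ValueError("true_activity and noise_sd must be >= 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    slope = true_activity * protein_mass_g / 1e6 / volume_l * epsilon * path_cm
    t = np.linspace(0.0, duration_min, n_points)
    a = baseline_au + slope * t
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, n_points)
    a = np.maximum(a, 0.0)
    return KineticsSeries(tuple(t), tuple(a))


# ---------------------------------------------------------------------------
# file export


def write_reference_fasta(taxa: Iterable[ReferenceTaxon], path: str | Path) -> None:
    """Reference FASTA: ``>taxon_id domain;phylum;...;genus``."""
    with open(path, "w") as fh:
        for t in taxa:
            fh.write(f">{t.taxon_id} {';'.join(t.path)}\n{t.sequence}\n")


def write_reads_fasta(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.bases}\n")


def write_ground_truth_tsv(truth: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxon_id\n")
        for rid in sorted(truth):
            fh.write(f"{rid}\t{truth[rid]}\n")


def write_annotation_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_kinetics_tsv(series: KineticsSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time_min\tabsorbance\n")
        for t, a in zip(series.times, series.absorbances):
            fh.write(f"{t:.6g}\t{a:.6g}\n")
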