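"""Functional annotation filtering and profiling (KEGG / COG / CAZy).

ORFs predicted from an assembled metagenome come with similarity-search
hits against functional databases.  A hit is accepted when its E-value is
strictly below 1e-5; CAZy (carbohydrate-active enzyme) hits additionally
require sequence homology of at least 50% (inclusive).  Accepted labels are
counted into normalised abundance profiles: per-KO percentages of all valid
KO assignments, per-GH-family percentages of all CAZy-like proteins, and
prevalence figures expressed as percent of all predicted ORFs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .profiles import AbundanceProfile, round_half_up

DATABASES = ("KEGG", "COG", "CAZy")

#: KO entries in the KEGG Orthology hierarchy used for normalisation.
DEFAULT_KO_UNIVERSE_SIZE = 20590

ORF_CATEGORIES = ("hypothetical", "conserved_hypothetical", "functional")


@dataclass(frozen=True)
class AnnotationHit:
    """One similarity-search hit of an ORF against a functional database."""

    orf_id: str
    database: str
    label: str
    evalue: float
    homology_pct: float | None = None

    def __post_init__(self) -> None:
        if self.database not in DATABASES:
            raise ValueError(f"unknown database {self.database!r}")
        if self.evalue < 0 or math.isnan(self.evalue):
            raise ValueError(f"{self.orf_id}: evalue must be >= 0")
        if self.homology_pct is not None and not 0.0 <= self.homology_pct <= 100.0:
            raise ValueError(f"{self.orf_id}: homology_pct must be in [0, 100]")


@dataclass(frozen=True)
class MatchCriteria:
    """Validity thresholds: E-value strictly below ``max_evalue``; for CAZy,
    homology of at least ``min_homology_pct`` (inclusive)."""

    max_evalue: float = 1e-5
    min_homology_pct: float = 50.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


@dataclass
class OrfCatalog:
    """ORF id -> category; categories partition the predicted gene set."""

    categories: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.categories.values()} - set(ORF_CATEGORIES)
        if bad:
            raise ValueError(f"unknown ORF categories: {sorted(bad)}")

    @property
    def total_orfs(self) -> int:
        return len(self.categories)

    def counts(self) -> dict[str, int]:
        out = dict.fromkeys(ORF_CATEGORIES, 0)
        for cat in self.categories.values():
            out[cat] += 1
        return out


def _hit_is_valid(hit: AnnotationHit, criteria: MatchCriteria) -> bool:
    if not hit.evalue < criteria.max_evalue:  # strict: exactly 1e-5 fails
        return False
    if hit.database == "CAZy":
        if hit.homology_pct is None:
            return False
        return hit.homology_pct >= criteria.min_homology_pct  # inclusive
    return True


def assign_labels(
    hits: Iterable[AnnotationHit],
    criteria: MatchCriteria = MatchCriteria(),
) -> list[AnnotationHit]:
    """Filter hits by the match criteria and keep one best label per
    (ORF, database): lowest E-value, ties broken by the lexicographically
    smallest label."""
    best: dict[tuple[str, str], AnnotationHit] = {}
    for hit in hits:
        if not _hit_is_valid(hit, criteria):
            continue
        key = (hit.orf_id, hit.database)
        cur = best.get(key)
        if cur is None or (hit.evalue, hit.label) < (cur.evalue, cur.label):
            best[key] = hit
    return sorted(best.values(), key=lambda h: (h.orf_id, h.database, h.label))


def ko_profile(
    assignments: Iterable[AnnotationHit],
    hierarchy: Mapping[str, tuple[str, str]] | None = None,
    ko_universe_size: int = DEFAULT_KO_UNIVERSE_SIZE,
) -> tuple[AbundanceProfile, AbundanceProfile | None]:
    """Per-KO counts with percentages of all valid KO assignments.

    ``hierarchy`` maps KO id -> (level-2 category, level-1 category); when
    given, a second profile rolled up to level-2 categories is returned,
    with KOs absent from the hierarchy collected into an ``"unmapped"``
    bucket (with a warning).  ``ko_universe_size`` records the size of the
    KO hierarchy the labels are drawn from; it is carried for reporting and
    does not affect normalisation, which uses total valid assignments.
    """
    kegg = [h for h in assignments if h.database == "KEGG"]
    profile = AbundanceProfile.from_labels("KO", (h.label for h in kegg), ndigits=2)
    rollup: AbundanceProfile | None = None
    if hierarchy is not None:
        unmapped = sorted({h.label for h in kegg} - set(hierarchy))
        if unmapped:
            warnings.warn(
                f"{len(unmapped)} KO label(s) not in the hierarchy "
                f"(e.g. {unmapped[0]}); counted as 'unmapped'",
                stacklevel=2,
            )
        labels = [
            hierarchy[h.label][0] if h.label in hierarchy else "unmapped"
            for h in kegg
        ]
        rollup = AbundanceProfile.from_labels("KEGG_category", labels, ndigits=2)
    return profile, rollup


def gene_family_prevalence(
    assignments: Iterable[AnnotationHit],
    family_labels: Iterable[str],
    total_orfs: int,
) -> float:
    """Percent of all ORFs carrying any of the listed labels (3 decimals)."""
    if total_orfs <= 0:
        raise ValueError("total_orfs must be > 0")
    wanted = set(family_labels)
    orfs = {h.orf_id for h in assignments if h.label in wanted}
    return round_half_up(100.0 * len(orfs) / total_orfs, 3)


def gh_family_profile(
    cazy_assignments: Iterable[AnnotationHit],
    *,
    denominator: int | None = None,
) -> AbundanceProfile:
    """Per GH/CBM family counts among CAZy-like proteins (1 decimal).

    The denominator defaults to the total number of CAZy assignments; pass
    ``denominator`` to normalise against a different total.
    """
    fams = [h.label for h in cazy_assignments if h.database == "CAZy"]
    return AbundanceProfile.from_labels("GH", fams, total=denominator, ndigits=1)


def orf_category_stats(catalog: OrfCatalog) -> dict[str, float]:
    """Percent of ORFs per category, 1 decimal.

    ``non_hypothetical`` aliases the functional category: ORFs with a
    database match of known function, as opposed to hypothetical ORFs (no
    similarity to anything) and conserved hypotheticals (similar only to
    proteins of unknown function).
    """
    total = catalog.total_orfs
    if total == 0:
        raise ValueError("catalog is empty")
    counts = catalog.counts()
    out = {cat: round_half_up(100.0 * c / total, 1) for cat, c in counts.items()}
    out["non_hypothetical"] = out["functional"]
    return out


# ---------------------------------------------------------------------------
# tabular IO

_HIT_COLUMNS = ("orf_id", "db", "label", "evalue", "homology_pct")


def read_hits_tsv(path: str | Path) -> list[AnnotationHit]:
    """Parse a hit table: orf_id, db, label, evalue, homology_pct ('' or '.'
    for absent homology).  Malformed rows raise with the 1-based line number."""
    hits: list[AnnotationHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == _HIT_COLUMNS[0]:
                continue  # header
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            try:
                homology: float | None = None
                if len(fields) >= 5 and fields[4] not in ("", "."):
                    homology = float(fields[4])
                hits.append(AnnotationHit(
                    orf_id=fields[0], database=fields[1], label=fields[2],
                    evalue=float(fields[3]), homology_pct=homology,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return hits


def read_ko_hierarchy_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    """KO hierarchy table: ko, category_level2, category_level1."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("ko", "ko_id"):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            out[fields[0]] = (fields[1], fields[2])
    return out


def write_profile_tsv(profile: AbundanceProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tlabel\tcount\tpercentage\n")
        for label, count, pct in profile.as_rows():
            fh.write(f"{profile.rank}\t{label}\t{count}\t{pct}\n")
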