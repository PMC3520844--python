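"""Labelled abundance profiles.

One container serves every counting stage of the pipeline: taxonomic read
counts per rank, KO occurrence counts, and CAZy/GH family counts.  A profile
stores raw integer counts plus a denominator; percentages are derived,
rounded half-up to a configurable number of decimals (2 for taxonomic
profiles, 1 for GH families, 3 for ORF prevalence figures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (``0.125 -> 0.13`` at 2 digits).

    Python's built-in ``round`` is banker's rounding; reported community
    percentages conventionally round half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AbundanceProfile:
    """Counts of labelled observations plus percentage normalisation.

    Parameters
    ----------
    rank:
        What the labels are (a taxonomic rank such as ``"phylum"``, or a
        database name such as ``"KO"`` or ``"GH"``).
    counts:
        Label -> nonnegative integer count.
    total:
        Denominator for percentages.  Defaults to the sum of counts; pass
        explicitly when percentages are relative to a larger universe
        (e.g. per-KO prevalence among all ORFs).
    ndigits:
        Decimals kept when reporting percentages.
    """

    rank: str
    counts: dict[str, int] = field(default_factory=dict)
    total: int | None = None
    ndigits: int = 2

    def __post_init__(self) -> None:
        for label, c in self.counts.items():
            if c < 0 or c != int(c):
                raise ValueError(f"count for {label!r} must be a nonnegative integer")
        if self.total is None:
            self.total = sum(self.counts.values())
        if self.total < 0:
            raise ValueError("total must be nonnegative")

    @classmethod
    def from_labels(cls, rank: str, labels: Iterable[str], *,
                    total: int | None = None, ndigits: int = 2) -> "AbundanceProfile":
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        return cls(rank=rank, counts=counts, total=total, ndigits=ndigits)

    def fraction(self, label: str) -> float:
        """Unrounded fraction of ``total`` for one label."""
        if self.total == 0:
            raise ValueError("profile has zero total")
        return self.counts.get(label, 0) / self.total

    @property
    def percentages(self) -> dict[str, float]:
        """Label -> percentage of ``total``, rounded half-up."""
        if self.total == 0:
            return {}
        return {
            label: round_half_up(100.0 * c / self.total, self.ndigits)
            for label, c in self.counts.items()
        }

    def percentage(self, label: str) -> float:
        if self.total == 0:
            raise ValueError("profile has zero total")
        return round_half_up(100.0 * self.counts.get(label, 0) / self.total,
                             self.ndigits)

    def as_rows(self) -> list[tuple[str, int, float]]:
        """(label, count, percentage) rows sorted by descending count then label."""
        pct = self.percentages
        return [
            (label, self.counts[label], pct[label])
            for label in sorted(self.counts, key=lambda l: (-self.counts[l], l))
        ]

    def __len__(self) -> int:
        return len(self.counts)


def merge_counts(profiles: Iterable[Mapping[str, int]]) -> dict[str, int]:
    """Sum label counts across several count mappings."""
    out: dict[str, int] = {}
    for prof in profiles:
        for label, c in prof.items():
            out[label] = out.get(label, 0) + c
    return out
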