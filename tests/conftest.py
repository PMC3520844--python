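"""Shared fixtures: tiny synthetic communities and reference oracles."""

from __future__ import annotations

import random

import pytest

from gutprof import CommunitySpec, generate_reference, simulate_reads
from gutprof.ssu import ReferenceTaxon


@pytest.fixture(scope="session")
def small_reference():
    """20 reference taxa, deterministic."""
    return generate_reference(20, seed=7)


@pytest.fixture(scope="session")
def ten_taxa():
    return generate_reference(10, seed=11)


@pytest.fixture(scope="session")
def uneven_weights(ten_taxa):
    w = [0.22, 0.18, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04, 0.03, 0.02]
    return {t.taxon_id: x for t, x in zip(ten_taxa, w)}


@pytest.fixture()
def clean_community(ten_taxa, uneven_weights):
    """1,000 error-free reads with ground truth."""
    spec = CommunitySpec(
        weights=uneven_weights, n_reads=1000,
        substitution_rate=0.0, ambiguity_rate=0.0,
        homopolymer_indel_rate=0.0, seed=11,
    )
    reads, truth = simulate_reads(ten_taxa, spec)
    return reads, truth, spec


def make_taxon(taxon_id: str, sequence: str, genus: str | None = None,
               phylum: str = "PhyA") -> ReferenceTaxon:
    """Hand-rolled reference taxon with a fixed-depth path."""
    genus = genus or f"Gen_{taxon_id}"
    return ReferenceTaxon(
        taxon_id=taxon_id,
        path=("Bacteria", phylum, "ClsA", "OrdA", "FamA", genus),
        sequence=sequence,
    )


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
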