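"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from barcodeverify.iolib import Checklist, ReferenceLibrary, ReferenceRecord, VerifyConfig
from barcodeverify.matchlib import Hit, HitTable

BASES = "ACGT"


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate_at(seq: str, sites, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in sites:
        out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def diverged(seq: str, k: int, rng: np.random.Generator) -> str:
    """Copy of seq with exactly k substituted sites."""
    sites = rng.choice(len(seq), size=k, replace=False)
    return mutate_at(seq, sites, rng)


def make_library(species_seqs: dict[str, str], locus: str = "COI") -> ReferenceLibrary:
    return ReferenceLibrary(
        ReferenceRecord(
            record_id=f"R_{sp.replace(' ', '_')}_{locus}",
            species=sp,
            locus=locus,
            sequence=seq,
        )
        for sp, seq in species_seqs.items()
    )


def make_hit_table(
    species_identities: dict[str, float],
    locus: str = "COI",
    query_id: str = "q",
    overlap: int = 300,
) -> HitTable:
    hits = sorted(
        (
            Hit(
                record_id=f"R_{sp.replace(' ', '_')}",
                species=sp,
                genus=sp.split()[0],
                identity=ident,
                overlap=overlap,
                locus=locus,
            )
            for sp, ident in species_identities.items()
        ),
        key=lambda h: (-h.identity, h.record_id),
    )
    return HitTable(query_id=query_id, locus=locus, hits=tuple(hits))


def make_checklist(species: list[str]) -> Checklist:
    cl = Checklist()
    for sp in species:
        cl.add(sp)
    return cl


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240624)


@pytest.fixture
def cfg() -> VerifyConfig:
    return VerifyConfig()
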