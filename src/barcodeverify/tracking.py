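"""Sample-tracking back-check at the genome-sequencing stage.

The barcode region is recovered from genome-scale reads (HiFi reads or
contigs — both are just templates to the in-silico PCR scan), compared with
the specimen's pre-sequencing verified barcode, and searched against the
reference library. A specimen passes when the recovered barcode is
near-identical to its own barcode and the top library match is the same
species; anything else flags a potential sample switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .insilico_pcr import PrimerSet, RecoveryFailure, recover_barcode
from .iolib import ReferenceLibrary, SynonymMap, VerifyConfig
from .matchlib import pairwise_identity, search_library


@dataclass(frozen=True)
class TrackingReport:
    specimen_id: str
    recovered: str | None
    support: int
    identity_to_specimen_barcode: float | None
    top_match_species: str | None
    same_species: bool
    verdict: str  # 'pass' | 'mismatch' | 'recovery_failed'


def track_specimen(
    specimen_id: str,
    reads: Iterable[tuple[str, str]] | Iterable[str],
    specimen_barcode: str,
    primer_sets: PrimerSet | Sequence[PrimerSet],
    library: ReferenceLibrary,
    locus: str,
    expected_species: str,
    cfg: VerifyConfig | None = None,
    synonyms: SynonymMap | None = None,
    max_mismatch: int = 2,
) -> TrackingReport:
    """Recover the barcode from reads and verify it against expectations.

    verdict 'pass' iff the top library match is the expected species (after
    synonym canonicalisation) and the recovered barcode's identity to the
    specimen's own barcode is >= ``cfg.tracking_identity_min``; recovery
    failure yields verdict 'recovery_failed' rather than an exception.
    """
    cfg = cfg or VerifyConfig()
    syn = synonyms or SynonymMap()
    try:
        rec = recover_barcode(reads, primer_sets, max_mismatch)
    except RecoveryFailure:
        return TrackingReport(
            specimen_id=specimen_id,
            recovered=None,
            support=0,
            identity_to_specimen_barcode=None,
            top_match_species=None,
            same_species=False,
            verdict="recovery_failed",
        )
    identity, _ = pairwise_identity(rec.consensus, specimen_barcode)
    ht = search_library(specimen_id, rec.consensus, library, locus, cfg)
    top_species = ht.hits[0].species if ht.hits else None
    same = (
        top_species is not None
        and syn.canonical(top_species) == syn.canonical(expected_species)
    )
    verdict = (
        "pass" if same and identity >= cfg.tracking_identity_min else "mismatch"
    )
    return TrackingReport(
        specimen_id=specimen_id,
        recovered=rec.consensus,
        support=rec.support,
        identity_to_specimen_barcode=identity,
        top_match_species=top_species,
        same_species=same,
        verdict=verdict,
    )
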