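"""Match categorisation, multi-locus combination and pipeline actions.

Each locus query is classified as definitive / consistent / inconsistent /
no_match against the reference library, taking into account how completely
the library samples the expected species' congeners (judged against a
regional checklist). Subcodes distinguish resolution-limited from
coverage-limited consistent matches (a/b) and congeneric from distant
inconsistent matches (a/b). Per-locus calls are then combined across loci
with inconsistency taking precedence, and the combined category maps to a
pipeline action: proceed to genome sequencing, proceed flagged, require
sample verification, or exempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .iolib import Checklist, ReferenceLibrary, SpecimenManifestRow, SynonymMap, VerifyConfig
from .matchlib import HitTable, top_band

CATEGORIES = ("definitive", "consistent", "inconsistent", "no_match")
#: conflict precedence when combining loci: a wrong-taxon signal on any locus
#: demands verification even if another locus matches perfectly
_PRECEDENCE = {"inconsistent": 3, "definitive": 2, "consistent": 1, "no_match": 0}


@dataclass(frozen=True)
class CoverageAssessment:
    """How well the library samples the expected species and its congeners.

    ``completeness`` is congeners_in_db / congeners_on_checklist (the
    expected species itself excluded from both counts); 1.0 when the
    checklist is silent about the genus, with a note.
    """

    species_in_db: bool
    congeners_in_db: int
    congeners_on_checklist: int
    completeness: float
    note: str = ""


@dataclass(frozen=True)
class MatchCall:
    """Per-locus category with its evidence."""

    locus: str
    category: str
    subcode: str  # 'a' | 'b' | 'none'
    band: frozenset[str]
    best_identity: float | None
    coverage: CoverageAssessment
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subcode != "none" and self.category not in ("consistent", "inconsistent"):
            raise ValueError("subcode only valid for consistent/inconsistent")


@dataclass(frozen=True)
class VerificationOutcome:
    """Combined multi-locus verdict and pipeline action for one specimen."""

    specimen_id: str
    expected_species: str
    calls: tuple[MatchCall, ...]
    combined_category: str | None
    action: str  # proceed | proceed_flagged | verify | exempt
    suggested_name: str | None = None
    hybrid_flag: bool = False
    contamination_flag: bool = False
    notes: str = ""


def assess_coverage(
    expected_species: str,
    genus: str,
    library: ReferenceLibrary,
    locus: str,
    checklist: Checklist | None = None,
) -> CoverageAssessment:
    """Count congeneric representation for the expected species at a locus.

    Genera absent from the checklist are treated as completely sampled
    (completeness 1.0) with a provenance note, since the checklist then
    offers no standard to judge the library against.
    """
    species_in_db = library.species_present(expected_species, locus)
    congeners_db = library.congener_species(genus, locus, exclude=expected_species)
    note = ""
    if checklist is not None and checklist.has_genus(genus):
        on_list = checklist.species_for(genus) - {expected_species}
        completeness = (
            len(congeners_db & on_list) / len(on_list) if on_list else 1.0
        )
        n_list = len(on_list)
    else:
        completeness = 1.0
        n_list = 0
        note = "checklist silent for genus; completeness assumed 1.0"
    return CoverageAssessment(
        species_in_db=species_in_db,
        congeners_in_db=len(congeners_db),
        congeners_on_checklist=n_list,
        completeness=completeness,
        note=note,
    )


def classify_locus(
    ht: HitTable,
    expected_species: str,
    cov: CoverageAssessment,
    cfg: VerifyConfig,
    taxon_group: str = "default",
    synonyms: SynonymMap | None = None,
) -> MatchCall:
    """Classify one locus query into a category with subcode.

    Decision procedure (total: every input reaches exactly one leaf):

    1. no hits above the near-match floor and no congeners in the library
       -> no_match (no relevant context at all);
    2. best identity >= exact_identity_min and expected in the top band:
       a. band is exactly {expected} and congener coverage complete
          -> definitive;
       b. otherwise -> consistent(a) (match to a suite of species that
          includes the target: lack of resolution, or incomplete congener
          sampling read conservatively);
    3. expected outside the band but the band contains congeners:
       a. expected species itself is in the library -> inconsistent(a)
          (well-populated library points at a congeneric misidentification
          or unrecognised intraspecific variation);
       b. expected absent from the library -> consistent(b) (right genus,
          target species missing: lack of reference data);
    4. band non-empty, entirely outside the genus, best identity within the
       group's species threshold of a full match -> inconsistent(b)
       (distantly related match: wrong name, sample switch, contamination
       or a mislabelled reference);
    5. otherwise: a near match to the expected species below the exact
       threshold counts as consistent(a); anything else is no_match
       (weak hits only).

    Step 5's first clause departs from treating only exact matches as
    informative: a 99% hit to the expected species is a near match with
    congeneric context, which the category definitions place under
    consistent rather than no_match.
    """
    syn = synonyms or SynonymMap()
    expected = syn.canonical(expected_species)
    genus = expected.split()[0]
    threshold = cfg.threshold_for(taxon_group)

    band_raw = top_band(ht, cfg)
    band = frozenset(syn.canonical(s) for s in band_raw)
    best = ht.best_identity

    if not ht.hits and cov.congeners_in_db == 0:
        return MatchCall(
            locus=ht.locus, category="no_match", subcode="none",
            band=band, best_identity=best, coverage=cov,
            notes="no near match and no congeneric representatives in database",
        )

    band_congeners = {s for s in band if s.split()[0] == genus and s != expected}

    if best is not None and best >= cfg.exact_identity_min and expected in band:
        if band == {expected} and cov.completeness >= cfg.completeness_min:
            return MatchCall(
                locus=ht.locus, category="definitive", subcode="none",
                band=band, best_identity=best, coverage=cov,
                notes="exact match with comprehensive congeneric sampling",
            )
        note = (
            "match to a suite of species including the target"
            if band != {expected}
            else "exact match but congeneric sampling incomplete"
        )
        return MatchCall(
            locus=ht.locus, category="consistent", subcode="a",
            band=band, best_identity=best, coverage=cov, notes=note,
        )

    if expected not in band and band_congeners:
        if cov.species_in_db:
            return MatchCall(
                locus=ht.locus, category="inconsistent", subcode="a",
                band=band, best_identity=best, coverage=cov,
                notes="match to a different congeneric species despite the "
                      "expected species being represented",
            )
        return MatchCall(
            locus=ht.locus, category="consistent", subcode="b",
            band=band, best_identity=best, coverage=cov,
            notes="match to the right genus; expected species absent from database",
        )

    if (
        band
        and all(s.split()[0] != genus for s in band)
        and best is not None
        and best >= 1.0 - threshold
    ):
        return MatchCall(
            locus=ht.locus, category="inconsistent", subcode="b",
            band=band, best_identity=best, coverage=cov,
            notes="strong match to a distantly related taxon",
        )

    if expected in band and best is not None and best >= 1.0 - threshold:
        return MatchCall(
            locus=ht.locus, category="consistent", subcode="a",
            band=band, best_identity=best, coverage=cov,
            notes="near match to the expected species below the exact threshold",
        )

    return MatchCall(
        locus=ht.locus, category="no_match", subcode="none",
        band=band, best_identity=best, coverage=cov,
        notes="weak hits only",
    )


def combine_loci(
    calls: Sequence[MatchCall],
    locus_expectations: Mapping[str, str] | None = None,
) -> str:
    """Combine per-locus categories into one verdict.

    Implements the dual-locus augmentation rules with precedence
    inconsistent > definitive > consistent > no_match:

    * inconsistent — at least one locus has a clear match to the wrong taxon;
    * definitive — at least one definitive locus, and every other scored
      locus has at least a consistent match whose lower resolution is
      expected for that locus (``locus_expectations[locus] == 'genus'``);
    * consistent — at least one locus matches a congeneric sample (missing
      data or no_match allowed elsewhere);
    * no_match — nothing congeneric on any locus.

    Failed loci should be omitted from ``calls`` (they enter as missing).
    """
    if not calls:
        raise ValueError("combine_loci requires at least one call")
    expectations = locus_expectations or {}
    cats = [c.category for c in calls]

    if "inconsistent" in cats:
        return "inconsistent"

    if "definitive" in cats:
        others_ok = True
        for c in calls:
            if c.category == "definitive":
                continue
            if c.category == "consistent":
                if expectations.get(c.locus, "species") != "genus":
                    others_ok = False
            else:  # no_match
                others_ok = False
        if others_ok:
            return "definitive"

    if any(c.category in ("definitive", "consistent") for c in calls):
        return "consistent"
    return "no_match"


def decide_action(
    combined: str | None,
    specimen: SpecimenManifestRow,
    hybrid_flag: bool = False,
    *,
    calls: Sequence[MatchCall] = (),
    contamination_flag: bool = False,
    cfg: VerifyConfig | None = None,
    synonyms: SynonymMap | None = None,
) -> VerificationOutcome:
    """Map the combined category (and flags) to a pipeline action.

    exempt specimens skip barcoding entirely; definitive proceeds;
    consistent proceeds (flagged when the configuration asks for review of
    consistent matches); no_match proceeds flagged (may warrant additional
    sampling or morphological reverification); inconsistent requires
    verification. A hybrid or contamination flag forces verification
    regardless of category.
    """
    cfg = cfg or VerifyConfig()
    syn = synonyms or SynonymMap()
    notes: list[str] = []

    if specimen.exempt:
        return VerificationOutcome(
            specimen_id=specimen.specimen_id,
            expected_species=specimen.expected_species,
            calls=tuple(calls),
            combined_category=None,
            action="exempt",
            notes="barcoding exemption list: submitted without barcoding",
        )
    if combined is None:
        raise ValueError("combined category required for non-exempt specimens")

    if combined == "definitive":
        action = "proceed"
    elif combined == "consistent":
        if cfg.consistent_requires_verification:
            action, _ = "verify", notes.append("consistent match held for review")
        else:
            action = "proceed_flagged"
            notes.append("consistent (not definitive) match")
    elif combined == "no_match":
        action = "proceed_flagged"
        notes.append("no match: consider additional samples or reverification")
    else:
        action = "verify"

    if hybrid_flag:
        action = "verify"
        notes.append("putative hybrid: elevated wobbles in nuclear locus; "
                     "withhold from genome sequencing pending review")
    if contamination_flag:
        action = "verify"
        notes.append("probable contamination: wobbles in uniparentally inherited locus")

    expected = syn.canonical(specimen.expected_species)
    suggested = _suggest_name(calls, expected)

    return VerificationOutcome(
        specimen_id=specimen.specimen_id,
        expected_species=specimen.expected_species,
        calls=tuple(calls),
        combined_category=combined,
        action=action,
        suggested_name=suggested,
        hybrid_flag=hybrid_flag,
        contamination_flag=contamination_flag,
        notes="; ".join(notes),
    )


def _suggest_name(calls: Sequence[MatchCall], expected: str) -> str | None:
    """A replacement name only when one non-expected species dominates every
    informative locus; disagreement defers to expert referral instead."""
    candidate_sets = []
    for c in calls:
        if c.category == "no_match" or not c.band:
            continue
        others = set(c.band) - {expected}
        candidate_sets.append(others)
    if not candidate_sets or any(not s for s in candidate_sets):
        return None
    common = set.intersection(*candidate_sets)
    if len(common) == 1:
        return next(iter(common))
    return None


def verify_specimen(
    specimen: SpecimenManifestRow,
    hit_tables: Mapping[str, HitTable],
    library: ReferenceLibrary,
    checklist: Checklist | None,
    cfg: VerifyConfig,
    synonyms: SynonymMap | None = None,
    locus_expectations: Mapping[str, str] | None = None,
    hybrid_flag: bool = False,
    contamination_flag: bool = False,
    failed_loci: Sequence[str] = (),
) -> VerificationOutcome:
    """Convenience end-to-end classification for one specimen.

    ``hit_tables`` maps each successfully sequenced locus to its hit table;
    loci listed in ``failed_loci`` (QC/merge failures) enter as missing.
    """
    syn = synonyms or SynonymMap()
    if specimen.exempt:
        return decide_action(None, specimen, cfg=cfg, synonyms=syn)
    expected = syn.canonical(specimen.expected_species)
    genus = expected.split()[0]
    calls = []
    for locus in specimen.loci:
        if locus in failed_loci or locus not in hit_tables:
            continue
        cov = assess_coverage(expected, genus, library, locus, checklist)
        calls.append(
            classify_locus(
                hit_tables[locus], expected, cov, cfg,
                taxon_group=specimen.taxon_group, synonyms=syn,
            )
        )
    if not calls:
        combined = "no_match"
        outcome = decide_action(
            combined, specimen, hybrid_flag,
            calls=(), contamination_flag=contamination_flag, cfg=cfg, synonyms=syn,
        )
        return VerificationOutcome(
            **{**outcome.__dict__, "notes": (outcome.notes + "; all loci failed QC").strip("; ")}
        )
    combined = combine_loci(calls, locus_expectations)
    return decide_action(
        combined, specimen, hybrid_flag,
        calls=calls, contamination_flag=contamination_flag, cfg=cfg, synonyms=syn,
    )
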