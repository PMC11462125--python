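"""Readers, writers, configuration and the shared domain vocabulary.

All external formats pass through here: FASTA/FASTQ sequences, the primer
catalogue, the specimen manifest, the regional taxon checklist, the synonym
map, hit tables and verification reports — every one a plain-text delimited
(tab by default) or sequence file, standing in for live database queries.

Readers reject inputs that violate the type invariants with a named error;
the only silent coercions anywhere are upper-casing and U->T.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .insilico_pcr import PrimerSet
from .iupac import DNA_CODES, PRIMER_CODES, validate
from .seqqc import TraceRead


class FormatError(ValueError):
    """An input file violates its declared format or a type invariant."""


class EmptyInputError(FormatError):
    """The input file contains no records."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SpecimenManifestRow:
    """One specimen in the sample manifest.

    ``expected_species`` is the field identification; ``loci`` the barcoding
    loci planned for the taxon group; ``exempt`` marks taxa on the barcoding
    exemption list (reliable morphology, persistently failing barcodes),
    which are submitted without barcoding being attempted.
    """

    specimen_id: str
    expected_species: str
    taxon_group: str
    loci: tuple[str, ...]
    genus: str = ""
    exempt: bool = False

    def __post_init__(self) -> None:
        if not self.genus:
            object.__setattr__(self, "genus", self.expected_species.split()[0])
        if not self.loci and not self.exempt:
            raise FormatError(
                f"specimen {self.specimen_id}: loci required unless exempt"
            )


@dataclass(frozen=True)
class ReferenceRecord:
    """One taxon-annotated barcode sequence in the reference library."""

    record_id: str
    species: str
    locus: str
    sequence: str
    family: str | None = None
    genus: str = ""

    def __post_init__(self) -> None:
        tokens = self.species.split()
        if len(tokens) < 2:
            raise FormatError(
                f"record {self.record_id}: species {self.species!r} is not a binomial"
            )
        if not self.genus:
            object.__setattr__(self, "genus", tokens[0])
        elif self.genus != tokens[0]:
            raise FormatError(
                f"record {self.record_id}: genus {self.genus!r} does not match "
                f"species {self.species!r}"
            )
        if not self.sequence:
            raise FormatError(f"record {self.record_id}: empty sequence")
        validate(self.sequence, DNA_CODES, f"record {self.record_id}")


class ReferenceLibrary:
    """Barcode records grouped by locus with a per-genus index."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self.records: list[ReferenceRecord] = list(records)
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate record_id in reference library")
        self._by_locus: dict[str, list[ReferenceRecord]] = {}
        self._genus_index: dict[tuple[str, str], list[ReferenceRecord]] = {}
        for r in self.records:
            self._by_locus.setdefault(r.locus, []).append(r)
            self._genus_index.setdefault((r.locus, r.genus), []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def loci(self) -> list[str]:
        return sorted(self._by_locus)

    def by_locus(self, locus: str) -> list[ReferenceRecord]:
        return self._by_locus.get(locus, [])

    def by_genus(self, locus: str, genus: str) -> list[ReferenceRecord]:
        return self._genus_index.get((locus, genus), [])

    def species_present(self, species: str, locus: str) -> bool:
        return any(r.species == species for r in self.by_locus(locus))

    def congener_species(self, genus: str, locus: str, exclude: str | None = None) -> set[str]:
        """Species of a genus present for the locus, optionally minus one."""
        out = {r.species for r in self.by_genus(locus, genus)}
        out.discard(exclude)
        return out


class SynonymMap:
    """Name canonicalisation through a nomenclatural synonym table.

    Lookups are case-insensitive; canonical names map to themselves, so
    canonicalisation is idempotent by construction (validated on load).
    """

    def __init__(self, pairs: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for name, canonical in (pairs or {}).items():
            self._map[name.strip().casefold()] = canonical.strip()
        for canonical in list(self._map.values()):
            key = canonical.casefold()
            if key in self._map and self._map[key] != canonical:
                raise FormatError(
                    f"synonym map not idempotent: {canonical!r} maps to "
                    f"{self._map[key]!r}"
                )
            self._map.setdefault(key, canonical)

    def canonical(self, name: str) -> str:
        return self._map.get(name.strip().casefold(), name.strip())

    def __len__(self) -> int:
        return len(self._map)


class Checklist:
    """Species known for the region, keyed by genus.

    Defines "all relevant congeneric taxa" when judging whether a reference
    library comprehensively samples a genus.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]] | None = None):
        self._entries: dict[str, set[str]] = {}
        for genus, species_list in (entries or {}).items():
            for sp in species_list:
                self.add(sp, genus)

    def add(self, species: str, genus: str | None = None) -> None:
        first = species.split()[0]
        genus = genus or first
        if first != genus:
            raise FormatError(
                f"checklist species {species!r} does not start with genus {genus!r}"
            )
        self._entries.setdefault(genus, set()).add(species)

    def species_for(self, genus: str) -> set[str]:
        return set(self._entries.get(genus, set()))

    def has_genus(self, genus: str) -> bool:
        return genus in self._entries

    def genera(self) -> list[str]:
        return sorted(self._entries)

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())


_DEFAULT_SPECIES_THRESHOLDS: dict[str, float] = {
    # conventional group-specific divergence thresholds; fully configurable
    "default": 0.02,
    "Arthropoda": 0.02,  # animal COI
    "Mollusca": 0.02,
    "Vertebrates": 0.02,
    "Seed plants": 0.01,  # plant plastid loci
    "Ferns, Lycophytes": 0.01,
    "Liverworts, Mosses, Hornworts": 0.01,
    "Fungi": 0.03,  # fungal/lichen ITS
    "Lichen-forming fungi": 0.03,
}


@dataclass(frozen=True)
class VerifyConfig:
    """Every tunable threshold of the verification engine, with defaults.

    All values are echoed into report headers for provenance. The invariant
    near_match_floor < 1 - species_threshold <= exact_identity_min <= 1 must
    hold for every taxon group.
    """

    exact_identity_min: float = 1.0
    species_threshold: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPECIES_THRESHOLDS)
    )
    near_match_floor: float = 0.80
    top_band_width: float = 0.001
    completeness_min: float = 1.0
    min_overlap_fraction: float = 0.5
    bin_threshold: float = 0.022
    wobble_hybrid_min: int = 3
    # read QC
    trim_window: int = 10
    trim_min_q: float = 20.0
    merge_min_overlap: int = 20
    merge_q_margin: int = 10
    # pipeline behaviour
    consistent_requires_verification: bool = False
    tracking_identity_min: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.exact_identity_min <= 1.0:
            raise ValueError("exact_identity_min must be in (0, 1]")
        if not 0.0 <= self.completeness_min <= 1.0:
            raise ValueError("completeness_min must be in [0, 1]")
        if self.wobble_hybrid_min < 1:
            raise ValueError("wobble_hybrid_min must be >= 1")
        for group, thr in self.species_threshold.items():
            if not self.near_match_floor < 1.0 - thr <= self.exact_identity_min:
                raise ValueError(
                    "invariant violated for taxon group "
                    f"{group!r}: need near_match_floor < 1 - species_threshold"
                    " <= exact_identity_min"
                )

    def threshold_for(self, taxon_group: str) -> float:
        return self.species_threshold.get(
            taxon_group, self.species_threshold.get("default", 0.02)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VerifyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "species_threshold" in data:
            base = dict(_DEFAULT_SPECIES_THRESHOLDS)
            base.update(data["species_threshold"])
            data["species_threshold"] = base
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def replace(self, **kw) -> "VerifyConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# sequence readers / writers


def _clean_sequence(raw: str, where: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    if "-" in seq or "." in seq:
        raise FormatError(f"gap characters not allowed in {where}")
    validate(seq, DNA_CODES, where)
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; upper-cased, U->T, gaps rejected, ids unique."""
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.seq) == 0:
                raise FormatError(f"{path}: empty sequence for {rec.id!r}")
            records.append((rec.id, _clean_sequence(rec.seq, f"record {rec.id}")))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[TraceRead]:
    """Trace reads from a 4-line FASTQ; direction from an _F/_R id suffix."""
    path = Path(path)
    reads: list[TraceRead] = []
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            if rec.id.endswith("_F"):
                direction = "forward"
            elif rec.id.endswith("_R"):
                direction = "reverse"
            else:
                raise FormatError(
                    f"{path}: read id {rec.id!r} lacks _F/_R direction suffix"
                )
            reads.append(
                TraceRead(
                    read_id=rec.id,
                    direction=direction,
                    sequence=_clean_sequence(rec.seq, f"read {rec.id}"),
                    quality=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    if not reads:
        raise EmptyInputError(f"{path}: no FASTQ records")
    return reads


def write_fastq(reads: Iterable[TraceRead], path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_reference_library(
    path: str | Path,
    taxonomy_style: str = "pipe",
    taxonomy_table: str | Path | None = None,
) -> ReferenceLibrary:
    """Reference library from FASTA with structured taxonomy.

    ``taxonomy_style='pipe'`` expects headers ``id|species|locus[|family]``;
    ``taxonomy_style='sidecar'`` expects plain ids plus a delimited table
    (columns record_id, species, locus[, family]) given as
    ``taxonomy_table``. Records whose species is not a binomial are
    quarantined with a warning rather than failing the whole load.
    """
    path = Path(path)
    entries: list[dict] = []
    if taxonomy_style == "pipe":
        with path.open() as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                header = rec.description if "|" in rec.description else rec.id
                parts = [p.strip() for p in header.split("|")]
                if len(parts) < 3:
                    raise FormatError(
                        f"{path}: header {header!r} is not id|species|locus[|family]"
                    )
                entries.append(
                    {
                        "record_id": parts[0],
                        "species": parts[1],
                        "locus": parts[2],
                        "family": parts[3] if len(parts) > 3 else None,
                        "sequence": _clean_sequence(rec.seq, f"record {parts[0]}"),
                    }
                )
    elif taxonomy_style == "sidecar":
        if taxonomy_table is None:
            raise FormatError("sidecar dialect requires taxonomy_table")
        taxa = {
            row["record_id"]: row
            for row in _read_table(taxonomy_table, {"record_id", "species", "locus"})
        }
        for rid, seq in read_fasta(path):
            if rid not in taxa:
                raise FormatError(f"{path}: record {rid!r} missing from taxonomy table")
            row = taxa[rid]
            entries.append(
                {
                    "record_id": rid,
                    "species": row["species"],
                    "locus": row["locus"],
                    "family": row.get("family") or None,
                    "sequence": seq,
                }
            )
    else:
        raise FormatError(f"unknown taxonomy_style {taxonomy_style!r}")

    records: list[ReferenceRecord] = []
    for e in entries:
        try:
            records.append(ReferenceRecord(**e))
        except FormatError as exc:
            warnings.warn(f"quarantined reference record: {exc}")
    return ReferenceLibrary(records)


def write_reference_library(library: ReferenceLibrary, path: str | Path) -> None:
    """Pipe-dialect FASTA round-trippable by :func:`read_reference_library`."""
    recs = []
    for r in library.records:
        header = f"{r.record_id}|{r.species}|{r.locus}"
        if r.family:
            header += f"|{r.family}"
        rec = SeqRecord(Seq(r.sequence), id=header, description="")
        recs.append(rec)
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# delimited tables


def _read_table(
    path: str | Path, required: set[str], delimiter: str = "\t"
) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty table")
        missing = required - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
        return [dict(row) for row in reader]


def read_primer_table(path: str | Path, delimiter: str = "\t") -> list[PrimerSet]:
    """Primer catalogue rows -> :class:`PrimerSet` list (one per F/R pair).

    Whitespace inside primer sequences (as printed in catalogue cells) is
    stripped on load; sequences are validated over IUPAC plus inosine.
    Cocktails occupy one row per pair and share taxon_group + locus.
    """
    required = {
        "taxon_group", "locus", "forward_name", "forward_seq",
        "reverse_name", "reverse_seq", "expected_len_min", "expected_len_max",
    }
    out: list[PrimerSet] = []
    for row in _read_table(path, required, delimiter):
        fseq = "".join(row["forward_seq"].split()).upper()
        rseq = "".join(row["reverse_seq"].split()).upper()
        for name, seq in ((row["forward_name"], fseq), (row["reverse_name"], rseq)):
            bad = set(seq) - PRIMER_CODES
            if bad:
                raise FormatError(
                    f"primer {name}: invalid character {sorted(bad)[0]!r}"
                )
        databases = tuple(
            d.strip() for d in row.get("databases", "").split("/") if d.strip()
        )
        out.append(
            PrimerSet(
                taxon_group=row["taxon_group"],
                locus=row["locus"],
                forward=(row["forward_name"], fseq),
                reverse=(row["reverse_name"], rseq),
                expected_len_min=int(row["expected_len_min"]),
                expected_len_max=int(row["expected_len_max"]),
                databases=databases,
                forward_tail=int(row.get("forward_tail") or 0),
                reverse_tail=int(row.get("reverse_tail") or 0),
            )
        )
    if not out:
        raise EmptyInputError(f"{path}: no primer rows")
    return out


def default_primer_catalogue() -> list[PrimerSet]:
    """The shipped locus/primer catalogue (one row per primer pair)."""
    from importlib.resources import files

    return read_primer_table(files("barcodeverify.data") / "primer_catalogue.tsv")


def read_manifest(path: str | Path, delimiter: str = "\t") -> list[SpecimenManifestRow]:
    """Specimen manifest; loci are comma-separated within the field."""
    required = {"specimen_id", "expected_species", "taxon_group", "loci"}
    rows: list[SpecimenManifestRow] = []
    seen: set[str] = set()
    for row in _read_table(path, required, delimiter):
        sid = row["specimen_id"].strip()
        if sid in seen:
            raise FormatError(f"duplicate specimen_id {sid!r} in manifest")
        seen.add(sid)
        loci = tuple(l.strip() for l in row["loci"].split(",") if l.strip())
        exempt = (row.get("exempt") or "false").strip().lower() in {"true", "1", "yes"}
        rows.append(
            SpecimenManifestRow(
                specimen_id=sid,
                expected_species=row["expected_species"].strip(),
                taxon_group=row["taxon_group"].strip(),
                loci=loci,
                genus=(row.get("genus") or "").strip(),
                exempt=exempt,
            )
        )
    if not rows:
        raise EmptyInputError(f"{path}: empty manifest")
    return rows


def read_checklist(path: str | Path, delimiter: str = "\t") -> Checklist:
    """Two-column (genus, species) regional checklist."""
    checklist = Checklist()
    for row in _read_table(path, {"genus", "species"}, delimiter):
        checklist.add(row["species"].strip(), row["genus"].strip())
    return checklist


def read_synonyms(path: str | Path, delimiter: str = "\t") -> SynonymMap:
    """Two-column (name, canonical) synonym table."""
    pairs = {
        row["name"].strip(): row["canonical"].strip()
        for row in _read_table(path, {"name", "canonical"}, delimiter)
    }
    return SynonymMap(pairs)


# ---------------------------------------------------------------------------
# reports


REPORT_COLUMNS = [
    "specimen_id", "expected_species", "combined_category", "action",
    "suggested_name", "hybrid_flag", "contamination_flag",
    "locus_calls", "notes",
]


def write_report(outcomes: Sequence, path: str | Path, cfg: VerifyConfig | None = None):
    """Write the per-specimen verification report plus a summary table.

    The report is tab-delimited with '#'-prefixed provenance lines echoing
    the configuration; the summary (category counts and percentages over
    non-exempt specimens) goes to ``<stem>_summary.tsv`` next to it. Returns
    (report_path, summary_path).
    """
    if not outcomes:
        raise ValueError("write_report requires at least one outcome")
    path = Path(path)
    buf = io.StringIO()
    if cfg is not None:
        for f in fields(cfg):
            buf.write(f"# {f.name}={getattr(cfg, f.name)}\n")
    buf.write("\t".join(REPORT_COLUMNS) + "\n")
    counts: dict[str, int] = {}
    n_scored = 0
    for o in outcomes:
        cat = o.combined_category if o.combined_category is not None else "exempt"
        if o.action != "exempt":
            counts[cat] = counts.get(cat, 0) + 1
            n_scored += 1
        locus_calls = ";".join(
            f"{c.locus}:{c.category}"
            + (f"({c.subcode})" if c.subcode != "none" else "")
            for c in o.calls
        )
        buf.write(
            "\t".join(
                [
                    o.specimen_id,
                    o.expected_species,
                    cat,
                    o.action,
                    o.suggested_name or "",
                    str(o.hybrid_flag).lower(),
                    str(o.contamination_flag).lower(),
                    locus_calls,
                    o.notes,
                ]
            )
            + "\n"
        )
    path.write_text(buf.getvalue())

    summary_path = path.with_name(path.stem + "_summary.tsv")
    with summary_path.open("w") as fh:
        fh.write("category\tcount\tpercent\n")
        for cat in sorted(counts):
            pct = 100.0 * counts[cat] / n_scored if n_scored else 0.0
            fh.write(f"{cat}\t{counts[cat]}\t{pct:.2f}\n")
        fh.write(f"total\t{n_scored}\t100.00\n")
    return path, summary_path
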