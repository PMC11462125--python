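"""Degenerate-primer site finding and in-silico amplicon extraction.

A primer binds where every primer base is IUPAC-compatible with the template
base (inosine and N match anything), allowing up to ``max_mismatch``
incompatible positions — a degenerate-aware Hamming model with no indels.
Amplicons are reported primer-inclusive in 0-based half-open forward-strand
coordinates; published amplicon sizes are treated as primer-inclusive (a
documented convention, configurable via ``strip_primers``).

M13-tailed primers carry a sequencing tail 5' of the gene-specific portion;
tails never anneal to the template, so the catalogue records their lengths
and they are trimmed before matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .iupac import PRIMER_CODES, mask, mask_array, revcomp, validate

#: default length slack as a fraction of the expected span bounds
LENGTH_SLACK_FRACTION = 0.2


class RecoveryFailure(Exception):
    """No read yielded an amplicon for the requested primer set."""


@dataclass(frozen=True)
class PrimerSet:
    """One forward/reverse primer pair for a locus (one catalogue row).

    Sequences are IUPAC plus inosine; ``forward_tail``/``reverse_tail`` give
    the number of 5' non-annealing tail bases (e.g. M13 tails) to trim before
    site matching. Expected amplicon lengths are primer-inclusive.
    """

    taxon_group: str
    locus: str
    forward: tuple[str, str]  # (name, sequence)
    reverse: tuple[str, str]
    expected_len_min: int
    expected_len_max: int
    databases: tuple[str, ...] = ()
    forward_tail: int = 0
    reverse_tail: int = 0

    def __post_init__(self) -> None:
        if self.expected_len_min > self.expected_len_max:
            raise ValueError(
                f"{self.locus}: expected_len_min > expected_len_max"
            )
        for name, seq in (self.forward, self.reverse):
            validate(seq, PRIMER_CODES, f"primer {name}")
            if len(seq) < 15:
                raise ValueError(f"primer {name} shorter than 15 nt")

    @property
    def forward_core(self) -> str:
        """Gene-specific (annealing) portion of the forward primer."""
        return self.forward[1][self.forward_tail :]

    @property
    def reverse_core(self) -> str:
        return self.reverse[1][self.reverse_tail :]


@dataclass(frozen=True)
class Amplicon:
    """A primer-inclusive amplicon on a template's forward strand."""

    template_id: str
    start: int  # 0-based, half-open
    end: int
    sequence: str  # in primer orientation (forward primer first)
    fwd_mismatches: int
    rev_mismatches: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("amplicon coordinates inconsistent with sequence")


@dataclass(frozen=True)
class RecoveredBarcode:
    """Majority-rule barcode recovered from a read set."""

    consensus: str
    support: int
    n_amplicons: int
    minority: tuple[tuple[str, int], ...] = ()
    per_read_hits: tuple[tuple[str, int], ...] = field(default=(), repr=False)


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True iff the two codes' base sets intersect ('I'/'N' match all)."""
    if primer_base not in PRIMER_CODES:
        raise ValueError(f"invalid primer base {primer_base!r}")
    if template_base not in PRIMER_CODES - {"I"}:
        raise ValueError(f"invalid template base {template_base!r}")
    return bool(mask(primer_base) & mask(template_base))


def _scan(template_masks: np.ndarray, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Positions (start, mismatches) where primer matches the forward strand."""
    m = len(primer)
    n = len(template_masks)
    if n < m:
        return []
    pm = mask_array(primer)
    windows = np.lib.stride_tricks.sliding_window_view(template_masks, m)
    mismatches = ((windows & pm) == 0).sum(axis=1)
    idx = np.nonzero(mismatches <= max_mismatch)[0]
    return [(int(i), int(mismatches[i])) for i in idx]


def find_primer_sites(
    template: str, primer: str, max_mismatch: int = 2
) -> list[tuple[int, str, int]]:
    """All (position, strand, mismatches) where the primer can anneal.

    Position is the 0-based start of the matched window on the forward
    strand for both orientations; a '-' hit means the reverse complement of
    the primer matches there (primer anneals to the forward strand and
    extends leftward). Sorted by position, '+' before '-'.
    """
    validate(primer, PRIMER_CODES, "primer")
    tm = mask_array(template)
    if (tm == 0).any():
        raise ValueError("template must be IUPAC DNA")
    hits = [(pos, "+", mm) for pos, mm in _scan(tm, primer, max_mismatch)]
    hits += [(pos, "-", mm) for pos, mm in _scan(tm, revcomp(primer), max_mismatch)]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _extract_forward(
    template: str,
    ps: PrimerSet,
    max_mismatch: int,
    slack: float,
) -> list[tuple[int, int, int, int]]:
    """(start, end, fwd_mm, rev_mm) spans on the given strand of template."""
    tm = mask_array(template)
    fwd_sites = _scan(tm, ps.forward_core, max_mismatch)
    if not fwd_sites:
        return []
    rev_sites = _scan(tm, revcomp(ps.reverse_core), max_mismatch)
    if not rev_sites:
        return []
    lo = ps.expected_len_min - int(round(slack * ps.expected_len_min))
    hi = ps.expected_len_max + int(round(slack * ps.expected_len_max))
    lr = len(ps.reverse_core)
    spans = []
    for fpos, fmm in fwd_sites:
        # shortest qualifying span per forward site
        candidates = [
            (rpos + lr - fpos, rpos, rmm)
            for rpos, rmm in rev_sites
            if rpos >= fpos and lo <= rpos + lr - fpos <= hi
        ]
        if candidates:
            span, rpos, rmm = min(candidates)
            spans.append((fpos, rpos + lr, fmm, rmm))
    return spans


def extract_amplicon(
    template: str,
    ps: PrimerSet,
    max_mismatch: int = 2,
    template_id: str = "template",
    slack: float = LENGTH_SLACK_FRACTION,
    strip_primers: bool = False,
) -> list[Amplicon]:
    """All amplicons the primer set would produce from the template.

    Both strands are considered; for each forward-primer site the shortest
    span within the slack-widened expected length window is taken. An empty
    list means no amplification (a reportable outcome, not an error).
    """
    template = template.upper().replace("U", "T")
    out: list[Amplicon] = []
    seen: set[tuple[int, int, str]] = set()
    L = len(template)
    for strand, seq in (("+", template), ("-", revcomp(template))):
        for s, e, fmm, rmm in _extract_forward(seq, ps, max_mismatch, slack):
            if strand == "+":
                start, end = s, e
                amp_seq = template[start:end]
            else:
                start, end = L - e, L - s
                amp_seq = revcomp(template[start:end])
            if (start, end, strand) in seen:
                continue
            seen.add((start, end, strand))
            if strip_primers:
                lf, lr = len(ps.forward_core), len(ps.reverse_core)
                amp_seq = amp_seq[lf : len(amp_seq) - lr]
                if strand == "+":
                    start, end = start + lf, end - lr
                else:
                    start, end = start + lr, end - lf
            out.append(
                Amplicon(
                    template_id=template_id,
                    start=start,
                    end=end,
                    sequence=amp_seq,
                    fwd_mismatches=fmm,
                    rev_mismatches=rmm,
                    strand=strand,
                )
            )
    out.sort(key=lambda a: (a.start, a.end, a.strand))
    return out


def extract_best_amplicon(
    template: str,
    primer_sets: Sequence[PrimerSet],
    max_mismatch: int = 2,
    template_id: str = "template",
) -> Amplicon | None:
    """Best single amplicon over a primer cocktail (all F x R rows).

    Catalogue cocktails are stored one pair per row; the pair with the
    fewest total primer mismatches wins (ties: earliest span, first row).
    """
    best: tuple[int, int, int] | None = None
    best_amp: Amplicon | None = None
    for k, ps in enumerate(primer_sets):
        for amp in extract_amplicon(template, ps, max_mismatch, template_id):
            key = (amp.fwd_mismatches + amp.rev_mismatches, amp.start, k)
            if best is None or key < best:
                best, best_amp = key, amp
    return best_amp


def recover_barcode(
    reads: Iterable[tuple[str, str]] | Iterable[str],
    primer_sets: PrimerSet | Sequence[PrimerSet],
    max_mismatch: int = 2,
) -> RecoveredBarcode:
    """Extract the barcode from genome-scale reads and take the majority.

    ``reads`` are (id, sequence) pairs or bare sequences of unknown
    orientation (long reads or contigs). One best amplicon is extracted per
    read; identical extracted sequences are grouped and the most frequent
    becomes the consensus (ties: lexicographically smallest). Raises
    :class:`RecoveryFailure` if no read yields an amplicon.
    """
    if isinstance(primer_sets, PrimerSet):
        primer_sets = [primer_sets]
    counts: Counter[str] = Counter()
    per_read: list[tuple[str, int]] = []
    for i, read in enumerate(reads):
        rid, seq = read if isinstance(read, tuple) else (f"read{i}", read)
        amp = extract_best_amplicon(seq, primer_sets, max_mismatch, template_id=rid)
        if amp is None:
            per_read.append((rid, 0))
        else:
            per_read.append((rid, 1))
            counts[amp.sequence] += 1
    if not counts:
        raise RecoveryFailure("no read contained both primer sites")
    consensus, support = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    minority = tuple(
        sorted(((s, c) for s, c in counts.items() if s != consensus),
               key=lambda kv: (-kv[1], kv[0]))
    )
    return RecoveredBarcode(
        consensus=consensus,
        support=support,
        n_amplicons=sum(counts.values()),
        minority=minority,
        per_read_hits=tuple(per_read),
    )
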