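"""Sanger-style read QC: quality trimming, bidirectional merging, wobbles.

Amplicons are sequenced in both directions as standard. Each directional
read is quality-trimmed, the reverse read is reverse-complemented, and the
pair is merged over their best ungapped overlap. Conflicting columns that
cannot be resolved by a clear quality advantage are encoded as IUPAC
ambiguity codes ("wobbles"); an elevated wobble count in a nuclear
ribosomal consensus flags a putative hybrid, while wobbles in uniparentally
inherited (plastid/mitochondrial) loci point at contamination instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .iupac import (
    DNA_CODES,
    compatible,
    count_wobble_codes,
    mask_array,
    revcomp,
    union_code,
    validate,
)

Support = Literal["forward-only", "reverse-only", "both-agree", "both-conflict"]

#: fraction of overlap columns that must be compatible for a merge to qualify
MIN_OVERLAP_MATCH_FRACTION = 0.8


class MergeFailure(Exception):
    """No qualifying forward/reverse overlap; route specimen to fallback."""


@dataclass(frozen=True)
class TraceRead:
    """One directional trace read with per-base phred qualities."""

    read_id: str
    direction: Literal["forward", "reverse"]
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )
        if any(q < 0 or q > 60 for q in self.quality):
            raise ValueError(f"{self.read_id}: phred values must lie in [0, 60]")
        validate(self.sequence, DNA_CODES, f"read {self.read_id}")
        object.__setattr__(self, "quality", tuple(self.quality))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MergedSequence:
    """Consensus of a forward/reverse pair with per-column provenance."""

    sequence: str
    overlap_len: int
    n_wobbles: int
    support: tuple[Support, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.sequence)


def trim_quality(read: TraceRead, window: int = 10, min_mean_q: float = 20) -> TraceRead:
    """Longest run whose every length-``window`` sliding window has mean
    quality >= ``min_mean_q``.

    Runs shorter than the window are judged on their whole-run mean; they are
    only used when no window-sized run qualifies. Ties go to the leftmost
    run. The result may be empty (all-poor read); emptiness is flagged
    downstream, not an error here.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = read.quality
    n = len(q)
    need = window * min_mean_q

    best_start, best_len = 0, 0
    if n >= window:
        # classic approach: maximal runs of consecutive qualifying windows;
        # a run of windows [i..j] covers sequence [i, j + window)
        sums = [sum(q[:window])] if n else []
        for i in range(1, n - window + 1):
            sums.append(sums[-1] - q[i - 1] + q[i + window - 1])
        i = 0
        while i < len(sums):
            if sums[i] >= need:
                j = i
                while j + 1 < len(sums) and sums[j + 1] >= need:
                    j += 1
                run_len = j - i + window
                if run_len > best_len:
                    best_start, best_len = i, run_len
                i = j + 1
            else:
                i += 1
    if best_len == 0:
        # fall back to the best sub-window-length segment with adequate mean
        limit = min(n, window - 1)
        for length in range(limit, 0, -1):
            for s in range(0, n - length + 1):
                if sum(q[s : s + length]) >= length * min_mean_q:
                    best_start, best_len = s, length
                    break
            if best_len:
                break

    return TraceRead(
        read_id=read.read_id,
        direction=read.direction,
        sequence=read.sequence[best_start : best_start + best_len],
        quality=read.quality[best_start : best_start + best_len],
    )


def _overlap_score(mf, mr, offset: int) -> tuple[int, int]:
    """(matches, overlap_len) of the ungapped layout with rc read at offset.

    ``mf``/``mr`` are iupac mask arrays of the forward and rc-reverse reads.
    """
    lo = max(0, offset)
    hi = min(len(mf), offset + len(mr))
    if hi <= lo:
        return 0, 0
    matches = int(((mf[lo:hi] & mr[lo - offset : hi - offset]) != 0).sum())
    return matches, hi - lo


def merge_reads(
    fwd: TraceRead,
    rev: TraceRead,
    min_overlap: int = 20,
    q_margin: int = 10,
) -> MergedSequence:
    """Merge a trimmed forward/reverse pair over their best ungapped overlap.

    The reverse read is reverse-complemented (qualities reversed) and slid
    against the forward read; the layout maximising compatible columns wins,
    provided the overlap is >= ``min_overlap`` columns of which >= 80% are
    compatible. Per column: agreeing bases are kept (higher-quality code on
    ambiguity vs plain base); conflicts go to the base with a quality
    advantage >= ``q_margin``, otherwise to the IUPAC union code, counted as
    a wobble. Raises :class:`MergeFailure` when no layout qualifies.
    """
    if not fwd.sequence or not rev.sequence:
        raise MergeFailure("empty read after trimming")
    rc_seq = revcomp(rev.sequence)
    rc_q = tuple(reversed(rev.quality))
    lf, lr = len(fwd), len(rc_seq)
    mf, mr = mask_array(fwd.sequence), mask_array(rc_seq)

    best: tuple[int, int, int] | None = None  # (matches, overlap, -offset)
    best_offset = 0
    for offset in range(-(lr - min_overlap), lf - min_overlap + 1):
        matches, ov = _overlap_score(mf, mr, offset)
        if ov < min_overlap or matches < MIN_OVERLAP_MATCH_FRACTION * ov:
            continue
        key = (matches, ov, -offset)
        if best is None or key > best:
            best, best_offset = key, offset
    if best is None:
        raise MergeFailure(
            f"no overlap >= {min_overlap} with >= "
            f"{MIN_OVERLAP_MATCH_FRACTION:.0%} compatible columns"
        )

    offset = best_offset
    start = min(0, offset)
    end = max(lf, offset + lr)
    seq_chars: list[str] = []
    support: list[Support] = []
    n_wobbles = 0
    for pos in range(start, end):
        f_ok = 0 <= pos < lf
        r_ok = 0 <= pos - offset < lr
        if f_ok and r_ok:
            fb, rb = fwd.sequence[pos], rc_seq[pos - offset]
            fq, rq = fwd.quality[pos], rc_q[pos - offset]
            if compatible(fb, rb):
                # agreement: prefer the more specific call, quality breaks ties
                if fb == rb:
                    base = fb
                elif fb == "N":
                    base = rb
                elif rb == "N":
                    base = fb
                else:
                    base = fb if fq >= rq else rb
                support.append("both-agree")
            else:
                support.append("both-conflict")
                if fq - rq >= q_margin:
                    base = fb
                elif rq - fq >= q_margin:
                    base = rb
                else:
                    base = union_code(fb, rb)
                    n_wobbles += 1
            seq_chars.append(base)
        elif f_ok:
            seq_chars.append(fwd.sequence[pos])
            support.append("forward-only")
        else:
            seq_chars.append(rc_seq[pos - offset])
            support.append("reverse-only")

    return MergedSequence(
        sequence="".join(seq_chars),
        overlap_len=best[1],
        n_wobbles=n_wobbles,
        support=tuple(support),
    )


def count_wobbles(seq: str) -> int:
    """Number of two-base ambiguity codes {R,Y,S,W,K,M} in ``seq``.

    N and three-base codes signal low quality rather than heterozygosity and
    are excluded; report them separately if needed.
    """
    return count_wobble_codes(seq)


def flag_hybrid(merged: MergedSequence, cfg, nuclear: bool = True) -> bool:
    """True iff a nuclear-locus consensus carries enough wobbles to suggest
    a hybrid (biparental inheritance required for the signal to make sense).

    ``cfg`` is a :class:`~barcodeverify.iolib.VerifyConfig` (or anything with
    ``wobble_hybrid_min``). For plastid/mitochondrial loci the same wobble
    signal indicates probable contamination and this flag stays False.
    """
    if not nuclear:
        return False
    return merged.n_wobbles >= cfg.wobble_hybrid_min
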