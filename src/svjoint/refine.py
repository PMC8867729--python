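"""Breakpoint and sequence refinement of noisy long-read SV calls.

Long-read callers report breakpoints and insertion sequences derived from
error-prone reads (8-10% base error), so both can be off by tens of bases.
The refinement pipeline rebuilds each DEL/INS call from the raw reads:

1. collect reads mapped within ``flank`` bp of the call,
2. build a polished consensus of the local haplotype,
3. split-align the consensus to the local reference window (one excised /
   inserted block between two aligned flanks),
4. adopt the alignment's breakpoints and insertion sequence when they are
   trustworthy, otherwise fall back to the original representation.

Duplications and inversions are not refined; their internal structure is not
representable as a single excision/insertion event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import edlib

from ._align import SplitAlignment, split_align
from .sv_io import SVRecord

__all__ = ["RefineParams", "RefineOutcome", "MappedRead",
           "extract_window_reads", "build_consensus", "age_align",
           "refine_sv", "refine_callset"]


@dataclass(frozen=True)
class RefineParams:
    flank: int = 200  # bp of reference context on each side of the call
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_flank_identity: float = 0.9
    min_flank_len: int = 20  # bp each aligned flank block must cover
    max_rel_size_change: float = 0.25
    min_reads: int = 3  # mirrors the caller's minimum read support
    #: residual bases tolerated on the other side of the event (alignment slop)
    max_other_event: int = 10

    def __post_init__(self):
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if not 0 < self.min_flank_identity <= 1:
            raise ValueError("min_flank_identity must be in (0, 1]")


@dataclass(frozen=True)
class MappedRead:
    """A read sequence with its mapped reference interval (0-based half-open)."""

    id: str
    seq: str
    chrom: str
    start: int
    end: int


@dataclass
class RefineOutcome:
    record: SVRecord
    status: str  # "refined" or "fallback"
    reason: str


def extract_window_reads(reads: Sequence[MappedRead], sv: SVRecord,
                         flank: int = 200, min_reads: int = 3) -> list:
    """Reads whose mapped interval overlaps the SV window +- ``flank``.

    Returns an empty list when fewer than ``min_reads`` reads overlap, which
    signals that the call cannot be refined and must fall back.
    """
    w_start = max(0, sv.pos - 1 - flank)
    w_end = sv.end + flank
    hits = [r.seq for r in reads
            if r.chrom == sv.chrom and r.start < w_end and w_start < r.end]
    return hits if len(hits) >= min_reads else []


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def build_consensus(reads: Sequence[str]) -> str:
    """Majority consensus of reads covering one local window.

    The read with the smallest total edit distance to all others is used as
    the backbone; every read is then globally aligned to it and each backbone
    column is polished by majority vote (substitutions and deletions), with
    insertions applied when more than half of the reads support the same
    inserted sequence at the same backbone position.  With identical
    error-free reads the consensus equals the read sequence exactly.
    """
    if not reads:
        raise ValueError("cannot build a consensus from zero reads")
    if len(reads) == 1:
        return reads[0]
    totals = []
    for i, r in enumerate(reads):
        totals.append(sum(_edit_distance(r, other)
                          for j, other in enumerate(reads) if j != i))
    backbone = reads[min(range(len(reads)), key=lambda i: totals[i])]

    n = len(backbone)
    base_votes = [Counter() for _ in range(n)]  # base or "-" per column
    ins_votes = [Counter() for _ in range(n + 1)]  # insertion before column i
    for read in reads:
        res = edlib.align(read, backbone, mode="NW", task="path")
        qi = bi = 0
        for length, op in _parse_cigar(res["cigar"]):
            if op in "=X":
                for _ in range(length):
                    base_votes[bi][read[qi]] += 1
                    qi += 1
                    bi += 1
            elif op == "D":  # gap in read: vote for deleting backbone bases
                for _ in range(length):
                    base_votes[bi]["-"] += 1
                    bi += 1
            elif op == "I":  # extra read bases between backbone columns
                ins_votes[bi][read[qi:qi + length]] += 1
                qi += length
    half = len(reads) / 2
    out = []
    for i in range(n + 1):
        if ins_votes[i]:
            seq, cnt = ins_votes[i].most_common(1)[0]
            if cnt > half:
                out.append(seq)
        if i < n:
            base, _ = base_votes[i].most_common(1)[0]
            if base != "-":
                out.append(base)
    return "".join(out)


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def age_align(query: str, reference_region: str,
              params: RefineParams = RefineParams()) -> SplitAlignment:
    """Split alignment of a consensus against the local reference region.

    Maximizes the summed local-alignment scores of a left and a right flank
    block over all split points; the skipped middle portions are the excised
    reference interval and the inserted query interval.
    """
    return split_align(query, reference_region, match=params.match,
                       mismatch=params.mismatch, gap_open=params.gap_open,
                       gap_extend=params.gap_extend)


def _classify_event(aln: SplitAlignment, params: RefineParams) -> Optional[str]:
    """The single event type shown by a split alignment, if any."""
    exc, ins = aln.excised_len, aln.inserted_len
    if exc > 0 and ins <= params.max_other_event and exc > ins:
        return "DEL"
    if ins > 0 and exc <= params.max_other_event and ins > exc:
        return "INS"
    return None


def refine_sv(sv: SVRecord, consensus: str, reference: dict,
              params: RefineParams = RefineParams()) -> RefineOutcome:
    """Refine one DEL/INS call from a local consensus sequence.

    The record is updated iff the split alignment shows exactly one event of
    the call's type, both flank blocks align with identity >=
    ``min_flank_identity`` over at least ``min_flank_len`` reference bp, and
    the refined length is within ``max_rel_size_change`` of the original.
    Any other outcome keeps the input record bit-for-bit (fallback).
    """
    if sv.svtype not in ("DEL", "INS"):
        raise ValueError("only deletions and insertions are refined; "
                         f"got {sv.svtype}")
    chrom_seq = reference[sv.chrom]
    w_start = max(0, sv.pos - 1 - params.flank)  # 0-based
    w_end = min(len(chrom_seq), sv.end + params.flank)
    region = chrom_seq[w_start:w_end]
    if not consensus:
        return RefineOutcome(sv, "fallback", "no_consensus")
    aln = age_align(consensus, region, params)

    for side, block in (("left", aln.left_block), ("right", aln.right_block)):
        if block.ref[1] - block.ref[0] < params.min_flank_len:
            return RefineOutcome(sv, "fallback", f"{side}_flank_too_short")
        if block.identity < params.min_flank_identity:
            return RefineOutcome(sv, "fallback", f"{side}_flank_identity")
    event = _classify_event(aln, params)
    if event != sv.svtype:
        return RefineOutcome(sv, "fallback", "no_matching_event")

    if event == "DEL":
        new_len = aln.excised_len
    else:
        new_len = aln.inserted_len
    if abs(new_len - sv.length) / sv.length > params.max_rel_size_change:
        return RefineOutcome(sv, "fallback", "size_change")

    if event == "DEL":
        s, e = aln.excised_ref
        pos = w_start + s  # 1-based anchor = base before the deleted span
        if pos < 1:
            return RefineOutcome(sv, "fallback", "window_edge")
        anchor = chrom_seq[pos - 1]
        ref_al, alt_al = anchor + chrom_seq[pos:pos + new_len], anchor
    else:
        qs, qe = aln.inserted_query
        s = aln.excised_ref[0]  # insertion point in region coordinates
        pos = w_start + s
        if pos < 1:
            return RefineOutcome(sv, "fallback", "window_edge")
        anchor = chrom_seq[pos - 1]
        ref_al, alt_al = anchor, anchor + consensus[qs:qe]
    # standardize the representation, as the pipeline does after refinement
    from .sv_io import left_normalize
    pos, ref_al, alt_al = left_normalize(chrom_seq, pos, ref_al, alt_al)
    refined = replace(sv, pos=pos, length=new_len, ref_allele=ref_al,
                      alt_allele=alt_al, refined=True)
    return RefineOutcome(refined, "refined", "ok")


def refine_callset(records: Sequence[SVRecord], reads: Sequence[MappedRead],
                   reference: dict,
                   params: RefineParams = RefineParams()) -> list:
    """Refine every DEL/INS record of a call set; other types pass through."""
    outcomes = []
    for sv in records:
        if sv.svtype not in ("DEL", "INS"):
            outcomes.append(RefineOutcome(sv, "fallback", "type_not_refined"))
            continue
        window = extract_window_reads(reads, sv, params.flank, params.min_reads)
        if not window:
            outcomes.append(RefineOutcome(sv, "fallback", "too_few_reads"))
            continue
        consensus = build_consensus(window)
        outcomes.append(refine_sv(sv, consensus, reference, params))
    return outcomes
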