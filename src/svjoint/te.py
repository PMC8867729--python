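"""Transposable-element classification of SVs and MITE structure analysis.

Deleted or inserted sequences of at least 100 bp are queried against a TE
library; a hit covering at least 80% of both the query and the TE sequence
annotates the SV with the best-matching TE's classification.  For DNA-TE
insertions at MITE scale, terminal inverted repeats (TIRs) and target-site
duplications (TSDs) are located directly from the insertion sequence and its
flanks, and the TIR match proportion quantifies how intact (potentially
active) the element is.  A three-allele analysis contrasts SNV haplotypes
between samples carrying a TE insertion, samples without it, and samples
carrying a short excision footprint at the same site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .benchmark import GT_AA, GT_MISSING, GT_RA, GT_RR, GenotypeMatrix
from .sv_io import SVRecord, _revcomp

TE_CLASSES = ("Copia_LTR", "Gypsy_LTR", "nonLTR", "DNA")


@dataclass(frozen=True)
class TEEntry:
    te_id: str
    seq: str
    te_class: str
    superfamily: str


@dataclass(frozen=True)
class TEAnnotation:
    sv_id: str
    te_id: str
    te_class: str
    superfamily: str
    query_cov: float
    subject_cov: float


@dataclass(frozen=True)
class TIRReport:
    tir_left: str
    tir_right: str
    tsd: str
    match_proportion: float


@dataclass
class ExcisionGroups:
    groups: dict  # allele in {absent, present, excised} -> list of samples
    snv_freqs: pd.DataFrame  # SNV id x group alternate-allele frequency
    contrasting: dict  # (group_a, group_b) -> count of SNVs with |df| > 0.5
    contrast_threshold: float = 0.5


# ---------------------------------------------------------------------------
# TE library and annotation
# ---------------------------------------------------------------------------

def read_te_library(fasta_path, metadata_path) -> list:
    """Load TE sequences (FASTA) and their classification (TSV with columns
    te_id, te_class, superfamily) into TEEntry objects."""
    from .sv_io import read_fasta
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    entries = []
    for _, row in meta.iterrows():
        if row["te_id"] not in seqs:
            raise ValueError(f"TE {row['te_id']} missing from library FASTA")
        entries.append(TEEntry(te_id=row["te_id"], seq=seqs[row["te_id"]],
                               te_class=row["te_class"],
                               superfamily=row["superfamily"]))
    return entries


def _local_hit(query: str, subject: str):
    """Best local alignment of query vs subject.

    Returns (score, q_start, q_end, s_start, s_end) or None.
    """
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    q = bseq.NucleotideSequence(query)
    s = bseq.NucleotideSequence(subject)
    matrix = balign.SubstitutionMatrix.std_nucleotide_matrix()
    alns = balign.align_optimal(q, s, matrix, gap_penalty=(-10, -1),
                                local=True, max_number=1)
    if not alns:
        return None
    aln = alns[0]
    trace = aln.trace
    q_cols = trace[:, 0][trace[:, 0] >= 0]
    s_cols = trace[:, 1][trace[:, 1] >= 0]
    if len(q_cols) == 0 or len(s_cols) == 0:
        return None
    return (aln.score, int(q_cols.min()), int(q_cols.max()) + 1,
            int(s_cols.min()), int(s_cols.max()) + 1)


def annotate_te(record: SVRecord, library: Sequence[TEEntry],
                min_len: int = 100, min_query_cov: float = 0.8,
                min_subject_cov: float = 0.8) -> Optional[TEAnnotation]:
    """Annotate one DEL/INS with the best-matching TE, or None.

    A hit passes when the local alignment covers at least ``min_query_cov``
    of the variant sequence and ``min_subject_cov`` of the TE sequence
    (the strict subject-coverage requirement is what keeps truncated or
    partial matches, e.g. solo fragments of long elements, unannotated).
    """
    if record.svtype not in ("DEL", "INS"):
        return None
    query = record.variant_seq
    if len(query) < min_len:
        return None
    best, best_score = None, -1
    for te in library:
        # cheap infix pre-screen before the O(nm) local alignment
        screen = edlib.align(query, te.seq, mode="HW", task="distance",
                             k=int(0.4 * len(query)))
        if screen["editDistance"] == -1 and len(query) <= len(te.seq):
            continue
        hit = _local_hit(query, te.seq)
        if hit is None:
            continue
        score, qs, qe, ss, se = hit
        qcov = (qe - qs) / len(query)
        scov = (se - ss) / len(te.seq)
        if qcov >= min_query_cov and scov >= min_subject_cov and \
                score > best_score:
            best_score = score
            best = TEAnnotation(sv_id=record.id, te_id=te.te_id,
                                te_class=te.te_class,
                                superfamily=te.superfamily,
                                query_cov=qcov, subject_cov=scov)
    return best


def annotate_te_from_hits(record: SVRecord, hits: pd.DataFrame,
                          te_meta: Dict[str, TEEntry], min_len: int = 100,
                          min_query_cov: float = 0.8,
                          min_subject_cov: float = 0.8) -> Optional[TEAnnotation]:
    """Annotate from an imported 12-column tabular alignment report.

    ``hits`` uses the standard columns (qseqid, sseqid, pident, length,
    mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore) with
    1-based inclusive coordinates, so externally computed reports can replace
    the internal aligner.
    """
    query_len = len(record.variant_seq)
    if query_len < min_len:
        return None
    sub = hits[hits["qseqid"] == record.id]
    best, best_score = None, -1.0
    for _, row in sub.iterrows():
        te = te_meta[row["sseqid"]]
        qcov = (abs(row["qend"] - row["qstart"]) + 1) / query_len
        scov = (abs(row["send"] - row["sstart"]) + 1) / len(te.seq)
        if qcov >= min_query_cov and scov >= min_subject_cov and \
                row["bitscore"] > best_score:
            best_score = row["bitscore"]
            best = TEAnnotation(sv_id=record.id, te_id=te.te_id,
                                te_class=te.te_class,
                                superfamily=te.superfamily,
                                query_cov=min(qcov, 1.0),
                                subject_cov=min(scov, 1.0))
    return best


# ---------------------------------------------------------------------------
# TIR / TSD identification
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def find_tir_tsd(sequence: str, flank: int, min_seed: int = 10,
                 max_mismatch_frac: float = 0.2, max_end_offset: int = 5,
                 tsd_range: tuple = (2, 10)) -> Optional[TIRReport]:
    """Locate the terminal inverted repeat pair and TSD of an insertion.

    ``sequence`` is the inserted sequence plus ``flank`` bp of genomic context
    on each side.  The longest inverted-repeat pair beginning within
    ``max_end_offset`` bp of the insertion ends, with length >= ``min_seed``
    and at most ``max_mismatch_frac`` mismatching positions, is reported
    together with the direct repeat shared by the two flanks (the TSD), when
    one of length 2-10 bp is present.  Returns None when no TIR pair exists.
    """
    sequence = sequence.upper()
    ins = sequence[flank:len(sequence) - flank]
    n = len(ins)
    if n < 2 * min_seed:
        return None
    best = None  # (score, -a, -b, -L, matches) -> maximize
    for a in range(max_end_offset + 1):
        for b in range(max_end_offset + 1):
            lmax = (n - a - b) // 2
            if lmax < min_seed:
                continue
            # match indicator between ins[a+k] and complement of ins[n-1-b-k]
            matches = np.empty(lmax, dtype=np.int32)
            for k in range(lmax):
                matches[k] = ins[a + k] == _COMP.get(ins[n - 1 - b - k], "N")
            csum = np.cumsum(matches)
            lengths = np.arange(1, lmax + 1)
            ok = (lengths >= min_seed) & \
                 (lengths - csum <= max_mismatch_frac * lengths)
            if not ok.any():
                continue
            # score rewards matches and penalizes mismatches (changepoint
            # likelihood ratio) so the repeat does not extend into sequence
            # that matches by chance; end offsets are mildly penalized so the
            # repeat stays anchored at the insertion boundaries
            scores = np.where(ok, 3 * csum - 2 * lengths, -10 ** 9)
            # on exact score ties prefer the longer repeat: a tie means the
            # extension is exactly score-neutral, and terminal repeats are
            # maximal by definition
            idx = len(scores) - 1 - int(np.argmax(scores[::-1]))
            L = int(lengths[idx])
            cand = (int(scores.max()) - (a + b), -a, -b, -L,
                    int(csum[L - 1]))
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    _score, na, nb, nL, m = best
    a, b, L = -na, -nb, -nL
    tir_left = ins[a:a + L]
    tir_right = ins[n - b - L:n - b]
    tsd = ""
    for k in range(tsd_range[1], tsd_range[0] - 1, -1):
        if flank >= k and sequence[flank - k:flank] == \
                sequence[len(sequence) - flank:len(sequence) - flank + k]:
            tsd = sequence[flank - k:flank]
            break
    return TIRReport(tir_left=tir_left, tir_right=tir_right, tsd=tsd,
                     match_proportion=m / L)


def tir_match_proportion(tir_left: str, tir_right: str) -> float:
    """Proportion of matching nucleotides between the two terminal repeats.

    Computed as 1 - d / max(len), where d is the global edit distance of the
    left TIR against the reverse complement of the right TIR; this equals
    matches / alignment columns for substitution-only differences and is
    exactly symmetric in its arguments.
    """
    if not tir_left or not tir_right:
        raise ValueError("empty TIR sequence")
    target = _revcomp(tir_right.upper())
    d = edlib.align(tir_left.upper(), target, mode="NW",
                    task="distance")["editDistance"]
    return 1.0 - d / max(len(tir_left), len(target))


# ---------------------------------------------------------------------------
# insertion vs excision haplotype analysis
# ---------------------------------------------------------------------------

def assign_excision_groups(matrix: GenotypeMatrix, te_sv_id: str,
                           footprint_sv_id: str) -> dict:
    """Partition samples by their homozygous allele at a three-allele site.

    ``present`` = homozygous for the TE insertion, ``excised`` = homozygous
    for the short footprint insertion, ``absent`` = homozygous reference at
    both; heterozygous or missing samples are left out.
    """
    te_row = matrix.gt.loc[te_sv_id]
    fp_row = matrix.gt.loc[footprint_sv_id]
    groups = {"absent": [], "present": [], "excised": []}
    for sample in matrix.samples:
        te_gt, fp_gt = te_row[sample], fp_row[sample]
        if te_gt == GT_AA and fp_gt in (GT_RR, GT_MISSING):
            groups["present"].append(sample)
        elif fp_gt == GT_AA and te_gt in (GT_RR, GT_MISSING):
            groups["excised"].append(sample)
        elif te_gt == GT_RR and fp_gt == GT_RR:
            groups["absent"].append(sample)
    return groups


def is_excision_footprint(record: SVRecord, site_pos: int, tsd: str,
                          max_dist: int = 20, max_len: int = 10) -> bool:
    """Candidate excision footprint: a short insertion at the TE site whose
    first bases equal the TSD left behind by the cut-and-paste excision."""
    return (record.svtype == "INS" and record.length <= max_len
            and abs(record.pos - site_pos) <= max_dist
            and record.variant_seq.upper().startswith(tsd.upper()))


def excision_analysis(groups: dict, snv_matrix: GenotypeMatrix,
                      region: tuple,
                      contrast_threshold: float = 0.5) -> ExcisionGroups:
    """Per-group SNV allele frequencies and contrasting-SNV counts.

    ``region`` is (chrom, start, end) with 1-based inclusive bounds limiting
    the SNVs considered (the linkage block around the insertion site).  For
    each pair of groups, a SNV is *contrasting* when the absolute difference
    of its alternate-allele frequencies exceeds ``contrast_threshold``.
    """
    chrom, start, end = region
    snvs = [sv for sv in snv_matrix.svs
            if sv.chrom == chrom and start <= sv.pos <= end]
    ids = [sv.id for sv in snvs]
    freqs = {}
    for group in sorted(groups):
        samples = groups[group]
        if not samples:
            freqs[group] = pd.Series(np.nan, index=ids)
            continue
        gt = snv_matrix.gt.loc[ids, samples]
        non_missing = (gt != GT_MISSING).sum(axis=1)
        alt = 2 * (gt == GT_AA).sum(axis=1) + (gt == GT_RA).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freqs[group] = alt / (2 * non_missing)
    freq_frame = pd.DataFrame(freqs)
    contrasting = {}
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = (freq_frame[a] - freq_frame[b]).abs()
            contrasting[(a, b)] = int((diff > contrast_threshold).sum())
    return ExcisionGroups(groups=groups, snv_freqs=freq_frame,
                          contrasting=contrasting,
                          contrast_threshold=contrast_threshold)
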