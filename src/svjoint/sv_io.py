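"""Domain types, standard-format I/O, and normalization of raw SV call sets.

Coordinate conventions
----------------------
``SVRecord`` and all VCF-facing code use 1-based inclusive coordinates (VCF
convention, with ``pos`` the padded anchor base).  All internal interval
arithmetic (N-gap overlap, repeat overlap, genic annotation) uses 0-based
half-open intervals; conversion happens only at the I/O boundary.

For a deletion/duplication/inversion of span ``length``, ``end = pos + length``
(the affected bases are ``pos+1 .. end`` in 1-based coordinates).  For an
insertion, ``end = pos``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV")

#: Size-class bin edges in bp; half-open binning, e.g. [50, 100).
SIZE_CLASS_EDGES = (50, 100, 1_000, 10_000)
SIZE_CLASS_LABELS = ("[50,100)", "[100,1k)", "[1k,10k)", ">=10k")

#: VCF breakend join classes.  ``t`` is the anchor base at the record's own
#: position; the bracket encodes which side of the mate it joins and in which
#: orientation: "t[" = t followed by mate's right side, "]t" = mate's left
#: side followed by t, "t]" / "[t" = same-sided (inverted) joins.
BND_ORIENTATIONS = ("t[", "t]", "]t", "[t")
_BND_RECIPROCAL = {"t[": "]t", "]t": "t[", "t]": "t]", "[t": "[t"}

_ALLELE_ALPHABET = frozenset("ACGTN")


class SVFormatError(ValueError):
    """Raised for structurally invalid SV records or files."""


@dataclass
class SVRecord:
    """One sequence-explicit structural variant (DEL/INS/DUP/INV).

    Alleles are literal nucleotide strings over {A,C,G,T,N}, padded with the
    anchor base as in a normalized VCF; symbolic tokens such as ``<DEL>`` are
    never stored (they are expanded against the reference at read time).
    """

    id: str
    chrom: str
    pos: int  # 1-based anchor base
    svtype: str
    length: int
    ref_allele: str
    alt_allele: str
    source_tools: frozenset = frozenset()
    tech: str = "illumina"  # "illumina" or "nanopore"
    refined: bool = False
    source_gt: Optional[str] = None  # "hom"/"het" genotype in the source call set

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise SVFormatError(f"unknown svtype {self.svtype!r}")
        if self.length < 1:
            raise SVFormatError(f"non-positive SV length {self.length}")
        if self.tech not in ("illumina", "nanopore"):
            raise SVFormatError(f"unknown tech {self.tech!r}")
        self.source_tools = frozenset(self.source_tools)

    @property
    def end(self) -> int:
        """1-based inclusive end; equals ``pos`` for insertions."""
        return self.pos if self.svtype == "INS" else self.pos + self.length

    def span0(self) -> tuple[int, int]:
        """Affected reference interval, 0-based half-open.

        Insertions are represented by their single anchor base.
        """
        if self.svtype == "INS":
            return (self.pos - 1, self.pos)
        return (self.pos, self.end)

    @property
    def variant_seq(self) -> str:
        """The gained (INS/DUP) or lost (DEL) or rearranged (INV) sequence."""
        if self.svtype == "DEL":
            return self.ref_allele[len(self.alt_allele):] if len(
                self.ref_allele) > len(self.alt_allele) else self.ref_allele[1:]
        if self.svtype in ("INS", "DUP"):
            return self.alt_allele[len(self.ref_allele):] if len(
                self.alt_allele) > len(self.ref_allele) else self.alt_allele[1:]
        return self.alt_allele[1:]  # INV: the inverted span


@dataclass(frozen=True)
class BreakendRecord:
    """One side of a VCF breakend (BND) pair."""

    chrom: str
    pos: int
    mate_chrom: str
    mate_pos: int
    orientation: str  # one of BND_ORIENTATIONS

    def __post_init__(self) -> None:
        if self.orientation not in BND_ORIENTATIONS:
            raise SVFormatError(f"unknown BND orientation {self.orientation!r}")


@dataclass(frozen=True)
class Gene:
    """Gene model with CDS sub-intervals, 0-based half-open internally."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: tuple = ()


@dataclass
class GenomeAnnotation:
    """Reference sequences plus gene/repeat tracks used by the pipeline."""

    reference: dict  # chrom -> sequence string
    genes: list = field(default_factory=list)  # list[Gene]
    repeats: list = field(default_factory=list)  # list[(chrom, start0, end0)]
    chrom_whitelist: Optional[set] = None

    def __post_init__(self) -> None:
        if self.chrom_whitelist is None:
            self.chrom_whitelist = set(self.reference)
        self._n_runs = {}

    def chrom_len(self, chrom: str) -> int:
        return len(self.reference[chrom])

    def n_runs(self, chrom: str) -> list:
        """Maximal runs of N in the reference, 0-based half-open, cached."""
        if chrom not in self._n_runs:
            seq = self.reference[chrom]
            runs, i = [], 0
            while True:
                j = seq.find("N", i)
                if j < 0:
                    break
                k = j
                while k < len(seq) and seq[k] == "N":
                    k += 1
                runs.append((j, k))
                i = k
            self._n_runs[chrom] = runs
        return self._n_runs[chrom]


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the common SV call-set filters."""

    min_length: int = 50
    max_length: int = 500_000
    drop_heterozygous_nanopore: bool = True
    min_n_distance_ins: int = 20  # bp between an insertion anchor and any N
    genotyping_prep: bool = False  # also drop calls near chromosome ends
    end_distance: int = 1_000


# ---------------------------------------------------------------------------
# size classes
# ---------------------------------------------------------------------------

def assign_size_class(record_or_length) -> str:
    """Half-open size-class binning at 100 bp, 1 kb and 10 kb."""
    length = getattr(record_or_length, "length", record_or_length)
    if length < SIZE_CLASS_EDGES[0]:
        raise ValueError(f"SV length {length} below {SIZE_CLASS_EDGES[0]} bp; "
                         "should have been filtered")
    for edge, label in zip(SIZE_CLASS_EDGES[1:], SIZE_CLASS_LABELS):
        if length < edge:
            return label
    return SIZE_CLASS_LABELS[-1]


# ---------------------------------------------------------------------------
# breakend classification
# ---------------------------------------------------------------------------

def classify_breakend_pair(a: BreakendRecord, b: BreakendRecord) -> Optional[str]:
    """Classify a reciprocal breakend pair into DEL/DUP/INV.

    The left breakend joining rightward onto the left side of the right
    breakend is a deletion junction; the reciprocal outward-facing pair is a
    tandem-duplication junction; two same-sided joins form an inversion
    junction.  Inter-chromosomal or non-reciprocal pairs are unresolvable.
    """
    if a.chrom != b.chrom or a.chrom != a.mate_chrom or b.chrom != b.mate_chrom:
        return None
    if not (a.mate_pos == b.pos and b.mate_pos == a.pos
            and _BND_RECIPROCAL[a.orientation] == b.orientation):
        logger.warning("non-reciprocal breakend mates at %s:%d/%d",
                       a.chrom, a.pos, b.pos)
        return None
    left, right = (a, b) if a.pos <= b.pos else (b, a)
    if left.orientation == "t[" and right.orientation == "]t":
        return "DEL"
    if left.orientation == "]t" and right.orientation == "t[":
        return "DUP"
    if left.orientation == right.orientation and left.orientation in ("t]", "[t"):
        return "INV"
    return None


# ---------------------------------------------------------------------------
# allele normalization
# ---------------------------------------------------------------------------

def left_normalize(chrom_seq: str, pos: int, ref: str, alt: str):
    """Left-align and trim an indel allele pair against the reference.

    ``pos`` is 1-based.  Returns ``(pos, ref, alt)`` with shared suffix/prefix
    trimmed down to a single padding base and the representation shifted as
    far left as the reference allows (standard VCF normalization).
    """
    ref, alt = ref.upper(), alt.upper()
    # right-trim equal ends; when one allele would empty, rotate leftward by
    # prepending the preceding reference base (vt-normalize style)
    while ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif pos > 1:
            prev = chrom_seq[pos - 2]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            break
    # trim shared prefix down to a single padding base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _infer_type_and_length(ref: str, alt: str, info: dict):
    svtype = info.get("SVTYPE")
    svlen = info.get("SVLEN")
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0]
    if svtype is None:
        if len(alt) > len(ref):
            svtype = "INS"
        elif len(ref) > len(alt):
            svtype = "DEL"
        else:
            return None, None
    if svlen is None:
        svlen = abs(len(alt) - len(ref))
        if svtype == "INV":
            svlen = len(ref) - 1
    return svtype, abs(int(svlen))


def read_sv_vcf(path, tech: str, tool: str,
                reference: Optional[dict] = None) -> list:
    """Read SVs from a VCF 4.x file into :class:`SVRecord` objects.

    Symbolic DEL/DUP/INV ALT alleles are expanded to sequence-explicit form
    against ``reference``; symbolic insertions carry no sequence and are
    dropped with a warning.  Multiallelic records are split into biallelic
    records, breakends (SVTYPE=BND) are skipped (they are classified
    separately), and allele representations are left-normalized.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            gt = None
            if rec.samples:
                alleles = next(iter(rec.samples.values())).get("GT")
                if alleles is not None and None not in alleles:
                    gt = "hom" if len(set(alleles)) == 1 else "het"
            for i, alt in enumerate(rec.alts or ()):
                rid = rec.id or f"{tool}_{rec.chrom}_{rec.pos}"
                if len(rec.alts) > 1:
                    rid = f"{rid}_{i + 1}"
                parsed = _parse_alt(rec, alt, info, reference)
                if parsed is None:
                    continue
                svtype, length, pos, ref_al, alt_al = parsed
                if (reference is not None and rec.chrom in reference
                        and svtype in ("DEL", "INS")):
                    pos, ref_al, alt_al = left_normalize(
                        reference[rec.chrom], pos, ref_al, alt_al)
                    if len(ref_al) != len(alt_al):
                        length = abs(len(ref_al) - len(alt_al))
                records.append(SVRecord(
                    id=rid, chrom=rec.chrom, pos=pos, svtype=svtype,
                    length=length, ref_allele=ref_al, alt_allele=alt_al,
                    source_tools=frozenset([tool]), tech=tech, source_gt=gt))
    return records


def _parse_alt(rec, alt, info, reference):
    chrom, pos = rec.chrom, rec.pos
    ref = rec.ref.upper()
    if alt.startswith("<"):
        token = alt.strip("<>").split(":")[0]
        if token == "INS":
            logger.warning("dropping symbolic insertion without sequence at "
                           "%s:%d", chrom, pos)
            return None
        if token not in ("DEL", "DUP", "INV"):
            logger.warning("skipping record with unsupported symbolic ALT %s "
                           "at %s:%d", alt, chrom, pos)
            return None
        if reference is None or chrom not in reference:
            raise SVFormatError(f"reference contig {chrom} required to expand "
                                f"symbolic ALT at {chrom}:{pos}")
        end = rec.stop  # INFO END, numerically 1-based inclusive
        seq = reference[chrom]
        span = seq[pos: end]  # bases pos+1..end
        anchor = seq[pos - 1]
        length = end - pos
        if token == "DEL":
            return "DEL", length, pos, anchor + span, anchor
        if token == "DUP":
            return "DUP", length, pos, anchor, anchor + span
        return "INV", length, pos, anchor + span, anchor + _revcomp(span)
    if "[" in alt or "]" in alt:
        return None  # breakend: handled by classify_breakend_pair
    svtype, length = _infer_type_and_length(ref, alt.upper(), info)
    if svtype is None or svtype == "BND":
        return None
    if svtype not in SV_TYPES:
        logger.warning("skipping record with unknown SVTYPE %s at %s:%d",
                       svtype, chrom, pos)
        return None
    return svtype, length, pos, ref, alt.upper()


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_sv_vcf(records: Sequence[SVRecord], path, contigs: dict,
                 extra_info: Optional[dict] = None) -> None:
    """Write SVRecords to an uncompressed VCF 4.2 file.

    ``contigs`` maps chromosome name to length.  ``extra_info`` maps record id
    to a dict of additional INFO key/values (used by the merge module for
    cluster metadata).
    """
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "SV length in bp")
    header.info.add("TOOLS", 1, "String", "Comma-separated source callers")
    header.info.add("SUPP_TOOLS", 1, "Integer",
                    "Number of distinct callers supporting the SV")
    header.info.add("TECH", 1, "String", "Sequencing technology of the call")
    header.info.add("REFINED", 0, "Flag", "Breakpoints refined by split alignment")
    header.info.add("ClusterIDs", 1, "String", "IDs of merged member calls")
    header.info.add("NumClusterSVs", 1, "Integer", "Number of merged member calls")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sv in sorted(records, key=lambda r: (r.chrom, r.pos, r.length, r.id)):
            rec = out.new_record(
                contig=sv.chrom, start=sv.pos - 1, stop=sv.end,
                alleles=(sv.ref_allele, sv.alt_allele), id=sv.id)
            rec.info["SVTYPE"] = sv.svtype
            rec.info["SVLEN"] = -sv.length if sv.svtype == "DEL" else sv.length
            if sv.source_tools:
                rec.info["TOOLS"] = ",".join(sorted(sv.source_tools))
                rec.info["SUPP_TOOLS"] = len(sv.source_tools)
            rec.info["TECH"] = sv.tech
            if sv.refined:
                rec.info["REFINED"] = True
            for key, val in (extra_info or {}).get(sv.id, {}).items():
                rec.info[key] = val
            out.write(rec)


def read_back_sv_vcf(path, reference: Optional[dict] = None) -> list:
    """Read a VCF written by :func:`write_sv_vcf`, restoring provenance."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            tools = frozenset(info.get("TOOLS", "").split(",")) - {""}
            svtype, length = _infer_type_and_length(
                rec.ref, rec.alts[0], info)
            records.append(SVRecord(
                id=rec.id, chrom=rec.chrom, pos=rec.pos, svtype=svtype,
                length=length, ref_allele=rec.ref.upper(),
                alt_allele=rec.alts[0].upper(), source_tools=tools,
                tech=info.get("TECH", "illumina"),
                refined=bool(info.get("REFINED", False))))
    return records


# ---------------------------------------------------------------------------
# normalization / filtering
# ---------------------------------------------------------------------------

def _overlaps_n(sv: SVRecord, annotation: GenomeAnnotation) -> bool:
    start, end = sv.span0()
    for n_start, n_end in annotation.n_runs(sv.chrom):
        if n_start < end and start < n_end:
            return True
    return False


def _ins_near_n(sv: SVRecord, annotation: GenomeAnnotation, min_dist: int) -> bool:
    anchor = sv.pos - 1  # 0-based
    for n_start, n_end in annotation.n_runs(sv.chrom):
        dist = n_start - anchor - 1 if anchor < n_start else anchor - n_end
        if dist < min_dist:
            return True
    return False


def normalize_and_filter(records: Iterable[SVRecord],
                         annotation: GenomeAnnotation,
                         params: FilterParams = FilterParams()) -> list:
    """Apply the common SV call-set filters.

    Retained records satisfy: 50 bp <= length <= 500 kb, chromosome in the
    whitelist (organelles and unanchored scaffolds excluded), type in
    DEL/INS/DUP/INV, no overlap with reference N runs, insertions at least 20
    bp away from any N, and (with ``genotyping_prep``) at least 1 kb from both
    chromosome ends, measured from ``pos`` and ``end``.  Heterozygous source
    calls from nanopore call sets are dropped: residual heterozygosity in
    inbred lines is almost surely spurious.  Filtering is total and idempotent.
    """
    kept = []
    for sv in records:
        if sv.svtype not in SV_TYPES:
            continue
        if sv.chrom not in annotation.chrom_whitelist:
            continue
        if not (params.min_length <= sv.length <= params.max_length):
            continue
        if (params.drop_heterozygous_nanopore and sv.tech == "nanopore"
                and sv.source_gt == "het"):
            continue
        if sv.chrom in annotation.reference:
            if _overlaps_n(sv, annotation):
                continue
            if sv.svtype == "INS" and _ins_near_n(
                    sv, annotation, params.min_n_distance_ins):
                continue
            if params.genotyping_prep:
                chrom_len = annotation.chrom_len(sv.chrom)
                if sv.pos - 1 < params.end_distance or \
                        chrom_len - sv.end < params.end_distance:
                    continue
        kept.append(sv)
    return kept


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BED
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3(path) -> list:
    """Read gene models (gene + CDS features) from GFF3 into Gene objects."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        cds = tuple(sorted((c.start - 1, c.end)
                           for c in db.children(g, featuretype="CDS")))
        genes.append(Gene(id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
                          strand=g.strand, cds=cds))
    return genes


def write_gff3(genes: Sequence[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsvjoint\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")
            fh.write(f"{g.chrom}\tsvjoint\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}.t1;Parent={g.id}\n")
            for i, (cs, ce) in enumerate(g.cds):
                fh.write(f"{g.chrom}\tsvjoint\tCDS\t{cs + 1}\t{ce}\t.\t"
                         f"{g.strand}\t0\tID={g.id}.cds{i};Parent={g.id}.t1\n")


def read_bed(path) -> list:
    """Read a 3+ column BED file into (chrom, start, end) tuples (0-based)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
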