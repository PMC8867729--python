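"""Seeded synthetic-data generator for the whole SV pipeline.

Emulates the study design the package is built for: an inbred crop population
(~100 samples, residual heterozygosity near zero, weak k=5 substructure), a
subset of samples with ~12x long-read data, per-sample truth SV sets with a
realistic type/size spectrum, "long-read" call sets with breakpoint jitter
and ~8-10% insertion-sequence error, "short-read" call sets with
caller-specific sensitivity/precision and no large insertions, genotype
matrices with per-call read support, and TE insertions with TIR/TSD structure
including a three-allele site carrying an excision footprint.

Every output derives from a single :class:`numpy.random.Generator`, so a
fixed config + seed reproduces byte-identical files, and every emitted call
traces back to a truth record or is flagged as a false positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .benchmark import GT_AA, GT_MISSING, GT_RA, GT_RR, GenotypeMatrix
from .refine import MappedRead
from .sv_io import (BreakendRecord, Gene, GenomeAnnotation, SVRecord,
                    _revcomp, left_normalize, SIZE_CLASS_LABELS)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# size-class sampling ranges; the top class is capped for desk-scale genomes
_SIZE_RANGES = {
    "[50,100)": (50, 100),
    "[100,1k)": (100, 1_000),
    "[1k,10k)": (1_000, 10_000),
    ">=10k": (10_000, 20_000),
}


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one SV discovery tool."""

    name: str
    tech: str  # "illumina" or "nanopore"
    sensitivity: dict  # svtype -> detection probability
    fp_rate: float  # expected false calls per true call emitted
    breakpoint_jitter_sd: float  # Gaussian sd in bp, truncated at +-50
    seq_error: float = 0.0  # insertion-sequence corruption rate
    max_ins_length: Optional[int] = None  # insertions above this are missed

    def detect_prob(self, svtype: str, length: int) -> float:
        if svtype == "INS" and self.max_ins_length is not None and \
                length > self.max_ins_length:
            return 0.0
        return self.sensitivity.get(svtype, 0.0)


@dataclass(frozen=True)
class GenotypingProfile:
    """Error model of the short-read genotyper applied to a candidate set."""

    sensitivity: dict  # svtype -> P(truth AA call genotyped AA)
    precision: dict  # svtype -> target precision of AA calls
    support_mean: float = 10.0  # Poisson mean reads supporting a true call
    fp_support_mean: float = 2.0  # Poisson mean for false-positive calls
    missing_rate: float = 0.02


@dataclass(frozen=True)
class TETemplate:
    """MITE-style element: TSD + TIR + core + reverse-complemented TIR."""

    te_id: str
    superfamily: str = "Tc1-Mariner"
    te_class: str = "DNA"
    tsd: str = "TA"
    tir_len_range: tuple = (15, 40)
    core_len_range: tuple = (150, 600)


def _default_sv_counts() -> dict:
    # type/size spectrum loosely following the merged short+long-read call
    # sets: deletions/insertions dominate and small events are most common
    return {
        ("DEL", "[50,100)"): 60, ("DEL", "[100,1k)"): 60,
        ("DEL", "[1k,10k)"): 15, ("DEL", ">=10k"): 4,
        ("INS", "[50,100)"): 50, ("INS", "[100,1k)"): 55,
        ("INS", "[1k,10k)"): 10, ("INS", ">=10k"): 2,
        ("DUP", "[50,100)"): 6, ("DUP", "[100,1k)"): 6,
        ("DUP", "[1k,10k)"): 3, ("DUP", ">=10k"): 1,
        ("INV", "[50,100)"): 4, ("INV", "[100,1k)"): 4,
        ("INV", "[1k,10k)"): 2, ("INV", ">=10k"): 1,
    }


def default_caller_profiles() -> list:
    """Short-read caller profiles mirroring the benchmark ranges of the four
    discovery tools, plus one long-read caller."""
    return [
        CallerProfile("asmvar", "illumina",
                      {"DEL": 0.50, "INS": 0.35, "DUP": 0.10, "INV": 0.10},
                      fp_rate=0.15, breakpoint_jitter_sd=2.0,
                      max_ins_length=1_000),
        CallerProfile("manta", "illumina",
                      {"DEL": 0.65, "INS": 0.40, "DUP": 0.20, "INV": 0.20},
                      fp_rate=0.10, breakpoint_jitter_sd=2.0,
                      max_ins_length=1_000),
        CallerProfile("smoove", "illumina",
                      {"DEL": 0.55, "INS": 0.05, "DUP": 0.15, "INV": 0.15},
                      fp_rate=0.10, breakpoint_jitter_sd=2.0,
                      max_ins_length=1_000),
        CallerProfile("svaba", "illumina",
                      {"DEL": 0.55, "INS": 0.30, "DUP": 0.10, "INV": 0.10},
                      fp_rate=0.25, breakpoint_jitter_sd=2.0,
                      max_ins_length=1_000),
        CallerProfile("sniffles", "nanopore",
                      {"DEL": 0.90, "INS": 0.90, "DUP": 0.60, "INV": 0.60},
                      fp_rate=0.05, breakpoint_jitter_sd=5.0,
                      seq_error=0.08),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 4
    chrom_len: int = 500_000
    gene_density: float = 55.0  # genes per Mb
    repeat_fraction: float = 0.4
    n_gaps_per_chrom: int = 1
    gap_len: int = 200
    n_samples: int = 102
    n_longread_samples: int = 17
    sv_counts: dict = field(default_factory=_default_sv_counts)
    freq_beta: tuple = (0.6, 2.5)  # allele-frequency spectrum shape
    caller_profiles: list = field(default_factory=default_caller_profiles)
    genotyping: GenotypingProfile = field(default_factory=lambda: GenotypingProfile(
        sensitivity={"DEL": 0.60, "INS": 0.45, "DUP": 0.20, "INV": 0.15},
        precision={"DEL": 0.85, "INS": 0.75, "DUP": 0.30, "INV": 0.55}))
    nanopore_depth: float = 12.0
    nanopore_seq_error: float = 0.08
    te_fraction: float = 0.5  # fraction of MITE-scale insertions built as TEs
    te_templates: list = field(default_factory=lambda: [
        TETemplate("soy_stowaway_1"), TETemplate("soy_stowaway_2"),
        TETemplate("soy_pif_1", superfamily="PIF-Harbinger", tsd="TAA")])
    excision_site: bool = True
    het_rate: float = 0.0
    k_subpops: int = 5
    fst: float = 0.15  # subpopulation differentiation (Balding-Nichols)
    admixture_alpha: float = 0.3


@dataclass
class TruthSV:
    """A truth record plus its population frequency and TE provenance."""

    record: SVRecord
    freq: float
    is_fp: bool = False
    te_id: Optional[str] = None
    tir: Optional[str] = None
    tsd: Optional[str] = None
    allele_class: str = "sv"  # "sv", "te", or "excision_footprint"
    element: Optional[str] = None  # TE element sequence (between TSD copies)
    te_site: Optional[int] = None  # element start on the carrier haplotype


@dataclass
class SimulationTruth:
    config: SimulationConfig
    annotation: GenomeAnnotation
    truth_svs: list  # list[TruthSV], placement order
    genotypes: GenotypeMatrix  # truth genotypes (no support/genotyping error)
    te_library: list  # list[te.TEEntry]
    excision: Optional[dict] = None  # te_sv_id / footprint_sv_id / site_pos
    admixture: Optional[np.ndarray] = None  # samples x k ancestry proportions

    @property
    def records(self) -> list:
        return [t.record for t in self.truth_svs if not t.is_fp]

    def sample_truth(self, sample: str) -> list:
        """Truth SVs carried homozygously by one sample.

        Excision footprints are excluded: they fall below the 50 bp SV size
        floor and never enter a normalized call set.
        """
        col = self.genotypes.gt[sample]
        return [t.record for t in self.truth_svs
                if not t.is_fp and t.allele_class != "excision_footprint"
                and col[t.record.id] == GT_AA]

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sv_id": t.record.id, "svtype": t.record.svtype,
            "chrom": t.record.chrom, "pos": t.record.pos,
            "length": t.record.length, "freq": t.freq, "is_fp": t.is_fp,
            "te_id": t.te_id, "tsd": t.tsd, "allele_class": t.allele_class,
        } for t in self.truth_svs])


# ---------------------------------------------------------------------------
# reference genome with gene and repeat tracks
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reference(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> GenomeAnnotation:
    """Random reference with embedded gene models, repeat tracts and N gaps."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    reference, genes, repeats = {}, [], []
    n_genes_per_chrom = round(config.gene_density * config.chrom_len / 1e6)
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        seq = list(_random_seq(rng, config.chrom_len))
        # N gaps away from chromosome ends
        for _ in range(config.n_gaps_per_chrom):
            start = int(rng.integers(50_000, config.chrom_len - 50_000))
            seq[start:start + config.gap_len] = "N" * config.gap_len
        reference[chrom] = "".join(seq)
        # non-overlapping gene models with CDS exons
        occupied: list = []
        placed = 0
        attempts = 0
        while placed < n_genes_per_chrom and attempts < n_genes_per_chrom * 50:
            attempts += 1
            glen = int(rng.integers(1_000, 6_000))
            start = int(rng.integers(2_000, config.chrom_len - glen - 2_000))
            if any(start < e and s < start + glen for s, e in occupied):
                continue
            occupied.append((start, start + glen))
            n_exons = int(rng.integers(2, 6))
            bounds = np.sort(rng.choice(
                np.arange(start + 50, start + glen - 50), size=2 * n_exons,
                replace=False))
            cds = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1]))
                        for i in range(n_exons)
                        if bounds[2 * i + 1] > bounds[2 * i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(id=f"gene_{chrom}_{placed:04d}", chrom=chrom,
                              start=start, end=start + glen, strand=strand,
                              cds=cds))
            placed += 1
        # repeat tracts drawn until the requested genome fraction is covered
        target = config.repeat_fraction * config.chrom_len
        covered = 0
        tracts: list = []
        while covered < target:
            tlen = int(min(rng.lognormal(np.log(800), 0.8) + 100, 20_000))
            start = int(rng.integers(0, config.chrom_len - tlen))
            if any(start < e and s < start + tlen for s, e in tracts):
                continue
            tracts.append((start, start + tlen))
            covered += tlen
        for s, e in sorted(tracts):
            repeats.append((chrom, s, e))
    return GenomeAnnotation(reference=reference, genes=genes, repeats=repeats,
                            chrom_whitelist=set(reference))


# ---------------------------------------------------------------------------
# TE insertion alleles
# ---------------------------------------------------------------------------

def simulate_te_insertion(template: TETemplate, rng: np.random.Generator,
                          tir_mismatches: int = 0,
                          element_seq: Optional[str] = None):
    """Build one MITE-style insertion allele.

    Returns ``(element, tir, provenance)`` where ``element`` is the sequence
    between the two TSD copies (TIR + core + reverse complement of the TIR,
    optionally with ``tir_mismatches`` substitutions in the right TIR) and
    ``provenance`` records template id, TIR and TSD.  Element sizes fall in
    the 198-681 bp range characteristic of MITEs.
    """
    if element_seq is not None:
        return element_seq, None, {"te_id": template.te_id, "tsd": template.tsd}
    tir_len = int(rng.integers(*template.tir_len_range))
    core_len = int(rng.integers(*template.core_len_range))
    tir = _random_seq(rng, tir_len)
    core = list(_random_seq(rng, core_len))
    # a TIR is maximal by definition: the first two core positions must not
    # continue the inverted repeat, otherwise the element's true TIR would be
    # longer than the declared one
    comp = dict(zip("ACGT", "TGCA"))
    for k in (0, 1):
        partner = core[core_len - 1 - k]
        if core[k] == comp[partner]:
            core[k] = str(rng.choice(
                [b for b in "ACGT" if b != comp[partner]]))
    core = "".join(core)
    right = list(_revcomp(tir))
    if tir_mismatches:
        idx = rng.choice(len(right), size=min(tir_mismatches, len(right)),
                         replace=False)
        for i in idx:
            right[i] = str(rng.choice([b for b in "ACGT" if b != right[i]]))
    element = tir + core + "".join(right)
    prov = {"te_id": template.te_id, "tir": tir, "tsd": template.tsd}
    return element, tir, prov


# ---------------------------------------------------------------------------
# population truth SVs and genotypes
# ---------------------------------------------------------------------------

def _draw_freq(config: SimulationConfig, rng: np.random.Generator) -> float:
    lo = 1.0 / config.n_samples
    f = float(rng.beta(*config.freq_beta))
    return min(max(f, lo), 0.99)


def _place_interval(rng, chrom_lens, occupied, length, margin=2_000,
                    max_tries=100):
    chroms = sorted(chrom_lens)
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        hi = chrom_lens[chrom] - length - margin
        if hi <= margin:
            continue
        start = int(rng.integers(margin, hi))
        ivs = occupied.setdefault(chrom, [])
        if any(start - 50 < e and s < start + length + 50 for s, e in ivs):
            continue
        ivs.append((start, start + length))
        return chrom, start
    return None


def _clear_of_ns(annotation, chrom, start, end, pad=25) -> bool:
    return not any(ns < end + pad and start - pad < ne
                   for ns, ne in annotation.n_runs(chrom))


def simulate_population_svs(annotation: GenomeAnnotation,
                            config: SimulationConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> SimulationTruth:
    """Place truth SVs on the reference and draw population genotypes.

    Genotypes are homozygous except for a ``het_rate`` residue, with weak
    k-subpopulation structure: per-SV subpopulation frequencies follow a
    Balding-Nichols model around the global frequency and samples carry
    Dirichlet admixture proportions.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    chrom_lens = {c: annotation.chrom_len(c) for c in annotation.reference}
    occupied: dict = {}
    truth: list = []
    te_library_seqs: dict = {}
    counter = 0
    excision = None

    def _canonical_element(template: TETemplate):
        if template.te_id not in te_library_seqs:
            element, tir, _ = simulate_te_insertion(template, rng)
            te_library_seqs[template.te_id] = (element, tir, template)
        return te_library_seqs[template.te_id]

    def _mutate_subs(seq: str, n_subs: int) -> str:
        if n_subs <= 0:
            return seq
        out = list(seq)
        idx = rng.choice(len(out), size=min(n_subs, len(out)), replace=False)
        for i in idx:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
        return "".join(out)

    for (svtype, size_class), count in sorted(config.sv_counts.items()):
        lo, hi = _SIZE_RANGES[size_class]
        shortfall = 0
        for _ in range(count):
            length = int(rng.integers(lo, hi))
            te_info = None
            if (svtype == "INS" and 198 <= length <= 681
                    and rng.random() < config.te_fraction):
                template = config.te_templates[
                    int(rng.integers(len(config.te_templates)))]
                canonical, tir, _tmpl = _canonical_element(template)
                # each insertion is a lightly diverged copy of the canonical
                # element (substitutions only, so the TIR ends stay in place)
                element = _mutate_subs(canonical, int(rng.poisson(2.0)))
                length = len(element) + len(template.tsd)
                te_info = (element, tir, template)
            span = length if svtype != "INS" else 1
            placed = _place_interval(rng, chrom_lens, occupied, span)
            if placed is None:
                shortfall += 1
                continue
            chrom, start = placed
            if not _clear_of_ns(annotation, chrom, start, start + span):
                shortfall += 1
                continue
            seq = annotation.reference[chrom]
            pos = start + 1  # 1-based anchor at the base before the event
            if svtype == "INS" and te_info is not None:
                # cut-and-paste biology: the element lands right after a TSD
                # occurrence in the reference and duplicates it on insertion
                tsd = te_info[2].tsd
                j = seq.find(tsd, start, start + 2_000)
                if j < 0:
                    shortfall += 1
                    continue
                pos = j + len(tsd)
            counter += 1
            rid = f"truth_{counter:05d}"
            anchor = seq[pos - 1]
            if svtype == "DEL":
                rec = SVRecord(rid, chrom, pos, "DEL", length,
                               anchor + seq[pos:pos + length], anchor)
            elif svtype == "INS":
                if te_info is not None:
                    element, tir, template = te_info
                    inserted = element + template.tsd
                    rec = SVRecord(rid, chrom, pos, "INS", len(inserted),
                                   anchor, anchor + inserted)
                else:
                    rec = SVRecord(rid, chrom, pos, "INS", length, anchor,
                                   anchor + _random_seq(rng, length))
            elif svtype == "DUP":
                rec = SVRecord(rid, chrom, pos, "DUP", length, anchor,
                               anchor + seq[pos:pos + length])
            else:  # INV
                rec = SVRecord(rid, chrom, pos, "INV", length,
                               anchor + seq[pos:pos + length],
                               anchor + _revcomp(seq[pos:pos + length]))
            if svtype in ("DEL", "INS"):
                # the pipeline compares left-normalized representations, so
                # the generator emits them normalized as well
                npos, nref, nalt = left_normalize(seq, pos, rec.ref_allele,
                                                  rec.alt_allele)
                rec = SVRecord(rid, chrom, npos, svtype, rec.length,
                               nref, nalt)
            entry = TruthSV(record=rec, freq=_draw_freq(config, rng))
            if te_info is not None:
                element, tir, template = te_info
                entry.te_id = template.te_id
                entry.tir = tir
                entry.tsd = template.tsd
                entry.allele_class = "te"
                entry.element = element
                entry.te_site = pos
            truth.append(entry)
        if shortfall:
            logger.warning("placement shortfall: %d of %d %s %s SVs dropped",
                           shortfall, count, svtype, size_class)

    # optional three-allele excision site derived from one TE insertion
    if config.excision_site:
        te_entries = [t for t in truth if t.allele_class == "te"]
        if te_entries:
            host = te_entries[int(rng.integers(len(te_entries)))]
            counter += 1
            fp_id = f"truth_{counter:05d}"
            seq = annotation.reference[host.record.chrom]
            site = host.te_site  # original insertion point, after the TSD
            # 4 repair-filler bases; the last one must differ from the base
            # preceding the site so the footprint representation is stable
            # under left-normalization and keeps its leading TSD
            filler = _random_seq(rng, 3) + str(rng.choice(
                [b for b in "ACGT" if b != seq[site - 1]]))
            footprint = host.tsd + filler  # e.g. TA + CGAG
            anchor = seq[site - 1]
            rec = SVRecord(fp_id, host.record.chrom, site, "INS",
                           len(footprint), anchor, anchor + footprint)
            fp_entry = TruthSV(record=rec, freq=0.0,
                               allele_class="excision_footprint",
                               te_id=host.te_id, tsd=host.tsd)
            truth.append(fp_entry)
            excision = {"te_sv_id": host.record.id, "footprint_sv_id": fp_id,
                        "site_pos": site}

    # genotypes with weak k-subpopulation structure
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    k = config.k_subpops
    admix = rng.dirichlet([config.admixture_alpha] * k, size=config.n_samples)
    gt = np.zeros((len(truth), config.n_samples), dtype=np.int8)
    fst = config.fst
    for vi, entry in enumerate(truth):
        f = entry.freq
        if entry.allele_class == "excision_footprint":
            continue  # assigned jointly with its host TE below
        if f <= 0:
            continue
        a, b = f * (1 - fst) / fst, (1 - f) * (1 - fst) / fst
        sub_freqs = rng.beta(a, b, size=k)
        p = admix @ sub_freqs
        carrier = rng.random(config.n_samples) < p
        gt[vi, carrier] = GT_AA
        if config.het_rate > 0:
            het = rng.random(config.n_samples) < config.het_rate
            gt[vi, het & carrier] = GT_RA

    if excision is not None:
        ids = [t.record.id for t in truth]
        te_vi = ids.index(excision["te_sv_id"])
        fp_vi = ids.index(excision["footprint_sv_id"])
        # roughly 70% absent / 10% TE present / 20% excision footprint
        alleles = rng.choice(3, size=config.n_samples, p=[0.70, 0.10, 0.20])
        gt[te_vi] = np.where(alleles == 1, GT_AA, GT_RR)
        gt[fp_vi] = np.where(alleles == 2, GT_AA, GT_RR)
        truth[te_vi].freq = float((alleles == 1).mean())
        truth[fp_vi].freq = float((alleles == 2).mean())

    ids = [t.record.id for t in truth]
    gt_frame = pd.DataFrame(gt, index=ids, columns=samples)
    support = pd.DataFrame(np.zeros_like(gt, dtype=np.int32), index=ids,
                           columns=samples)
    matrix = GenotypeMatrix(svs=[t.record for t in truth], gt=gt_frame,
                            support=support)

    from .te import TEEntry
    library = [TEEntry(te_id=tid, seq=seq, te_class=tmpl.te_class,
                       superfamily=tmpl.superfamily)
               for tid, (seq, _tir, tmpl) in sorted(te_library_seqs.items())]
    return SimulationTruth(config=config, annotation=annotation,
                           truth_svs=truth, genotypes=matrix,
                           te_library=library, excision=excision,
                           admixture=admix)


def flanked_te_sequence(truth: SimulationTruth, sv_id: str,
                        flank: int = 30) -> Tuple[str, int]:
    """Carrier-haplotype context of a TE insertion for TIR/TSD analysis.

    Returns ``(sequence, flank)`` where the sequence is the element framed by
    ``flank`` bp of carrier-haplotype context on each side, so both flanks
    end/begin with a TSD copy.
    """
    entry = next(t for t in truth.truth_svs if t.record.id == sv_id)
    if entry.allele_class != "te":
        raise ValueError(f"{sv_id} is not a TE insertion")
    rec = entry.record
    seq = truth.annotation.reference[rec.chrom]
    site = entry.te_site  # haplotype framing is representation-independent
    left = seq[site - flank:site]
    right = (entry.tsd + seq[site:])[:flank]
    return left + entry.element + right, flank


def simulate_excision_snvs(truth: SimulationTruth, region: tuple,
                           groups: dict, n_snvs: int,
                           n_discordant_present_excised: int,
                           n_discordant_absent_present: int,
                           rng: Optional[np.random.Generator] = None
                           ) -> GenotypeMatrix:
    """SNV genotypes in a linkage block with controlled group haplotypes.

    The ``present`` group carries a fixed haplotype; the ``excised`` group
    carries the same haplotype except at ``n_discordant_present_excised``
    SNVs, and the ``absent`` group differs from ``present`` at
    ``n_discordant_absent_present`` SNVs.  Frequencies within groups are 0 or
    1, so contrasting-SNV counts (|df| > 0.5) are exact by construction.
    """
    config = truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 5)
    present = rng.integers(0, 2, size=n_snvs).astype(float)
    excised = present.copy()
    flip_pe = rng.choice(n_snvs, size=n_discordant_present_excised,
                         replace=False)
    excised[flip_pe] = 1 - excised[flip_pe]
    absent = present.copy()
    pool = np.setdiff1d(np.arange(n_snvs), flip_pe)
    flip_ap = rng.choice(pool, size=n_discordant_absent_present,
                         replace=False)
    absent[flip_ap] = 1 - absent[flip_ap]
    hap = {"absent": absent, "present": present, "excised": excised,
           "freqs": {"absent": absent, "present": present, "excised": excised}}
    hap_groups = {g: groups[g] for g in ("absent", "present", "excised")}
    hap_groups["freqs"] = hap["freqs"]
    return simulate_snv_matrix(truth, n_snvs=n_snvs, rng=rng, region=region,
                               haplotype_groups=hap_groups)


# ---------------------------------------------------------------------------
# breakend emission (round-trip oracle for the classifier)
# ---------------------------------------------------------------------------

def emit_breakend_pair(sv: SVRecord) -> tuple:
    """Encode a DEL/DUP/INV as its reciprocal VCF breakend pair."""
    s, e = sv.pos, sv.end + 1
    if sv.svtype == "DEL":
        a = BreakendRecord(sv.chrom, s, sv.chrom, e, "t[")
        b = BreakendRecord(sv.chrom, e, sv.chrom, s, "]t")
    elif sv.svtype == "DUP":
        a = BreakendRecord(sv.chrom, s, sv.chrom, e, "]t")
        b = BreakendRecord(sv.chrom, e, sv.chrom, s, "t[")
    elif sv.svtype == "INV":
        a = BreakendRecord(sv.chrom, s, sv.chrom, e, "t]")
        b = BreakendRecord(sv.chrom, e, sv.chrom, s, "t]")
    else:
        raise ValueError("insertions have no breakend representation here")
    return a, b


# ---------------------------------------------------------------------------
# caller call sets
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, sd: float) -> int:
    return int(np.clip(round(rng.normal(0, sd)), -50, 50))


def _corrupt(seq: str, rate: float, rng: np.random.Generator) -> str:
    """iid substitution (60%), insertion (20%), deletion (20%) errors."""
    if rate <= 0:
        return seq
    out = []
    for base in seq:
        r = rng.random()
        if r >= rate:
            out.append(base)
            continue
        kind = rng.random()
        if kind < 0.6:  # substitution
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        elif kind < 0.8:  # insertion
            out.append(base)
            out.append(str(_BASES[rng.integers(0, 4)]))
        # else deletion: emit nothing
    return "".join(out)


def _jittered_call(sv: SVRecord, profile: CallerProfile, annotation,
                   rng: np.random.Generator, call_id: str) -> SVRecord:
    seq = annotation.reference[sv.chrom]
    dpos = _jitter(rng, profile.breakpoint_jitter_sd)
    dlen = _jitter(rng, profile.breakpoint_jitter_sd)
    pos = max(2, sv.pos + dpos)
    length = max(50, sv.length + dlen)
    anchor = seq[pos - 1]
    if sv.svtype == "DEL":
        length = min(length, len(seq) - pos - 1)
        ref_al, alt_al = anchor + seq[pos:pos + length], anchor
    elif sv.svtype == "INS":
        ins = sv.variant_seq
        if profile.seq_error > 0:
            ins = _corrupt(ins, profile.seq_error, rng)
        if dlen > 0:
            ins = ins + _random_seq(rng, dlen)
        elif dlen < 0 and len(ins) + dlen >= 50:
            ins = ins[:dlen]
        length = len(ins)
        ref_al, alt_al = anchor, anchor + ins
    elif sv.svtype == "DUP":
        length = min(length, len(seq) - pos - 1)
        ref_al, alt_al = anchor, anchor + seq[pos:pos + length]
    else:
        length = min(length, len(seq) - pos - 1)
        span = seq[pos:pos + length]
        ref_al, alt_al = anchor + span, anchor + _revcomp(span)
    return SVRecord(call_id, sv.chrom, pos, sv.svtype, length, ref_al,
                    alt_al, source_tools=frozenset([profile.name]),
                    tech=profile.tech)


def _false_positive_call(profile: CallerProfile, annotation, config,
                         occupied, rng, call_id: str) -> Optional[SVRecord]:
    svtype = ("DEL", "INS")[int(rng.integers(2))]
    length = int(rng.integers(50, 1_000))
    chrom_lens = {c: annotation.chrom_len(c) for c in annotation.reference}
    span = length if svtype != "INS" else 1
    placed = _place_interval(rng, chrom_lens, occupied, span)
    if placed is None:
        return None
    chrom, start = placed
    seq = annotation.reference[chrom]
    pos = start + 1
    anchor = seq[pos - 1]
    if svtype == "DEL":
        rec = SVRecord(call_id, chrom, pos, "DEL", length,
                       anchor + seq[pos:pos + length], anchor)
    else:
        rec = SVRecord(call_id, chrom, pos, "INS", length, anchor,
                       anchor + _random_seq(rng, length))
    return replace(rec, source_tools=frozenset([profile.name]),
                   tech=profile.tech)


def simulate_callsets(truth: SimulationTruth,
                      rng: Optional[np.random.Generator] = None) -> dict:
    """Per-caller discovery call sets over the population truth.

    Short-read callers see the population-level truth records (discovery is
    pooled across samples); the long-read caller produces one call set per
    long-read sample restricted to that sample's homozygous SVs.  Each caller
    drops truth records per its per-type sensitivity (short-read profiles
    have zero sensitivity for insertions above 1 kb), jitters breakpoints,
    corrupts insertion sequences at the long-read error rate, and adds false
    calls at its fp_rate.  Returns ``{caller: [SVRecord, ...]}`` for
    short-read callers and ``{"sniffles": {sample: [SVRecord, ...]}}``-style
    nested dicts for long-read callers.
    """
    config = truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    annotation = truth.annotation
    occupied: dict = {}
    for t in truth.truth_svs:
        s, e = t.record.span0()
        occupied.setdefault(t.record.chrom, []).append((s, e))
    callsets: dict = {}
    fp_counter = 0
    for profile in config.caller_profiles:
        if profile.tech == "illumina":
            calls = []
            for t in truth.truth_svs:
                if t.is_fp or t.allele_class == "excision_footprint":
                    continue
                if rng.random() < profile.detect_prob(t.record.svtype,
                                                      t.record.length):
                    calls.append(_jittered_call(
                        t.record, profile, annotation, rng,
                        f"{profile.name}_{t.record.id}"))
            n_fp = rng.poisson(profile.fp_rate * max(len(calls), 1))
            for _ in range(n_fp):
                fp_counter += 1
                fp = _false_positive_call(profile, annotation, config,
                                          occupied, rng,
                                          f"{profile.name}_fp_{fp_counter:04d}")
                if fp is not None:
                    calls.append(fp)
            callsets[profile.name] = calls
        else:
            per_sample: dict = {}
            samples = truth.genotypes.samples[:config.n_longread_samples]
            for sample in samples:
                calls = []
                for rec in truth.sample_truth(sample):
                    if rng.random() < profile.detect_prob(rec.svtype,
                                                          rec.length):
                        calls.append(_jittered_call(
                            rec, profile, annotation, rng,
                            f"{profile.name}_{sample}_{rec.id}"))
                n_fp = rng.poisson(profile.fp_rate * max(len(calls), 1))
                for _ in range(n_fp):
                    fp_counter += 1
                    fp = _false_positive_call(
                        profile, annotation, config, occupied, rng,
                        f"{profile.name}_{sample}_fp_{fp_counter:04d}")
                    if fp is not None:
                        calls.append(replace(fp, tech="nanopore"))
                per_sample[sample] = calls
            callsets[profile.name] = per_sample
    return callsets


# ---------------------------------------------------------------------------
# genotyped multi-sample call set with read support
# ---------------------------------------------------------------------------

def simulate_genotyped_matrix(truth: SimulationTruth,
                              candidates: Optional[Sequence[SVRecord]] = None,
                              rng: Optional[np.random.Generator] = None
                              ) -> Tuple[GenotypeMatrix, set]:
    """Genotype a candidate SV set across the population with read supports.

    For each candidate matching a truth record, a sample's homozygous-ALT
    truth genotype is recovered with the per-type genotyping sensitivity and
    supported by ~Poisson(support_mean) reads; missed or absent alleles are
    homozygous reference.  False-positive AA calls are injected at novel loci
    (low read support) so that the expected per-sample precision equals the
    configured per-type precision.  Returns the matrix and the set of ids of
    injected false-positive records.
    """
    config = truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    prof = config.genotyping
    if candidates is None:
        # sub-50 bp alleles (the excision footprint) are short indels, not
        # SVs: they never enter a normalized SV candidate set
        records = [t.record for t in truth.truth_svs if t.record.length >= 50]
        truth_ids = {r.id for r in records}
    else:
        records = list(candidates)
        truth_ids = {r.id for r in records}

    samples = truth.genotypes.samples
    n = len(samples)
    truth_gt = truth.genotypes.gt

    # expected AA truth calls per type (for FP budgeting)
    type_counts = {svt: 0.0 for svt in ("DEL", "INS", "DUP", "INV")}
    for rec in records:
        if rec.id in truth_gt.index:
            type_counts[rec.svtype] += (truth_gt.loc[rec.id] == GT_AA).mean()

    fp_records: list = []
    occupied: dict = {}
    for rec in records:
        s, e = rec.span0()
        occupied.setdefault(rec.chrom, []).append((s, e))
    fp_rates: dict = {}
    for svt, aa_mean in type_counts.items():
        sens = prof.sensitivity.get(svt, 0.0)
        prec = prof.precision.get(svt, 1.0)
        exp_tp = aa_mean * sens
        exp_fp = exp_tp * (1 - prec) / prec if prec > 0 else 0.0
        if exp_fp <= 0:
            continue
        n_fp_records = max(int(np.ceil(exp_fp / 0.3)), 1)
        made = 0
        chrom_lens = {c: truth.annotation.chrom_len(c)
                      for c in truth.annotation.reference}
        for i in range(n_fp_records):
            length = int(rng.integers(50, 2_000))
            span = length if svt != "INS" else 1
            placed = _place_interval(rng, chrom_lens, occupied, span)
            if placed is None:
                continue
            chrom, start = placed
            seq = truth.annotation.reference[chrom]
            pos = start + 1
            anchor = seq[pos - 1]
            rid = f"gtfp_{svt}_{i:04d}"
            if svt == "DEL":
                rec = SVRecord(rid, chrom, pos, "DEL", length,
                               anchor + seq[pos:pos + length], anchor)
            elif svt == "INS":
                rec = SVRecord(rid, chrom, pos, "INS", length, anchor,
                               anchor + _random_seq(rng, length))
            elif svt == "DUP":
                rec = SVRecord(rid, chrom, pos, "DUP", length, anchor,
                               anchor + seq[pos:pos + length])
            else:
                rec = SVRecord(rid, chrom, pos, "INV", length,
                               anchor + seq[pos:pos + length],
                               anchor + _revcomp(seq[pos:pos + length]))
            fp_records.append(rec)
            made += 1
        fp_rates[svt] = exp_fp / made if made else 0.0

    all_records = records + fp_records
    ids = [r.id for r in all_records]
    gt = np.full((len(all_records), n), GT_RR, dtype=np.int8)
    support = np.zeros((len(all_records), n), dtype=np.int32)
    for vi, rec in enumerate(all_records):
        sens = prof.sensitivity.get(rec.svtype, 0.0)
        if rec.id in truth_gt.index:
            tg = truth_gt.loc[rec.id].to_numpy()
            aa = tg == GT_AA
            called = aa & (rng.random(n) < sens)
            missed = aa & ~called
            true_rr = ~aa
            gt[vi, called] = GT_AA
            support[vi, called] = rng.poisson(prof.support_mean,
                                              size=int(called.sum())) + 1
            # a genotyping failure is a low-evidence locus: the reported
            # hom-ref call carries almost no read support, so the standard
            # two-read filter turns it into a missing call downstream
            support[vi, missed] = rng.poisson(0.7, size=int(missed.sum()))
            support[vi, true_rr] = rng.poisson(prof.support_mean,
                                               size=int(true_rr.sum()))
        else:  # injected false positive
            p = fp_rates.get(rec.svtype, 0.0)
            called = rng.random(n) < p
            gt[vi, called] = GT_AA
            support[vi, called] = rng.poisson(prof.fp_support_mean,
                                              size=int(called.sum())) + 1
        missing = rng.random(n) < prof.missing_rate
        gt[vi, missing] = GT_MISSING
        support[vi, missing] = 0
    matrix = GenotypeMatrix(
        svs=all_records,
        gt=pd.DataFrame(gt, index=ids, columns=samples),
        support=pd.DataFrame(support, index=ids, columns=samples))
    return matrix, {r.id for r in fp_records}


# ---------------------------------------------------------------------------
# SNV genotypes (for population genetics and the excision analysis)
# ---------------------------------------------------------------------------

def simulate_snv_matrix(truth: SimulationTruth, n_snvs: int = 2_000,
                        rng: Optional[np.random.Generator] = None,
                        region: Optional[tuple] = None,
                        haplotype_groups: Optional[dict] = None
                        ) -> GenotypeMatrix:
    """Biallelic SNV genotypes with the same population structure as the SVs.

    With ``haplotype_groups`` (mapping group name -> sample list, plus key
    ``"freqs"`` -> group -> per-SNV alternate allele frequency), genotypes
    inside ``region`` follow the given per-group haplotype frequencies: this
    builds the linkage block used by the excision analysis.
    """
    config = truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    samples = truth.genotypes.samples
    n = len(samples)
    k = config.k_subpops
    # share the population's ancestry so SNV- and SV-based structure agree
    admix = truth.admixture if truth.admixture is not None else \
        rng.dirichlet([config.admixture_alpha] * k, size=n)
    chroms = sorted(truth.annotation.reference)
    gt = np.zeros((n_snvs, n), dtype=np.int8)
    recs = []
    for vi in range(n_snvs):
        if region is not None:
            chrom = region[0]
            hi = min(region[2], truth.annotation.chrom_len(chrom))
            pos = int(rng.integers(max(region[1], 1), hi + 1))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1_500, truth.annotation.chrom_len(chrom)))
        ref = truth.annotation.reference[chrom][pos - 1]
        if ref == "N":
            ref = "A"
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        recs.append(SVRecord(f"snv_{vi:05d}", chrom, pos, "INS", 1, ref, alt))
        f = min(max(float(rng.beta(0.8, 2.0)), 1.0 / n), 0.99)
        a, b = (f * (1 - config.fst) / config.fst,
                (1 - f) * (1 - config.fst) / config.fst)
        sub = rng.beta(a, b, size=k)
        p = admix @ sub
        gt[vi, rng.random(n) < p] = GT_AA
    if haplotype_groups is not None:
        freqs = haplotype_groups["freqs"]
        for group, members in haplotype_groups.items():
            if group == "freqs":
                continue
            cols = [samples.index(s) for s in members]
            gf = freqs[group]
            for vi in range(n_snvs):
                carrier = rng.random(len(cols)) < gf[vi]
                gt[vi, cols] = np.where(carrier, GT_AA, GT_RR)
    ids = [r.id for r in recs]
    return GenotypeMatrix(
        svs=recs, gt=pd.DataFrame(gt, index=ids, columns=samples),
        support=pd.DataFrame(np.full((n_snvs, n), 10, dtype=np.int32),
                             index=ids, columns=samples))


# ---------------------------------------------------------------------------
# reads for refinement windows
# ---------------------------------------------------------------------------

def apply_allele(chrom_seq: str, sv: SVRecord) -> Tuple[str, int]:
    """Carrier haplotype for one SV; returns (sequence, length_change)."""
    pos = sv.pos  # 1-based anchor
    if sv.svtype == "DEL":
        return chrom_seq[:pos] + chrom_seq[pos + sv.length:], -sv.length
    if sv.svtype == "INS":
        return (chrom_seq[:pos] + sv.variant_seq + chrom_seq[pos:], sv.length)
    if sv.svtype == "DUP":
        span = chrom_seq[pos:pos + sv.length]
        return chrom_seq[:pos + sv.length] + span + \
            chrom_seq[pos + sv.length:], sv.length
    span = chrom_seq[pos:pos + sv.length]
    return chrom_seq[:pos] + _revcomp(span) + chrom_seq[pos + sv.length:], 0


def simulate_reads(haplotype: str, window: tuple, depth: float,
                   error_rate: float, rng: np.random.Generator,
                   chrom: str = "chr1", ref_window: Optional[tuple] = None,
                   overhang: int = 100) -> list:
    """Long-read-like reads spanning one local window of a haplotype.

    Each read covers the whole window with random overhangs (long reads
    easily span the desk-scale refinement windows) and carries iid
    substitution/indel errors at ``error_rate``.  The mapping interval is
    the reference-coordinate window (``ref_window`` when the haplotype
    coordinates differ from the reference).
    """
    w_start, w_end = window
    n_reads = rng.poisson(depth)
    ref_window = ref_window or window
    reads = []
    for i in range(n_reads):
        s = max(0, w_start - int(rng.integers(0, overhang + 1)))
        e = min(len(haplotype), w_end + int(rng.integers(0, overhang + 1)))
        seq = _corrupt(haplotype[s:e], error_rate, rng)
        reads.append(MappedRead(id=f"read_{chrom}_{w_start}_{i:03d}", seq=seq,
                                chrom=chrom, start=ref_window[0],
                                end=ref_window[1]))
    return reads


def simulate_refinement_case(annotation: GenomeAnnotation, sv: SVRecord,
                             rng: np.random.Generator, jitter: int = 15,
                             depth: float = 20.0, read_error: float = 0.05,
                             ins_seq_error: float = 0.08, flank: int = 200):
    """One refinement problem: a jittered call plus reads from the carrier.

    Returns ``(truth_sv, noisy_call, reads)``.  The noisy call's breakpoints
    are shifted uniformly within +-``jitter`` bp and insertion sequences are
    corrupted at ``ins_seq_error``, emulating a raw long-read call.
    """
    chrom_seq = annotation.reference[sv.chrom]
    hap, delta = apply_allele(chrom_seq, sv)
    w_start = max(0, sv.pos - 1 - flank)
    hap_end = (sv.end if sv.svtype != "DEL" else sv.pos) + \
        (sv.length if sv.svtype == "INS" else 0)
    w_end_hap = min(len(hap), hap_end + flank)
    ref_window = (w_start, sv.end + flank)
    reads = simulate_reads(hap, (w_start, w_end_hap), depth, read_error, rng,
                           chrom=sv.chrom, ref_window=ref_window)

    dpos = int(rng.integers(-jitter, jitter + 1))
    dlen = int(rng.integers(-jitter, jitter + 1))
    pos = max(2, sv.pos + dpos)
    anchor = chrom_seq[pos - 1]
    if sv.svtype == "DEL":
        length = max(50, sv.length + dlen)
        call = SVRecord(f"{sv.id}_call", sv.chrom, pos, "DEL", length,
                        anchor + chrom_seq[pos:pos + length], anchor,
                        tech="nanopore")
    else:
        ins = _corrupt(sv.variant_seq, ins_seq_error, rng)
        call = SVRecord(f"{sv.id}_call", sv.chrom, pos, "INS", len(ins),
                        anchor, anchor + ins, tech="nanopore")
    return sv, call, reads


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_dataset(truth: SimulationTruth, outdir) -> dict:
    """Write the simulated dataset to standard text formats.

    Emits reference FASTA, genes GFF3, repeats BED, a truth VCF, the TE
    library FASTA + classification TSV and the provenance table; returns the
    path map.
    """
    from pathlib import Path
    from .sv_io import write_bed, write_fasta, write_gff3, write_sv_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = truth.annotation
    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.gff3",
        "repeats": outdir / "repeats.bed",
        "truth_vcf": outdir / "truth.vcf",
        "te_fasta": outdir / "te_library.fa",
        "te_meta": outdir / "te_library.tsv",
        "provenance": outdir / "truth_provenance.tsv",
    }
    write_fasta(ann.reference, paths["reference"])
    write_gff3(ann.genes, paths["genes"])
    write_bed(ann.repeats, paths["repeats"])
    contigs = {c: ann.chrom_len(c) for c in sorted(ann.reference)}
    write_sv_vcf([t.record for t in truth.truth_svs], paths["truth_vcf"],
                 contigs)
    write_fasta({te.te_id: te.seq for te in truth.te_library},
                paths["te_fasta"])
    pd.DataFrame([{"te_id": te.te_id, "te_class": te.te_class,
                   "superfamily": te.superfamily}
                  for te in truth.te_library]).to_csv(
        paths["te_meta"], sep="\t", index=False)
    truth.provenance_frame().to_csv(paths["provenance"], sep="\t", index=False)
    return paths


def simulate_dataset(config: SimulationConfig) -> SimulationTruth:
    """End-to-end generation: reference + truth SVs + genotypes."""
    rng = np.random.default_rng(config.seed)
    annotation = simulate_reference(config, rng)
    return simulate_population_svs(annotation, config, rng)
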