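"""Genic-feature annotation of SVs and the associated statistical tests.

Every SV receives exactly one label with precedence coding sequence > other
genic sequence > 5-kb-upstream window > intergenic: an SV touching both
coding and non-coding gene sequence is labelled ``cds``, and the upstream
label applies only to SVs that touch no genic sequence at all.  Upstream
windows are strand-aware (5' of the gene start).

Three tests accompany the annotation:

* a randomization test that reshuffles SV start positions uniformly within
  the 100-kb genome-tiling bins that contain them (conserving per-bin SV
  counts and SV lengths) and compares observed label proportions against the
  shuffled null;
* a label-permutation test on mean SV allele-frequency differences between
  the six feature pairs, Bonferroni-corrected at alpha = 0.05/6;
* a plain hypergeometric over/under-representation test of annotation terms
  in a gene set, Bonferroni-corrected by the number of terms tested.

All permutation p-values use the (count + 1) / (iterations + 1) convention,
so the smallest attainable p is 1/(iterations + 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .benchmark import GT_AA, GT_MISSING, GT_RA, GenotypeMatrix
from .sv_io import Gene, SVRecord

logger = logging.getLogger(__name__)

GENIC_LABELS = ("cds", "gene", "upstream5kb", "intergenic")
_LABEL_CODE = {lab: i for i, lab in enumerate(GENIC_LABELS)}

FEATURE_PAIRS = tuple(itertools.combinations(GENIC_LABELS, 2))
FREQ_TEST_ALPHA = 0.05 / len(FEATURE_PAIRS)  # Bonferroni over the 6 pairs


def _merge_boundaries(intervals) -> np.ndarray:
    """Merge 0-based half-open intervals into a flat sorted boundary array
    [s0, e0, s1, e1, ...]; a point x is covered iff searchsorted parity is odd."""
    if not intervals:
        return np.empty(0, dtype=np.int64)
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array([x for iv in merged for x in iv], dtype=np.int64)


def _overlaps(bounds: np.ndarray, starts: np.ndarray,
              ends: np.ndarray) -> np.ndarray:
    """Vectorized: does [start, end) overlap the merged interval union?"""
    if bounds.size == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(bounds, starts, side="right")
    inside = idx % 2 == 1  # start falls within an interval
    nxt = np.full(len(starts), np.iinfo(np.int64).max)
    has_next = idx < len(bounds)
    nxt[has_next] = bounds[idx[has_next]]
    return inside | (nxt < ends)


class GenicIndex:
    """Precedence-ready merged feature tracks per chromosome."""

    def __init__(self, cds: Dict[str, np.ndarray], gene: Dict[str, np.ndarray],
                 upstream: Dict[str, np.ndarray]):
        self.cds = cds
        self.gene = gene
        self.upstream = upstream

    @classmethod
    def from_genes(cls, genes: Sequence[Gene], upstream_bp: int = 5_000,
                   chrom_lens: Optional[dict] = None) -> "GenicIndex":
        cds: dict = {}
        body: dict = {}
        up: dict = {}
        for g in genes:
            body.setdefault(g.chrom, []).append((g.start, g.end))
            for c in g.cds:
                cds.setdefault(g.chrom, []).append(tuple(c))
            if g.strand == "-":
                win = (g.end, g.end + upstream_bp)
            else:
                win = (max(0, g.start - upstream_bp), g.start)
            if chrom_lens and g.chrom in chrom_lens:
                win = (min(win[0], chrom_lens[g.chrom]),
                       min(win[1], chrom_lens[g.chrom]))
            if win[1] > win[0]:
                up.setdefault(g.chrom, []).append(win)
        chroms = set(body) | set(cds) | set(up)
        return cls(cds={c: _merge_boundaries(cds.get(c, [])) for c in chroms},
                   gene={c: _merge_boundaries(body.get(c, [])) for c in chroms},
                   upstream={c: _merge_boundaries(up.get(c, [])) for c in chroms})

    def label_codes(self, chrom: str, starts: np.ndarray,
                    ends: np.ndarray) -> np.ndarray:
        """Label codes (0=cds, 1=gene, 2=upstream5kb, 3=intergenic)."""
        codes = np.full(len(starts), _LABEL_CODE["intergenic"], dtype=np.int8)
        empty = np.empty(0, dtype=np.int64)
        up = _overlaps(self.upstream.get(chrom, empty), starts, ends)
        codes[up] = _LABEL_CODE["upstream5kb"]
        gene = _overlaps(self.gene.get(chrom, empty), starts, ends)
        codes[gene] = _LABEL_CODE["gene"]
        cds = _overlaps(self.cds.get(chrom, empty), starts, ends)
        codes[cds] = _LABEL_CODE["cds"]
        return codes


def _as_index(genes) -> GenicIndex:
    return genes if isinstance(genes, GenicIndex) else GenicIndex.from_genes(genes)


def annotate_genic(record: SVRecord, genes) -> str:
    """Single label for one SV under the cds > gene > upstream > intergenic
    precedence.  ``genes`` may be a list of Gene models or a GenicIndex."""
    index = _as_index(genes)
    s, e = record.span0()
    code = index.label_codes(record.chrom, np.array([s]), np.array([e]))[0]
    return GENIC_LABELS[code]


def annotate_all(records: Sequence[SVRecord], genes) -> pd.DataFrame:
    """Labels for a whole call set; returns a tidy DataFrame."""
    index = _as_index(genes)
    rows = []
    by_chrom: dict = {}
    for i, sv in enumerate(records):
        by_chrom.setdefault(sv.chrom, []).append(i)
    labels = [None] * len(records)
    for chrom, idxs in by_chrom.items():
        spans = np.array([records[i].span0() for i in idxs])
        codes = index.label_codes(chrom, spans[:, 0], spans[:, 1])
        for i, code in zip(idxs, codes):
            labels[i] = GENIC_LABELS[code]
    for sv, lab in zip(records, labels):
        rows.append({"sv_id": sv.id, "chrom": sv.chrom, "pos": sv.pos,
                     "svtype": sv.svtype, "length": sv.length, "label": lab})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# randomization test on label proportions
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    observed: dict  # (svtype, label) -> proportion
    null: dict  # svtype -> (iterations x 4) array of label proportions
    p_one_sided: dict  # (svtype, label) -> p-value
    iterations: int
    seed: int


def overlap_randomization_test(records: Sequence[SVRecord], genes,
                               chrom_lens: dict, bin_size: int = 100_000,
                               iterations: int = 5_000,
                               seed: int = 0) -> RandomizationResult:
    """Bin-conservative randomization test of genic-feature overlap.

    Each iteration re-draws every SV start uniformly within the genome-tiling
    bin that contains it (length preserved, the start stays in-bin), then
    re-annotates and records the four label proportions per SV type.  The
    one-sided p per (type, label) counts null proportions at least as extreme
    as the observed one, in the direction of the observed departure from the
    null mean, with the (count + 1)/(iterations + 1) convention.
    """
    index = _as_index(genes)
    rng = np.random.default_rng(seed)
    svtypes = sorted({sv.svtype for sv in records})
    by_type = {t: [sv for sv in records if sv.svtype == t] for t in svtypes}

    observed, null = {}, {}
    for svtype, svs in by_type.items():
        chroms = np.array([sv.chrom for sv in svs])
        spans = np.array([sv.span0() for sv in svs])
        widths = spans[:, 1] - spans[:, 0]
        starts = spans[:, 0]

        codes = np.empty(len(svs), dtype=np.int8)
        for chrom in np.unique(chroms):
            m = chroms == chrom
            codes[m] = index.label_codes(chrom, starts[m], starts[m] + widths[m])
        obs_props = np.bincount(codes, minlength=4) / len(svs)
        for lab, prop in zip(GENIC_LABELS, obs_props):
            observed[(svtype, lab)] = float(prop)

        bin_start = (starts // bin_size) * bin_size
        bin_end = np.minimum(bin_start + bin_size,
                             np.array([chrom_lens[c] for c in chroms]))
        too_long = widths > (bin_end - bin_start)
        if too_long.any():
            logger.warning("%d SVs longer than their bin; starts pinned to "
                           "bin start", int(too_long.sum()))
        null_props = np.empty((iterations, 4))
        chrom_masks = {c: chroms == c for c in np.unique(chroms)}
        for it in range(iterations):
            new_starts = bin_start + rng.integers(
                0, np.maximum(bin_end - bin_start, 1))
            new_starts[too_long] = bin_start[too_long]
            it_codes = np.empty(len(svs), dtype=np.int8)
            for chrom, m in chrom_masks.items():
                it_codes[m] = index.label_codes(
                    chrom, new_starts[m], new_starts[m] + widths[m])
            null_props[it] = np.bincount(it_codes, minlength=4) / len(svs)
        null[svtype] = null_props

    p = {}
    for (svtype, lab), obs in observed.items():
        col = null[svtype][:, _LABEL_CODE[lab]]
        if obs >= col.mean():
            count = int((col >= obs).sum())
        else:
            count = int((col <= obs).sum())
        p[(svtype, lab)] = (count + 1) / (iterations + 1)
    return RandomizationResult(observed=observed, null=null, p_one_sided=p,
                               iterations=iterations, seed=seed)


# ---------------------------------------------------------------------------
# frequency-difference permutation test
# ---------------------------------------------------------------------------

@dataclass
class FreqTestResult:
    svtype: str
    pair: tuple  # (label_a, label_b)
    observed_diff: float  # mean(freq | label_a) - mean(freq | label_b)
    p_one_sided: float
    significant: bool
    alpha: float = FREQ_TEST_ALPHA


def frequency_difference_test(frame: pd.DataFrame, iterations: int = 10_000,
                              seed: int = 0) -> list:
    """Permutation test of mean allele-frequency differences between labels.

    ``frame`` needs columns ``svtype``, ``label``, ``freq``.  SVs with a
    population frequency of exactly 1 are excluded (they are more likely
    reference-assembly errors than real variants).  For each SV type and each
    of the six label pairs, the null distribution of mean differences is
    obtained by shuffling the labels across SVs; the one-sided p follows the
    direction of the observed difference.
    """
    rng = np.random.default_rng(seed)
    frame = frame[frame["freq"] < 1].copy()
    results = []
    for svtype, sub in frame.groupby("svtype", sort=True):
        codes = sub["label"].map(_LABEL_CODE).to_numpy()
        freqs = sub["freq"].to_numpy(dtype=float)
        counts = np.bincount(codes, minlength=4)

        def group_means(c):
            sums = np.bincount(c, weights=freqs, minlength=4)
            with np.errstate(invalid="ignore"):
                return np.where(counts_perm(c) > 0,
                                sums / np.maximum(counts_perm(c), 1), np.nan)

        def counts_perm(c):
            return np.bincount(c, minlength=4)

        obs_means = group_means(codes)
        null_means = np.empty((iterations, 4))
        for it in range(iterations):
            null_means[it] = group_means(rng.permutation(codes))
        for a, b in FEATURE_PAIRS:
            ia, ib = _LABEL_CODE[a], _LABEL_CODE[b]
            if counts[ia] == 0 or counts[ib] == 0:
                results.append(FreqTestResult(svtype, (a, b), float("nan"),
                                              float("nan"), False))
                continue
            obs = obs_means[ia] - obs_means[ib]
            null = null_means[:, ia] - null_means[:, ib]
            if obs >= 0:
                count = int((null >= obs).sum())
            else:
                count = int((null <= obs).sum())
            p = (count + 1) / (iterations + 1)
            results.append(FreqTestResult(svtype, (a, b), float(obs), p,
                                          p < FREQ_TEST_ALPHA))
    return results


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def enrichment_test(gene_set, universe, term_to_genes: dict,
                    min_term_size: int = 20,
                    direction: str = "over") -> pd.DataFrame:
    """Hypergeometric over/under-representation of terms in a gene set.

    Terms represented by fewer than ``min_term_size`` genes in the universe
    are skipped; reported p-values are Bonferroni-corrected by the number of
    terms actually tested (multiplied, capped at 1).
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    N, n = len(universe), len(gene_set)
    tested = []
    for term, genes in sorted(term_to_genes.items()):
        term_genes = set(genes) & universe
        if len(term_genes) < min_term_size:
            continue
        K = len(term_genes)
        k = len(term_genes & gene_set)
        if direction == "over":
            p = float(hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(hypergeom.cdf(k, N, K, n))
        tested.append({"term": term, "k": k, "term_size": K,
                       "gene_set_size": n, "universe_size": N, "p_raw": p})
    out = pd.DataFrame(tested)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p_raw"] * len(out), 1.0)
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def alt_allele_frequency(matrix: GenotypeMatrix, sv_id: str) -> float:
    """Alternate allele frequency (2*AA + RA) / (2 * non-missing calls)."""
    if sv_id not in matrix.gt.index:
        raise KeyError(f"unknown SV id {sv_id!r}")
    row = matrix.gt.loc[sv_id]
    non_missing = int((row != GT_MISSING).sum())
    if non_missing == 0:
        return float("nan")
    return (2 * int((row == GT_AA).sum()) + int((row == GT_RA).sum())) / (
        2 * non_missing)


def alt_allele_frequencies(matrix: GenotypeMatrix) -> pd.Series:
    gt = matrix.gt
    non_missing = (gt != GT_MISSING).sum(axis=1)
    alt = 2 * (gt == GT_AA).sum(axis=1) + (gt == GT_RA).sum(axis=1)
    return alt / (2 * non_missing)


def feature_span_fractions(genes, chrom_lens: dict,
                           upstream_bp: int = 5_000) -> dict:
    """Fraction of the genome covered by each precedence-exclusive feature.

    Descriptive companion to the randomization test: the naive random
    expectation for each label is simply the fraction of the genome it spans.
    """
    index = genes if isinstance(genes, GenicIndex) else GenicIndex.from_genes(
        genes, upstream_bp=upstream_bp, chrom_lens=chrom_lens)
    total = sum(chrom_lens.values())
    spans = dict.fromkeys(GENIC_LABELS, 0)
    for chrom, clen in chrom_lens.items():
        starts = np.arange(clen, dtype=np.int64)
        codes = index.label_codes(chrom, starts, starts + 1)
        counts = np.bincount(codes, minlength=4)
        for lab, cnt in zip(GENIC_LABELS, counts):
            spans[lab] += int(cnt)
    return {lab: spans[lab] / total for lab in GENIC_LABELS}
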