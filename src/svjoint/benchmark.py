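"""Genotype benchmarking of SV call sets against a per-sample truth set.

The truth set contains homozygous SV calls made from long reads for a subset
of samples.  Short-read genotype calls are compared against it per sample:
only homozygous-ALT calls count (heterozygous calls are ignored in these
inbred lines), deletions/duplications/inversions match by reciprocal overlap,
and insertions match by breakpoint distance plus insertion-sequence identity.
Sensitivity and precision are reported per SV type, size class, read-support
threshold and repeat status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import pandas as pd

from .sv_io import SVRecord, assign_size_class

GT_MISSING, GT_RR, GT_RA, GT_AA = -1, 0, 1, 2
_GT_NAMES = {GT_MISSING: "missing", GT_RR: "RR", GT_RA: "RA", GT_AA: "AA"}


@dataclass(frozen=True)
class MatchParams:
    min_reciprocal_overlap: float = 0.5  # DEL/DUP/INV
    max_ins_dist: int = 20  # bp between insertion anchors
    min_ins_seq_identity: float = 0.8
    min_repeat_overlap: float = 0.2

    def __post_init__(self):
        for name in ("min_reciprocal_overlap", "min_ins_seq_identity",
                     "min_repeat_overlap"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class GenotypeMatrix:
    """SV x sample genotype calls with per-call read-support counts.

    ``gt`` and ``support`` are pandas DataFrames indexed by SV id with one
    column per sample; genotypes are coded RR=0, RA=1, AA=2, missing=-1.
    """

    svs: list  # list[SVRecord], order matches gt.index
    gt: pd.DataFrame
    support: pd.DataFrame

    def __post_init__(self):
        ids = [sv.id for sv in self.svs]
        if list(self.gt.index) != ids or list(self.support.index) != ids:
            raise ValueError("genotype/support rows must match SV record order")
        if list(self.gt.columns) != list(self.support.columns):
            raise ValueError("genotype/support samples differ")

    @property
    def samples(self) -> list:
        return list(self.gt.columns)

    def sv_by_id(self, sv_id: str) -> SVRecord:
        try:
            return self.svs[list(self.gt.index).index(sv_id)]
        except ValueError:
            raise KeyError(f"unknown SV id {sv_id!r}") from None


@dataclass
class BenchmarkResult:
    svtype: str
    size_class: str
    threshold: int
    region: str  # "all" or "nonrepeat"
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def filter_calls_by_support(matrix: GenotypeMatrix,
                            min_reads: int) -> GenotypeMatrix:
    """Set genotype calls with fewer than ``min_reads`` supporting reads to
    missing; calls at or above the threshold are unchanged."""
    gt = matrix.gt.where(matrix.support >= min_reads, GT_MISSING)
    return GenotypeMatrix(svs=matrix.svs, gt=gt, support=matrix.support.copy())


def _reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    a0, a1 = a.span0()
    b0, b1 = b.span0()
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def _ins_identity(a: SVRecord, b: SVRecord) -> float:
    sa, sb = a.variant_seq, b.variant_seq
    if not sa or not sb:
        return 0.0
    d = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(sa), len(sb))


def _match_score(call: SVRecord, truth: SVRecord,
                 p: MatchParams) -> Optional[float]:
    """Match score in [0, 1] if the pair satisfies the match rules, else None."""
    if call.svtype != truth.svtype or call.chrom != truth.chrom:
        return None
    if call.svtype == "INS":
        if abs(call.pos - truth.pos) > p.max_ins_dist:
            return None
        ident = _ins_identity(call, truth)
        return ident if ident >= p.min_ins_seq_identity else None
    ro = _reciprocal_overlap(call, truth)
    return ro if ro >= p.min_reciprocal_overlap else None


def match_sv(call: SVRecord, truth_set: Sequence[SVRecord],
             p: MatchParams = MatchParams()) -> Optional[str]:
    """Best-matching truth id for a single call, or None."""
    best, best_score = None, -1.0
    for truth in truth_set:
        score = _match_score(call, truth, p)
        if score is not None and score > best_score:
            best, best_score = truth.id, score
    return best


def _greedy_match(calls: Sequence[SVRecord], truth: Sequence[SVRecord],
                  p: MatchParams) -> dict:
    """One-to-one greedy matching by descending overlap/identity score."""
    pairs = []
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truth):
            score = _match_score(call, t, p)
            if score is not None:
                pairs.append((score, ci, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_calls, matched_truth, mapping = set(), set(), {}
    for score, ci, ti in pairs:
        if ci in matched_calls or ti in matched_truth:
            continue
        matched_calls.add(ci)
        matched_truth.add(ti)
        mapping[ci] = ti
    return mapping


def subset_by_repeat(records: Sequence[SVRecord], repeats: Sequence,
                     min_repeat_overlap: float = 0.2):
    """Partition records into (repeat, nonrepeat) sets.

    A record belongs to the repeat set iff the fraction of its span covered
    by repeat intervals is >= the threshold; insertions use anchor-point
    containment.
    """
    by_chrom: dict = {}
    for chrom, start, end in repeats:
        by_chrom.setdefault(chrom, []).append((start, end))
    for ivs in by_chrom.values():
        ivs.sort()
    rep, nonrep = [], []
    for sv in records:
        s, e = sv.span0()
        covered = 0
        for rs, re_ in by_chrom.get(sv.chrom, ()):
            if rs >= e:
                break
            ov = min(e, re_) - max(s, rs)
            if ov > 0:
                covered += ov
        frac = covered / (e - s)
        threshold = 1.0 if sv.svtype == "INS" else min_repeat_overlap
        (rep if frac >= threshold else nonrep).append(sv)
    return rep, nonrep


def evaluate_sample(calls: Sequence[SVRecord], truth: Sequence[SVRecord],
                    p: MatchParams = MatchParams(),
                    threshold: int = 0, region: str = "all") -> list:
    """TP/FP/FN and sensitivity/precision per (svtype, size class) stratum.

    ``calls`` must already be restricted to homozygous-ALT genotype calls for
    one sample; heterozygous calls are excluded upstream (neither TP nor FP).
    """
    strata: dict = {}

    def stratum(sv: SVRecord) -> BenchmarkResult:
        key = (sv.svtype, assign_size_class(sv))
        if key not in strata:
            strata[key] = BenchmarkResult(svtype=key[0], size_class=key[1],
                                          threshold=threshold, region=region)
        return strata[key]

    mapping = _greedy_match(calls, truth, p)
    matched_truth = set(mapping.values())
    for ci, call in enumerate(calls):
        if ci in mapping:
            stratum(truth[mapping[ci]]).tp += 1
        else:
            stratum(call).fp += 1
    for ti, t in enumerate(truth):
        if ti not in matched_truth:
            stratum(t).fn += 1
    return [strata[k] for k in sorted(strata)]


def _aa_calls(matrix: GenotypeMatrix, sample: str) -> list:
    col = matrix.gt[sample]
    return [sv for sv in matrix.svs if col[sv.id] == GT_AA]


def pr_curve(matrix: GenotypeMatrix, truth: Sequence[SVRecord], sample: str,
             thresholds: Sequence[int],
             p: MatchParams = MatchParams(), region: str = "all") -> list:
    """Benchmark one sample at each ascending read-support threshold."""
    results = []
    for thr in thresholds:
        filtered = filter_calls_by_support(matrix, thr)
        calls = _aa_calls(filtered, sample)
        results.extend(evaluate_sample(calls, truth, p, threshold=thr,
                                       region=region))
    return results


def homozygous_alt_count(matrix: GenotypeMatrix, sv_id: str) -> int:
    """Number of samples with a homozygous-ALT call for one SV."""
    if sv_id not in matrix.gt.index:
        raise KeyError(f"unknown SV id {sv_id!r}")
    return int((matrix.gt.loc[sv_id] == GT_AA).sum())


def filter_by_alt_count(matrix: GenotypeMatrix, min_count: int) -> GenotypeMatrix:
    """Keep SV records observed as homozygous ALT in >= ``min_count`` samples."""
    counts = (matrix.gt == GT_AA).sum(axis=1)
    keep = counts[counts >= min_count].index
    svs = [sv for sv in matrix.svs if sv.id in set(keep)]
    ids = [sv.id for sv in svs]
    return GenotypeMatrix(svs=svs, gt=matrix.gt.loc[ids],
                          support=matrix.support.loc[ids])


def filter_by_tool_support(records: Sequence[SVRecord],
                           min_tools: int) -> list:
    """Keep records reported by at least ``min_tools`` distinct callers."""
    return [sv for sv in records if len(sv.source_tools) >= min_tools]


def results_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tidy table of benchmark results."""
    return pd.DataFrame([{
        "svtype": r.svtype, "size_class": r.size_class,
        "threshold": r.threshold, "region": r.region,
        "tp": r.tp, "fp": r.fp, "fn": r.fn,
        "sensitivity": r.sensitivity, "precision": r.precision,
    } for r in results])


def plot_pr_curve(frame: pd.DataFrame, path) -> None:
    """Sensitivity/precision scatter per stratum over thresholds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for (svtype, size_class), sub in frame.groupby(["svtype", "size_class"]):
        sub = sub.sort_values("threshold")
        ax.plot(sub["sensitivity"], sub["precision"], marker="o",
                label=f"{svtype} {size_class}")
    ax.set_xlabel("sensitivity")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
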