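"""Cross-tool/cross-sample clustering of near-identical SV calls.

Two calls of the same type and chromosome are *compatible* when their
breakpoints and lengths agree either in absolute terms (both within
``maxdist`` bp) or in relative terms (position shift, size difference and
sequence edit distance all small relative to the mean SV length).  Clusters
are connected components of the compatibility graph (single linkage), and one
representative allele per cluster is selected with configurable priority
overrides: refined alleles first (long-read call sets) or short-read alleles
first (mixed-technology call sets), falling back to a uniform random choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import edlib
import numpy as np

from .sv_io import SVRecord


@dataclass(frozen=True)
class MergeParams:
    maxdist: int = 15
    reldist: float = 0.2
    relsizediff: float = 0.1
    relshift: float = 0.1
    #: sequences longer than this skip the edit-distance check (bounded runtime)
    max_seq_len_for_dist: int = 10_000

    def __post_init__(self):
        if self.maxdist < 0:
            raise ValueError("maxdist must be >= 0")
        for name in ("reldist", "relsizediff", "relshift"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class SVCluster:
    members: list
    representative: SVRecord

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


def _comparison_seq(sv: SVRecord) -> str:
    # deletions differ in their REF allele, everything else in ALT
    return sv.ref_allele if sv.svtype == "DEL" else sv.alt_allele


def compatible(a: SVRecord, b: SVRecord, p: MergeParams = MergeParams()) -> bool:
    """True iff two normalized calls are representations of the same allele."""
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    dpos = abs(a.pos - b.pos)
    dlen = abs(a.length - b.length)
    if dpos <= p.maxdist and dlen <= p.maxdist:
        return True
    mean_len = (a.length + b.length) / 2
    if dpos / mean_len > p.relshift or dlen / mean_len > p.relsizediff:
        return False
    seq_a, seq_b = _comparison_seq(a), _comparison_seq(b)
    if max(len(seq_a), len(seq_b)) > p.max_seq_len_for_dist:
        return True  # size agreement already established; skip O(n*k) check
    max_ed = int(p.reldist * mean_len)
    res = edlib.align(seq_a, seq_b, mode="NW", task="distance", k=max_ed)
    return res["editDistance"] != -1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _sort_key(sv: SVRecord):
    return (sv.chrom, sv.pos, sv.length, sv.id)


def cluster_svs(records: Sequence[SVRecord],
                p: MergeParams = MergeParams()) -> list:
    """Single-linkage clustering of compatible calls.

    Returns :class:`SVCluster` objects (representative provisionally set to
    the first member in deterministic order) sorted by (chrom, pos, length,
    id) of their first member.  Input order does not affect the result.
    """
    records = sorted(records, key=_sort_key)
    uf = _UnionFind(len(records))
    # group by (chrom, svtype); sweep sorted by pos with a distance cutoff
    groups: dict = {}
    for idx, sv in enumerate(records):
        groups.setdefault((sv.chrom, sv.svtype), []).append(idx)
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: records[i].pos)
        max_len = max(records[i].length for i in idxs)
        for ai, i in enumerate(idxs):
            a = records[i]
            cutoff = max(p.maxdist, p.relshift * (a.length + max_len) / 2)
            for j in idxs[ai + 1:]:
                b = records[j]
                if b.pos - a.pos > cutoff:
                    break
                if uf.find(i) != uf.find(j):
                    if compatible(a, b, p):
                        uf.union(i, j)
    comps: dict = {}
    for i in range(len(records)):
        comps.setdefault(uf.find(i), []).append(records[i])
    clusters = [SVCluster(members=members, representative=members[0])
                for _, members in sorted(comps.items())]
    clusters.sort(key=lambda c: _sort_key(c.members[0]))
    return clusters


def select_representative(cluster: SVCluster, policy: str = "random",
                          rng: Optional[np.random.Generator] = None) -> SVRecord:
    """Pick one allele from a cluster.

    ``random`` samples uniformly; ``prefer_refined`` restricts the draw to
    refined alleles when any exist; ``prefer_illumina`` restricts it to
    short-read alleles when any exist (their basecalls are more accurate, so
    their representation is preferred whenever both technologies saw the SV).
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    if policy not in ("random", "prefer_refined", "prefer_illumina"):
        raise ValueError(f"unknown policy {policy!r}")
    rng = rng if rng is not None else np.random.default_rng()
    pool = cluster.members
    if policy == "prefer_refined":
        refined = [m for m in pool if m.refined]
        pool = refined or pool
    elif policy == "prefer_illumina":
        illumina = [m for m in pool if m.tech == "illumina"]
        pool = illumina or pool
    pool = sorted(pool, key=_sort_key)
    return pool[int(rng.integers(len(pool)))]


def merge_callsets(records: Sequence[SVRecord],
                   p: MergeParams = MergeParams(),
                   policy: str = "random",
                   seed: int = 0):
    """Cluster calls and select representatives.

    Returns ``(representatives, clusters, extra_info)`` where the
    representative of each cluster carries the union of member source tools
    and ``extra_info`` maps representative id to merge metadata (ClusterIDs,
    NumClusterSVs) suitable for VCF INFO output.
    """
    rng = np.random.default_rng(seed)
    clusters = cluster_svs(records, p)
    reps, extra = [], {}
    for cl in clusters:
        rep = select_representative(cl, policy, rng)
        tools = frozenset().union(*(m.source_tools for m in cl.members))
        rep = replace(rep, source_tools=tools)
        cl.representative = rep
        reps.append(rep)
        extra[rep.id] = {
            "ClusterIDs": ",".join(sorted(m.id for m in cl.members)),
            "NumClusterSVs": len(cl.members),
        }
    return reps, clusters, extra
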