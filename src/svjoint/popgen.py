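"""Population-genetics summaries from SNV or SV genotype matrices.

Variants are filtered (allele frequency, missingness, heterozygosity; SV mode
additionally drops duplications/inversions and rare alleles), pairwise
allele-sharing distances (1 - IBS) are computed, neighbor-joining trees are
built with bootstrap bipartition support, and a permutation Mantel test
relates two distance matrices (e.g. SNV-based vs SV-based) over the same
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .benchmark import GT_AA, GT_MISSING, GT_RA, GenotypeMatrix


@dataclass
class DistanceMatrix:
    samples: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.samples), len(self.samples)):
            raise ValueError("distance matrix shape does not match samples")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have a zero diagonal")


class TreeNode:
    """Minimal rooted representation of an unrooted NJ tree."""

    __slots__ = ("name", "children")

    def __init__(self, name: Optional[str] = None, children=None):
        self.name = name
        self.children = children or []  # list of (TreeNode, branch_length)

    def leaves(self) -> list:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, support: Optional[dict] = None,
               all_leaves: Optional[frozenset] = None) -> str:
        if all_leaves is None:
            all_leaves = frozenset(self.leaves())

        def fmt(node, length):
            if not node.children:
                return f"{node.name}:{length:.6g}"
            inner = ",".join(fmt(c, l) for c, l in node.children)
            label = ""
            if support is not None:
                split = _canonical_split(frozenset(node.leaves()), all_leaves)
                if split in support:
                    label = str(support[split])
            return f"({inner}){label}:{length:.6g}"

        inner = ",".join(fmt(c, l) for c, l in self.children)
        return f"({inner});"


@dataclass
class TreeWithSupport:
    tree: TreeNode
    samples: list
    n_bootstrap: int = 0
    support: dict = field(default_factory=dict)  # canonical split -> count

    def newick(self) -> str:
        return self.tree.newick(self.support if self.support else None)


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def filter_variants_for_popgen(matrix: GenotypeMatrix, mode: str = "snv",
                               maf_min: float = 0.05, miss_max: float = 0.4,
                               het_max: float = 0.1,
                               min_alt_count: int = 4) -> GenotypeMatrix:
    """Filter a genotype matrix for population analyses.

    SNV mode retains variants with minor allele frequency >= ``maf_min``,
    missing proportion <= ``miss_max`` and heterozygosity rate <= ``het_max``.
    SV mode drops duplications and inversions and removes records with a
    homozygous-ALT count below ``min_alt_count`` or a missing proportion >=
    ``miss_max`` (strict boundary: exactly 40% missing is removed).
    """
    gt = matrix.gt
    n = gt.shape[1]
    missing = (gt == GT_MISSING).sum(axis=1) / n
    non_missing = n - (gt == GT_MISSING).sum(axis=1)
    if mode == "snv":
        alt = 2 * (gt == GT_AA).sum(axis=1) + (gt == GT_RA).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freq = alt / (2 * non_missing)
        maf = np.minimum(freq, 1 - freq)
        het = (gt == GT_RA).sum(axis=1) / np.maximum(non_missing, 1)
        keep = (maf >= maf_min) & (missing <= miss_max) & (het <= het_max)
    elif mode == "sv":
        alt_count = (gt == GT_AA).sum(axis=1)
        types = np.array([sv.svtype for sv in matrix.svs])
        keep = (~np.isin(types, ("DUP", "INV"))) & \
            (alt_count >= min_alt_count) & (missing < miss_max)
    else:
        raise ValueError("mode must be 'snv' or 'sv'")
    keep_ids = gt.index[np.asarray(keep, dtype=bool)]
    svs = [sv for sv in matrix.svs if sv.id in set(keep_ids)]
    ids = [sv.id for sv in svs]
    return GenotypeMatrix(svs=svs, gt=gt.loc[ids],
                          support=matrix.support.loc[ids])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance 1 - IBS.

    IBS(i, j) is the mean over shared non-missing variants of (shared alleles
    / 2): identical genotypes share 2 alleles, het vs hom share 1, opposite
    homozygotes share 0, so d = mean(|g_i - g_j|) / 2 on 0/1/2 genotype codes.
    """
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    g = matrix.gt.to_numpy(dtype=float).T  # samples x variants
    g[g == GT_MISSING] = np.nan
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g - g[i])  # nan where either is missing
        counts = np.sum(~np.isnan(diff), axis=1)
        if (counts == 0).any():
            j = int(np.argmin(counts))
            raise ValueError(f"samples {samples[i]} and {samples[j]} share no "
                             "non-missing variants")
        d[i] = np.nansum(diff, axis=1) / counts / 2.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(samples=list(samples), d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix) -> TreeWithSupport:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken toward the smallest sample-index pair;
    branch lengths may be negative and are left as computed.  The unrooted
    tree is returned rooted at the final three-way join.
    """
    n = len(dist.samples)
    if n < 3:
        raise ValueError("need at least three samples")
    d = dist.d.copy()
    nodes = [TreeNode(name=s) for s in dist.samples]
    active = list(range(n))
    next_col = n
    # grow d as nodes are added
    size = 2 * n
    big = np.zeros((size, size))
    big[:n, :n] = d

    while len(active) > 2:
        r = len(active)
        ridx = np.array(active)
        sub = big[np.ix_(ridx, ridx)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimum in row-major order = smallest index pair on ties
        a, b = np.unravel_index(int(np.argmin(q)), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = big[i, j]
        li = dij / 2 + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lj = dij - li
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        k = next_col
        next_col += 1
        for c in active:
            if c in (i, j):
                continue
            big[k, c] = big[c, k] = (big[i, c] + big[j, c] - dij) / 2
        active = [c for c in active if c not in (i, j)] + [k]

    i, j = active
    root = TreeNode(children=[(nodes[i], big[i, j] / 2),
                              (nodes[j], big[i, j] / 2)])
    return TreeWithSupport(tree=root, samples=list(dist.samples))


def _canonical_split(leafset: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side without the smallest leaf."""
    anchor = min(all_leaves)
    return all_leaves - leafset if anchor in leafset else leafset


def bipartitions(tree: TreeNode, samples: Sequence[str]) -> set:
    """Non-trivial bipartitions (unrooted splits) induced by internal edges."""
    all_leaves = frozenset(samples)
    splits = set()

    def walk(node):
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below = below | walk(child)
        if 2 <= len(below) <= len(all_leaves) - 2:
            splits.add(_canonical_split(below, all_leaves))
        return below

    walk(tree)
    return splits


def bootstrap_support(matrix: GenotypeMatrix, B: int = 100,
                      seed: int = 0) -> TreeWithSupport:
    """Bootstrap clade support by resampling variants with replacement.

    Builds the reference NJ tree from the full matrix, then ``B`` replicate
    trees from column-resampled matrices; the support of each internal edge
    of the reference tree is the number of replicate trees containing the
    same (unrooted) bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    ref = neighbor_joining(pairwise_distance(matrix))
    ref_splits = bipartitions(ref.tree, matrix.samples)
    counts = dict.fromkeys(ref_splits, 0)
    n_var = matrix.gt.shape[0]
    for _ in range(B):
        idx = rng.integers(0, n_var, size=n_var)
        gt = matrix.gt.iloc[idx].reset_index(drop=True)
        gt.index = [f"v{i}" for i in range(n_var)]
        sup = matrix.support.iloc[idx].reset_index(drop=True)
        sup.index = gt.index
        svs = [matrix.svs[i] for i in idx]
        from dataclasses import replace as _replace
        svs = [_replace(sv, id=f"v{i}") for i, sv in enumerate(svs)]
        boot = GenotypeMatrix(svs=svs, gt=gt, support=sup)
        rep = neighbor_joining(pairwise_distance(boot))
        rep_splits = bipartitions(rep.tree, matrix.samples)
        for split in ref_splits & rep_splits:
            counts[split] += 1
    ref.support = counts
    ref.n_bootstrap = B
    return ref


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix,
                permutations: int = 999, seed: int = 0):
    """Two-sided permutation Mantel test between two distance matrices.

    The statistic is the cross-product Z = sum over unordered pairs of
    d1[i,j] * d2[i,j]; the null jointly permutes rows and columns of d2.
    The two-sided p compares |Z - mean(Z_perm)| against the permuted values,
    with the (count + 1)/(permutations + 1) convention, so the smallest
    attainable p with 999 permutations is 0.001.
    """
    if d1.samples != d2.samples:
        raise ValueError("distance matrices must share the same sample order")
    rng = np.random.default_rng(seed)
    n = len(d1.samples)
    iu = np.triu_indices(n, k=1)
    z_obs = float((d1.d[iu] * d2.d[iu]).sum())
    z_perm = np.empty(permutations)
    for it in range(permutations):
        perm = rng.permutation(n)
        dp = d2.d[np.ix_(perm, perm)]
        z_perm[it] = (d1.d[iu] * dp[iu]).sum()
    center = z_perm.mean()
    count = int((np.abs(z_perm - center) >= abs(z_obs - center) - 1e-12).sum())
    p = (count + 1) / (permutations + 1)
    return z_obs, p


def write_distance_tsv(dist: DistanceMatrix, path) -> None:
    import pandas as pd
    pd.DataFrame(dist.d, index=dist.samples,
                 columns=dist.samples).to_csv(path, sep="\t")


def write_transposed_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Transposed genotype text (variants as rows, samples as columns, allele
    dosage 0/1/2 with NA for missing) for external structure/PCA tools."""
    gt = matrix.gt.replace(GT_MISSING, np.nan)
    gt.to_csv(path, sep="\t", na_rep="NA")
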