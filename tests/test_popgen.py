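"""Variant filtering, 1-IBS distances, neighbor joining, bootstrap, Mantel."""

import itertools

import numpy as np
import pandas as pd
import pytest

from svjoint.benchmark import GT_AA, GT_MISSING, GT_RA, GT_RR, GenotypeMatrix
from svjoint.popgen import (DistanceMatrix, bipartitions, bootstrap_support,
                            filter_variants_for_popgen, mantel_test,
                            neighbor_joining, pairwise_distance)
from svjoint.sv_io import SVRecord


def _sv(id, svtype="DEL", pos=100):
    length = 60
    if svtype == "INS":
        return SVRecord(id=id, chrom="chr1", pos=pos, svtype="INS",
                        length=length, ref_allele="A",
                        alt_allele="A" + "G" * length)
    return SVRecord(id=id, chrom="chr1", pos=pos, svtype=svtype,
                    length=length, ref_allele="A" * 61, alt_allele="A")


def _matrix(gt, svtypes=None, samples=None):
    gt = np.asarray(gt, dtype=np.int8)
    n_var, n_samp = gt.shape
    samples = samples or [f"s{i}" for i in range(n_samp)]
    svtypes = svtypes or ["DEL"] * n_var
    svs = [_sv(f"v{i}", svtype=svtypes[i], pos=100 + 10_000 * i)
           for i in range(n_var)]
    ids = [sv.id for sv in svs]
    return GenotypeMatrix(
        svs=svs, gt=pd.DataFrame(gt, index=ids, columns=samples),
        support=pd.DataFrame(np.full(gt.shape, 5), index=ids,
                             columns=samples))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_snv_filter_maf_missing_het_boundaries():
    n = 20
    # MAF 0.04 < 0.05 (removed); MAF 0.05 retained
    low_maf = [GT_RA] + [GT_RR] * 19  # freq = 1/40 = 0.025 -> removed
    ok_maf = [GT_AA] + [GT_RA] * 2 + [GT_RR] * 17  # freq 4/40 = 0.1
    # heterozygosity exactly 0.1 retained (2 RA of 20)
    het_edge = [GT_RA, GT_RA] + [GT_AA] * 4 + [GT_RR] * 14
    # 45% missing removed in SNV mode (<= 0.4 retained)
    missing = [GT_MISSING] * 9 + [GT_AA] * 6 + [GT_RR] * 5
    m = _matrix([low_maf, ok_maf, het_edge, missing])
    kept = filter_variants_for_popgen(m, mode="snv")
    assert list(kept.gt.index) == ["v1", "v2"]


def test_sv_filter_drops_dup_inv_and_rare_alleles():
    n = 20
    common = [GT_AA] * 4 + [GT_RR] * 16
    rare = [GT_AA] * 3 + [GT_RR] * 17  # homozygous ALT count 3 < 4
    missing_40 = [GT_MISSING] * 8 + [GT_AA] * 6 + [GT_RR] * 6  # exactly 0.4
    dup = [GT_AA] * 10 + [GT_RR] * 10
    m = _matrix([common, rare, missing_40, dup],
                svtypes=["DEL", "DEL", "INS", "DUP"])
    kept = filter_variants_for_popgen(m, mode="sv")
    assert list(kept.gt.index) == ["v0"]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_identical_and_opposite_and_het():
    gt = np.array([[GT_AA, GT_AA, GT_RR, GT_RA]] * 10)
    m = _matrix(gt, samples=["a", "b", "c", "d"])
    d = pairwise_distance(m)
    assert d.d[0, 1] == 0.0  # identical genotype rows
    assert d.d[0, 2] == 1.0  # AA vs RR at every variant
    assert d.d[0, 3] == 0.5  # AA vs RA at every variant


def test_distance_invariant_to_variant_order(rng):
    gt = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
    m = _matrix(gt)
    d1 = pairwise_distance(m).d
    perm = rng.permutation(30)
    m2 = GenotypeMatrix(svs=[m.svs[i] for i in perm],
                        gt=m.gt.iloc[perm], support=m.support.iloc[perm])
    assert np.allclose(pairwise_distance(m2).d, d1)


def test_distance_errors_on_disjoint_missingness():
    gt = np.array([[GT_AA, GT_MISSING], [GT_MISSING, GT_RR]])
    with pytest.raises(ValueError):
        pairwise_distance(_matrix(gt))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _tree_distances(edges, leaves):
    """Path-length matrix of a tree given as {(u, v): length} edges."""
    import networkx as nx
    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    n = len(leaves)
    d = np.zeros((n, n))
    for i, a in enumerate(leaves):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(leaves):
            d[i, j] = lengths[b]
    return d


def test_nj_recovers_four_taxon_additive_tree():
    # ((A:2,B:3):1,(C:4,D:5)) with internal edge 1
    edges = {("A", "x"): 2, ("B", "x"): 3, ("x", "y"): 1,
             ("C", "y"): 4, ("D", "y"): 5}
    leaves = ["A", "B", "C", "D"]
    dist = DistanceMatrix(samples=leaves, d=_tree_distances(edges, leaves))
    tree = neighbor_joining(dist)
    splits = bipartitions(tree.tree, leaves)
    assert splits == {frozenset({"C", "D"})}  # the unique internal edge
    # branch lengths: leaf branch lengths are recovered exactly
    leaf_len = {}
    def walk(node, length):
        if not node.children:
            leaf_len[node.name] = length
        for child, l in node.children:
            walk(child, l)
    walk(tree.tree, 0)
    assert leaf_len == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})


def test_nj_three_taxa_unique_topology():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(samples=["A", "B", "C"], d=d))
    assert sorted(tree.tree.leaves()) == ["A", "B", "C"]
    assert bipartitions(tree.tree, ["A", "B", "C"]) == set()


def test_nj_ladder_topology():
    # caterpillar tree over 8 taxa from its additive matrix
    leaves = [f"L{i}" for i in range(8)]
    edges = {}
    prev = "L0"
    for i in range(1, 7):
        edges[(f"L{i}", f"n{i}")] = 1.0
        edges[(prev, f"n{i}")] = 1.0 if i == 1 else 2.0
        prev = f"n{i}"
    edges[("L7", prev)] = 1.0
    # rebuild cleanly: chain of internal nodes n1..n6, leaf Li hangs off ni
    edges = {("L0", "n1"): 1.0, ("L1", "n1"): 1.0, ("L7", "n6"): 1.0}
    for i in range(2, 7):
        edges[(f"L{i}", f"n{i}")] = 1.0
        edges[(f"n{i - 1}", f"n{i}")] = 2.0
    dist = DistanceMatrix(samples=leaves, d=_tree_distances(edges, leaves))
    tree = neighbor_joining(dist)
    splits = bipartitions(tree.tree, leaves)
    expected = set()
    for i in range(1, 6):
        side = frozenset(leaves[:i + 1])
        expected.add(side if "L0" not in side else frozenset(leaves) - side)
    assert splits == expected


def _all_five_taxon_topologies(leaves):
    """All 15 unrooted binary topologies on 5 leaves, as edge structures."""
    a, b, c, d, e = leaves
    base_edges = [(a, "x"), (b, "x"), (c, "y"), ("x", "y")]  # quartet ab|cd
    topologies = []
    for quartet in [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]:
        (p, q), (r, s) = quartet
        edges = [(p, "x"), (q, "x"), (r, "y"), (s, "y"), ("x", "y")]
        for edge in list(edges):
            new = [t for t in edges if t != edge]
            u, v = edge
            new += [(u, "z"), (v, "z"), (e, "z")]
            topologies.append(new)
    return topologies


def _min_evolution_splits(dist: DistanceMatrix):
    """Brute-force minimum-evolution oracle over all 5-taxon topologies."""
    leaves = dist.samples
    best, best_splits = None, None
    for edges in _all_five_taxon_topologies(leaves):
        nodes = sorted({u for edge in edges for u in edge})
        idx = {u: i for i, u in enumerate(nodes)}
        pairs = list(itertools.combinations(range(len(leaves)), 2))
        X = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        import networkx as nx
        g = nx.Graph()
        for k, (u, v) in enumerate(edges):
            g.add_edge(u, v, key=k)
        for row, (i, j) in enumerate(pairs):
            path = nx.shortest_path(g, leaves[i], leaves[j])
            for u, v in zip(path, path[1:]):
                k = edges.index((u, v)) if (u, v) in edges else \
                    edges.index((v, u))
                X[row, k] = 1
            y[row] = dist.d[i, j]
        lengths, *_ = np.linalg.lstsq(X, y, rcond=None)
        total = lengths.sum()
        if best is None or total < best - 1e-9:
            best = total
            g2 = nx.Graph(edges)
            splits = set()
            for u, v in edges:
                g2.remove_edge(u, v)
                comp = nx.node_connected_component(g2, u) & set(leaves)
                g2.add_edge(u, v)
                if 2 <= len(comp) <= 3:
                    side = frozenset(comp)
                    if min(leaves) in side:
                        side = frozenset(leaves) - side
                    splits.add(side)
            best_splits = splits
    return best_splits


def test_nj_matches_minimum_evolution_oracle(rng):
    """NJ recovers the minimum-evolution topology on additive matrices."""
    leaves = ["A", "B", "C", "D", "E"]
    for _ in range(10):
        edges = {}
        topo = _all_five_taxon_topologies(leaves)[int(rng.integers(15))]
        for u, v in topo:
            edges[(u, v)] = float(rng.uniform(0.5, 3.0))
        dist = DistanceMatrix(samples=leaves,
                              d=_tree_distances(edges, leaves))
        tree = neighbor_joining(dist)
        assert bipartitions(tree.tree, leaves) == _min_evolution_splits(dist)


def test_nj_rejects_asymmetric_input():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(samples=["a", "b", "c"], d=d))


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def test_two_populations_give_full_support(rng):
    """500 fixed-difference variants: the separating edge appears in every
    bootstrap replicate."""
    n_per = 6
    gt = np.zeros((500, 2 * n_per), dtype=np.int8)
    gt[:, n_per:] = GT_AA
    noise = rng.random(gt.shape) < 0.02  # a little within-group noise
    gt[noise] = GT_RA
    m = _matrix(gt)
    tws = bootstrap_support(m, B=20, seed=3)
    split = frozenset(m.samples[n_per:])
    assert tws.support[split] == 20


def test_bootstrap_reproducible_under_seed(rng):
    gt = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
    m = _matrix(gt)
    s1 = bootstrap_support(m, B=10, seed=4).support
    s2 = bootstrap_support(m, B=10, seed=4).support
    assert s1 == s2


def test_unstructured_data_has_weak_support(rng):
    gt = rng.integers(0, 3, size=(80, 12)).astype(np.int8)
    m = _matrix(gt)
    tws = bootstrap_support(m, B=20, seed=5)
    assert np.mean(list(tws.support.values())) < 15


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _structured_distance(rng, n=12):
    coords = np.r_[rng.normal(0, 1, (n // 2, 2)),
                   rng.normal(5, 1, (n - n // 2, 2))]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    return DistanceMatrix(samples=[f"s{i}" for i in range(n)], d=d)


def test_mantel_self_comparison_hits_floor(rng):
    d1 = _structured_distance(rng)
    z, p = mantel_test(d1, d1, permutations=199, seed=0)
    assert p == pytest.approx(1 / 200)


def test_mantel_floor_is_0_001_at_999_permutations(rng):
    d1 = _structured_distance(rng)
    _, p = mantel_test(d1, d1, permutations=999, seed=0)
    assert p == pytest.approx(0.001)


def test_mantel_requires_matching_samples(rng):
    d1 = _structured_distance(rng)
    d2 = DistanceMatrix(samples=[f"t{i}" for i in range(12)], d=d1.d)
    with pytest.raises(ValueError):
        mantel_test(d1, d2)


def test_mantel_independent_matrices_not_extreme(rng):
    ps = []
    n = 12
    for seed in range(20):
        r = np.random.default_rng(seed)
        r2 = np.random.default_rng(seed + 1000)
        # unstructured, mutually independent distance matrices
        c1 = r.normal(0, 1, (n, 2))
        c2 = r2.normal(0, 1, (n, 2))
        samples = [f"s{i}" for i in range(n)]
        d1 = DistanceMatrix(samples=samples, d=np.linalg.norm(
            c1[:, None] - c1[None, :], axis=2))
        d2 = DistanceMatrix(samples=samples, d=np.linalg.norm(
            c2[:, None] - c2[None, :], axis=2))
        ps.append(mantel_test(d1, d2, permutations=99, seed=seed)[1])
    assert np.mean(ps) > 0.2  # roughly uniform, certainly not all small
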