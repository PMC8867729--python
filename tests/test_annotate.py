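"""Genic labelling precedence, randomization tests, enrichment, frequencies."""

import math

import numpy as np
import pandas as pd
import pytest

from svjoint.annotate import (FREQ_TEST_ALPHA, GENIC_LABELS,
                              alt_allele_frequency, annotate_all,
                              annotate_genic, enrichment_test,
                              feature_span_fractions,
                              frequency_difference_test,
                              overlap_randomization_test)
from svjoint.benchmark import GT_AA, GT_MISSING, GT_RA, GT_RR, GenotypeMatrix
from svjoint.sv_io import Gene, SVRecord


def _sv(id, pos, length=100, svtype="DEL", chrom="chr1"):
    if svtype == "INS":
        return SVRecord(id=id, chrom=chrom, pos=pos, svtype="INS",
                        length=length, ref_allele="A",
                        alt_allele="A" + "G" * length)
    return SVRecord(id=id, chrom=chrom, pos=pos, svtype=svtype, length=length,
                    ref_allele="A" * (length + 1), alt_allele="A")


@pytest.fixture()
def genes():
    # gene A: [20000, 30000) on +, CDS exons [21000,22000) and [25000,26000)
    # gene B: [60000, 70000) on -, CDS [62000,64000)
    return [
        Gene(id="A", chrom="chr1", start=20_000, end=30_000, strand="+",
             cds=((21_000, 22_000), (25_000, 26_000))),
        Gene(id="B", chrom="chr1", start=60_000, end=70_000, strand="-",
             cds=((62_000, 64_000),)),
    ]


# ---------------------------------------------------------------------------
# precedence
# ---------------------------------------------------------------------------

def test_cds_wins_over_intron(genes):
    # spans the CDS/intron boundary of gene A
    assert annotate_genic(_sv("x", 21_900, 300), genes) == "cds"


def test_intron_only_is_gene(genes):
    assert annotate_genic(_sv("x", 23_000, 300), genes) == "gene"


def test_upstream_requires_no_genic_overlap(genes):
    # within 5 kb upstream of gene A (plus strand: [15000, 20000))
    assert annotate_genic(_sv("x", 16_000, 300), genes) == "upstream5kb"
    # overlapping both the upstream window and the gene body -> gene wins
    assert annotate_genic(_sv("x", 19_900, 300), genes) == "gene"


def test_upstream_is_strand_aware(genes):
    # gene B is on the minus strand: upstream window is [70000, 75000)
    assert annotate_genic(_sv("x", 71_000, 300), genes) == "upstream5kb"
    # the plus-strand side of B (i.e. [55000, 60000)) is NOT upstream
    assert annotate_genic(_sv("x", 56_000, 300), genes) == "intergenic"


def test_intergenic_fallback(genes):
    assert annotate_genic(_sv("x", 90_000, 300), genes) == "intergenic"


def test_insertion_uses_anchor_point(genes):
    assert annotate_genic(_sv("x", 21_500, 300, svtype="INS"), genes) == "cds"
    assert annotate_genic(_sv("x", 19_999, 300, svtype="INS"),
                          genes) == "upstream5kb"


def test_annotate_all_matches_single(genes, rng):
    records = [_sv(f"r{i}", int(p), 200)
               for i, p in enumerate(rng.integers(1_000, 95_000, 100))]
    frame = annotate_all(records, genes)
    for rec in records:
        expected = annotate_genic(rec, genes)
        assert frame.loc[frame.sv_id == rec.id, "label"].item() == expected


# ---------------------------------------------------------------------------
# randomization test
# ---------------------------------------------------------------------------

def test_randomization_p_floor_and_determinism(genes):
    # all SVs inside CDS while their bins are mostly non-genic: observed is
    # more extreme than every permutation, so p hits the (count+1) floor
    records = [_sv(f"r{i}", 21_100 + i, 50, svtype="DEL") for i in range(20)]
    chrom_lens = {"chr1": 100_000}
    res = overlap_randomization_test(records, genes, chrom_lens,
                                     iterations=400, seed=5)
    assert res.p_one_sided[("DEL", "cds")] == pytest.approx(1 / 401)
    res2 = overlap_randomization_test(records, genes, chrom_lens,
                                      iterations=400, seed=5)
    assert np.array_equal(res.null["DEL"], res2.null["DEL"])


def test_randomization_proportions_sum_to_one(genes, rng):
    records = [_sv(f"r{i}", int(p), 200, svtype=t)
               for i, (p, t) in enumerate(zip(
                   rng.integers(1_000, 95_000, 60),
                   rng.choice(["DEL", "INS"], 60)))]
    res = overlap_randomization_test(records, genes, {"chr1": 100_000},
                                     iterations=50, seed=1)
    for svtype, null in res.null.items():
        assert np.allclose(null.sum(axis=1), 1.0)
        obs = sum(res.observed[(svtype, lab)] for lab in GENIC_LABELS)
        assert obs == pytest.approx(1.0)


def test_shuffling_stays_within_bins(genes):
    """SVs in a bin whose span is entirely intergenic can never acquire a
    genic label, however many times they are shuffled."""
    records = [_sv(f"r{i}", 85_000 + 7 * i, 60) for i in range(15)]
    # bin [80000, 90000) contains no gene features at all
    res = overlap_randomization_test(records, genes, {"chr1": 100_000},
                                     bin_size=10_000, iterations=300, seed=2)
    null = res.null["DEL"]
    intergenic_col = GENIC_LABELS.index("intergenic")
    assert np.all(null[:, intergenic_col] == 1.0)


def test_sv_longer_than_bin_is_pinned(genes, caplog):
    records = [_sv("big", 85_000, 30_000)]
    with caplog.at_level("WARNING"):
        res = overlap_randomization_test(records, genes, {"chr1": 130_000},
                                         bin_size=10_000, iterations=10,
                                         seed=0)
    assert "longer than their bin" in caplog.text
    assert res.null["DEL"].shape == (10, 4)


# ---------------------------------------------------------------------------
# frequency-difference test
# ---------------------------------------------------------------------------

def test_freq_test_alpha_is_bonferroni_over_six_pairs():
    assert FREQ_TEST_ALPHA == pytest.approx(0.05 / 6)
    assert FREQ_TEST_ALPHA == pytest.approx(0.0083, abs=5e-5)


def test_freq_test_excludes_fixed_variants(rng):
    frame = pd.DataFrame({
        "svtype": ["DEL"] * 40,
        "label": ["cds"] * 20 + ["intergenic"] * 20,
        "freq": [0.2] * 20 + [1.0] * 20,
    })
    results = frequency_difference_test(frame, iterations=100, seed=0)
    pair = next(r for r in results if r.pair == ("cds", "intergenic"))
    # every intergenic SV is fixed and excluded -> the pair is NA
    assert math.isnan(pair.observed_diff)


def test_freq_test_detects_constructed_difference(rng):
    frame = pd.DataFrame({
        "svtype": ["DEL"] * 80,
        "label": ["cds"] * 40 + ["intergenic"] * 40,
        "freq": np.r_[rng.uniform(0.05, 0.15, 40),
                      rng.uniform(0.55, 0.65, 40)],
    })
    results = frequency_difference_test(frame, iterations=500, seed=0)
    pair = next(r for r in results if r.pair == ("cds", "intergenic"))
    assert pair.observed_diff < -0.3
    assert pair.p_one_sided == pytest.approx(1 / 501)
    assert pair.significant


def test_freq_test_null_not_significant(rng):
    frame = pd.DataFrame({
        "svtype": ["INS"] * 100,
        "label": rng.choice(GENIC_LABELS, 100),
        "freq": rng.uniform(0.05, 0.9, 100),
    })
    results = frequency_difference_test(frame, iterations=300, seed=3)
    assert sum(r.significant for r in results) <= 1


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def _hypergeom_tail_enumeration(k, N, K, n, upper=True):
    """Exhaustive tail sum of the hypergeometric pmf via binomials."""
    def pmf(x):
        return (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    xs = range(k, min(K, n) + 1) if upper else range(0, k + 1)
    return sum(pmf(x) for x in xs)


def test_hypergeometric_matches_enumeration(rng):
    for _ in range(25):
        N = int(rng.integers(20, 200))
        universe = [f"g{i}" for i in range(N)]
        n = int(rng.integers(5, N))
        gene_set = list(rng.choice(universe, size=n, replace=False))
        K = int(rng.integers(3, N))
        term_genes = list(rng.choice(universe, size=K, replace=False))
        table = enrichment_test(gene_set, universe, {"T": term_genes},
                                min_term_size=1, direction="over")
        k = len(set(term_genes) & set(gene_set))
        assert table.p_raw.item() == pytest.approx(
            _hypergeom_tail_enumeration(k, N, K, n, upper=True), rel=1e-9)
        table = enrichment_test(gene_set, universe, {"T": term_genes},
                                min_term_size=1, direction="under")
        assert table.p_raw.item() == pytest.approx(
            _hypergeom_tail_enumeration(k, N, K, n, upper=False), rel=1e-9)


def test_enrichment_term_size_threshold_and_bonferroni():
    universe = [f"g{i}" for i in range(100)]
    gene_set = universe[:10]
    terms = {"small": universe[:19], "big": universe[:25],
             "other": universe[40:80]}
    table = enrichment_test(gene_set, universe, terms, min_term_size=20)
    assert set(table.term) == {"big", "other"}  # 19-gene term skipped
    assert (table.p_bonferroni <= 1).all()
    assert np.allclose(table.p_bonferroni,
                       np.minimum(table.p_raw * len(table), 1))


def test_enrichment_input_validation():
    with pytest.raises(ValueError):
        enrichment_test(["a"], [], {"T": ["a"]})
    with pytest.raises(ValueError):
        enrichment_test(["a", "zzz"], ["a", "b"], {"T": ["a"]})


def test_random_gene_set_rarely_significant(rng):
    universe = [f"g{i}" for i in range(300)]
    terms = {f"T{j}": list(rng.choice(universe, size=40, replace=False))
             for j in range(15)}
    hits = 0
    for seed in range(30):
        r = np.random.default_rng(seed)
        gene_set = list(r.choice(universe, size=50, replace=False))
        table = enrichment_test(gene_set, universe, terms, min_term_size=20)
        if (table.p_bonferroni < 0.05).any():
            hits += 1
    assert hits <= 3


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def test_alt_allele_frequency_arithmetic():
    svs = [_sv("a", 100), _sv("b", 300)]
    samples = ("s1", "s2", "s3", "s4")
    gt = pd.DataFrame([[GT_AA, GT_AA, GT_RR, GT_RR],
                       [GT_AA, GT_RA, GT_RR, GT_RR]],
                      index=["a", "b"], columns=samples)
    support = pd.DataFrame(np.full((2, 4), 5), index=["a", "b"],
                           columns=samples)
    m = GenotypeMatrix(svs=svs, gt=gt, support=support)
    assert alt_allele_frequency(m, "a") == pytest.approx(0.5)
    assert alt_allele_frequency(m, "b") == pytest.approx(0.375)
    gt.loc["a"] = GT_MISSING
    assert math.isnan(alt_allele_frequency(m, "a"))


def test_feature_span_fractions_sum_to_one(genes):
    fractions = feature_span_fractions(genes, {"chr1": 100_000})
    assert sum(fractions.values()) == pytest.approx(1.0)
    assert fractions["cds"] == pytest.approx(0.04)  # 4 kb of CDS / 100 kb
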