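"""TE classification, TIR/TSD structure, and the excision haplotype analysis."""

import numpy as np
import pytest

from svjoint.simulate import (TETemplate, simulate_excision_snvs,
                              simulate_te_insertion)
from svjoint.sv_io import SVRecord, _revcomp
from svjoint.te import (TEEntry, annotate_te, annotate_te_from_hits,
                        assign_excision_groups, excision_analysis,
                        find_tir_tsd, is_excision_footprint,
                        tir_match_proportion)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _ins(id, seq, pos=5_000):
    return SVRecord(id=id, chrom="chr1", pos=pos, svtype="INS",
                    length=len(seq), ref_allele="A", alt_allele="A" + seq)


def _del(id, seq, pos=5_000):
    return SVRecord(id=id, chrom="chr1", pos=pos, svtype="DEL",
                    length=len(seq), ref_allele="A" + seq, alt_allele="A")


# ---------------------------------------------------------------------------
# 80/80 TE annotation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def te_library():
    rng = np.random.default_rng(4)
    return [
        TEEntry("te_short", _random_seq(rng, 520), "DNA", "Tc1-Mariner"),
        TEEntry("te_long", _random_seq(rng, 4_000), "Copia_LTR", "Copia"),
    ]


def test_annotate_te_passing_hit(te_library, rng):
    te = te_library[0]
    # 450 bp of the TE plus 50 bp of novel sequence: query coverage 90%,
    # subject coverage 450/520 = 86.5% -> annotated
    query = te.seq[:450] + _random_seq(rng, 50)
    ann = annotate_te(_ins("x", query), te_library)
    assert ann is not None and ann.te_id == "te_short"
    assert ann.query_cov >= 0.8 and ann.subject_cov >= 0.8


def test_annotate_te_subject_coverage_failure(te_library, rng):
    te = te_library[0]
    # the query aligns over ~95% of itself but covers only 70% of the TE:
    # this is the filter that keeps partial/truncated matches unannotated
    query = te.seq[:364] + _random_seq(rng, 20)
    ann = annotate_te(_ins("x", query), te_library)
    assert ann is None


def test_annotate_te_length_threshold(te_library):
    te = te_library[0]
    short = _del("x", te.seq[:99])
    assert annotate_te(short, te_library) is None
    just_long_enough = _del("y", te.seq[:100])
    # 100 bp of a 520 bp TE fails subject coverage; still None
    assert annotate_te(just_long_enough, te_library) is None


def test_annotate_te_monotone_in_thresholds(te_library, rng):
    """Relaxing the 80/80 thresholds never removes an annotation."""
    for i in range(10):
        frac = 0.5 + 0.05 * i
        te = te_library[0]
        n = int(len(te.seq) * frac)
        query = te.seq[:max(n, 120)]
        strict = annotate_te(_ins("q", query), te_library)
        relaxed = annotate_te(_ins("q", query), te_library,
                              min_query_cov=0.5, min_subject_cov=0.5)
        if strict is not None:
            assert relaxed is not None


def test_annotate_te_deletion_matches_whole_element(te_library):
    te = te_library[0]
    ann = annotate_te(_del("d", te.seq), te_library)
    assert ann is not None
    assert ann.te_class == "DNA" and ann.superfamily == "Tc1-Mariner"


def test_annotate_te_from_tabular_hits(te_library):
    import pandas as pd
    te = te_library[0]
    record = _ins("q1", te.seq[:500])
    hits = pd.DataFrame([{
        "qseqid": "q1", "sseqid": "te_short", "pident": 99.0, "length": 500,
        "mismatch": 2, "gapopen": 0, "qstart": 1, "qend": 500, "sstart": 1,
        "send": 500, "evalue": 1e-100, "bitscore": 900.0,
    }])
    meta = {te.te_id: te for te in te_library}
    ann = annotate_te_from_hits(record, hits, meta)
    assert ann is not None and ann.te_id == "te_short"
    # a hit covering too little of the subject is rejected
    hits.loc[0, ["send"]] = 350
    assert annotate_te_from_hits(record, hits, meta) is None


# ---------------------------------------------------------------------------
# TIR / TSD identification
# ---------------------------------------------------------------------------

def _mite_context(rng, tir_len=30, core_len=400, tsd="TA", mismatches=0,
                  flank=40):
    template = TETemplate("t", tsd=tsd, tir_len_range=(tir_len, tir_len + 1),
                          core_len_range=(core_len, core_len + 1))
    element, tir, _ = simulate_te_insertion(template, rng,
                                            tir_mismatches=mismatches)
    left = _random_seq(rng, flank - len(tsd)) + tsd
    right = tsd + _random_seq(rng, flank - len(tsd))
    return left + element + right, flank, tir, tsd


def test_find_tir_tsd_on_constructed_mite(rng):
    seq, flank, tir, tsd = _mite_context(rng)
    report = find_tir_tsd(seq, flank)
    assert report is not None
    assert report.tsd == tsd
    assert report.tir_left == tir
    assert report.match_proportion == 1.0
    assert report.tir_right == _revcomp(tir)


def test_find_tir_tsd_tolerates_tir_mismatches(rng):
    seq, flank, tir, tsd = _mite_context(rng, mismatches=2)
    report = find_tir_tsd(seq, flank)
    assert report is not None and report.tsd == tsd
    assert abs(len(report.tir_left) - len(tir)) <= 2
    assert report.match_proportion >= (len(tir) - 2 - 2) / len(tir)


def test_find_tir_tsd_rejects_random_sequence(rng):
    false_hits = 0
    for _ in range(200):
        seq = _random_seq(rng, 480)
        if find_tir_tsd(seq, 40) is not None:
            false_hits += 1
    assert false_hits <= 4  # >= 98% of random sequences yield no TIR


def test_find_tir_tsd_too_short_returns_none(rng):
    assert find_tir_tsd(_random_seq(rng, 90), 40) is None


# ---------------------------------------------------------------------------
# TIR match proportion
# ---------------------------------------------------------------------------

def test_tir_match_proportion_identical(rng):
    tir = _random_seq(rng, 30)
    assert tir_match_proportion(tir, _revcomp(tir)) == 1.0


def test_tir_match_proportion_single_substitution(rng):
    tir = _random_seq(rng, 30)
    other = list(_revcomp(tir))
    other[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[10]]
    assert tir_match_proportion(tir, "".join(other)) == pytest.approx(29 / 30)


def test_tir_match_proportion_symmetric(rng):
    for _ in range(20):
        a = _random_seq(rng, int(rng.integers(15, 40)))
        b = _random_seq(rng, int(rng.integers(15, 40)))
        assert tir_match_proportion(a, b) == pytest.approx(
            tir_match_proportion(b, a))


def test_tir_match_proportion_rejects_empty():
    with pytest.raises(ValueError):
        tir_match_proportion("", "ACGT")


# ---------------------------------------------------------------------------
# excision analysis
# ---------------------------------------------------------------------------

def test_excision_footprint_detection():
    fp = _ins("fp", "TACGAG", pos=5_002)
    assert is_excision_footprint(fp, site_pos=5_000, tsd="TA")
    assert not is_excision_footprint(fp, site_pos=6_000, tsd="TA")
    assert not is_excision_footprint(fp, site_pos=5_000, tsd="GG")
    long_ins = _ins("x", "TA" + "G" * 40, pos=5_000)
    assert not is_excision_footprint(long_ins, site_pos=5_000, tsd="TA")


def test_excision_groups_and_contrasting_counts(default_truth):
    """The constructed number of discordant SNVs between the TE-present and
    excised haplotypes is recovered exactly."""
    truth = default_truth
    assert truth.excision is not None
    site = truth.excision
    groups = assign_excision_groups(truth.genotypes, site["te_sv_id"],
                                    site["footprint_sv_id"])
    assert all(groups.values())  # three non-empty groups
    assert not set(groups["present"]) & set(groups["excised"])

    host = next(t for t in truth.truth_svs
                if t.record.id == site["te_sv_id"])
    region = (host.record.chrom, max(1, host.record.pos - 20_000),
              host.record.pos + 20_000)
    snvs = simulate_excision_snvs(truth, region, groups, n_snvs=156,
                                  n_discordant_present_excised=3,
                                  n_discordant_absent_present=129)
    res = excision_analysis(groups, snvs, region)
    assert res.contrasting[("excised", "present")] == 3
    assert res.contrasting[("absent", "present")] == 129


def test_excision_identical_groups_contrast_zero(default_truth):
    truth = default_truth
    samples = truth.genotypes.samples
    groups = {"absent": samples[:10], "present": samples[10:20],
              "excised": samples[10:20]}
    host = next(t for t in truth.truth_svs if t.allele_class == "te")
    region = (host.record.chrom, 1, 400_000)
    snvs = simulate_excision_snvs(truth, region, groups, n_snvs=50,
                                  n_discordant_present_excised=0,
                                  n_discordant_absent_present=10)
    res = excision_analysis(groups, snvs, region)
    assert res.contrasting[("excised", "present")] == 0


def test_excision_counts_invariant_to_sample_order(default_truth):
    truth = default_truth
    site = truth.excision
    groups = assign_excision_groups(truth.genotypes, site["te_sv_id"],
                                    site["footprint_sv_id"])
    host = next(t for t in truth.truth_svs if t.record.id == site["te_sv_id"])
    region = (host.record.chrom, 1, 400_000)
    snvs = simulate_excision_snvs(truth, region, groups, n_snvs=60,
                                  n_discordant_present_excised=5,
                                  n_discordant_absent_present=20)
    res1 = excision_analysis(groups, snvs, region)
    shuffled = {g: list(reversed(v)) for g, v in groups.items()}
    res2 = excision_analysis(shuffled, snvs, region)
    assert res1.contrasting == res2.contrasting
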