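import numpy as np
import pandas as pd
import pytest

from backfold import (
    aa_gc_comparison,
    composition_by_quantile,
    derive_sets_by_trend,
    gc_rank_partition,
    validate_orf,
)
from backfold.composition_analysis import CodonSetPartition, QuantileCompositionTable
from backfold.dbf_scoring import DbfResult
from backfold.sequence_io import AMINO_ACIDS, SENSE_CODONS, SYNONYMOUS_FAMILIES


def _result(rid, score):
    return DbfResult(rid, 2, 0.5, np.zeros(1), 0, 0, 1, score)


class TestCompositionByQuantile:
    def test_single_group_equals_pooled_corpus(self):
        recs = [validate_orf("a", "ATGGTGGTGTAA"), validate_orf("b", "ATGCTGAAATAA")]
        results = [_result("a", 0.5), _result("b", 0.5)]
        table = composition_by_quantile(recs, results)
        # 6 sense codons pooled: ATG x2, GTG x2, CTG, AAA
        assert table.codon_freq.at["GTG", "mid"] == pytest.approx(2 / 6)
        assert table.codon_freq.at["ATG", "mid"] == pytest.approx(2 / 6)
        assert np.isnan(table.codon_freq["low"]).all()
        assert table.n_orfs == {"low": 0, "mid": 2, "high": 0}

    def test_disjoint_codon_groups_separate(self):
        lo = validate_orf("lo", "ATGAAAAAATAA")   # AT-rich
        hi = validate_orf("hi", "ATGGGCGGCTAA")   # GC-rich
        table = composition_by_quantile(
            [lo, hi], [_result("lo", 0.01), _result("hi", 0.99)]
        )
        assert table.codon_freq.at["AAA", "low"] > 0
        assert table.codon_freq.at["AAA", "high"] == 0
        assert table.codon_freq.at["GGC", "high"] > 0
        assert table.gc["high"] > table.gc["low"]

    def test_frequencies_sum_to_one_per_group(self):
        recs = [validate_orf("a", "ATGGTGCTGAAATAA")]
        table = composition_by_quantile([recs[0]], [_result("a", 0.98)])
        assert table.codon_freq["high"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table.aa_freq["high"].sum() == pytest.approx(1.0, abs=1e-9)


class TestGcRankPartition:
    def test_glycine_and_phenylalanine_splits(self):
        p = gc_rank_partition()
        assert set(p.codons_for("G", 2)) == {"GGC", "GGG"}
        assert set(p.codons_for("G", 1)) == {"GGA", "GGT"}
        assert p.codons_for("F", 2) == ["TTC"]
        assert p.codons_for("F", 1) == ["TTT"]

    def test_m_and_w_excluded_from_codon_sets(self):
        p = gc_rank_partition()
        assert "ATG" not in p.set1_codons | p.set2_codons
        assert "TGG" not in p.set1_codons | p.set2_codons
        # but single-codon families still resolve for ORF construction
        assert p.codons_for("M", 1) == ["ATG"]
        assert p.codons_for("W", 2) == ["TGG"]

    def test_every_multicodon_family_covered_both_sides(self):
        p = gc_rank_partition()
        for aa in AMINO_ACIDS:
            if len(SYNONYMOUS_FAMILIES[aa]) > 1:
                assert p.codons_for(aa, 1) and p.codons_for(aa, 2)

    def test_aa_sets_are_ten_and_ten_and_deterministic(self):
        p, q = gc_rank_partition(), gc_rank_partition()
        assert len(p.set1_aas) == len(p.set2_aas) == 10
        assert p.set1_aas == q.set1_aas and p.set2_codons == q.set2_codons

    def test_set2_codons_never_less_gc_than_family_mates(self):
        p = gc_rank_partition()
        gc = lambda c: sum(b in "GC" for b in c)
        for aa in AMINO_ACIDS:
            fam = SYNONYMOUS_FAMILIES[aa]
            if len(fam) == 1:
                continue
            assert min(gc(c) for c in p.codons_for(aa, 2)) >= max(
                gc(c) for c in p.codons_for(aa, 1)
            )


def _table_with_trends(up_codons, down_codons, jitter=0.0):
    """Composition table where up_codons rise strictly low->high and
    down_codons fall; all other codons flat."""
    base = 1.0 / len(SENSE_CODONS)
    data = {}
    for g, delta in (("low", -0.2), ("mid", 0.0), ("high", 0.2)):
        col = {}
        for c in SENSE_CODONS:
            if c in up_codons:
                col[c] = base * (1 + delta + jitter)
            elif c in down_codons:
                col[c] = base * (1 - delta - jitter)
            else:
                col[c] = base
        data[g] = pd.Series(col)
    codon_freq = pd.DataFrame(data)
    aa_rows = {}
    for g in ("low", "mid", "high"):
        per_aa = {}
        for aa in AMINO_ACIDS:
            per_aa[aa] = sum(codon_freq.at[c, g] for c in SYNONYMOUS_FAMILIES[aa])
        aa_rows[g] = pd.Series(per_aa)
    return QuantileCompositionTable(codon_freq, pd.DataFrame(aa_rows), {}, {})


class TestTrendVote:
    def test_single_dataset_strict_increase_is_set2(self):
        t = _table_with_trends({"GGC"}, {"GGA"})
        p = derive_sets_by_trend([t])
        assert "GGC" in p.set2_codons and "GGA" in p.set1_codons

    def test_majority_vote_across_datasets(self):
        up = _table_with_trends({"GGC"}, {"GGA"})
        down = _table_with_trends({"GGA"}, {"GGC"})
        p = derive_sets_by_trend([up, up, down])
        assert "GGC" in p.set2_codons and "GGA" in p.set1_codons

    def test_tied_votes_fall_back_to_gc_rule(self):
        up = _table_with_trends({"GGC"}, {"GGA"})
        down = _table_with_trends({"GGA"}, {"GGC"})
        flat = _table_with_trends(set(), set())
        p = derive_sets_by_trend([up, down, flat])
        fallback = gc_rank_partition()
        assert ("GGC" in p.set2_codons) == ("GGC" in fallback.set2_codons)
        assert ("GGA" in p.set1_codons) == ("GGA" in fallback.set1_codons)

    def test_gc_driven_trends_recover_gc_rank_partition(self):
        # trends generated directly from codon G+C rank across 20 datasets
        gc = lambda c: sum(b in "GC" for b in c)
        fallback = gc_rank_partition()
        tables = []
        for _ in range(20):
            tables.append(_table_with_trends(fallback.set2_codons, fallback.set1_codons))
        p = derive_sets_by_trend(tables)
        agreement = len(
            p.set2_codons & fallback.set2_codons | p.set1_codons & fallback.set1_codons
        ) / len(p.set1_codons | p.set2_codons)
        assert agreement >= 0.9

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            derive_sets_by_trend([])


def test_partition_file_round_trip(tmp_path):
    from backfold.composition_analysis import read_partition, write_partition

    part = gc_rank_partition()
    path = tmp_path / "partition.tsv"
    write_partition(part, path)
    again = read_partition(path)
    assert again == part


class TestAaGcComparison:
    def test_gc_rank_sets_differ_significantly(self):
        u, p = aa_gc_comparison(gc_rank_partition())
        assert p < 0.001

    def test_swapping_sets_reflects_u_keeps_p(self):
        part = gc_rank_partition()
        swapped = CodonSetPartition(
            part.set1_codons, part.set2_codons, part.set2_aas, part.set1_aas
        )
        u1, p1 = aa_gc_comparison(part)
        u2, p2 = aa_gc_comparison(swapped)
        assert p1 == pytest.approx(p2)
        assert u1 + u2 == pytest.approx(100)  # U + U' = n1*n2

    def test_identical_gc_profiles_give_p_one(self):
        # sets with identical GC-share multisets: D,C,E,H,Q vs five 1.5-mates
        part = gc_rank_partition()
        u, p = aa_gc_comparison(
            CodonSetPartition(
                part.set1_codons,
                part.set2_codons,
                frozenset("CDEHQSTVLM"),
                frozenset("AGPRWFKNYI"),
            )
        )
        assert 0 < p <= 1.0
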