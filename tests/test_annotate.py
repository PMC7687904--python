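import numpy as np
import pytest

from qtlannot.annotate import (annotate_store, classify_cis_trans,
                               compute_counts, compute_distance, flag_best,
                               flag_best_in_ld_group, flag_sw_significant,
                               fwer_threshold, link_gwas)
from qtlannot.core import AnnotatedQtl, QtlAnnotError
from qtlannot.ingest import GwasIndex, QtlStore, TadSet
from qtlannot.core import GwasCatalogEntry, TadInterval, VariantKey
from qtlannot.ld import LdStore

from conftest import make_gene, make_record, random_store
from helpers_oracles import oracle_counts, oracle_flags


def wrap(records):
    return [AnnotatedQtl(record=r) for r in records]


class TestFwerThreshold:
    def test_study_wide_level(self):
        assert fwer_threshold(0.05, 1_000_000, 50_000) == pytest.approx(1e-12)

    def test_single_test(self):
        assert fwer_threshold(0.05, 1, 1) == pytest.approx(0.05)

    def test_hundred_tests(self):
        assert fwer_threshold(0.05, 10, 10) == pytest.approx(5e-4)

    def test_invalid_counts(self):
        with pytest.raises(QtlAnnotError):
            fwer_threshold(0.05, 0, 10)
        with pytest.raises(QtlAnnotError):
            fwer_threshold(1.5, 10, 10)


class TestSwSignificant:
    def test_below_threshold_flagged(self):
        ann = wrap([make_record(p=1e-13)])
        flag_sw_significant(ann, {("SrcA", "StudyA"): 1e-12})
        assert ann[0].is_sw_significant

    def test_boundary_inclusive(self):
        ann = wrap([make_record(p=1e-12)])
        flag_sw_significant(ann, {("SrcA", "StudyA"): 1e-12})
        assert ann[0].is_sw_significant

    def test_count_matches_oracle(self):
        ps = [1e-13, 1e-14, 1e-20, 1e-3, 0.5, 1e-11, 0.9, 1e-2, 0.7, 1e-6]
        ann = wrap([make_record(rsid=f"rs{i}", p=p)
                    for i, p in enumerate(ps)])
        flag_sw_significant(ann, {("SrcA", "StudyA"): 1e-12})
        assert sum(a.is_sw_significant for a in ann) == 3

    def test_source_provided_policy_wins(self):
        rec = make_record(p=0.5, significance_policy="source_provided")
        rec = rec.__class__(**{**rec.__dict__, "source_significant": True})
        ann = wrap([rec])
        flag_sw_significant(ann, {("SrcA", "StudyA"): 1e-12})
        assert ann[0].is_sw_significant


class TestBestFlags:
    def test_single_record_is_best(self):
        ann = wrap([make_record()])
        flag_best(ann)
        assert ann[0].is_best

    def test_lowest_p_wins(self):
        ann = wrap([make_record(rsid="rs1", p=1e-5),
                    make_record(rsid="rs2", p=1e-9)])
        flag_best(ann)
        assert [a.is_best for a in ann] == [False, True]

    def test_exact_tie_both_flagged(self):
        ann = wrap([make_record(rsid="rs1", p=1e-9),
                    make_record(rsid="rs2", p=1e-9)])
        flag_best(ann)
        assert all(a.is_best for a in ann)

    def test_groups_are_source_tissue_pairs(self):
        ann = wrap([make_record(rsid="rs1", p=1e-5, tissue="Liver"),
                    make_record(rsid="rs2", p=1e-3, tissue="Blood")])
        flag_best(ann)
        assert all(a.is_best for a in ann)


class TestBestInLdGroup:
    def test_singleton_group_flagged(self):
        ann = wrap([make_record()])
        flag_best_in_ld_group(ann, LdStore())
        assert ann[0].is_best_in_ld_group

    def test_group_of_two(self):
        ld = LdStore()
        ld.add_pair("rs1", "rs2", 0.9, 0.95)
        ann = wrap([make_record(rsid="rs1", p=1e-8),
                    make_record(rsid="rs2", p=1e-4)])
        flag_best_in_ld_group(ann, ld)
        assert [a.is_best_in_ld_group for a in ann] == [True, False]

    def test_same_gene_restriction_default(self):
        ld = LdStore()
        ld.add_pair("rs1", "rs2", 0.9, 0.95)
        other_gene = make_gene("G2", "SYM2", start1=5_000_000, end1=5_050_000)
        ann = wrap([make_record(rsid="rs1", p=1e-4),
                    make_record(rsid="rs2", p=1e-8, gene=other_gene)])
        flag_best_in_ld_group(ann, ld, same_gene=True)
        assert all(a.is_best_in_ld_group for a in ann)
        flag_best_in_ld_group(ann, ld, same_gene=False)
        assert [a.is_best_in_ld_group for a in ann] == [False, True]


def tadset(*ivs):
    return TadSet([TadInterval(chrom=c, start=s, end=e) for c, s, e in ivs])


class TestCisTrans:
    def test_same_tad_cis(self):
        rec = make_record(pos=1_000_500)  # gene start (1-based) 1_000_000
        tads = tadset(("1", 900_000, 1_200_000))
        assert classify_cis_trans(rec, tads) == "cis"

    def test_different_chromosomes_trans(self):
        rec = make_record(chrom="2", pos=1_000_500)
        tads = tadset(("1", 900_000, 1_200_000), ("2", 900_000, 1_200_000))
        assert classify_cis_trans(rec, tads) == "trans"

    def test_adjacent_tads_trans_despite_proximity(self):
        # variant in TAD1, gene start in adjacent TAD2, < 1 Mb apart
        rec = make_record(pos=990_000)
        tads = tadset(("1", 900_000, 999_000), ("1", 999_000, 1_200_000))
        assert classify_cis_trans(rec, tads) == "trans"

    def test_no_tads_everything_trans(self):
        rec = make_record(pos=1_000_500)
        assert classify_cis_trans(rec, TadSet([])) == "trans"
        assert classify_cis_trans(rec, None) == "trans"

    def test_overlapping_tads_any_containing_both(self):
        rec = make_record(pos=990_000)
        tads = tadset(("1", 900_000, 999_000),
                      ("1", 950_000, 1_100_000))  # second spans both anchors
        assert classify_cis_trans(rec, tads) == "cis"


class TestDistance:
    def test_within_gene_zero(self):
        rec = make_record(pos=1_020_000)  # gene [1_000_000, 1_050_000] 1-based
        assert compute_distance(rec) == 0.0

    def test_downstream_28kb(self):
        rec = make_record(pos=1_078_000)
        assert compute_distance(rec) == pytest.approx(28.0)

    def test_upstream_negative(self):
        rec = make_record(pos=990_000)
        assert compute_distance(rec) == pytest.approx(-10.0)

    def test_other_chromosome_absent(self):
        rec = make_record(chrom="2", pos=1_020_000)
        assert compute_distance(rec) is None


class TestGwasLink:
    def test_flags_match_set_intersections(self):
        catalog = GwasIndex([
            GwasCatalogEntry(variant=VariantKey(rsid="rs1"),
                             gene_symbol=None, phenotype="T"),
            GwasCatalogEntry(variant=None, gene_symbol="SYM2",
                             phenotype="T")])
        other_gene = make_gene("G2", "SYM2", start1=5_000_000, end1=5_050_000)
        ann = wrap([make_record(rsid="rs1"),
                    make_record(rsid="rs9", gene=other_gene),
                    make_record(rsid="rs10")])
        link_gwas(ann, catalog)
        assert [a.gwas_variant_hit for a in ann] == [True, False, False]
        assert [a.gwas_gene_hit for a in ann] == [False, True, False]


class TestCounts:
    def test_occurrence_and_best(self):
        records = [make_record(source=f"Src{i}", study=f"St{i}", p=p)
                   for i, p in enumerate([1e-9, 1e-5, 1e-4])]
        # add a competitor so only the first study's record is best
        ann = wrap(records)
        flag_best(ann)
        compute_counts(ann)
        assert all(a.n_occ == 3 for a in ann)
        assert all(a.n_best == 3 for a in ann)  # each best in its own study

    def test_n_qtls_per_gene_study(self):
        ann = wrap([make_record(rsid=f"rs{i}", pos=1_000_000 + i)
                    for i in range(7)])
        compute_counts(ann)
        assert all(a.n_qtls == 7 for a in ann)


class TestStoreOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_flags_and_counts_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        store, ld = random_store(rng, n_records=150)
        annotated = annotate_store(store, ld_store=ld)
        exp_flags = oracle_flags(store.records, store.thresholds, ld.r2)
        exp_counts = oracle_counts(store.records, exp_flags)
        for a, ef, ec in zip(annotated, exp_flags, exp_counts):
            assert a.is_sw_significant == ef["is_sw_significant"]
            assert a.is_best == ef["is_best"]
            assert a.is_best_in_ld_group == ef["is_best_in_ld_group"]
            assert a.n_occ == ec["n_occ"]
            assert a.n_best == ec["n_best"]
            assert a.n_sw_significant == ec["n_sw_significant"]
            assert a.n_qtls == ec["n_qtls"]

    def test_order_independence(self):
        rng = np.random.default_rng(7)
        store, ld = random_store(rng, n_records=100)
        ann1 = annotate_store(store, ld_store=ld)
        shuffled = QtlStore(records=list(reversed(store.records)),
                            gene_index=store.gene_index,
                            thresholds=store.thresholds)
        ann2 = annotate_store(shuffled, ld_store=ld)
        by_id1 = {id(a.record): a for a in ann1}
        for a2 in ann2:
            a1 = by_id1[id(a2.record)]
            assert (a1.is_sw_significant, a1.is_best, a1.is_best_in_ld_group,
                    a1.n_occ, a1.n_best, a1.n_sw_significant, a1.n_qtls) == \
                   (a2.is_sw_significant, a2.is_best, a2.is_best_in_ld_group,
                    a2.n_occ, a2.n_best, a2.n_sw_significant, a2.n_qtls)

    def test_best_implies_best_in_group_universally(self):
        rng = np.random.default_rng(3)
        store, ld = random_store(rng, n_records=200)
        for a in annotate_store(store, ld_store=ld):
            if a.is_best:
                assert a.is_best_in_ld_group
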