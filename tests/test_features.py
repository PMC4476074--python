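import pytest

from irdetect import (
    AlignedRead,
    GenomicInterval,
    ReadIndex,
    build_feature_table,
    build_normalization_plan,
    count_flanking_exon_reads,
    count_intron_reads,
    count_junction_reads,
    count_splice_site_reads,
    gene_rpkm,
    intron_coverage,
)
from irdetect.annotation import GeneModel, IntronRecord
from irdetect.features import count_gene_exonic_reads

import _oracle


def make_intron(start=50, end=80, strand="+"):
    return IntronRecord(
        intron_id=f"chr1:{start}-{end}:{strand}",
        interval=GenomicInterval("chr1", start, end, strand),
        gene_id="g1",
        upstream_exon=GenomicInterval("chr1", 0, start, strand),
        downstream_exon=GenomicInterval("chr1", end, end + 50, strand),
        ss5_pos=start if strand != "-" else end,
        ss3_pos=end if strand != "-" else start,
    )


def unspliced(start, end, name="r", unique=True):
    return AlignedRead(name, "chr1", ((start, end),), unique=unique)


class TestCountIntronReads:
    def test_empty(self):
        assert count_intron_reads([], make_intron()) == 0

    def test_contained_straddling_and_spliced(self):
        intron = make_intron(50, 80)
        reads = [unspliced(50 + i, 55 + i, f"in{i}") for i in range(5)]
        reads += [unspliced(45, 55, "straddle1"), unspliced(75, 85, "straddle2")]
        reads.append(AlignedRead("spliced", "chr1", ((40, 50), (80, 90))))
        assert count_intron_reads(reads, intron) == 5

    def test_read_equal_to_intron_counted(self):
        assert count_intron_reads([unspliced(50, 80)], make_intron(50, 80)) == 1

    def test_multimapper_ignored(self):
        assert count_intron_reads([unspliced(55, 70, unique=False)], make_intron()) == 0


class TestCountFlankingExonReads:
    def test_additivity_over_disjoint_exons(self):
        intron = make_intron(50, 80)
        reads = [unspliced(i, i + 10, f"up{i}") for i in range(0, 30, 10)]
        reads += [unspliced(80 + i, 90 + i, f"dn{i}") for i in range(4)]
        assert count_flanking_exon_reads(reads, intron) == 7

    def test_exon_intron_overlap_not_counted(self):
        assert count_flanking_exon_reads([unspliced(45, 55)], make_intron()) == 0


class TestCountJunctionReads:
    def test_exact_gap_with_anchors(self):
        intron = make_intron(50, 80)
        read = AlignedRead("j", "chr1", ((40, 50), (80, 90)))
        assert count_junction_reads([read], intron, min_anchor=4) == 1

    def test_short_anchor_rejected(self):
        intron = make_intron(50, 80)
        read = AlignedRead("j", "chr1", ((47, 50), (80, 90)))
        assert count_junction_reads([read], intron, min_anchor=4) == 0

    def test_off_by_one_gap_rejected(self):
        intron = make_intron(50, 80)
        reads = [
            AlignedRead(f"ok{i}", "chr1", ((40, 50), (80, 90))) for i in range(12)
        ]
        reads.append(AlignedRead("off1", "chr1", ((40, 51), (80, 90))))
        reads.append(AlignedRead("off2", "chr1", ((40, 50), (81, 90))))
        assert count_junction_reads(reads, intron) == 12


class TestCountSpliceSiteReads:
    def test_straddling_read_counted(self):
        assert count_splice_site_reads([unspliced(45, 55)], make_intron(), "5ss") == 1

    def test_read_ending_at_boundary_not_counted(self):
        assert count_splice_site_reads([unspliced(40, 50)], make_intron(), "5ss") == 0

    def test_min_overhang_respected(self):
        intron = make_intron(50, 80)
        assert count_splice_site_reads([unspliced(45, 55)], intron, "5ss", 5) == 1
        assert count_splice_site_reads([unspliced(45, 55)], intron, "5ss", 6) == 0

    def test_minus_strand_sides_swap(self):
        intron = make_intron(50, 80, strand="-")
        assert count_splice_site_reads([unspliced(75, 85)], intron, "5ss") == 1
        assert count_splice_site_reads([unspliced(45, 55)], intron, "3ss") == 1

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError, match="side"):
            count_splice_site_reads([], make_intron(), "donor")


class TestIntronCoverage:
    def test_no_reads(self):
        assert intron_coverage([], make_intron()) == 0.0

    def test_partial_coverage_fraction(self):
        intron = IntronRecord(
            "i", GenomicInterval("chr1", 100, 200), "g1",
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300),
            100, 200,
        )
        reads = [unspliced(100, 150), unspliced(140, 195, "b")]
        assert intron_coverage(reads, intron) == pytest.approx(0.95)

    def test_single_spanning_read(self):
        assert intron_coverage([unspliced(50, 80)], make_intron()) == 1.0

    def test_monotone_in_reads(self):
        intron = make_intron(50, 80)
        reads = [unspliced(50 + 3 * i, 55 + 3 * i, f"r{i}") for i in range(8)]
        prev = 0.0
        for k in range(len(reads) + 1):
            cov = intron_coverage(reads[:k], intron)
            assert cov >= prev
            prev = cov


class TestGeneRpkm:
    def test_closed_form(self):
        assert gene_rpkm(1000, 10**7, 2000) == pytest.approx(50.0)

    def test_zero_reads(self):
        assert gene_rpkm(0, 10**7, 2000) == 0.0

    def test_halves_when_total_doubles(self):
        assert gene_rpkm(10, 2 * 10**6, 500) == gene_rpkm(10, 10**6, 500) / 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gene_rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            gene_rpkm(1, 100, 0)


class TestNormalizationPlan:
    def test_basic(self):
        plan = build_normalization_plan({"a": 100, "b": 200})
        assert plan.sns == 100
        assert plan.scale_factors == {"a": 1.0, "b": 0.5}

    def test_published_library_sizes(self):
        totals = {
            "skip1": 28465249, "skip2": 20849546, "wt1": 44865242, "wt2": 18343654,
        }
        plan = build_normalization_plan(totals)
        assert plan.sns == 18343654
        # a raw count of 100 in skip1 rescales to 100 * 18343654 / 28465249
        assert 100 * plan.scale_factors["skip1"] == pytest.approx(64.4423, abs=5e-4)

    def test_single_sample_factor_one(self):
        assert build_normalization_plan({"only": 7}).scale_factors == {"only": 1.0}

    def test_conservation_total_times_factor_is_sns(self):
        plan = build_normalization_plan({"a": 3141, "b": 2718, "c": 9001})
        for s, total in plan.sample_totals.items():
            assert total * plan.scale_factors[s] == pytest.approx(plan.sns, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_normalization_plan({})
        with pytest.raises(ValueError):
            build_normalization_plan({"a": 0})


class TestOracleEquivalence:
    """Every counting feature matches an independent per-read brute-force scan."""

    def test_all_features_match_brute_force(self, dataset):
        sample = next(iter(dataset.treatment))
        reads = dataset.samples[sample]
        assert len(reads) >= 1000
        assert len(dataset.catalog) >= 60
        index = ReadIndex(reads)
        for intron in dataset.catalog:
            assert count_intron_reads(index, intron) == _oracle.brute_count_intron(
                reads, intron
            )
            assert count_flanking_exon_reads(
                index, intron
            ) == _oracle.brute_count_exon(reads, intron)
            assert count_junction_reads(index, intron) == _oracle.brute_count_junc(
                reads, intron
            )
            for side in ("5ss", "3ss"):
                assert count_splice_site_reads(
                    index, intron, side
                ) == _oracle.brute_count_ss(reads, intron, side)
            assert intron_coverage(index, intron) == pytest.approx(
                _oracle.brute_coverage(reads, intron)
            )
        for gene in dataset.genes:
            assert count_gene_exonic_reads(index, gene) == _oracle.brute_gene_exonic(
                reads, gene
            )

    def test_feature_disjointness(self, dataset):
        """A spliced read never enters n_intron/n_5ss/n_3ss; junction and
        intron-contained read sets are disjoint by construction."""
        sample = next(iter(dataset.treatment))
        reads = dataset.samples[sample]
        spliced = [r for r in reads if r.spliced]
        unspliced_contained = [r for r in reads if not r.spliced]
        for intron in dataset.catalog[:10]:
            assert count_intron_reads(spliced, intron) == 0
            assert count_splice_site_reads(spliced, intron, "5ss") == 0
            assert count_splice_site_reads(spliced, intron, "3ss") == 0
            assert count_junction_reads(unspliced_contained, intron) == 0


class TestBuildFeatureTable:
    def _toy(self):
        intron = make_intron(50, 80)
        gene = GeneModel(
            "g1",
            [("t1", [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 80, 130)])],
        )
        reads = [unspliced(55, 70, "i1"), unspliced(10, 40, "e1"),
                 unspliced(45, 55, "s5"), unspliced(75, 85, "s3"),
                 AlignedRead("j1", "chr1", ((40, 50), (80, 90)))]
        return intron, gene, reads

    def test_identity_plan_equals_raw_counts(self):
        intron, gene, reads = self._toy()
        plan = build_normalization_plan({"t": len(reads), "c": len(reads)})
        table = build_feature_table(
            {"t": reads}, {"c": reads}, [intron], [gene], plan
        )
        row = table.iloc[0]
        assert row["TNintron"] == 1 and row["CNintron"] == 1
        assert row["TNexon"] == 1
        assert row["TNjunc"] == 1
        assert row["TN5ss"] == 1 and row["TN3ss"] == 1

    def test_identical_replicates_double_counts(self):
        intron, gene, reads = self._toy()
        plan = build_normalization_plan({"a": 5, "b": 5, "c": 5})
        single = build_feature_table({"a": reads}, {"c": reads}, [intron], [gene], plan)
        double = build_feature_table(
            {"a": reads, "b": reads}, {"c": reads}, [intron], [gene], plan
        )
        for col in ("TNintron", "TNexon", "TNjunc", "TN5ss", "TN3ss"):
            assert double.iloc[0][col] == 2 * single.iloc[0][col]
        # coverage is a fraction: pooling identical replicates leaves it unchanged
        assert double.iloc[0]["TNcoverage"] == single.iloc[0]["TNcoverage"]

    def test_fixture_counts_match_per_intron_oracle(self, dataset, feature_table):
        plan = build_normalization_plan(
            {s: len(r) for s, r in dataset.samples.items()}
        )
        treat = dataset.treatment
        expected = {}
        for intron in dataset.catalog:
            expected[intron.intron_id] = sum(
                _oracle.brute_count_intron(reads, intron) * plan.scale_factors[s]
                for s, reads in treat.items()
            )
        got = feature_table.set_index("intron_id")["TNintron"]
        for intron_id, value in expected.items():
            assert got[intron_id] == pytest.approx(value)

    def test_empty_catalog_warns_and_returns_empty(self):
        intron, gene, reads = self._toy()
        with pytest.warns(UserWarning, match="empty"):
            table = build_feature_table({"t": reads}, {"c": reads}, [], [gene])
        assert table.empty
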