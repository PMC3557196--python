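"""Aggregation, percentage arithmetic, release comparison and report tests.

The printed-figure checks use the published residue counts of a large
sequence database (5.64E9 aa total, 2.90E9 in domains, region counts
per type) purely as arithmetic inputs.
"""

import pytest

from darkspace.model import (
    AnnotationTable,
    DataError,
    DomainHit,
    ProteinRecord,
    RegionAnnotation,
)
from darkspace.synthetic_data import GeneratorConfig, generate_proteome
from darkspace.universe_stats import (
    ReleaseSnapshot,
    SpaceTable,
    aggregate,
    compare_releases,
    darkmatter_summary,
    percent_table,
    read_report_tsv,
    round_half_up,
    sci3,
    write_report,
)

NR_TABLE = dict(
    total_aa=5_640_000_000,
    domain_aa=2_900_000_000,
    region_total_aa={"LC": 414_000_000, "TM": 374_000_000,
                     "CC": 67_800_000, "SP": 54_300_000},
    region_within_aa={"LC": 272_000_000, "TM": 120_000_000,
                      "CC": 46_500_000, "SP": 46_200_000},
)


@pytest.fixture
def nr_space():
    return SpaceTable(**NR_TABLE)


class TestPercentTable:
    def test_published_total_space_row(self, nr_space):
        row = percent_table(nr_space)["total_space"]
        assert row == {"all_proteins": 100.0, "LC": 7.3, "TM": 6.6,
                       "CC": 1.2, "SP": 1.0, "all_regions": 16.1}

    def test_published_domain_space_row(self, nr_space):
        row = percent_table(nr_space)["domain_space"]
        assert row == {"all_proteins": 51.4, "LC": 9.4, "TM": 4.1,
                       "CC": 1.6, "SP": 1.6, "all_regions": 16.7}

    def test_all_regions_cells_are_row_sums(self, nr_space):
        assert nr_space.all_regions_total_aa == sum(
            NR_TABLE["region_total_aa"].values())
        assert nr_space.all_regions_within_aa == sum(
            NR_TABLE["region_within_aa"].values())

    def test_full_coverage_row(self):
        space = SpaceTable(total_aa=100, domain_aa=100)
        assert percent_table(space)["domain_space"]["all_proteins"] == 100.0

    def test_zero_denominator_rejected(self):
        space = SpaceTable(total_aa=100, domain_aa=0)
        with pytest.raises(DataError):
            percent_table(space)

    def test_rounding_is_half_up(self):
        assert round_half_up(16.65) == 16.7
        assert round_half_up(9.349) == 9.3
        assert round_half_up(0.05) == 0.1


class TestDarkMatterSummary:
    def test_published_subtraction(self):
        s = darkmatter_summary(5_640_000_000, 2_900_000_000, 509_000_000)
        assert s.pct_classic_dark == 48.6
        assert s.pct_expanded_dark == 39.6
        assert s.pct_short_linker == 9.0

    def test_fully_covered_space(self):
        s = darkmatter_summary(100, 100, 0)
        assert s.pct_classic_dark == 0.0 and s.pct_expanded_dark == 0.0

    def test_hand_arithmetic(self):
        s = darkmatter_summary(100, 40, 10)
        assert s.pct_classic_dark == 60.0
        assert s.pct_expanded_dark == 50.0

    def test_classic_plus_domain_is_100(self):
        for args in [(1000, 517, 91), (12345, 6789, 1000), (7, 3, 1)]:
            s = darkmatter_summary(*args)
            assert abs(s.pct_domain + s.pct_classic_dark - 100.0) <= 0.1

    def test_precondition_enforced(self):
        with pytest.raises(DataError):
            darkmatter_summary(100, 80, 30)


class TestCompareReleases:
    def test_published_deltas(self):
        snaps = [ReleaseSnapshot("r22", 2_800_000_000, 47.7),
                 ReleaseSnapshot("r24", 4_000_000_000, 48.9),
                 ReleaseSnapshot("r26", 5_600_000_000, 51.4)]
        comp = compare_releases(snaps)
        assert comp.deltas == [1.2, 2.5]

    def test_database_doubling_ratio(self):
        comp = compare_releases([ReleaseSnapshot("a", 2_800_000_000, 47.7),
                                 ReleaseSnapshot("b", 5_600_000_000, 51.4)])
        assert comp.total_ratios == [2.0]

    def test_identical_snapshots_zero_deltas(self):
        s = ReleaseSnapshot("x", 1000, 50.0)
        assert compare_releases([s, s, s]).deltas == [0.0, 0.0]

    def test_absolute_dark_matter_grows_while_pct_shrinks(self):
        comp = compare_releases([ReleaseSnapshot("a", 2_800_000_000, 47.7),
                                 ReleaseSnapshot("b", 5_600_000_000, 51.4)])
        assert comp.darkmatter_aa[1] > comp.darkmatter_aa[0]

    def test_single_snapshot_rejected(self):
        with pytest.raises(DataError):
            compare_releases([ReleaseSnapshot("a", 10, 1.0)])


def toy_table():
    return AnnotationTable(
        proteins=[ProteinRecord("p1", 100), ProteinRecord("p2", 100)],
        domain_hits=[DomainHit("p1", "D", 1, 100, 50.0, 1e-10, "pfam")],
        regions=[])


class TestAggregate:
    def test_single_protein_half_covered(self):
        table = AnnotationTable(
            proteins=[ProteinRecord("p1", 100)],
            domain_hits=[DomainHit("p1", "D", 1, 50, 50.0, 1e-10, "pfam")])
        space, summary = aggregate(table)
        assert (space.total_aa, space.domain_aa) == (100, 50)
        assert summary.pct_domain == 50.0

    def test_two_protein_half_dark(self):
        space, summary = aggregate(toy_table())
        assert summary.pct_domain == 50.0
        assert summary.pct_classic_dark == 50.0

    def test_ground_truth_recovered_exactly(self, small_proteome):
        cfg, table, truth = small_proteome
        space, summary = aggregate(table, threshold_aa=cfg.linker_threshold_aa)
        assert space.total_aa == truth.total_aa
        assert space.domain_aa == truth.domain_aa
        assert summary.short_linker_aa == sum(
            t.short_linker_aa for t in truth.proteins)
        assert summary.darkmatter_aa == sum(
            t.darkmatter_aa for t in truth.proteins)

    def test_empty_proteome_rejected(self):
        with pytest.raises(DataError):
            aggregate(AnnotationTable())

    def test_additive_over_disjoint_proteomes(self):
        cfg_a = GeneratorConfig(n_proteins=40, seed=1, with_sequences=False)
        ta, _ = generate_proteome(cfg_a)
        cfg_b = GeneratorConfig(n_proteins=40, seed=2, with_sequences=False)
        tb, _ = generate_proteome(cfg_b)
        # relabel the second proteome to keep identifiers disjoint
        tb_renamed = AnnotationTable(
            proteins=[ProteinRecord("b" + p.seq_id, p.length)
                      for p in tb.proteins],
            domain_hits=[DomainHit("b" + h.seq_id, h.model_name, h.start, h.end,
                                   h.bit_score, h.evalue, h.source, h.model_acc)
                         for h in tb.domain_hits],
            regions=[RegionAnnotation("b" + r.seq_id, r.region_type, r.start,
                                      r.end, r.source_tool)
                     for r in tb.regions])
        merged = AnnotationTable(
            proteins=ta.proteins + tb_renamed.proteins,
            domain_hits=ta.domain_hits + tb_renamed.domain_hits,
            regions=ta.regions + tb_renamed.regions)
        sa, _ = aggregate(ta)
        sb, _ = aggregate(tb_renamed)
        sm, _ = aggregate(merged)
        assert sm.total_aa == sa.total_aa + sb.total_aa
        assert sm.domain_aa == sa.domain_aa + sb.domain_aa
        for t in ("LC", "TM", "CC", "SP"):
            assert sm.region_total_aa[t] == (sa.region_total_aa[t]
                                             + sb.region_total_aa[t])

    def test_duplication_leaves_percentages_unchanged(self):
        cfg = GeneratorConfig(n_proteins=40, seed=3, with_sequences=False)
        t, _ = generate_proteome(cfg)
        doubled = AnnotationTable(
            proteins=t.proteins + [ProteinRecord("x" + p.seq_id, p.length)
                                   for p in t.proteins],
            domain_hits=t.domain_hits + [
                DomainHit("x" + h.seq_id, h.model_name, h.start, h.end,
                          h.bit_score, h.evalue, h.source, h.model_acc)
                for h in t.domain_hits],
            regions=t.regions + [
                RegionAnnotation("x" + r.seq_id, r.region_type, r.start, r.end,
                                 r.source_tool) for r in t.regions])
        _, s1 = aggregate(t)
        _, s2 = aggregate(doubled)
        assert (s1.pct_domain, s1.pct_classic_dark, s1.pct_expanded_dark) == (
            s2.pct_domain, s2.pct_classic_dark, s2.pct_expanded_dark)

    def test_phobius_tm_excluded_by_default(self):
        table = AnnotationTable(
            proteins=[ProteinRecord("p1", 100)],
            domain_hits=[DomainHit("p1", "D", 1, 50, 50.0, 1e-10, "pfam")],
            regions=[RegionAnnotation("p1", "TM", 10, 30, "tmhmm"),
                     RegionAnnotation("p1", "TM", 60, 80, "phobius")])
        space, _ = aggregate(table)
        assert space.region_total_aa["TM"] == 21
        space2, _ = aggregate(table, tm_source="phobius")
        assert space2.region_total_aa["TM"] == 21
        assert space2.region_within_aa["TM"] == 0


class TestReports:
    def test_tsv_report_contains_published_cell(self, nr_space, tmp_path):
        summary = darkmatter_summary(nr_space.total_aa, nr_space.domain_aa,
                                     509_000_000)
        path = tmp_path / "stats.tsv"
        write_report(nr_space, summary, path, format="tsv")
        text = path.read_text()
        assert "51.4" in text and "2.90E+09" in text

    def test_tsv_report_roundtrip(self, nr_space, tmp_path):
        summary = darkmatter_summary(nr_space.total_aa, nr_space.domain_aa,
                                     509_000_000)
        path = tmp_path / "stats.tsv"
        write_report(nr_space, summary, path, format="tsv")
        space2, summary2 = read_report_tsv(path)
        assert space2.total_aa == nr_space.total_aa
        assert space2.domain_aa == nr_space.domain_aa
        assert space2.region_total_aa == nr_space.region_total_aa
        assert space2.region_within_aa == nr_space.region_within_aa
        assert summary2 == summary

    def test_empty_regions_render_zero(self, tmp_path):
        space = SpaceTable(total_aa=100, domain_aa=50)
        summary = darkmatter_summary(100, 50, 10)
        path = tmp_path / "stats.tsv"
        write_report(space, summary, path, format="tsv")
        space2, _ = read_report_tsv(path)
        assert all(v == 0 for v in space2.region_total_aa.values())

    def test_scientific_notation_style(self):
        assert sci3(2_900_000_000) == "2.90E+09"
        assert sci3(509_000_000) == "5.09E+08"
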