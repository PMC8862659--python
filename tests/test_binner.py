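"""Alignment parsing, retention filters and per-read assignment rules."""

import io

import numpy as np
import pytest

from lcabin.binner import (
    NO_HITS,
    UNASSIGNED,
    AlignmentRecord,
    BinnerError,
    BinningParams,
    ReadAlignments,
    assign_function_best_hit,
    assign_taxon_interval_union_lca,
    assign_taxon_naive_lca,
    bin_run,
    filter_alignments,
    parse_alignments_tab,
    percent,
    ratio,
    restrict_to_clades,
    subtree_cover,
    summarize_run,
    taxon_interval_cover,
    write_assignments_tsv,
)
from lcabin.refdb import MappingDatabase
from lcabin.taxonomy import parse_ncbi_nodes


def record(query="r1", subject="s__G", score=100.0, evalue=1e-10, start=1, end=90):
    return AlignmentRecord(
        query_id=query,
        subject_accession=subject,
        percent_identity=95.0,
        align_length=30,
        query_start=start,
        query_end=end,
        evalue=evalue,
        bit_score=score,
    )


@pytest.fixture(scope="module")
def small_tree():
    # root 1 -> {2 (bacteria-like), 2157 (archaea-like), 2759 (off-target)}
    # 2 -> genus 10 -> species 11, 12 ; 2157 -> species 20
    return parse_ncbi_nodes(
        "1|1|no rank\n2|1|superkingdom\n2157|1|superkingdom\n2759|1|superkingdom\n"
        "10|2|genus\n11|10|species\n12|10|species\n20|2157|species\n"
    )


@pytest.fixture(scope="module")
def small_mapping():
    db = MappingDatabase()
    db.add_row("a__G1", {"Taxonomy": "11", "KEGG": "K00001"})
    db.add_row("b__G1", {"Taxonomy": "12"})
    db.add_row("c__G2", {"Taxonomy": "20", "KEGG": "K00002"})
    db.add_row("d__G3", {"Taxonomy": "2759"})
    db.add_row("e__G9", {})  # unmapped subject
    return db


class TestParseAlignments:
    LINE = "r1\ta__G1\t95.0\t30\t1\t0\t1\t90\t1\t30\t1e-20\t100.0"

    def test_groups_by_query(self):
        parsed = parse_alignments_tab(self.LINE + "\n" + self.LINE + "\n")
        assert len(parsed.reads) == 1
        assert len(parsed.reads[0]) == 2
        assert parsed.aligned_reads == 1

    def test_reverse_coordinates_flagged(self):
        line = "r1\ta__G1\t95.0\t30\t1\t0\t90\t1\t1\t30\t1e-20\t100.0"
        parsed = parse_alignments_tab(line)
        rec = parsed.reads[0].records[0]
        assert rec.reverse_frame and rec.interval == (1, 90)

    def test_wrong_column_count_reports_line(self):
        with pytest.raises(BinnerError, match="line 2"):
            parse_alignments_tab(self.LINE + "\nr2\tonly\tthree\n")

    def test_non_numeric_field_reports_line(self):
        bad = self.LINE.replace("100.0", "high")
        with pytest.raises(BinnerError, match="line 1"):
            parse_alignments_tab(bad)

    def test_declared_total_reads(self):
        parsed = parse_alignments_tab(self.LINE, declared_total_reads=50)
        assert parsed.total_reads == 50 and parsed.aligned_reads == 1
        with pytest.raises(BinnerError):
            parse_alignments_tab(self.LINE, declared_total_reads=0)

    def test_fixture_regrouping_matches_truth(self, bundle):
        parsed = parse_alignments_tab("\n".join(bundle.alignment_lines))
        assert parsed.aligned_reads == len(bundle.truth.read_sources)
        assert {ra.query_id for ra in parsed.reads} == set(
            bundle.truth.read_sources
        )


class TestFilterAlignments:
    def test_top_percent_boundary(self):
        ra = ReadAlignments(
            "r1", [record(score=s) for s in (100.0, 91.0, 89.0)]
        )
        kept = filter_alignments(ra, BinningParams(top_percent=10.0))
        assert [r.bit_score for r in kept.records] == [100.0, 91.0]

    def test_all_below_min_score_empty(self):
        ra = ReadAlignments("r1", [record(score=10.0), record(score=20.0)])
        assert len(filter_alignments(ra, BinningParams())) == 0

    def test_evalue_cutoff(self):
        ra = ReadAlignments("r1", [record(evalue=0.5), record(evalue=1e-5)])
        kept = filter_alignments(ra, BinningParams())
        assert len(kept) == 1 and kept.records[0].evalue == 1e-5

    def test_matches_brute_force_two_pass_filter(self):
        """500 random score sets agree with an independent two-pass filter."""
        rng = np.random.default_rng(53)
        params = BinningParams(min_bit_score=50, max_evalue=0.01, top_percent=10)
        for _ in range(500):
            n = int(rng.integers(1, 12))
            scores = rng.uniform(20, 200, size=n)
            evalues = 10.0 ** rng.uniform(-30, 1, size=n)
            ra = ReadAlignments(
                "r1", [record(score=float(s), evalue=float(e))
                       for s, e in zip(scores, evalues)]
            )
            kept = filter_alignments(ra, params)
            survivors = [
                r for r in ra.records
                if r.bit_score >= 50 and r.evalue <= 0.01
            ]
            if survivors:
                best = max(r.bit_score for r in survivors)
                expected = [r for r in survivors if r.bit_score >= 0.9 * best]
            else:
                expected = []
            assert kept.records == expected
            # idempotence
            assert filter_alignments(kept, params).records == kept.records

    def test_invalid_params_rejected(self):
        with pytest.raises(BinnerError):
            BinningParams(top_percent=150)
        with pytest.raises(BinnerError):
            BinningParams(percent_to_cover=0)


class TestRestrictToClades:
    def test_subject_inside_clade_kept(self, small_tree, small_mapping):
        ra = ReadAlignments("r1", [record(subject="a__G1")])
        kept = restrict_to_clades(ra, small_mapping, small_tree, {"2"})
        assert len(kept) == 1

    def test_off_clade_and_unmapped_dropped(self, small_tree, small_mapping):
        ra = ReadAlignments(
            "r1", [record(subject="d__G3"), record(subject="e__G9")]
        )
        kept = restrict_to_clades(ra, small_mapping, small_tree, {"2", "2157"})
        assert len(kept) == 0

    def test_unknown_clade_root_raises(self, small_tree, small_mapping):
        with pytest.raises(Exception, match="clade root"):
            restrict_to_clades(
                ReadAlignments("r1", []), small_mapping, small_tree, {"404"}
            )

    def test_matches_brute_force_ancestor_test(self, bundle, mapping_db):
        tree = bundle.taxonomy.ncbi_tree
        roots = {"2", "3"}  # the two generated superkingdoms
        parsed = parse_alignments_tab("\n".join(bundle.alignment_lines))
        for ra in parsed.reads[:100]:
            kept = restrict_to_clades(ra, mapping_db, tree, roots)
            expected = []
            for rec in ra.records:
                taxon = mapping_db.get_class(rec.subject_accession, "Taxonomy")
                if taxon is None:
                    continue
                lineage = tree.lineage(taxon)
                if any(root in lineage for root in roots):
                    expected.append(rec)
            assert kept.records == expected


class TestNaiveLca:
    def test_single_species(self, small_tree, small_mapping, default_params):
        ra = ReadAlignments("r1", [record(subject="a__G1")] * 2)
        assert (
            assign_taxon_naive_lca(ra, small_mapping, small_tree, default_params)
            == "11"
        )

    def test_two_species_meet_at_genus(self, small_tree, small_mapping, default_params):
        ra = ReadAlignments("r1", [record(subject="a__G1"), record(subject="b__G1")])
        assert (
            assign_taxon_naive_lca(ra, small_mapping, small_tree, default_params)
            == "10"
        )

    def test_sentinels(self, small_tree, small_mapping, default_params):
        empty = ReadAlignments("r1", [])
        assert (
            assign_taxon_naive_lca(empty, small_mapping, small_tree, default_params)
            == NO_HITS
        )
        unmapped = ReadAlignments("r1", [record(subject="e__G9")])
        assert (
            assign_taxon_naive_lca(unmapped, small_mapping, small_tree, default_params)
            == UNASSIGNED
        )

    def test_matches_lca_oracle_on_fixture(self, bundle, mapping_db, default_params):
        tree = bundle.taxonomy.ncbi_tree
        parsed = parse_alignments_tab("\n".join(bundle.alignment_lines))
        for ra in parsed.reads:
            filtered = filter_alignments(ra, default_params)
            got = assign_taxon_naive_lca(filtered, mapping_db, tree, default_params)
            taxa = {
                mapping_db.get_class(r.subject_accession, "Taxonomy")
                for r in filtered.records
            } - {None}
            if taxa:
                common = set(tree.lineage(sorted(taxa)[0]))
                for taxon in taxa:
                    common &= set(tree.lineage(taxon))
                assert got == max(common, key=tree.depth)

    def test_monotone_under_added_alignment(self, small_tree, small_mapping, default_params):
        ra = ReadAlignments("r1", [record(subject="a__G1")])
        before = assign_taxon_naive_lca(ra, small_mapping, small_tree, default_params)
        grown = ReadAlignments("r1", ra.records + [record(subject="c__G2")])
        after = assign_taxon_naive_lca(grown, small_mapping, small_tree, default_params)
        assert small_tree.is_ancestor(after, before)


class TestIntervalUnionLca:
    def test_single_alignment_hits_species(self, small_tree, small_mapping):
        params = BinningParams(long_read_mode=True)
        ra = ReadAlignments("r1", [record(subject="a__G1", start=1, end=500)])
        assert (
            assign_taxon_interval_union_lca(ra, small_mapping, small_tree, params)
            == "11"
        )

    def test_dominant_cover_beats_unrelated_hit(self, small_tree, small_mapping):
        """Two disjoint 400-nt segments to one species outweigh a 300-nt
        alignment to an unrelated species at 80% cover."""
        params = BinningParams(long_read_mode=True, percent_to_cover=80.0)
        ra = ReadAlignments(
            "r1",
            [
                record(subject="a__G1", start=1, end=400),
                record(subject="a__G1", start=1001, end=1400),
                record(subject="c__G2", start=2001, end=2300),
            ],
        )
        cover = taxon_interval_cover(ra, small_mapping, small_tree)
        assert cover == {"11": 800, "20": 300}
        assert (
            assign_taxon_interval_union_lca(ra, small_mapping, small_tree, params)
            == "11"
        )

    def test_balanced_cover_meets_at_lca(self, small_tree, small_mapping):
        params = BinningParams(long_read_mode=True, percent_to_cover=80.0)
        ra = ReadAlignments(
            "r1",
            [
                record(subject="a__G1", start=1, end=400),
                record(subject="b__G1", start=1001, end=1400),
            ],
        )
        assert (
            assign_taxon_interval_union_lca(ra, small_mapping, small_tree, params)
            == "10"
        )

    def test_overlapping_intervals_counted_once(self, small_tree, small_mapping):
        ra = ReadAlignments(
            "r1",
            [
                record(subject="a__G1", start=1, end=100),
                record(subject="a__G1", start=50, end=150),
                record(subject="a__G1", start=151, end=200),  # adjacent merges
            ],
        )
        assert taxon_interval_cover(ra, small_mapping, small_tree) == {"11": 200}

    def test_subtree_cover_matches_brute_force_and_is_monotone(
        self, long_bundle, long_mapping_db
    ):
        """Per-node cover equals an independent per-node interval union and
        never shrinks toward the root."""
        tree = long_bundle.taxonomy.ncbi_tree
        params = BinningParams(long_read_mode=True)
        parsed = parse_alignments_tab("\n".join(long_bundle.alignment_lines))
        for ra in parsed.reads[:60]:
            filtered = filter_alignments(ra, params)
            cover = subtree_cover(filtered, long_mapping_db, tree)
            # brute force: per node, union intervals of taxa in its subtree
            taxa_records = []
            for rec in filtered.records:
                taxon = long_mapping_db.get_class(rec.subject_accession, "Taxonomy")
                if taxon is not None:
                    taxa_records.append((taxon, rec.interval))
            for node, value in cover.items():
                members = tree.subtree(node)
                intervals = sorted(
                    iv for taxon, iv in taxa_records if taxon in members
                )
                merged, total = None, 0
                for start, end in intervals:
                    if merged is None:
                        merged = [start, end]
                    elif start <= merged[1] + 1:
                        merged[1] = max(merged[1], end)
                    else:
                        total += merged[1] - merged[0] + 1
                        merged = [start, end]
                if merged:
                    total += merged[1] - merged[0] + 1
                assert value == total
            for node in cover:
                if node != tree.root_id and tree.parent(node) in cover:
                    assert cover[tree.parent(node)] >= cover[node]

    def test_sentinels(self, small_tree, small_mapping):
        params = BinningParams(long_read_mode=True)
        assert (
            assign_taxon_interval_union_lca(
                ReadAlignments("r1", []), small_mapping, small_tree, params
            )
            == NO_HITS
        )
        assert (
            assign_taxon_interval_union_lca(
                ReadAlignments("r1", [record(subject="e__G9")]),
                small_mapping,
                small_tree,
                params,
            )
            == UNASSIGNED
        )


class TestBestHitFunction:
    def test_best_mapped_hit_wins_over_better_unmapped(
        self, small_mapping, default_params
    ):
        ra = ReadAlignments(
            "r1",
            [record(subject="a__G1", score=90.0), record(subject="e__G9", score=95.0)],
        )
        assert (
            assign_function_best_hit(ra, small_mapping, "KEGG", default_params)
            == "K00001"
        )

    def test_no_mapped_hits_unassigned(self, small_mapping, default_params):
        ra = ReadAlignments("r1", [record(subject="e__G9")])
        assert (
            assign_function_best_hit(ra, small_mapping, "KEGG", default_params)
            == UNASSIGNED
        )
        assert (
            assign_function_best_hit(
                ReadAlignments("r1", []), small_mapping, "KEGG", default_params
            )
            == NO_HITS
        )

    def test_tie_breaks_to_smallest_accession(self, small_mapping, default_params):
        ra = ReadAlignments(
            "r1",
            [record(subject="c__G2", score=90.0), record(subject="a__G1", score=90.0)],
        )
        assert (
            assign_function_best_hit(ra, small_mapping, "KEGG", default_params)
            == "K00001"
        )

    def test_matches_argmax_oracle(self, bundle, mapping_db, default_params):
        parsed = parse_alignments_tab("\n".join(bundle.alignment_lines))
        for ra in parsed.reads[:150]:
            filtered = filter_alignments(ra, default_params)
            got = assign_function_best_hit(
                filtered, mapping_db, "KEGG", default_params
            )
            mapped = [
                (r, mapping_db.get_class(r.subject_accession, "KEGG"))
                for r in filtered.records
            ]
            mapped = [(r, k) for r, k in mapped if k is not None]
            if mapped:
                best = min(mapped, key=lambda p: (-p[0].bit_score, p[0].subject_accession))
                assert got == best[1]
            elif filtered.records:
                assert got == UNASSIGNED


class TestBinRun:
    def test_empty_alignment_file(self, mapping_db, ncbi_tree):
        run = bin_run("", mapping_db, ncbi_tree=ncbi_tree)
        assert run.aligned_reads == 0 and run.assignments == []

    def test_noise_free_recovery(self, bundle, mapping_db):
        """With no planted noise every read lands on its source species
        (or, per classification, some class) and never below it."""
        run = bin_run(
            "\n".join(bundle.alignment_lines),
            mapping_db,
            ncbi_tree=bundle.taxonomy.ncbi_tree,
            gtdb_tree=bundle.taxonomy.gtdb_tree,
        )
        for assignment in run.assignments:
            genome, ncbi_species, gtdb_string = bundle.truth.read_sources[
                assignment.query_id
            ]
            assert assignment.outcomes["Taxonomy"] == ncbi_species
            assert assignment.outcomes["GTDB"] == gtdb_string

    def test_counts_are_ordered(self, bundle, mapping_db):
        run = bin_run(
            "\n".join(bundle.alignment_lines),
            mapping_db,
            ncbi_tree=bundle.taxonomy.ncbi_tree,
            declared_total_reads=1000,
        )
        assert run.aligned_reads <= run.total_reads
        for classification in ("Taxonomy", "KEGG", "EC"):
            assert run.assigned_count(classification) <= run.aligned_reads

    def test_rerun_is_byte_identical(self, bundle, mapping_db):
        exports = []
        for _ in range(2):
            run = bin_run(
                "\n".join(bundle.alignment_lines),
                mapping_db,
                ncbi_tree=bundle.taxonomy.ncbi_tree,
            )
            buffer = io.StringIO()
            write_assignments_tsv(run, buffer)
            exports.append(buffer.getvalue())
        assert exports[0] == exports[1]


class TestSummaries:
    def test_published_percent_of_aligned(self):
        # pooled taxonomic assignments over aligned reads round to 99.5%
        assert percent(305_150_157, 306_653_424) == 99.5

    def test_published_kegg_ratio(self):
        assert ratio(209_371_499, 123_130_673) == 1.7

    def test_zero_assigned(self):
        assert percent(0, 1000) == 0.0
        assert percent(5, 0) == 0.0

    def test_summarize_run_flags_zero_aligned(self, mapping_db, ncbi_tree):
        run = bin_run("", mapping_db, ncbi_tree=ncbi_tree, declared_total_reads=10)
        summary = summarize_run(run)
        assert summary.aligned_reads_zero
        assert all(v == 0 for v in summary.assigned.values())

    def test_summarize_run_rates(self, bundle, mapping_db):
        run = bin_run(
            "\n".join(bundle.alignment_lines),
            mapping_db,
            ncbi_tree=bundle.taxonomy.ncbi_tree,
            declared_total_reads=800,
        )
        summary = summarize_run(run)
        assert summary.percent_of_aligned["Taxonomy"] == 100.0
        assert summary.percent_of_reads["Taxonomy"] == 50.0
        # % of aligned never falls below % of reads
        for c in summary.assigned:
            assert summary.percent_of_aligned[c] >= summary.percent_of_reads[c]
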