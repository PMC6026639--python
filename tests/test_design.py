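"""Design scans: enumeration, ranking, classification, correlation."""

import itertools
import math
import random
import warnings

import pytest

import iappdesign as iap
from iappdesign.design import (
    DesignError,
    hotspot_deletion_flags,
    read_annotations_tsv,
    write_scan_tsv,
)
from iappdesign.sequences import PeptideSequence, parse_variant_notation


def variants(*names):
    return [parse_variant_notation(n) for n in names]


class TestSingleScan:
    def test_one_record_per_scorable_variant(self, single_scan_table):
        assert len(single_scan_table) == 112  # 113 catalog entries minus L27X

    def test_extremes_match_reference_table(self, single_scan_table):
        top, bottom = single_scan_table.records[0], single_scan_table.records[-1]
        assert top.label == "V17D"
        assert iap.display_na4vss(top.na4vss) == -14.8
        assert bottom.label == "N22I"
        assert iap.display_na4vss(bottom.na4vss) == 2.9

    def test_records_score_exactly_like_fresh_evaluation(self, single_scan_table, hiapp, scale):
        rng = random.Random(2)
        for rec in rng.sample(single_scan_table.records, 15):
            fresh = iap.score_sequence(iap.apply_variants(hiapp, rec.variants), scale)
            assert rec.na4vss == fresh.na4vss
            assert rec.delta_na4vss == rec.na4vss - single_scan_table.reference_profile.na4vss

    def test_sorted_ascending_with_deterministic_ties(self, single_scan_table):
        scores = [r.na4vss for r in single_scan_table.records]
        assert scores == sorted(scores)

    def test_nonstandard_variant_warned_and_skipped(self, hiapp, species_catalog):
        with pytest.warns(UserWarning, match="nonstandard"):
            table = iap.single_scan(hiapp, species_catalog)
        assert all("X" not in r.label for r in table.records)

    def test_reference_mismatch_rejected(self, species_catalog):
        other = PeptideSequence("other", "A" * 37)
        with pytest.raises(DesignError, match="does not match"):
            iap.single_scan(other, species_catalog)

    def test_empty_catalog_gives_empty_table(self, hiapp):
        empty = iap.VariantCatalog(reference=hiapp)
        table = iap.single_scan(hiapp, empty)
        assert len(table) == 0


class TestClassification:
    def test_class_label_consistent_with_delta_sign(self, single_scan_table):
        for rec in single_scan_table.records:
            assert (rec.classification == "lower") == (rec.delta_na4vss < 0)

    def test_minus_infinity_threshold_counts_nothing(self, single_scan_table):
        n, pct = iap.classify_vs_reference(single_scan_table, float("-inf"))
        assert (n, pct) == (0, 0)

    def test_plus_infinity_threshold_counts_everything(self, single_scan_table):
        n, pct = iap.classify_vs_reference(single_scan_table, float("inf"))
        assert (n, pct) == (112, 100)

    def test_empty_table_is_signalled(self, hiapp):
        table = iap.single_scan(hiapp, iap.VariantCatalog(reference=hiapp))
        with pytest.raises(DesignError, match="empty"):
            iap.classify_vs_reference(table, 0.0)


class TestMultiScan:
    def test_named_double_substitution_scores(self, hiapp, species_catalog):
        table = iap.multi_scan(
            hiapp, species_catalog, 2, candidate_pool=variants("V17D", "F23R")
        )
        assert len(table) == 1
        assert table.records[0].label == "V17D+F23R"
        assert iap.display_na4vss(table.records[0].na4vss) == -22.9

    def test_three_variant_pool_ranks_published_pairs(self, hiapp, species_catalog):
        table = iap.multi_scan(
            hiapp, species_catalog, 2,
            candidate_pool=variants("V17D", "F23R", "L27H"),
        )
        assert len(table) == 3
        assert [r.label for r in table.records[:2]] == ["V17D+F23R", "V17D+L27H"]
        assert iap.display_na4vss(table.records[1].na4vss) == -21.3

    def test_same_position_pairs_excluded(self, hiapp, species_catalog):
        table = iap.multi_scan(
            hiapp, species_catalog, 2,
            candidate_pool=variants("F23R", "F23G", "V17D"),
        )
        assert {r.label for r in table.records} == {"V17D+F23R", "V17D+F23G"}

    def test_record_count_matches_combinatorial_expectation(self, hiapp, species_catalog):
        pool = species_catalog.scorable_variants()[:20]
        table = iap.multi_scan(hiapp, species_catalog, 2, candidate_pool=pool)
        expected = sum(
            1
            for a, b in itertools.combinations(pool, 2)
            if a.position != b.position
        )
        assert len(table) == expected

    def test_k_too_large_and_budget_errors(self, hiapp, species_catalog):
        with pytest.raises(DesignError, match="exceeds"):
            iap.multi_scan(
                hiapp, species_catalog, 3, candidate_pool=variants("V17D", "F23R")
            )
        with pytest.raises(DesignError, match="budget"):
            iap.multi_scan(hiapp, species_catalog, 3, combination_budget=10)

    def test_window_separated_pair_delta_is_additive(self, hiapp, species_catalog, scale):
        """Positions 17 and 23 are more than a window apart, so the double's
        score shift is exactly the sum of the single shifts (window locality)."""
        singles = {
            v.notation: iap.na4vss(iap.apply_variants(hiapp, [v]), scale)
            for v in variants("V17D", "F23R")
        }
        ref = iap.na4vss(hiapp, scale)
        double = iap.na4vss(
            iap.apply_variants(hiapp, variants("V17D", "F23R")), scale
        )
        assert double - ref == pytest.approx(
            (singles["V17D"] - ref) + (singles["F23R"] - ref), abs=1e-12
        )


class TestHotspotFlags:
    def test_deleting_variants_flagged(self, single_scan_table):
        by_label = {r.label: r for r in single_scan_table.records}
        for label in ["V17D", "F23R", "F23G", "I26A"]:
            assert by_label[label].hotspot_deleted, label

    def test_aggregating_variants_not_flagged(self, single_scan_table):
        ref_cover = single_scan_table.reference_profile.hot_spot_residue_count
        by_label = {r.label: r for r in single_scan_table.records}
        for label in ["N22I", "N31V", "R11W"]:
            assert not by_label[label].hotspot_deleted
            assert by_label[label].hot_spot_residue_count >= ref_cover

    def test_explicit_flags_match_records(self, single_scan_table):
        flags = hotspot_deletion_flags(
            single_scan_table, single_scan_table.reference_profile
        )
        assert flags == [r.hotspot_deleted for r in single_scan_table.records]


class TestPearson:
    def test_perfect_linear_relations(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert iap.pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert iap.pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = random.Random(17)
        x = [rng.uniform(-5, 5) for _ in range(20)]
        y = [rng.uniform(-5, 5) for _ in range(20)]
        mx, my = sum(x) / 20, sum(y) / 20
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sx = math.sqrt(sum((a - mx) ** 2 for a in x))
        sy = math.sqrt(sum((b - my) ** 2 for b in y))
        assert iap.pearson(x, y) == pytest.approx(cov / (sx * sy), abs=1e-12)

    def test_degenerate_inputs_signalled(self):
        with pytest.raises(DesignError):
            iap.pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DesignError):
            iap.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DesignError):
            iap.pearson([1.0, 2.0, 3.0], [1.0, 2.0])


class TestScanReport:
    def test_byte_identical_on_rerun(self, tmp_path, single_scan_table):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_scan_tsv(single_scan_table, p1)
        write_scan_tsv(single_scan_table, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_annotations_merged_by_variant_key(self, tmp_path, single_scan_table):
        ann_path = tmp_path / "ann.tsv"
        ann_path.write_text(
            "variant\tpasta\torganisms\nV17D\t-3.46\tS. crofa\n"
        )
        out = tmp_path / "scan.tsv"
        write_scan_tsv(single_scan_table, out, read_annotations_tsv(ann_path))
        lines = out.read_text().rstrip("\n").split("\n")
        assert lines[0].endswith("pasta\torganisms")
        top = lines[1].split("\t")
        assert top[1] == "V17D" and top[-2] == "-3.46"
        assert lines[2].split("\t")[-1] == "."

    def test_packaged_annotations_cover_reference_table(self, tmp_path, single_scan_table):
        from importlib import resources

        src = resources.files("iappdesign.data").joinpath("variant_annotations.tsv")
        ann = read_annotations_tsv(str(src))
        assert len(ann) == 30
        assert ann["V17D"]["pasta"] == "-3.46"
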