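"""Orientation tests, deviation classification, and the standard-form
round trip on corrupted synthetic plastomes."""

import pytest

from chloronorm import (
    AnnotatedSequence,
    Arc,
    Feature,
    SynthSpec,
    Transformation,
    UndeterminedOrientationError,
    apply_recipe,
    apply_transformation,
    assign_ir_labels,
    batch_report,
    classify_form,
    compute_offset,
    corrupt,
    expected_classification,
    generate_genome,
    partition_from_annotations,
    region_needs_flip,
    revcomp,
    strand_counts,
    to_standard_form,
)
from chloronorm.standardize import ORIENTATION_RULES, remap_features
from chloronorm.structure import partition_from_annotations as _partition


def _arc_record(genes, L=10_000):
    """A bare record with gene features for strand-count tests."""
    features = [
        Feature.from_spans("gene", name, [(s, ln, st)], L) for name, s, ln, st in genes
    ]
    return AnnotatedSequence("t", "ACGT" * (L // 4), features=features)


class TestStrandCounts:
    def test_prefix_filter_counts_only_matching_genes(self):
        rec = _arc_record(
            [("rpl2", 100, 200, "-"), ("rps12", 400, 150, "-"), ("psbA", 700, 300, "+")]
        )
        arc = Arc(0, 2_000)
        assert strand_counts(rec, arc, frozenset({"rpl", "rps"})) == (0, 2)
        assert strand_counts(rec, arc, None) == (1, 2)

    def test_empty_arc_counts_zero(self):
        rec = _arc_record([("rpl2", 5_000, 200, "-")])
        assert strand_counts(rec, Arc(0, 1_000), None) == (0, 0)

    def test_matching_is_case_insensitive(self):
        rec = _arc_record([("RPL2", 100, 200, "-")])
        assert strand_counts(rec, Arc(0, 1_000), frozenset({"rpl"})) == (0, 1)

    def test_boundary_straddling_genes_are_excluded(self):
        rec = _arc_record([("rpl2", 900, 300, "-")])
        assert strand_counts(rec, Arc(0, 1_000), None) == (0, 0)
        assert strand_counts(rec, Arc(0, 1_300), None) == (0, 1)

    def test_generator_quota_is_visible_in_counts(self, default_genome):
        seq, part = default_genome
        n_plus, n_minus = strand_counts(seq, part.lsc, frozenset({"rpl", "rps"}))
        assert (n_plus, n_minus) == (5, 15)


class TestRegionNeedsFlip:
    def test_negative_majority_means_no_flip(self):
        rec = _arc_record([("rpl2", 100, 200, "-"), ("rps3", 400, 150, "-")])
        assert not region_needs_flip(rec, Arc(0, 2_000), ORIENTATION_RULES["LSC"])

    def test_positive_majority_means_flip(self):
        rec = _arc_record(
            [
                ("rpl2", 100, 200, "+"),
                ("rps3", 400, 150, "+"),
                ("rpl16", 700, 150, "+"),
                ("rps4", 1_000, 150, "-"),
            ]
        )
        assert region_needs_flip(rec, Arc(0, 2_000), ORIENTATION_RULES["LSC"])

    def test_tie_falls_back_to_all_genes(self):
        # rpl/rps tie 1:1; all genes 4+:9- decides no flip
        genes = [("rpl2", 100, 50, "+"), ("rps3", 200, 50, "-")]
        genes += [(f"psb{c}", 300 + 60 * i, 50, "+") for i, c in enumerate("ABC")]
        genes += [(f"ndh{c}", 600 + 60 * i, 50, "-") for i, c in enumerate("ABCDEFGH")]
        rec = _arc_record(genes)
        assert not region_needs_flip(rec, Arc(0, 2_000), ORIENTATION_RULES["LSC"])

    def test_double_tie_raises(self):
        rec = _arc_record([("rpl2", 100, 50, "+"), ("rps3", 200, 50, "-")])
        with pytest.raises(UndeterminedOrientationError):
            region_needs_flip(rec, Arc(0, 2_000), ORIENTATION_RULES["LSC"])

    def test_empty_region_raises(self):
        rec = _arc_record([])
        with pytest.raises(UndeterminedOrientationError):
            region_needs_flip(rec, Arc(0, 2_000), ORIENTATION_RULES["SSC"])


class TestAssignIRLabels:
    def test_standard_genome_keeps_positional_labels(self, default_genome):
        seq, truth = default_genome
        part = partition_from_annotations(seq)
        labeled = assign_ir_labels(seq, part)
        assert labeled.irb == truth.irb
        assert labeled.ira == truth.ira

    def test_labels_swap_when_both_copies_inverted(self, default_genome):
        seq, truth = default_genome
        flipped = corrupt(seq, ("invert", "IR"))
        labeled = assign_ir_labels(flipped, partition_from_annotations(flipped))
        # orientation-based IRb is now the copy at the positional-IRa arc
        assert labeled.irb == truth.ira
        assert labeled.ira == truth.irb

    def test_no_rrn_genes_raises(self, default_genome):
        seq, _ = default_genome
        stripped = AnnotatedSequence(
            seq.id,
            seq.residues,
            features=[f for f in seq.features if not (f.name or "").startswith("rrn")],
        )
        with pytest.raises(UndeterminedOrientationError):
            assign_ir_labels(stripped, partition_from_annotations(stripped))


class TestComputeOffset:
    def test_standard_genome_has_zero_offset(self, default_genome):
        seq, part = default_genome
        assert compute_offset(part, len(seq)) == 0

    @pytest.mark.parametrize("k", [5_000, 7, 151_993])
    def test_rotated_genome_reports_raw_offset(self, default_genome, k):
        seq, _ = default_genome
        rotated = corrupt(seq, ("rotate", k))
        part = _partition(rotated)
        assert compute_offset(part, len(seq)) == k


class TestClassifyForm:
    def test_standard_genome(self, default_genome):
        seq, _ = default_genome
        c = classify_form(seq)
        assert (c.category, c.offset_bp, c.flipped_regions) == (
            "standard",
            0,
            frozenset(),
        )

    def test_no_ir_record(self):
        rec = _arc_record([("rpl2", 100, 200, "-")])
        c = classify_form(rec)
        assert c.category == "no_ir"
        assert c.offset_bp is None and c.flipped_regions is None

    def test_inverted_ssc_in_place(self, default_genome):
        seq, _ = default_genome
        c = classify_form(corrupt(seq, ("invert", "SSC")))
        assert (c.category, c.offset_bp, c.flipped_regions) == (
            "inverted_ssc",
            0,
            frozenset({"SSC"}),
        )

    def test_shift_plus_inversion_is_combination(self, default_genome):
        seq, _ = default_genome
        bad = apply_recipe(seq, [("invert", "SSC"), ("rotate", 40_289)])
        c = classify_form(bad)
        assert c.category == "combination"
        assert c.offset_bp == 40_289
        assert c.flipped_regions == frozenset({"SSC"})

    @pytest.mark.parametrize("k", [1, 5, 9, 151_991])
    def test_subthreshold_rotation_is_standard(self, default_genome, k):
        seq, _ = default_genome
        c = classify_form(corrupt(seq, ("rotate", k)))
        assert c.category == "standard"
        assert c.offset_bp == k

    def test_whole_revcomp_is_combination_of_shift_and_sc_flips(self, default_genome):
        # reverse-complementing the circle swaps the IR copies' contents,
        # which cancels for an exact repeat: only LSC, SSC and the origin move
        seq, _ = default_genome
        c = classify_form(corrupt(seq, ("revcomp",)))
        assert c.category == "combination"
        assert c.flipped_regions == frozenset({"LSC", "SSC"})

    def test_invariant_to_record_id_and_feature_order(self, default_genome):
        seq, _ = default_genome
        bad = corrupt(seq, ("invert", "LSC"))
        shuffled = AnnotatedSequence(
            "renamed", bad.residues, features=list(reversed(bad.features))
        )
        assert classify_form(shuffled) == classify_form(bad)


RECIPES = [
    [("rotate", 10)],
    [("rotate", 5_000)],
    [("rotate", 68_671)],
    [("invert", "LSC")],
    [("invert", "SSC")],
    [("invert", "IR")],
    [("revcomp",)],
    [("invert", "SSC"), ("rotate", 500)],
    [("invert", "LSC"), ("invert", "SSC")],
    [("invert", "LSC"), ("invert", "IR"), ("rotate", 40_289)],
    [("revcomp",), ("rotate", 18)],
    [("rotate", 151_000), ("invert", "SSC")],
]


class TestToStandardForm:
    def test_standard_input_is_identity(self, default_genome):
        seq, _ = default_genome
        std, t = to_standard_form(seq)
        assert t == Transformation(0, ())
        assert std.residues == seq.residues
        assert std.features == seq.features

    @pytest.mark.parametrize("recipe", RECIPES, ids=repr)
    def test_round_trip_recovers_residues_and_features(self, default_genome, recipe):
        seq, part = default_genome
        bad = apply_recipe(seq, recipe)
        std, t = to_standard_form(bad)
        assert std.residues == seq.residues
        assert sorted(std.features, key=repr) == sorted(seq.features, key=repr)
        exp = expected_classification(recipe, len(seq), part.lsc.length)
        got = classify_form(bad)
        assert got == exp

    @pytest.mark.parametrize("recipe", RECIPES, ids=repr)
    def test_idempotence_and_conservation(self, default_genome, recipe):
        seq, _ = default_genome
        bad = apply_recipe(seq, recipe)
        std1, _ = to_standard_form(bad)
        std2, t2 = to_standard_form(std1)
        assert t2.is_identity
        assert std2.residues == std1.residues
        assert len(std1.residues) == len(seq.residues)
        assert len(std1.features) == len(seq.features)

    def test_replaying_transformation_is_deterministic(self, default_genome):
        seq, _ = default_genome
        bad = apply_recipe(seq, [("invert", "SSC"), ("rotate", 12_345)])
        std, t = to_standard_form(bad)
        assert apply_transformation(bad, t).residues == std.residues
        assert apply_transformation(bad, t).features == std.features

    def test_outputs_pass_all_orientation_tests(self, default_genome):
        seq, _ = default_genome
        for recipe in RECIPES[:6]:
            std, _ = to_standard_form(apply_recipe(seq, recipe))
            part = _partition(std)
            assert not region_needs_flip(std, part.lsc, ORIENTATION_RULES["LSC"])
            assert not region_needs_flip(std, part.ssc, ORIENTATION_RULES["SSC"])
            assert not region_needs_flip(std, part.irb, ORIENTATION_RULES["IRb"])
            irb = std.residues[part.irb.start : part.irb.start + part.irb.length]
            ira = std.residues[part.ira.start : part.ira.start + part.ira.length]
            assert ira == revcomp(irb)

    def test_subthreshold_rotation_left_untouched(self, default_genome):
        seq, _ = default_genome
        bad = corrupt(seq, ("rotate", 7))
        std, t = to_standard_form(bad)
        assert t.is_identity
        assert std.residues == bad.residues  # not rotated back

    def test_subthreshold_rotation_with_flip_still_repairs_flip(self, default_genome):
        seq, _ = default_genome
        bad = apply_recipe(seq, [("invert", "SSC"), ("rotate", 3)])
        std, t = to_standard_form(bad)
        assert t.rotate_by == 0
        assert t.invert == ("SSC",)
        # the repaired molecule equals the original rotated by 3
        assert std.residues == corrupt(seq, ("rotate", 3)).residues


class TestRemapFeatures:
    def test_pure_rotation_shifts_coordinates(self, default_genome):
        _, part = default_genome
        L = part.genome_length
        f = Feature.from_spans("gene", "rpl2", [(100, 900, "+")], L)
        t = Transformation(rotate_by=100)
        (out,) = remap_features([f], t, part, L)
        assert out.intervals == ((0, 900, "+"),)

    def test_gene_in_inverted_ssc_lands_mirrored_on_plus_strand(self, default_genome):
        seq, part = default_genome
        bad = corrupt(seq, ("invert", "SSC"))
        genes = {
            f.name: f for f in bad.features if f.name and f.name.startswith("ndh")
        }
        std, _ = to_standard_form(bad)
        genes_std = {
            f.name: f for f in std.features if f.name and f.name.startswith("ndh")
        }
        for name, g in genes.items():
            s, e, st = g.intervals[0]
            s2, e2, st2 = genes_std[name].intervals[0]
            assert st2 != st
            # mirror within the SSC arc
            a, ln = part.ssc.start, part.ssc.length
            assert (s2, e2) == (a + (a + ln) - e, a + (a + ln) - s)

    def test_boundary_spanning_gene_is_dropped_with_warning(self, default_genome, caplog):
        seq, part = default_genome
        L = len(seq)
        bad = corrupt(seq, ("rotate", 5_000))
        bad.features.append(
            Feature.from_spans(
                "gene", "straddler", [((part.irb.start - 50 + 5_000) % L, 100, "+")], L
            )
        )
        with caplog.at_level("WARNING", logger="chloronorm.standardize"):
            std, _ = to_standard_form(bad)
        assert all(f.name != "straddler" for f in std.features)
        assert any("straddler" in rec.message for rec in caplog.records)


class TestBatchReport:
    def _batch(self):
        records = []
        for i in range(6):
            g, _ = generate_genome(SynthSpec(seed=100 + i))
            g.id = f"std{i}"
            records.append(g)
        for i, k in enumerate((5_000, 20_000)):
            g, _ = generate_genome(SynthSpec(seed=200 + i))
            g = corrupt(g, ("rotate", k))
            g.id = f"shift{i}"
            records.append(g)
        g, _ = generate_genome(SynthSpec(seed=300))
        g = corrupt(g, ("invert", "SSC"))
        g.id = "flipped"
        records.append(g)
        records.append(AnnotatedSequence("noir", "ACGT" * 1_000))
        return records

    def test_census_counts_and_percentages(self):
        report = batch_report(self._batch())
        census = dict(zip(report.census["category"], report.census["percent"]))
        assert census == {
            "standard": 60.0,
            "cyclic_shift": 20.0,
            "inverted_ssc": 10.0,
            "no_ir": 10.0,
        }
        assert len(report.records) == 10

    def test_all_standard_batch(self):
        records = self._batch()[:6]
        report = batch_report(records)
        assert list(report.census["category"]) == ["standard"]
        assert list(report.census["percent"]) == [100.0]

    def test_undetermined_records_are_tallied_not_fatal(self, default_genome):
        seq, _ = default_genome
        stripped = AnnotatedSequence(
            "norrn",
            seq.residues,
            features=[f for f in seq.features if not (f.name or "").startswith("rrn")],
        )
        report = batch_report([stripped])
        assert dict(zip(report.census["category"], report.census["count"])) == {
            "undetermined": 1
        }

    def test_duplicate_ids_rejected(self, default_genome):
        seq, _ = default_genome
        with pytest.raises(ValueError, match="duplicate"):
            batch_report([seq, seq])
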