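"""Fixed-difference SNP calling, coordinate mapping, spectrum summary."""

import itertools
import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fixmark.discovery import (
    PAIRING_CLASSES,
    build_reference_map,
    classify_substitution,
    column_profiles,
    find_diagnostic_snps,
    map_column,
    summarize_markers,
)
from fixmark.errors import FixmarkError, ManifestError, NoCoordinateError
from fixmark.io import Alignment, GroupManifest, SequenceRecord
from fixmark.simulate import SimulationConfig, simulate_alignment

from conftest import make_alignment, make_manifest


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "a,b,mutation,pairing",
        [
            ("T", "C", "transition", "pyrimidine-pyrimidine"),
            ("A", "G", "transition", "purine-purine"),
            ("A", "C", "transversion", "purine-pyrimidine"),
            ("G", "T", "transversion", "purine-pyrimidine"),
        ],
    )
    def test_examples(self, a, b, mutation, pairing):
        assert classify_substitution(a, b) == (mutation, pairing)

    def test_exhaustive_against_chemical_definition(self):
        # independent oracle: purine/pyrimidine set membership
        purines, pyrimidines = set("AG"), set("CT")
        transitions = 0
        for a, b in itertools.permutations("ACGT", 2):
            mutation, pairing = classify_substitution(a, b)
            same_family = ({a, b} <= purines) or ({a, b} <= pyrimidines)
            assert mutation == ("transition" if same_family else "transversion")
            if {a, b} <= purines:
                assert pairing == "purine-purine"
            elif {a, b} <= pyrimidines:
                assert pairing == "pyrimidine-pyrimidine"
            else:
                assert pairing == "purine-pyrimidine"
            transitions += mutation == "transition"
        assert transitions == 4  # 4 ordered transitions, 8 transversions

    def test_identity_and_ambiguity_rejected(self):
        with pytest.raises(FixmarkError):
            classify_substitution("A", "A")
        with pytest.raises(FixmarkError):
            classify_substitution("N", "A")


class TestColumnProfiles:
    def test_toy_counts(self):
        aln = make_alignment({"w1": "AC", "w2": "AC", "d1": "AT", "d2": "AT"})
        man = make_manifest({"w1": "wild", "w2": "wild", "d1": "dom", "d2": "dom"}, "wild")
        profiles = column_profiles(aln, man)
        assert profiles[1].counts["wild"]["C"] == 2
        assert profiles[1].counts["dom"]["T"] == 2
        assert profiles[1].counts["wild"]["T"] == 0

    def test_all_gap_column(self):
        aln = make_alignment({"a": "A-", "b": "C-", "c": "G-"})
        man = make_manifest({"a": "x", "b": "x", "c": "y"}, "x")
        profiles = column_profiles(aln, man)
        assert profiles[1].counts["x"]["gap"] + profiles[1].counts["y"]["gap"] == 3

    def test_unassigned_id_is_named(self):
        aln = make_alignment({"a": "AC", "b": "AC", "mystery": "AC"})
        man = make_manifest({"a": "x", "b": "y"}, "x")
        with pytest.raises(ManifestError, match="mystery"):
            column_profiles(aln, man)

    def test_simulated_alignment_matches_naive_tally(self):
        aln, man, _ = simulate_alignment(SimulationConfig(seed=11, within_group_mutation_rate=0.02))
        profiles = column_profiles(aln, man)
        # independent naive counter
        rng = random.Random(0)
        for col in rng.sample(range(aln.length), 40):
            for group in man.groups:
                expected = Counter(
                    r.residues[col] for r in aln if man.group_of(r.id) == group
                )
                tally = profiles[col].counts[group]
                for base in "ACGT":
                    assert tally[base] == expected.get(base, 0)
                assert profiles[col].group_total(group) == sum(expected.values())


class TestReferenceMap:
    def test_gapless_identity(self):
        aln = make_alignment({"r": "ACGT", "s": "ACGT"})
        refmap = build_reference_map(aln, "r", offset=1)
        assert map_column(refmap, 0) == 1
        assert map_column(refmap, 3) == 4

    def test_gap_skipped(self):
        aln = make_alignment({"r": "AC-GT", "s": "ACAGT"})
        refmap = build_reference_map(aln, "r", offset=100)
        assert map_column(refmap, 3) == 102
        with pytest.raises(NoCoordinateError):
            map_column(refmap, 2)

    def test_genbank_style_absolute_positions(self):
        # cytochrome b-style fixture: offset 15689, reference with one gap
        aln = make_alignment({"ref": "AAC-GTAC", "s": "AACTGTAC"})
        refmap = build_reference_map(aln, "ref", offset=15689)
        # hand-computed: columns 0,1,2 -> 15689..15691; column 3 gap;
        # columns 4..7 -> 15692..15695
        assert [map_column(refmap, c) for c in (0, 1, 2, 4, 7)] == [
            15689, 15690, 15691, 15692, 15695,
        ]


class TestFindDiagnosticSnps:
    def test_toy_diagnostic_columns(self, toy_alignment):
        aln, man = toy_alignment
        markers = find_diagnostic_snps(aln, man)
        assert [(m.alignment_column, m.substitution) for m in markers] == [
            (1, "T>C"),
            (4, "G>A"),
        ]

    def test_not_fixed_in_focal_rejected(self):
        # column not fixed in focal group: w2 carries the background allele
        aln = make_alignment({"w1": "C", "w2": "T", "d1": "T", "d2": "T"})
        man = make_manifest({"w1": "wild", "w2": "wild", "d1": "dom", "d2": "dom"}, "wild")
        assert find_diagnostic_snps(aln, man) == []

    def test_ambiguity_policy(self):
        aln = make_alignment({"w1": "C", "w2": "C", "d1": "T", "d2": "N"})
        man = make_manifest({"w1": "wild", "w2": "wild", "d1": "dom", "d2": "dom"}, "wild")
        assert find_diagnostic_snps(aln, man, policy="strict") == []
        permissive = find_diagnostic_snps(aln, man, policy="permissive")
        assert [(m.reference_position, m.substitution) for m in permissive] == [(1, "T>C")]

    def test_group_fixed_for_gap_never_a_snp(self):
        aln = make_alignment({"w1": "C", "w2": "C", "d1": "-", "d2": "-"})
        man = make_manifest({"w1": "wild", "w2": "wild", "d1": "dom", "d2": "dom"}, "wild")
        assert find_diagnostic_snps(aln, man, policy="permissive") == []

    def test_zero_noise_simulation_recovers_truth(self):
        config = SimulationConfig(seed=3, within_group_mutation_rate=0.0)
        aln, man, truth = simulate_alignment(config)
        markers = find_diagnostic_snps(aln, man)
        assert [(m.reference_position, m.focal_allele, m.background_allele) for m in markers] == [
            (m.reference_position, m.focal_allele, m.background_allele) for m in truth.markers
        ]

    def test_single_group_errors(self):
        aln = make_alignment({"a": "AC", "b": "AC"})
        with pytest.raises(ManifestError):
            man = GroupManifest({"a": "x", "b": "x"}, "x")  # already invalid
            find_diagnostic_snps(aln, man)

    def test_empty_focal_group_errors(self):
        aln = make_alignment({"a": "AC", "b": "AT"})
        man = make_manifest({"a": "x", "b": "y", "ghost": "z"}, "z")
        with pytest.raises(ManifestError, match="no sequences"):
            find_diagnostic_snps(aln, man)

    def test_invariant_markers_are_polymorphic_columns(self):
        aln, man, _ = simulate_alignment(SimulationConfig(seed=5, within_group_mutation_rate=0.02))
        markers = find_diagnostic_snps(aln, man)
        for m in markers:
            column = aln.column(m.alignment_column)
            assert len(set(column)) >= 2

    def test_order_and_label_invariance(self, toy_alignment):
        aln, man = toy_alignment
        baseline = find_diagnostic_snps(aln, man)
        shuffled = Alignment(tuple(reversed(aln.records)))
        assert find_diagnostic_snps(shuffled, man) == baseline
        renamed = GroupManifest(
            {i: {"wild": "focal_taxon", "dom": "bkg"}[g] for i, g in man.assignments.items()},
            "focal_taxon",
        )
        assert find_diagnostic_snps(aln, renamed) == baseline


@st.composite
def small_labeled_alignments(draw):
    n_cols = draw(st.integers(1, 6))
    n_focal = draw(st.integers(1, 3))
    n_other = draw(st.integers(1, 3))
    alphabet = "ACGTN-"
    rows, groups = {}, {}
    for i in range(n_focal + n_other):
        seq_id = f"s{i}"
        rows[seq_id] = "".join(draw(st.sampled_from(alphabet)) for _ in range(n_cols))
        groups[seq_id] = "focal" if i < n_focal else "other"
    return rows, groups


class TestPolicyProperty:
    @settings(max_examples=120, derandomize=True)
    @given(small_labeled_alignments())
    def test_permissive_superset_of_strict(self, data):
        rows, groups = data
        aln = make_alignment(rows)
        man = make_manifest(groups, "focal")
        strict = find_diagnostic_snps(aln, man, policy="strict")
        permissive = find_diagnostic_snps(aln, man, policy="permissive")
        strict_cols = {(m.alignment_column, m.focal_allele, m.background_allele) for m in strict}
        permissive_cols = {
            (m.alignment_column, m.focal_allele, m.background_allele) for m in permissive
        }
        assert strict_cols <= permissive_cols


class TestSummarizeMarkers:
    def test_published_panel_spectrum(self):
        from fixmark.assay import FRAGMENT_LENGTHS, published_markers

        summary = summarize_markers(published_markers(), list(FRAGMENT_LENGTHS.values()))
        assert summary.total_markers == 15
        assert summary.total_fragment_length == 1936
        assert summary.class_counts["pyrimidine-pyrimidine"] == 9
        assert summary.class_counts["purine-purine"] == 4
        assert summary.class_counts["purine-pyrimidine"] == 2
        assert summary.class_percentages["pyrimidine-pyrimidine"] == 60
        assert summary.class_percentages["purine-purine"] == 27
        assert summary.class_percentages["purine-pyrimidine"] == 13

    def test_single_marker_is_100_percent(self):
        from fixmark.discovery import SnpMarker

        summary = summarize_markers([SnpMarker.from_alleles("f", 1, 0, "C", "T")], [100])
        assert summary.class_percentages["pyrimidine-pyrimidine"] == 100
        assert summary.class_percentages["purine-purine"] == 0

    def test_round_half_up(self):
        from fixmark.discovery import SnpMarker

        # 1 of 8 = 12.5% -> rounds up to 13, not banker's 12
        markers = [SnpMarker.from_alleles("f", i + 1, i, "C", "T") for i in range(7)]
        markers.append(SnpMarker.from_alleles("f", 8, 7, "G", "A"))
        summary = summarize_markers(markers, [10])
        assert summary.class_percentages["purine-purine"] == 13

    def test_counts_sum_to_total(self):
        from fixmark.assay import published_markers

        summary = summarize_markers(published_markers(), [1936])
        assert sum(summary.class_counts[c] for c in PAIRING_CLASSES) == summary.total_markers

    def test_empty_rejected(self):
        with pytest.raises(FixmarkError):
            summarize_markers([], [100])
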