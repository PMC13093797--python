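"""Haplotype collapsing, p-distances, Hd and Pi."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slossgen.haplotypes import (
    collapse_haplotypes,
    distance_matrix,
    distance_summary,
    diversity_table,
    haplotype_diversity,
    nucleotide_diversity,
    nucleotide_diversity_from_counts,
    p_distance,
)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGT", 0.0),  # gap excluded: 0 diffs / 3 comparable
            ("ANGT", "ACGT", 0.0),  # ambiguity excluded likewise
            ("AAAA", "TTTT", 1.0),
        ],
    )
    def test_pairwise_deletion_convention(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_sites_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("--", "AC")

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            p_distance("ACG", "AC")


class TestCollapse:
    def test_identical_sequences_one_haplotype(self):
        seqs = {f"s{i}": "ACGTACGT" for i in range(5)}
        haps = collapse_haplotypes(seqs, {f"s{i}": "A" for i in range(5)})
        assert haps.n_haplotypes == 1
        assert haps.occurrence.to_numpy().sum() == 5

    def test_hand_enumerated_counts(self):
        seqs = {"s1": "ACGT", "s2": "ACGT", "s3": "ACGA", "s4": "TCGA"}
        haps = collapse_haplotypes(seqs, {s: "A" for s in seqs})
        counts = sorted(haps.occurrence["A"].tolist(), reverse=True)
        assert haps.n_haplotypes == 3
        assert counts == [2, 1, 1]

    def test_first_occurrence_naming(self):
        seqs = {"s1": "ACGT", "s2": "TTTT", "s3": "ACGT"}
        haps = collapse_haplotypes(seqs, {s: "A" for s in seqs})
        assert haps.specimen_map == {"s1": "H01", "s2": "H02", "s3": "H01"}

    def test_gap_only_difference_merges_into_earlier(self):
        seqs = {"s1": "ACGT", "s2": "AC-T"}
        haps = collapse_haplotypes(seqs, {"s1": "A", "s2": "B"})
        assert haps.n_haplotypes == 1

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            collapse_haplotypes({"a": "ACG", "b": "AC"}, {"a": "A", "b": "A"})

    def test_occurrence_conserves_specimens(self, default_system):
        haps = collapse_haplotypes(
            default_system.alignment, default_system.island_map
        )
        assert haps.occurrence.to_numpy().sum() == len(default_system.alignment)


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([16, 1], 0.118),   # n=17, two haplotypes
            ([14, 1], 0.133),   # n=15
            ([5, 1], 0.333),    # n=6
            ([10, 1, 1, 1], 0.423),  # n=13, four haplotypes
            ([1, 1, 1, 1], 1.000),   # all singletons
        ],
    )
    def test_unbiased_estimator_values(self, counts, expected):
        assert round(haplotype_diversity(counts), 3) == expected

    def test_single_haplotype_undefined(self):
        assert np.isnan(haplotype_diversity([12]))

    def test_sample_too_small(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    @given(
        st.lists(st.integers(min_value=1, max_value=30), min_size=2, max_size=8)
    )
    @settings(max_examples=100, deadline=None)
    def test_range_and_bruteforce_identity(self, counts):
        """Hd in [0,1]; equals the draw-two-distinct probability, unbiased."""
        hd = haplotype_diversity(counts)
        n = sum(counts)
        # brute force: probability two draws without replacement differ
        pool = [i for i, c in enumerate(counts) for _ in range(c)]
        pairs = list(itertools.combinations(range(n), 2))
        p_diff = sum(pool[i] != pool[j] for i, j in pairs) / len(pairs)
        assert hd == pytest.approx(p_diff, abs=1e-12)
        assert -1e-12 <= hd <= 1 + 1e-12

    def test_merging_two_haplotypes_decreases_hd(self, rng):
        for _ in range(20):
            k = rng.integers(3, 7)
            counts = rng.integers(1, 20, size=k).tolist()
            merged = [counts[0] + counts[1]] + counts[2:]
            if len(merged) == 1:
                continue
            assert haplotype_diversity(merged) < haplotype_diversity(counts)


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        assert nucleotide_diversity(["ACGT"] * 4) == 0.0

    def test_two_sequences_one_of_ten(self):
        a = "ACGTACGTAC"
        b = "ACGTACGTAT"
        assert nucleotide_diversity([a, b]) == pytest.approx(0.1)

    def test_matches_bruteforce_double_loop(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 30)]) for _ in range(6)]
        expected = np.mean(
            [p_distance(a, b) for a, b in itertools.combinations(seqs, 2)]
        )
        assert nucleotide_diversity(seqs) == pytest.approx(expected, abs=1e-15)

    def test_frequency_weighted_form_equivalent(self, rng):
        """Specimen-pair Pi equals the count-weighted haplotype-distance form."""
        bases = np.array(list("ACGT"))
        hap_seqs = {f"H{i}": "".join(bases[rng.integers(0, 4, 25)]) for i in range(4)}
        counts = {f"H{i}": int(rng.integers(1, 6)) for i in range(4)}
        specimens = [s for h, c in counts.items() for s in [hap_seqs[h]] * c]
        dmat = distance_matrix(hap_seqs)
        assert nucleotide_diversity(specimens) == pytest.approx(
            nucleotide_diversity_from_counts(counts, dmat), abs=1e-12
        )


class TestDistanceSummary:
    def test_two_haplotypes_symmetric(self):
        dm = pd.DataFrame([[0, 0.1], [0.1, 0]], index=["a", "b"], columns=["a", "b"])
        out = distance_summary(dm)
        assert out.loc["a", "Max"] == out.loc["a", "Min"] == 0.1

    def test_three_haplotype_hand_check(self):
        ids = ["h1", "h2", "h3"]
        dm = pd.DataFrame(
            [[0, 0.1, 0.3], [0.1, 0, 0.2], [0.3, 0.2, 0]], index=ids, columns=ids
        )
        out = distance_summary(dm)
        assert (out.loc["h1", "Max"], out.loc["h1", "Min"]) == (0.3, 0.1)

    def test_single_haplotype_error(self):
        dm = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            distance_summary(dm)


class TestDiversityTable:
    def test_single_specimen_island_row(self):
        seqs = {"s1": "ACGT", "s2": "ACGA", "s3": "ACGA"}
        imap = {"s1": "lonely", "s2": "other", "s3": "other"}
        haps = collapse_haplotypes(seqs, imap)
        table = diversity_table(haps, seqs, imap, {"lonely": 0.001, "other": 0.002})
        row = table.loc["lonely"]
        assert row["Sn"] == 1 and row["H"] == 1
        assert np.isnan(row["Hd"]) and row["Pi"] == 0.0
        assert row["PD"] == 0.001

    def test_monomorphic_system_all_h_one(self):
        seqs = {f"s{i}": "ACGT" for i in range(6)}
        imap = {f"s{i}": f"I{i % 3}" for i in range(6)}
        haps = collapse_haplotypes(seqs, imap)
        table = diversity_table(haps, seqs, imap)
        assert (table["H"] == 1).all()
        assert table["Hd"].isna().all()
        assert (table["Pi"] == 0).all()

    def test_default_system_invariants(self, default_system, default_view):
        haps, tree = default_view
        from slossgen.phylo import pd_by_island

        pdisl = pd_by_island(tree, haps.occurrence)
        table = diversity_table(
            haps, default_system.alignment, default_system.island_map, pdisl
        )
        assert (table["H"] <= table["Sn"]).all()
        assert (table["H"] <= haps.n_haplotypes).all()
        assert int(table["Sn"].sum()) == len(default_system.alignment)
        undefined = table["Hd"].isna()
        assert (table.loc[undefined, "H"] == 1).all()
        assert (table.loc[~undefined, "H"] > 1).all()
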