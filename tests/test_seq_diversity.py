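"""Identity, clustering, nucleotide diversity and synteny statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdptools import (
    GeneMap,
    GenomeCollection,
    GenomeTruthSpec,
    check_synteny,
    cluster_species,
    generate_genome_collection,
    identity_matrix,
    pairwise_identity,
    per_gene_diversity,
    variant_table,
    windowed_pi,
)
from pdptools.seq_diversity import (
    Gene,
    read_gene_map,
    read_genome_collection,
    write_gene_map,
    write_genome_collection,
)


def collection_of(*seqs, reference=None):
    reference = reference or seqs[0]
    return GenomeCollection(
        reference_id="REF",
        reference=reference,
        ids=[f"s{i}" for i in range(len(seqs))],
        sequences=list(seqs),
    )


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 100.0),
            ("ACGT", "ACGA", 75.0),
            ("AC-T", "ACGT", 100.0),  # gap column excluded: 3 comparable, 3 match
            ("ACNT", "ACGT", 100.0),  # N treated like a gap
        ],
    )
    def test_comparable_position_rule(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_no_comparable_positions_flagged(self):
        assert np.isnan(pairwise_identity("--", "AA"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACG", "ACGT")


class TestIdentityMatrix:
    def test_single_isolate(self):
        mat = identity_matrix(collection_of("ACGTACGT"))
        assert mat.shape == (1, 1)
        assert mat.iloc[0, 0] == 100.0

    def test_identical_triplet(self):
        mat = identity_matrix(collection_of("ACGT", "ACGT", "ACGT"))
        assert (mat.to_numpy() == 100.0).all()

    def test_matches_per_pair_brute_force(self):
        spec = GenomeTruthSpec(reference_length_bp=600, n_genes=3,
                               cluster_sizes=(2, 3), rng_seed=11)
        coll, _, _ = generate_genome_collection(spec)
        mat = identity_matrix(coll)
        for i, j in itertools.combinations(range(coll.n), 2):
            a, b = coll.sequences[i], coll.sequences[j]
            comparable = [
                (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
            ]
            expected = 100.0 * sum(x == y for x, y in comparable) / len(comparable)
            assert mat.iloc[i, j] == pytest.approx(expected)
            assert mat.iloc[j, i] == pytest.approx(expected)


def matrix_from_pairs(ids, pairs):
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for (a, b), v in pairs.items():
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


class TestClusterSpecies:
    def test_single_isolate_single_cluster(self):
        clusters = cluster_species(matrix_from_pairs(["A"], {}))
        assert clusters.n_clusters == 1

    def test_single_linkage_chains_through_intermediate(self):
        mat = matrix_from_pairs(
            ["A", "B", "C"], {("A", "B"): 96, ("B", "C"): 96, ("A", "C"): 92}
        )
        clusters = cluster_species(mat, 95.0)
        assert clusters.n_clusters == 1

    def test_complete_linkage_splits_the_chain(self):
        mat = matrix_from_pairs(
            ["A", "B", "C"], {("A", "B"): 96, ("B", "C"): 96, ("A", "C"): 92}
        )
        clusters = cluster_species(mat, 95.0, linkage="complete")
        assert clusters.n_clusters == 2

    def test_pair_below_cutoff_separated(self):
        clusters = cluster_species(matrix_from_pairs(["A", "B"], {("A", "B"): 94.9}))
        assert clusters.n_clusters == 2

    def test_identity_exactly_at_threshold_links(self):
        clusters = cluster_species(matrix_from_pairs(["A", "B"], {("A", "B"): 95.0}))
        assert clusters.n_clusters == 1

    def test_threshold_extremes(self):
        mat = matrix_from_pairs(
            ["A", "B", "C"], {("A", "B"): 80, ("B", "C"): 70, ("A", "C"): 60}
        )
        assert cluster_species(mat, 0.0).n_clusters == 1
        assert cluster_species(mat, 100.0 + 1e-9).n_clusters == 3


class TestVariantTable:
    def test_identical_collection_has_no_variant_sites(self):
        table = variant_table(collection_of("ACGTACGT", "ACGTACGT"))
        assert not table.variant_sites().any()

    def test_single_difference_counted(self):
        seqs = ["ACGTACGTAC"] * 3 + ["ACGTAGGTAC"]  # alt at position 5
        table = variant_table(collection_of(*seqs))
        assert table.variant_sites().sum() == 1
        assert table.variant_sites()[5]
        assert sorted(table.counts[5][table.counts[5] > 0]) == [1, 3]

    def test_gap_reduces_coverage(self):
        table = variant_table(collection_of("ACGT", "AC-T", "ACGT"))
        assert table.coverage[2] == 2
        assert table.coverage[0] == 3

    def test_reference_gap_columns_dropped(self):
        coll = GenomeCollection(
            reference_id="REF", reference="AC-GT",
            ids=["a", "b"], sequences=["ACTGT", "ACTGT"],
        )
        table = variant_table(coll)
        assert table.length == 4
        np.testing.assert_array_equal(table.positions, [0, 1, 3, 4])


class TestWindowedPi:
    def test_identical_sequences_zero_everywhere(self):
        table = variant_table(collection_of("ACGT" * 100, "ACGT" * 100))
        profile = windowed_pi(table, 100)
        assert (profile["pi"] == 0).all()

    def test_two_sequences_one_snp_in_100bp_window(self):
        a = "A" * 200
        b = "A" * 50 + "C" + "A" * 149
        profile = windowed_pi(variant_table(collection_of(a, b)), 100)
        assert profile["pi"].iloc[0] == pytest.approx(0.01)
        assert profile["pi"].iloc[1] == 0.0

    def test_balanced_biallelic_site(self):
        seqs = ["A" * 100] * 2 + ["A" * 40 + "G" + "A" * 59] * 2
        profile = windowed_pi(variant_table(collection_of(*seqs)), 100)
        assert profile["pi"].iloc[0] == pytest.approx((4 / 6) / 100)

    def test_short_final_window_uses_actual_span(self):
        a = "A" * 150
        b = "A" * 120 + "C" + "A" * 29
        profile = windowed_pi(variant_table(collection_of(a, b)), 100)
        assert profile["end"].iloc[-1] - profile["start"].iloc[-1] == 50
        assert profile["pi"].iloc[-1] == pytest.approx(1 / 50)

    def test_invalid_window_rejected(self):
        table = variant_table(collection_of("ACGT", "ACGT"))
        with pytest.raises(ValueError):
            windowed_pi(table, 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_mean_pairwise_difference_oracle(self, data):
        """Window pi from allele counts equals the direct mean pairwise
        difference over all sequence pairs (gap-free collections)."""
        n = data.draw(st.integers(2, 6))
        L = data.draw(st.integers(2, 500))
        w = data.draw(st.integers(1, 120))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)
        ]
        profile = windowed_pi(variant_table(collection_of(*seqs)), w)
        n_pairs = n * (n - 1) // 2
        for _, row in profile.iterrows():
            start, end = int(row["start"]), int(row["end"])
            diff_total = sum(
                sum(x != y for x, y in zip(a[start:end], b[start:end]))
                for a, b in itertools.combinations(seqs, 2)
            )
            oracle = diff_total / n_pairs / (end - start)
            assert row["pi"] == pytest.approx(oracle, abs=1e-12)

    def test_permutation_invariance(self):
        spec = GenomeTruthSpec(reference_length_bp=400, n_genes=2,
                               cluster_sizes=(2, 2), rng_seed=5)
        coll, _, _ = generate_genome_collection(spec)
        shuffled = GenomeCollection(
            reference_id="REF", reference=coll.reference,
            ids=list(reversed(coll.ids)), sequences=list(reversed(coll.sequences)),
        )
        pd.testing.assert_frame_equal(
            windowed_pi(variant_table(coll), 100),
            windowed_pi(variant_table(shuffled), 100),
        )

    def test_mean_pi_monotone_in_mutation_rate(self):
        means = []
        for mu in (0.001, 0.005, 0.01, 0.02):
            spec = GenomeTruthSpec(
                reference_length_bp=2000, n_genes=4, cluster_sizes=(20,),
                within_identity_pct=100 * (1 - 2 * mu),
                between_identity_pct=50.0, rng_seed=8,
            )
            coll, _, _ = generate_genome_collection(spec)
            means.append(windowed_pi(variant_table(coll), 100)["pi"].mean())
        assert np.all(np.diff(means) > 0)

    def test_window_pi_sums_to_pairwise_mismatches_for_two_sequences(self):
        rng = np.random.default_rng(10)
        a = "".join(rng.choice(list("ACGT"), size=350))
        b_list = list(a)
        for pos in rng.choice(350, size=12, replace=False):
            b_list[pos] = "ACGT"[("ACGT".index(b_list[pos]) + 1) % 4]
        b = "".join(b_list)
        profile = windowed_pi(variant_table(collection_of(a, b)), 100)
        weighted = (profile["pi"] * (profile["end"] - profile["start"])).sum()
        assert weighted == pytest.approx(12.0)


class TestPerGeneDiversity:
    def test_empty_gene_map(self):
        table = variant_table(collection_of("ACGT", "ACGT"))
        assert per_gene_diversity(table, GeneMap(genes=[])).empty

    def test_uniform_diversity_gives_equal_means(self):
        # one SNP in each of two equal-length genes
        a = "A" * 200
        b = "A" * 10 + "C" + "A" * 99 + "G" + "A" * 89
        table = variant_table(collection_of(a, b))
        genes = GeneMap(genes=[Gene("g1", 0, 100), Gene("g2", 100, 200)])
        result = per_gene_diversity(table, genes)
        assert result["pi"].iloc[0] == pytest.approx(result["pi"].iloc[1])

    def test_hotspot_gene_has_highest_diversity(self):
        multipliers = [1.0] * 31
        multipliers[18] = 10.0
        spec = GenomeTruthSpec(
            reference_length_bp=15000, cluster_sizes=(10,),
            within_identity_pct=99.6, between_identity_pct=99.0,
            gene_multipliers=tuple(multipliers), rng_seed=21,
        )
        coll, genes, _ = generate_genome_collection(spec)
        result = per_gene_diversity(variant_table(coll), genes)
        assert result["pi"].idxmax() == 18

    def test_out_of_range_gene_named_in_error(self):
        table = variant_table(collection_of("ACGT", "ACGT"))
        genes = GeneMap(genes=[Gene("geneX", 0, 10)])
        with pytest.raises(ValueError, match="geneX"):
            per_gene_diversity(table, genes)


class TestSynteny:
    REF = [f"g{i}" for i in range(1, 32)]

    def test_conserved_order_passes(self):
        report = check_synteny({"isoA": self.REF, "isoB": self.REF}, self.REF)
        assert report.passed
        assert report.violations == []

    def test_missing_gene_reported(self):
        report = check_synteny({"isoA": self.REF[:-1]}, self.REF)
        assert not report.passed
        assert report.violations == [
            {"isolate": "isoA", "kind": "missing", "gene": "g31"}
        ]

    def test_adjacent_swap_reported_out_of_order(self):
        swapped = self.REF.copy()
        swapped[4], swapped[5] = swapped[5], swapped[4]
        report = check_synteny({"isoA": swapped}, self.REF)
        assert not report.passed
        kinds = {v["kind"] for v in report.violations}
        assert kinds == {"out-of-order"}
        assert len(report.violations) == 1

    def test_extra_gene_reported(self):
        report = check_synteny({"isoA": self.REF + ["gX"]}, self.REF)
        assert [v["kind"] for v in report.violations] == ["extra"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            check_synteny({"isoA": ["g1"]}, [])


class TestFileIO:
    def test_fasta_round_trip(self, tmp_path):
        spec = GenomeTruthSpec(reference_length_bp=500, n_genes=2,
                               cluster_sizes=(2,), rng_seed=0)
        coll, _, _ = generate_genome_collection(spec)
        path = tmp_path / "genomes.fasta"
        write_genome_collection(coll, path)
        back = read_genome_collection(path)
        assert back.reference == coll.reference
        assert back.ids == coll.ids
        assert back.sequences == coll.sequences

    def test_gff3_round_trip_one_based_inclusive(self, tmp_path):
        genes = GeneMap(genes=[Gene("g1", 0, 100), Gene("g2", 100, 250, "-")])
        path = tmp_path / "genes.gff3"
        write_gene_map(genes, path)
        text = path.read_text()
        assert "\t1\t100\t" in text  # 0-based [0,100) -> 1-based 1..100
        assert "\t101\t250\t" in text
        back = read_gene_map(path)
        assert [(g.gene_id, g.start, g.end, g.strand) for g in back] == [
            ("g1", 0, 100, "+"), ("g2", 100, 250, "-"),
        ]
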