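"""Per-gene feature computation: distances, TES, EES, SNPs, degree, GO."""

import math

import numpy as np
import pandas as pd
import pytest

from denpipe.gene_features import (
    STAGE_TO_ORDINAL,
    chrom_pair_distances,
    chromosome_den_table,
    earliest_stage_table,
    is_disease_snp,
    ppi_degrees,
    subcellular_classes,
    subcellular_table,
    tissue_specificity,
    tissue_specificity_scores,
    variant_summaries,
    variant_summary,
)
from denpipe.io_formats import GeneLocus, InteractionEdge, VariantRecord
from oracles import brute_force_pair_distances


def loci_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


class TestChromPairDistances:
    def test_two_genes_single_midpoint_distance(self):
        loci = loci_frame([("A", "chr1", 50, 150), ("B", "chr1", 450, 550)])
        out = chrom_pair_distances(loci, {"A", "B"})
        assert out.tolist() == [400.0]

    def test_different_chromosomes_emit_no_pair(self):
        loci = loci_frame([("A", "chr1", 0, 100), ("B", "chr2", 0, 100)])
        assert chrom_pair_distances(loci, {"A", "B"}).size == 0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(12):
            start = int(rng.integers(0, 10_000))
            rows.append((f"G{i}", f"chr{rng.integers(1, 4)}", start,
                         start + int(rng.integers(10, 500))))
        genes = {f"G{i}" for i in range(12)}
        got = sorted(chrom_pair_distances(loci_frame(rows), genes).tolist())
        want = sorted(brute_force_pair_distances(rows, genes))
        assert got == pytest.approx(want)

    def test_pair_count_formula(self):
        rows = [(f"G{i}", "chr1", i * 1000, i * 1000 + 10) for i in range(5)]
        rows += [(f"H{i}", "chr2", i * 1000, i * 1000 + 10) for i in range(3)]
        out = chrom_pair_distances(loci_frame(rows),
                                   {r[0] for r in rows})
        assert out.size == math.comb(5, 2) + math.comb(3, 2)

    def test_subsample_is_seed_deterministic_subset(self):
        rng = np.random.default_rng(0)
        rows = [(f"G{i}", "chr1", int(rng.integers(0, 10**6)),
                 int(rng.integers(0, 10**6)) + 10**6) for i in range(40)]
        genes = {r[0] for r in rows}
        full = chrom_pair_distances(loci_frame(rows), genes)
        sub1 = chrom_pair_distances(loci_frame(rows), genes, max_pairs=100, seed=7)
        sub2 = chrom_pair_distances(loci_frame(rows), genes, max_pairs=100, seed=7)
        assert np.array_equal(sub1, sub2)
        assert sub1.size == 100
        full_sorted = np.sort(full)
        assert all(np.any(np.isclose(full_sorted, d)) for d in sub1)

    def test_no_shared_chromosome_is_flagged_empty(self, caplog):
        loci = loci_frame([("A", "chr1", 0, 10)])
        with caplog.at_level("WARNING"):
            out = chrom_pair_distances(loci, {"A"})
        assert out.size == 0


class TestChromosomeDenTable:
    def test_bookkeeping_and_conservation(self):
        counts = pd.DataFrame(
            {"up_count": [5, 4, 6, 9], "down_count": [1, 0, 2, 3],
             "n_samples": 10},
            index=pd.Index(["A", "B", "C", "NOLOC"], name="unit_id"))
        loci = loci_frame([("A", "chrY", 0, 10), ("B", "chrY", 20, 30),
                           ("C", "chrY", 40, 50)])
        table = chromosome_den_table(counts, loci)
        assert set(table["gene_id"]) == {"A", "B", "C"}  # NOLOC excluded
        y = table[table["chromosome"] == "chrY"]
        assert sorted(zip(y["up_count"], y["down_count"])) == [(4, 0), (5, 1), (6, 2)]
        assert table["up_count"].sum() == counts.loc[["A", "B", "C"], "up_count"].sum()


class TestTissueSpecificity:
    def test_closed_forms(self):
        assert tissue_specificity([10, 10, 10, 10]) == 0.25
        assert tissue_specificity([5, 0, 0, 0]) == 1.0
        assert tissue_specificity([3.0] * 79) == pytest.approx(1 / 79)

    def test_zero_profile_is_undefined(self):
        assert math.isnan(tissue_specificity([0, 0, 0]))

    def test_extremes_characterise_profiles(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            profile = rng.gamma(1.0, 1.0, size=8)
            profile[rng.random(8) < 0.4] = 0.0
            if profile.sum() == 0:
                continue
            tes = tissue_specificity(profile)
            n_positive = int((profile > 0).sum())
            assert (tes == 1.0) == (n_positive == 1)
            uniform_positive = n_positive == 8 and len(set(profile)) == 1
            assert (tes == pytest.approx(1 / 8)) == uniform_positive

    def test_vectorised_scores_match_scalar(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.gamma(0.5, 1.0, size=(20, 10)),
                             index=[f"G{i}" for i in range(20)])
        scores = tissue_specificity_scores(frame)
        for gid in frame.index:
            assert scores[gid] == pytest.approx(
                tissue_specificity(frame.loc[gid].to_numpy()))


class TestEarliestStage:
    def test_fixed_stage_order(self):
        labels = pd.Series({"G1": "fetus", "G2": "adult", "G3": "Embryoid Body"})
        ordinals = earliest_stage_table(labels)
        assert ordinals["G1"] == 3
        assert ordinals["G2"] == 7
        assert ordinals["G3"] == 1

    def test_unknown_label_excluded_with_warning(self, caplog):
        labels = pd.Series({"G1": "larva", "G2": "neonate"})
        with caplog.at_level("WARNING"):
            ordinals = earliest_stage_table(labels)
        assert list(ordinals.index) == ["G2"]
        assert STAGE_TO_ORDINAL["neonate"] == 4


class TestDiseaseSnp:
    def test_pathogenic_with_rsid_is_dsnp(self):
        v = VariantRecord("chr1", 5, "rs1", frozenset({"pathogenic"}))
        assert is_disease_snp(v)

    @pytest.mark.parametrize("label", [
        "likely_benign", "benign", "protective", "uncertain_significance",
        "conflicting_data_from_submitters", "other", "not_provided",
    ])
    def test_excluded_labels(self, label):
        v = VariantRecord("chr1", 5, "rs1", frozenset({label}))
        assert not is_disease_snp(v)

    def test_requires_rsid_and_some_label(self):
        assert not is_disease_snp(
            VariantRecord("chr1", 5, None, frozenset({"pathogenic"})))
        assert not is_disease_snp(VariantRecord("chr1", 5, "rs1", frozenset()))

    def test_mixed_labels_with_exclusion_fail(self):
        v = VariantRecord("chr1", 5, "rs1",
                          frozenset({"pathogenic", "likely_benign"}))
        assert not is_disease_snp(v)


class TestVariantSummary:
    def test_density_formula(self):
        locus = GeneLocus("G", "chr1", 1000, 2000)
        variants = [VariantRecord("chr1", 1000 + 100 * i, f"rs{i}",
                                  frozenset({"pathogenic"})) for i in range(5)]
        summary = variant_summary(locus, variants)
        assert summary.snp_count == 5
        assert summary.dsnp_count == 5
        assert summary.snp_density == 5 / 1000

    def test_half_open_boundaries(self):
        locus = GeneLocus("G", "chr1", 100, 200)
        at_start = VariantRecord("chr1", 100)
        at_end = VariantRecord("chr1", 200)
        summary = variant_summary(locus, [at_start, at_end])
        assert summary.snp_count == 1  # start inclusive, end exclusive

    def test_one_inside_variant_increments_density_by_inverse_length(self):
        locus = GeneLocus("G", "chr2", 0, 400)
        base = variant_summary(locus, [])
        more = variant_summary(locus, [VariantRecord("chr2", 10)])
        assert more.snp_count == base.snp_count + 1
        assert more.snp_density - base.snp_density == pytest.approx(1 / 400)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_vectorised_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        loci = [GeneLocus(f"G{i}", f"chr{rng.integers(1, 3)}",
                          int(s := rng.integers(0, 5000)),
                          int(s + rng.integers(100, 1500)))
                for i in range(10)]
        variants = [
            VariantRecord(f"chr{rng.integers(1, 3)}", int(rng.integers(0, 7000)),
                          f"rs{i}" if rng.random() < 0.8 else None,
                          frozenset({"pathogenic"}) if rng.random() < 0.5
                          else frozenset({"benign"}))
            for i in range(200)
        ]
        table = variant_summaries(loci, variants).set_index("gene_id")
        for locus in loci:
            expected = variant_summary(locus, variants)
            assert table.loc[locus.gene_id, "snp_count"] == expected.snp_count
            assert table.loc[locus.gene_id, "dsnp_count"] == expected.dsnp_count
            assert table.loc[locus.gene_id, "snp_density"] == pytest.approx(
                expected.snp_density)


class TestPpiDegrees:
    def test_triangle(self):
        edges = [InteractionEdge("A", "B"), InteractionEdge("B", "C"),
                 InteractionEdge("A", "C")]
        degrees = ppi_degrees(edges)
        assert degrees.to_dict() == {"A": 2, "B": 2, "C": 2}

    def test_genetic_duplicate_filtered_then_deduplicated(self):
        edges = [InteractionEdge("A", "B", system_class="genetic"),
                 InteractionEdge("A", "B", system_class="physical")]
        degrees = ppi_degrees(edges)
        assert degrees.to_dict() == {"A": 1, "B": 1}
        unfiltered = ppi_degrees(edges, drop_genetic=False)
        assert unfiltered.to_dict() == {"A": 1, "B": 1}  # still one partner

    def test_ubiquitination_edges_removed(self):
        edges = [InteractionEdge("A", "B", modification="Ubiquitination"),
                 InteractionEdge("A", "C")]
        assert ppi_degrees(edges).to_dict() == {"A": 1, "C": 1}

    def test_self_loops_ignored(self):
        assert ppi_degrees([InteractionEdge("A", "A")]).empty

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_adjacency_set_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"N{i}" for i in range(25)]
        edges = [InteractionEdge(names[rng.integers(25)], names[rng.integers(25)])
                 for _ in range(100)]
        degrees = ppi_degrees(edges)
        adjacency: dict[str, set[str]] = {}
        for e in edges:
            if e.gene_a == e.gene_b:
                continue
            adjacency.setdefault(e.gene_a, set()).add(e.gene_b)
            adjacency.setdefault(e.gene_b, set()).add(e.gene_a)
        assert degrees.to_dict() == {k: len(v) for k, v in adjacency.items()}
        # handshake lemma on the collapsed simple graph
        n_simple = len({tuple(sorted((e.gene_a, e.gene_b))) for e in edges
                        if e.gene_a != e.gene_b})
        assert degrees.sum() == 2 * n_simple


class TestSubcellular:
    def gaf(self):
        return pd.DataFrame({
            "gene_id": ["G1", "G2", "G2", "G3", "G4"],
            "qualifier": ["located_in", "located_in", "located_in",
                          "NOT|located_in", "located_in"],
            "go_id": ["GO:0005634", "GO:0005634", "GO:0005737",
                      "GO:0005634", "GO:0099999"],
        })

    def test_single_and_multi_class(self):
        assert subcellular_classes(self.gaf(), "G1") == {"nucleus"}
        assert subcellular_classes(self.gaf(), "G2") == {"nucleus", "cytoplasm"}

    def test_not_qualifier_ignored(self):
        assert subcellular_classes(self.gaf(), "G3") == frozenset()

    def test_unrelated_term_leaves_gene_uncategorised(self):
        table = subcellular_table(self.gaf())
        assert "G4" in table.index
        assert not table.loc["G4"].any()
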