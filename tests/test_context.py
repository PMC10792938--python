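"""Context partitions vs per-bp oracles, chi-square, nearest genes, overlaps."""

import numpy as np
import pandas as pd
import pytest

from epirevert import intervals as ivl
from epirevert.context import (
    CPG_CATEGORIES,
    GENE_CATEGORIES,
    ContextComposition,
    annotate_gene_context,
    annotate_region_context,
    build_cpg_context,
    build_gene_context,
    composition_chisq,
    genome_composition,
    label_expression_change,
    nearest_flanking_genes,
    overlap_fraction,
    regions_composition,
)


def perbp_labels_cpg(islands, length, flank=2000):
    """Per-bp oracle for the island/shore/shelf/ocean partition."""
    lab = np.full(length, "ocean", dtype=object)
    isl = np.zeros(length, dtype=bool)
    for s, e in islands:
        isl[s:e] = True
    shore = np.zeros(length, dtype=bool)
    for s, e in islands:
        shore[max(0, s - flank) : min(length, e + flank)] = True
    shore &= ~isl
    shelf = np.zeros(length, dtype=bool)
    cover = isl | shore
    idx = np.flatnonzero(cover)
    for i in idx:
        shelf[max(0, i - flank) : min(length, i + flank + 1)] = True
    shelf &= ~cover
    lab[shelf] = "shelf"
    lab[shore] = "shore"
    lab[isl] = "island"
    return lab


class TestCpGContext:
    def test_single_island_textbook_layout(self):
        part = build_cpg_context({"chr1": np.array([[1000, 2000]])}, {"chr1": 100_000})
        np.testing.assert_array_equal(part["island"]["chr1"], [[1000, 2000]])
        np.testing.assert_array_equal(part["shore"]["chr1"], [[0, 1000], [2000, 4000]])
        np.testing.assert_array_equal(part["shelf"]["chr1"], [[4000, 6000]])
        np.testing.assert_array_equal(part["ocean"]["chr1"], [[6000, 100_000]])

    def test_close_islands_share_a_shore(self):
        part = build_cpg_context(
            {"chr1": np.array([[3000, 4000], [5000, 6000]])}, {"chr1": 50_000}
        )
        gap_lab = [
            cat
            for cat in CPG_CATEGORIES
            if ivl.overlap_bp(4000, 5000, part[cat]["chr1"]) > 0
        ]
        assert gap_lab == ["shore"]
        assert ivl.overlap_bp(4000, 5000, part["shore"]["chr1"]) == 1000

    def test_no_islands_all_ocean(self):
        part = build_cpg_context({}, {"chr1": 10_000})
        assert ivl.total_length(part["ocean"]["chr1"]) == 10_000

    def test_out_of_bounds_island_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            build_cpg_context({"chr1": np.array([[500, 20_000]])}, {"chr1": 10_000})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_tiles_genome_and_matches_perbp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = 10_000
        starts = np.sort(rng.choice(length - 600, size=3, replace=False))
        islands = ivl.merge([(int(s), int(s) + int(rng.integers(50, 500))) for s in starts])
        part = build_cpg_context({"chr1": islands}, {"chr1": length}, flank=700)
        # exact tiling
        total = sum(ivl.total_length(part[c]["chr1"]) for c in CPG_CATEGORIES)
        assert total == length
        union = ivl.merge(np.concatenate([part[c]["chr1"] for c in CPG_CATEGORIES]))
        np.testing.assert_array_equal(union, [[0, length]])
        # per-bp equality on random regions
        lab = perbp_labels_cpg(islands, length, flank=700)
        for _ in range(20):
            s = int(rng.integers(0, length - 50))
            e = s + int(rng.integers(1, 800))
            e = min(e, length)
            comp = annotate_region_context(("chr1", s, e), part)
            for cat in CPG_CATEGORIES:
                assert comp.counts[cat] == int(np.sum(lab[s:e] == cat)), (cat, s, e)

    def test_region_inside_island_is_pure_island(self):
        part = build_cpg_context({"chr1": np.array([[1000, 2000]])}, {"chr1": 100_000})
        comp = annotate_region_context(("chr1", 1200, 1400), part)
        assert comp.fractions["island"] == 1.0

    def test_straddling_region_splits_half_half(self):
        part = build_cpg_context({"chr1": np.array([[1000, 2000]])}, {"chr1": 100_000})
        comp = annotate_region_context(("chr1", 1900, 2100), part)
        assert comp.fractions["island"] == pytest.approx(0.5)
        assert comp.fractions["shore"] == pytest.approx(0.5)

    def test_composition_additivity_over_disjoint_regions(self):
        part = build_cpg_context({"chr1": np.array([[1000, 2000]])}, {"chr1": 100_000})
        a = annotate_region_context(("chr1", 0, 3000), part)
        b = annotate_region_context(("chr1", 5000, 8000), part)
        both = regions_composition([("chr1", 0, 3000), ("chr1", 5000, 8000)], part)
        assert (a + b).counts == both.counts


class TestGeneContext:
    @staticmethod
    def _toy_genes():
        return pd.DataFrame(
            [
                {
                    "gene_id": "g1", "chrom": "chr1", "strand": "+",
                    "tss": 1000, "start": 1000, "end": 5000,
                    "exons": [(1000, 1500), (3000, 3600), (4500, 5000)],
                },
                {
                    "gene_id": "g2", "chrom": "chr1", "strand": "-",
                    "tss": 8999, "start": 6000, "end": 9000,
                    "exons": [(6000, 6400), (8500, 9000)],
                },
            ]
        )

    def test_region_inside_intron(self):
        part = build_gene_context(self._toy_genes(), {"chr1": 10_000})
        comp = annotate_gene_context(("chr1", 2000, 2500), part)
        assert comp.fractions["intron"] == 1.0

    def test_region_without_gene_is_intergenic(self):
        part = build_gene_context(self._toy_genes(), {"chr1": 10_000})
        comp = annotate_gene_context(("chr1", 9500, 9900), part)
        assert comp.fractions["intergenic"] == 1.0

    def test_perbp_oracle_equality(self):
        genes = self._toy_genes()
        length = 10_000
        part = build_gene_context(genes, {"chr1": length})
        lab = np.full(length, "intergenic", dtype=object)
        for _, g in genes.iterrows():
            lab[g["start"] : g["end"]] = "intron"
        for _, g in genes.iterrows():
            for s, e in g["exons"]:
                lab[s:e] = "exon"
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = int(rng.integers(0, length - 100))
            e = s + int(rng.integers(1, 2000))
            e = min(e, length)
            comp = annotate_gene_context(("chr1", s, e), part)
            for cat in GENE_CATEGORIES:
                assert comp.counts[cat] == int(np.sum(lab[s:e] == cat))

    def test_partition_tiles_genome(self):
        part = build_gene_context(self._toy_genes(), {"chr1": 10_000})
        total = sum(ivl.total_length(part[c]["chr1"]) for c in GENE_CATEGORIES)
        assert total == 10_000


class TestChiSquare:
    def test_identical_composition_gives_zero_stat_p_one(self):
        obs = ContextComposition({"a": 50, "b": 50})
        bg = ContextComposition({"a": 500, "b": 500})
        stat, p = composition_chisq(obs, bg)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_ninety_ten(self):
        obs = ContextComposition({"a": 90, "b": 10})
        bg = ContextComposition({"a": 1, "b": 1})
        stat, p = composition_chisq(obs, bg)
        # sum (O-E)^2 / E = 40^2/50 + 40^2/50 = 64
        assert stat == pytest.approx(64.0)
        assert p < 1e-10

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            composition_chisq(
                ContextComposition({"a": 0, "b": 0}), ContextComposition({"a": 1, "b": 1})
            )

    def test_genome_background_vs_itself(self):
        part = build_cpg_context({"chr1": np.array([[1000, 2000]])}, {"chr1": 100_000})
        bg = genome_composition(part)
        stat, p = composition_chisq(bg, bg)
        assert stat == pytest.approx(0.0)


class TestNearestGenes:
    genes = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "strand": "+", "tss": 4000,
             "start": 4000, "end": 6000, "exons": [(4000, 6000)]},
            {"gene_id": "gB", "chrom": "chr1", "strand": "+", "tss": 10_000,
             "start": 10_000, "end": 12_000, "exons": [(10_000, 12_000)]},
        ]
    )

    def test_flanking_distances(self):
        res = nearest_flanking_genes(("chr1", 5000, 5001), self.genes)
        # region sits inside gA's span but contains no TSS -> both sides
        by_side = {r.side: r for r in res}
        assert by_side["left"].gene_id == "gA"
        assert by_side["left"].distance == -1000
        assert by_side["right"].gene_id == "gB"
        assert by_side["right"].distance == 5000

    def test_tss_inside_region_distance_zero(self):
        res = nearest_flanking_genes(("chr1", 3500, 4500), self.genes)
        assert len(res) == 1
        assert res[0].gene_id == "gA" and res[0].distance == 0

    def test_single_sided_chromosome(self):
        res = nearest_flanking_genes(("chr1", 100, 200), self.genes)
        assert [r.side for r in res] == ["right"]

    def test_empty_chromosome_gives_empty(self):
        assert nearest_flanking_genes(("chrY", 0, 100), self.genes) == []

    def test_tie_breaks_by_coordinate_then_id(self):
        genes = pd.DataFrame(
            [
                {"gene_id": "gZ", "chrom": "chr1", "strand": "+", "tss": 500,
                 "start": 500, "end": 600, "exons": [(500, 600)]},
                {"gene_id": "gA", "chrom": "chr1", "strand": "+", "tss": 500,
                 "start": 500, "end": 700, "exons": [(500, 700)]},
            ]
        )
        res = nearest_flanking_genes(("chr1", 1000, 1100), genes)
        assert res[0].gene_id == "gA"  # same coordinate, lexicographic id


class TestExpressionLabels:
    @pytest.mark.parametrize(
        "fc,expected",
        [(1.5, "up"), (-2.0, "down"), (0.99, "neutral"), (1.0, "neutral"), (-1.0, "neutral")],
    )
    def test_threshold_rule(self, fc, expected):
        assert label_expression_change(fc) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            label_expression_change(float("nan"))


class TestOverlapFraction:
    def test_all_regions_inside_features(self):
        track = {"chr1": np.array([[0, 10_000]])}
        regions = [("chr1", i * 100, i * 100 + 50) for i in range(10)]
        assert overlap_fraction(regions, track) == 1.0

    def test_empty_track_gives_zero(self):
        assert overlap_fraction([("chr1", 0, 100)], {}) == 0.0

    def test_shared_endpoint_is_not_overlap(self):
        track = {"chr1": np.array([[100, 200]])}
        assert overlap_fraction([("chr1", 0, 100)], track) == 0.0
        assert overlap_fraction([("chr1", 200, 300)], track) == 0.0
        assert overlap_fraction([("chr1", 199, 300)], track) == 1.0

    def test_matches_quadratic_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        regions = []
        feats = []
        for _ in range(60):
            s = int(rng.integers(0, 9000))
            regions.append(("chr1", s, s + int(rng.integers(1, 500))))
        for _ in range(30):
            s = int(rng.integers(0, 9000))
            feats.append((s, s + int(rng.integers(1, 300))))
        track = {"chr1": ivl.merge(feats)}
        frac = overlap_fraction(regions, track)
        naive = np.mean(
            [any(s < fe and e > fs for fs, fe in feats) for _, s, e in regions]
        )
        assert frac == pytest.approx(naive)
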