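import numpy as np
import pandas as pd
import pytest

from telandscape.core_model import ProximityConfig, RegionCategory, SeqRegion
from telandscape.gene_context import (
    build_feature_table,
    category_distribution,
    classify_te,
    count_couples,
    filter_couples,
    go_distribution_for_genes,
    nearest_genes,
    neighbor_go_distribution,
    region_position_histogram,
)
from telandscape.ontology_io import GODag, GeneGOMap, SlimSet

from .conftest import make_gene, make_genome, make_te

CFG = ProximityConfig()


class TestNearestGenes:
    def test_flank_gaps(self):
        te = make_te(start=1000, end=1500)
        genes = [make_gene(start=100, end=400, name="L"), make_gene(start=4000, end=6000, name="R")]
        rep = nearest_genes(te, genes)
        assert rep.left_gene[0].gene_name == "L" and rep.left_gene[1] == 599
        assert rep.right_gene[0].gene_name == "R" and rep.right_gene[1] == 2499
        assert rep.containing_genes == ()

    def test_containing_gene_excluded_from_flanks(self):
        te = make_te(start=1000, end=1500)
        genes = [make_gene(start=900, end=2000, name="host")]
        rep = nearest_genes(te, genes)
        assert [g.gene_name for g in rep.containing_genes] == ["host"]
        assert rep.left_gene is None and rep.right_gene is None

    def test_no_genes_means_no_neighbors(self):
        rep = nearest_genes(make_te(), [])
        assert rep.left_gene is None and rep.right_gene is None

    def test_unsorted_input_rejected(self):
        genes = [make_gene(start=500, end=600), make_gene(start=100, end=200, name="b")]
        with pytest.raises(ValueError, match="sorted"):
            nearest_genes(make_te(start=1000, end=1100), genes)

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            genes = []
            for i in range(int(rng.integers(0, 15))):
                s = int(rng.integers(1, 5000))
                genes.append(make_gene(start=s, end=s + int(rng.integers(1, 400)), name=f"g{i}"))
            genes.sort(key=lambda g: g.region.start)
            s = int(rng.integers(1, 5000))
            te = make_te(start=s, end=s + int(rng.integers(1, 300)))
            rep = nearest_genes(te, genes)

            # oracle: look at every gene
            left = [g for g in genes if g.region.end < te.region.start]
            right = [g for g in genes if g.region.start > te.region.end]
            inside = [g for g in genes if g.region.overlaps(te.region)]
            want_left = max(left, key=lambda g: (g.region.end, -g.region.start), default=None)
            want_right = min(right, key=lambda g: (g.region.start, g.region.end), default=None)
            assert (rep.left_gene[0] if rep.left_gene else None) == want_left
            assert (rep.right_gene[0] if rep.right_gene else None) == want_right
            assert sorted(g.gene_name for g in rep.containing_genes) == sorted(
                g.gene_name for g in inside
            )


class TestClassifyTe:
    def _classify(self, te, genes, config=CFG):
        return classify_te(nearest_genes(te, sorted(genes, key=lambda g: g.region.start)), config)

    def test_promoter_on_5prime_side_of_forward_gene(self):
        te = make_te(start=1000, end=1500)
        cat = self._classify(te, [make_gene(start=4000, end=6000, strand="+")])
        assert cat is RegionCategory.PROXIMAL_PROMOTER

    def test_3end_on_3prime_side_of_forward_gene(self):
        te = make_te(start=7000, end=7400)
        cat = self._classify(te, [make_gene(start=4000, end=6000, strand="+")])
        assert cat is RegionCategory.PROXIMAL_3_END

    def test_strand_flips_promoter_side(self):
        te = make_te(start=7000, end=7400)
        cat = self._classify(te, [make_gene(start=4000, end=6000, strand="-")])
        assert cat is RegionCategory.PROXIMAL_PROMOTER

    def test_overlap_takes_precedence_over_proximity(self):
        te = make_te(start=3990, end=4010)
        genes = [make_gene(start=4000, end=6000), make_gene(start=1000, end=2000, name="near")]
        assert self._classify(te, genes) is RegionCategory.EXON_INTRON_UTR

    def test_distance_cutoff_inclusive_at_D_exclusive_past_it(self):
        gene = make_gene(start=10_000, end=12_000, strand="+")
        at_d = make_te(start=6500, end=6999)  # gap exactly 3000
        past_d = make_te(start=6499, end=6998)  # gap 3001
        assert self._classify(at_d, [gene]) is RegionCategory.PROXIMAL_PROMOTER
        assert self._classify(past_d, [gene]) is RegionCategory.INTERGENIC

    def test_exact_gap_tie_resolves_to_promoter(self):
        # both flanks 100 bp away: left gene (forward) puts the copy 3' of it,
        # right gene (forward) puts it 5' — promoter must win the tie
        te = make_te(start=2101, end=2200)
        genes = [
            make_gene(start=1000, end=2000, name="L", strand="+"),
            make_gene(start=2301, end=3000, name="R", strand="+"),
        ]
        assert self._classify(te, genes) is RegionCategory.PROXIMAL_PROMOTER

    def test_increasing_D_never_demotes_to_intergenic(self):
        rng = np.random.default_rng(13)
        gene = make_gene(start=50_000, end=55_000)
        for _ in range(50):
            s = int(rng.integers(1, 100_000))
            te = make_te(start=s, end=min(s + int(rng.integers(1, 800)), 100_000))
            small = self._classify(te, [gene], ProximityConfig(proximal_distance=2000))
            large = self._classify(te, [gene], ProximityConfig(proximal_distance=8000))
            if small in (RegionCategory.PROXIMAL_PROMOTER, RegionCategory.PROXIMAL_3_END):
                assert large is not RegionCategory.INTERGENIC
            if small is RegionCategory.EXON_INTRON_UTR:
                assert large is RegionCategory.EXON_INTRON_UTR


class TestCategoryDistribution:
    def test_planted_proportions_recovered(self):
        genes = [make_gene(start=50_000, end=54_000, name="g0", strand="+")]
        genome = make_genome(chrom_len=200_000, genes=genes)
        tes = (
            [make_te(start=51_000, end=51_100) for _ in range(10)]  # within
            + [make_te(start=48_000, end=48_500) for _ in range(10)]  # promoter side
            + [make_te(start=100_000 + i * 1000, end=100_100 + i * 1000) for i in range(80)]
        )
        dist = category_distribution(tes, genome, CFG)
        assert dist[RegionCategory.EXON_INTRON_UTR] == pytest.approx(0.10)
        assert dist[RegionCategory.PROXIMAL_PROMOTER] == pytest.approx(0.10)
        assert dist[RegionCategory.INTERGENIC] == pytest.approx(0.80)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_empty_input_gives_empty_distribution(self):
        assert category_distribution([], make_genome(), CFG) == {}

    def test_gene_free_chromosome_is_all_intergenic(self):
        genome = make_genome(chrom_len=10_000, genes=[])
        dist = category_distribution([make_te(), make_te(start=2000, end=2100)], genome, CFG)
        assert dist == {RegionCategory.INTERGENIC: 1.0}


class TestRegionPositionHistogram:
    def _genome_with_copies_at_gaps(self, gaps):
        gene = make_gene(start=100_000, end=105_000, strand="+")
        genome = make_genome(chrom_len=300_000, genes=[gene])
        tes = []
        for gap in gaps:  # 5' side of a forward gene
            end = gene.region.start - gap - 1
            tes.append(make_te(start=end - 99, end=end))
        return genome, tes

    def test_left_closed_bins(self):
        genome, tes = self._genome_with_copies_at_gaps([0, 149, 150])
        curve = region_position_histogram(tes, genome, CFG, RegionCategory.PROXIMAL_PROMOTER)
        assert curve.counts[0] == 2 and curve.counts[1] == 1
        assert curve.total == 3

    def test_gap_equal_to_D_lands_in_last_bin(self):
        genome, tes = self._genome_with_copies_at_gaps([3000, 3000])
        curve = region_position_histogram(tes, genome, CFG, RegionCategory.PROXIMAL_PROMOTER)
        assert curve.counts[-1] == 2

    def test_empty_input_all_zero(self):
        genome, _ = self._genome_with_copies_at_gaps([])
        curve = region_position_histogram([], genome, CFG, RegionCategory.PROXIMAL_3_END)
        assert curve.total == 0 and len(curve.counts) == CFG.region_bins

    def test_categories_without_distance_axis_rejected(self):
        genome, tes = self._genome_with_copies_at_gaps([10])
        with pytest.raises(ValueError, match="distance axis"):
            region_position_histogram(tes, genome, CFG, RegionCategory.INTERGENIC)


TOY_DAG = GODag.from_parent_map(
    {"GO:0000001": [], "GO:0000002": ["GO:0000001"], "GO:0000003": ["GO:0000001"]}
)
TOY_SLIM = SlimSet("toy", frozenset({"GO:0000002", "GO:0000003"}))


class TestGoDistributions:
    def test_single_annotated_neighbor(self):
        genes = [make_gene(numeric=1)]
        gm = GeneGOMap({1: frozenset({"GO:0000002"})})
        dist = go_distribution_for_genes(genes, gm, TOY_DAG, TOY_SLIM)
        assert dist.proportions == {"GO:0000002": 1.0}

    def test_assignment_counting_over_two_genes(self):
        genes = [make_gene(name="a", numeric=1), make_gene(name="b", numeric=2)]
        gm = GeneGOMap(
            {1: frozenset({"GO:0000002"}), 2: frozenset({"GO:0000002", "GO:0000003"})}
        )
        dist = go_distribution_for_genes(genes, gm, TOY_DAG, TOY_SLIM)
        assert dist.proportions["GO:0000002"] == pytest.approx(2 / 3)
        assert dist.proportions["GO:0000003"] == pytest.approx(1 / 3)

    def test_unannotated_bucket_and_sum_to_one(self):
        genes = [make_gene(name="a", numeric=1), make_gene(name="b")]  # b has no id
        gm = GeneGOMap({1: frozenset({"GO:0000002"})})
        dist = go_distribution_for_genes(genes, gm, TOY_DAG, TOY_SLIM)
        assert dist.proportions["unannotated"] == pytest.approx(0.5)
        assert sum(dist.proportions.values()) == pytest.approx(1.0)

    def test_display_threshold_pools_small_slices(self):
        from telandscape.gene_context import GODistribution

        dist = GODistribution(
            proportions={"A": 0.6, "B": 0.395, "C": 0.005}, display_threshold=0.01
        )
        shown = dist.displayed()
        assert "C" not in shown and shown["other"] == pytest.approx(0.005)
        assert sum(shown.values()) == pytest.approx(1.0)

    def test_neighbor_collection_includes_both_flanks(self):
        genes = [
            make_gene(start=100, end=400, name="L", numeric=1),
            make_gene(start=4000, end=6000, name="R", numeric=2),
        ]
        genome = make_genome(chrom_len=100_000, genes=genes)
        gm = GeneGOMap(
            {1: frozenset({"GO:0000002"}), 2: frozenset({"GO:0000003"})}
        )
        dist = neighbor_go_distribution([make_te(start=1000, end=1500)], genome, gm, TOY_DAG, TOY_SLIM)
        assert dist.proportions == {"GO:0000002": 0.5, "GO:0000003": 0.5}


class TestFeatureTable:
    def _genome(self):
        genes = [
            make_gene(start=100, end=400, name="L", strand="+"),
            make_gene(start=4000, end=6000, name="R", strand="+"),
            make_gene(start=8000, end=9000, name="F", strand="+"),
        ]
        return make_genome(chrom_len=100_000, genes=genes)

    def test_two_rows_for_flanked_copy(self):
        df = build_feature_table([make_te(start=1000, end=1500)], self._genome())
        assert len(df) == 2
        assert sorted(df.relation) == ["left", "right"]
        assert list(df.distance) == [599, 2499]

    def test_third_row_when_inserted_within_a_gene(self):
        df = build_feature_table([make_te(start=4500, end=4600)], self._genome())
        assert len(df) == 3
        assert sorted(df.relation) == ["left", "right", "within"]
        within = df[df.relation == "within"].iloc[0]
        assert within.gene_name == "R" and within.distance == 0
        assert set(df.region_category) == {"ExonIntronUTR"}

    def test_placeholder_row_on_gene_free_chromosome(self):
        genome = make_genome(chrom_len=10_000, genes=[])
        df = build_feature_table([make_te()], genome)
        assert len(df) == 1
        assert df.relation.iloc[0] == "none"
        assert df.region_category.iloc[0] == "Intergenic"


class TestCouples:
    def _table(self, org, rows):
        base = dict(
            organism=org, chrom="c", te_start=1, te_end=2, te_strand="+",
            superfamily="H", similarity=90.0, gene_start=1, gene_end=2,
            gene_strand="+", distance=0, region_category="Intergenic",
            go_terms="", ortholog_X=1,
        )
        return pd.DataFrame([{**base, "te_family": f, "gene_name": g, "relation": r} for f, g, r in rows])

    def test_x_counts_distinct_organisms(self):
        tables = {
            "O1": self._table("O1", [("AtREP1", "geneZ", "left"), ("AtREP1", "geneZ", "left")]),
            "O2": self._table("O2", [("AtREP1", "GENEZ", "left")]),  # case-insensitive
        }
        (c,) = count_couples(tables)
        assert c.x == 2 and c.gene_name == "genez"

    def test_duplicates_within_one_organism_count_once(self):
        tables = {"O1": self._table("O1", [("f", "g", "right"), ("f", "g", "right")])}
        (c,) = count_couples(tables)
        assert c.x == 1

    def test_ortholog_map_overrides_name_matching(self):
        tables = {
            "O1": self._table("O1", [("f", "geneA", "left")]),
            "O2": self._table("O2", [("f", "geneB", "left")]),
        }
        assert all(c.x == 1 for c in count_couples(tables))
        (c,) = count_couples(tables, ortholog_map={"genea": "OG1", "geneb": "OG1"})
        assert c.x == 2 and c.gene_name == "OG1"

    def test_min_organisms_threshold_filters(self):
        tables = {
            "O1": self._table("O1", [("f", "g", "left")]),
            "O2": self._table("O2", [("f", "g", "left")]),
        }
        couples = count_couples(tables)
        assert filter_couples(couples, ProximityConfig(min_organisms=3)) == []
        assert len(filter_couples(couples, ProximityConfig(min_organisms=2))) == 1
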