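"""Flanking-gene contexts, linkage relations, conservation matrices."""

import numpy as np
import pytest

from tdnakit.model import GeneAnnotation, OrthologyMap
from tdnakit.synteny import (
    ConservationMatrix,
    GeneIndex,
    SpeciesData,
    conservation_matrix,
    distance_regression,
    flanking_genes,
    link_loci,
    single_sided_linkage,
    two_sided_linkage,
    window_ortholog_support,
    window_synteny,
)
from tdnakit.simulate import simulate_species_pair

from conftest import make_locus


def gene_row(gene_id, start, end, strand="+", seq_id="chr1"):
    return GeneAnnotation(gene_id, seq_id, start, end, strand)


@pytest.fixture
def annotated_scaffold():
    # genes left of 50_000 and right of 51_000, all plus strand
    genes = [gene_row(f"L{i}", 50_000 - (i + 1) * 2000, 50_000 - (i + 1) * 2000 + 1000)
             for i in range(3)]
    genes += [gene_row(f"R{i}", 51_000 + i * 2000, 51_000 + i * 2000 + 1000)
              for i in range(6)]
    return genes


class TestFlankingGenes:
    def test_fewer_than_k_upstream(self, annotated_scaffold):
        tdna = make_locus(start=50_100, end=50_180)
        ctx = flanking_genes(tdna, annotated_scaffold, k=5)
        assert ctx.upstream == ["L0", "L1", "L2"]
        assert ctx.downstream == ["R0", "R1", "R2", "R3", "R4"]

    def test_strand_specific_filter(self, annotated_scaffold):
        tdna = make_locus(start=50_100, end=50_180, strand="-")
        ctx = flanking_genes(tdna, annotated_scaffold, k=5, strand_specific=True)
        assert ctx.empty
        ctx2 = flanking_genes(tdna, annotated_scaffold, k=5, strand_specific=False)
        assert not ctx2.empty

    def test_reading_orientation_flips_for_minus_strand(self, annotated_scaffold):
        genes = [GeneAnnotation(g.gene_id, g.seq_id, g.start, g.end, "-")
                 for g in annotated_scaffold]
        tdna = make_locus(start=50_100, end=50_180, strand="-")
        ctx = flanking_genes(tdna, genes, k=3, orientation="reading")
        assert ctx.upstream == ["R0", "R1", "R2"]
        assert ctx.downstream == ["L0", "L1", "L2"]
        ctx_g = flanking_genes(tdna, genes, k=3, orientation="genomic")
        assert ctx_g.upstream == ["L0", "L1", "L2"]

    def test_unannotated_scaffold_gives_empty_context(self):
        tdna = make_locus(seq_id="chrX", start=100, end=180)
        assert flanking_genes(tdna, []).empty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_nearest_k(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        position = 0
        for i in range(200):
            position += int(rng.integers(200, 3000))
            length = int(rng.integers(100, 900))
            genes.append(
                gene_row(f"g{i}", position, position + length,
                         strand="+" if rng.random() < 0.5 else "-")
            )
            position += length
        tdna = make_locus(start=position // 2, end=position // 2 + 80)
        ctx = flanking_genes(tdna, genes, k=5, strand_specific=True,
                             orientation="genomic")
        same = [g for g in genes if g.strand == "+"]
        up = sorted((g for g in same if g.end <= tdna.start), key=lambda g: -g.end)[:5]
        down = sorted((g for g in same if g.start >= tdna.end), key=lambda g: g.start)[:5]
        assert ctx.upstream == [g.gene_id for g in up]
        assert ctx.downstream == [g.gene_id for g in down]


class TestLinkageRelations:
    def _contexts(self):
        ctx_a = flanking_genes(
            make_locus(start=50_100, end=50_180),
            [gene_row("a_up", 48_000, 49_000), gene_row("a_down", 51_000, 52_000)],
            k=5,
        )
        ctx_b = flanking_genes(
            make_locus(seq_id="chr1", start=50_100, end=50_180),
            [gene_row("b_up", 48_000, 49_000), gene_row("b_down", 51_000, 52_000)],
            k=5,
        )
        return ctx_a, ctx_b

    def test_single_sided_any_pair_suffices(self):
        ctx_a, ctx_b = self._contexts()
        omap = OrthologyMap({("a_up", "b_down")})
        assert single_sided_linkage(ctx_a, ctx_b, omap)
        assert not two_sided_linkage(ctx_a, ctx_b, omap)

    def test_two_sided_needs_both_sides(self):
        ctx_a, ctx_b = self._contexts()
        upstream_only = OrthologyMap({("a_up", "b_up")})
        assert single_sided_linkage(ctx_a, ctx_b, upstream_only)
        assert not two_sided_linkage(ctx_a, ctx_b, upstream_only)
        both = OrthologyMap({("a_up", "b_up"), ("a_down", "b_down")})
        assert two_sided_linkage(ctx_a, ctx_b, both)

    def test_empty_orthology_links_nothing(self):
        ctx_a, ctx_b = self._contexts()
        assert not single_sided_linkage(ctx_a, ctx_b, OrthologyMap())

    @pytest.mark.parametrize("seed", range(10))
    def test_two_sided_implies_single_sided(self, seed):
        """Logical strictness over random contexts and orthologies."""
        rng = np.random.default_rng(seed)
        pool_a = [f"a{i}" for i in range(12)]
        pool_b = [f"b{i}" for i in range(12)]
        pairs = {
            (a, b)
            for a in pool_a for b in pool_b
            if rng.random() < 0.08
        }
        omap = OrthologyMap(pairs)
        from tdnakit.synteny import FlankContext
        ctx_a = FlankContext(
            tdna=make_locus(start=1000, end=1080),
            upstream=list(rng.choice(pool_a, 5, replace=False)),
            downstream=list(rng.choice(pool_a, 5, replace=False)),
        )
        ctx_b = FlankContext(
            tdna=make_locus(start=1000, end=1080),
            upstream=list(rng.choice(pool_b, 5, replace=False)),
            downstream=list(rng.choice(pool_b, 5, replace=False)),
        )
        if two_sided_linkage(ctx_a, ctx_b, omap):
            assert single_sided_linkage(ctx_a, ctx_b, omap)


class TestWindowSynteny:
    def _setup(self, orth_pairs):
        genes_a = [gene_row("wa1", 10_000, 11_000), gene_row("wa2", 20_000, 21_000)]
        genes_b = [gene_row("wb1", 10_000, 11_000, seq_id="chrB"),
                   gene_row("wb2", 20_000, 21_000, seq_id="chrB")]
        tdna_a = make_locus(start=15_000, end=15_080)
        tdna_b = make_locus(seq_id="chrB", start=15_000, end=15_080)
        return (
            tdna_a, tdna_b, GeneIndex(genes_a), GeneIndex(genes_b),
            OrthologyMap(orth_pairs),
        )

    def test_two_disjoint_pairs_syntenic_one_not(self):
        args = self._setup({("wa1", "wb1"), ("wa2", "wb2")})
        assert window_synteny(*args, window=40_000, min_orthologs=2)
        args = self._setup({("wa1", "wb1")})
        assert not window_synteny(*args, window=40_000, min_orthologs=2)

    def test_promiscuous_gene_counts_once(self):
        # one A gene orthologous to both B genes: matching size is 1
        args = self._setup({("wa1", "wb1"), ("wa1", "wb2")})
        assert window_ortholog_support(*args, window=40_000) == 1
        assert not window_synteny(*args, window=40_000, min_orthologs=2)

    def test_zero_window_excludes_off_locus_genes(self):
        args = self._setup({("wa1", "wb1"), ("wa2", "wb2")})
        assert not window_synteny(*args, window=0, min_orthologs=2)


class TestConservationMatrix:
    def test_fraction_arithmetic_from_counts(self):
        matrix = ConservationMatrix.from_counts({("human", "chimp"): (493, 394)})
        assert matrix.fraction("human", "chimp") == 0.80
        assert matrix.cells[("human", "chimp")].fraction == pytest.approx(394 / 493)

    def test_zero_conserved(self):
        matrix = ConservationMatrix.from_counts({("a", "b"): (100, 0)})
        assert matrix.fraction("a", "b") == 0.0

    def test_missing_orthology_leaves_cell_absent(self):
        pair = simulate_species_pair(n_loci=10, retention=1.0, seed=1)
        A = SpeciesData.build("A", pair.loci_a, pair.genes_a)
        B = SpeciesData.build("B", pair.loci_b, pair.genes_b)
        C = SpeciesData.build("C", [], [])
        matrix = conservation_matrix([A, B, C], {("A", "B"): pair.orthology})
        assert ("A", "C") not in matrix.cells
        assert ("A", "B") in matrix.cells

    def test_total_is_species_a_locus_count(self):
        pair = simulate_species_pair(n_loci=25, retention=0.5, seed=2)
        A = SpeciesData.build("A", pair.loci_a, pair.genes_a)
        B = SpeciesData.build("B", pair.loci_b, pair.genes_b)
        matrix = conservation_matrix([A, B], {("A", "B"): pair.orthology})
        assert matrix.cells[("A", "B")].total == 25

    @pytest.mark.parametrize("retention", [0.2, 0.5, 0.8])
    def test_realized_retention_recovered_exactly(self, retention):
        """The linkage detector recovers exactly the loci the generator
        retained: no false positives from relocated loci, no false
        negatives among retained ones.  (The statistical recovery band
        against the planted rate is exercised in the acceptance suite.)"""
        pair = simulate_species_pair(n_loci=300, retention=retention, seed=7)
        A = SpeciesData.build("A", pair.loci_a, pair.genes_a)
        B = SpeciesData.build("B", pair.loci_b, pair.genes_b)
        matrix = conservation_matrix([A, B], {("A", "B"): pair.orthology},
                                     mode="two_sided")
        cell = matrix.cells[("A", "B")]
        assert cell.fraction == pytest.approx(pair.truth.realized_retention)
        links = link_loci(A, B, pair.orthology, mode="two_sided")
        conserved_ids = {pair.loci_a[i].locus_id for i in links}
        assert conserved_ids == pair.truth.retained_ids

    def test_window_mode_agrees_on_clean_pair(self):
        pair = simulate_species_pair(n_loci=40, retention=0.5, seed=9)
        A = SpeciesData.build("A", pair.loci_a, pair.genes_a)
        B = SpeciesData.build("B", pair.loci_b, pair.genes_b)
        m2 = conservation_matrix([A, B], {("A", "B"): pair.orthology}, mode="two_sided")
        mw = conservation_matrix([A, B], {("A", "B"): pair.orthology}, mode="window")
        assert m2.cells[("A", "B")].conserved == mw.cells[("A", "B")].conserved


class TestDistanceRegression:
    def _matrix(self, fractions):
        return ConservationMatrix.from_counts(
            {pair: (100, int(round(100 * f))) for pair, f in fractions.items()}
        )

    def test_perfectly_linear(self):
        fractions = {("a", "b"): 0.9, ("a", "c"): 0.7, ("a", "d"): 0.5}
        distances = {("a", "b"): 0.1, ("a", "c"): 0.3, ("a", "d"): 0.5}
        fit = distance_regression(self._matrix(fractions), distances)
        assert fit.pearson == pytest.approx(-1.0)
        assert fit.slope == pytest.approx(-1.0)

    def test_exclusion_removes_species_points(self):
        fractions = {("a", "b"): 0.9, ("a", "c"): 0.7, ("a", "d"): 0.5,
                     ("a", "m"): 0.99}
        distances = {("a", "b"): 0.1, ("a", "c"): 0.3, ("a", "d"): 0.5,
                     ("a", "m"): 0.6}
        fit = distance_regression(self._matrix(fractions), distances, exclude=("m",))
        assert fit.n_points == 3
        assert fit.slope == pytest.approx(-1.0)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(4)
        fractions, distances = {}, {}
        for i in range(20):
            d = rng.uniform(0.05, 1.0)
            f = np.clip(0.8 - 0.4 * d + rng.normal(0, 0.02), 0, 1)
            fractions[("a", f"s{i}")] = round(float(f), 2)
            distances[("a", f"s{i}")] = d
        fit = distance_regression(self._matrix(fractions), distances)
        assert abs(fit.slope - (-0.4)) <= 2 * fit.slope_stderr + 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            distance_regression(
                self._matrix({("a", "b"): 0.5}), {("a", "b"): 0.1}
            )

    def test_average_reciprocal_merges_ordered_pairs(self):
        fractions = {("a", "b"): 0.8, ("b", "a"): 0.6,
                     ("a", "c"): 0.5, ("c", "a"): 0.5,
                     ("b", "c"): 0.4, ("c", "b"): 0.4}
        base = {("a", "b"): 0.1, ("a", "c"): 0.3, ("b", "c"): 0.2}
        distances = {}
        for (x, y), d in base.items():
            distances[(x, y)] = d
            distances[(y, x)] = d
        fit = distance_regression(self._matrix(fractions), distances,
                                  average_reciprocal=True)
        assert fit.n_points == 3
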