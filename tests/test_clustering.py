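"""Cluster calculus: ordering, distances, maximal runs, pair classes.

The cluster detector is checked against an independent brute-force oracle
that builds connected components over qualifying adjacent gaps.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnakit.clustering import (
    classify_pair,
    consecutive_distances,
    cumulative_distance_distribution,
    find_clusters,
    sort_loci,
)
from tdnakit.model import TDNALocus

from conftest import make_locus


def brute_force_partition(loci, cutoff):
    """Independent oracle: connected components over adjacent qualifying gaps."""
    groups = {}
    for locus in loci:
        groups.setdefault(locus.seq_id, []).append(locus)
    clusters, isolated = [], []
    for _seq, group in sorted(groups.items()):
        ordered = sorted(group, key=lambda l: (l.start, l.end, l.locus_id or ""))
        # adjacency matrix over consecutive positions
        n = len(ordered)
        adjacent = [
            ordered[i + 1].start - ordered[i].end < cutoff for i in range(n - 1)
        ]
        component = [ordered[0]]
        for i in range(1, n):
            if adjacent[i - 1]:
                component.append(ordered[i])
            else:
                (clusters if len(component) > 1 else isolated).append(component)
                component = [ordered[i]]
        (clusters if len(component) > 1 else isolated).append(component)
    return (
        sorted(tuple(l.locus_id for l in c) for c in clusters),
        sorted(c[0].locus_id for c in isolated),
    )


def random_loci(rng, n, n_scaffolds=3, span=200_000):
    loci = []
    for i in range(n):
        start = int(rng.integers(0, span))
        loci.append(
            make_locus(
                seq_id=f"s{rng.integers(n_scaffolds)}",
                start=start,
                length=int(rng.integers(60, 90)),
                strand="+" if rng.random() < 0.5 else "-",
                locus_id=f"r{i}",
            )
        )
    return loci


class TestSortAndDistances:
    def test_sorted_by_start_within_scaffold(self):
        loci = [make_locus(start=50), make_locus(start=10)]
        ordered = sort_loci(loci)["chr1"]
        assert [l.start for l in ordered] == [10, 50]

    def test_scaffolds_are_independent_groups(self):
        loci = [make_locus(seq_id="a", start=10), make_locus(seq_id="b", start=5)]
        groups = sort_loci(loci)
        assert set(groups) == {"a", "b"}

    def test_tie_on_start_broken_by_end(self):
        short = make_locus(start=0, end=80, locus_id="short")
        long = make_locus(start=0, end=100, locus_id="long")
        ordered = sort_loci([long, short])["chr1"]
        assert [l.locus_id for l in ordered] == ["short", "long"]

    def test_distance_is_gap_between_end_and_next_start(self):
        loci = [make_locus(start=100, end=170), make_locus(start=500, end=570)]
        assert consecutive_distances(loci) == [330]

    def test_single_locus_has_no_distances(self):
        assert consecutive_distances([make_locus()]) == []

    def test_overlap_gives_negative_distance_and_warning(self):
        loci = [make_locus(start=100, end=170), make_locus(start=150, end=220)]
        with pytest.warns(UserWarning, match="overlapping"):
            assert consecutive_distances(loci) == [-20]

    def test_mixed_scaffolds_rejected(self):
        loci = [make_locus(seq_id="a"), make_locus(seq_id="b")]
        with pytest.raises(ValueError):
            consecutive_distances(loci)


class TestFindClusters:
    def test_small_gap_clusters_large_gap_isolates(self):
        # gaps [500, 2000]: first two cluster, third is isolated
        loci = [
            make_locus(start=0, end=72, locus_id="p1"),
            make_locus(start=572, end=644, locus_id="p2"),
            make_locus(start=2644, end=2716, locus_id="p3"),
        ]
        partition = find_clusters(loci)
        assert [c.size for c in partition.clusters] == [2]
        assert [l.locus_id for l in partition.isolated] == ["p3"]

    @pytest.mark.parametrize(
        "gap,expect_clustered", [(999, True), (1000, False), (1001, False)]
    )
    def test_cutoff_is_strict(self, gap, expect_clustered):
        loci = [make_locus(start=0, end=72), make_locus(start=72 + gap)]
        partition = find_clusters(loci, cutoff=1000)
        assert (len(partition.clusters) == 1) is expect_clustered

    def test_replacing_one_gap_at_cutoff_splits_exactly_one_cluster(self):
        # five loci in one run; pushing the middle gap to the cutoff splits it
        starts = [0, 572, 1144, 1716, 2288]
        loci = [make_locus(start=s, end=s + 72, locus_id=f"x{i}") for i, s in enumerate(starts)]
        assert len(find_clusters(loci).clusters) == 1
        # move loci 3,4 right so that gap(x2, x3) becomes exactly 1000
        shifted = [
            make_locus(start=s if i < 3 else s + 500, length=72, locus_id=f"x{i}")
            for i, s in enumerate(starts)
        ]
        partition = find_clusters(shifted)
        assert sorted(c.size for c in partition.clusters) == [2, 3]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        loci = random_loci(rng, n=int(rng.integers(2, 300)))
        partition = find_clusters(loci, cutoff=1000)
        got_clusters = sorted(
            tuple(l.locus_id for l in c.loci) for c in partition.clusters
        )
        got_isolated = sorted(l.locus_id for l in partition.isolated)
        exp_clusters, exp_isolated = brute_force_partition(loci, 1000)
        assert got_clusters == exp_clusters
        assert got_isolated == exp_isolated

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_conserves_loci_and_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        loci = random_loci(rng, n=150)
        partition = find_clusters(loci)
        assert partition.n_loci == len(loci)
        assert partition.n_pairs == sum(c.size - 1 for c in partition.clusters)
        ids = sorted(
            [l.locus_id for c in partition.clusters for l in c.loci]
            + [l.locus_id for l in partition.isolated]
        )
        assert ids == sorted(l.locus_id for l in loci)


class TestClassifyPair:
    def test_same_type_same_strand_is_homogeneous_parallel(self):
        pair = classify_pair(
            make_locus(start=0, iso_type="Ala"), make_locus(start=500, iso_type="Ala")
        )
        assert pair.homogeneous and pair.orientation == "parallel"

    def test_different_amino_acids_heterogeneous(self):
        pair = classify_pair(
            make_locus(start=0, iso_type="Lys"), make_locus(start=500, iso_type="Asn")
        )
        assert not pair.homogeneous

    @pytest.mark.parametrize(
        "left_strand,right_strand,expected,label",
        [
            ("+", "+", "parallel", "parallel"),
            ("-", "-", "parallel", "parallel"),
            ("+", "-", "plus_minus", "head-to-head"),
            ("-", "+", "minus_plus", "tail-to-tail"),
        ],
    )
    def test_orientation_classes_follow_strand_signs(
        self, left_strand, right_strand, expected, label
    ):
        pair = classify_pair(
            make_locus(start=0, strand=left_strand),
            make_locus(start=500, strand=right_strand),
        )
        assert pair.orientation == expected
        assert pair.orientation_label == label

    def test_pseudo_classes(self):
        gene = make_locus(start=0)
        pseudo = make_locus(start=500, is_pseudogene=True)
        assert classify_pair(gene, pseudo).pseudo_class == "gene-pseudo"
        assert classify_pair(pseudo, make_locus(start=1000, is_pseudogene=True)).pseudo_class == "pseudo-pseudo"

    def test_out_of_order_pair_rejected(self):
        with pytest.raises(ValueError, match="genomic order"):
            classify_pair(make_locus(start=500), make_locus(start=0))


class TestCumulativeDistribution:
    def test_steps_accumulate_pair_counts(self):
        # deltas 10, 10, 2000
        starts_ends = [(0, 72), (82, 154), (164, 236), (2236, 2308)]
        loci = [make_locus(start=a, end=b) for a, b in starts_ends]
        assert cumulative_distance_distribution(loci) == [(10, 2), (2000, 3)]

    def test_single_locus_yields_empty(self):
        assert cumulative_distance_distribution([make_locus()]) == []

    @settings(max_examples=50, deadline=None)
    @given(st.permutations(list(range(8))), st.data())
    def test_monotone_and_order_invariant(self, order, data):
        starts = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=50_000),
                min_size=8, max_size=8, unique=True,
            )
        )
        loci = [make_locus(start=s, locus_id=f"h{i}") for i, s in enumerate(sorted(starts))]
        shuffled = [loci[i] for i in order]
        steps = cumulative_distance_distribution(shuffled)
        assert steps == cumulative_distance_distribution(loci)
        counts = [c for _, c in steps]
        assert counts == sorted(counts)
        assert counts[-1] == len(loci) - 1
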