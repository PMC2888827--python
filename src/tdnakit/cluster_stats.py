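"""Per-genome summary statistics over the cluster partition.

Covers the counts a comparative survey reports for each genome: numbers of
intact tRNA genes and pseudogenes, cluster counts and the fraction of loci in
clusters, the cluster-size histogram, pair counts stratified by homogeneity,
orientation and pseudogene involvement, isoacceptor co-occurrence matrices,
and an exact test for whether including pseudogenes changes the proportion of
homogeneous pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as _stats

from .clustering import (
    DEFAULT_CLUSTER_CUTOFF,
    GENE_GENE,
    Cluster,
    ClusterPartition,
    Pair,
    find_clusters,
)
from .model import TDNALocus

SAME_DIRECTION = "same"
OPPOSITE_DIRECTION = "opposite"
FUNCTIONAL = "functional"
PSEUDOGENE_INVOLVED = "pseudogene"


@dataclass
class GenomeSummary:
    """Counts and fractions describing one genome's tDNA organisation."""

    n_genes: int
    n_pseudo: int
    n_clusters: int
    n_clustered_loci: int
    n_pairs: int
    fraction_clustered: float
    pair_counts: dict[tuple[str, str, str], int]
    cluster_size_histogram: dict[int, int]
    cutoff: int = DEFAULT_CLUSTER_CUTOFF

    @property
    def n_tdna(self) -> int:
        return self.n_genes + self.n_pseudo


def summarize_genome(
    loci: list[TDNALocus], cutoff: int = DEFAULT_CLUSTER_CUTOFF
) -> GenomeSummary:
    """Compute the full per-genome summary; an empty input yields zeros."""
    partition = find_clusters(loci, cutoff=cutoff) if loci else ClusterPartition([], [], cutoff)
    pairs = partition.all_pairs()
    pair_counts: dict[tuple[str, str, str], int] = {}
    for pair in pairs:
        key = (
            "homogeneous" if pair.homogeneous else "heterogeneous",
            pair.orientation,
            pair.pseudo_class,
        )
        pair_counts[key] = pair_counts.get(key, 0) + 1
    n_pseudo = sum(1 for locus in loci if locus.is_pseudogene)
    return GenomeSummary(
        n_genes=len(loci) - n_pseudo,
        n_pseudo=n_pseudo,
        n_clusters=len(partition.clusters),
        n_clustered_loci=partition.n_clustered_loci,
        n_pairs=partition.n_pairs,
        fraction_clustered=partition.fraction_clustered,
        pair_counts=pair_counts,
        cluster_size_histogram=cluster_size_histogram(partition.clusters),
        cutoff=cutoff,
    )


def cluster_size_histogram(clusters: list[Cluster]) -> dict[int, int]:
    """Histogram of cluster sizes (keys >= 2; values sum to #clusters)."""
    return dict(sorted(Counter(c.size for c in clusters).items()))


@dataclass
class CoOccurrenceMatrix:
    """Symmetric isoacceptor co-occurrence counts for clustered pairs.

    Cells are indexed by the unordered type pair, the reading direction
    (``same`` for parallel pairs, ``opposite`` otherwise), and the member
    status (``functional`` when both members are intact genes, ``pseudogene``
    when at least one member is a pseudogene — mixed gene/pseudogene pairs
    are counted in the pseudogene-involved stratum).
    """

    counts: dict[tuple[str, str, str, str], int] = field(default_factory=dict)

    @staticmethod
    def _key(t1: str, t2: str, direction: str, status: str):
        a, b = sorted((t1, t2))
        return (a, b, direction, status)

    def add(self, pair: Pair) -> None:
        direction = SAME_DIRECTION if pair.same_direction else OPPOSITE_DIRECTION
        status = FUNCTIONAL if pair.pseudo_class == GENE_GENE else PSEUDOGENE_INVOLVED
        key = self._key(pair.left.iso_type, pair.right.iso_type, direction, status)
        self.counts[key] = self.counts.get(key, 0) + 1

    def count(
        self,
        t1: str,
        t2: str,
        direction: str | None = None,
        status: str | None = None,
    ) -> int:
        """Count for an unordered type pair, optionally filtered by stratum."""
        a, b = sorted((t1, t2))
        return sum(
            n
            for (ka, kb, kdir, kstat), n in self.counts.items()
            if (ka, kb) == (a, b)
            and (direction is None or kdir == direction)
            and (status is None or kstat == status)
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_long(self) -> pd.DataFrame:
        """Long-format table with per-genome relative abundances.

        Fractions are normalised by the total pair count of the genome.
        """
        total = self.total
        rows = [
            {
                "type1": a,
                "type2": b,
                "direction": direction,
                "status": status,
                "count": n,
                "fraction": n / total if total else 0.0,
            }
            for (a, b, direction, status), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["type1", "type2", "direction", "status", "count", "fraction"]
        )


def cooccurrence_matrix(pairs: list[Pair]) -> CoOccurrenceMatrix:
    """Build the isoacceptor co-occurrence matrix from classified pairs.

    Homogeneous pairs land on the diagonal, heterogeneous pairs off it; the
    totals over all cells conserve the number of pairs.
    """
    matrix = CoOccurrenceMatrix()
    for pair in pairs:
        matrix.add(pair)
    return matrix


@dataclass
class FisherResult:
    """Result of the 2x2 exact test on homogeneous-pair proportions."""

    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool


def homogeneity_fisher_test(
    pairs_all_tdna: list[Pair], pairs_genes_only: list[Pair]
) -> FisherResult:
    """Fisher's exact test: does pseudogene filtering change the proportion
    of homogeneous versus heterogeneous pairs?

    Rows of the 2x2 table are {homogeneous, heterogeneous}; columns are
    {all tDNAs, intact genes only}.  The p-value is the two-sided exact
    (hypergeometric-sum) probability.  A table with a zero margin carries no
    information and is reported as p = 1 with the degenerate flag set.
    """
    hom_all = sum(1 for p in pairs_all_tdna if p.homogeneous)
    het_all = len(pairs_all_tdna) - hom_all
    hom_gen = sum(1 for p in pairs_genes_only if p.homogeneous)
    het_gen = len(pairs_genes_only) - hom_gen
    table = ((hom_all, hom_gen), (het_all, het_gen))
    margins = (
        hom_all + hom_gen,
        het_all + het_gen,
        hom_all + het_all,
        hom_gen + het_gen,
    )
    if 0 in margins:
        return FisherResult(odds_ratio=float("nan"), p_value=1.0, table=table, degenerate=True)
    odds_ratio, p_value = _stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(odds_ratio=odds_ratio, p_value=p_value, table=table, degenerate=False)
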