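"""Ordering, inter-locus distances, cluster detection, pair classification.

Loci on one scaffold are ordered by their start coordinate.  The distance
between consecutive loci is the gap ``delta = start[i+1] - end[i]`` (negative
for overlapping loci).  A *cluster* is a maximal run of consecutive loci whose
internal gaps are all strictly below the cutoff (default 1000 nt); runs of
size one are *isolated* loci.  Each consecutive pair inside a cluster is
classified by isoacceptor homogeneity (amino-acid level), relative
orientation, and pseudogene involvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import TDNALocus

DEFAULT_CLUSTER_CUTOFF = 1000

PARALLEL = "parallel"
# Anti-parallel classes are keyed by the strand signs; the conventional
# labels below are attached for reporting only, since arrow glyphs in the
# literature are used inconsistently.
PLUS_MINUS = "plus_minus"
MINUS_PLUS = "minus_plus"

ORIENTATION_LABELS = {
    PARALLEL: "parallel",
    PLUS_MINUS: "head-to-head",
    MINUS_PLUS: "tail-to-tail",
}

GENE_GENE = "gene-gene"
GENE_PSEUDO = "gene-pseudo"
PSEUDO_PSEUDO = "pseudo-pseudo"


def _sort_key(locus: TDNALocus):
    return (locus.start, locus.end, locus.locus_id or "")


def sort_loci(loci: list[TDNALocus]) -> dict[str, list[TDNALocus]]:
    """Order loci by start coordinate within each scaffold.

    Ties on the start are broken by (end, locus_id) so the order is stable
    and reproducible.
    """
    by_seq: dict[str, list[TDNALocus]] = {}
    for locus in loci:
        by_seq.setdefault(locus.seq_id, []).append(locus)
    return {seq_id: sorted(group, key=_sort_key) for seq_id, group in sorted(by_seq.items())}


def consecutive_distances(ordered: list[TDNALocus]) -> list[int]:
    """Gaps between consecutive ordered loci on a single scaffold.

    Negative values indicate overlapping loci and are flagged with a warning
    but retained (overlaps are never merged).
    """
    if len({locus.seq_id for locus in ordered}) > 1:
        raise ValueError("consecutive_distances requires loci from one scaffold")
    deltas = [
        ordered[i + 1].start - ordered[i].end for i in range(len(ordered) - 1)
    ]
    n_overlap = sum(1 for d in deltas if d < 0)
    if n_overlap:
        warnings.warn(f"{n_overlap} overlapping consecutive locus pair(s)")
    return deltas


@dataclass
class Pair:
    """A consecutive pair of loci within a cluster."""

    left: TDNALocus
    right: TDNALocus
    delta: int
    homogeneous: bool
    orientation: str  # parallel | plus_minus | minus_plus
    pseudo_class: str  # gene-gene | gene-pseudo | pseudo-pseudo

    @property
    def orientation_label(self) -> str:
        return ORIENTATION_LABELS[self.orientation]

    @property
    def same_direction(self) -> bool:
        return self.orientation == PARALLEL


def classify_pair(left: TDNALocus, right: TDNALocus) -> Pair:
    """Classify a consecutive locus pair.

    Homogeneity is at the isoacceptor (amino-acid) level, never the
    anticodon.  Orientation follows the strand signs: equal strands are
    parallel; (+,-) is the head-to-head class and (-,+) tail-to-tail.
    """
    if left.seq_id != right.seq_id:
        raise ValueError("pair members must lie on the same scaffold")
    if _sort_key(right) < _sort_key(left):
        raise ValueError("pair members must be given in genomic order")
    if left.strand == right.strand:
        orientation = PARALLEL
    elif left.strand == "+":
        orientation = PLUS_MINUS
    else:
        orientation = MINUS_PLUS
    n_pseudo = int(left.is_pseudogene) + int(right.is_pseudogene)
    pseudo_class = (GENE_GENE, GENE_PSEUDO, PSEUDO_PSEUDO)[n_pseudo]
    return Pair(
        left=left,
        right=right,
        delta=right.start - left.end,
        homogeneous=left.iso_type == right.iso_type,
        orientation=orientation,
        pseudo_class=pseudo_class,
    )


@dataclass
class Cluster:
    """A maximal run of near-adjacent loci (size >= 2) on one scaffold."""

    loci: list[TDNALocus]
    cutoff: int = DEFAULT_CLUSTER_CUTOFF

    @property
    def seq_id(self) -> str:
        return self.loci[0].seq_id

    @property
    def size(self) -> int:
        return len(self.loci)

    @property
    def homogeneous(self) -> bool:
        return len({locus.iso_type for locus in self.loci}) == 1

    def pairs(self) -> list[Pair]:
        return [
            classify_pair(self.loci[i], self.loci[i + 1])
            for i in range(len(self.loci) - 1)
        ]


@dataclass
class ClusterPartition:
    """Partition of a genome's loci into clusters and isolated loci."""

    clusters: list[Cluster]
    isolated: list[TDNALocus]
    cutoff: int = DEFAULT_CLUSTER_CUTOFF

    @property
    def n_loci(self) -> int:
        return sum(c.size for c in self.clusters) + len(self.isolated)

    @property
    def n_clustered_loci(self) -> int:
        return sum(c.size for c in self.clusters)

    @property
    def n_pairs(self) -> int:
        return sum(c.size - 1 for c in self.clusters)

    @property
    def fraction_clustered(self) -> float:
        return self.n_clustered_loci / self.n_loci if self.n_loci else 0.0

    def all_pairs(self) -> list[Pair]:
        return [pair for cluster in self.clusters for pair in cluster.pairs()]


def find_clusters(
    loci: list[TDNALocus], cutoff: int = DEFAULT_CLUSTER_CUTOFF
) -> ClusterPartition:
    """Partition loci into maximal clusters (gap < cutoff) and isolated loci.

    The cutoff is strict: a gap of exactly ``cutoff`` separates clusters.
    Clusters never span scaffolds.  Overlapping loci (negative gaps) always
    satisfy the cutoff and are kept unmerged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    clusters: list[Cluster] = []
    isolated: list[TDNALocus] = []
    for _seq_id, ordered in sort_loci(loci).items():
        run = [ordered[0]]
        for nxt in ordered[1:]:
            if nxt.start - run[-1].end < cutoff:
                run.append(nxt)
            else:
                _flush_run(run, cutoff, clusters, isolated)
                run = [nxt]
        _flush_run(run, cutoff, clusters, isolated)
    return ClusterPartition(clusters=clusters, isolated=isolated, cutoff=cutoff)


def _flush_run(
    run: list[TDNALocus],
    cutoff: int,
    clusters: list[Cluster],
    isolated: list[TDNALocus],
) -> None:
    if len(run) >= 2:
        clusters.append(Cluster(loci=list(run), cutoff=cutoff))
    else:
        isolated.append(run[0])


def cumulative_distance_distribution(
    loci: list[TDNALocus],
) -> list[tuple[int, int]]:
    """Cumulative count of consecutive locus pairs by gap size.

    Returns the step function ``[(delta, pairs with gap <= delta), ...]``
    over the sorted unique gaps of all consecutive pairs on all scaffolds;
    the final count equals the total number of consecutive pairs.  Fewer than
    two loci on every scaffold yields an empty list.
    """
    deltas: list[int] = []
    for ordered in sort_loci(loci).values():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            deltas.extend(consecutive_distances(ordered))
    if not deltas:
        return []
    deltas.sort()
    steps: list[tuple[int, int]] = []
    for i, d in enumerate(deltas, start=1):
        if steps and steps[-1][0] == d:
            steps[-1] = (d, i)
        else:
            steps.append((d, i))
    return steps
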