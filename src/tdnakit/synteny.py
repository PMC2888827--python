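"""Cross-species tDNA synteny via flanking-gene orthology linkage.

Because tRNA genes of one isoacceptor family are near-identical within and
between genomes, orthology of the tRNAs themselves cannot anchor a
cross-species comparison.  Instead, a tDNA locus is characterised by its
protein-coding neighbourhood: the nearest (up to) k flanking genes upstream
and downstream on the same scaffold (and, by default, the same strand).  Two
loci in different species are then linked through orthology relations among
those flanking genes:

* *single-sided linkage* — at least one ortholog pair anywhere among the two
  loci's flanking genes;
* *two-sided linkage* — at least one ortholog pair among the upstream genes
  of both loci AND one among the downstream genes, so each tDNA sits between
  matched genes;
* *window mode* — at least ``min_orthologs`` distinct ortholog pairs whose
  members lie within a fixed window (default 40 kb) around each locus, with
  distinctness enforced by maximum bipartite matching so one promiscuous
  gene family cannot satisfy the threshold alone.

The identity (type/anticodon) of the tDNAs is deliberately ignored: the
question is whether *a* tDNA is retained at the syntenic position, not
whether the same isoacceptor is.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _stats

from .model import GeneAnnotation, OrthologyMap, TDNALocus

DEFAULT_FLANK_K = 5
DEFAULT_WINDOW_NT = 40_000
DEFAULT_MIN_ORTHOLOGS = 2

SINGLE_SIDED = "single_sided"
TWO_SIDED = "two_sided"
WINDOW = "window"


class GeneIndex:
    """Per-scaffold positional index over gene annotations."""

    def __init__(self, genes: list[GeneAnnotation]):
        self._by_seq: dict[str, list[GeneAnnotation]] = {}
        for gene in genes:
            self._by_seq.setdefault(gene.seq_id, []).append(gene)
        # one list sorted by end (upstream queries), one by start (downstream)
        self._by_end: dict[str, tuple[list[int], list[GeneAnnotation]]] = {}
        self._by_start: dict[str, tuple[list[int], list[GeneAnnotation]]] = {}
        for seq_id, group in self._by_seq.items():
            ge = sorted(group, key=lambda g: (g.end, g.start, g.gene_id))
            gs = sorted(group, key=lambda g: (g.start, g.end, g.gene_id))
            self._by_end[seq_id] = ([g.end for g in ge], ge)
            self._by_start[seq_id] = ([g.start for g in gs], gs)

    def has_seq(self, seq_id: str) -> bool:
        return seq_id in self._by_seq

    def left_of(
        self, seq_id: str, position: int, k: int, strand: str | None
    ) -> list[GeneAnnotation]:
        """Nearest <= k genes ending at or before ``position``, nearest first."""
        if seq_id not in self._by_end:
            return []
        ends, genes = self._by_end[seq_id]
        i = bisect_right(ends, position)
        out = []
        for gene in reversed(genes[:i]):
            if strand is None or gene.strand == strand:
                out.append(gene)
                if len(out) == k:
                    break
        return out

    def right_of(
        self, seq_id: str, position: int, k: int, strand: str | None
    ) -> list[GeneAnnotation]:
        """Nearest <= k genes starting at or after ``position``, nearest first."""
        if seq_id not in self._by_start:
            return []
        starts, genes = self._by_start[seq_id]
        i = bisect_left(starts, position)
        out = []
        for gene in genes[i:]:
            if strand is None or gene.strand == strand:
                out.append(gene)
                if len(out) == k:
                    break
        return out

    def in_window(self, seq_id: str, lo: int, hi: int) -> list[GeneAnnotation]:
        """Genes overlapping the half-open window [lo, hi)."""
        if seq_id not in self._by_start:
            return []
        _starts, genes = self._by_start[seq_id]
        return [g for g in genes if g.start < hi and g.end > lo]


@dataclass
class FlankContext:
    """The protein-coding neighbourhood of one tDNA locus.

    ``upstream``/``downstream`` hold up to k gene ids ordered by proximity to
    the locus, oriented by the locus's own reading direction when built with
    ``orientation='reading'``.
    """

    tdna: TDNALocus
    upstream: list[str]
    downstream: list[str]
    k: int = DEFAULT_FLANK_K

    @property
    def all_genes(self) -> set[str]:
        return set(self.upstream) | set(self.downstream)

    @property
    def empty(self) -> bool:
        return not (self.upstream or self.downstream)


def flanking_genes(
    tdna: TDNALocus,
    genes: GeneIndex | list[GeneAnnotation],
    k: int = DEFAULT_FLANK_K,
    strand_specific: bool = True,
    orientation: str = "reading",
) -> FlankContext:
    """Map a tDNA to its nearest <= k flanking genes on each side.

    Flanks are chromosome-specific and, when ``strand_specific``, restricted
    to genes on the tDNA's strand.  With ``orientation='reading'`` (default)
    upstream/downstream follow the tDNA's reading direction, so the genomic
    left side is upstream for a plus-strand locus and downstream for a
    minus-strand one; ``orientation='genomic'`` keeps genomic left/right.
    A locus on an unannotated scaffold yields an empty context.
    """
    if orientation not in ("reading", "genomic"):
        raise ValueError("orientation must be 'reading' or 'genomic'")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    strand = tdna.strand if strand_specific else None
    left = [g.gene_id for g in index.left_of(tdna.seq_id, tdna.start, k, strand)]
    right = [g.gene_id for g in index.right_of(tdna.seq_id, tdna.end, k, strand)]
    if orientation == "reading" and tdna.strand == "-":
        upstream, downstream = right, left
    else:
        upstream, downstream = left, right
    return FlankContext(tdna=tdna, upstream=upstream, downstream=downstream, k=k)


# ---------------------------------------------------------------------------
# Linkage relations
# ---------------------------------------------------------------------------

def single_sided_linkage(
    ctx_a: FlankContext, ctx_b: FlankContext, orthology: OrthologyMap
) -> bool:
    """At least one ortholog pair anywhere among the two flank sets.

    Relative orientation and position of the matched genes are ignored.
    """
    return orthology.any_link(ctx_a.all_genes, ctx_b.all_genes)


def two_sided_linkage(
    ctx_a: FlankContext, ctx_b: FlankContext, orthology: OrthologyMap
) -> bool:
    """Ortholog pairs on both sides, each tDNA between its matched genes.

    Requires one ortholog pair within the upstream gene lists of both loci
    and one within the downstream lists, sidedness being evaluated in each
    species' own coordinate/strand frame.  Implies single-sided linkage.
    """
    return orthology.any_link(ctx_a.upstream, ctx_b.upstream) and orthology.any_link(
        ctx_a.downstream, ctx_b.downstream
    )


def window_ortholog_support(
    tdna_a: TDNALocus,
    tdna_b: TDNALocus,
    index_a: GeneIndex,
    index_b: GeneIndex,
    orthology: OrthologyMap,
    window: int = DEFAULT_WINDOW_NT,
) -> int:
    """Number of *distinct* ortholog pairs supporting a window-mode link.

    Genes overlapping the +/- window around each locus are collected and the
    orthology relation restricted to them; the support is the size of a
    maximum bipartite matching, so each gene participates in at most one
    counted pair.
    """
    genes_a = {
        g.gene_id
        for g in index_a.in_window(
            tdna_a.seq_id, max(0, tdna_a.start - window), tdna_a.end + window
        )
    }
    genes_b = {
        g.gene_id
        for g in index_b.in_window(
            tdna_b.seq_id, max(0, tdna_b.start - window), tdna_b.end + window
        )
    }
    pairs = orthology.restricted_pairs(genes_a, genes_b)
    if not pairs:
        return 0
    graph = nx.Graph()
    left = {("a", a) for a, _ in pairs}
    graph.add_nodes_from(left, bipartite=0)
    graph.add_nodes_from(("b", b) for _, b in pairs)
    graph.add_edges_from((("a", a), ("b", b)) for a, b in pairs)
    matching = nx.bipartite.maximum_matching(graph, top_nodes=left)
    return len(matching) // 2


def window_synteny(
    tdna_a: TDNALocus,
    tdna_b: TDNALocus,
    index_a: GeneIndex,
    index_b: GeneIndex,
    orthology: OrthologyMap,
    window: int = DEFAULT_WINDOW_NT,
    min_orthologs: int = DEFAULT_MIN_ORTHOLOGS,
) -> bool:
    """Fixed-window synteny call for one locus pair."""
    return (
        window_ortholog_support(tdna_a, tdna_b, index_a, index_b, orthology, window)
        >= min_orthologs
    )


# ---------------------------------------------------------------------------
# Species-level linkage and conservation matrices
# ---------------------------------------------------------------------------

@dataclass
class SpeciesData:
    """One species' inputs to the synteny analysis."""

    name: str
    loci: list[TDNALocus]
    gene_index: GeneIndex
    contexts: list[FlankContext] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        name: str,
        loci: list[TDNALocus],
        genes: list[GeneAnnotation],
        k: int = DEFAULT_FLANK_K,
        strand_specific: bool = True,
        orientation: str = "reading",
    ) -> "SpeciesData":
        index = GeneIndex(genes)
        contexts = [
            flanking_genes(t, index, k=k, strand_specific=strand_specific,
                           orientation=orientation)
            for t in loci
        ]
        return cls(name=name, loci=loci, gene_index=index, contexts=contexts)


def link_loci(
    species_a: SpeciesData,
    species_b: SpeciesData,
    orthology: OrthologyMap,
    mode: str = TWO_SIDED,
    window: int = DEFAULT_WINDOW_NT,
    min_orthologs: int = DEFAULT_MIN_ORTHOLOGS,
) -> dict[int, set[int]]:
    """All cross-species locus links: index in A -> set of indices in B.

    For the flank-linkage modes an inverted index from B gene ids to B locus
    positions keeps the search linear in practice; window mode prefilters
    candidate B loci through the orthologs of A's window genes before running
    the matching.
    """
    if mode in (SINGLE_SIDED, TWO_SIDED):
        return _link_by_flanks(species_a, species_b, orthology, mode)
    if mode == WINDOW:
        return _link_by_windows(
            species_a, species_b, orthology, window, min_orthologs
        )
    raise ValueError(f"unknown synteny mode {mode!r}")


def _invert_contexts(contexts: list[FlankContext]):
    up: dict[str, set[int]] = {}
    down: dict[str, set[int]] = {}
    for i, ctx in enumerate(contexts):
        for g in ctx.upstream:
            up.setdefault(g, set()).add(i)
        for g in ctx.downstream:
            down.setdefault(g, set()).add(i)
    return up, down


def _link_by_flanks(
    species_a: SpeciesData,
    species_b: SpeciesData,
    orthology: OrthologyMap,
    mode: str,
) -> dict[int, set[int]]:
    b_up, b_down = _invert_contexts(species_b.contexts)
    links: dict[int, set[int]] = {}
    for i, ctx_a in enumerate(species_a.contexts):
        up_hits: set[int] = set()
        down_hits: set[int] = set()
        for gene_a in ctx_a.upstream:
            for gene_b in orthology.orthologs_of_a(gene_a):
                up_hits |= b_up.get(gene_b, set())
                if mode == SINGLE_SIDED:
                    up_hits |= b_down.get(gene_b, set())
        for gene_a in ctx_a.downstream:
            for gene_b in orthology.orthologs_of_a(gene_a):
                down_hits |= b_down.get(gene_b, set())
                if mode == SINGLE_SIDED:
                    down_hits |= b_up.get(gene_b, set())
        partners = up_hits | down_hits if mode == SINGLE_SIDED else up_hits & down_hits
        if partners:
            links[i] = partners
    return links


def _link_by_windows(
    species_a: SpeciesData,
    species_b: SpeciesData,
    orthology: OrthologyMap,
    window: int,
    min_orthologs: int,
) -> dict[int, set[int]]:
    # B gene id -> B loci whose window contains it
    b_window_genes: dict[str, set[int]] = {}
    for j, tdna_b in enumerate(species_b.loci):
        for g in species_b.gene_index.in_window(
            tdna_b.seq_id, max(0, tdna_b.start - window), tdna_b.end + window
        ):
            b_window_genes.setdefault(g.gene_id, set()).add(j)
    links: dict[int, set[int]] = {}
    for i, tdna_a in enumerate(species_a.loci):
        candidates: set[int] = set()
        for g in species_a.gene_index.in_window(
            tdna_a.seq_id, max(0, tdna_a.start - window), tdna_a.end + window
        ):
            for gene_b in orthology.orthologs_of_a(g.gene_id):
                candidates |= b_window_genes.get(gene_b, set())
        partners = {
            j
            for j in candidates
            if window_synteny(
                tdna_a,
                species_b.loci[j],
                species_a.gene_index,
                species_b.gene_index,
                orthology,
                window,
                min_orthologs,
            )
        }
        if partners:
            links[i] = partners
    return links


@dataclass
class ConservationCell:
    total: int
    conserved: int

    @property
    def fraction(self) -> float:
        return self.conserved / self.total if self.total else 0.0


@dataclass
class ConservationMatrix:
    """Per ordered species pair: loci analysed, conserved count, fraction.

    A locus of species A counts as conserved in B when at least one B locus
    is linked to it; multiple partners count once.  Cells for pairs without
    orthology data are absent (NA).  The matrix need not be symmetric.
    """

    cells: dict[tuple[str, str], ConservationCell] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, counts: dict[tuple[str, str], tuple[int, int]]
    ) -> "ConservationMatrix":
        """Build directly from (total, conserved) count pairs."""
        return cls(
            {pair: ConservationCell(total=t, conserved=c) for pair, (t, c) in counts.items()}
        )

    def fraction(self, a: str, b: str, digits: int | None = 2) -> float:
        f = self.cells[(a, b)].fraction
        return round(f, digits) if digits is not None else f

    def to_frame(self, digits: int | None = 2) -> pd.DataFrame:
        rows = [
            {
                "species_a": a,
                "species_b": b,
                "total": cell.total,
                "conserved": cell.conserved,
                "fraction": round(cell.fraction, digits) if digits is not None else cell.fraction,
            }
            for (a, b), cell in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["species_a", "species_b", "total", "conserved", "fraction"]
        )


def conservation_matrix(
    species: list[SpeciesData],
    orthologies: dict[tuple[str, str], OrthologyMap],
    mode: str = TWO_SIDED,
    window: int = DEFAULT_WINDOW_NT,
    min_orthologs: int = DEFAULT_MIN_ORTHOLOGS,
) -> ConservationMatrix:
    """Conservation counts for every ordered species pair with orthology.

    ``orthologies`` maps ordered pairs (A, B) to orthology with A's genes in
    the first column; a map given for (B, A) only is reversed automatically.
    The total for (A, B) is the number of A loci (independent of B), so the
    fraction denominator is comparable across partners.
    """
    by_name = {sp.name: sp for sp in species}
    matrix = ConservationMatrix()
    for sp_a in species:
        for sp_b in species:
            if sp_a.name == sp_b.name:
                continue
            omap = _oriented_orthology(orthologies, sp_a.name, sp_b.name)
            if omap is None:
                continue
            links = link_loci(
                by_name[sp_a.name], by_name[sp_b.name], omap, mode, window, min_orthologs
            )
            matrix.cells[(sp_a.name, sp_b.name)] = ConservationCell(
                total=len(sp_a.loci), conserved=len(links)
            )
    return matrix


def _oriented_orthology(
    orthologies: dict[tuple[str, str], OrthologyMap], a: str, b: str
) -> OrthologyMap | None:
    if (a, b) in orthologies:
        return orthologies[(a, b)]
    if (b, a) in orthologies:
        rev = orthologies[(b, a)]
        return OrthologyMap(
            {(y, x) for x, y in rev.pairs}, species_a=a, species_b=b
        )
    return None


# ---------------------------------------------------------------------------
# Conservation vs evolutionary distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceRegression:
    pearson: float
    slope: float
    slope_stderr: float
    intercept: float
    n_points: int


def distance_regression(
    matrix: ConservationMatrix,
    distances: dict[tuple[str, str], float],
    exclude: tuple[str, ...] = (),
    average_reciprocal: bool = False,
) -> DistanceRegression:
    """OLS of conservation fraction on evolutionary distance.

    Species named in ``exclude`` contribute no points.  With
    ``average_reciprocal`` the two ordered comparisons of each species pair
    are averaged into a single point.  Fewer than three points is an error.
    """
    points: dict[tuple[str, str], tuple[float, float]] = {}
    for (a, b), cell in matrix.cells.items():
        if a in exclude or b in exclude:
            continue
        if (a, b) not in distances:
            continue
        points[(a, b)] = (distances[(a, b)], cell.fraction)
    if average_reciprocal:
        merged: dict[tuple[str, str], tuple[float, float]] = {}
        for (a, b), (d, f) in points.items():
            key = tuple(sorted((a, b)))
            if key in merged:
                d0, f0 = merged[key]
                merged[key] = (d0, (f0 + f) / 2.0)
            else:
                merged[key] = (d, f)
        points = merged
    if len(points) < 3:
        raise ValueError("need at least 3 species-pair points for a regression")
    xs = np.array([d for d, _ in points.values()])
    ys = np.array([f for _, f in points.values()])
    fit = _stats.linregress(xs, ys)
    return DistanceRegression(
        pearson=fit.rvalue,
        slope=fit.slope,
        slope_stderr=fit.stderr,
        intercept=fit.intercept,
        n_points=len(points),
    )
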