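"""Synthetic genomes and species pairs with known planted structure.

Every downstream statistic in this package is testable against ground truth
produced here, with no genome downloads:

* :func:`simulate_genome` plants tDNA clusters with a geometric size
  distribution (matching the rapid decay of cluster sizes seen in real
  genomes) and a configurable clustered-locus fraction, pseudogene fraction
  and isoacceptor frequency vector, on a multi-scaffold assembly.  Within
  planted clusters consecutive gaps are strictly below the cutoff; between
  planted entities they are at least the cutoff, so the planted partition is
  exactly the one the cluster detector must recover.
* :func:`simulate_species_pair` derives a second species from a first by
  retaining each tDNA in its gene neighbourhood with a known probability and
  relocating the rest into fresh, orthology-free neighbourhoods, giving a
  planted syntenic-retention rate for the linkage machinery to recover.

No nucleotide sequence is generated: loci and genes are intervals only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import DEFAULT_CLUSTER_CUTOFF
from .model import (
    AMINO_ACIDS,
    GeneAnnotation,
    GenomeAssembly,
    OrthologyMap,
    TDNALocus,
)


def default_iso_frequencies() -> dict[str, float]:
    """Uniform weight over the 20 amino-acid families plus rare SeC/Sup."""
    freqs = {aa: 1.0 for aa in AMINO_ACIDS}
    freqs["SeC"] = 0.02
    freqs["Sup"] = 0.02
    return freqs


@dataclass
class GenomeTruth:
    """Planted parameters and memberships of a synthetic genome."""

    n_loci: int
    n_clustered: int
    n_clusters: int
    cluster_sizes: dict[int, int]
    cluster_members: list[list[str]]
    n_pseudo: int
    pseudogene_fraction: float
    cutoff: int
    seed: int | None
    params: dict = field(default_factory=dict)

    @property
    def fraction_clustered(self) -> float:
        return self.n_clustered / self.n_loci if self.n_loci else 0.0


def _draw_cluster_sizes(
    n_target: int, size_p: float, rng: np.random.Generator
) -> list[int]:
    """Cluster sizes (>= 2) summing exactly to ``n_target`` clustered loci.

    Sizes are 1 + Geometric(size_p) (support >= 2); the last cluster is
    trimmed to hit the target, and a single leftover locus is absorbed by
    the previous cluster rather than forming an illegal size-1 cluster.
    """
    if n_target == 0:
        return []
    if n_target < 2:
        raise ValueError("cannot plant clusters with fewer than 2 clustered loci")
    sizes: list[int] = []
    remaining = n_target
    while remaining > 0:
        size = 1 + int(rng.geometric(size_p))
        if size >= remaining:
            if remaining >= 2:
                sizes.append(remaining)
            else:
                sizes[-1] += remaining
            remaining = 0
        else:
            sizes.append(size)
            remaining -= size
    return sizes


def simulate_genome(
    n_loci: int = 200,
    cluster_fraction: float = 0.4,
    n_scaffolds: int = 5,
    scaffold_length: int = 2_000_000,
    cluster_size_p: float = 0.45,
    cutoff: int = DEFAULT_CLUSTER_CUTOFF,
    locus_length_range: tuple[int, int] = (70, 90),
    pseudogene_fraction: float = 0.1,
    iso_frequencies: dict[str, float] | None = None,
    plus_strand_prob: float = 0.5,
    seed: int | None = None,
) -> tuple[GenomeAssembly, list[TDNALocus], GenomeTruth]:
    """Generate one genome with planted tDNA clusters.

    ``cluster_fraction`` of the loci (rounded) are placed in clusters drawn
    from a geometric size law with parameter ``cluster_size_p``; the rest are
    isolated.  Raises if the requested loci cannot fit on the assembly with
    the required spacing.
    """
    if not 0.0 <= cluster_fraction <= 1.0:
        raise ValueError("cluster_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iso_frequencies = iso_frequencies or default_iso_frequencies()
    iso_types = list(iso_frequencies)
    iso_probs = np.array([iso_frequencies[t] for t in iso_types], dtype=float)
    iso_probs /= iso_probs.sum()

    n_clustered = int(round(cluster_fraction * n_loci))
    if n_clustered == 1:
        n_clustered = 2
    sizes = _draw_cluster_sizes(n_clustered, cluster_size_p, rng)
    n_isolated = n_loci - sum(sizes)

    lo, hi = locus_length_range
    lengths = rng.integers(lo, hi + 1, size=n_loci)

    # entities = cluster blocks + isolated loci, dealt round-robin-free:
    # each entity is a list of per-locus lengths with planted internal gaps
    entity_sizes = sizes + [1] * n_isolated
    order = rng.permutation(len(entity_sizes))
    entity_sizes = [entity_sizes[i] for i in order]

    # assign loci (by running index) to entities in order
    entities: list[dict] = []
    cursor = 0
    for size in entity_sizes:
        member_lengths = lengths[cursor : cursor + size]
        internal_gaps = rng.integers(0, cutoff, size=size - 1) if size > 1 else np.array([], dtype=int)
        entities.append(
            {
                "lengths": member_lengths,
                "gaps": internal_gaps,
                "width": int(member_lengths.sum() + internal_gaps.sum()),
            }
        )
        cursor += size

    # distribute entities over scaffolds
    scaffold_of = rng.integers(0, n_scaffolds, size=len(entities))
    assembly = GenomeAssembly({f"scaf{i+1}": scaffold_length for i in range(n_scaffolds)})

    loci: list[TDNALocus] = []
    cluster_members: list[list[str]] = []
    locus_counter = 0
    for scaf_idx in range(n_scaffolds):
        mine = [entities[e] for e in range(len(entities)) if scaffold_of[e] == scaf_idx]
        if not mine:
            continue
        widths = sum(e["width"] for e in mine)
        required = widths + (len(mine) - 1) * cutoff
        slack = scaffold_length - required
        if slack < 0:
            raise ValueError(
                f"infeasible density: scaffold {scaf_idx+1} needs {required} nt "
                f"but has {scaffold_length}"
            )
        # spread the slack over the len(mine)+1 inter-entity spaces
        extra = rng.multinomial(slack, np.full(len(mine) + 1, 1.0 / (len(mine) + 1)))
        position = int(extra[0])
        for k, entity in enumerate(mine):
            members: list[str] = []
            for j, length in enumerate(entity["lengths"]):
                locus_id = f"sim{locus_counter}"
                locus_counter += 1
                iso = iso_types[rng.choice(len(iso_types), p=iso_probs)]
                loci.append(
                    TDNALocus(
                        seq_id=f"scaf{scaf_idx+1}",
                        start=position,
                        end=position + int(length),
                        strand="+" if rng.random() < plus_strand_prob else "-",
                        iso_type=iso,
                        is_pseudogene=bool(rng.random() < pseudogene_fraction),
                        locus_id=locus_id,
                    )
                )
                members.append(locus_id)
                position += int(length)
                if j < len(entity["gaps"]):
                    position += int(entity["gaps"][j])
            if len(members) > 1:
                cluster_members.append(members)
            position += cutoff + int(extra[k + 1])

    size_hist: dict[int, int] = {}
    for size in sizes:
        size_hist[size] = size_hist.get(size, 0) + 1
    truth = GenomeTruth(
        n_loci=n_loci,
        n_clustered=sum(sizes),
        n_clusters=len(sizes),
        cluster_sizes=dict(sorted(size_hist.items())),
        cluster_members=cluster_members,
        n_pseudo=sum(1 for l in loci if l.is_pseudogene),
        pseudogene_fraction=pseudogene_fraction,
        cutoff=cutoff,
        seed=seed,
        params={
            "n_loci": n_loci,
            "cluster_fraction": cluster_fraction,
            "cluster_size_p": cluster_size_p,
            "n_scaffolds": n_scaffolds,
            "scaffold_length": scaffold_length,
            "pseudogene_fraction": pseudogene_fraction,
            "plus_strand_prob": plus_strand_prob,
        },
    )
    return assembly, loci, truth


# ---------------------------------------------------------------------------
# Species pairs with planted syntenic retention
# ---------------------------------------------------------------------------

@dataclass
class PairTruth:
    """Planted parameters of a synthetic species pair."""

    retention: float
    retained_ids: set[str]
    n_loci: int
    seed: int | None
    params: dict = field(default_factory=dict)

    @property
    def realized_retention(self) -> float:
        return len(self.retained_ids) / self.n_loci if self.n_loci else 0.0


@dataclass
class SpeciesPair:
    """A synthetic two-species data set for the synteny machinery."""

    loci_a: list[TDNALocus]
    genes_a: list[GeneAnnotation]
    loci_b: list[TDNALocus]
    genes_b: list[GeneAnnotation]
    orthology: OrthologyMap
    truth: PairTruth


def simulate_species_pair(
    n_loci: int = 100,
    retention: float = 0.5,
    flank_genes: int = 5,
    gene_length: int = 1_000,
    gene_spacing: int = 2_000,
    neighborhood_gap: int = 100_000,
    locus_length: int = 80,
    ortholog_retention: float = 1.0,
    extra_ortholog_noise: float = 0.0,
    seed: int | None = None,
    species_a: str = "A",
    species_b: str = "B",
) -> SpeciesPair:
    """Generate two species with a planted tDNA syntenic-retention rate.

    Species A holds ``n_loci`` tDNAs, each centred in a neighbourhood of
    ``flank_genes`` protein-coding genes per side.  Species B retains each
    neighbourhood's genes (each with an ortholog with probability
    ``ortholog_retention``); the tDNA itself is kept in place with
    probability ``retention`` and otherwise relocated into a fresh
    neighbourhood of non-orthologous genes, so relocated loci provide no
    flank-orthology signal.  ``extra_ortholog_noise`` adds, per A gene, a
    spurious ortholog to a random B gene with that probability, creating
    many-to-many relations.
    """
    if not 0.0 <= retention <= 1.0:
        raise ValueError("retention must be in [0, 1]")
    rng = np.random.default_rng(seed)
    step = gene_length + gene_spacing
    block = 2 * flank_genes * step + locus_length + gene_spacing

    loci_a: list[TDNALocus] = []
    genes_a: list[GeneAnnotation] = []
    loci_b: list[TDNALocus] = []
    genes_b: list[GeneAnnotation] = []
    orthology = OrthologyMap(species_a=species_a, species_b=species_b)
    retained_ids: set[str] = set()
    relocated: list[str] = []

    pos_b = 0
    for i in range(n_loci):
        base_a = i * (block + neighborhood_gap)
        base_b = pos_b
        b_genes_here: list[str] = []
        offset = 0
        for j in range(2 * flank_genes):
            gid_a = f"{species_a}.n{i}.g{j}"
            genes_a.append(
                GeneAnnotation(gid_a, "chrA", base_a + offset, base_a + offset + gene_length, "+")
            )
            if rng.random() < ortholog_retention:
                gid_b = f"{species_b}.n{i}.g{j}"
                genes_b.append(
                    GeneAnnotation(gid_b, "chrB", base_b + offset, base_b + offset + gene_length, "+")
                )
                orthology.add(gid_a, gid_b)
                b_genes_here.append(gid_b)
            if j == flank_genes - 1:
                # slot for the tDNA between the two flanks
                locus_a_start = base_a + offset + gene_length + gene_spacing // 2
                locus_b_start = base_b + offset + gene_length + gene_spacing // 2
                offset += gene_length + gene_spacing + locus_length
            else:
                offset += step
        locus_id = f"tdna{i}"
        loci_a.append(
            TDNALocus("chrA", locus_a_start, locus_a_start + locus_length, "+",
                      iso_type="Ala", locus_id=f"{species_a}.{locus_id}")
        )
        if rng.random() < retention:
            retained_ids.add(f"{species_a}.{locus_id}")
            loci_b.append(
                TDNALocus("chrB", locus_b_start, locus_b_start + locus_length, "+",
                          iso_type="Ala", locus_id=f"{species_b}.{locus_id}")
            )
        else:
            relocated.append(locus_id)
        pos_b += block + neighborhood_gap

    # relocated tDNAs: fresh neighbourhoods of B-only genes, no orthology
    for locus_id in relocated:
        base_b = pos_b
        offset = 0
        for j in range(2 * flank_genes):
            gid_b = f"{species_b}.reloc.{locus_id}.g{j}"
            genes_b.append(
                GeneAnnotation(gid_b, "chrB", base_b + offset, base_b + offset + gene_length, "+")
            )
            if j == flank_genes - 1:
                locus_b_start = base_b + offset + gene_length + gene_spacing // 2
                offset += gene_length + gene_spacing + locus_length
            else:
                offset += step
        loci_b.append(
            TDNALocus("chrB", locus_b_start, locus_b_start + locus_length, "+",
                      iso_type="Ala", locus_id=f"{species_b}.{locus_id}")
        )
        pos_b += block + neighborhood_gap

    if extra_ortholog_noise > 0 and genes_b:
        for gene in genes_a:
            if rng.random() < extra_ortholog_noise:
                partner = genes_b[int(rng.integers(len(genes_b)))]
                orthology.add(gene.gene_id, partner.gene_id)

    truth = PairTruth(
        retention=retention,
        retained_ids=retained_ids,
        n_loci=n_loci,
        seed=seed,
        params={
            "n_loci": n_loci,
            "retention": retention,
            "flank_genes": flank_genes,
            "gene_length": gene_length,
            "gene_spacing": gene_spacing,
            "neighborhood_gap": neighborhood_gap,
            "ortholog_retention": ortholog_retention,
            "extra_ortholog_noise": extra_ortholog_noise,
        },
    )
    return SpeciesPair(
        loci_a=loci_a,
        genes_a=genes_a,
        loci_b=loci_b,
        genes_b=genes_b,
        orthology=orthology,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Scaling cohorts
# ---------------------------------------------------------------------------

def simulate_scaling_cohort(
    n_genomes: int = 30,
    alphas: dict[str, float] | None = None,
    size_range: tuple[float, float] = (1e7, 1e10),
    base_counts: dict[str, float] | None = None,
    log10_noise_sd: float = 0.2,
    seed: int | None = None,
):
    """Cohort of genomes whose counts follow planted power laws.

    Genome sizes are log-uniform on ``size_range``; each series' count is
    C * size**alpha perturbed by lognormal noise (sd in log10 units).
    Returns a dict ``{"size": array, series: array, ...}`` plus the planted
    alphas; counts are reals, not rounded, so the planted exponent is the
    exact truth of the regression model.
    """
    rng = np.random.default_rng(seed)
    alphas = alphas or {"genes": 0.658, "total": 0.930, "pseudo": 1.615}
    base_counts = base_counts or {"genes": 2e-3, "total": 3e-6, "pseudo": 1e-12}
    log_lo, log_hi = np.log10(size_range[0]), np.log10(size_range[1])
    sizes = 10 ** rng.uniform(log_lo, log_hi, size=n_genomes)
    data: dict[str, np.ndarray] = {"size": sizes}
    for series, alpha in alphas.items():
        noise = rng.normal(0.0, log10_noise_sd, size=n_genomes)
        data[series] = base_counts[series] * sizes**alpha * 10**noise
    return data, alphas
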