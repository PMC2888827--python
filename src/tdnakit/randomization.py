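"""Uniform-reinsertion null model for tDNA placement and empirical p-values.

The null hypothesis is that tDNA loci are placed independently and uniformly
on the assembly: the observed locus collection is removed and re-inserted at
positions drawn uniformly from the remaining sequence, keeping each locus's
length, type, flags and strand.  The test statistic is either the number of
clustered loci (members of clusters of size >= 2) or the number of
consecutive clustered pairs, counted under the same cutoff as the observed
data.  Empirical p-values count replicates at least as extreme as the
observation.

The statistic is a small non-negative integer, so the plain empirical
p-value ``#{y >= x}/N`` is discrete and *conservative* under the null (its
distribution is stochastically larger than uniform).  For calibration
studies :func:`randomized_empirical_pvalue` provides the standard randomized
(fuzzy) p-value, which is exactly Uniform(0, 1) under the null for any
discrete statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import DEFAULT_CLUSTER_CUTOFF, find_clusters
from .model import GenomeAssembly, TDNALocus

CLUSTERED_LOCI = "clustered_loci"
PAIRS = "pairs"

_MAX_REJECTION_TRIES = 10_000


# ---------------------------------------------------------------------------
# Locus relocation
# ---------------------------------------------------------------------------

def _scaffold_choice_cdf(
    scaffold_lengths: np.ndarray, locus_length: int
) -> np.ndarray:
    """CDF over scaffolds with probability proportional to the number of
    admissible start positions (L - l + 1) for a locus of the given length."""
    weights = np.maximum(scaffold_lengths - locus_length + 1, 0).astype(float)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"no scaffold can hold a locus of length {locus_length}"
        )
    return np.cumsum(weights) / total


class _NullSampler:
    """Vectorised sampler of uniform non-overlapping locus placements.

    Locus lengths are fixed across replicates, so the per-length scaffold
    choice distributions are precomputed once.  Placements where any two
    relocated loci overlap are rejected wholesale and redrawn; at the tDNA
    densities in scope the acceptance rate is close to one.
    """

    def __init__(self, assembly: GenomeAssembly, locus_lengths: np.ndarray):
        self.seq_ids = list(assembly.lengths)
        self.scaffold_lengths = np.array(
            [assembly.lengths[s] for s in self.seq_ids], dtype=np.int64
        )
        self.locus_lengths = np.asarray(locus_lengths, dtype=np.int64)
        if len(self.locus_lengths) and (
            self.locus_lengths.max() > self.scaffold_lengths.max()
        ):
            raise ValueError("a locus is longer than the longest scaffold")
        # group loci by length: one scaffold-choice CDF per distinct length
        self._groups = []
        for length in np.unique(self.locus_lengths):
            idx = np.nonzero(self.locus_lengths == length)[0]
            cdf = _scaffold_choice_cdf(self.scaffold_lengths, int(length))
            self._groups.append((int(length), idx, cdf))

    def draw(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """One non-overlapping placement: (scaffold index, start) per locus."""
        n = len(self.locus_lengths)
        for _ in range(_MAX_REJECTION_TRIES):
            scaf = np.empty(n, dtype=np.int64)
            start = np.empty(n, dtype=np.int64)
            for length, idx, cdf in self._groups:
                u = rng.random(len(idx))
                s = np.searchsorted(cdf, u, side="right")
                scaf[idx] = s
                max_start = self.scaffold_lengths[s] - length
                start[idx] = np.floor(rng.random(len(idx)) * (max_start + 1)).astype(
                    np.int64
                )
            if not self._has_overlap(scaf, start):
                return scaf, start
        raise RuntimeError(
            "rejection sampling failed: locus density too high for "
            "non-overlapping uniform placement"
        )

    def _has_overlap(self, scaf: np.ndarray, start: np.ndarray) -> bool:
        if len(start) < 2:
            return False
        order = np.lexsort((start, scaf))
        s, a = scaf[order], start[order]
        ends = a + self.locus_lengths[order]
        same = s[1:] == s[:-1]
        return bool(np.any(same & (a[1:] < ends[:-1])))

    def statistic(
        self,
        scaf: np.ndarray,
        start: np.ndarray,
        cutoff: int,
        kind: str,
    ) -> int:
        """Cluster statistic of a placement without building locus objects."""
        if len(start) < 2:
            return 0
        order = np.lexsort((start, scaf))
        s, a = scaf[order], start[order]
        ends = a + self.locus_lengths[order]
        qualifying = (s[1:] == s[:-1]) & ((a[1:] - ends[:-1]) < cutoff)
        if kind == PAIRS:
            return int(qualifying.sum())
        if kind == CLUSTERED_LOCI:
            in_cluster = np.zeros(len(start), dtype=bool)
            in_cluster[:-1] |= qualifying
            in_cluster[1:] |= qualifying
            return int(in_cluster.sum())
        raise ValueError(f"unknown statistic kind {kind!r}")


def randomize_loci(
    loci: list[TDNALocus],
    assembly: GenomeAssembly,
    rng: np.random.Generator | int | None = None,
) -> list[TDNALocus]:
    """Re-insert loci at uniform positions on the assembly.

    Every locus keeps its length, type, flags, identifier and strand; the
    scaffold is chosen with probability proportional to the sequence it can
    accommodate, and the start is uniform on the admissible range.  Relocated
    loci never overlap one another (rejection sampling).
    """
    rng = np.random.default_rng(rng)
    if not loci:
        return []
    sampler = _NullSampler(assembly, np.array([l.length for l in loci]))
    scaf, start = sampler.draw(rng)
    relocated = []
    for i, locus in enumerate(loci):
        relocated.append(
            TDNALocus(
                seq_id=sampler.seq_ids[scaf[i]],
                start=int(start[i]),
                end=int(start[i]) + locus.length,
                strand=locus.strand,
                iso_type=locus.iso_type,
                anticodon=locus.anticodon,
                is_pseudogene=locus.is_pseudogene,
                score=locus.score,
                locus_id=locus.locus_id,
            )
        )
    return relocated


# ---------------------------------------------------------------------------
# Statistics and p-values
# ---------------------------------------------------------------------------

def count_statistic(
    loci: list[TDNALocus],
    cutoff: int = DEFAULT_CLUSTER_CUTOFF,
    kind: str = PAIRS,
) -> int:
    """Observed cluster statistic of a locus collection."""
    partition = find_clusters(loci, cutoff=cutoff) if loci else None
    if partition is None:
        return 0
    if kind == PAIRS:
        return partition.n_pairs
    if kind == CLUSTERED_LOCI:
        return partition.n_clustered_loci
    raise ValueError(f"unknown statistic kind {kind!r}")


def empirical_pvalue(
    x: float,
    ys,
    direction: str = "enrichment",
    pseudocount: bool = False,
) -> float:
    """Empirical p-value of an observed statistic against null replicates.

    ``enrichment`` counts replicates with y >= x, ``depletion`` those with
    y <= x.  The default convention is the plain fraction #{extreme}/N,
    under which p-values of exactly 0 and 1 are attainable; with
    ``pseudocount=True`` the (+1)/(N+1) variant is used instead.
    """
    ys = np.asarray(ys)
    if ys.size == 0:
        raise ValueError("need at least one replicate")
    if direction == "enrichment":
        extreme = int(np.sum(ys >= x))
    elif direction == "depletion":
        extreme = int(np.sum(ys <= x))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if pseudocount:
        return (extreme + 1) / (ys.size + 1)
    return extreme / ys.size


def randomized_empirical_pvalue(
    x: float, ys, rng: np.random.Generator | int | None = None
) -> float:
    """Randomized (fuzzy) empirical p-value, exactly uniform under the null.

    With G = #{y > x} and E = #{y = x}, returns (G + U*(E + 1)) / (N + 1)
    for U ~ Uniform(0, 1).  When observed and replicate statistics are drawn
    from the same (arbitrary, possibly discrete) distribution this p-value
    is exactly Uniform(0, 1), which makes it the appropriate quantity for
    calibration studies of discrete test statistics.
    """
    rng = np.random.default_rng(rng)
    ys = np.asarray(ys)
    greater = int(np.sum(ys > x))
    equal = int(np.sum(ys == x))
    return (greater + rng.random() * (equal + 1)) / (ys.size + 1)


@dataclass
class RandomizationResult:
    """Outcome of a uniform-reinsertion randomization test."""

    observed: int
    replicates: np.ndarray
    n_replicates: int
    expected: float
    p_enrich: float
    p_deplete: float
    statistic_kind: str
    cutoff: int
    seed: int | None
    early_stopped: bool


def run_randomization_test(
    loci: list[TDNALocus],
    assembly: GenomeAssembly,
    cutoff: int = DEFAULT_CLUSTER_CUTOFF,
    n_max: int = 1000,
    n_min: int = 50,
    seed: int | None = None,
    early_stop_p: float | None = 0.2,
    statistic_kind: str = PAIRS,
    pseudocount: bool = False,
) -> RandomizationResult:
    """Run the uniform-reinsertion randomization test.

    Replicates are drawn up to ``n_max``; once at least ``n_min`` replicates
    have accumulated, the simulation stops early if the running enrichment
    p-value has reached ``early_stop_p`` (pass ``None`` to disable), since
    large p-values do not need tight resolution.  The result is reproducible
    given the seed.
    """
    if n_min < 1 or n_max < n_min:
        raise ValueError("need 1 <= n_min <= n_max")
    rng = np.random.default_rng(seed)
    observed = count_statistic(loci, cutoff=cutoff, kind=statistic_kind)
    sampler = _NullSampler(assembly, np.array([l.length for l in loci]))
    ys: list[int] = []
    n_extreme = 0
    early_stopped = False
    for i in range(1, n_max + 1):
        scaf, start = sampler.draw(rng)
        y = sampler.statistic(scaf, start, cutoff, statistic_kind)
        ys.append(y)
        if y >= observed:
            n_extreme += 1
        if (
            early_stop_p is not None
            and i >= n_min
            and n_extreme / i >= early_stop_p
        ):
            early_stopped = i < n_max
            break
    replicates = np.array(ys)
    return RandomizationResult(
        observed=observed,
        replicates=replicates,
        n_replicates=len(replicates),
        expected=float(replicates.mean()),
        p_enrich=empirical_pvalue(observed, replicates, "enrichment", pseudocount),
        p_deplete=empirical_pvalue(observed, replicates, "depletion", pseudocount),
        statistic_kind=statistic_kind,
        cutoff=cutoff,
        seed=seed,
        early_stopped=early_stopped,
    )


def null_statistics(
    assembly: GenomeAssembly,
    locus_lengths,
    cutoff: int = DEFAULT_CLUSTER_CUTOFF,
    n_reps: int = 1000,
    statistic_kind: str = PAIRS,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample the null distribution of the cluster statistic directly.

    This is the fast path used by calibration studies: loci are represented
    only by their lengths, and each replicate is a fresh uniform
    non-overlapping placement.
    """
    rng = np.random.default_rng(rng)
    sampler = _NullSampler(assembly, np.asarray(locus_lengths))
    out = np.empty(n_reps, dtype=np.int64)
    for i in range(n_reps):
        scaf, start = sampler.draw(rng)
        out[i] = sampler.statistic(scaf, start, cutoff, statistic_kind)
    return out


def expected_pairs_poisson(n: int, L: float, d: float) -> float:
    """Approximate expected number of clustered consecutive pairs when ``n``
    point loci are dropped uniformly on a sequence of length ``L``.

    Uses the spacing approximation (n-1) * (1 - (1 - d/L)**(n-1)), valid in
    the sparse regime n*d << L; outside that regime a warning is emitted.
    This serves as an analytic oracle for the Monte-Carlo machinery.
    """
    if n < 2 or L <= 0 or d < 0:
        raise ValueError("need n >= 2, L > 0, d >= 0")
    if n * d > 0.2 * L:
        warnings.warn(
            "outside the sparse regime (n*d comparable to L); the spacing "
            "approximation degrades"
        )
    return (n - 1) * (1.0 - (1.0 - d / L) ** (n - 1))
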