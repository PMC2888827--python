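"""Power-law scaling of tDNA counts with genome size.

Across eukaryotic genomes the number of tDNA loci grows roughly as a power
of genome size N, with different exponents for intact tRNA genes, tRNA
pseudogenes, and their union.  The exponent alpha is estimated by ordinary
least squares of log10(count) on log10(genome size); alongside the slope and
its standard error, the fit reports the Pearson correlation on the log-log
scale and Spearman's rho on the raw counts (the rank correlation is robust
to the choice of scale and is reported because correlation summaries in the
comparative literature rarely name their estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats


@dataclass
class ScalingFit:
    """A fitted power law count ~ C * size**alpha."""

    slope: float
    slope_stderr: float
    intercept: float
    pearson_log: float
    spearman: float
    n_genomes: int
    n_dropped: int = 0


def fit_scaling(genome_sizes, counts) -> ScalingFit:
    """Fit log10(count) = alpha * log10(size) + c by OLS.

    Genomes with zero counts cannot enter the log fit and are dropped
    pairwise with a warning (their number is reported in ``n_dropped``).
    Fewer than three usable genomes is an error.
    """
    sizes = np.asarray(genome_sizes, dtype=float)
    cnts = np.asarray(counts, dtype=float)
    if sizes.shape != cnts.shape:
        raise ValueError("genome_sizes and counts must have equal length")
    if np.any(sizes <= 0):
        raise ValueError("genome sizes must be positive")
    if np.any(cnts < 0):
        raise ValueError("counts must be non-negative")
    usable = cnts > 0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        warnings.warn(f"{n_dropped} zero-count genome(s) dropped from log fit")
    sizes, cnts = sizes[usable], cnts[usable]
    if sizes.size < 3:
        raise ValueError("need at least 3 genomes with non-zero counts")
    log_s, log_c = np.log10(sizes), np.log10(cnts)
    fit = _stats.linregress(log_s, log_c)
    spearman = _stats.spearmanr(sizes, cnts).statistic
    return ScalingFit(
        slope=fit.slope,
        slope_stderr=fit.stderr,
        intercept=fit.intercept,
        pearson_log=fit.rvalue,
        spearman=float(spearman),
        n_genomes=int(sizes.size),
        n_dropped=n_dropped,
    )


def fit_three_series(summary_table) -> dict[str, ScalingFit]:
    """Fit the three canonical series from a per-genome summary table.

    ``summary_table`` is a DataFrame-like with columns ``size``, ``n_genes``,
    ``n_pseudo``, ``n_tdna``.  Returns fits keyed ``genes``, ``pseudo``,
    ``total``; a series with fewer than three non-zero genomes is omitted.
    """
    fits: dict[str, ScalingFit] = {}
    for key, column in (("genes", "n_genes"), ("pseudo", "n_pseudo"), ("total", "n_tdna")):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[key] = fit_scaling(summary_table["size"], summary_table[column])
        except ValueError:
            continue
    return fits
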