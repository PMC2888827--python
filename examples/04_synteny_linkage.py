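"""Measure cross-species tDNA syntenic conservation by flanking-gene linkage.

A pair of species is generated in which each tDNA of species A is retained
at its syntenic position in species B with probability 0.6.  Conservation
is then measured three ways: single-sided linkage (one ortholog pair among
the flanks), two-sided linkage (ortholog pairs on both sides with the tDNA
between them), and the fixed-window mode (>= 2 distinct ortholog pairs
within +/- 40 kb).
"""

from tdnakit import SpeciesData, conservation_matrix, simulate_species_pair

pair = simulate_species_pair(n_loci=250, retention=0.6, seed=13)
A = SpeciesData.build("A", pair.loci_a, pair.genes_a)
B = SpeciesData.build("B", pair.loci_b, pair.genes_b)

print(f"planted retention: {pair.truth.retention} "
      f"(realized: {pair.truth.realized_retention:.3f})")
for mode in ("single_sided", "two_sided", "window"):
    matrix = conservation_matrix([A, B], {("A", "B"): pair.orthology}, mode=mode)
    cell = matrix.cells[("A", "B")]
    print(f"{mode:>13}: {cell.conserved}/{cell.total} conserved "
          f"-> fraction {cell.fraction:.2f}")

# On this clean generator all three modes agree with the realized retention;
# on real annotations single-sided linkage overcounts because one promiscuous
# gene family can link unrelated loci.
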