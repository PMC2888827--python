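"""Parse detector output, normalise coordinates, and write GFF3 reports.

Shows the I/O boundary conventions: tRNAscan-SE tabular output is 1-based
inclusive with begin > end on the minus strand; internally everything is
0-based half-open; the GFF3 writer converts back, and parse(write(x)) == x.
"""

import io

from tdnakit import parse_tdna_gff, parse_trnascan, write_tdna_gff

TRNASCAN = """\
Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tCove
Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore
--------\t------\t-----\t------\t----\t-----\t-----\t----\t------
chr1\t1\t100\t171\tAla\tAGC\t0\t0\t55.2
chr1\t2\t570\t499\tLys\tTTT\t0\t0\t61.0
chr1\t3\t5000\t5072\tPseudo\t???\t0\t0\t25.0
"""

loci = parse_trnascan(io.StringIO(TRNASCAN))
for locus in loci:
    flag = " (pseudogene)" if locus.is_pseudogene else ""
    print(f"{locus.locus_id}: {locus.seq_id}:{locus.start}-{locus.end} "
          f"[{locus.strand}] {locus.iso_type}{flag}")

buf = io.StringIO()
write_tdna_gff(loci, buf)
print("\nGFF3 output (1-based inclusive again):")
print(buf.getvalue())

buf.seek(0)
assert parse_tdna_gff(buf) == loci
print("round-trip: parse(write(loci)) == loci")
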