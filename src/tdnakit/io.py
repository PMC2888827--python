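"""Readers and writers for tDNA loci, gene annotations, and linkage tables.

Supported formats:

* tRNAscan-SE v1.x tabular output (reader) — 1-based inclusive coordinates,
  minus-strand records have begin > end;
* GFF3 (reader/writer for tDNA loci, reader for gene annotations) — 1-based
  inclusive;
* BED6 (reader for tDNA loci) — 0-based half-open;
* two-column orthology TSV, seq_id/length TSV, species-pair distance TSV.

Everything is normalised to the package's internal 0-based half-open
convention on input and converted back on output, so that
``parse(write(loci)) == loci``.
"""

from __future__ import annotations

import io as _io
import warnings
from typing import Iterable, TextIO

from .model import (
    GeneAnnotation,
    GenomeAssembly,
    OrthologyMap,
    TDNALocus,
    normalize_isoacceptor,
)


class ParseError(ValueError):
    """A record-level parsing failure, carrying the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        prefix = f"line {line_number}: " if line_number is not None else ""
        super().__init__(prefix + message)


def _as_text_stream(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source, "rt", encoding="utf-8")


def _maybe_close(stream, source) -> None:
    if not hasattr(source, "read"):
        stream.close()


# ---------------------------------------------------------------------------
# tRNAscan-SE tabular output
# ---------------------------------------------------------------------------

def parse_trnascan(source) -> list[TDNALocus]:
    """Parse tRNAscan-SE v1.x tabular output into normalised loci.

    Header/separator lines are tolerated.  Coordinates are 1-based inclusive;
    records with begin > end are minus-strand and are normalised by swapping.
    A ``Pseudo`` isoacceptor label, or a trailing ``pseudo`` note, sets the
    pseudogene flag.  Anticodon ``???`` is treated as absent.
    """
    stream = _as_text_stream(source)
    loci: list[TDNALocus] = []
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields]
            if _is_trnascan_header(fields):
                continue
            if len(fields) < 9:
                raise ParseError(
                    f"expected >=9 columns, got {len(fields)}", line_no
                )
            seq_id, trna_no, begin_s, end_s = fields[0], fields[1], fields[2], fields[3]
            try:
                begin, end = int(begin_s), int(end_s)
                score = float(fields[8])
            except ValueError as exc:
                raise ParseError(f"malformed numeric field ({exc})", line_no) from None
            type_label, anticodon = fields[4], fields[5]
            is_pseudo = type_label.lower() == "pseudo"
            if len(fields) > 9 and any("pseudo" in f.lower() for f in fields[9:]):
                is_pseudo = True
            iso_type = normalize_isoacceptor(type_label)
            if anticodon in ("???", "", "NNN", "."):
                anticodon = None
            if begin <= end:
                start, stop, strand = begin - 1, end, "+"
            else:
                start, stop, strand = end - 1, begin, "-"
            loci.append(
                TDNALocus(
                    seq_id=seq_id,
                    start=start,
                    end=stop,
                    strand=strand,
                    iso_type=iso_type,
                    anticodon=anticodon,
                    is_pseudogene=is_pseudo,
                    score=score,
                    locus_id=f"{seq_id}.trna{trna_no}",
                    source_line=line_no,
                )
            )
    finally:
        _maybe_close(stream, source)
    return loci


def _is_trnascan_header(fields: list[str]) -> bool:
    if fields[0].startswith("-----"):
        return True
    first = fields[0].lower()
    return first in ("sequence", "name") or first.startswith("sequence")


# ---------------------------------------------------------------------------
# GFF3 for tDNA loci
# ---------------------------------------------------------------------------

_GFF_COLUMNS = 9


def write_tdna_gff(loci: Iterable[TDNALocus], dest) -> None:
    """Write loci as GFF3 (1-based inclusive), attributes carrying the
    isoacceptor type, anticodon, and pseudogene flag."""
    stream = dest if hasattr(dest, "write") else open(dest, "wt", encoding="utf-8")
    try:
        stream.write("##gff-version 3\n")
        for locus in loci:
            attrs = []
            if locus.locus_id is not None:
                attrs.append(f"ID={locus.locus_id}")
            attrs.append(f"isoacceptor={locus.iso_type}")
            if locus.anticodon is not None:
                attrs.append(f"anticodon={locus.anticodon}")
            attrs.append(f"pseudogene={'true' if locus.is_pseudogene else 'false'}")
            score = "." if locus.score is None else repr(locus.score)
            stream.write(
                "\t".join(
                    (
                        locus.seq_id,
                        "tdnakit",
                        "tRNA",
                        str(locus.start + 1),
                        str(locus.end),
                        score,
                        locus.strand,
                        ".",
                        ";".join(attrs),
                    )
                )
                + "\n"
            )
    finally:
        if not hasattr(dest, "write"):
            stream.close()


def parse_tdna_gff(source) -> list[TDNALocus]:
    """Read tDNA loci from GFF3 written by :func:`write_tdna_gff` (or any
    GFF3 whose tRNA features carry the same attribute keys)."""
    stream = _as_text_stream(source)
    loci: list[TDNALocus] = []
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLUMNS:
                raise ParseError(
                    f"expected {_GFF_COLUMNS} GFF columns, got {len(fields)}",
                    line_no,
                )
            seq_id, _source, _ftype, start_s, end_s, score_s, strand, _phase, attr_s = fields
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError:
                raise ParseError("malformed coordinates", line_no) from None
            if strand not in ("+", "-"):
                warnings.warn(f"line {line_no}: missing strand; record rejected")
                continue
            attrs = _parse_gff_attributes(attr_s)
            loci.append(
                TDNALocus(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    strand=strand,
                    iso_type=normalize_isoacceptor(attrs.get("isoacceptor", "Undet")),
                    anticodon=attrs.get("anticodon"),
                    is_pseudogene=attrs.get("pseudogene", "false").lower()
                    in ("true", "1", "yes"),
                    score=None if score_s == "." else float(score_s),
                    locus_id=attrs.get("ID"),
                    source_line=line_no,
                )
            )
    finally:
        _maybe_close(stream, source)
    return loci


def _parse_gff_attributes(attr_s: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_s.split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        attrs[key] = value
    return attrs


# ---------------------------------------------------------------------------
# BED6 for tDNA loci
# ---------------------------------------------------------------------------

def parse_tdna_bed(source) -> list[TDNALocus]:
    """Read tDNA loci from BED6 (0-based half-open).

    The name field is parsed for the isoacceptor type and anticodon using the
    common ``tRNA-Ala-AGC`` convention; a name containing ``pseudo`` (any
    case) marks a pseudogene.
    """
    stream = _as_text_stream(source)
    loci: list[TDNALocus] = []
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"expected >=6 BED columns, got {len(fields)}", line_no)
            seq_id, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("malformed coordinates", line_no) from None
            if strand not in ("+", "-"):
                warnings.warn(f"line {line_no}: missing strand; record rejected")
                continue
            iso_type, anticodon, is_pseudo = _parse_bed_name(name)
            loci.append(
                TDNALocus(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    strand=strand,
                    iso_type=iso_type,
                    anticodon=anticodon,
                    is_pseudogene=is_pseudo,
                    score=None if score_s in (".", "") else float(score_s),
                    locus_id=name or None,
                    source_line=line_no,
                )
            )
    finally:
        _maybe_close(stream, source)
    return loci


def _parse_bed_name(name: str) -> tuple[str, str | None, bool]:
    is_pseudo = "pseudo" in name.lower()
    tokens = [t for t in name.split("-") if t and t.lower() not in ("trna", "tdna")]
    iso_type = "Undet"
    anticodon = None
    for token in tokens:
        if token.lower() == "pseudo":
            continue
        if iso_type == "Undet" and token.lower() != "pseudo":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                iso_type = normalize_isoacceptor(token)
            if iso_type != "Undet":
                continue
        if len(token) == 3 and token.isalpha() and token.upper() == token:
            anticodon = token
    return iso_type, anticodon, is_pseudo


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def parse_annotation(source, biotype_filter: str | None = "protein_coding") -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or a 5-column gene table.

    GFF3 ``gene`` features are used, with the biotype taken from the
    ``gene_biotype``/``biotype`` attribute (defaulting to ``protein_coding``
    when absent).  The alternative table format is TSV with columns
    ``gene_id  seq_id  start  end  strand  [biotype]`` in 0-based half-open
    coordinates.  Records not passing ``biotype_filter`` are dropped; records
    without a strand are rejected with a warning.
    """
    stream = _as_text_stream(source)
    genes: list[GeneAnnotation] = []
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == _GFF_COLUMNS and fields[3].isdigit():
                gene = _gene_from_gff(fields, line_no)
            else:
                gene = _gene_from_table(fields, line_no)
            if gene is None:
                continue
            if biotype_filter is not None and gene.biotype != biotype_filter:
                continue
            genes.append(gene)
    finally:
        _maybe_close(stream, source)
    seen: set[str] = set()
    for gene in genes:
        if gene.gene_id in seen:
            raise ParseError(f"duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
    return genes


def _gene_from_gff(fields: list[str], line_no: int) -> GeneAnnotation | None:
    seq_id, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
    if ftype not in ("gene", "protein_coding_gene", "pseudogene"):
        return None
    if strand not in ("+", "-"):
        warnings.warn(f"line {line_no}: gene without strand rejected")
        return None
    attrs = _parse_gff_attributes(attr_s)
    gene_id = attrs.get("ID") or attrs.get("gene_id")
    if gene_id is None:
        raise ParseError("gene feature without ID", line_no)
    biotype = attrs.get("gene_biotype") or attrs.get("biotype")
    if biotype is None:
        biotype = "pseudogene" if ftype == "pseudogene" else "protein_coding"
    return GeneAnnotation(
        gene_id=gene_id,
        seq_id=seq_id,
        start=int(start_s) - 1,
        end=int(end_s),
        strand=strand,
        biotype=biotype,
    )


def _gene_from_table(fields: list[str], line_no: int) -> GeneAnnotation | None:
    if len(fields) < 5:
        raise ParseError(f"expected >=5 gene-table columns, got {len(fields)}", line_no)
    gene_id, seq_id, start_s, end_s, strand = fields[:5]
    if strand not in ("+", "-"):
        warnings.warn(f"line {line_no}: gene without strand rejected")
        return None
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError("malformed coordinates", line_no) from None
    biotype = fields[5] if len(fields) > 5 else "protein_coding"
    return GeneAnnotation(gene_id, seq_id, start, end, strand, biotype)


# ---------------------------------------------------------------------------
# Orthology, scaffold-length, and distance tables
# ---------------------------------------------------------------------------

def parse_orthology(source, species_a: str = "A", species_b: str = "B") -> OrthologyMap:
    """Read a two-column (optionally weighted) orthology table.

    Duplicate pairs are de-duplicated; self-pairs are rejected.  Many-to-many
    relations are allowed and preserved.
    """
    stream = _as_text_stream(source)
    omap = OrthologyMap(species_a=species_a, species_b=species_b)
    n_lines = 0
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError("expected two gene-id columns", line_no)
            n_lines += 1
            omap.add(fields[0], fields[1])
    finally:
        _maybe_close(stream, source)
    if n_lines != len(omap):
        warnings.warn(
            f"orthology {species_a}-{species_b}: {n_lines} rows -> "
            f"{len(omap)} unique pairs"
        )
    return omap


def parse_scaffold_lengths(source) -> GenomeAssembly:
    """Read a two-column seq_id/length TSV into a :class:`GenomeAssembly`."""
    stream = _as_text_stream(source)
    lengths: dict[str, int] = {}
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError("expected seq_id and length columns", line_no)
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError("malformed length", line_no) from None
    finally:
        _maybe_close(stream, source)
    return GenomeAssembly(lengths)


def parse_distance_table(source) -> dict[tuple[str, str], float]:
    """Read species-pair evolutionary distances (three-column TSV).

    Distances are stored under both orderings of the pair.
    """
    stream = _as_text_stream(source)
    distances: dict[tuple[str, str], float] = {}
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError("expected species_a species_b distance", line_no)
            try:
                d = float(fields[2])
            except ValueError:
                raise ParseError("malformed distance", line_no) from None
            distances[(fields[0], fields[1])] = d
            distances[(fields[1], fields[0])] = d
    finally:
        _maybe_close(stream, source)
    return distances


def loci_to_string(loci: Iterable[TDNALocus]) -> str:
    """Serialise loci to a GFF3 string (convenience for tests and reports)."""
    buf = _io.StringIO()
    write_tdna_gff(loci, buf)
    return buf.getvalue()
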