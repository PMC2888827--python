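"""Core domain objects for the genomic organisation of tRNA genes.

A *tDNA* is any genomic locus encoding a tRNA gene or tRNA pseudogene.  Each
locus is modelled by its scaffold, a half-open coordinate interval, a strand,
an isoacceptor type (the amino acid the tRNA charges, or one of the special
classes ``SeC``/``Sup``/``Undet``), and a pseudogene flag.  All coordinates
inside the package are 0-based half-open; file readers and writers convert at
the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

AMINO_ACIDS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
#: selenocysteine, suppressor, and undetermined-class loci get their own types
SPECIAL_TYPES: tuple[str, ...] = ("SeC", "Sup", "Undet")
ISOACCEPTOR_TYPES: tuple[str, ...] = AMINO_ACIDS + SPECIAL_TYPES

# labels seen in detector output that map onto canonical types
_TYPE_ALIASES = {
    "SelCys": "SeC", "Sec": "SeC", "SeCe": "SeC", "SeC(e)": "SeC",
    "Supres": "Sup", "Sup?": "Sup",
    "iMet": "Met", "fMet": "Met", "Ile2": "Ile",
    "Undet": "Undet", "Unknown": "Undet",
}

#: plausible length range for a tDNA locus after normalisation (nt)
MIN_TDNA_LENGTH = 50
MAX_TDNA_LENGTH = 600


def normalize_isoacceptor(label: str) -> str:
    """Map a detector isoacceptor label to a canonical type.

    Unknown labels map to ``Undet`` with a warning; ``Pseudo`` (used by older
    detector versions for pseudogenes of undetermined class) also maps to
    ``Undet`` — the pseudogene flag itself is handled by the caller.
    """
    if label in ISOACCEPTOR_TYPES:
        return label
    if label in _TYPE_ALIASES:
        return _TYPE_ALIASES[label]
    if label.capitalize() in ISOACCEPTOR_TYPES:
        return label.capitalize()
    if label.lower() == "pseudo":
        return "Undet"
    warnings.warn(f"unknown isoacceptor label {label!r}; mapped to Undet")
    return "Undet"


@dataclass
class TDNALocus:
    """One tDNA locus: interval, strand, isoacceptor type, pseudogene flag.

    ``start``/``end`` are 0-based half-open genomic coordinates with
    ``start < end`` regardless of strand.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    iso_type: str = "Undet"
    anticodon: str | None = None
    is_pseudogene: bool = False
    score: float | None = None
    locus_id: str | None = None
    source_line: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.locus_id or ''}: start ({self.start}) must be "
                f"< end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.iso_type not in ISOACCEPTOR_TYPES:
            raise ValueError(f"unknown isoacceptor type {self.iso_type!r}")
        if not MIN_TDNA_LENGTH <= self.length <= MAX_TDNA_LENGTH:
            warnings.warn(
                f"locus {self.locus_id or self.seq_id}:{self.start}-{self.end} "
                f"has unusual length {self.length} nt"
            )
        if (
            self.iso_type == "Undet"
            and self.anticodon is not None
            and not self.is_pseudogene
        ):
            warnings.warn(
                "iso_type 'Undet' with a known anticodon on a non-pseudogene "
                f"locus ({self.locus_id or self.seq_id})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAssembly:
    """Scaffold/chromosome lengths of one genome assembly."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for seq_id, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"scaffold {seq_id!r} has non-positive length")

    @property
    def genome_size(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_loci(cls, loci: list[TDNALocus]) -> "GenomeAssembly":
        """Infer scaffold lengths as max(end) per seq_id.

        This underestimates the true sequence space available to the
        randomization null, so a warning is always emitted.
        """
        warnings.warn(
            "scaffold lengths inferred from locus coordinates; randomization "
            "will underestimate the available sequence space"
        )
        lengths: dict[str, int] = {}
        for locus in loci:
            lengths[locus.seq_id] = max(lengths.get(locus.seq_id, 0), locus.end)
        return cls(lengths)


@dataclass
class GeneAnnotation:
    """A protein-coding (or other) gene, 0-based half-open."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


class OrthologyMap:
    """Many-to-many orthology relations between the genes of two species."""

    def __init__(
        self,
        pairs: set[tuple[str, str]] | list[tuple[str, str]] = (),
        species_a: str = "A",
        species_b: str = "B",
    ):
        self.species_a = species_a
        self.species_b = species_b
        self.pairs: set[tuple[str, str]] = set()
        self._a_to_b: dict[str, set[str]] = {}
        self._b_to_a: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, gene_a: str, gene_b: str) -> None:
        if gene_a == gene_b:
            raise ValueError(f"self-pair rejected: {gene_a!r}")
        if (gene_a, gene_b) in self.pairs:
            return
        self.pairs.add((gene_a, gene_b))
        self._a_to_b.setdefault(gene_a, set()).add(gene_b)
        self._b_to_a.setdefault(gene_b, set()).add(gene_a)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def orthologs_of_a(self, gene_a: str) -> set[str]:
        return self._a_to_b.get(gene_a, set())

    def orthologs_of_b(self, gene_b: str) -> set[str]:
        return self._b_to_a.get(gene_b, set())

    def any_link(self, genes_a, genes_b) -> bool:
        """True iff some ortholog pair joins the two gene sets."""
        genes_b = set(genes_b)
        return any(self._a_to_b.get(a, set()) & genes_b for a in genes_a)

    def restricted_pairs(self, genes_a, genes_b) -> list[tuple[str, str]]:
        """All ortholog pairs with both members inside the given gene sets."""
        genes_b = set(genes_b)
        out = []
        for a in genes_a:
            for b in self._a_to_b.get(a, set()) & genes_b:
                out.append((a, b))
        return out
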