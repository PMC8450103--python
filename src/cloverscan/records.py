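"""Core record types shared across the toolkit.

Coordinate convention: every in-memory interval is 0-based half-open on the
plus strand of the containing sequence, with an explicit ``strand`` field
(``+``/``-``).  Conversion to the 1-based inclusive tabular convention
(begin > end on the minus strand), GFF3 or BED happens only in writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# IUPAC nucleotide ambiguity codes -> the set of bases each may stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(residues: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes handled)."""
    return residues.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A malformed external file (FASTA/Stockholm/table/config)."""


class StructureError(FormatError):
    """Unbalanced or crossing brackets in a consensus structure line."""


@dataclass
class NucSequence:
    """A named nucleotide sequence.

    Residues are uppercased and U is normalised to T on construction;
    IUPAC ambiguity codes other than N are retained (scored as N later).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be nonempty")
        res = self.residues.upper().replace("U", "T")
        bad = set(res) - set(IUPAC)
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: invalid residue(s) {sorted(bad)}"
            )
        self.residues = res

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.residues))

    def slice(self, begin: int, end: int) -> str:
        return self.residues[begin:end]


@dataclass
class AnnotationRecord:
    """One annotated tRNA locus in internal coordinates (parsed tables)."""

    seq_id: str
    begin: int              # 0-based half-open
    end: int
    strand: str             # '+' or '-'
    isotype: str
    anticodon: str          # 3-mer over {A,C,G,T,N}
    score: float
    note: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.begin:
            raise ValueError("end must exceed begin (internal half-open)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGTN"):
            raise ValueError(f"bad anticodon {self.anticodon!r}")


@dataclass
class IntronAnnotation:
    """A detected tRNA intron, canonical (position 37/38) or BHB-type."""

    kind: str               # 'canonical' | 'noncanonical'
    begin: int              # genomic, 0-based half-open
    end: int
    bhb_bits: float = 0.0   # noncanonical only
    iteration: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("canonical", "noncanonical"):
            raise ValueError(f"unknown intron kind {self.kind!r}")
        if self.end <= self.begin:
            raise ValueError("inverted intron bounds")

    def __len__(self) -> int:
        return self.end - self.begin


@dataclass
class TRNAPrediction:
    """One detected tRNA gene locus with scores, identity and flags."""

    seq_id: str
    begin: int
    end: int
    strand: str
    overall_bits: float
    primary_bits: float = 0.0
    secondary_bits: float = 0.0
    anticodon: str = "NNN"
    isotype_by_anticodon: str = "Undet"
    isotype_scores: dict = field(default_factory=dict)
    isotype_by_model: str = ""
    isotype_override: str = ""     # mito mode reports the winning model class
    model: str = ""
    flags: set = field(default_factory=set)
    introns: list = field(default_factory=list)

    @property
    def isotype(self) -> str:
        """Reported isotype: anticodon-derived, CAU resolved by subtype model."""
        return self.isotype_override or self.isotype_by_anticodon

    def span(self) -> tuple:
        return (self.seq_id, self.strand, self.begin, self.end)
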