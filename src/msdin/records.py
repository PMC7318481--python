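"""Domain types shared across the pipeline.

The MSDIN precursor grammar is leader + core + recognition:

* leader: 9-10 aa, highly conserved, ends at the first prolyl-oligopeptidase
  (POPB) cleavage site (P10 in the consensus);
* core: 6-11 aa, hypervariable, excised and head-to-tail cyclised into the
  mature cyclopeptide, usually Pro-terminal (the second POPB cleavage site);
* recognition: 13-18 aa C-terminal segment required for POPB substrate
  recognition, consensus start CVGDD.

A premature stop codon inside the core (written ``*``) marks a pseudogene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

LEADER_LENGTHS = (9, 10)
CORE_LENGTHS = range(6, 12)
RECOGNITION_LENGTHS = range(13, 19)
PRECURSOR_LENGTHS = range(31, 39)


class FormatError(ValueError):
    """Raised for malformed external input (FASTA, fixture tables)."""


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""
    moltype: str = "dna"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET | {"*"}
        bad = set(self.seq) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FixtureRow:
    """One curated MSDIN gene: segmented precursor plus provenance."""

    species: str
    gene_id: str
    leader: str
    core: str
    recognition: str
    product: str = ""
    accession: str = ""
    source: str = "transcriptome"

    def __post_init__(self) -> None:
        if len(self.leader) not in LEADER_LENGTHS:
            raise FormatError(f"{self.gene_id}: leader length {len(self.leader)}")
        if len(self.core) not in CORE_LENGTHS:
            raise FormatError(f"{self.gene_id}: core length {len(self.core)}")
        if len(self.recognition) not in RECOGNITION_LENGTHS:
            raise FormatError(
                f"{self.gene_id}: recognition length {len(self.recognition)}"
            )
        if not self.is_pseudogene and len(self.precursor) not in PRECURSOR_LENGTHS:
            raise FormatError(
                f"{self.gene_id}: precursor length {len(self.precursor)}"
            )

    @property
    def precursor(self) -> str:
        return self.leader + self.core + self.recognition

    @property
    def is_pseudogene(self) -> bool:
        return "*" in self.core

    @property
    def genus(self) -> str:
        return self.species.split()[0]


@dataclass
class PrecursorRecord:
    """A mined MSDIN precursor, parsed into its three segments."""

    species: str = ""
    gene_id: str = ""
    contig_id: str = ""
    strand: str = ""
    frame: int | None = None
    leader: str = ""
    core: str = ""
    recognition: str = ""
    is_pseudogene: bool = False
    parse_score: float = 0.0
    product: str = ""
    coords: tuple[int, int] | None = None  # 0-based half-open, forward strand

    @property
    def precursor(self) -> str:
        return self.leader + self.core + self.recognition

    @property
    def genus(self) -> str:
        return self.species.split()[0] if self.species else ""


@dataclass
class CyclicPeptide:
    core: str
    toxin_class: str
    monoisotopic_mass_da: float
    tryptathionine_capable: bool

    @property
    def length(self) -> int:
        return len(self.core)


@dataclass
class GeneModel:
    """Exon/intron structure on a genomic sequence.

    Coordinates are 0-based half-open on the given strand; exons are ordered
    and non-overlapping, introns are the gaps between consecutive exons and
    each begins GT and ends AG.
    """

    gene_id: str
    exons: list[tuple[int, int]]
    strand: str = "+"

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)


@dataclass
class LocalAlignment:
    query_id: str
    target_id: str
    score: float
    strand: str = "+"
    frame: int = 0
    query_span: tuple[int, int] = (0, 0)
    target_span: tuple[int, int] = (0, 0)  # aa coords in the translated frame
    aligned: list[tuple[int, int]] = field(default_factory=list)
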