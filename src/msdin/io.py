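"""Readers and writers: FASTA, fixture tables, GFF3, Newick, TSV."""

from __future__ import annotations

import csv
import dataclasses
import importlib.resources
from pathlib import Path
from typing import Iterable, Sequence

import skbio
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Seq import Seq

from .records import FixtureRow, FormatError, GeneModel, SequenceRecord

FIXTURE_COLUMNS = [
    "species", "gene_id", "leader", "core", "recognition",
    "product", "accession", "source",
]


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (upper-cased, order preserved)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description,
                           moltype=moltype)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def load_fixture_table(path: str | Path) -> list[FixtureRow]:
    """Load a tab-separated precursor table, validating every row."""
    rows: list[FixtureRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(FIXTURE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for lineno, raw in enumerate(reader, start=2):
            try:
                rows.append(FixtureRow(**{c: raw[c] for c in FIXTURE_COLUMNS}))
            except (FormatError, TypeError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def load_packaged_fixtures() -> list[FixtureRow]:
    """The curated precursor collection shipped with the package.

    110 transcriptome-derived rows followed by 70 rows cloned from genomic
    DNA, spanning ten Amanita species, two Galerina species and Lepiota
    venenata.
    """
    root = importlib.resources.files("msdin") / "data"
    rows = load_fixture_table(str(root / "precursors_transcriptome.tsv"))
    rows += load_fixture_table(str(root / "precursors_cloned.tsv"))
    return rows


def read_hits_tsv(path: str | Path):
    """Load a miner hits TSV back into PrecursorRecords."""
    from .records import PrecursorRecord

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"leader", "core", "recognition"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for raw in reader:
            out.append(PrecursorRecord(
                species=raw.get("species", ""),
                gene_id=raw.get("gene_id", ""),
                contig_id=raw.get("contig_id", ""),
                strand=raw.get("strand", ""),
                leader=raw["leader"], core=raw["core"],
                recognition=raw["recognition"],
                is_pseudogene=raw.get("is_pseudogene", "") in ("True", "true", "1"),
                parse_score=float(raw.get("parse_score", 0) or 0),
                product=raw.get("product", ""),
            ))
    return out


def write_tsv(records: Sequence, path: str | Path, columns: list[str] | None = None) -> None:
    """Write dataclass instances (or dicts) as a TSV that round-trips."""
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    if columns is None:
        columns = list(rows[0].keys()) if rows else FIXTURE_COLUMNS
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})


def write_gff3(models: Iterable[GeneModel], path: str | Path,
               source: str = "msdin") -> None:
    """Write gene models as GFF3.

    Internal coordinates are 0-based half-open; GFF3 is 1-based inclusive,
    so a feature (start, end) is emitted as (start + 1, end).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            for ftype, start, end, parent in _gff_features(m):
                fh.write(
                    "\t".join([
                        m.gene_id, source, ftype, str(start + 1), str(end),
                        ".", m.strand, ".", parent,
                    ]) + "\n"
                )


def _gff_features(m: GeneModel):
    gstart, gend = m.exons[0][0], m.exons[-1][1]
    yield "gene", gstart, gend, f"ID=gene:{m.gene_id}"
    yield "mRNA", gstart, gend, f"ID=mrna:{m.gene_id};Parent=gene:{m.gene_id}"
    for i, (s, e) in enumerate(m.exons, 1):
        yield "exon", s, e, f"ID=exon:{m.gene_id}.{i};Parent=mrna:{m.gene_id}"
    for i, (s, e) in enumerate(m.introns, 1):
        yield "intron", s, e, f"ID=intron:{m.gene_id}.{i};Parent=mrna:{m.gene_id}"


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")
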