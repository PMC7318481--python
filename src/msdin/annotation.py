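"""Mature-cyclopeptide prediction, toxin classification and census statistics."""

from __future__ import annotations

from collections import Counter
from typing import Sequence

from Bio.SeqUtils import molecular_weight

from .records import CyclicPeptide, FixtureRow, PrecursorRecord

WATER_MONOISOTOPIC = 18.010565

#: Exact core sequences of the four named toxins.
KNOWN_CORES = {
    "IWGIGCNP": "alpha-amanitin",
    "IWGIGCDP": "beta-amanitin",
    "AWLVDCP": "phallacidin",
    "AWLATCP": "phalloidin",
}

#: Virotoxins are phallotoxin-like heptapeptides with the Cys replaced by Ser;
#: no encoding gene is known, so a Cys->Ser neighbour is only noted.
VIROTOXIN_NOTE = "virotoxin composition one C->S substitution away"


def classify_core(core: str) -> str:
    """Toxin class of a core peptide.

    Exact matches to the four named toxins win; otherwise a heptapeptide with
    Trp2 and Cys6 is phallotoxin-like, an octapeptide with Trp2 and Cys6 is
    amatoxin-like (both tryptathionine-capable layouts), and anything else is
    unknown.
    """
    if "*" in core:
        raise ValueError(f"pseudogene core {core!r} cannot be classified")
    if not 6 <= len(core) <= 11:
        raise ValueError(f"core length {len(core)} outside 6-11")
    if core in KNOWN_CORES:
        return KNOWN_CORES[core]
    if len(core) == 7 and core[1] == "W" and core[5] == "C":
        return "phallotoxin-like"
    if len(core) == 8 and core[1] == "W" and core[5] == "C":
        return "amatoxin-like"
    return "unknown"


def predict_cyclopeptide(core: str) -> CyclicPeptide:
    """Head-to-tail macrocycle predicted from a core peptide.

    The mass is the unmodified monoisotopic macrocycle mass (sum of residue
    masses; the cyclising amide bond removes the terminal water of the linear
    peptide). Amatoxin-type post-translational modifications (hydroxylations,
    the tryptathionine bridge) are not modelled.
    """
    if "*" in core:
        raise ValueError(f"pseudogene core {core!r} has no mature product")
    mass = molecular_weight(core, seq_type="protein", monoisotopic=True)
    return CyclicPeptide(
        core=core,
        toxin_class=classify_core(core) if 6 <= len(core) <= 11 else "unknown",
        monoisotopic_mass_da=mass - WATER_MONOISOTOPIC,
        tryptathionine_capable=("W" in core and "C" in core),
    )


def _precursor(row) -> str:
    return row.precursor


def _is_verified_duplicate(a: FixtureRow | PrecursorRecord,
                           b: FixtureRow | PrecursorRecord) -> bool:
    """Same gene re-sequenced: identical species and named product, and a
    single substitution confined to the recognition segment.

    Cloned copies of named-toxin genes occasionally differ from their
    transcriptome counterpart by one recognition-site substitution
    (allelic or amplification variation); such pairs are one locus.
    """
    if a.species != b.species:
        return False
    pa, pb = getattr(a, "product", ""), getattr(b, "product", "")
    if not pa or pa != pb:
        return False
    if a.leader != b.leader or a.core != b.core:
        return False
    ra, rb = a.recognition, b.recognition
    if len(ra) != len(rb):
        return False
    return sum(x != y for x, y in zip(ra, rb)) == 1


def dedup_genes(rows: Sequence[FixtureRow | PrecursorRecord],
                merge_verified: bool = True) -> list:
    """Collapse repeated genes to a nonrepetitive list.

    Rows sharing (species, precursor amino-acid string) collapse to the first
    occurrence, transcriptome-derived rows preferred. With ``merge_verified``
    (default) near-duplicates satisfying :func:`_is_verified_duplicate` also
    collapse. Output order is stable.
    """
    ordered = sorted(
        range(len(rows)),
        key=lambda i: (0 if getattr(rows[i], "source", "") == "transcriptome" else 1, i),
    )
    kept: list = []
    seen_exact: dict[tuple[str, str], int] = {}
    for i in ordered:
        row = rows[i]
        key = (row.species, _precursor(row))
        if key in seen_exact:
            continue
        if merge_verified and any(_is_verified_duplicate(row, k) for k in kept):
            continue
        seen_exact[key] = i
        kept.append(row)
    kept_ids = set(map(id, kept))
    return [r for r in rows if id(r) in kept_ids]


def core_census(rows: Sequence[FixtureRow | PrecursorRecord],
                include_pseudogene_cores: bool = False) -> dict:
    """Census over a nonrepetitive gene list.

    Returns the number of distinct core peptides (pseudogene cores excluded
    by default), the split into named toxins vs unnamed cores, and the
    histogram of core lengths over all genes.
    """
    cores = {
        r.core for r in rows
        if include_pseudogene_cores or "*" not in r.core
    }
    classifiable = {c for c in cores if "*" not in c}
    known = {c for c in classifiable if c in KNOWN_CORES}
    histogram = Counter(len(r.core) for r in rows)
    return {
        "n_genes": len(rows),
        "unique_core_count": len(cores),
        "known_cores": sorted(known),
        "n_known": len(known),
        "n_unknown": len(cores) - len(known),
        "length_histogram": {k: histogram[k] for k in sorted(histogram)},
    }


def annotate(records: Sequence[PrecursorRecord]) -> list[PrecursorRecord]:
    """Fill the product field of mined precursors in place (pseudogenes skipped)."""
    for r in records:
        if not r.is_pseudogene:
            cls = classify_core(r.core)
            r.product = "" if cls == "unknown" else cls
    return list(records)
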