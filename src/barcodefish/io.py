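"""Readers and writers for the standard formats the pipeline touches.

FASTA and FASTQ go through Biopython's SeqIO; Newick through dendropy.
This module adds the validation the pipeline's contracts need (alphabet
checks, label-table joins, phred ranges) on top.
"""

from __future__ import annotations

import csv
from os import PathLike
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    LabelledSequence,
    ParseError,
    Read,
    ReferencePanel,
    SEQUENCE_ALPHABET,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "attach_labels",
    "read_label_table",
    "write_newick",
    "read_newick",
]


def _find_bad_line(path: str | PathLike, bad_chars: set[str]) -> int:
    """Best-effort line number of the first illegal sequence character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith((">", "@", "+")):
                continue
            if set(line.strip().upper()) & bad_chars:
                return lineno
    return 0


def read_fasta(path: str | PathLike) -> list[LabelledSequence]:
    """Read a FASTA file into unlabelled sequences.

    Sequence lines are concatenated and upper-cased; taxonomic labels are
    left empty (fill them with :func:`attach_labels`).  An empty file
    yields an empty list.
    """
    out: list[LabelledSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - SEQUENCE_ALPHABET
        if bad:
            lineno = _find_bad_line(path, bad)
            raise ParseError(
                f"{path}: record {rec.id!r}: illegal characters "
                f"{sorted(bad)} (line {lineno})"
            )
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        try:
            out.append(LabelledSequence(id=rec.id, residues=residues))
        except ValueError as exc:  # pragma: no cover - guarded above
            raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fasta(seqs: list[LabelledSequence], path: str | PathLike) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | PathLike) -> list[Read]:
    """Read a phred+33 FASTQ file."""
    out: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(
                Read(
                    id=rec.id,
                    bases=str(rec.seq).upper(),
                    quals=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fastq(reads: list[Read], path: str | PathLike) -> None:
    """Write reads as phred+33 FASTQ."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


LABEL_COLUMNS = ("id", "locus", "species", "lineage", "phylogroup")


def read_label_table(path: str | PathLike) -> dict[str, dict[str, str]]:
    """Read the TSV label map: id -> {locus, species, lineage, phylogroup}.

    Raises
    ------
    ParseError
        On missing columns or a duplicated sequence id.
    """
    table: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(LABEL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            sid = row["id"]
            if sid in table:
                raise ParseError(f"{path}: duplicate id {sid!r}")
            table[sid] = {k: (row[k] or "") for k in LABEL_COLUMNS[1:]}
    return table


def attach_labels(
    seqs: list[LabelledSequence], label_table: str | PathLike
) -> tuple[ReferencePanel, list[str]]:
    """Join sequences with a TSV label map and group them into a panel.

    Returns the panel plus a list of warnings (table ids with no matching
    sequence, and sequences absent from the table, which are dropped
    because their locus is unknown).  Alignment lengths are checked per
    locus by the panel constructor.
    """
    table = read_label_table(label_table)
    warnings: list[str] = []
    loci: dict[str, list[LabelledSequence]] = {}
    seen: set[str] = set()
    for s in seqs:
        row = table.get(s.id)
        if row is None:
            warnings.append(f"sequence {s.id!r} not in label table; dropped")
            continue
        seen.add(s.id)
        labelled = LabelledSequence(
            id=s.id,
            residues=s.residues,
            locus=row["locus"],
            species=row["species"],
            lineage=row["lineage"],
            phylogroup=row["phylogroup"],
        )
        loci.setdefault(row["locus"], []).append(labelled)
    for sid in table:
        if sid not in seen:
            warnings.append(f"label table id {sid!r} matches no sequence")
    return ReferencePanel(loci=loci), warnings


def write_newick(tree: dendropy.Tree, path: str | PathLike) -> None:
    """Write a tree as Newick: branch lengths to 6 decimals, integer
    bootstrap supports as internal-node labels."""
    Path(path).write_text(tree_to_newick(tree) + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    ).strip()


def read_newick(path: str | PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
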