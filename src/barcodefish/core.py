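"""Shared domain types for the barcode-fishing pipeline.

Coordinates throughout the package are 0-based, half-open, in the
reference frame of each locus alignment.  Missing-data characters on
input are ``{N, ?, -}``; internally ``N`` means "no call" and ``-``
means "called deletion".  Sequence input is case-insensitive and
normalised to upper case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BarcodefishError",
    "ParseError",
    "LabelledSequence",
    "Read",
    "ReferencePanel",
    "IUPAC_CODES",
    "SEQUENCE_ALPHABET",
    "MISSING",
    "revcomp",
]

# IUPAC nucleotide ambiguity codes mapped to the base sets they denote.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Characters permitted in reference/consensus sequences.
SEQUENCE_ALPHABET = frozenset(IUPAC_CODES) | {"-", "?"}

#: Characters treated as missing data on input.
MISSING = frozenset("N?-")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-?", "TGCAYRSWMKVHDBN-?")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class BarcodefishError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BarcodefishError):
    """A file could not be parsed; the message names the offending line."""


@dataclass
class LabelledSequence:
    """A reference barcode sequence with taxonomic labels.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header word).
    residues : str
        Upper-case nucleotides over the IUPAC alphabet plus ``-`` and
        ``?``.  Within one locus of a panel all sequences share the same
        (aligned) length.
    locus : str
        Locus name, e.g. ``"16S"``, ``"cox1"``, ``"cytb"``.
    species, lineage, phylogroup : str
        Taxonomic labels; empty string when unknown.  ``lineage`` is the
        coarse split (e.g. low- vs high-elevation, "LE"/"HE");
        ``phylogroup`` a named sub-clade (e.g. "LE4").
    """

    id: str
    residues: str
    locus: str = ""
    species: str = ""
    lineage: str = ""
    phylogroup: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        """Residues with alignment gaps and '?' removed."""
        return self.residues.replace("-", "").replace("?", "")

    def label(self, level: str) -> str:
        """Return the label at ``level`` ("species"/"lineage"/"phylogroup")."""
        try:
            return {"species": self.species,
                    "lineage": self.lineage,
                    "phylogroup": self.phylogroup}[level]
        except KeyError:
            raise ValueError(f"unknown label level {level!r}") from None


@dataclass
class Read:
    """A single-end sequencing read with per-base phred qualities."""

    id: str
    bases: str
    quals: list[int] = field(default_factory=list)
    truth: str | None = None  # source label for simulated reads

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if set(self.bases) - set("ACGTN"):
            raise ValueError(f"read {self.id!r}: bases must be over ACGTN")
        if not self.quals:
            self.quals = [40] * len(self.bases)
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 93):
            raise ValueError(f"read {self.id!r}: phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReferencePanel:
    """Aligned, labelled barcode references grouped by locus."""

    loci: dict[str, list[LabelledSequence]]
    label_levels: tuple[str, ...] = ("species", "lineage", "phylogroup")

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("a reference panel needs at least one locus")
        for locus, seqs in self.loci.items():
            if not seqs:
                raise ValueError(f"locus {locus!r}: no sequences")
            lengths = {len(s) for s in seqs}
            if len(lengths) > 1:
                raise ValueError(
                    f"locus {locus!r}: aligned sequences of unequal length "
                    f"{sorted(lengths)}"
                )
            for s in seqs:
                if s.locus and s.locus != locus:
                    raise ValueError(
                        f"sequence {s.id!r} tagged {s.locus!r} stored under "
                        f"locus {locus!r}"
                    )
                s.locus = locus

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    def alignment_length(self, locus: str) -> int:
        return len(self.loci[locus][0])

    def groups(self, locus: str, level: str) -> dict[str, list[LabelledSequence]]:
        """Panel members of one locus grouped by their label at ``level``."""
        out: dict[str, list[LabelledSequence]] = {}
        for s in self.loci[locus]:
            out.setdefault(s.label(level), []).append(s)
        return out
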