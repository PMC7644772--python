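"""Synthetic archival-specimen reads.

Emulates the salient properties of sequencing libraries built from old
wet-collection specimens: short fragments read as 75-nt single-end
reads, coverage that is uneven by orders of magnitude with whole
reference stretches absent, terminal cytosine-deamination damage (C->T
at the 5' end of a fragment, G->A at the 3' end, decaying exponentially
with distance from the terminus), uniform sequencing error, and a
fraction of off-target contaminant reads.

The generator is the ground-truth side of every downstream test: it
returns, along with the reads, a :class:`SimTruth` recording each
read's source, fragment coordinates and damaged positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from os import PathLike

import dendropy
import numpy as np

from .core import LabelledSequence, Read, ReferencePanel, revcomp

__all__ = [
    "SimConfig",
    "SimTruth",
    "mutate_sequence",
    "simulate_lineages",
    "degrade_and_read",
    "random_sequence",
    "write_run",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of the synthetic archival library.

    Defaults mirror the study conditions of the motivating system: a
    ~500-nt mitochondrial barcode frame, two candidate lineages at 6%
    expected divergence (the complex's 16S lineages differ by 5.6-6.8%
    uncorrected), 75-cycle single-end reads, low sequencing error,
    end-concentrated deamination and a minority of contaminant reads.
    """

    seed: int = 0
    loci: tuple[str, ...] = ("16S", "cox1")
    ancestor_length: int = 500
    n_lineages: int = 2
    between_divergence: float = 0.06  # expected subs/site lineage vs ancestor
    within_diversity: float = 0.005   # expected subs/site within a lineage
    members_per_lineage: int = 5
    fragment_mean: float = 60.0
    fragment_sd: float = 15.0
    read_length: int = 75
    n_reads: int = 170  # ~20x mean depth on a 500-nt locus at ~59-nt reads
    error_rate: float = 0.002
    deam_rate: float = 0.2       # C->T probability at the 5' terminus
    deam_decay: float = 3.0      # e-folding length (positions) of damage
    contam_fraction: float = 0.1
    coverage_dropout: tuple[tuple[int, int], ...] = ((200, 260),)
    emit_revcomp: bool = False   # emit ~50% of reads reverse-complemented

    def __post_init__(self) -> None:
        for name in ("between_divergence", "within_diversity", "error_rate",
                     "deam_rate", "contam_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fragment_mean <= 0:
            raise ValueError("fragment_mean must be positive")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.deam_decay <= 0:
            raise ValueError("deam_decay must be positive")


@dataclass
class SimTruth:
    """Per-read provenance: one entry per emitted read."""

    reads: list[dict] = field(default_factory=list)

    def sources(self) -> list[str]:
        return [r["source"] for r in self.reads]

    def n_contaminant(self) -> int:
        return sum(1 for r in self.reads if r["source"] == "contaminant")

    def to_json(self, path: str | PathLike, config: SimConfig | None = None) -> None:
        doc: dict = {"reads": self.reads}
        if config is not None:
            cfg = asdict(config)
            cfg["loci"] = list(cfg["loci"])
            cfg["coverage_dropout"] = [list(t) for t in cfg["coverage_dropout"]]
            doc["config"] = cfg
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """A uniform random ACGT string (ancestors, contaminants)."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate each site independently with probability ``rate``.

    A mutated site is replaced by one of the three other bases chosen
    uniformly (Jukes-Cantor-style), so the expected per-site difference
    from ``seq`` is exactly ``rate``.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode()


def simulate_lineages(cfg: SimConfig) -> tuple[ReferencePanel, dendropy.Tree]:
    """Simulate a labelled reference panel and its true tree.

    Per locus: one random ancestor; one founder per lineage mutated from
    the ancestor at ``between_divergence`` (so two founders differ by
    ~2x that rate, ignoring multiple hits); members mutated from their
    founder at ``within_diversity``.  Members are split into two named
    phylogroups per lineage.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    loci: dict[str, list[LabelledSequence]] = {}
    for locus in cfg.loci:
        ancestor = random_sequence(cfg.ancestor_length, rng)
        seqs = []
        for li in range(1, cfg.n_lineages + 1):
            founder = mutate_sequence(ancestor, cfg.between_divergence, rng)
            half = math.ceil(cfg.members_per_lineage / 2)
            for mi in range(1, cfg.members_per_lineage + 1):
                member = mutate_sequence(founder, cfg.within_diversity, rng)
                seqs.append(
                    LabelledSequence(
                        id=f"L{li}_m{mi}_{locus}",
                        residues=member,
                        locus=locus,
                        species=f"sp{li}",
                        lineage=f"L{li}",
                        phylogroup=f"L{li}g{1 if mi <= half else 2}",
                    )
                )
        loci[locus] = seqs
    panel = ReferencePanel(loci=loci)
    tree = _true_tree(cfg)
    return panel, tree


def _true_tree(cfg: SimConfig) -> dendropy.Tree:
    parts = []
    for li in range(1, cfg.n_lineages + 1):
        tips = ",".join(
            f"L{li}_m{mi}:{cfg.within_diversity:.6f}"
            for mi in range(1, cfg.members_per_lineage + 1)
        )
        parts.append(f"({tips}):{cfg.between_divergence:.6f}")
    newick = "(" + ",".join(parts) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def _sample_fragment(
    length: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    dropout: tuple[tuple[int, int], ...],
) -> tuple[int, int]:
    """Fragment (start, end) avoiding dropout intervals; rejection-sampled."""
    for _ in range(10_000):
        flen = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        flen = max(20, min(flen, length))
        start = int(rng.integers(0, length - flen + 1))
        end = start + flen
        if any(start < d1 and d0 < end for d0, d1 in dropout):
            continue
        return start, end
    raise ValueError("could not place a fragment outside dropout intervals")


def _deaminate(
    frag: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Terminal C->T (5') and G->A (3') damage; returns fragment + positions."""
    if cfg.deam_rate == 0.0:
        return frag, []
    arr = list(frag)
    n = len(arr)
    damaged = []
    for i in range(n):
        p5 = cfg.deam_rate * math.exp(-i / cfg.deam_decay)
        if arr[i] == "C" and rng.random() < p5:
            arr[i] = "T"
            damaged.append(i)
            continue
        p3 = cfg.deam_rate * math.exp(-(n - 1 - i) / cfg.deam_decay)
        if arr[i] == "G" and rng.random() < p3:
            arr[i] = "A"
            damaged.append(i)
    return "".join(arr), damaged


def degrade_and_read(
    source: LabelledSequence,
    cfg: SimConfig,
    contaminants: list[LabelledSequence] | None = None,
    seed: int | None = None,
) -> tuple[list[Read], SimTruth]:
    """Fragment, damage and read a source sequence.

    Fragments are normal(``fragment_mean``, ``fragment_sd``) truncated to
    [20, len(source)], placed uniformly outside ``coverage_dropout``
    intervals; the read is the first ``read_length`` bases of the
    fragment.  Deamination is applied to the fragment, then uniform
    sequencing errors to the read.  A ``contam_fraction`` of reads is
    drawn from the contaminant pool instead (no dropout applied there).
    Deterministic given the seed (``cfg.seed`` unless overridden).
    """
    src = source.ungapped
    if len(src) < cfg.fragment_mean:
        raise ValueError("source shorter than the mean fragment length")
    contaminants = contaminants or []
    if cfg.contam_fraction > 0 and not contaminants:
        raise ValueError("contam_fraction > 0 but no contaminants supplied")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    reads: list[Read] = []
    truth = SimTruth()
    for i in range(cfg.n_reads):
        if cfg.contam_fraction > 0 and rng.random() < cfg.contam_fraction:
            donor = contaminants[int(rng.integers(len(contaminants)))]
            dseq, source_label, dropout = donor.ungapped, "contaminant", ()
        else:
            dseq, source_label, dropout = src, "target", cfg.coverage_dropout
        start, end = _sample_fragment(len(dseq), cfg, rng, dropout)
        frag, damaged = _deaminate(dseq[start:end], cfg, rng)
        bases = frag[: cfg.read_length]
        damaged = [d for d in damaged if d < len(bases)]
        # sequencing errors on the read
        barr = np.frombuffer(bases.encode(), dtype=np.uint8).copy()
        errs = np.nonzero(rng.random(barr.size) < cfg.error_rate)[0]
        if errs.size:
            idx = np.searchsorted(_BASES, barr[errs])
            barr[errs] = _BASES[(idx + rng.integers(1, 4, size=errs.size)) % 4]
        bases = barr.tobytes().decode()
        strand = "+"
        if cfg.emit_revcomp and rng.random() < 0.5:
            bases = revcomp(bases)
            strand = "-"
        rid = f"read{i:06d}"
        reads.append(Read(id=rid, bases=bases, quals=[37] * len(bases),
                          truth=source_label))
        truth.reads.append(
            {
                "id": rid,
                "source": source_label,
                "donor": source.id if source_label == "target" else donor.id,
                "start": start,
                "end": end,
                "strand": strand,
                "damaged_positions": damaged,
                "error_positions": [int(e) for e in errs],
            }
        )
    return reads, truth


def write_run(
    cfg: SimConfig,
    outdir: str | PathLike,
    query_lineage: int = 1,
    n_contaminants: int = 3,
) -> dict[str, str]:
    """Simulate a full input set on disk: panel FASTA + label TSV, query
    FASTQ, truth JSON and the true tree as Newick.

    The query source is the first member of ``query_lineage`` at the
    first locus, so downstream assignment has a known right answer.
    Returns the paths written, keyed by role.
    """
    from pathlib import Path

    from .io import write_fasta, write_fastq, write_newick

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel, tree = simulate_lineages(cfg)
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    contaminants = [
        LabelledSequence(id=f"contam{i}",
                         residues=random_sequence(cfg.ancestor_length, rng))
        for i in range(n_contaminants)
    ]
    locus = cfg.loci[0]
    source = next(
        s for s in panel.loci[locus] if s.lineage == f"L{query_lineage}"
    )
    reads, truth = degrade_and_read(source, cfg, contaminants)

    paths = {
        "panel_fasta": str(out / "panel.fasta"),
        "labels_tsv": str(out / "labels.tsv"),
        "reads_fastq": str(out / "reads.fastq"),
        "truth_json": str(out / "truth.json"),
        "tree_newick": str(out / "true_tree.nwk"),
    }
    allseqs = [s for seqs in panel.loci.values() for s in seqs]
    write_fasta(allseqs, paths["panel_fasta"])
    with open(paths["labels_tsv"], "w") as fh:
        fh.write("id\tlocus\tspecies\tlineage\tphylogroup\n")
        for s in allseqs:
            fh.write(f"{s.id}\t{s.locus}\t{s.species}\t{s.lineage}\t{s.phylogroup}\n")
    write_fastq(reads, paths["reads_fastq"])
    truth.to_json(paths["truth_json"], config=cfg)
    write_newick(tree, paths["tree_newick"])
    return paths
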