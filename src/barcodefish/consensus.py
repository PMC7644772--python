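"""Reference-guided majority consensus.

Each fished read is placed by semi-global alignment (read fully aligned,
reference locally) against its locus reference; read insertions relative
to the reference are dropped, so the consensus lives entirely in the
reference alignment frame.  Columns are called by strict majority of
the non-N states, with a minimum depth; everything else is N.  A
deletion is callable like a base and emitted as ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .core import IUPAC_CODES, LabelledSequence, Read, revcomp
from .fishing import make_aligner

__all__ = [
    "ReadPlacement",
    "ConsensusResult",
    "place_read",
    "build_consensus",
    "consensus_stats",
]

#: Per-column state for a reference position deleted in the read.
DELETION = "-"

_IUPAC_FROM_SET = {frozenset(v): k for k, v in IUPAC_CODES.items()}


def make_placement_aligner() -> Align.PairwiseAligner:
    """Semi-global aligner: read fully aligned, reference end gaps free."""
    aligner = make_aligner("global")
    # free gaps in the query row at the ends = the reference may overhang
    try:
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.query_end_gap_score = 0
    return aligner


@dataclass
class ReadPlacement:
    """One read's alignment to a reference, in alignment-frame columns."""

    read_id: str
    reference_id: str
    start: int
    end: int
    states: str  # one of A,C,G,T,N,'-' per column in [start, end)
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.states):
            raise ValueError("placement span does not match its states")


@dataclass
class ConsensusResult:
    """A called consensus with per-position coverage and recovery stats."""

    locus: str
    called: str
    coverage: list[int]
    alignment_length: int
    recovered_nt: int = 0
    missing_runs: list[tuple[int, int]] = field(default_factory=list)
    max_coverage: int = 0

    def __post_init__(self) -> None:
        self.recovered_nt = sum(1 for c in self.called if c != "N")
        self.missing_runs = _runs(self.called, "N")
        self.max_coverage = max(self.coverage, default=0)


def _runs(called: str, char: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, c in enumerate(called):
        if (c == char) and start is None:
            start = i
        elif (c != char) and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(called)))
    return runs


def _column_map(reference: LabelledSequence) -> list[int]:
    """Ungapped reference position -> alignment column."""
    return [i for i, c in enumerate(reference.residues) if c not in "-?"]


def place_read(
    read: Read,
    reference: LabelledSequence,
    min_score: float = 20.0,
    aligner: Align.PairwiseAligner | None = None,
) -> ReadPlacement | None:
    """Place a read on a reference; ``None`` if the score is below floor.

    Both strands are tried; the better-scoring one is kept.  Reference
    positions deleted in the read are recorded as ``-`` states; read
    insertions are discarded.  Coordinates are alignment-frame columns
    of the (possibly gapped) reference.
    """
    aligner = aligner or make_placement_aligner()
    ref = reference.ungapped
    best = None
    for strand, query in (("+", read.bases), ("-", revcomp(read.bases))):
        alns = aligner.align(ref, query)
        try:
            score = alns.score
        except (IndexError, ValueError):
            continue
        if best is None or score > best[0]:
            best = (score, strand, query, alns[0])
    if best is None or best[0] < min_score:
        return None
    score, strand, query, aln = best

    blocks = aln.aligned  # ((tstart, tend), ...), ((qstart, qend), ...)
    tblocks, qblocks = blocks
    if len(tblocks) == 0:
        return None
    start_u = int(tblocks[0][0])
    end_u = int(tblocks[-1][1])
    states_u = [DELETION] * (end_u - start_u)
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(te - ts):
            states_u[ts - start_u + k] = query[qs + k]

    cmap = _column_map(reference)
    start = cmap[start_u]
    end = cmap[end_u - 1] + 1
    states = ["N"] * (end - start)  # reference-gap columns stay uncovered
    for k, state in enumerate(states_u):
        states[cmap[start_u + k] - start] = state
    return ReadPlacement(
        read_id=read.id,
        reference_id=reference.id,
        start=start,
        end=end,
        states="".join(states),
        strand=strand,
        score=float(score),
    )


def build_consensus(
    placements: list[ReadPlacement],
    reference: LabelledSequence,
    locus: str | None = None,
    min_depth: int = 3,
    majority_fraction: float = 0.5,
    iupac: bool = False,
) -> ConsensusResult:
    """Majority-call a consensus from read placements.

    Per column, non-N states are tallied; coverage is the tally total.
    The state with the strictly greatest count is called iff
    ``count / coverage > majority_fraction`` and coverage reaches
    ``min_depth``; exact ties give N (or a two-base IUPAC code when
    ``iupac`` is set).  Deletions are called like bases, as ``-``.
    """
    length = len(reference.residues)
    tallies: list[dict[str, int]] = [dict() for _ in range(length)]
    for p in placements:
        if p.end > length:
            raise ValueError(f"placement {p.read_id!r} beyond reference end")
        for col, state in zip(range(p.start, p.end), p.states):
            if state != "N":
                t = tallies[col]
                t[state] = t.get(state, 0) + 1
    coverage = [sum(t.values()) for t in tallies]
    called = []
    for t, cov in zip(tallies, coverage):
        if cov < min_depth or not t:
            called.append("N")
            continue
        ranked = sorted(t.items(), key=lambda kv: (-kv[1], kv[0]))
        top_state, top_n = ranked[0]
        tied = [s for s, n in ranked if n == top_n]
        if len(tied) > 1:
            if iupac and len(tied) == 2 and DELETION not in tied:
                called.append(_IUPAC_FROM_SET.get(frozenset(tied), "N"))
            else:
                called.append("N")
        elif top_n / cov > majority_fraction:
            called.append(top_state)
        else:
            called.append("N")
    return ConsensusResult(
        locus=locus or reference.locus,
        called="".join(called),
        coverage=coverage,
        alignment_length=length,
    )


def consensus_stats(result: ConsensusResult) -> dict:
    """Recovery accounting: called positions, missing runs, coverage."""
    # covered runs are the complement of the missing runs
    covered_runs = []
    edges = [0] + [e for run in result.missing_runs for e in run] + [
        result.alignment_length
    ]
    for a, b in zip(edges[::2], edges[1::2]):
        if b > a:
            seg = result.coverage[a:b]
            covered_runs.append(
                {"start": a, "end": b, "length": b - a,
                 "min_coverage": min(seg), "max_coverage": max(seg)}
            )
    return {
        "locus": result.locus,
        "recovered_nt": result.recovered_nt,
        "alignment_length": result.alignment_length,
        "recovered_fraction": round(
            result.recovered_nt / result.alignment_length, 6
        ),
        "missing_runs": [
            {"start": s, "end": e, "length": e - s}
            for s, e in result.missing_runs
        ],
        "max_coverage": result.max_coverage,
        "covered_runs": covered_runs,
    }
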