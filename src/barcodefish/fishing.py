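"""'Barcode fishing': retain reads similar to a barcode reference panel.

Reads are quality/adapter trimmed, then scored by best local alignment
against every reference of every locus on both strands; a read is kept
iff its best identity reaches the similarity threshold (default 90%),
and is assigned to the locus of its best hit.  Identity is defined as
matches / alignment columns of the best local alignment, with mismatch
and gap columns in the denominator.

Clonal (duplicate) reads are kept by default: the downstream consensus
is majority-based, so duplicates carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .core import LabelledSequence, Read, ReferencePanel, revcomp

__all__ = ["FishingConfig", "FishingResult", "trim_read", "similarity", "fish_reads"]

#: Local-alignment scoring used for similarity filtering and placement.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -2, -1


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass
class FishingConfig:
    """Trimming and similarity-filter parameters."""

    similarity_threshold: float = 0.90
    min_aligned_length: int = 30
    min_read_length_after_trim: int = 25
    quality_window: int = 5
    quality_threshold: int = 20
    adapter: str | None = None
    dedupe: bool = False          # the motivating study kept clonal reads
    prefilter_k: int | None = None  # shared k-mer prescreen; None = exhaustive

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must be in [0, 1]")


@dataclass
class FishingResult:
    """Retained reads per locus plus per-read best hits and counts."""

    per_locus: dict[str, list[Read]]
    hits: list[dict]  # read id, locus, reference id, identity, strand, columns
    counts: dict

    def retained(self) -> list[Read]:
        return [r for reads in self.per_locus.values() for r in reads]


def trim_read(read: Read, cfg: FishingConfig) -> Read | None:
    """Adapter- and quality-trim the 3' end; ``None`` means discarded.

    Adapter removal: the longest read suffix matching a prefix of the
    adapter over >= 8 nt with at most one mismatch per 10 nt is cut.
    Quality: scanning 5'->3', at the first window of ``quality_window``
    bases whose mean phred drops below ``quality_threshold``, the read
    is cut before the first sub-threshold base in that window.
    """
    bases, quals = read.bases, list(read.quals)

    if cfg.adapter:
        adapter = cfg.adapter.upper()
        max_k = min(len(bases), len(adapter))
        for k in range(max_k, 7, -1):  # longest qualifying overlap wins
            tail, prefix = bases[-k:], adapter[:k]
            mism = sum(a != b for a, b in zip(tail, prefix))
            if mism <= k // 10:
                bases, quals = bases[:-k], quals[:-k]
                break

    w = cfg.quality_window
    if len(quals) >= w:
        window_sum = sum(quals[:w])
        cut = None
        for start in range(len(quals) - w + 1):
            if start:
                window_sum += quals[start + w - 1] - quals[start - 1]
            if window_sum < cfg.quality_threshold * w:
                cut = start
                while cut < len(quals) and quals[cut] >= cfg.quality_threshold:
                    cut += 1
                break
        if cut is not None:
            bases, quals = bases[:cut], quals[:cut]

    if len(bases) < cfg.min_read_length_after_trim:
        return None
    return Read(id=read.id, bases=bases, quals=quals, truth=read.truth)


def similarity(
    read: Read,
    reference: LabelledSequence,
    min_aligned_length: int = 30,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, str, int]:
    """Best-local-alignment identity of a read against one reference.

    Both the read and its reverse complement are aligned (match +1,
    mismatch -1, gap open -2, gap extend -1); the better-scoring strand
    is reported.  Returns ``(identity, strand, aligned_columns)`` with
    identity = matches / alignment columns; identity is 0.0 when fewer
    than ``min_aligned_length`` columns align.
    """
    if not read.bases:
        raise ValueError("empty read")
    aligner = aligner or make_aligner("local")
    ref = reference.ungapped
    best = (float("-inf"), 0.0, "+", 0)
    for strand, query in (("+", read.bases), ("-", revcomp(read.bases))):
        alns = aligner.align(ref, query)
        try:
            score = alns.score
        except (IndexError, ValueError):  # no alignment at all
            continue
        if score <= best[0]:
            continue
        counts = alns[0].counts()
        columns = counts.gaps + counts.identities + counts.mismatches
        identity = counts.identities / columns if columns else 0.0
        best = (score, identity, strand, columns)
    _, identity, strand, columns = best
    if columns < min_aligned_length:
        return 0.0, strand, columns
    return identity, strand, columns


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def fish_reads(
    reads: list[Read], panel: ReferencePanel, cfg: FishingConfig | None = None
) -> FishingResult:
    """Trim and similarity-filter reads against a reference panel.

    Each trimmed read is scored against every reference of every locus;
    it is retained iff its best identity >= ``similarity_threshold`` and
    assigned to the locus of the best-scoring reference (identity ties
    broken by panel locus order, then reference order).
    """
    cfg = cfg or FishingConfig()
    if not panel.loci:
        raise ValueError("empty reference panel")
    aligner = make_aligner("local")

    ref_kmers = None
    if cfg.prefilter_k:
        ref_kmers = {
            (locus, ref.id): _kmers(ref.ungapped, cfg.prefilter_k)
            for locus in panel.loci
            for ref in panel.loci[locus]
        }

    per_locus: dict[str, list[Read]] = {locus: [] for locus in panel.loci}
    hits: list[dict] = []
    seen: set[tuple] = set()
    n_trimmed_out = 0
    n_unmatched = 0
    for read in reads:
        trimmed = trim_read(read, cfg)
        if trimmed is None:
            n_trimmed_out += 1
            continue
        best = (0.0, None, None, "+", 0)  # identity, locus, ref, strand, cols
        for locus in panel.loci:
            for ref in panel.loci[locus]:
                if ref_kmers is not None:
                    kms = _kmers(trimmed.bases, cfg.prefilter_k) | _kmers(
                        revcomp(trimmed.bases), cfg.prefilter_k
                    )
                    if not (kms & ref_kmers[(locus, ref.id)]):
                        continue
                ident, strand, cols = similarity(
                    trimmed, ref, cfg.min_aligned_length, aligner
                )
                if ident > best[0]:
                    best = (ident, locus, ref.id, strand, cols)
        identity, locus, ref_id, strand, cols = best
        if locus is None or identity < cfg.similarity_threshold:
            n_unmatched += 1
            continue
        if cfg.dedupe:
            key = (trimmed.bases, strand)
            if key in seen:
                continue
            seen.add(key)
        per_locus[locus].append(trimmed)
        hits.append(
            {
                "read_id": trimmed.id,
                "locus": locus,
                "reference_id": ref_id,
                "identity": round(identity, 6),
                "strand": strand,
                "aligned_columns": cols,
            }
        )
    counts = {
        "total_input": len(reads),
        "trimmed_out": n_trimmed_out,
        "unmatched": n_unmatched,
        "retained_total": sum(len(v) for v in per_locus.values()),
        "retained_per_locus": {k: len(v) for k, v in per_locus.items()},
    }
    return FishingResult(per_locus=per_locus, hits=hits, counts=counts)
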