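"""One reproducible run: fish -> consensus -> assign -> tree -> report.

The report mirrors how an archival-specimen identification is written
up: read accounting per stage, per-locus consensus recovery (called
positions, missing stretches, coverage), diagnostic-site agreement
counts with a verdict per locus and combined, bootstrap trees, and
cross-lineage distance ranges.  Every number in the report is
recomputable from the run's intermediate files.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

from . import __version__
from .assign import find_diagnostic_sites, group_distance_range, score_query
from .consensus import (
    build_consensus,
    consensus_stats,
    make_placement_aligner,
    place_read,
)
from .core import LabelledSequence, ReferencePanel
from .fishing import FishingConfig, fish_reads
from .io import read_fasta, read_fastq, attach_labels, tree_to_newick, write_fasta
from .phylo import PhyloConfig, bootstrap_tree

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    The single ``seed`` fans out to per-stage seeds by fixed offsets so
    stages can be re-run individually.
    """

    reads: str
    panel: str
    labels: str
    outdir: str = "barcodefish_run"
    fishing: FishingConfig = field(default_factory=FishingConfig)
    min_depth: int = 3
    majority_fraction: float = 0.5
    level: str = "lineage"
    focal_groups: list[str] | None = None
    phylo: PhyloConfig = field(default_factory=PhyloConfig)
    build_trees: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if isinstance(doc.get("fishing"), dict):
            doc["fishing"] = FishingConfig(**doc["fishing"])
        if isinstance(doc.get("phylo"), dict):
            doc["phylo"] = PhyloConfig(**doc["phylo"])
        return cls(**doc)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    config: dict
    read_counts: dict
    consensus: dict          # locus -> stats block
    assignment: dict         # locus -> AssignmentReport dict
    combined_verdict: str
    trees: dict              # locus -> newick string or None
    distance_ranges: dict    # locus -> {"groups": [...], "min": x, "max": y}
    version: str = __version__
    wall_clock_s: float = 0.0

    def to_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | PathLike) -> "RunReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _combined_verdict(verdicts: list[str]) -> str:
    real = [v for v in verdicts if v not in ("ambiguous", "")]
    if not real:
        return "ambiguous"
    if len(set(real)) == 1:
        return real[0]
    return "conflicting"


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order, writing intermediates to ``outdir``."""
    t0 = time.monotonic()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    seqs = read_fasta(cfg.panel)
    panel, warns = attach_labels(seqs, cfg.labels)
    reads = read_fastq(cfg.reads)

    fished = fish_reads(reads, panel, cfg.fishing)
    with open(out / "fishing_hits.tsv", "w") as fh:
        fh.write("read_id\tlocus\treference_id\tidentity\tstrand\taligned_columns\n")
        for h in fished.hits:
            fh.write(
                f"{h['read_id']}\t{h['locus']}\t{h['reference_id']}\t"
                f"{h['identity']}\t{h['strand']}\t{h['aligned_columns']}\n"
            )

    aligner = make_placement_aligner()
    consensus_blocks: dict[str, dict] = {}
    assignment: dict[str, dict] = {}
    trees: dict[str, str | None] = {}
    distance_ranges: dict[str, dict] = {}
    consensus_seqs: list[LabelledSequence] = []
    n_placed: dict[str, int] = {}

    for li, locus in enumerate(panel.loci):
        reference = panel.loci[locus][0]  # the locus's alignment frame
        placements = []
        for read in fished.per_locus[locus]:
            p = place_read(read, reference, aligner=aligner)
            if p is not None:
                placements.append(p)
        n_placed[locus] = len(placements)
        result = build_consensus(
            placements,
            reference,
            locus=locus,
            min_depth=cfg.min_depth,
            majority_fraction=cfg.majority_fraction,
        )
        consensus_blocks[locus] = consensus_stats(result)
        consensus_seqs.append(
            LabelledSequence(id=f"query_{locus}", residues=result.called,
                             locus=locus)
        )
        with open(out / f"coverage_{locus}.tsv", "w") as fh:
            fh.write("position\tdepth\tcall\n")
            for pos, (depth, call) in enumerate(
                zip(result.coverage, result.called)
            ):
                fh.write(f"{pos}\t{depth}\t{call}\n")

        groups = sorted(panel.groups(locus, cfg.level))
        focal = cfg.focal_groups or groups
        sites = find_diagnostic_sites(panel, locus, cfg.level, focal)
        report = score_query(result, sites,
                             alignment_length=panel.alignment_length(locus))
        assignment[locus] = report.to_dict()

        if len(focal) >= 2:
            lo, hi = group_distance_range(
                panel, locus, focal[0], focal[1], cfg.level
            )
            distance_ranges[locus] = {
                "groups": [focal[0], focal[1]],
                "min": round(lo, 6),
                "max": round(hi, 6),
            }

        trees[locus] = None
        if cfg.build_trees and result.recovered_nt > 0:
            phylo_cfg = PhyloConfig(
                bootstrap_replicates=cfg.phylo.bootstrap_replicates,
                seed=cfg.seed + 101 * (li + 1),
                model=cfg.phylo.model,
                gamma_shape=cfg.phylo.gamma_shape,
            )
            alignment = panel.loci[locus] + [consensus_seqs[-1]]
            try:
                tree = bootstrap_tree(alignment, phylo_cfg)
                trees[locus] = tree_to_newick(tree)
            except ValueError:
                trees[locus] = None  # saturated/undefined distances

    write_fasta(consensus_seqs, out / "consensus.fasta")

    report = RunReport(
        config=cfg.to_dict(),
        read_counts={
            **fished.counts,
            "placed_per_locus": n_placed,
            "label_warnings": warns,
        },
        consensus=consensus_blocks,
        assignment=assignment,
        combined_verdict=_combined_verdict(
            [assignment[locus]["verdict"] for locus in assignment]
        ),
        trees=trees,
        distance_ranges=distance_ranges,
        wall_clock_s=round(time.monotonic() - t0, 3),
    )
    report.to_json(out / "report.json")
    return report


def render_report(report: RunReport) -> str:
    """Human-readable Markdown summary of a run."""
    lines = [
        "# Barcode-fishing run report",
        "",
        f"software version: {report.version}",
        "",
        "## Read accounting",
        f"- total input reads: {report.read_counts['total_input']}",
        f"- removed by trimming: {report.read_counts['trimmed_out']}",
        f"- below similarity threshold: {report.read_counts['unmatched']}",
        f"- retained: {report.read_counts['retained_total']}",
    ]
    for locus, n in report.read_counts["retained_per_locus"].items():
        lines.append(f"    - {locus}: {n}")
    lines += ["", "## Consensus recovery"]
    for locus, blk in report.consensus.items():
        runs = ", ".join(
            f"[{r['start']},{r['end']}) len {r['length']}"
            for r in blk["missing_runs"]
        ) or "none"
        lines.append(
            f"- {locus}: {blk['recovered_nt']}/{blk['alignment_length']} nt "
            f"recovered (max coverage {blk['max_coverage']}); "
            f"missing runs: {runs}"
        )
    lines += ["", "## Diagnostic-site assignment"]
    for locus, rep in report.assignment.items():
        lines.append(
            f"- {locus}: {rep['n_sites_total']} diagnostic sites at level "
            f"'{rep['level']}', {rep['n_sites_query_informative']} scorable "
            f"in the query"
        )
        lines.append("")
        lines.append("  | group | agreements |")
        lines.append("  |-------|------------|")
        for g in rep["groups"]:
            lines.append(f"  | {g} | {rep['agreement'][g]} |")
        lines.append("")
        lines.append(f"  verdict: **{rep['verdict']}**")
    verdict = report.combined_verdict
    flag = " (loci disagree!)" if verdict == "conflicting" else ""
    lines += ["", f"## Combined verdict: **{verdict}**{flag}", ""]
    if report.distance_ranges:
        lines.append("## Uncorrected distance ranges between focal groups")
        for locus, d in report.distance_ranges.items():
            lines.append(
                f"- {locus} ({d['groups'][0]} vs {d['groups'][1]}): "
                f"{100 * d['min']:.1f}% - {100 * d['max']:.1f}%"
            )
        lines.append("")
    if any(report.trees.values()):
        lines.append("## Trees (Newick, bootstrap % on internal nodes)")
        for locus, nwk in report.trees.items():
            if nwk:
                lines.append(f"- {locus}: `{nwk}`")
        lines.append("")
    return "\n".join(lines)
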