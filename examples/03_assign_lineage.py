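"""Assign a partial consensus to a lineage via diagnostic positions.

Runs the whole pipeline in one call, then shows the per-lineage
agreement counts at alignment columns that are fixed within and
different between the two candidate lineages.
"""

from barcodefish import PipelineConfig, render_report, run_pipeline
from barcodefish.phylo import PhyloConfig
from barcodefish.simulate import SimConfig, write_run

paths = write_run(SimConfig(seed=7, loci=("16S",)), "example_sim")
report = run_pipeline(
    PipelineConfig(
        reads=paths["reads_fastq"],
        panel=paths["panel_fasta"],
        labels=paths["labels_tsv"],
        outdir="example_run",
        phylo=PhyloConfig(bootstrap_replicates=100),
        seed=7,
    )
)

print(render_report(report))
print(
    "The query reads were simulated from a lineage-1 member, so the "
    "verdict above should read L1: the consensus matches the L1 state at "
    "essentially every diagnostic column it covers."
)
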