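import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from barcodefish.core import LabelledSequence, ReferencePanel
from barcodefish.simulate import SimConfig, random_sequence, simulate_lineages

DATA = Path(__file__).parent.parent / "src" / "barcodefish" / "data"


@pytest.fixture(scope="session")
def measurements_path() -> Path:
    return DATA / "measurements.tsv"


@pytest.fixture(scope="session")
def localities_path() -> Path:
    return DATA / "localities.tsv"


@pytest.fixture(scope="session")
def sim_panel():
    """A deterministic two-lineage, one-locus panel plus its config."""
    cfg = SimConfig(seed=11, loci=("16S",))
    panel, tree = simulate_lineages(cfg)
    return cfg, panel, tree


@pytest.fixture()
def toy_panel() -> ReferencePanel:
    """Tiny hand-built two-lineage panel with known diagnostic columns."""
    seqs = [
        LabelledSequence(id="a1", residues="ACGTACGT", locus="16S",
                         species="sp1", lineage="L1", phylogroup="L1g1"),
        LabelledSequence(id="a2", residues="ACGTACGT", locus="16S",
                         species="sp1", lineage="L1", phylogroup="L1g2"),
        LabelledSequence(id="b1", residues="ATGTACCT", locus="16S",
                         species="sp2", lineage="L2", phylogroup="L2g1"),
        LabelledSequence(id="b2", residues="ATGTACCT", locus="16S",
                         species="sp2", lineage="L2", phylogroup="L2g1"),
    ]
    return ReferencePanel(loci={"16S": seqs})


@pytest.fixture(scope="session")
def random_reference() -> str:
    """A fixed 500-nt random reference for alignment tests."""
    rng = np.random.default_rng(20260920)
    return random_sequence(500, rng)
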