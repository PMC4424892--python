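import numpy as np
import pytest
from hypothesis import settings

from ersplice.models import GeneModel, TranscriptAnnotation, TranscriptModel

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


def make_gene(gene_id, chrom, strand, isoforms):
    """Build a GeneModel from {transcript_id: [(start, end), ...]}."""
    gene = GeneModel(gene_id, chrom, strand)
    for tid, exons in isoforms.items():
        gene.add_transcript(TranscriptModel(tid, gene_id, chrom, strand, exons))
    return gene


def make_annotation(*genes):
    return TranscriptAnnotation(genes={g.gene_id: g for g in genes})


@pytest.fixture(scope="session")
def four_isoform_toy():
    """Hand-built 4-isoform gene whose event list is enumerated manually.

    t1 = full backbone A,B,C,D; t2 skips B; t3 shortens B's donor side;
    t4 fuses B..C (retained intron) with a shifted acceptor.
    """
    gene = make_gene("TOY1", "chr1", "+", {
        "TOY1.t1": [(100, 200), (300, 400), (500, 600), (700, 800)],
        "TOY1.t2": [(100, 200), (500, 600), (700, 800)],
        "TOY1.t3": [(100, 200), (300, 450), (500, 600), (700, 800)],
        "TOY1.t4": [(100, 200), (300, 600), (700, 800)],
    })
    manual_events = {
        ("chr1", "+", "SE", (200, 300, 400, 500)),
        ("chr1", "+", "SE", (200, 300, 450, 500)),
        ("chr1", "+", "A5SS", (400, 450, 500)),
        ("chr1", "+", "A3SS", (200, 300, 500)),
        ("chr1", "+", "RI", (300, 400, 500, 600)),
        ("chr1", "+", "RI", (300, 450, 500, 600)),
    }
    return make_annotation(gene), manual_events


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small synthetic study (planted truth, default effects)."""
    from ersplice.synthetic import SimulationConfig, simulate

    return simulate(SimulationConfig(n_genes=40, seed=20240915))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
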