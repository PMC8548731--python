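"""Shared fixtures: session-scoped simulations and tiny hand-built objects."""

import numpy as np
import pytest

from lncm6a import call_peaks, differential_peaks, merge_peak_sets
from lncm6a.genome_model import Gene, GenomeAnnotation, Transcript
from lncm6a.syn_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One full simulation at default generator settings."""
    return simulate(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def default_peaks(default_sim):
    """Called peaks per condition plus differential records for default_sim."""
    wcm = default_sim.window_counts
    peaks = {c: call_peaks(wcm, c) for c in ("GM", "D4")}
    union = merge_peak_sets(*peaks.values())
    diffs = differential_peaks(union, wcm)
    return {"peaks": peaks, "union": union, "diffs": diffs}


def make_annotation(transcripts, gene_types=None):
    """Build an annotation from (gene_id, chrom, strand, exons) tuples."""
    gene_types = gene_types or {}
    genes, txs = [], []
    for gene_id, chrom, strand, exons in transcripts:
        exons = tuple(sorted(exons))
        genes.append(Gene(gene_id, gene_id,
                          gene_types.get(gene_id, "lincRNA"),
                          chrom, strand, exons[0][0], exons[-1][1]))
        txs.append(Transcript(f"{gene_id}.T1", gene_id, chrom, strand, exons))
    return GenomeAnnotation(genes, txs)


@pytest.fixture
def three_exon_plus():
    return make_annotation([("G1", "chr1", "+",
                             [(100, 200), (300, 400), (500, 600)])])


@pytest.fixture
def rng():
    return np.random.default_rng(7)
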