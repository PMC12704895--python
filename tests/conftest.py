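"""Shared fixtures: a small reference design and simulations built from it."""

import pytest

import splitpool as sp
from splitpool import synth


@pytest.fixture(scope="session")
def scheme():
    """The default 3-round / 96-well design (4-nt barcodes, 8-nt linkers)."""
    return sp.default_scheme()


@pytest.fixture(scope="session")
def transcriptome():
    return synth.make_transcriptome(
        n_genes_per_species=40, length_range=(300, 700), intron_fraction_of_genes=0.5, seed=11
    )


@pytest.fixture(scope="session")
def clean_sim(scheme, transcriptome):
    """Error-free, frameshift-free simulation (collisions possible but rare)."""
    cells = synth.draw_cells(
        60, 0.7, scheme, seed=21, genes=transcriptome, reads_per_cell_mean=80
    )
    sim = synth.simulate_reads(
        cells, transcriptome, scheme, error_rate=0.0, frameshift_rate=0.0, seed=22
    )
    return sim


@pytest.fixture(scope="session")
def gene_index(transcriptome):
    from splitpool import quantify

    return quantify.build_index(transcriptome, k=31)


@pytest.fixture(scope="session")
def clean_reads(clean_sim, scheme, gene_index):
    """Read-level records (barcode, gene, category, umi) of the clean simulation."""
    from splitpool import demux, quantify

    calls, _ = demux.demux_reads(clean_sim.read2, scheme)
    hits = quantify.assign_reads(clean_sim.read1, gene_index)
    return quantify.join_reads(calls, hits)
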