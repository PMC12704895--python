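"""Gene assignment, UMI collapse, count tables, and depth subsampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitpool import quantify
from splitpool.quantify import (
    CountTable,
    assign_read,
    build_index,
    collapse_umis,
    intronic_fraction,
    make_count_table,
    subsample_reads,
)
from splitpool.synth import SyntheticGene


def _gene(gene_id, pre, exons):
    return SyntheticGene(gene_id=gene_id, pre_mrna=pre, exons=tuple(exons))


class TestBuildIndex:
    def test_disjoint_genes_have_no_ambiguity(self, gene_index):
        # distinct random transcriptome: sharing a 31-mer is essentially impossible
        assert gene_index.n_ambiguous == 0

    def test_duplicated_gene_is_fully_ambiguous(self):
        seq = "ACGTACGGTTCAGGCAT" * 4
        genes = [
            _gene("HS_A", seq, [(0, len(seq))]),
            _gene("HS_B", seq, [(0, len(seq))]),
        ]
        idx = build_index(genes, k=20)
        assert idx.n_ambiguous == len(idx.lookup)

    def test_small_k_refused(self, transcriptome):
        with pytest.raises(ValueError):
            build_index(transcriptome, k=11)

    def test_first_kmer_lookup_recovers_source_gene(self, clean_sim, gene_index):
        truth = clean_sim.truth.reads.set_index("read_id")
        for read_id, seq in clean_sim.read1[:200]:
            a = assign_read(seq, gene_index)
            assert a.gene_id == truth.loc[read_id, "gene_id"]


class TestAssignRead:
    def test_exon_intron_categories_match_truth(self, clean_sim, gene_index):
        truth = clean_sim.truth.reads.set_index("read_id")
        for read_id, seq in clean_sim.read1:
            a = assign_read(seq, gene_index)
            assert a.mapped
            assert (a.category == "intron") == bool(truth.loc[read_id, "intronic"])

    def test_random_absent_kmer_unmapped(self, gene_index, transcriptome):
        rng = np.random.default_rng(99)
        while True:
            probe = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            # brute-force absence check across the whole transcriptome
            if not any(
                probe[:31] in g.pre_mrna or probe[:31] in g.mature
                for g in transcriptome
            ):
                break
        assert assign_read(probe, gene_index).category == "unmapped"


class TestCollapseUmis:
    def test_exact_mode_counts_distinct(self):
        assert collapse_umis(["AAAA", "AAAA", "AAAT"], 0) == 2

    def test_hamming_one_merges_neighbors(self):
        assert collapse_umis(["AAAA", "AAAA", "AAAT"], 1) == 1

    def test_empty(self):
        assert collapse_umis([], 0) == 0

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            collapse_umis(["AAA", "AAAA"], 0)

    @settings(max_examples=40, deadline=None)
    @given(
        umis=st.lists(
            st.text(alphabet="ACGT", min_size=4, max_size=4), min_size=1, max_size=60
        ),
        h=st.integers(0, 2),
    )
    def test_matches_networkx_connected_components(self, umis, h):
        import networkx as nx

        g = nx.Graph()
        distinct = sorted(set(umis))
        g.add_nodes_from(distinct)
        for a, b in itertools.combinations(distinct, 2):
            if sum(x != y for x, y in zip(a, b)) <= h:
                g.add_edge(a, b)
        assert collapse_umis(umis, h) == nx.number_connected_components(g)


class TestMakeCountTable:
    def test_clean_simulation_totals_match_truth(self, clean_sim, clean_reads):
        table = make_count_table(clean_reads)
        truth = clean_sim.truth
        path_of = dict(zip(truth.cells.cell_id, truth.cells.well_path))
        truth_per_bc = (
            truth.reads.assign(barcode=truth.reads.cell_id.map(path_of))
            .groupby("barcode")
            .size()
        )
        got = table.counts_per_barcode(layer="inex", unit="reads")
        assert sorted(got.index) == sorted(truth_per_bc.index)
        for bc in got.index:
            assert got[bc] == truth_per_bc[bc]

    def test_species_of_counted_genes_match_truth(self, clean_sim, clean_reads):
        species_of = dict(
            zip(clean_sim.truth.cells.well_path, clean_sim.truth.cells.species)
        )
        # collision-free subset: barcodes used by exactly one cell
        counts = clean_sim.truth.cells.well_path.value_counts()
        singles = set(counts.index[counts == 1])
        for _i, row in clean_reads.iterrows():
            if row.barcode in singles:
                expected = "HS_" if species_of[row.barcode] == "human" else "MM_"
                assert row.gene_id.startswith(expected)

    def test_umi_read_arithmetic(self):
        reads = pd.DataFrame(
            {
                "barcode": ["b"] * 5,
                "gene_id": ["HS_G"] * 5,
                "category": ["exon"] * 5,
                "umi": ["AAAA", "AAAA", "AAAA", "CCCC", "CCCC"],
            }
        )
        t = make_count_table(reads)
        assert t.reads["exon"][0, 0] == 5
        assert t.umis["exon"][0, 0] == 2

    def test_empty_input_empty_table(self):
        t = make_count_table(pd.DataFrame(columns=["barcode", "gene_id", "category", "umi"]))
        assert t.shape == (0, 0)

    def test_inex_bounds_hold_everywhere(self, clean_reads):
        t = make_count_table(clean_reads, umi_hamming=1)
        exon = t.umis["exon"].toarray()
        intron = t.umis["intron"].toarray()
        inex = t.umis["inex"].toarray()
        assert (inex >= np.maximum(exon, intron)).all()
        assert (inex <= exon + intron).all()
        assert (t.umis["inex"].toarray() <= t.reads["inex"].toarray()).all()

    def test_inex_union_collapses_shared_molecules(self):
        # same UMI seen as exon and intron: one molecule in the union layer
        reads = pd.DataFrame(
            {
                "barcode": ["b", "b"],
                "gene_id": ["HS_G", "HS_G"],
                "category": ["exon", "intron"],
                "umi": ["ACGT", "ACGT"],
            }
        )
        t = make_count_table(reads)
        assert t.umis["exon"][0, 0] == 1
        assert t.umis["intron"][0, 0] == 1
        assert t.umis["inex"][0, 0] == 1
        assert t.reads["inex"][0, 0] == 2


class TestSubsample:
    def test_depth_equal_to_total_is_identity(self, clean_reads):
        bc = clean_reads["barcode"].value_counts().index[0]
        sub = clean_reads[clean_reads.barcode == bc]
        t_full = make_count_table(sub)
        t_sub = subsample_reads(sub, depth=len(sub), seed=1)
        assert (
            t_full.reads["inex"].toarray() == t_sub.reads["inex"].toarray()
        ).all()

    def test_every_retained_barcode_at_exact_depth(self, clean_reads):
        depth = 30
        t = subsample_reads(clean_reads, depth=depth, seed=2)
        totals = t.counts_per_barcode(layer="inex", unit="reads")
        assert len(totals) > 0
        assert (totals == depth).all()
        # under-depth barcodes are excluded
        eligible = (clean_reads["barcode"].value_counts() >= depth).sum()
        assert len(totals) == eligible

    def test_gene_detection_monotone_under_nested_draws(self, clean_reads):
        t1 = subsample_reads(clean_reads, depth=15, seed=3)
        t2 = subsample_reads(clean_reads, depth=40, seed=3)
        g1 = t1.genes_per_barcode()
        g2 = t2.genes_per_barcode()
        shared = g1.index.intersection(g2.index)
        assert len(shared) > 0
        assert (g1[shared] <= g2[shared]).all()


class TestIntronicFraction:
    def test_boundary_values(self):
        reads = pd.DataFrame(
            {
                "barcode": ["all_ex"] * 2 + ["all_in"] * 2 + ["mix"] * 4,
                "gene_id": ["HS_G"] * 8,
                "category": ["exon"] * 2 + ["intron"] * 2 + ["intron"] * 3 + ["exon"],
                "umi": ["AAAA", "CCCC", "AAAA", "CCCC", "AAAA", "CCCC", "GGGG", "TTTT"],
            }
        )
        frac = intronic_fraction(make_count_table(reads))
        assert frac["all_ex"] == 0.0
        assert frac["all_in"] == 1.0
        assert frac["mix"] == 0.75
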