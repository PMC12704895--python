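"""Build layered count tables from simulated reads and subsample to a depth.

Shows the exon/intron/inex UMI layers, the per-barcode intronic
fraction, and depth-matched subsampling.
"""

import splitpool as sp
from splitpool import demux, quantify, synth

scheme = sp.default_scheme()
genes = synth.make_transcriptome(n_genes_per_species=50, seed=1)
cells = synth.draw_cells(80, 0.7, scheme, seed=2, genes=genes, reads_per_cell_mean=120)
sim = synth.simulate_reads(cells, genes, scheme, intronic_read_fraction=0.25, seed=3)

calls, _ = demux.demux_reads(sim.read2, scheme)
index = quantify.build_index(genes, k=31)
hits = quantify.assign_reads(sim.read1, index)
reads = quantify.join_reads(calls, hits)
table = quantify.make_count_table(reads)

print(f"count table: {table.shape[0]} barcodes x {table.shape[1]} genes")
for layer in ("exon", "intron", "inex"):
    print(f"  {layer:6s} UMIs total: {table.umis[layer].sum():,}")

frac = quantify.intronic_fraction(table)
print(f"median per-barcode intronic UMI fraction: {frac.median():.3f}")

# depth-matched comparison: every retained barcode at exactly 50 reads
sub = quantify.subsample_reads(reads, depth=50, seed=7)
per_bc, medians = sp.sensitivity_at_depth(sub)
print(f"\nat 50 reads/barcode ({sub.shape[0]} barcodes retained):")
print(f"  median genes: {medians['median_genes']:.0f}")
print(f"  median UMIs:  {medians['median_umis']:.0f}")
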