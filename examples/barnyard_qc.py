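"""Barnyard QC: gene filter, species classification, saturation curve.

Classifies each barcode as human, mouse, or multiplet by the strict
>90% rule after the gene-count filter, and computes the cumulative
gene-detection curve from 1 to 20 sampled barcodes.
"""

import splitpool as sp
from splitpool import demux, qc, quantify, synth

scheme = sp.default_scheme()
genes = synth.make_transcriptome(n_genes_per_species=50, seed=1)
cells = synth.draw_cells(120, 0.7, scheme, seed=2, genes=genes, reads_per_cell_mean=150)
sim = synth.simulate_reads(cells, genes, scheme, seed=3)

calls, _ = demux.demux_reads(sim.read2, scheme)
index = quantify.build_index(genes, k=31)
reads = quantify.join_reads(calls, quantify.assign_reads(sim.read1, index))
table = quantify.make_count_table(reads)

filtered = qc.filter_barcodes(table, min_genes=20)  # small synthetic run
species = qc.classify_species(filtered, threshold=0.9, unit="umis")
print(f"{len(filtered.barcodes)}/{len(table.barcodes)} barcodes pass the gene filter")
print(species["call"].value_counts().to_string())
print(f"multiplet rate: {qc.multiplet_rate(species):.4f}")
print("(multiplets here are barcode collisions: two cells sharing a well path)")

curve = qc.cumulative_gene_curve(filtered, k_max=20, reps=50, seed=4)
print("\ncumulative genes detected (mean over 50 nested samplings):")
for k in (1, 5, 10, 20):
    print(f"  {k:2d} barcodes -> {curve.mean_genes[k - 1]:.1f} genes")
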