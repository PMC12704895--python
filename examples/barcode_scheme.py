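"""Model a split-pool barcode design and assemble a barcoded molecule.

Prints the combination spaces of the common designs, the segment layout
of the default 3-round read, and one assembled construct.
"""

import splitpool as sp
from splitpool.scheme import RoundSpec, WellPath, random_whitelist

# combination space = product of wells over rounds
for wells in ([384, 384], [96, 96], [96, 96, 96], [96, 96, 96, 96]):
    rounds = tuple(
        RoundSpec(r, random_whitelist(n, 6 if n > 256 else 4, seed=900 + r))
        for r, n in enumerate(wells)
    )
    kwargs = dict(n_reads_for_barcodes=2, read2_rounds=2) if len(wells) == 4 else {}
    scheme = sp.BarcodeScheme(rounds=rounds, **kwargs)
    print(f"{'x'.join(map(str, wells))} wells -> {scheme.combination_count():,} combinations")

# the default design: 3 rounds x 96 wells, 4-nt barcodes, 8-nt linkers,
# 28-nt constant prefix, 8-nt UMI -> a 64-nt barcode read
scheme = sp.default_scheme()
layout = sp.read_layout(scheme)
print(f"\nbarcode read span: {layout.span} nt")
for name, s, e in layout.segments:
    print(f"  {name:10s} [{s:3d}, {e:3d})")

# assemble one molecule for the cell that visited wells 3 -> 41 -> 7
construct = sp.assemble_construct(scheme, WellPath((3, 41, 7)), "ACGTACGT", "A" * 50)
print(f"\nconstruct ({len(construct)} nt): {construct[:64]}...")
print("the first 64 nt above are exactly what the barcode read sequences")
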