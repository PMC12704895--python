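"""Barcode-collision expectations: closed form vs Monte-Carlo.

For n cells over B combinations the per-cell collision probability is
1 - (1 - 1/B)^(n-1); the simulation also reports the multiplet rate
among a sequenced subsample under both denominators.
"""

from splitpool.collision import (
    CollisionDesign,
    expected_collision_fraction,
    expected_collision_pairs,
    simulate_multiplet_rate,
)

# two 384-well rounds, 8,000 cells: the ~5% regime
B, n = 384 * 384, 8_000
est = simulate_multiplet_rate(CollisionDesign(B=B, n=n, reps=200, seed=1))
print(f"B={B:,} n={n:,}")
print(f"  analytic per-cell collision fraction: {expected_collision_fraction(B, n):.4f}")
print(f"  simulated: {est.per_cell_rate:.4f} +/- {est.per_cell_se:.4f} (200 reps)")

# four 96-well rounds, 400,000 cells barcoded, 16,450 sequenced
B4, n4, s4 = 96**4, 400_000, 16_450
est4 = simulate_multiplet_rate(CollisionDesign(B=B4, n=n4, s=s4, reps=200, seed=1))
print(f"\nB={B4:,} n={n4:,} s={s4:,}")
print(f"  expected same-combination pairs among sequenced: "
      f"{expected_collision_pairs(B4, n4, s4):.2f}")
print(f"  simulated multiplet rate per sequenced barcode: "
      f"{est4.per_barcode_rate * 100:.4f}% +/- {est4.per_barcode_se * 100:.4f}%")
print(f"  simulated multiplet rate per sequenced cell:    "
      f"{est4.per_cell_rate * 100:.4f}%")
print("the combinatorial rate bounds the observed multiplet rate from below:")
print("observed rates also include physical doublets and ambient RNA")
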