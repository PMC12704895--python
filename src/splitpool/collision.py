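"""Barcode-collision model for split-pool designs.

With ``n`` cells assigned uniformly at random over ``B`` barcode
combinations (the birthday problem), the probability that a given cell
shares its combination with at least one other cell is

    p_collision = 1 - (1 - 1/B)^(n-1),

and among ``s`` cells subsampled for sequencing the expected number of
same-combination pairs is ``C(s, 2) / B``.  Monte-Carlo simulation
reports the multiplet rate under both denominators the field uses:
per sequenced *barcode* (combinations carrying >= 2 sampled cells over
combinations observed) and per sequenced *cell* (cells in shared
combinations over s), with standard errors over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CollisionDesign",
    "MultipletEstimate",
    "expected_collision_fraction",
    "expected_collision_pairs",
    "simulate_multiplet_rate",
]


@dataclass(frozen=True)
class CollisionDesign:
    """B combinations, n barcoded cells, s sequenced (s <= n)."""

    B: int
    n: int
    s: int | None = None
    reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        s = self.n if self.s is None else self.s
        if not 0 <= s <= self.n:
            raise ValueError("need 0 <= s <= n")
        object.__setattr__(self, "s", s)
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def expected_collision_fraction(B: int, n: int) -> float:
    """P(a given cell shares its combination with >= 1 of the other n-1)."""
    if B < 1 or n < 1:
        raise ValueError("B and n must be >= 1")
    return 1.0 - (1.0 - 1.0 / B) ** (n - 1)


def expected_collision_pairs(B: int, n: int, s: int | None = None) -> float:
    """Expected same-combination pairs among the s sequenced cells."""
    s = n if s is None else s
    if not 0 <= s <= n:
        raise ValueError("need 0 <= s <= n")
    return math.comb(s, 2) / B


@dataclass(frozen=True)
class MultipletEstimate:
    per_barcode_rate: float
    per_barcode_se: float
    per_cell_rate: float
    per_cell_se: float
    reps: int

    def to_dict(self) -> dict[str, float]:
        return {
            "per_barcode_rate": self.per_barcode_rate,
            "per_barcode_se": self.per_barcode_se,
            "per_cell_rate": self.per_cell_rate,
            "per_cell_se": self.per_cell_se,
            "reps": self.reps,
        }


def simulate_multiplet_rate(design: CollisionDesign) -> MultipletEstimate:
    """Monte-Carlo multiplet rates under uniform well assignment.

    Per replicate: assign ``n`` cells uniformly over ``B`` combinations,
    sample ``s`` of them without replacement, and count sequenced
    combinations carrying >= 2 sampled cells.  Seed-reproducible.
    """
    rng = np.random.default_rng(design.seed)
    s = design.s
    assert s is not None
    per_bc = np.empty(design.reps)
    per_cell = np.empty(design.reps)
    for r in range(design.reps):
        combos = rng.integers(0, design.B, size=design.n)
        if s < design.n:
            sampled = combos[rng.choice(design.n, size=s, replace=False)]
        else:
            sampled = combos
        if s == 0:
            per_bc[r] = per_cell[r] = 0.0
            continue
        _uniq, counts = np.unique(sampled, return_counts=True)
        per_bc[r] = (counts >= 2).sum() / counts.size
        per_cell[r] = counts[counts >= 2].sum() / s
    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    return MultipletEstimate(
        per_barcode_rate=float(per_bc.mean()),
        per_barcode_se=se(per_bc),
        per_cell_rate=float(per_cell.mean()),
        per_cell_se=se(per_cell),
        reps=design.reps,
    )
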