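"""Barnyard QC and sensitivity metrics.

Implements the standard mixed-species quality checks for split-pool
data: gene-count filtering (strictly more than ``min_genes`` detected
genes), species classification of each barcode (human or mouse only
when that species contributes strictly more than the threshold —
default 90% — of its counts, otherwise multiplet), the multiplet rate
among filtered barcodes, per-barcode genes/UMIs at a matched read
depth, and cumulative gene-detection (saturation) curves over
increasing numbers of sampled barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import CountTable
from .synth import HUMAN_PREFIX, MOUSE_PREFIX

__all__ = [
    "SaturationCurve",
    "FILTER_PRESETS",
    "filter_barcodes",
    "classify_species",
    "multiplet_rate",
    "sensitivity_at_depth",
    "cumulative_gene_curve",
]

#: Named min-gene presets for the gene-count filter (strict >).
FILTER_PRESETS = {
    "barnyard": 400,
    "joint": 500,
    "nuclei": 200,
    "maize_root": 120,
    "maize_shoot": 400,
}


def filter_barcodes(
    table: CountTable, min_genes: int, layer: str = "inex", unit: str = "umis"
) -> CountTable:
    """Keep barcodes with strictly more than ``min_genes`` detected genes."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    genes = table.genes_per_barcode(layer=layer, unit=unit)
    keep = genes.index[genes > min_genes].tolist()
    return table.subset_barcodes(keep)


def classify_species(
    table: CountTable,
    threshold: float = 0.9,
    unit: str = "umis",
    layer: str = "inex",
) -> pd.DataFrame:
    """Per-barcode species call from species-prefixed gene ids.

    A barcode is ``human`` (``mouse``) only when that species
    contributes strictly more than ``threshold`` of its counts;
    otherwise it is a ``multiplet``.  Returns barcode, human_fraction,
    mouse_fraction, call.
    """
    m = table.matrix(layer=layer, unit=unit)
    is_human = np.array([g.startswith(HUMAN_PREFIX) for g in table.genes])
    is_mouse = np.array([g.startswith(MOUSE_PREFIX) for g in table.genes])
    human = np.asarray(m[:, is_human].sum(axis=1)).ravel().astype(float)
    mouse = np.asarray(m[:, is_mouse].sum(axis=1)).ravel().astype(float)
    total = np.asarray(m.sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        hf = np.where(total > 0, human / total, 0.0)
        mf = np.where(total > 0, mouse / total, 0.0)
    call = np.where(hf > threshold, "human", np.where(mf > threshold, "mouse", "multiplet"))
    return pd.DataFrame(
        {
            "barcode": table.barcodes,
            "human_fraction": hf,
            "mouse_fraction": mf,
            "call": call,
        }
    )


def multiplet_rate(calls: pd.DataFrame) -> float:
    """Fraction of (filter-passing) barcodes called multiplet."""
    if calls.empty:
        raise ValueError("no species calls to summarize")
    return float((calls["call"] == "multiplet").mean())


def sensitivity_at_depth(
    table: CountTable, layer: str = "inex"
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-barcode genes and UMIs of a depth-matched table, plus medians."""
    genes = table.genes_per_barcode(layer=layer, unit="umis")
    umis = table.counts_per_barcode(layer=layer, unit="umis")
    per_barcode = pd.DataFrame({"genes": genes, "umis": umis})
    medians = {
        "median_genes": float(genes.median()),
        "median_umis": float(umis.median()),
    }
    return per_barcode, medians


@dataclass(frozen=True)
class SaturationCurve:
    """Mean cumulative genes detected over k sampled barcodes, k = 1..k_max."""

    k: np.ndarray
    mean_genes: np.ndarray
    reps: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "mean_genes": self.mean_genes})


def cumulative_gene_curve(
    table: CountTable,
    k_max: int,
    reps: int = 50,
    seed: int = 0,
    nested: bool = True,
    layer: str = "inex",
    unit: str = "umis",
) -> SaturationCurve:
    """Mean size of the union of detected genes across k sampled barcodes.

    Sampling is without replacement.  With ``nested=True`` (default)
    each replicate draws one permutation of the barcodes and uses its
    prefixes for k = 1..k_max, so the curve is non-decreasing within
    every replicate; ``nested=False`` redraws independently per k.
    """
    n_bc = len(table.barcodes)
    if not 1 <= k_max <= n_bc:
        raise ValueError(f"k_max must be in [1, {n_bc}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    detected = (table.matrix(layer=layer, unit=unit) > 0).toarray()
    rng = np.random.default_rng(seed)
    total = np.zeros(k_max, dtype=float)
    for _ in range(reps):
        if nested:
            perm = rng.permutation(n_bc)[:k_max]
            cum = np.cumsum(detected[perm], axis=0) > 0
            total += cum.sum(axis=1)
        else:
            for k in range(1, k_max + 1):
                pick = rng.choice(n_bc, size=k, replace=False)
                total[k - 1] += detected[pick].any(axis=0).sum()
    return SaturationCurve(
        k=np.arange(1, k_max + 1), mean_genes=total / reps, reps=reps
    )
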