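"""Gene assignment, UMI collapse, and layered count tables.

Reads are assigned to genes of the synthetic transcriptome with an
exact first-k-mer lookup (``k = 31`` by default) under a unique-gene
requirement; a read is *intronic* when its span on the pre-mRNA
overlaps at least one intronic base, else *exonic*.  Molecules are
counted by collapsing UMIs within each (barcode, gene): connected
components of the graph joining UMIs at Hamming distance <= ``h``
(``h = 0``, the default, is simply the number of distinct UMI strings).
The resulting :class:`CountTable` carries read and UMI counts in three
layers — ``exon``, ``intron`` and ``inex`` (their union: a molecule is
counted once if seen in either) — and supports seeded, nested
subsampling of every barcode to a fixed read depth for depth-matched
sensitivity comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .scheme import hamming
from .synth import SyntheticGene

__all__ = [
    "GeneIndex",
    "ReadAssignment",
    "CountTable",
    "build_index",
    "assign_read",
    "assign_reads",
    "collapse_umis",
    "join_reads",
    "make_count_table",
    "subsample_reads",
    "intronic_fraction",
]

LAYERS = ("exon", "intron", "inex")

UNMAPPED = "unmapped"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    gene_id: str | None
    category: str  # 'exon' | 'intron' | 'unmapped' | 'ambiguous'

    @property
    def mapped(self) -> bool:
        return self.category in ("exon", "intron")


@dataclass
class GeneIndex:
    """Exact k-mer lookup over the synthetic transcriptome.

    Every length-``k`` substring of every pre-mRNA and mature sequence
    is indexed to ``(gene_id, offset, source)``; k-mers shared across
    genes are recorded as ambiguous.
    """

    k: int
    lookup: dict[str, tuple[tuple[str, int, str], ...]]
    genes: dict[str, SyntheticGene]

    @property
    def n_ambiguous(self) -> int:
        return sum(
            1
            for hits in self.lookup.values()
            if len({g for g, _o, _s in hits}) > 1
        )


def build_index(genes: Sequence[SyntheticGene], k: int = 31) -> GeneIndex:
    """Index every pre-mRNA and mature k-mer of the transcriptome."""
    if k < 12:
        raise ValueError(f"k={k} would explode ambiguity; use k >= 12")
    shortest = min(min(len(g.mature), len(g.pre_mrna)) for g in genes)
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest transcript ({shortest} nt)")
    lookup: dict[str, list[tuple[str, int, str]]] = {}
    for g in genes:
        for source, seq in (("pre", g.pre_mrna), ("mature", g.mature)):
            for off in range(len(seq) - k + 1):
                lookup.setdefault(seq[off : off + k], []).append((g.gene_id, off, source))
    return GeneIndex(
        k=k,
        lookup={kmer: tuple(hits) for kmer, hits in lookup.items()},
        genes={g.gene_id: g for g in genes},
    )


def assign_read(cdna: str, index: GeneIndex) -> ReadAssignment:
    """Assign one cDNA read by its first k-mer (unique-gene requirement).

    Category resolution for the hit gene: if the full read matches the
    mature transcript at a candidate offset it is exonic; else if it
    matches the pre-mRNA it is intronic when the span overlaps an
    intron, exonic otherwise; with substitution errors the candidate
    location of minimal Hamming distance decides.
    """
    if len(cdna) < index.k:
        return ReadAssignment("", None, UNMAPPED)
    hits = index.lookup.get(cdna[: index.k])
    if hits is None:
        return ReadAssignment("", None, UNMAPPED)
    gene_ids = {g for g, _o, _s in hits}
    if len(gene_ids) > 1:
        return ReadAssignment("", None, AMBIGUOUS)
    gene_id = next(iter(gene_ids))
    gene = index.genes[gene_id]
    n = len(cdna)

    def category_at(off: int, source: str) -> str:
        if source == "mature":
            return "exon"
        return "intron" if gene.span_overlaps_intron(off, off + n) else "exon"

    # exact full-length match first (mature preferred: no intronic bases)
    for preferred in ("mature", "pre"):
        for g, off, source in hits:
            if source != preferred:
                continue
            seq = gene.mature if source == "mature" else gene.pre_mrna
            if seq[off : off + n] == cdna:
                return ReadAssignment("", gene_id, category_at(off, source))
    # substitution errors downstream of the seed: nearest candidate wins
    best_d, best_cat = n + 1, "exon"
    for g, off, source in hits:
        seq = gene.mature if source == "mature" else gene.pre_mrna
        window = seq[off : off + n]
        if len(window) < n:
            continue
        d = hamming(window, cdna)
        if d < best_d:
            best_d, best_cat = d, category_at(off, source)
    return ReadAssignment("", gene_id, best_cat)


def assign_reads(
    reads: Iterable[tuple[str, str]], index: GeneIndex
) -> pd.DataFrame:
    """Assign a stream of (read_id, cdna) pairs; returns read_id, gene_id, category."""
    rows = []
    for read_id, seq in reads:
        a = assign_read(seq, index)
        rows.append((read_id, a.gene_id, a.category))
    return pd.DataFrame(rows, columns=["read_id", "gene_id", "category"])


def collapse_umis(umis: Sequence[str], max_hamming: int = 0) -> int:
    """Number of molecules: connected components at Hamming <= max_hamming.

    With ``max_hamming = 0`` this is the number of distinct UMI strings.
    """
    if not umis:
        return 0
    lengths = {len(u) for u in umis}
    if len(lengths) != 1:
        raise ValueError(f"UMIs of mixed length: {sorted(lengths)}")
    distinct = sorted(set(umis))
    if max_hamming == 0:
        return len(distinct)
    # union-find over distinct sequences
    parent = list(range(len(distinct)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            if hamming(distinct[i], distinct[j]) <= max_hamming:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(len(distinct))})


@dataclass
class CountTable:
    """Barcode x gene counts: read and UMI values in exon/intron/inex layers.

    ``reads[layer]`` and ``umis[layer]`` are CSR matrices of shape
    (n_barcodes, n_genes); for every entry
    ``inex >= max(exon, intron)`` and ``inex <= exon + intron``.
    """

    barcodes: list[str]
    genes: list[str]
    reads: dict[str, sp.csr_matrix]
    umis: dict[str, sp.csr_matrix]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.barcodes), len(self.genes)

    def matrix(self, layer: str = "inex", unit: str = "umis") -> sp.csr_matrix:
        store = self.umis if unit == "umis" else self.reads
        return store[layer]

    def genes_per_barcode(self, layer: str = "inex", unit: str = "umis") -> pd.Series:
        m = self.matrix(layer, unit)
        n = np.asarray((m > 0).sum(axis=1)).ravel()
        return pd.Series(n, index=self.barcodes, name="genes")

    def counts_per_barcode(self, layer: str = "inex", unit: str = "umis") -> pd.Series:
        m = self.matrix(layer, unit)
        return pd.Series(np.asarray(m.sum(axis=1)).ravel(), index=self.barcodes, name=unit)

    def subset_barcodes(self, keep: Sequence[str]) -> "CountTable":
        order = {b: i for i, b in enumerate(self.barcodes)}
        idx = [order[b] for b in keep]
        return CountTable(
            barcodes=list(keep),
            genes=list(self.genes),
            reads={l: m[idx] for l, m in self.reads.items()},
            umis={l: m[idx] for l, m in self.umis.items()},
        )

    def to_anndata(self, unit: str = "umis"):
        """AnnData with X = inex and exon/intron layers, barcodes as obs."""
        import anndata as ad

        store = self.umis if unit == "umis" else self.reads
        return ad.AnnData(
            X=store["inex"].copy(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene_id")),
            layers={"exon": store["exon"].copy(), "intron": store["intron"].copy()},
        )

    def write_mtx(self, out_dir: str | Path) -> None:
        """MatrixMarket triplet per layer/unit, with barcode and gene sidecars."""
        from scipy.io import mmwrite

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "barcodes.tsv").write_text("\n".join(self.barcodes) + "\n")
        (out_dir / "genes.tsv").write_text("\n".join(self.genes) + "\n")
        for unit, store in (("reads", self.reads), ("umis", self.umis)):
            for layer, m in store.items():
                mmwrite(str(out_dir / f"{layer}_{unit}.mtx"), sp.coo_matrix(m))


def join_reads(calls: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Join demux calls with gene assignments into read-level records.

    Keeps reads with an assigned barcode (status ok or
    frameshift_recovered) and a unique mapped gene.
    """
    merged = calls.merge(assignments, on="read_id", how="inner")
    keep = merged["status"].isin(["ok", "frameshift_recovered"]) & merged[
        "category"
    ].isin(["exon", "intron"])
    return merged.loc[
        keep, ["read_id", "barcode", "umi", "gene_id", "category"]
    ].reset_index(drop=True)


def make_count_table(reads: pd.DataFrame, umi_hamming: int = 0) -> CountTable:
    """Tally read-level records into a layered CountTable.

    ``reads`` columns: barcode, gene_id, category ('exon'|'intron'), umi.
    UMI counts collapse per (barcode, gene) within each layer; the inex
    molecule count collapses the union of both layers' UMI lists.
    """
    if reads.empty:
        empty = sp.csr_matrix((0, 0), dtype=np.int64)
        return CountTable([], [], {l: empty.copy() for l in LAYERS},
                          {l: empty.copy() for l in LAYERS})
    barcodes = sorted(reads["barcode"].unique())
    genes = sorted(reads["gene_id"].unique())
    b_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: i for i, g in enumerate(genes)}
    rows: dict[str, dict[str, list]] = {
        unit: {l: [[], [], []] for l in LAYERS} for unit in ("reads", "umis")
    }

    def push(unit: str, layer: str, bi: int, gi: int, val: int) -> None:
        r, c, v = rows[unit][layer]
        if val:
            r.append(bi)
            c.append(gi)
            v.append(val)

    for (bc, gene), grp in reads.groupby(["barcode", "gene_id"], sort=False):
        bi, gi = b_idx[bc], g_idx[gene]
        exon_umis = grp.loc[grp["category"] == "exon", "umi"].tolist()
        intron_umis = grp.loc[grp["category"] == "intron", "umi"].tolist()
        push("reads", "exon", bi, gi, len(exon_umis))
        push("reads", "intron", bi, gi, len(intron_umis))
        push("reads", "inex", bi, gi, len(exon_umis) + len(intron_umis))
        push("umis", "exon", bi, gi, collapse_umis(exon_umis, umi_hamming))
        push("umis", "intron", bi, gi, collapse_umis(intron_umis, umi_hamming))
        push("umis", "inex", bi, gi, collapse_umis(exon_umis + intron_umis, umi_hamming))

    shape = (len(barcodes), len(genes))

    def to_csr(unit: str, layer: str) -> sp.csr_matrix:
        r, c, v = rows[unit][layer]
        return sp.csr_matrix(
            (np.asarray(v, dtype=np.int64), (r, c)), shape=shape
        )

    return CountTable(
        barcodes=barcodes,
        genes=genes,
        reads={l: to_csr("reads", l) for l in LAYERS},
        umis={l: to_csr("umis", l) for l in LAYERS},
    )


def subsample_reads(
    reads: pd.DataFrame, depth: int, seed: int = 0, umi_hamming: int = 0
) -> CountTable:
    """Subsample every barcode to exactly ``depth`` reads and re-tally.

    Barcodes with fewer than ``depth`` reads are excluded (depth-matched
    per-barcode comparisons).  Draws are without replacement via a
    seeded per-barcode permutation whose first ``depth`` elements are
    taken, so draws at increasing depths under one seed are nested and
    gene detection is monotone in depth by construction.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    kept = []
    barcodes = sorted(reads["barcode"].unique())
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(barcodes))
    for bc, child in zip(barcodes, children):
        grp = reads[reads["barcode"] == bc]
        if len(grp) < depth:
            continue
        rng = np.random.default_rng(child)
        order = rng.permutation(len(grp))[:depth]
        kept.append(grp.iloc[np.sort(order)])
    if not kept:
        return make_count_table(reads.iloc[0:0], umi_hamming)
    return make_count_table(pd.concat(kept, ignore_index=True), umi_hamming)


def intronic_fraction(table: CountTable, unit: str = "umis") -> pd.Series:
    """Per-barcode intron / (intron + exon) counts; NaN when the denominator is 0."""
    store = table.umis if unit == "umis" else table.reads
    intron = np.asarray(store["intron"].sum(axis=1)).ravel().astype(float)
    exon = np.asarray(store["exon"].sum(axis=1)).ravel().astype(float)
    denom = intron + exon
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, intron / denom, np.nan)
    return pd.Series(frac, index=table.barcodes, name="intronic_fraction")
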