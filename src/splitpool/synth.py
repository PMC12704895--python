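"""Synthetic two-species transcriptome, cells, and barcoded read pairs.

The generator emulates a barnyard (mixed human + mouse) split-pool
experiment end-to-end and emits exact ground truth for every read, so
the demultiplexer and quantifier can be audited read-by-read.  It
models:

* a small two-species transcriptome with species-prefixed gene ids
  (``HS_`` / ``MM_``), a configurable fraction of genes carrying
  introns (mature sequence = concatenated exons of the pre-mRNA);
* cells with Dirichlet expression weights over their species' genes,
  negative-binomial read depths, and well paths drawn uniformly at
  random *with replacement* over the combination space, so barcode
  collisions arise at their natural combinatorial rate;
* reads built through the in-silico barcoding of :mod:`splitpool.scheme`:
  Read-1 is the leading ``cdna_len`` bases of a transcript fragment,
  Read-2 (and Read-3 for two-read designs) the barcode construct, with
  optional uniform substitution errors and 8-nt frameshift truncations
  of a linker.

Quality is not modeled: FASTQ qualities are constant Phred 'I'.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scheme import (
    BASES,
    FRAMESHIFT_DELETION_LEN,
    BarcodeScheme,
    WellPath,
    assemble_construct,
    read_layout,
    truncation_window,
)

__all__ = [
    "SyntheticGene",
    "CellProfile",
    "SyntheticTruth",
    "SyntheticReads",
    "make_transcriptome",
    "draw_cells",
    "simulate_reads",
    "write_fastq",
]

HUMAN_PREFIX = "HS_"
MOUSE_PREFIX = "MM_"


@dataclass(frozen=True)
class SyntheticGene:
    """A synthetic gene: its pre-mRNA and exon blocks on it.

    ``exons`` are sorted, non-overlapping 0-based half-open intervals on
    the pre-mRNA; the mature transcript is their concatenation.
    """

    gene_id: str
    pre_mrna: str
    exons: tuple[tuple[int, int], ...]
    polyadenylated: bool = True

    def __post_init__(self) -> None:
        prev = 0
        for s, e in self.exons:
            if not (prev <= s < e <= len(self.pre_mrna)):
                raise ValueError(f"{self.gene_id}: bad exon block ({s}, {e})")
            prev = e

    @property
    def species(self) -> str:
        return "human" if self.gene_id.startswith(HUMAN_PREFIX) else "mouse"

    @property
    def mature(self) -> str:
        return "".join(self.pre_mrna[s:e] for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        prev = 0
        for s, e in self.exons:
            if s > prev:
                out.append((prev, s))
            prev = e
        if prev < len(self.pre_mrna):
            out.append((prev, len(self.pre_mrna)))
        return tuple(out)

    @property
    def has_intron(self) -> bool:
        return bool(self.introns)

    def span_overlaps_intron(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.introns)


@dataclass(frozen=True)
class CellProfile:
    cell_id: str
    species: str
    gene_ids: tuple[str, ...]
    weights: np.ndarray
    well_path: WellPath
    target_reads: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.cell_id}: weights must be a probability vector")
        object.__setattr__(self, "weights", w)


@dataclass
class SyntheticTruth:
    """Exact per-read and per-cell ground truth."""

    reads: pd.DataFrame  # read_id, cell_id, gene_id, umi, frameshifted, intronic
    cells: pd.DataFrame  # cell_id, species, well_path

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.reads.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)
        self.cells.to_csv(out_dir / "truth_cells.tsv", sep="\t", index=False)


@dataclass
class SyntheticReads:
    """In-memory FASTQ records plus their ground truth."""

    read1: list[tuple[str, str]]  # (read_id, sequence)
    read2: list[tuple[str, str]]
    read3: list[tuple[str, str]] | None
    truth: SyntheticTruth
    scheme: BarcodeScheme

    def write(self, out_dir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "read1": out_dir / f"{prefix}_R1.fastq.gz",
            "read2": out_dir / f"{prefix}_R2.fastq.gz",
        }
        write_fastq(self.read1, paths["read1"])
        write_fastq(self.read2, paths["read2"])
        if self.read3 is not None:
            paths["read3"] = out_dir / f"{prefix}_R3.fastq.gz"
            write_fastq(self.read3, paths["read3"])
        self.truth.write(out_dir)
        return paths


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write 4-line FASTQ records (gzipped iff the path ends in .gz)."""
    import io

    path = Path(path)
    if path.suffix == ".gz":
        # mtime pinned to 0 so identical records give identical bytes
        raw = gzip.GzipFile(path, "wb", mtime=0)
        fh = io.TextIOWrapper(raw)
    else:
        fh = open(path, "wt")
    with fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_transcriptome(
    n_genes_per_species: int = 200,
    length_range: tuple[int, int] = (300, 1500),
    intron_fraction_of_genes: float = 0.5,
    seed: int = 0,
    intron_length_range: tuple[int, int] = (60, 200),
    polya_fraction: float = 0.9,
) -> list[SyntheticGene]:
    """Deterministic synthetic transcriptome, species-balanced.

    ``length_range`` bounds the *mature* transcript length; genes chosen
    to carry introns get 1-2 intron insertions, lengthening the pre-mRNA.
    """
    lo, hi = length_range
    if n_genes_per_species < 1:
        raise ValueError("need at least one gene per species")
    if lo < 100 or hi < lo:
        raise ValueError(f"degenerate length range ({lo}, {hi}); lengths must be >= 100")
    rng = np.random.default_rng(seed)
    genes: list[SyntheticGene] = []
    for prefix in (HUMAN_PREFIX, MOUSE_PREFIX):
        for i in range(n_genes_per_species):
            mature_len = int(rng.integers(lo, hi + 1))
            with_intron = rng.random() < intron_fraction_of_genes
            n_introns = int(rng.integers(1, 3)) if with_intron else 0
            # split the mature sequence into n_introns+1 exon chunks and
            # insert intron sequence between consecutive chunks
            if n_introns:
                cuts = sorted(
                    set(rng.integers(50, max(51, mature_len - 50), size=n_introns).tolist())
                )
            else:
                cuts = []
            chunks = []
            prev = 0
            for c in cuts + [mature_len]:
                chunks.append(int(c - prev))
                prev = c
            parts: list[str] = []
            exons: list[tuple[int, int]] = []
            pos = 0
            for j, chunk in enumerate(chunks):
                exon_seq = _random_dna(rng, chunk)
                parts.append(exon_seq)
                exons.append((pos, pos + chunk))
                pos += chunk
                if j < len(chunks) - 1:
                    ilen = int(rng.integers(*intron_length_range))
                    parts.append(_random_dna(rng, ilen))
                    pos += ilen
            genes.append(
                SyntheticGene(
                    gene_id=f"{prefix}G{i:04d}",
                    pre_mrna="".join(parts),
                    exons=tuple(exons),
                    polyadenylated=bool(rng.random() < polya_fraction),
                )
            )
    return genes


def draw_cells(
    n_cells: int,
    species_mix: float,
    scheme: BarcodeScheme,
    seed: int = 0,
    genes: Sequence[SyntheticGene] | None = None,
    gene_ids_by_species: dict[str, Sequence[str]] | None = None,
    reads_per_cell_mean: float = 2000.0,
    reads_per_cell_dispersion: float = 2.0,
    expression_alpha: float = 0.3,
) -> list[CellProfile]:
    """Draw cell profiles: species, expression weights, well path, depth.

    Well paths are uniform with replacement over the combination space,
    so collision multiplets arise at the natural birthday-problem rate.
    ``species_mix`` is the probability a cell is human.
    """
    if not 0.0 <= species_mix <= 1.0:
        raise ValueError("species_mix must be in [0, 1]")
    if gene_ids_by_species is None:
        if genes is None:
            raise ValueError("provide genes or gene_ids_by_species")
        gene_ids_by_species = {
            "human": [g.gene_id for g in genes if g.species == "human"],
            "mouse": [g.gene_id for g in genes if g.species == "mouse"],
        }
    rng = np.random.default_rng(seed)
    cells: list[CellProfile] = []
    p_nb = reads_per_cell_dispersion / (reads_per_cell_dispersion + reads_per_cell_mean)
    for i in range(n_cells):
        species = "human" if rng.random() < species_mix else "mouse"
        ids = tuple(gene_ids_by_species[species])
        weights = rng.dirichlet(np.full(len(ids), expression_alpha))
        path = WellPath(tuple(int(rng.integers(0, rs.n_wells)) for rs in scheme.rounds))
        depth = int(rng.negative_binomial(reads_per_cell_dispersion, p_nb)) + 1
        cells.append(
            CellProfile(
                cell_id=f"cell{i:05d}",
                species=species,
                gene_ids=ids,
                weights=weights,
                well_path=path,
                target_reads=depth,
            )
        )
    return cells


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if hits.size == 0:
        return seq
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = base_bytes[base_bytes != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_reads(
    cells: Sequence[CellProfile],
    genes: Sequence[SyntheticGene],
    scheme: BarcodeScheme,
    error_rate: float = 0.0,
    frameshift_rate: float = 0.0,
    intronic_read_fraction: float = 0.15,
    seed: int = 0,
) -> SyntheticReads:
    """Simulate paired reads through the in-silico barcoding process.

    Per read: a gene of the cell's species is drawn by its expression
    weights; the fragment comes from the pre-mRNA with probability
    ``intronic_read_fraction`` when the gene has introns, else from the
    mature transcript.  Read-1 is the fragment's first ``cdna_len``
    bases.  The barcode construct fills Read-2 (and Read-3 for two-read
    schemes); with probability ``frameshift_rate`` one 8-nt linker is
    deleted from the construct before the fixed-length read is taken, so
    downstream bases shift into frame exactly as on a real sequencer.
    Substitution errors apply uniformly at ``error_rate``.  The truth
    ``intronic`` flag records whether the sampled span actually overlaps
    intronic bases.
    """
    for rate, name in (
        (error_rate, "error_rate"),
        (frameshift_rate, "frameshift_rate"),
        (intronic_read_fraction, "intronic_read_fraction"),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    layout = read_layout(scheme)
    gene_map = {g.gene_id: g for g in genes}
    min_mature = min(len(g.mature) for g in genes)
    if scheme.cdna_len > min_mature:
        raise ValueError(
            f"cdna_len {scheme.cdna_len} exceeds shortest mature transcript ({min_mature} nt)"
        )
    win_start, _ = truncation_window(scheme)
    del_len = FRAMESHIFT_DELETION_LEN
    rng = np.random.default_rng(seed)

    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    r3: list[tuple[str, str]] = [] if layout.read_split is not None else None  # type: ignore[assignment]
    truth_rows: list[tuple] = []
    read_no = 0
    for cell in cells:
        gene_counts = rng.multinomial(cell.target_reads, cell.weights)
        for gi in np.nonzero(gene_counts)[0]:
            gene = gene_map[cell.gene_ids[gi]]
            for _ in range(int(gene_counts[gi])):
                read_id = f"read{read_no:08d}"
                read_no += 1
                from_pre = gene.has_intron and rng.random() < intronic_read_fraction
                src = gene.pre_mrna if from_pre else gene.mature
                start = int(rng.integers(0, len(src) - scheme.cdna_len + 1))
                fragment = src[start : start + scheme.cdna_len]
                # a read barely overhanging an intron can coincidentally
                # equal a mature substring; such a read carries no intronic
                # information, so the truth flag tracks the sequence content
                intronic = (
                    from_pre
                    and gene.span_overlaps_intron(start, start + scheme.cdna_len)
                    and fragment not in gene.mature
                )
                umi = _random_dna(rng, scheme.umi_len)
                construct = assemble_construct(scheme, cell.well_path, umi, fragment)
                shifted = rng.random() < frameshift_rate
                if shifted:
                    construct = construct[:win_start] + construct[win_start + del_len :]
                bc_read = construct[: layout.span]
                if len(bc_read) < layout.span:  # pad if the insert was short
                    bc_read += "A" * (layout.span - len(bc_read))
                seq1 = _apply_errors(fragment, error_rate, rng)
                bc_read = _apply_errors(bc_read, error_rate, rng)
                r1.append((read_id, seq1))
                if layout.read_split is None:
                    r2.append((read_id, bc_read))
                else:
                    r2.append((read_id, bc_read[: layout.read_split]))
                    r3.append((read_id, bc_read[layout.read_split :]))
                truth_rows.append(
                    (read_id, cell.cell_id, gene.gene_id, umi, shifted, intronic)
                )
    truth = SyntheticTruth(
        reads=pd.DataFrame(
            truth_rows,
            columns=["read_id", "cell_id", "gene_id", "umi", "frameshifted", "intronic"],
        ),
        cells=pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in cells],
                "species": [c.species for c in cells],
                "well_path": [c.well_path.serialize() for c in cells],
            }
        ),
    )
    return SyntheticReads(read1=r1, read2=r2, read3=r3, truth=truth, scheme=scheme)
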