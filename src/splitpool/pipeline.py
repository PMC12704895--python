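"""End-to-end orchestration: simulate -> demux -> quantify -> qc.

A :class:`RunConfig` captures every parameter and a single top-level
seed; per-stage seeds are derived by fixed offsets so each stage is
independently reproducible.  :func:`run_pipeline` writes every stage
output (FASTQs, truth tables, assignment TSV, reject FASTQ, MTX count
matrices, QC tables) plus a manifest JSON listing parameters, per-stage
seeds and a SHA-256 checksum of every output file.  Reruns with the
same config produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import demux as dx
from . import qc as qcm
from . import quantify as qt
from . import synth
from .scheme import BarcodeScheme, default_scheme, load_scheme

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("splitpool")

# fixed per-stage seed offsets derived from the top-level seed
SEED_OFFSETS = {"transcriptome": 1, "cells": 2, "reads": 3, "subsample": 4, "curve": 5}


@dataclass
class RunConfig:
    scheme_path: str | None = None  # None -> built-in default 3-round/96-well design
    n_cells: int = 1000
    species_mix: float = 0.7
    n_genes_per_species: int = 100
    gene_length_range: tuple[int, int] = (300, 900)
    intron_fraction_of_genes: float = 0.5
    reads_per_cell_mean: float = 200.0
    error_rate: float = 0.0
    frameshift_rate: float = 0.0
    intronic_read_fraction: float = 0.15
    max_hamming: int = 0
    frameshift_recovery: bool = True
    kmer: int = 31
    depth: int | None = None
    umi_hamming: int = 0
    qc_preset: str = "barnyard"
    min_genes: int | None = None  # overrides the preset's gene filter
    species_threshold: float = 0.9
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gene_length_range" in doc:
            doc["gene_length_range"] = tuple(doc["gene_length_range"])
        return cls(**doc)

    def resolve_scheme(self) -> BarcodeScheme:
        if self.scheme_path is None:
            return default_scheme()
        p = Path(self.scheme_path)
        if not p.exists():
            raise FileNotFoundError(f"scheme config not found: {p}")
        return load_scheme(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run all stages and write outputs plus a manifest; returns the run dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = config.resolve_scheme()
    seeds = {stage: config.seed * 1000 + off for stage, off in SEED_OFFSETS.items()}
    stages_done: list[str] = []

    def stage(name: str, **params) -> None:
        log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in params.items()))
        stages_done.append(name)

    # 1. simulate
    stage(
        "simulate",
        cells=config.n_cells,
        mix=config.species_mix,
        error_rate=config.error_rate,
        frameshift_rate=config.frameshift_rate,
        seed=seeds["reads"],
    )
    genes = synth.make_transcriptome(
        n_genes_per_species=config.n_genes_per_species,
        length_range=config.gene_length_range,
        intron_fraction_of_genes=config.intron_fraction_of_genes,
        seed=seeds["transcriptome"],
    )
    cells = synth.draw_cells(
        config.n_cells,
        config.species_mix,
        scheme,
        seed=seeds["cells"],
        genes=genes,
        reads_per_cell_mean=config.reads_per_cell_mean,
    )
    sim = synth.simulate_reads(
        cells,
        genes,
        scheme,
        error_rate=config.error_rate,
        frameshift_rate=config.frameshift_rate,
        intronic_read_fraction=config.intronic_read_fraction,
        seed=seeds["reads"],
    )
    sim.write(out)

    # 2. demux
    stage("demux", max_hamming=config.max_hamming, recovery=config.frameshift_recovery)
    barcode_reads = sim.read2
    if sim.read3 is not None:
        r3 = dict(sim.read3)
        barcode_reads = [(rid, seq + r3[rid]) for rid, seq in sim.read2]
    calls, rejects = dx.demux_reads(
        barcode_reads,
        scheme,
        max_hamming=config.max_hamming,
        enable_frameshift_recovery=config.frameshift_recovery,
    )
    calls.to_csv(out / "assignments.tsv", sep="\t", index=False)
    synth.write_fastq(rejects, out / "rejects.fastq")

    # 3. quantify
    stage("quantify", k=config.kmer, depth=config.depth)
    index = qt.build_index(genes, k=config.kmer)
    assignments = qt.assign_reads(sim.read1, index)
    reads = qt.join_reads(calls, assignments)
    table = qt.make_count_table(reads, umi_hamming=config.umi_hamming)
    table.write_mtx(out / "counts")
    if config.depth is not None:
        sub = qt.subsample_reads(
            reads, config.depth, seed=seeds["subsample"], umi_hamming=config.umi_hamming
        )
        sub.write_mtx(out / f"counts_depth{config.depth}")

    # 4. qc
    stage("qc", preset=config.qc_preset, threshold=config.species_threshold)
    min_genes = (
        config.min_genes
        if config.min_genes is not None
        else qcm.FILTER_PRESETS[config.qc_preset]
    )
    filtered = qcm.filter_barcodes(table, min_genes)
    if filtered.barcodes:
        species = qcm.classify_species(
            filtered, threshold=config.species_threshold, unit="umis"
        )
        rate = qcm.multiplet_rate(species)
    else:  # tiny runs may leave nothing above the preset filter
        species = qcm.classify_species(table, threshold=config.species_threshold)
        species = species.iloc[0:0]
        rate = float("nan")
    species.to_csv(out / "species_calls.tsv", sep="\t", index=False)
    qt.intronic_fraction(table).to_csv(out / "intronic_fraction.tsv", sep="\t")
    metrics = {
        "n_barcodes": len(table.barcodes),
        "n_barcodes_filtered": len(filtered.barcodes),
        "min_genes": min_genes,
        "multiplet_rate": rate,
    }

    # 5. manifest
    stage("manifest")
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stages": stages_done,
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "metrics": metrics,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
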