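# Methods

## The barcode model

Split-pool barcoding labels each cell with one well barcode per round:
round 0 during reverse transcription, later rounds by ligation. The
combination space is `B = Π_r n_wells(r)`; two 384-well rounds give
147,456 combinations, two 96-well rounds 9,216, and four 96-well rounds
96⁴ ≈ 8.5 × 10⁷. Because each ligation stacks a new adapter onto the
outside of the molecule, the barcode-side read presents rounds in
reverse barcoding order: constant adapter stem (28 nt by default), UMI
(8 nt), then per round a 4-nt barcode followed by the 8-nt
single-stranded linker that templated the next ligation, with the RT
barcode last. The default geometry gives a 64-nt barcode span
(28 + 8 + (4+8) + (4+8) + 4). All coordinates are 0-based half-open and
live in one `SegmentLayout` that both the read simulator and the
demultiplexer consume, so the two cannot drift apart. Exact per-round
read offsets are configuration, not a law of the design: schemes built
from other adapters simply declare different prefix/linker lengths.
Four-round designs split the barcode span across two reads at a
configurable round boundary; demultiplexing operates on the
concatenation.

## Synthetic data: what it emulates and what it does not

The generator emulates a barnyard (human + mouse) experiment:

* **Transcriptome** — random-sequence genes with species-prefixed ids
  (`HS_`/`MM_`), mature lengths 300–1,500 nt by default, and a
  configurable fraction of genes (default 0.5) carrying 1–2 introns.
  Mature sequence = concatenated exons of the pre-mRNA.
* **Cells** — species Bernoulli(`species_mix`, default 0.7 human,
  matching a 70:30 mixed input), expression weights symmetric
  Dirichlet(0.3) over the species' genes (chosen to give realistic
  gene-detection saturation behaviour), read depth negative binomial
  (mean 2,000, dispersion 2) so depth-subsampling has variance, and a
  well path drawn uniformly **with replacement** over the combination
  space, so collision multiplets arise at the natural birthday-problem
  rate.
* **Reads** — Read-1 is the first `cdna_len` (default 50) bases of a
  fragment drawn from the mature transcript, or from the pre-mRNA with
  probability `intronic_read_fraction` when the gene has introns;
  Read-2 is the leading 64 nt of the assembled construct. Substitution
  errors are uniform per base; qualities are constant Phred 'I'
  (quality is not modeled); strand orientation is ignored.

Not modeled: PCR duplication and chimeras, ambient RNA, physical
doublets, polyA- vs random-primed capture differences, index hopping,
alignment ambiguity of real genomes. Passing tests therefore
demonstrate the correctness of the demultiplexing/quantification logic
and of the collision arithmetic, not robustness to the full error
structure of real libraries.

A subtlety of ground truth: a pre-mRNA fragment that overhangs an
intron by a base or two can coincidentally equal a substring of the
mature transcript. Such a read carries no intronic information, so the
truth `intronic` flag requires both intron overlap and that the emitted
sequence is not a mature substring; with zero error rate the quantifier
then agrees with truth read-for-read.

## Frameshift truncations and their recovery

A rare library artifact deletes 8 nt inside the barcode read,
shifting every downstream barcode out of frame and causing systematic
misassignment. The generator models this as the deletion of one full
8-nt linker (default: the first linker along the read, the mid-read
window) applied to the construct before the fixed-length read is taken,
so downstream bases shift in exactly as on a sequencer. Diagnosis uses
per-base composition: downstream of the 9-nt window the profile of a
contaminated read set is the mixture of the two pure frames.

Recovery re-extracts every segment downstream of the window at an
8-nt upstream offset. Both candidate deletion starts within the 9-nt
window (linker start and linker start + 1) are hypothesised; a segment
overlapping the assumed deleted interval is unrecoverable under that
hypothesis, so only the full-linker hypothesis can match every round.
Frames are gated exclusively — in-frame matching is attempted first and
a read is never reported in both frames. Whitelist generation for the
default scheme excludes barcodes equal to substrings of the constant
regions (prefix, linker, polyT spacer) so a frame-shifted constant
region can never masquerade as a valid well; without this exclusion a
shifted read could, with appreciable probability, match in frame by
accident.

Whitelist matching defaults to exact (`max_hamming = 0`). With
`max_hamming = 1`, the unique nearest entry wins and ties at the
minimal distance are rejected; single substitutions are provably always
corrected when the whitelist's minimum pairwise distance is ≥ 3. Note
a feasibility bound: q-ary codes obey the Singleton bound
`|C| ≤ 4^(L−d+1)`, so 96 four-nt barcodes cannot have minimum distance
2; the default 96-well 4-nt whitelists enforce distinctness only.

## Quantification

Alignment is replaced by an exact first-k-mer lookup (default k = 31)
over both pre-mRNA and mature sequences, with a unique-gene
requirement; k-mers shared across genes are ambiguous and their reads
discarded. Category: a read matching the mature transcript is exonic;
one matching only the pre-mRNA is intronic iff its span overlaps an
intron (intron-if-any-intronic-base); with substitution errors the
candidate location of minimal Hamming distance decides. This is a
deliberate simplification — the test data is synthetic and exact, and
alignment science is out of scope.

UMI collapse counts connected components of the graph joining UMIs at
Hamming ≤ h within each (barcode, gene); h = 0 (the default) is the
number of distinct UMI strings. UMIs are taken verbatim; N-containing
UMIs are kept as distinct. Count tables carry read and UMI values in
three layers: `exon`, `intron`, and `inex` — the union layer, where a
molecule seen in both categories counts once (UMI lists of both layers
are collapsed together), so `max(exon, intron) ≤ inex ≤ exon + intron`
entry-wise.

Depth subsampling draws, per barcode with at least `depth` reads,
exactly `depth` reads without replacement via a seeded per-barcode
permutation whose prefix is taken; barcodes below depth are excluded.
Because the permutation depends only on (seed, barcode), draws at
increasing depths under one seed are nested and gene detection is
monotone in depth by construction.

## QC metrics

* **Gene filter**: keep barcodes with strictly more than `min_genes`
  detected genes. Presets: barnyard 400, joint models 500, nuclei 200,
  maize root 120, maize shoot 400.
* **Species call**: a barcode is human (mouse) only when that species
  contributes strictly more than the threshold (default 90%) of its
  counts, else multiplet. The unit is a flag — reads or UMIs — with
  UMIs the default. Barcodes failing both thresholds are multiplets
  only after passing the gene filter; the multiplet rate is multiplets
  over filter-passing barcodes.
* **Sensitivity at depth**: per-barcode genes (≥ 1 UMI) and total UMIs
  of a depth-matched table, with medians.
* **Saturation curves**: mean over replicates of the union of detected
  genes across k sampled barcodes, k = 1..k_max (defaults 50 reps,
  matching the usual 1–50 cells × 50 repeats protocol). Default
  sampling is nested — each replicate draws one permutation and uses
  its prefixes — so the curve is non-decreasing within every replicate;
  independent redraws per k are available via `nested=False`.

## Collision model

Under uniform assignment of n cells over B combinations, the
probability a given cell shares its combination is
`1 − (1 − 1/B)^(n−1)`, and the expected number of same-combination
pairs among s sequenced cells is `C(s,2)/B`. For B = 147,456 and
n = 8,000 the closed form gives 5.28%, the familiar ~5% regime of
two-round 384-well designs. Monte-Carlo simulation (default 200
replicates, seeded) reports the multiplet rate under both denominators
used in the field — per sequenced barcode (combinations with ≥ 2
sampled cells over combinations observed) and per sequenced cell — with
standard errors; the per-barcode figure for four 96-well rounds with
400,000 cells and 16,450 sequenced is ≈ 0.01%, far below observed
multiplet rates of such designs, which also contain physical doublets
and ambient RNA. Well-occupancy skew is not modeled: pooling between
rounds makes uniformity the natural null.

## Numerical and design choices

* Single top-level pipeline seed; per-stage seeds derived by fixed
  offsets (`seed × 1000 + stage offset`) so stages are independently
  reproducible. All randomness flows through `numpy.random.default_rng`.
* Gzipped FASTQ is written with mtime pinned to 0 so identical records
  give identical bytes; the pipeline manifest checksums every output.
* Degenerate inputs are errors, not silent defaults: empty read sets
  for composition profiles, mixed-length UMI lists, k below 12,
  subsample depth below 1, k_max beyond the number of barcodes.
* Unassigned reads are always written to a reject stream.
* Test and example problem sizes (tens of cells, ~10⁴ reads, 200
  Monte-Carlo replicates) are the package's desk-scale defaults; the
  scientific defaults of the generator (2,000 reads/cell, 70/30 mix)
  remain available unchanged.

## Known limitations

The pseudo-mapper cannot express splice-aware or mismatch-tolerant
seeding, so real FASTQ data is out of scope end-to-end (the
demultiplexer itself is format-faithful and could front a real
aligner). The collision model bounds only combinatorial multiplets.
The intron/exon precedence rule (intron-if-any-intronic-base) is one of
several defensible conventions and is stated here because published
pipelines differ in how reads overlapping both categories are counted.
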